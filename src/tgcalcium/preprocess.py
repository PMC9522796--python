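"""Bleach correction, rigid motion correction, and frame quality control.

These run before any trace analysis. Bleach correction divides out a
global monoexponential fit to the frame means (with a simple-ratio
fallback); motion correction estimates a rigid translation per frame by
phase correlation; quality control flags (never deletes) frames with
excessive shift or frame-mean jumps, so frame indices stay aligned with
the acquisition clock.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .movie import MovieStack

logger = logging.getLogger(__name__)

__all__ = ["bleach_correct", "motion_correct", "drop_bad_frames", "MovieQualityError"]


class MovieQualityError(RuntimeError):
    """Raised when quality control deems the movie unusable."""


def _exp_offset(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def bleach_correct(movie: MovieStack, method: str = "exponential_fit") -> MovieStack:
    """Remove global photobleaching.

    ``exponential_fit`` (default) fits ``a*exp(-t/tau) + c`` to the frame
    means and multiplies each frame by ``fit(0)/fit(t)``; if the fit
    diverges it falls back to ``simple_ratio`` with a logged warning.
    ``simple_ratio`` scales each frame so its mean matches the first
    frame's mean (robust but flattens genuine global signal).

    Output intensities remain nonnegative; a movie with no trend is
    returned essentially unchanged.
    """
    if movie.n_frames < 10:
        raise ValueError("bleach correction requires at least 10 frames")
    if method not in ("exponential_fit", "simple_ratio"):
        raise ValueError(f"unknown bleach-correction method: {method}")
    means = movie.data.reshape(movie.n_frames, -1).mean(axis=1).astype(float)
    t = movie.times_s

    factors = None
    if method == "exponential_fit":
        try:
            span = means[0] - means[-1]
            p0 = (max(span, 1e-3), max(t[-1] / 2.0, 1.0), max(means[-1], 1e-3))
            popt, _ = optimize.curve_fit(
                _exp_offset, t, means, p0=p0,
                bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
            fit = _exp_offset(t, *popt)
            if np.any(fit <= 0) or not np.all(np.isfinite(fit)):
                raise RuntimeError("degenerate exponential fit")
            factors = fit[0] / fit
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            logger.warning("exponential bleach fit failed (%s); "
                           "falling back to simple_ratio", exc)
            factors = None
    if factors is None:  # simple_ratio (requested or fallback)
        safe = np.where(means > 0, means, 1.0)
        factors = means[0] / safe
    corrected = movie.data * factors[:, None, None].astype(movie.data.dtype)
    np.maximum(corrected, 0, out=corrected)
    return movie.copy_with(data=corrected)


def motion_correct(movie: MovieStack, reference: str = "mean"
                   ) -> tuple[MovieStack, pd.DataFrame]:
    """Rigid translation correction by phase correlation.

    Each frame's (dy, dx) translation relative to the reference image
    (temporal ``mean`` or ``first_frame``) is estimated by subpixel phase
    correlation and undone with linear interpolation; the table reports
    the estimated translation of the frame (so a frame moved by (2, -1)
    px reports (2, -1)). Frames whose estimated shift exceeds 25% of the
    frame size are flagged (``kept = False``) and left unshifted.

    Returns the corrected movie and a shift table with columns
    ``frame, dy_px, dx_px, kept``.
    """
    if reference not in ("mean", "first_frame"):
        raise ValueError(f"unknown reference: {reference}")
    ref = movie.data.mean(axis=0) if reference == "mean" else movie.data[0]
    n_rows, n_cols = ref.shape
    max_ok = 0.25 * min(n_rows, n_cols)

    out = movie.data.copy()
    kept = movie.frame_kept_flags.copy()
    shifts = np.zeros((movie.n_frames, 2))
    for i in range(movie.n_frames):
        reg_shift, _, _ = phase_cross_correlation(ref, movie.data[i],
                                                  upsample_factor=10)
        shifts[i] = -reg_shift  # estimated translation of the frame
        if np.hypot(*reg_shift) > max_ok:
            kept[i] = False
            logger.warning("frame %d: shift %s exceeds 25%% of frame; flagged",
                           i, shifts[i])
            continue
        if np.any(reg_shift != 0):
            out[i] = ndimage.shift(movie.data[i], reg_shift, order=1, mode="nearest")
    table = pd.DataFrame({
        "frame": np.arange(movie.n_frames),
        "dy_px": shifts[:, 0],
        "dx_px": shifts[:, 1],
        "kept": kept,
    })
    return movie.copy_with(data=out, frame_kept_flags=kept), table


def drop_bad_frames(movie: MovieStack, max_shift_px: float = 5.0,
                    max_mean_jump_frac: float = 0.5,
                    shift_table: pd.DataFrame | None = None) -> MovieStack:
    """Flag frames with large fluctuations.

    A frame is flagged when its mean intensity jumps by more than
    ``max_mean_jump_frac`` relative to the previous frame, or (when a
    shift table from :func:`motion_correct` is given) when its estimated
    shift magnitude exceeds ``max_shift_px``. Flagged frames keep their
    data; downstream trace extraction interpolates across them.

    Raises
    ------
    MovieQualityError
        If more than 20% of frames end up flagged.
    """
    if max_shift_px <= 0 or max_mean_jump_frac <= 0:
        raise ValueError("thresholds must be positive")
    kept = movie.frame_kept_flags.copy()
    means = movie.data.reshape(movie.n_frames, -1).mean(axis=1).astype(float)
    prev = np.where(means[:-1] > 0, means[:-1], 1.0)
    jumps = np.abs(np.diff(means)) / prev
    kept[1:][jumps > max_mean_jump_frac] = False
    if shift_table is not None:
        mag = np.hypot(shift_table["dy_px"].to_numpy(),
                       shift_table["dx_px"].to_numpy())
        kept[mag > max_shift_px] = False
    n_dropped = int((~kept).sum())
    if n_dropped > 0.2 * movie.n_frames:
        raise MovieQualityError(
            f"{n_dropped}/{movie.n_frames} frames flagged; movie unusable")
    if n_dropped:
        logger.info("flagged %d frames as unusable", n_dropped)
    return movie.copy_with(frame_kept_flags=kept)
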