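"""Figure rendering: temporal color-coding maps, rasters, matrices.

The temporal color-coding map paints each pixel with a hue encoding the
time of its maximal background-subtracted response within a block, with
brightness scaled by the response magnitude — a one-image summary of
when and where neurons fired.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .movie import MovieStack

__all__ = ["render_temporal_map", "save_raster_png", "save_matrix_png"]


def render_temporal_map(movie: MovieStack, block: tuple[int, int] | None = None,
                        sigma_px: float = 1.5, brightness_percentile: float = 99.5
                        ) -> np.ndarray:
    """Temporal color-coding map of one imaging block.

    F0 is the mean image of the block; each frame's F - F0 is Gaussian
    smoothed, then every pixel is colored by the frame index of its
    maximum (hue from the start to the end of the block) with brightness
    proportional to that maximum (negative responses render dark).

    Returns an RGB float image in [0, 1].
    """
    start, stop = block if block is not None else (0, movie.n_frames)
    if stop - start < 2:
        raise ValueError("block must span at least 2 frames")
    sub = movie.data[start:stop].astype(float)
    f0 = sub.mean(axis=0)
    resp = sub - f0
    if sigma_px > 0:
        resp = ndimage.gaussian_filter(resp, sigma=(0, sigma_px, sigma_px))
    t_max = resp.argmax(axis=0)
    mag = resp.max(axis=0)
    mag = np.clip(mag, 0, None)
    scale = np.percentile(mag, brightness_percentile)
    value = np.clip(mag / scale, 0, 1) if scale > 0 else np.zeros_like(mag)
    hue = 0.75 * t_max / max(stop - start - 1, 1)  # blue (early) -> red (late)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)


def save_temporal_map(movie: MovieStack, path: str | Path,
                      block: tuple[int, int] | None = None, **kwargs) -> None:
    rgb = render_temporal_map(movie, block=block, **kwargs)
    plt.imsave(Path(path), rgb)


def save_raster_png(matrix: np.ndarray, path: str | Path,
                    frame_rate_hz: float = 1.0) -> None:
    """Render a binary ROI x frame raster."""
    fig, ax = plt.subplots(figsize=(8, max(2, matrix.shape[0] * 0.12)))
    ax.imshow(matrix, aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xlabel("time (frames)")
    ax.set_ylabel("ROI")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def save_matrix_png(matrix: np.ndarray, path: str | Path,
                    vmin: float = -1.0, vmax: float = 1.0) -> None:
    """Render a correlation matrix heatmap."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix, cmap="RdBu_r", vmin=vmin, vmax=vmax)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xlabel("ROI")
    ax.set_ylabel("ROI")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
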