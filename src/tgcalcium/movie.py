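"""Movie container and TIFF I/O.

A :class:`MovieStack` is the in-memory representation of one imaging
session: a single-channel time-lapse (frames x rows x cols) together with
the acquisition frame rate and pixel size. Frames flagged as unusable by
quality control stay in the stack (so frame indices remain aligned with
the 1 Hz timestamps) and are only excluded/interpolated downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["MovieStack", "read_movie", "write_movie"]


@dataclass
class MovieStack:
    """Single-channel fluorescence movie with acquisition metadata.

    Parameters
    ----------
    data
        Nonnegative intensities, shape ``(n_frames, n_rows, n_cols)``.
    frame_rate_hz
        Acquisition rate in frames per second.
    pixel_size_um
        Side length of one pixel in micrometres.
    frame_kept_flags
        Boolean per frame; ``False`` marks frames removed by quality
        control. Defaults to all ``True``.
    """

    data: np.ndarray
    frame_rate_hz: float = 1.0
    pixel_size_um: float = 1.0
    frame_kept_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie must be 3-D (frames, rows, cols); got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.frame_kept_flags is None:
            self.frame_kept_flags = np.ones(self.n_frames, dtype=bool)
        else:
            self.frame_kept_flags = np.asarray(self.frame_kept_flags, dtype=bool)
            if self.frame_kept_flags.shape != (self.n_frames,):
                raise ValueError("frame_kept_flags must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times_s(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def copy_with(self, data: np.ndarray | None = None,
                  frame_kept_flags: np.ndarray | None = None) -> "MovieStack":
        return MovieStack(
            data=self.data.copy() if data is None else data,
            frame_rate_hz=self.frame_rate_hz,
            pixel_size_um=self.pixel_size_um,
            frame_kept_flags=(self.frame_kept_flags.copy()
                              if frame_kept_flags is None else np.asarray(frame_kept_flags, bool)),
        )


def write_movie(movie: MovieStack, path: str | Path) -> None:
    """Write a movie as an ImageJ-compatible multi-page TIFF.

    Frame interval and pixel size are stored in ImageJ metadata /
    resolution tags so a round-trip through :func:`read_movie` recovers
    them.
    """
    path = Path(path)
    data = movie.data
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    res = 1.0 / movie.pixel_size_um  # pixels per micrometre
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(res, res),
        metadata={
            "axes": "TYX",
            "finterval": 1.0 / movie.frame_rate_hz,
            "unit": "um",
        },
    )


def read_movie(path: str | Path, frame_rate_hz: float | None = None,
               pixel_size_um: float | None = None) -> MovieStack:
    """Read a single-channel multi-page TIFF as a :class:`MovieStack`.

    Metadata (frame interval, pixel size) is parsed from ImageJ tags when
    present; otherwise the keyword overrides are used with a logged
    warning. A multi-channel file is rejected.

    Raises
    ------
    ValueError
        If the file is not a single-channel 3-D stack, or if metadata is
        absent and no override is supplied.
    OSError
        If the file is corrupt/truncated; the error names the frame at
        which reading failed.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes
        if "C" in axes or "S" in axes:
            raise ValueError(f"{path}: multi-channel TIFF not supported (axes={axes})")
        n_pages = len(series)
        try:
            data = series.asarray()
        except Exception as exc:  # pragma: no cover - depends on corruption mode
            # fall back page by page so the failing frame can be named
            pages = []
            for i in range(n_pages):
                try:
                    pages.append(series.pages[i].asarray())
                except Exception:
                    raise OSError(f"{path}: failed reading frame {i}: {exc}") from exc
            raise OSError(f"{path}: failed assembling stack: {exc}") from exc
        meta_rate = None
        meta_px = None
        if tf.imagej_metadata is not None:
            finterval = tf.imagej_metadata.get("finterval")
            if finterval:
                meta_rate = 1.0 / float(finterval)
        page0 = tf.pages[0]
        if "XResolution" in page0.tags:
            num, den = page0.tags["XResolution"].value
            if num:
                meta_px = float(den) / float(num)

    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D single-channel stack, got shape {data.shape}")

    if meta_rate is None:
        if frame_rate_hz is None:
            raise ValueError(f"{path}: no frame-interval metadata; pass frame_rate_hz")
        meta_rate = frame_rate_hz
        warnings.warn(f"{path}: frame rate not in metadata; using override {frame_rate_hz} Hz")
    elif frame_rate_hz is not None:
        meta_rate = frame_rate_hz
    if meta_px is None:
        if pixel_size_um is None:
            raise ValueError(f"{path}: no pixel-size metadata; pass pixel_size_um")
        meta_px = pixel_size_um
        warnings.warn(f"{path}: pixel size not in metadata; using override {pixel_size_um} um/px")
    elif pixel_size_um is not None:
        meta_px = pixel_size_um

    return MovieStack(data=np.asarray(data, dtype=np.float32),
                      frame_rate_hz=meta_rate, pixel_size_um=meta_px)
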