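"""dF/F0 computation, firing thresholds, transient detection, rasters.

A calcium transient is a local maximum of the Savitzky-Golay-smoothed
dF/F0 trace that (a) exceeds the firing threshold, (b) rose by at least
``required_rise_pct`` percent of its height above the trendline within
``max_lookback`` frames before the peak, and (c) falls by at least
``required_fall_pct`` percent within ``max_lookahead`` frames after it
(a transient truncated by the end of the recording keeps its amplitude
but has no decay time, so decay/duration counts can be smaller than
amplitude counts). The trendline is a two-sided exponential moving
average and is used only for the percentage criteria. Detection and the
rise/fall crossing times run on the smoothed trace, but the amplitude is
read from the raw dF/F0 at the peak (refined to the raw argmax within
half a smoothing window), since at 1 Hz the smoothing visibly attenuates
a one-frame transient peak.

The baseline F0 is a sliding 60-frame window mean (trailing by default,
so no future frames are used; edges use truncated windows), and
dF/F0 = (F - F0) / F0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "DffTrace",
    "CalciumEvent",
    "Raster",
    "compute_dff",
    "firing_threshold",
    "detect_peaks",
    "build_raster",
    "count_active",
    "high_k_response",
]


@dataclass
class DffTrace:
    """Per-ROI raw trace, sliding-window baseline, dF/F0, firing threshold."""

    roi_id: int
    raw: np.ndarray
    f0: np.ndarray
    dff: np.ndarray
    threshold: float
    threshold_rule: str

    def __len__(self) -> int:
        return len(self.dff)


@dataclass
class CalciumEvent:
    """One detected transient and its kinetic parameters (seconds)."""

    roi_id: int
    peak_frame: int
    amplitude: float
    rise_time_s: float
    decay_time_s: float | None
    duration_s: float | None
    onset_frame: int
    end_frame: int


@dataclass
class Raster:
    """Binary ROI x frame firing matrix."""

    matrix: np.ndarray
    roi_ids: list[int]
    rule: str


def _sliding_mean(x: np.ndarray, window: int, alignment: str) -> np.ndarray:
    """Windowed mean with truncated edge windows."""
    n = len(x)
    csum = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    idx = np.arange(n)
    if alignment == "trailing":
        lo = np.maximum(idx - window + 1, 0)
        hi = idx + 1
    elif alignment == "centered":
        half = window // 2
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + (window - half), n)
    else:
        raise ValueError(f"unknown alignment: {alignment}")
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_dff(raw: np.ndarray, window_frames: int = 60,
                alignment: str = "trailing", roi_id: int = -1,
                threshold_rule: str = "mean_plus_sd") -> DffTrace:
    """Sliding-window baseline and dF/F0 for one raw trace.

    ``f0[t]`` is the mean raw intensity over a ``window_frames`` window
    (trailing or centered; truncated at the edges) and
    ``dff[t] = (raw[t] - f0[t]) / f0[t]``.

    Raises ``ValueError`` for nonpositive raw values (baseline undefined)
    or a trace shorter than the window.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("raw trace must be 1-D")
    if len(raw) < window_frames:
        raise ValueError(f"trace length {len(raw)} < window {window_frames}")
    if np.any(raw <= 0):
        raise ValueError("raw trace must be strictly positive for dF/F0")
    f0 = _sliding_mean(raw, window_frames, alignment)
    dff = (raw - f0) / f0
    thr = firing_threshold(dff, threshold_rule)
    return DffTrace(roi_id=roi_id, raw=raw, f0=f0, dff=dff,
                    threshold=thr, threshold_rule=threshold_rule)


def firing_threshold(dff: np.ndarray, rule: str = "mean_plus_sd") -> float:
    """Firing threshold of a dF/F0 trace.

    ``mean_plus_sd``: mean + sample standard deviation (the spontaneous-
    activity rule). ``ten_sem``: 10 x standard error of the mean (the
    high-potassium viability rule). Statistics are over the whole trace.
    """
    dff = np.asarray(dff, dtype=float)
    if len(dff) < 2:
        raise ValueError("need at least 2 frames")
    sd = float(dff.std(ddof=1))
    if rule == "mean_plus_sd":
        return float(dff.mean()) + sd
    if rule == "ten_sem":
        return 10.0 * sd / np.sqrt(len(dff))
    raise ValueError(f"unknown threshold rule: {rule}")


def two_sided_ema(x: np.ndarray, alpha: float) -> np.ndarray:
    """Average of a forward and a backward exponential moving average."""
    x = np.asarray(x, dtype=float)
    fwd = np.empty_like(x)
    bwd = np.empty_like(x)
    fwd[0] = x[0]
    for t in range(1, len(x)):
        fwd[t] = alpha * x[t] + (1 - alpha) * fwd[t - 1]
    bwd[-1] = x[-1]
    for t in range(len(x) - 2, -1, -1):
        bwd[t] = alpha * x[t] + (1 - alpha) * bwd[t + 1]
    return 0.5 * (fwd + bwd)


def detect_peaks(dff: DffTrace, required_rise_pct: float = 20.0,
                 required_fall_pct: float = 15.0, max_lookback: int = 30,
                 max_lookahead: int = 25, sg_window: int = 7, sg_order: int = 3,
                 ema_alpha: float = 0.05, frame_rate_hz: float = 1.0
                 ) -> list[CalciumEvent]:
    """Detect and parametrize calcium transients in one dF/F0 trace.

    See the module docstring for the peak criteria. The returned events
    are ordered by peak frame; every event's smoothed peak value exceeds
    ``dff.threshold``. The detection is invariant to multiplying the
    dF/F0 trace by a positive constant.
    """
    x = dff.dff
    n = len(x)
    if sg_window >= n or max_lookback >= n or max_lookahead >= n:
        raise ValueError("window parameters exceed trace length")
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    smoothed = savgol_filter(x, sg_window, sg_order)
    trend = two_sided_ema(smoothed, ema_alpha)
    threshold = dff.threshold

    events: list[CalciumEvent] = []
    for p in range(1, n - 1):
        v = smoothed[p]
        if not (v > smoothed[p - 1] and v > smoothed[p + 1]):
            continue
        height = v - trend[p]
        if v <= threshold or height <= 0:
            continue
        rise_level = v - (required_rise_pct / 100.0) * height
        lo = max(0, p - max_lookback)
        below = np.nonzero(smoothed[lo:p] <= rise_level)[0]
        if below.size == 0:
            continue  # did not rise enough within the lookback window
        onset = lo + int(below[-1])
        fall_level = v - (required_fall_pct / 100.0) * height
        hi = min(n - 1, p + max_lookahead)
        end = None
        for q in range(p + 1, hi + 1):
            if smoothed[q] <= fall_level:
                end = q
                break
        truncated = p + max_lookahead > n - 1
        if end is None and not truncated:
            continue  # did not fall enough within the lookahead window
        rise_time = (p - onset) / frame_rate_hz
        decay_time = (end - p) / frame_rate_hz if end is not None else None
        duration = rise_time + decay_time if decay_time is not None else None
        # Amplitude from the raw dF/F0 at the peak: refine the peak frame
        # to the raw argmax within half a smoothing window, then measure
        # height above the trendline there.
        half = sg_window // 2
        w_lo = max(0, p - half)
        w_hi = min(n, p + half + 1)
        p_raw = w_lo + int(np.argmax(x[w_lo:w_hi]))
        if events and events[-1].peak_frame == p_raw:
            continue  # two smoothed maxima refined to the same raw peak
        amplitude = float(x[p_raw] - trend[p])
        events.append(CalciumEvent(
            roi_id=dff.roi_id, peak_frame=p_raw, amplitude=amplitude,
            rise_time_s=float(rise_time), decay_time_s=decay_time,
            duration_s=duration, onset_frame=onset,
            end_frame=end if end is not None else n - 1,
        ))
    return events


def build_raster(events_by_roi: dict[int, list[CalciumEvent]], n_frames: int,
                 rule: str = "mean_plus_sd") -> Raster:
    """Binary firing raster: 1 from each event's onset through its decay end."""
    roi_ids = sorted(events_by_roi)
    mat = np.zeros((len(roi_ids), n_frames), dtype=np.uint8)
    for row, rid in enumerate(roi_ids):
        for ev in events_by_roi[rid]:
            mat[row, ev.onset_frame:ev.end_frame + 1] = 1
    return Raster(matrix=mat, roi_ids=roi_ids, rule=rule)


def count_active(events_by_roi: dict[int, list[CalciumEvent]],
                 block_ranges: list[tuple[int, int]],
                 ) -> tuple[list[int], float]:
    """Number of active neurons per imaging block and the across-block mean.

    A neuron is active in a block iff it has at least one event whose
    peak frame falls in ``[start, stop)``. Block ranges are in frames
    (5 min at 1 Hz = 300 frames).
    """
    counts = []
    for start, stop in block_ranges:
        c = sum(
            1 for evs in events_by_roi.values()
            if any(start <= ev.peak_frame < stop for ev in evs)
        )
        counts.append(c)
    return counts, float(np.mean(counts)) if counts else 0.0


def high_k_response(dff_traces: list[DffTrace], epoch: tuple[int, int],
                    rule: str = "ten_sem") -> tuple[np.ndarray, np.ndarray]:
    """Binary response heatmap for the depolarizing high-K epoch.

    Each entry is 1 where dF/F0 >= the per-ROI threshold under ``rule``
    (default 10 x SEM). A neuron responds iff any frame within
    ``epoch = [start, stop)`` is 1. Returns (heatmap, responder flags).
    """
    start, stop = epoch
    n_frames = len(dff_traces[0].dff)
    heat = np.zeros((len(dff_traces), n_frames), dtype=np.uint8)
    for i, tr in enumerate(dff_traces):
        thr = firing_threshold(tr.dff, rule)
        heat[i] = (tr.dff >= thr).astype(np.uint8)
    responders = heat[:, start:stop].any(axis=1)
    return heat, responders
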