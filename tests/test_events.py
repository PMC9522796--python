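"""dF/F0, thresholds, transient detection (with a brute-force oracle),
rasters, per-block activity, high-K response."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import savgol_filter

from tgcalcium import (build_raster, compute_dff, count_active, detect_peaks,
                       firing_threshold, high_k_response, transient_kernel)
from tgcalcium.events import DffTrace, two_sided_ema


# --------------------------------------------------------------------------
# dF/F0
# --------------------------------------------------------------------------

def brute_force_dff(raw, window, alignment="trailing"):
    raw = np.asarray(raw, float)
    n = len(raw)
    f0 = np.empty(n)
    for t in range(n):
        if alignment == "trailing":
            lo, hi = max(0, t - window + 1), t + 1
        else:
            half = window // 2
            lo, hi = max(0, t - half), min(t + (window - half), n)
        f0[t] = raw[lo:hi].mean()
    return f0, (raw - f0) / f0


def test_dff_matches_brute_force_loop():
    rng = np.random.default_rng(0)
    for alignment in ("trailing", "centered"):
        raw = 100.0 + rng.normal(0, 5, 200)
        tr = compute_dff(raw, window_frames=60, alignment=alignment)
        f0, dff = brute_force_dff(raw, 60, alignment)
        assert np.allclose(tr.f0, f0, atol=1e-10)
        assert np.allclose(tr.dff, dff, atol=1e-12)


def test_dff_constant_trace_is_zero():
    tr = compute_dff(np.full(100, 42.0))
    assert np.allclose(tr.dff, 0.0)
    assert np.allclose(tr.f0, 42.0)


def test_dff_algebraic_example():
    # constant 100 with one frame at 110: at that frame (trailing window
    # fully inside) f0 = (59*100 + 110)/60 and dff follows exactly
    raw = np.full(120, 100.0)
    raw[80] = 110.0
    tr = compute_dff(raw, window_frames=60)
    f0 = (59 * 100 + 110) / 60
    assert tr.f0[80] == pytest.approx(f0)
    assert tr.dff[80] == pytest.approx((110 - f0) / f0)
    assert tr.dff[10] == 0.0  # before the transient


def test_dff_input_validation():
    with pytest.raises(ValueError):
        compute_dff(np.full(30, 5.0), window_frames=60)  # too short
    with pytest.raises(ValueError):
        compute_dff(np.concatenate([np.full(70, 5.0), [-1.0]]))
    with pytest.raises(ValueError):
        compute_dff(np.full(100, 5.0), alignment="sideways")


def test_firing_threshold_arithmetic():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    assert firing_threshold(x, "mean_plus_sd") == pytest.approx(
        x.mean() + x.std(ddof=1))
    assert firing_threshold(x, "ten_sem") == pytest.approx(
        10 * x.std(ddof=1) / np.sqrt(4))
    with pytest.raises(ValueError):
        firing_threshold(x, "three_sigma")


# --------------------------------------------------------------------------
# detect_peaks vs a brute-force enumerator
# --------------------------------------------------------------------------

def oracle_detect(dff_obj, rise_pct=20.0, fall_pct=15.0, lookback=30,
                  lookahead=25, sg_window=7, sg_order=3, alpha=0.05,
                  frame_rate_hz=1.0):
    """Plain-loop re-statement of the transient criteria."""
    x = dff_obj.dff
    n = len(x)
    s = savgol_filter(x, sg_window, sg_order)
    trend = two_sided_ema(s, alpha)
    out = []
    for p in range(1, n - 1):
        if not (s[p] > s[p - 1] and s[p] > s[p + 1]):
            continue
        h = s[p] - trend[p]
        if s[p] <= dff_obj.threshold or h <= 0:
            continue
        rise_level = s[p] - rise_pct / 100 * h
        onset = None
        for q in range(p - 1, max(-1, p - lookback - 1), -1):
            if s[q] <= rise_level:
                onset = q
                break
        if onset is None:
            continue
        fall_level = s[p] - fall_pct / 100 * h
        end = None
        for q in range(p + 1, min(n, p + lookahead + 1)):
            if s[q] <= fall_level:
                end = q
                break
        truncated = p + lookahead > n - 1
        if end is None and not truncated:
            continue
        half = sg_window // 2
        w = range(max(0, p - half), min(n, p + half + 1))
        p_raw = max(w, key=lambda q: x[q])
        if out and out[-1][0] == p_raw:
            continue
        amp = x[p_raw] - trend[p]
        rise = (p - onset) / frame_rate_hz
        decay = None if end is None else (end - p) / frame_rate_hz
        out.append((p_raw, amp, rise, decay, onset,
                    end if end is not None else n - 1))
    return out


def test_detect_peaks_matches_oracle_on_random_traces():
    rng = np.random.default_rng(42)
    n_compared = 0
    for _ in range(100):
        n = int(rng.integers(80, 201))
        raw = 100.0 + rng.normal(0, 3, n)
        for _ in range(rng.integers(0, 5)):
            f = int(rng.integers(0, n))
            amp = rng.uniform(10, 60)
            t = np.arange(n, dtype=float) - f
            raw += amp * transient_kernel(t, 0.2, rng.uniform(1.0, 3.0))
        tr = compute_dff(raw, window_frames=60)
        got = detect_peaks(tr)
        want = oracle_detect(tr)
        assert len(got) == len(want)
        for ev, (p, amp, rise, decay, onset, end) in zip(got, want):
            assert ev.peak_frame == p
            assert ev.amplitude == pytest.approx(amp, abs=1e-12)
            assert ev.rise_time_s == rise
            assert ev.decay_time_s == decay
            assert ev.onset_frame == onset
            assert ev.end_frame == end
        n_compared += len(got)
    assert n_compared > 50  # the comparison actually exercised events


def test_detect_peaks_planted_kernel():
    # one planted 0.5-dF/F transient; expectations derived by sampling
    # the kernel at 1 Hz frame times (the sampled maximum is 0.843 of
    # the continuous unit peak because frames miss t* = 0.48 s)
    n, onset = 300, 150
    raw = np.full(n, 100.0)
    t = np.arange(n, dtype=float) - onset
    raw += 100.0 * 0.5 * transient_kernel(t, 0.2, 2.0)
    sampled = 0.5 * transient_kernel(t, 0.2, 2.0)
    expected_amp = sampled.max()
    tr = compute_dff(raw)
    events = detect_peaks(tr)
    assert len(events) == 1
    ev = events[0]
    assert ev.peak_frame == onset + sampled.argmax() - onset
    assert ev.amplitude == pytest.approx(expected_amp, rel=0.10)
    # kernel crossing times on the sampled kernel: one frame each side
    assert abs(ev.rise_time_s - 1.0) <= 1.0
    assert abs(ev.decay_time_s - 1.0) <= 1.0


def test_detect_peaks_two_events_and_flat_trace():
    n = 300
    raw = np.full(n, 100.0)
    t = np.arange(n, dtype=float)
    for f in (100, 200):
        raw += 100.0 * 0.5 * transient_kernel(t - f, 0.2, 2.0)
    events = detect_peaks(compute_dff(raw))
    assert len(events) == 2
    assert [abs(e.peak_frame - f) <= 2 for e, f in zip(events, (101, 201))]
    assert detect_peaks(compute_dff(np.full(300, 100.0))) == []


def test_detect_peaks_scale_invariance():
    rng = np.random.default_rng(7)
    raw = 100.0 + rng.normal(0, 2, 200)
    t = np.arange(200, dtype=float)
    raw += 40 * transient_kernel(t - 90, 0.2, 2.0)
    tr = compute_dff(raw)
    scaled = DffTrace(roi_id=tr.roi_id, raw=tr.raw, f0=tr.f0,
                      dff=tr.dff * 3.0, threshold=tr.threshold * 3.0,
                      threshold_rule=tr.threshold_rule)
    a, b = detect_peaks(tr), detect_peaks(scaled)
    assert [e.peak_frame for e in a] == [e.peak_frame for e in b]
    for ea, eb in zip(a, b):
        assert eb.amplitude == pytest.approx(3.0 * ea.amplitude, rel=1e-9)
        assert eb.rise_time_s == ea.rise_time_s
        assert eb.decay_time_s == ea.decay_time_s


def test_truncated_event_keeps_amplitude_drops_decay():
    n = 120
    raw = np.full(n, 100.0)
    t = np.arange(n, dtype=float)
    raw += 60 * transient_kernel(t - 116, 0.2, 50.0)  # slow decay at the end
    events = detect_peaks(compute_dff(raw, window_frames=60))
    assert len(events) == 1
    assert events[0].decay_time_s is None
    assert events[0].duration_s is None
    assert events[0].amplitude > 0


def test_detect_peaks_window_validation():
    tr = compute_dff(np.full(70, 100.0), window_frames=60)
    with pytest.raises(ValueError):
        detect_peaks(tr, max_lookback=80)
    with pytest.raises(ValueError):
        detect_peaks(tr, sg_window=6)


def test_all_event_peaks_exceed_threshold(study_session):
    for rid, evs in study_session.events.items():
        tr = study_session.dffs[rid]
        s = savgol_filter(tr.dff, 7, 3)
        for ev in evs:
            lo = max(0, ev.peak_frame - 3)
            assert s[lo:ev.peak_frame + 4].max() > tr.threshold
            assert ev.amplitude > 0
            assert ev.onset_frame < ev.peak_frame + 4


# --------------------------------------------------------------------------
# rasters, per-block counts, high-K response
# --------------------------------------------------------------------------

def _ev(rid, peak, onset, end):
    from tgcalcium import CalciumEvent
    return CalciumEvent(roi_id=rid, peak_frame=peak, amplitude=1.0,
                        rise_time_s=1.0, decay_time_s=1.0, duration_s=2.0,
                        onset_frame=onset, end_frame=end)


def test_build_raster_marks_onset_to_end():
    events = {3: [_ev(3, 10, 8, 12)], 5: [_ev(5, 2, 1, 3), _ev(5, 18, 17, 19)]}
    raster = build_raster(events, n_frames=20)
    assert raster.roi_ids == [3, 5]
    assert raster.matrix.shape == (2, 20)
    assert raster.matrix[0].sum() == 5            # frames 8..12
    assert set(np.nonzero(raster.matrix[0])[0]) == set(range(8, 13))
    assert raster.matrix[1].sum() == 3 + 3


def test_count_active_blocks():
    events = {0: [_ev(0, 10, 9, 11)], 1: [_ev(1, 10, 9, 11), _ev(1, 40, 39, 41)],
              2: [], 3: [_ev(3, 45, 44, 46)]}
    counts, mean = count_active(events, [(0, 30), (30, 60)])
    assert counts == [2, 2]
    assert mean == 2.0
    assert count_active({}, [(0, 30)]) == ([0], 0.0)


def test_high_k_response_flags_responders():
    # the 10xSEM threshold of each trace is sd/sqrt(n)*10 = 0.87 here;
    # the quiet trace stays at 0 inside the epoch, the responder steps to 5
    n = 100
    quiet = np.zeros(n)
    quiet[:75] = np.tile([1.0, -1.0], 38)[:75]
    responder = quiet.copy()
    responder[80:] += 5.0
    traces = [DffTrace(0, quiet, quiet, quiet, 0.0, "ten_sem"),
              DffTrace(1, responder, responder, responder, 0.0, "ten_sem")]
    heat, resp = high_k_response(traces, epoch=(75, 100))
    assert heat.shape == (2, n)
    assert list(resp) == [False, True]
    assert heat[1, 80:].all()
    assert not heat[0, 75:].any()
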