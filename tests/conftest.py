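"""Shared fixtures.

``study_session`` runs the whole analysis chain once at the default
study conditions (660 x 660 um, 1 Hz, 600 frames, 300 neurons, 12%
active, 10 planted correlated pairs, SNR 5) and is reused by every test
that needs a realistic session, so the expensive simulation + detection
happens once per test run.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from tgcalcium import (SimConfig, bleach_correct, compute_dff, detect_peaks,
                       detect_rois, extract_traces, motion_correct,
                       pair_distances, pairwise_correlation, refine_rois,
                       simulate_movie, thresholded_signal)
from tgcalcium.correlation import attach_distances
from tgcalcium.movie import MovieStack


@pytest.fixture(scope="session")
def study_session():
    """Full chain at study conditions, seed 1, with ROI-to-truth matching."""
    cfg = SimConfig(seed=1)
    movie, gt = simulate_movie(cfg)
    corrected = bleach_correct(movie)
    corrected, shift_table = motion_correct(corrected)
    rois = detect_rois(corrected)
    traces = extract_traces(corrected, rois)
    dffs = {int(rid): compute_dff(traces[rid].to_numpy(float), roi_id=int(rid))
            for rid in traces.columns}
    events = {rid: detect_peaks(d) for rid, d in dffs.items()}
    kept, refine_log = refine_rois(rois, traces)
    kept_ids = {r.id for r in kept.rois}
    events_kept = {rid: events[rid] for rid in events if rid in kept_ids}

    # match each kept ROI to the nearest active ground-truth neuron
    active_xy = {n.id: n.centroid_xy_um for n in gt.neurons if n.active}
    roi_to_truth = {}
    for roi in kept.rois:
        x0, y0 = roi.centroid_xy_um
        d = {i: np.hypot(x0 - c[0], y0 - c[1]) for i, c in active_xy.items()}
        best = min(d, key=d.get)
        roi_to_truth[roi.id] = best if d[best] <= 15.0 else None

    signals = {rid: thresholded_signal(dffs[rid]) for rid in events_kept}
    cmat, records = pairwise_correlation(signals)
    attach_distances(records, pair_distances(kept))

    return SimpleNamespace(
        cfg=cfg, movie=movie, corrected=corrected, gt=gt,
        rois=rois, kept=kept, refine_log=refine_log, traces=traces,
        dffs=dffs, events=events_kept, roi_to_truth=roi_to_truth,
        cmat=cmat, records=records,
    )


@pytest.fixture()
def make_movie():
    """Factory for small in-memory movies."""
    def _make(data, frame_rate_hz=1.0, pixel_size_um=1.0, **kw):
        return MovieStack(data=np.asarray(data, dtype=np.float32),
                          frame_rate_hz=frame_rate_hz,
                          pixel_size_um=pixel_size_um, **kw)
    return _make
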