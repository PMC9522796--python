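"""Ground-truthed synthetic explant movies and nuclear-label stills.

The generator emulates the statistical structure of a 1 Hz GCaMP6s
recording from an intact sensory ganglion: a mosaic of circular somata
drawn from a small/medium/large diameter mixture, sparse Poisson-timed
calcium transients in a minority of neurons, a handful of spatially
proximal neuron pairs that fire together, global monoexponential
photobleaching, additive Gaussian read noise, optional rigid jitter, and
an optional terminal high-potassium epoch in which every neuron responds.

Defaults correspond to a postnatal day 4-6 locus: a 660 x 660 um field
imaged at 1 Hz for 600 frames containing 300 neurons of which 12% fire
spontaneously, with 10 correlated pairs planted within 150 um of each
other and a per-pixel event signal-to-noise ratio of 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .movie import MovieStack

__all__ = [
    "SimConfig",
    "NeuronTruth",
    "GroundTruth",
    "PlacementError",
    "transient_kernel",
    "simulate_movie",
    "simulate_nuclei_image",
    "write_ground_truth",
    "read_ground_truth",
]


class PlacementError(RuntimeError):
    """Somata/nuclei could not be placed without overlap in the field."""


# (mean_um, sd_um, weight) per soma-diameter class; weights follow the
# measured class shares of a high-K-depolarized neonatal locus
# (67.3% small / 27.3% medium / 5.5% large).
DEFAULT_DIAMETER_MIXTURE = (
    (15.0, 2.5, 0.673),  # SD: < 20 um
    (22.5, 1.4, 0.273),  # MD: 20-25 um
    (28.0, 2.5, 0.055),  # LD: > 25 um
)
_CLASS_BOUNDS = {"SD": (6.0, 20.0), "MD": (20.0, 25.0), "LD": (25.0, 40.0)}
_CLASS_LABELS = ("SD", "MD", "LD")


@dataclass
class SimConfig:
    """Parameters of one simulated imaging session.

    All spatial quantities are in micrometres, times in seconds, rates in
    events per minute per neuron. ``noise_sd`` is the per-pixel Gaussian
    noise standard deviation in intensity units; with the default soma
    baseline of 100 and transient peak dF/F of 0.8 the per-pixel event
    SNR is ``soma_baseline * amp_dff / noise_sd`` = 5.
    """

    field_size_um: float = 660.0
    pixels_per_side: int = 330
    frame_rate_hz: float = 1.0
    n_frames: int = 600
    n_neurons: int = 300
    diameter_mixture: tuple = DEFAULT_DIAMETER_MIXTURE
    event_rate_per_min: float = 0.4
    frac_active: float = 0.12
    n_correlated_pairs: int = 10
    correlated_pair_max_dist_um: float = 150.0
    correlated_pair_min_dist_um: float = 40.0
    rise_tau_s: float = 0.2
    decay_tau_s: float = 2.0
    bleach_tau_s: float | None = 600.0
    amp_dff: float = 0.8
    soma_baseline: float = 100.0
    background_level: float = 100.0  # includes camera offset, keeps noise off the floor
    noise_sd: float = 16.0
    jitter_px: float = 0.0
    high_k_start_frame: int | None = None
    event_frame_range: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_size_um <= 0 or self.pixels_per_side <= 0:
            raise ValueError("field_size_um and pixels_per_side must be positive")
        if not 0.0 <= self.frac_active <= 1.0:
            raise ValueError("frac_active must lie in [0, 1]")
        if self.event_rate_per_min < 0 or self.noise_sd < 0 or self.jitter_px < 0:
            raise ValueError("rates/noise/jitter must be nonnegative")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("kernel time constants must be positive")
        # printed class shares can carry rounding error; weights are
        # normalized at sampling time
        w = sum(m[2] for m in self.diameter_mixture)
        if abs(w - 1.0) > 1e-2:
            raise ValueError(f"diameter mixture weights must sum to 1 (got {w})")
        if self.n_correlated_pairs < 0:
            raise ValueError("n_correlated_pairs must be nonnegative")

    @property
    def pixel_size_um(self) -> float:
        return self.field_size_um / self.pixels_per_side

    @property
    def snr(self) -> float:
        """Per-pixel peak event amplitude over noise standard deviation."""
        if self.noise_sd == 0:
            return float("inf")
        return self.soma_baseline * self.amp_dff / self.noise_sd


@dataclass
class NeuronTruth:
    id: int
    centroid_xy_um: tuple[float, float]  # (x, y) = (col, row) * pixel size
    diameter_um: float
    size_class: str
    active: bool
    onset_frames: list[int]


@dataclass
class GroundTruth:
    """Everything the generator knows about one rendered session."""

    neurons: list[NeuronTruth]
    correlated_pairs: list[tuple[int, int]]
    bleach_tau_s: float | None
    noise_sd: float
    jitter_trajectory: np.ndarray  # (n_frames, 2) of (dy, dx) px
    pixel_size_um: float
    frame_rate_hz: float
    n_frames: int
    amp_dff: float = 0.8

    def active_ids(self) -> list[int]:
        return [n.id for n in self.neurons if n.active]

    def active_in_block(self, start: int, stop: int) -> list[int]:
        """Neurons with at least one event onset in frames [start, stop)."""
        return [n.id for n in self.neurons
                if any(start <= f < stop for f in n.onset_frames)]


def transient_kernel(t_s: np.ndarray, rise_tau_s: float, decay_tau_s: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium transient.

    ``k(t) = (1 - exp(-t/rise)) * exp(-t/decay)`` for ``t >= 0``, scaled
    so the maximum equals 1. Rise and decay are independently tunable,
    matching how transients are parametrized downstream (rise time /
    decay time read off the trace).
    """
    t = np.asarray(t_s, dtype=float)
    k = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / rise_tau_s))
                 * np.exp(-np.maximum(t, 0) / decay_tau_s), 0.0)
    t_peak = rise_tau_s * np.log1p(decay_tau_s / rise_tau_s)
    peak = (1.0 - np.exp(-t_peak / rise_tau_s)) * np.exp(-t_peak / decay_tau_s)
    return k / peak


def _sample_diameter(rng: np.random.Generator, mixture: tuple) -> tuple[float, str]:
    """Draw one soma diameter; each mixture component is truncated to its
    size-class interval so the realized class shares equal the weights."""
    weights = np.array([m[2] for m in mixture])
    comp = rng.choice(len(mixture), p=weights / weights.sum())
    mean, sd, _ = mixture[comp]
    lo, hi = _CLASS_BOUNDS[_CLASS_LABELS[comp]]
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if comp == 0 and lo < d < hi:
            return d, "SD"
        if comp == 1 and lo <= d <= hi:
            return d, "MD"
        if comp == 2 and hi > d > lo:
            return d, "LD"
    raise RuntimeError("diameter sampling failed; check mixture parameters")


def _place_disk(rng, centers, radii_px, r_px, n_px, margin_px=2.0,
                near: tuple | None = None, dist_range_px: tuple | None = None,
                max_tries: int = 2000):
    """Find a centre for a disk of radius r_px not overlapping existing disks."""
    for _ in range(max_tries):
        if near is not None:
            lo, hi = dist_range_px
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(lo, hi)
            cy = near[0] + dist * np.sin(ang)
            cx = near[1] + dist * np.cos(ang)
            if not (r_px + 1 <= cy < n_px - r_px - 1 and r_px + 1 <= cx < n_px - r_px - 1):
                continue
        else:
            cy = rng.uniform(r_px + 1, n_px - r_px - 1)
            cx = rng.uniform(r_px + 1, n_px - r_px - 1)
        ok = True
        for (oy, ox), orad in zip(centers, radii_px):
            if (cy - oy) ** 2 + (cx - ox) ** 2 < (r_px + orad + margin_px) ** 2:
                ok = False
                break
        if ok:
            return cy, cx
    raise PlacementError("could not place soma without overlap; "
                         "reduce n_neurons or diameters")


def _poisson_onsets(rng: np.random.Generator, rate_per_min: float,
                    frame_rate_hz: float, frame_range: tuple[int, int]) -> list[int]:
    lo, hi = frame_range
    duration_min = (hi - lo) / frame_rate_hz / 60.0
    n = rng.poisson(rate_per_min * duration_min)
    return sorted(int(f) for f in rng.integers(lo, hi, size=n))


def simulate_movie(cfg: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Render one synthetic session and its ground truth.

    The rendered intensity at pixel p, frame t is::

        [bg + sum_n baseline * (1 + amp * sum_k kernel(t - onset_nk)) * disk_n(p)]
            * exp(-t / bleach_tau) + N(0, noise_sd)

    shifted rigidly by the per-frame jitter trajectory. Rendering is
    deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_px = cfg.pixels_per_side
    px_um = cfg.pixel_size_um
    fr = cfg.frame_rate_hz
    n_frames = cfg.n_frames

    # --- geometry -------------------------------------------------------
    n_active = int(round(cfg.frac_active * cfg.n_neurons))
    n_pairs = cfg.n_correlated_pairs
    if 2 * n_pairs > n_active:
        raise ValueError("n_correlated_pairs requires 2*pairs <= active neurons")

    diameters: list[float] = []
    classes: list[str] = []
    centers: list[tuple[float, float]] = []
    radii_px: list[float] = []
    pair_list: list[tuple[int, int]] = []

    def add_neuron(near=None, dist_range_px=None):
        d, cls = _sample_diameter(rng, cfg.diameter_mixture)
        r_px = d / 2.0 / px_um
        cy, cx = _place_disk(rng, centers, radii_px, r_px, n_px,
                             near=near, dist_range_px=dist_range_px)
        diameters.append(d)
        classes.append(cls)
        centers.append((cy, cx))
        radii_px.append(r_px)
        return len(centers) - 1

    # planted correlated pairs first (both members active, spatially close)
    for _ in range(n_pairs):
        i = add_neuron()
        j = add_neuron(near=centers[i],
                       dist_range_px=(cfg.correlated_pair_min_dist_um / px_um,
                                      cfg.correlated_pair_max_dist_um / px_um))
        pair_list.append((i, j))
    while len(centers) < cfg.n_neurons:
        add_neuron()

    active = np.zeros(cfg.n_neurons, dtype=bool)
    active[: 2 * n_pairs] = True
    remaining = np.arange(2 * n_pairs, cfg.n_neurons)
    extra = rng.choice(remaining, size=n_active - 2 * n_pairs, replace=False)
    active[extra] = True

    # --- event times ----------------------------------------------------
    ev_range = cfg.event_frame_range or (0, max(1, n_frames - 5))
    onsets: list[list[int]] = [[] for _ in range(cfg.n_neurons)]
    neuron_rngs = rng.spawn(cfg.n_neurons)  # per-neuron sub-streams
    for i, j in pair_list:
        shared = _poisson_onsets(neuron_rngs[i], cfg.event_rate_per_min, fr, ev_range)
        onsets[i] = shared
        jitter = neuron_rngs[j].choice([-1, 0, 1], size=len(shared), p=[0.25, 0.5, 0.25])
        onsets[j] = sorted(int(np.clip(f + dj, ev_range[0], ev_range[1] - 1))
                           for f, dj in zip(shared, jitter))
    for idx in np.nonzero(active)[0]:
        if idx < 2 * n_pairs:
            continue
        onsets[idx] = _poisson_onsets(neuron_rngs[idx], cfg.event_rate_per_min, fr, ev_range)

    # --- render ---------------------------------------------------------
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    base = np.full((n_px, n_px), cfg.background_level, dtype=np.float32)
    masks_idx: list[np.ndarray] = []
    for (cy, cx), r_px in zip(centers, radii_px):
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        masks_idx.append(np.flatnonzero(m))
        base[m] += cfg.soma_baseline

    movie = np.broadcast_to(base.ravel(), (n_frames, n_px * n_px)).copy()
    t_frames = np.arange(n_frames, dtype=float)
    for idx in range(cfg.n_neurons):
        if not onsets[idx]:
            continue
        dff = np.zeros(n_frames)
        for f0 in onsets[idx]:
            dff += cfg.amp_dff * transient_kernel((t_frames - f0) / fr,
                                                  cfg.rise_tau_s, cfg.decay_tau_s)
        movie[:, masks_idx[idx]] += (cfg.soma_baseline * dff)[:, None].astype(np.float32)

    if cfg.high_k_start_frame is not None:
        k0 = cfg.high_k_start_frame
        # global depolarization: sustained plateau in every soma
        ramp = 1.0 - np.exp(-np.maximum(t_frames - k0, 0) / (3.0 * fr))
        ramp[t_frames < k0] = 0.0
        step = (2.0 * cfg.amp_dff * cfg.soma_baseline * ramp).astype(np.float32)
        for idx in range(cfg.n_neurons):
            movie[:, masks_idx[idx]] += step[:, None]

    movie = movie.reshape(n_frames, n_px, n_px)

    if cfg.bleach_tau_s is not None:
        decay = np.exp(-(t_frames / fr) / cfg.bleach_tau_s).astype(np.float32)
        movie *= decay[:, None, None]

    jitter_traj = np.zeros((n_frames, 2))
    if cfg.jitter_px > 0:
        jitter_traj = rng.normal(0.0, cfg.jitter_px, size=(n_frames, 2))
        jitter_traj[0] = 0.0
        for t in range(n_frames):
            if np.any(jitter_traj[t] != 0):
                movie[t] = ndimage.shift(movie[t], jitter_traj[t], order=1,
                                         mode="nearest")

    if cfg.noise_sd > 0:
        movie += rng.normal(0.0, cfg.noise_sd, size=movie.shape).astype(np.float32)
    np.maximum(movie, 0.0, out=movie)

    neurons = [
        NeuronTruth(
            id=i,
            centroid_xy_um=(centers[i][1] * px_um, centers[i][0] * px_um),
            diameter_um=diameters[i],
            size_class=classes[i],
            active=bool(active[i]),
            onset_frames=list(onsets[i]),
        )
        for i in range(cfg.n_neurons)
    ]
    gt = GroundTruth(
        neurons=neurons,
        correlated_pairs=pair_list,
        bleach_tau_s=cfg.bleach_tau_s,
        noise_sd=cfg.noise_sd,
        jitter_trajectory=jitter_traj,
        pixel_size_um=px_um,
        frame_rate_hz=fr,
        n_frames=n_frames,
        amp_dff=cfg.amp_dff,
    )
    stack = MovieStack(data=movie.astype(np.float32), frame_rate_hz=fr,
                       pixel_size_um=px_um)
    return stack, gt


def simulate_nuclei_image(
    n_nuclei: int,
    field_size_um: float = 660.0,
    pixels_per_side: int = 512,
    diameter_um: float = 12.0,
    seed: int = 0,
    noise_sd: float = 4.0,
    n_touching_pairs: int = 0,
    margin_px: float = 2.0,
) -> tuple[np.ndarray, dict]:
    """Render a nuclear-label still: bright disks on a dark background.

    Nuclei are placed with at least ``margin_px`` clearance by default;
    ``n_touching_pairs`` of them are instead planted as tangent pairs
    (centre distance ~= one diameter) to exercise watershed splitting.

    Returns the image and a ground-truth dict with ``count`` and
    ``centroids_px`` (row, col).
    """
    if n_nuclei < 0 or 2 * n_touching_pairs > n_nuclei:
        raise ValueError("need 0 <= 2*n_touching_pairs <= n_nuclei")
    rng = np.random.default_rng(seed)
    px_um = field_size_um / pixels_per_side
    r_px = diameter_um / 2.0 / px_um
    centers: list[tuple[float, float]] = []
    radii: list[float] = []

    def place_free():
        c = _place_disk(rng, centers, radii, r_px, pixels_per_side,
                        margin_px=margin_px)
        centers.append(c)
        radii.append(r_px)

    def place_partner(mate: tuple[float, float]) -> None:
        # tangent partner: fixed distance to its mate, normal clearance to
        # every other nucleus
        d = 2.0 * r_px * 0.98
        for _ in range(2000):
            ang = rng.uniform(0, 2 * np.pi)
            cy = mate[0] + d * np.sin(ang)
            cx = mate[1] + d * np.cos(ang)
            if not (r_px + 1 <= cy < pixels_per_side - r_px - 1
                    and r_px + 1 <= cx < pixels_per_side - r_px - 1):
                continue
            if all((cy - c[0]) ** 2 + (cx - c[1]) ** 2 >= (2 * r_px + margin_px) ** 2
                   for c in centers if c is not mate):
                centers.append((cy, cx))
                radii.append(r_px)
                return
        raise PlacementError("could not place touching nucleus pair")

    for _ in range(n_touching_pairs):
        place_free()
        place_partner(centers[-1])
    while len(centers) < n_nuclei:
        place_free()

    yy, xx = np.mgrid[0:pixels_per_side, 0:pixels_per_side]
    img = np.full((pixels_per_side, pixels_per_side), 10.0, dtype=np.float32)
    for (cy, cx) in centers:
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        img[m] = 200.0 * rng.uniform(0.85, 1.0)
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, img.shape).astype(np.float32)
    np.maximum(img, 0, out=img)
    gt = {
        "count": n_nuclei,
        "centroids_px": [(float(cy), float(cx)) for cy, cx in centers],
        "radius_px": float(r_px),
    }
    return img, gt


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth: neurons.csv, events.csv, pairs.csv + scalars.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": [n.id for n in gt.neurons],
            "centroid_x_um": [n.centroid_xy_um[0] for n in gt.neurons],
            "centroid_y_um": [n.centroid_xy_um[1] for n in gt.neurons],
            "diameter_um": [n.diameter_um for n in gt.neurons],
            "size_class": [n.size_class for n in gt.neurons],
            "active": [n.active for n in gt.neurons],
        }
    ).to_csv(path / "neurons.csv", index=False)
    rows = [(n.id, f) for n in gt.neurons for f in n.onset_frames]
    pd.DataFrame(rows, columns=["neuron_id", "onset_frame"]).to_csv(
        path / "events.csv", index=False)
    pd.DataFrame(gt.correlated_pairs, columns=["neuron_i", "neuron_j"]).to_csv(
        path / "pairs.csv", index=False)
    scalars = {
        "bleach_tau_s": gt.bleach_tau_s,
        "noise_sd": gt.noise_sd,
        "pixel_size_um": gt.pixel_size_um,
        "frame_rate_hz": gt.frame_rate_hz,
        "n_frames": gt.n_frames,
        "amp_dff": gt.amp_dff,
    }
    (path / "scalars.json").write_text(json.dumps(scalars, indent=2))
    np.savetxt(path / "jitter.csv", gt.jitter_trajectory, delimiter=",",
               header="dy_px,dx_px", comments="")


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Inverse of :func:`write_ground_truth` (lossless for stored fields)."""
    path = Path(path)
    neurons_df = pd.read_csv(path / "neurons.csv")
    events_df = pd.read_csv(path / "events.csv")
    pairs_df = pd.read_csv(path / "pairs.csv")
    scalars = json.loads((path / "scalars.json").read_text())
    jitter = np.loadtxt(path / "jitter.csv", delimiter=",", skiprows=1, ndmin=2)
    by_id = events_df.groupby("neuron_id")["onset_frame"].apply(list).to_dict()
    neurons = [
        NeuronTruth(
            id=int(r.id),
            centroid_xy_um=(float(r.centroid_x_um), float(r.centroid_y_um)),
            diameter_um=float(r.diameter_um),
            size_class=str(r.size_class),
            active=bool(r.active),
            onset_frames=[int(f) for f in by_id.get(int(r.id), [])],
        )
        for r in neurons_df.itertuples()
    ]
    return GroundTruth(
        neurons=neurons,
        correlated_pairs=[(int(i), int(j)) for i, j in
                          zip(pairs_df.neuron_i, pairs_df.neuron_j)],
        bleach_tau_s=scalars["bleach_tau_s"],
        noise_sd=scalars["noise_sd"],
        jitter_trajectory=jitter,
        pixel_size_um=scalars["pixel_size_um"],
        frame_rate_hz=scalars["frame_rate_hz"],
        n_frames=scalars["n_frames"],
        amp_dff=scalars.get("amp_dff", 0.8),
    )
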