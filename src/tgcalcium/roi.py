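"""ROI detection, trace extraction, refinement, and nuclei counting.

Somata of spontaneously firing neurons are detected from a per-pixel
activity projection of the preprocessed movie (by default the temporal
peak of the denoised, median-subtracted movie, which stays sensitive to
neurons that fire only once in a session; a classic smoothed temporal
standard-deviation image is available as an option). Local maxima above
an intensity percentile seed a watershed segmentation, segments are
filtered by equivalent diameter, and touching segments whose traces are
near-identical (Pearson r above a merge threshold, default 0.95) are
merged — fragments of one soma correlate almost perfectly, distinct
neighbouring neurons do not.

This detector replaces a constrained-factorization toolbox: the
downstream science depends on traces and events, not on the particular
segmentation algorithm, and ground-truth or manually drawn ROI masks are
accepted everywhere via :meth:`RoiSet.from_centroids`.

Coordinate convention: pixel indices are 0-based (row, col); centroids
are reported in micrometres as (x, y) = (col, row) * pixel size, origin
at the top-left pixel centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, restoration, segmentation
from skimage.feature import peak_local_max
from skimage.transform import resize

from .movie import MovieStack

logger = logging.getLogger(__name__)

__all__ = ["Roi", "RoiSet", "detect_rois", "extract_traces", "refine_rois",
           "count_nuclei"]


@dataclass
class Roi:
    """One labelled soma region."""

    id: int
    centroid_xy_um: tuple[float, float]
    pixel_mask: np.ndarray  # (k, 2) array of (row, col) indices
    equivalent_diameter_um: float

    @classmethod
    def from_mask(cls, roi_id: int, mask_rc: np.ndarray, pixel_size_um: float) -> "Roi":
        mask_rc = np.asarray(mask_rc)
        if mask_rc.size == 0:
            raise ValueError("ROI mask must be nonempty")
        area_px = mask_rc.shape[0]
        diam = 2.0 * np.sqrt(area_px / np.pi) * pixel_size_um
        cy, cx = mask_rc[:, 0].mean(), mask_rc[:, 1].mean()
        return cls(id=roi_id, centroid_xy_um=(cx * pixel_size_um, cy * pixel_size_um),
                   pixel_mask=mask_rc, equivalent_diameter_um=diam)


@dataclass
class RoiSet:
    """A collection of disjoint ROIs plus their provenance."""

    rois: list[Roi]
    source: str = "auto"  # auto | manual | ground_truth
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise ValueError("ROI ids must be unique")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def ids(self) -> list[int]:
        return [r.id for r in self.rois]

    @classmethod
    def from_centroids(cls, centroids_xy_um, radii_um, pixel_size_um: float,
                       image_shape: tuple[int, int], source: str = "manual") -> "RoiSet":
        """Build circular ROIs from centroid/radius tables (manual input path)."""
        yy, xx = np.mgrid[0:image_shape[0], 0:image_shape[1]]
        rois = []
        for i, ((x_um, y_um), r_um) in enumerate(zip(centroids_xy_um, radii_um)):
            cy, cx = y_um / pixel_size_um, x_um / pixel_size_um
            m = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r_um / pixel_size_um) ** 2
            rc = np.argwhere(m)
            if rc.size == 0:
                rc = np.array([[int(round(cy)), int(round(cx))]])
            rois.append(Roi.from_mask(i, rc, pixel_size_um))
        return cls(rois=rois, source=source, pixel_size_um=pixel_size_um)

    @classmethod
    def from_label_image(cls, labels: np.ndarray, pixel_size_um: float,
                         source: str = "manual") -> "RoiSet":
        rois = []
        for lab in np.unique(labels):
            if lab == 0:
                continue
            rc = np.argwhere(labels == lab)
            rois.append(Roi.from_mask(int(lab), rc, pixel_size_um))
        return cls(rois=rois, source=source, pixel_size_um=pixel_size_um)

    def to_label_image(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=np.uint16)
        for r in self.rois:
            out[r.pixel_mask[:, 0], r.pixel_mask[:, 1]] = r.id + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [r.id for r in self.rois],
            "centroid_x_um": [r.centroid_xy_um[0] for r in self.rois],
            "centroid_y_um": [r.centroid_xy_um[1] for r in self.rois],
            "diameter_um": [r.equivalent_diameter_um for r in self.rois],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _labels_to_roiset(labels: np.ndarray, pixel_size_um: float) -> RoiSet:
    rois = []
    for i, lab in enumerate(l for l in np.unique(labels) if l != 0):
        rc = np.argwhere(labels == lab)
        rois.append(Roi.from_mask(i, rc, pixel_size_um))
    return RoiSet(rois=rois, source="auto", pixel_size_um=pixel_size_um)


def activity_image(movie: MovieStack, stat: str = "peak",
                   smooth_sigma_um: float = 3.0,
                   boxcar_frames: int = 3) -> np.ndarray:
    """Per-pixel activity statistic used to find firing somata.

    ``peak`` (default): temporal maximum of the boxcar-denoised,
    median-subtracted, spatially smoothed movie — sensitive to sparse
    transients, since a soma firing even once rises far above the noise
    envelope. ``std``: Gaussian-smoothed temporal standard deviation (the
    classic projection; less sensitive when a neuron fires only once or
    twice in the session).
    """
    px_um = movie.pixel_size_um
    sigma_px = max(smooth_sigma_um / px_um, 1.0)
    data = movie.data[movie.frame_kept_flags]
    if stat == "std":
        return ndimage.gaussian_filter(data.std(axis=0), sigma_px)
    if stat != "peak":
        raise ValueError(f"unknown activity statistic: {stat}")
    den = ndimage.uniform_filter1d(data, boxcar_frames, axis=0)
    resp = den - np.median(den, axis=0)
    resp = ndimage.gaussian_filter(resp, (0, sigma_px, sigma_px))
    return resp.max(axis=0)


def detect_rois(movie: MovieStack, min_diam_um: float = 8.0,
                max_diam_um: float = 45.0, activity_percentile: float = 98.0,
                merge_r: float = 0.95, smooth_sigma_um: float = 3.0,
                stat: str = "peak") -> RoiSet:
    """Detect somata of firing neurons from a preprocessed movie.

    Pipeline: activity image (see :func:`activity_image`) -> local maxima
    above the ``activity_percentile`` of the image -> watershed ->
    equivalent-diameter filter ``[min_diam_um, max_diam_um]`` -> merge
    touching segments whose raw traces correlate above ``merge_r``.

    Returns an empty :class:`RoiSet` (with a warning) when nothing is
    found; that is a valid outcome for a quiet movie.
    """
    px_um = movie.pixel_size_um
    sm = activity_image(movie, stat=stat, smooth_sigma_um=smooth_sigma_um)

    thr = np.percentile(sm, activity_percentile)
    fg = sm > thr
    # seed one marker per h-maximum: a secondary maximum inside one soma
    # (noise ripple on the plateau) must dip at least ~4 noise SDs to
    # seed its own region, while distinct neurons are separated by deep
    # background valleys and keep separate seeds
    med = np.median(sm)
    sigma_bg = 1.4826 * np.median(np.abs(sm - med))
    seeds = morphology.h_maxima(sm, max(4.0 * sigma_bg, 1e-9)) & fg
    if not seeds.any():
        logger.warning("detect_rois: no ROIs found")
        return RoiSet(rois=[], source="auto", pixel_size_um=px_um)
    markers, _ = ndimage.label(seeds, structure=np.ones((3, 3), dtype=bool))
    labels = segmentation.watershed(-sm, markers, mask=fg)

    # equivalent-diameter filter
    for region in measure.regionprops(labels):
        d_um = region.equivalent_diameter_area * px_um
        if not (min_diam_um <= d_um <= max_diam_um):
            labels[labels == region.label] = 0

    if labels.max() == 0:
        logger.warning("detect_rois: no ROIs passed the size filter")
        return RoiSet(rois=[], source="auto", pixel_size_um=px_um)

    labels = _merge_touching_correlated(movie, labels, merge_r)
    return _labels_to_roiset(labels, px_um)


def _merge_touching_correlated(movie: MovieStack, labels: np.ndarray,
                               merge_r: float) -> np.ndarray:
    """Union-find merge of adjacent labels whose traces correlate > merge_r."""
    labs = [int(l) for l in np.unique(labels) if l != 0]
    if len(labs) < 2:
        return labels
    traces = {}
    flat = movie.data.reshape(movie.n_frames, -1)
    for lab in labs:
        idx = np.flatnonzero((labels == lab).ravel())
        traces[lab] = flat[:, idx].mean(axis=1)
    # adjacency: labels touching after 1-px dilation
    parent = {lab: lab for lab in labs}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    struct = ndimage.generate_binary_structure(2, 2)
    for lab in labs:
        dil = ndimage.binary_dilation(labels == lab, structure=struct)
        neighbours = set(np.unique(labels[dil])) - {0, lab}
        for nb in neighbours:
            if find(lab) == find(int(nb)):
                continue
            a, b = traces[lab], traces[int(nb)]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r > merge_r:
                parent[find(int(nb))] = find(lab)
    out = labels.copy()
    for lab in labs:
        root = find(lab)
        if root != lab:
            out[labels == lab] = root
    return out


def extract_traces(movie: MovieStack, rois: RoiSet) -> pd.DataFrame:
    """Mean-intensity trace per ROI.

    Returns a DataFrame indexed by frame with one column per ROI id.
    Frames flagged as dropped are filled by linear interpolation between
    the nearest kept frames (edges held constant).
    """
    n_rows, n_cols = movie.data.shape[1:]
    flat = movie.data.reshape(movie.n_frames, -1)
    out = {}
    for roi in rois:
        rc = roi.pixel_mask
        if (rc[:, 0].min() < 0 or rc[:, 1].min() < 0
                or rc[:, 0].max() >= n_rows or rc[:, 1].max() >= n_cols):
            raise ValueError(f"ROI {roi.id}: mask out of image bounds")
        idx = rc[:, 0] * n_cols + rc[:, 1]
        out[roi.id] = flat[:, idx].mean(axis=1)
    df = pd.DataFrame(out, index=pd.RangeIndex(movie.n_frames, name="frame"))
    if not movie.frame_kept_flags.all():
        df[~movie.frame_kept_flags] = np.nan
        df = df.interpolate(method="linear", limit_direction="both")
    return df


def refine_rois(rois: RoiSet, traces: pd.DataFrame, min_events: int = 1,
                min_peak_dff: float = 0.0, frame_rate_hz: float = 1.0,
                **peak_kwargs) -> tuple[RoiSet, pd.DataFrame]:
    """Drop low-activity false positives.

    An ROI is kept iff its dF/F0 trace yields at least ``min_events``
    detected transients and a maximum dF/F0 of at least ``min_peak_dff``.
    Returns the refined set and a removal log (roi_id, n_events,
    max_dff, kept).
    """
    from .events import compute_dff, detect_peaks

    log_rows = []
    kept_rois = []
    for roi in rois:
        raw = traces[roi.id].to_numpy(dtype=float)
        try:
            dff = compute_dff(raw, roi_id=roi.id)
            events = detect_peaks(dff, frame_rate_hz=frame_rate_hz, **peak_kwargs)
            max_dff = float(dff.dff.max())
        except ValueError:
            events, max_dff = [], float("-inf")
        ok = len(events) >= min_events and max_dff >= min_peak_dff
        log_rows.append((roi.id, len(events), max_dff, ok))
        if ok:
            kept_rois.append(roi)
    log = pd.DataFrame(log_rows, columns=["roi_id", "n_events", "max_dff", "kept"])
    n_removed = len(rois) - len(kept_rois)
    if n_removed:
        logger.info("refine_rois removed %d of %d ROIs", n_removed, len(rois))
    return RoiSet(rois=kept_rois, source=rois.source,
                  pixel_size_um=rois.pixel_size_um), log


def _rolling_ball_background(image: np.ndarray, radius_px: float) -> np.ndarray:
    """Rolling-ball background; computed on a downscaled copy for large radii
    (the same shrink trick the classic implementation uses)."""
    shrink = max(1, int(radius_px // 25))
    if shrink == 1:
        return restoration.rolling_ball(image, radius=radius_px)
    small = resize(image, (image.shape[0] // shrink, image.shape[1] // shrink),
                   anti_aliasing=True, preserve_range=True)
    bg_small = restoration.rolling_ball(small, radius=radius_px / shrink)
    return resize(bg_small, image.shape, preserve_range=True)


def count_nuclei(image: np.ndarray, background_radius_px: float = 100.0,
                 min_area_px: float = 20.0, max_area_px: float = 10000.0
                 ) -> tuple[int, np.ndarray]:
    """Count bright nuclei in a still nuclear-label image.

    Procedure: rolling-ball background subtraction (default radius 100 px)
    -> Otsu binarization -> distance-transform watershed to split touching
    nuclei -> connected components filtered by ``[min_area, max_area]``.

    Returns the count and the filtered label image. A blank or saturated
    image yields count 0 with a warning. Invariant to adding a constant
    offset to the whole image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("count_nuclei expects a 2-D image")
    if img.max() == img.min():
        logger.warning("count_nuclei: image has no contrast; count 0")
        return 0, np.zeros(img.shape, dtype=np.int32)

    bg = _rolling_ball_background(img, background_radius_px)
    sub = img - bg
    thr = filters.threshold_otsu(sub)
    binary = sub > thr
    binary = morphology.remove_small_objects(
        binary, max_size=max(0, int(min_area_px // 4) - 1))
    if not binary.any():
        logger.warning("count_nuclei: nothing above threshold; count 0")
        return 0, np.zeros(img.shape, dtype=np.int32)

    dist = ndimage.distance_transform_edt(binary)
    min_sep = max(2, int(round(0.8 * np.sqrt(min_area_px / np.pi))))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=binary,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-dist, markers, mask=binary)

    count = 0
    out = np.zeros(img.shape, dtype=np.int32)
    for region in measure.regionprops(labels):
        if min_area_px <= region.area <= max_area_px:
            count += 1
            out[labels == region.label] = count
    return count, out
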