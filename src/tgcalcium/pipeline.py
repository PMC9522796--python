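"""End-to-end pipeline: preprocess -> ROIs -> events -> correlation ->
population summaries -> figures.

A run is driven by a single configuration mapping (YAML file or dict)
and writes per-stage CSV/JSON outputs into a result directory. Every
output table carries the configuration hash and seed in a leading
comment line, and a rerun with an identical configuration and seed is
byte-identical for all CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import correlation as corr
from . import events as ev
from . import population as pop
from . import preprocess as pre
from . import roi as roimod
from .manifest import SessionManifest
from .movie import read_movie
from .synthetic import SimConfig, simulate_movie, write_ground_truth

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "ConfigError", "StageError", "default_config"]

_ALLOWED_KEYS = {"seed", "simulate", "input", "rois", "manifest", "preprocess",
                 "detect", "refine", "events", "render", "write_ground_truth"}
_STAGES = ("preprocess", "roi", "events", "correlation", "population", "render")


class ConfigError(ValueError):
    """Invalid configuration (detected before any computation)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def default_config() -> dict:
    """A complete configuration with all defaults spelled out."""
    return {
        "seed": 0,
        "simulate": {f.name: f.default for f in dataclasses.fields(SimConfig)
                     if f.name not in ("diameter_mixture", "seed")},
        "input": None,  # {"movie": path, "frame_rate_hz": ..., "pixel_size_um": ...}
        "rois": None,   # CSV of id,centroid_x_um,centroid_y_um,diameter_um
        "manifest": {"block_frames": 300, "high_k_start": None},
        "preprocess": {"bleach": "exponential_fit", "motion": None,
                       "max_shift_px": 5.0, "max_mean_jump_frac": 0.5},
        "detect": {"min_diam_um": 8.0, "max_diam_um": 45.0,
                   "activity_percentile": 98.0, "merge_r": 0.95},
        "refine": {"min_events": 1, "min_peak_dff": 0.0},
        "events": {"window_frames": 60, "alignment": "trailing",
                   "threshold_rule": "mean_plus_sd"},
        "render": False,
        "write_ground_truth": False,
    }


def _validate(config: dict) -> dict:
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = default_config()
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            sub = dict(merged[k])
            extra = set(v) - set(sub)
            if extra and k != "simulate":
                raise ConfigError(f"unknown {k} options: {sorted(extra)}")
            sub.update(v)
            merged[k] = sub
        else:
            merged[k] = v
    if merged["input"] is None and merged["simulate"] is None:
        raise ConfigError("config needs either 'input' or 'simulate'")
    return merged


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {tag}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the full analysis described by ``config``.

    Returns the summary dict (also written to ``summary.json`` in
    ``outdir``). Raises :class:`ConfigError` for an invalid
    configuration and :class:`StageError` (naming the stage) when a
    stage fails.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _validate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    tag = f"config_sha256={_config_hash(cfg)} seed={seed}"
    logging.basicConfig(filename=outdir / "run.log", level=logging.INFO,
                        force=False)

    summary: dict = {"config_hash": _config_hash(cfg), "seed": seed,
                     "stages": {}}
    gt = None

    # ---------------- input ----------------
    try:
        if cfg["input"] is not None:
            inp = cfg["input"]
            movie = read_movie(inp["movie"],
                               frame_rate_hz=inp.get("frame_rate_hz"),
                               pixel_size_um=inp.get("pixel_size_um"))
        else:
            sim = SimConfig(seed=seed, **cfg["simulate"])
            movie, gt = simulate_movie(sim)
            if cfg["write_ground_truth"]:
                write_ground_truth(gt, outdir / "ground_truth")
    except (OSError, ValueError) as exc:
        raise StageError(f"stage 'input' failed: {exc}") from exc

    man_cfg = cfg["manifest"]
    manifest = SessionManifest.default_blocks(
        movie.n_frames, block_frames=int(man_cfg["block_frames"]),
        high_k_start=man_cfg["high_k_start"])
    manifest.validate_against(movie.n_frames)

    # ---------------- preprocess ----------------
    try:
        p = cfg["preprocess"]
        shift_table = None
        if p["bleach"] not in (None, "none"):
            movie = pre.bleach_correct(movie, method=p["bleach"])
        if p["motion"] not in (None, "none"):
            movie, shift_table = pre.motion_correct(movie, reference=p["motion"])
            _write_table(shift_table, outdir / "shifts.csv", tag)
        movie = pre.drop_bad_frames(movie, max_shift_px=p["max_shift_px"],
                                    max_mean_jump_frac=p["max_mean_jump_frac"],
                                    shift_table=shift_table)
        summary["stages"]["preprocess"] = {
            "n_frames": movie.n_frames,
            "n_dropped": int((~movie.frame_kept_flags).sum()),
        }
    except Exception as exc:
        raise StageError(f"stage 'preprocess' failed: {exc}") from exc

    # ---------------- roi ----------------
    try:
        if cfg["rois"] is not None:
            df = pd.read_csv(cfg["rois"], comment="#")
            rois = roimod.RoiSet.from_centroids(
                list(zip(df["centroid_x_um"], df["centroid_y_um"])),
                (df["diameter_um"] / 2.0).tolist(),
                movie.pixel_size_um, movie.data.shape[1:],
                source="ground_truth")
        else:
            rois = roimod.detect_rois(movie, **cfg["detect"])
        traces = roimod.extract_traces(movie, rois)
        rois, refine_log = roimod.refine_rois(
            rois, traces, frame_rate_hz=movie.frame_rate_hz, **cfg["refine"])
        traces = traces[rois.ids()]
        _write_table(rois.to_frame(), outdir / "rois.csv", tag)
        _write_table(refine_log, outdir / "refine_log.csv", tag)
        _write_table(traces.reset_index(), outdir / "traces.csv", tag)
        summary["stages"]["roi"] = {"n_rois": len(rois)}
    except Exception as exc:
        raise StageError(f"stage 'roi' failed: {exc}") from exc

    # ---------------- events ----------------
    try:
        e = cfg["events"]
        dffs: dict[int, ev.DffTrace] = {}
        events_by_roi: dict[int, list[ev.CalciumEvent]] = {}
        for rid in rois.ids():
            d = ev.compute_dff(traces[rid].to_numpy(float),
                               window_frames=int(e["window_frames"]),
                               alignment=e["alignment"], roi_id=rid,
                               threshold_rule=e["threshold_rule"])
            dffs[rid] = d
            events_by_roi[rid] = ev.detect_peaks(
                d, frame_rate_hz=movie.frame_rate_hz)
        ev_rows = [
            (x.roi_id, x.peak_frame, x.amplitude, x.rise_time_s,
             x.decay_time_s, x.duration_s)
            for evs in events_by_roi.values() for x in evs
        ]
        ev_df = pd.DataFrame(ev_rows, columns=[
            "roi_id", "peak_frame", "amplitude", "rise_s", "decay_s",
            "duration_s"]).sort_values(["roi_id", "peak_frame"])
        _write_table(ev_df, outdir / "events.csv", tag)
        raster = ev.build_raster(events_by_roi, movie.n_frames)
        _write_table(pd.DataFrame(raster.matrix, index=raster.roi_ids),
                     outdir / "raster.csv", tag)
        block_ranges = [b.range for b in manifest.baseline_blocks]
        counts, mean_active = ev.count_active(events_by_roi, block_ranges)
        summary["stages"]["events"] = {
            "n_events": len(ev_rows),
            "active_per_block": counts,
            "mean_active": mean_active,
        }
        if manifest.high_k_block is not None and dffs:
            _, responders = ev.high_k_response(
                list(dffs.values()), manifest.high_k_block.range)
            summary["stages"]["events"]["high_k_responders"] = int(responders.sum())
    except Exception as exc:
        raise StageError(f"stage 'events' failed: {exc}") from exc

    # ---------------- correlation ----------------
    try:
        if len(rois) >= 2:
            signals = {rid: corr.thresholded_signal(dffs[rid]) for rid in rois.ids()}
            cmat, records = corr.pairwise_correlation(signals)
            dists = corr.pair_distances(rois)
            corr.attach_distances(records, dists)
            if records:
                correlated, non_corr, frac = corr.classify_pairs(records)
                summary["fraction_correlated_pct"] = round(frac, 4)
                if correlated and non_corr:
                    summary["distance_comparison"] = corr.compare_distance_distributions(
                        [r.distance_um for r in correlated],
                        [r.distance_um for r in non_corr])
            pair_df = pd.DataFrame(
                [(r.roi_i, r.roi_j, r.pearson_r, r.distance_um, r.correlated)
                 for r in records],
                columns=["roi_i", "roi_j", "r", "distance_um", "correlated"])
            _write_table(pair_df, outdir / "pairs.csv", tag)
            _write_table(cmat.to_frame().reset_index(), outdir / "matrix.csv", tag)
            summary["stages"]["correlation"] = {"n_pairs": len(records)}
    except Exception as exc:
        raise StageError(f"stage 'correlation' failed: {exc}") from exc

    # ---------------- population ----------------
    try:
        if len(rois):
            diam = [r.equivalent_diameter_um for r in rois]
            active = [len(events_by_roi[r.id]) > 0 for r in rois]
            comp = pop.subtype_composition(diam, active)
            _write_table(comp.reset_index(names="size_class"),
                         outdir / "subtype_composition.csv", tag)
            summary["stages"]["population"] = {
                "share_all_pct": comp["share_all_pct"].to_dict(),
                "share_active_pct": comp["share_active_pct"].to_dict(),
            }
        n_total = gt.neurons.__len__() if gt is not None else None
        if n_total:
            summary["pct_active"] = round(
                pop.percent_active(summary["stages"]["events"]["mean_active"],
                                   n_total), 4)
    except Exception as exc:
        raise StageError(f"stage 'population' failed: {exc}") from exc

    # ---------------- render ----------------
    if cfg["render"]:
        try:
            from .render import save_matrix_png, save_raster_png, save_temporal_map

            save_temporal_map(movie, outdir / "temporal_map.png",
                              block=manifest.baseline_blocks[0].range)
            if len(rois) >= 2:
                save_matrix_png(cmat.matrix, outdir / "matrix.png")
            save_raster_png(raster.matrix, outdir / "raster.png")
        except Exception as exc:
            raise StageError(f"stage 'render' failed: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary
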