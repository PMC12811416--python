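"""End-to-end orchestration: simulate -> analyze -> summarize.

A single JSON configuration drives a run.  Each stage reads and writes
files inside the run's output directory (inputs may also reference
pre-existing files by absolute path); a manifest capturing the full
configuration, the seed, input hashes and the package version is written
at the end, and an identical configuration plus seed reproduces every
CSV byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import coloc as coloc_mod
from . import gc_morpho, kymo, profiles, sholl, synthetic
from .config import AnalysisConfig
from .io import (load_roi, read_image, read_mask, read_movie, save_roi,
                 write_mask, write_movie, write_table)
from .types import Calibration, PolylineROI

__all__ = ["run_pipeline", "summarize_groups", "per_sample_folds"]


def _calibration(cfg: AnalysisConfig) -> Calibration:
    c = cfg["calibration"]
    return Calibration(c["pixel_size_x_um"], c["pixel_size_y_um"],
                       c.get("frame_interval_s"))


def _resolve(out_dir: Path, name: str) -> Path:
    p = Path(name)
    return p if p.is_absolute() else out_dir / name


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ----------------------------------------------------------------- stages

def _stage_simulate_comets(cfg, stage, out_dir, cal):
    shape = tuple(stage.get("shape", (30, 520)))
    n_frames = int(stage.get("n_frames", 360))
    seed = int(stage.get("seed", cfg["seed"]))
    rng = np.random.default_rng(seed)
    px = cal.pixel_size_um
    y = (shape[0] - 1) / 2.0
    x0, x1 = 10.0, shape[1] - 10.0
    axis = PolylineROI(np.array([[x0, y], [x1, y]]), width_um=1.0)
    axis_len = (x1 - x0) * px
    total = n_frames * cal.require_time()
    comets = synthetic.random_comets(rng, int(stage.get("n_comets", 50)),
                                     axis_len, total,
                                     amplitude=float(stage.get("amplitude", 100.0)))
    spots = tuple(synthetic.StaticSpot(x=rng.uniform(x0, x1), y=y,
                                       amplitude=float(stage.get("amplitude", 100.0)))
                  for _ in range(int(stage.get("n_static_spots", 5))))
    noise_sd = float(stage.get("noise_sd", stage.get("amplitude", 100.0) / 5.0))
    movie, truth = synthetic.make_comet_movie(axis, comets, spots, shape,
                                              n_frames, cal,
                                              noise_sd=noise_sd, seed=seed)
    write_movie(movie, _resolve(out_dir, stage.get("out_movie", "movie.tif")))
    save_roi(axis, _resolve(out_dir, stage.get("out_axis", "axis.json")))
    truth_rows = [{"start_time_s": c.start_time_s, "start_pos_um": c.start_pos_um,
                   "velocity_um_s": c.velocity_um_s, "lifetime_s": c.lifetime_s}
                  for c in truth.comets]
    write_table(truth_rows, _resolve(out_dir, stage.get("out_truth", "comet_truth.csv")))


def _stage_kymo(cfg, stage, out_dir, cal):
    movie = read_movie(_resolve(out_dir, stage["movie"]), cal)
    roi = load_roi(_resolve(out_dir, stage["roi"]))
    params = kymo.SeparationParams(cfg["kymo"]["sigma_mobile"],
                                   cfg["kymo"]["sigma_static"])
    separated = kymo.separate_mobile_static(movie, params)
    kg = kymo.build_kymograph(separated, roi)
    if "dashes" in stage:       # manually traced dashes bypass detection
        df = pd.read_csv(_resolve(out_dir, stage["dashes"]))
        dashes = [kymo.Dash(r.x0, r.y0, r.x1, r.y1) for r in df.itertuples()]
    else:
        dashes = kymo.detect_dashes(kg, threshold=cfg["kymo"]["threshold"],
                                    min_dash_len_px=cfg["kymo"]["min_dash_len_px"])
    dash_rows = [{"x0": d.x0, "y0": d.y0, "x1": d.x1, "y1": d.y1,
                  "length_px": d.length_px, "theta_rad": d.theta_rad}
                 for d in dashes]
    write_table(dash_rows, _resolve(out_dir, stage.get("out_dashes", "dashes.csv")),
                columns=["x0", "y0", "x1", "y1", "length_px", "theta_rad"])
    params_list = [kymo.dash_params(d, kg) for d in dashes]
    rows = [{"track_length_um": p.track_length_um, "lifetime_s": p.lifetime_s,
             "growth_rate_um_per_s": p.growth_rate_um_per_s} for p in params_list]
    write_table(rows, _resolve(out_dir, stage.get("out_params", "comet_params.csv")),
                columns=["track_length_um", "lifetime_s", "growth_rate_um_per_s"])
    if params_list:
        write_table([kymo.summarize_dynamics(params_list)],
                    _resolve(out_dir, stage.get("out_summary", "dynamics_summary.csv")))


def _stage_sholl(cfg, stage, out_dir, cal):
    block = cfg["sholl"]
    mask = read_mask(_resolve(out_dir, stage["mask"]), cal)
    center = stage.get("center", block["center"])
    if center is None:
        raise ValueError("sholl stage needs a center")
    params = sholl.ShollParams(center=tuple(center),
                               direction=tuple(stage.get("direction", block["direction"])),
                               radius_step_um=stage.get("step", block["radius_step_um"]),
                               r_max_um=stage.get("r_max", block["r_max_um"]),
                               bin_edges_um=tuple(stage.get("bins", block["bin_edges_um"])))
    profile = sholl.sholl_intersections(mask, params)
    write_table(pd.DataFrame({"radius_um": profile.radii_um, "count": profile.counts}),
                _resolve(out_dir, stage.get("out_profile", "sholl_profile.csv")))
    sums = sholl.bin_sums(profile)
    write_table(pd.DataFrame({"lo_um": [b[0] for b in sums.bins],
                              "hi_um": [b[1] for b in sums.bins],
                              "sum": sums.sums}),
                _resolve(out_dir, stage.get("out_sums", "sholl_bins.csv")))


def _stage_gc(cfg, stage, out_dir, cal):
    mask = read_mask(_resolve(out_dir, stage["mask"]), cal)
    params = gc_morpho.GCParams(cfg["gc"]["min_filopodium_len_um"],
                                cfg["gc"]["prune_len_um"])
    m = gc_morpho.measure_growth_cone(mask, params)
    write_table([{"area_um2": m.area_um2, "perimeter_um": m.perimeter_um,
                  "elongation_ratio": m.elongation_ratio, "lsp_um": m.lsp_um,
                  "n_filopodia": m.n_filopodia}],
                _resolve(out_dir, stage.get("out", "gc_metrics.csv")))


def _stage_profile(cfg, stage, out_dir, cal):
    block = cfg["profile"]
    image = read_image(_resolve(out_dir, stage["image"]), cal)
    roi = load_roi(_resolve(out_dir, stage["roi"]))
    prof = profiles.extract_profile(image, roi, length_um=block["length_um"])
    prof = profiles.subtract_background(prof, stage.get("background",
                                                        block["background"]))
    mode = stage.get("baseline_mode", block["baseline_mode"])
    rows = {"distance_um": prof.distances_um, "intensity": prof.values}
    if mode != "none":
        corrected = profiles.correct_baseline(prof, mode,
                                              tuple(block["distal_window_um"]))
        rows["corrected"] = corrected.values
    write_table(pd.DataFrame(rows),
                _resolve(out_dir, stage.get("out_profile", "profile.csv")))
    summary = {"integral": profiles.integrate(prof, 0.0, block["length_um"]),
               "terminal_fraction_pct": profiles.terminal_fraction(
                   prof, block["terminal_window_um"])}
    write_table([summary], _resolve(out_dir, stage.get("out_summary",
                                                       "profile_summary.csv")))


def _stage_coloc(cfg, stage, out_dir, cal):
    ch1 = read_image(_resolve(out_dir, stage["ch1"]), cal)
    ch2 = read_image(_resolve(out_dir, stage["ch2"]), cal)
    res = coloc_mod.manders(ch1, ch2, stage.get("thr1", cfg["coloc"]["thr1"]),
                            stage.get("thr2", cfg["coloc"]["thr2"]))
    write_table([{"M1": res.M1, "M2": res.M2, "thr1": res.thr1, "thr2": res.thr2,
                  "variant": res.variant}],
                _resolve(out_dir, stage.get("out", "coloc.csv")))


def _stage_puncta(cfg, stage, out_dir, cal):
    image = read_image(_resolve(out_dir, stage["image"]), cal)
    mask = read_mask(_resolve(out_dir, stage["mask"]), cal)
    block = cfg["puncta"]
    res = coloc_mod.count_puncta(image, mask,
                                 stage.get("threshold", block["threshold"]),
                                 block["min_area_px"], block["max_area_px"])
    write_table([{"count": res.count, "mask_area_um2": res.mask_area_um2,
                  "density_per_um2": res.density_per_um2}],
                _resolve(out_dir, stage.get("out", "puncta.csv")))


_STAGES = {
    "simulate_comets": _stage_simulate_comets,
    "kymo": _stage_kymo,
    "sholl": _stage_sholl,
    "gc": _stage_gc,
    "profile": _stage_profile,
    "coloc": _stage_coloc,
    "puncta": _stage_puncta,
}


def run_pipeline(cfg: AnalysisConfig | dict, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in order and write a manifest.

    Stage errors are re-raised with the stage name; outputs written
    before the failure are retained next to a failure marker.
    """
    if isinstance(cfg, dict):
        cfg = AnalysisConfig.from_dict(cfg)
    out_dir = Path(out_dir if out_dir is not None else cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    cal = _calibration(cfg)
    input_hashes: dict[str, str] = {}
    for i, stage in enumerate(cfg["stages"]):
        kind = stage.get("stage")
        if kind not in _STAGES:
            raise ValueError(f"stage {i}: unknown stage kind {kind!r}")
        for key in ("movie", "roi", "mask", "image", "ch1", "ch2", "dashes"):
            if key in stage:
                p = _resolve(out_dir, stage[key])
                if not p.exists():
                    raise FileNotFoundError(f"stage {i} ({kind}): missing input {p}")
                input_hashes[str(p)] = _hash_file(p)
        try:
            _STAGES[kind](cfg, stage, out_dir, cal)
        except Exception as exc:
            (out_dir / "FAILED").write_text(f"stage {i} ({kind}): {exc}\n")
            raise RuntimeError(f"stage {i} ({kind}) failed: {exc}") from exc
    manifest = {"config": cfg.data, "seed": cfg["seed"],
                "input_hashes": input_hashes, "version": __version__}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return out_dir


def summarize_groups(table: pd.DataFrame, group_col: str, control_label,
                     value_cols: list[str] | None = None) -> pd.DataFrame:
    """Per-group n / mean / SE plus per-group fold change vs the control mean.

    SE = sd / sqrt(n) (sample sd, ddof=1; 0 for n = 1).  Fold change of
    a group is its mean divided by the control group's mean, so the
    control group folds to exactly 1.  Row order of the input is
    irrelevant.
    """
    if control_label not in set(table[group_col]):
        raise ValueError(f"control group {control_label!r} missing from table")
    if value_cols is None:
        value_cols = [c for c in table.columns
                      if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    groups = sorted(table[group_col].unique(), key=str)
    for g in groups:
        sub = table[table[group_col] == g]
        row: dict = {"group": g, "n": len(sub)}
        for c in value_cols:
            v = sub[c].to_numpy(dtype=float)
            ctrl_mean = table.loc[table[group_col] == control_label, c].mean()
            row[f"{c}_mean"] = float(v.mean())
            row[f"{c}_se"] = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
            row[f"{c}_fold_vs_control"] = float(v.mean() / ctrl_mean)
        rows.append(row)
    return pd.DataFrame(rows)


def per_sample_folds(table: pd.DataFrame, group_col: str, control_label,
                     value_col: str) -> pd.Series:
    """Each sample's value normalized to the control group's mean."""
    ctrl = table.loc[table[group_col] == control_label, value_col]
    if ctrl.empty:
        raise ValueError(f"control group {control_label!r} missing from table")
    return table[value_col] / ctrl.mean()
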