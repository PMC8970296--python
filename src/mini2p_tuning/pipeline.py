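"""End-to-end orchestration: simulate -> signal -> tracking -> classify.

``RunConfig`` collects every stage parameter with its standard default
(2.5 cm bins, 3 cm smoothing, 2.5 cm/s speed floor, 30 s shuffle margins,
95th-percentile thresholds, SNR > 3 and > 100 events for eligibility,
1.5 s indicator decay, the plane/FOV dedup thresholds) plus the mandatory
seed.  ``run_pipeline`` executes the stages on a synthetic session and
writes a verdict table, a summary and a provenance record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import signal as sig
from .align import align_planes, eligibility
from .classify import (SessionContext, classify_grid_cell, classify_hd_cell,
                       classify_place_cell, conjunctive_flag)
from .synthetic import (ArenaSpec, CalciumModel, Mobility, TuningModel,
                        simulate_session)

REGION_PRESETS = {
    "vc": {"n_perm": 200, "min_field_rate": 0.1, "classifiers": ("place", "head_direction")},
    "ca1": {"n_perm": 1000, "min_field_rate": 0.02, "classifiers": ("place",)},
    "mec": {"n_perm": 1000, "min_field_rate": 0.1, "classifiers": ("grid", "head_direction")},
}


@dataclass
class RunConfig:
    """Full parameter set of one pipeline run; defaults are the standard
    analysis constants."""

    seed: int = 0
    region: str = "vc"
    # arena / session
    arena_width_cm: float = 80.0
    arena_height_cm: float = 80.0
    frame_rate_hz: float = 15.0
    duration_s: float = 1800.0
    n_planes: int = 1
    # synthetic population
    n_place: int = 2
    n_grid: int = 2
    n_hd: int = 2
    n_untuned: int = 2
    # signal stage
    neuropil_coefficient: float = 0.7
    decay_s: float = 1.5
    baseline_window_s: float = 15.0
    baseline_percentile: float = 8.0
    transient_k_sigma: float = 2.0
    transient_min_duration_s: float = 0.75
    # maps / classification
    bin_cm: float = 2.5
    smooth_sd_cm: float = 3.0
    speed_floor_cm_s: float = 2.5
    min_visit_s: float = 0.1
    shuffle_margin_s: float = 30.0
    percentile: float = 95.0
    snr_min: float = 3.0
    events_min: int = 100
    # dedup
    plane_d_max_um: float = 15.0
    plane_overlap_min: float = 0.5
    plane_corr_min: float = 0.5
    fov_overlap_min: float = 0.75
    stitch_max_shift_px: int = 5

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _default_models(cfg: RunConfig, rng: np.random.Generator) -> list:
    models = []
    w, h = cfg.arena_width_cm, cfg.arena_height_cm
    for _ in range(cfg.n_place):
        models.append(TuningModel("place", {
            "center_cm": (rng.uniform(0.2 * w, 0.8 * w), rng.uniform(0.2 * h, 0.8 * h)),
            "width_cm": 8.0, "peak_rate_hz": 5.0}, baseline_rate_hz=0.2))
    for _ in range(cfg.n_grid):
        models.append(TuningModel("grid", {
            "spacing_cm": rng.uniform(35.0, 45.0),
            "orientation_deg": rng.uniform(0.0, 60.0),
            "phase_cm": (rng.uniform(0, w), rng.uniform(0, h)),
            "peak_rate_hz": 5.0}, baseline_rate_hz=0.05))
    for _ in range(cfg.n_hd):
        models.append(TuningModel("head_direction", {
            "preferred_deg": rng.uniform(0, 360), "concentration": 4.0,
            "peak_rate_hz": 3.0}, baseline_rate_hz=0.2))
    for _ in range(cfg.n_untuned):
        models.append(TuningModel("untuned", baseline_rate_hz=0.5))
    return models


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute the full stack on a seeded synthetic session.

    Returns the summary dict; writes verdicts.csv, summary.json and
    provenance.json under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preset = REGION_PRESETS[cfg.region]
    rng = np.random.default_rng(cfg.seed)

    arena = ArenaSpec(cfg.arena_width_cm, cfg.arena_height_cm,
                      cfg.frame_rate_hz, cfg.duration_s)
    session = simulate_session(arena, _default_models(cfg, rng),
                               CalciumModel(amplitude_scale=25.0, noise_sd=0.5,
                                            neuropil_fraction=0.3),
                               Mobility(), seed=cfg.seed, n_planes=cfg.n_planes)

    rows = []
    contexts: dict = {}
    for cell in session.cells:
        act = sig.process_trace(
            cell.raw, cell.neuropil, arena.frame_rate_hz / cfg.n_planes,
            neuropil_coefficient=cfg.neuropil_coefficient, decay_s=cfg.decay_s,
            window_s=cfg.baseline_window_s, percentile=cfg.baseline_percentile,
            k_sigma=cfg.transient_k_sigma,
            min_duration_s=cfg.transient_min_duration_s)
        elig = eligibility(act.snr, act.n_events, cfg.snr_min, cfg.events_min)
        if cell.plane not in contexts:
            _, sub = align_planes(len(cell.raw), session.tracking, cell.plane,
                                  cfg.n_planes)
            contexts[cell.plane] = SessionContext(
                x=sub.x, y=sub.y, speed=sub.speed, direction=sub.direction,
                frame_rate_hz=sub.frame_rate_hz,
                extent_cm=(arena.width_cm, arena.height_cm),
                bin_cm=cfg.bin_cm, smooth_sd_cm=cfg.smooth_sd_cm,
                speed_floor=cfg.speed_floor_cm_s, min_visit_s=cfg.min_visit_s)
        ctx = contexts[cell.plane]
        cell_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 7919, cell.cell_id]))
        row = {"cell_id": cell.cell_id, "plane": cell.plane,
               "true_kind": cell.model.kind, "snr": act.snr,
               "n_events": act.n_events, "eligible": elig["eligible"]}
        verdicts = {}
        common = dict(cell_id=cell.cell_id, eligible=elig["eligible"],
                      snr=act.snr, margin_s=cfg.shuffle_margin_s,
                      percentile=cfg.percentile)
        if "place" in preset["classifiers"]:
            verdicts["place"] = classify_place_cell(
                act.events_clear, ctx, cell_rng, n_perm=preset["n_perm"],
                min_field_rate=preset["min_field_rate"], **common)
        if "head_direction" in preset["classifiers"]:
            verdicts["head_direction"] = classify_hd_cell(
                act.events_clear, ctx, cell_rng, n_perm=preset["n_perm"], **common)
        if "grid" in preset["classifiers"]:
            verdicts["grid"] = classify_grid_cell(
                act.events_clear, ctx, cell_rng, n_perm=preset["n_perm"], **common)
        for name, v in verdicts.items():
            row[name] = bool(v.flags.get(name, False))
            for cname, res in v.criteria.items():
                row[f"{name}_{cname}"] = res.statistic
        if "grid" in verdicts and "head_direction" in verdicts:
            row["conjunctive"] = conjunctive_flag(verdicts["grid"],
                                                  verdicts["head_direction"])
        rows.append(row)

    verdict_table = pd.DataFrame(rows)
    verdict_table.to_csv(out / "verdicts.csv", index=False)
    summary = summarize(verdict_table)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "provenance.json").write_text(json.dumps({
        "seed": cfg.seed, "config_digest": cfg.digest(),
        "n_cells": len(session.cells), "region": cfg.region}, indent=2))
    return summary


def summarize(verdicts: pd.DataFrame) -> dict:
    """Counts and fractions per flag, on the eligible denominator."""
    flags = [c for c in ("place", "head_direction", "grid", "conjunctive")
             if c in verdicts.columns]
    if len(verdicts) == 0:
        return {"n_cells": 0, "n_eligible": 0,
                **{f"n_{f}": 0 for f in flags},
                **{f"frac_{f}": 0.0 for f in flags}}
    elig = verdicts["eligible"].astype(bool)
    n_elig = int(elig.sum())
    summary = {"n_cells": int(len(verdicts)), "n_eligible": n_elig}
    for f in flags:
        n = int((verdicts[f].fillna(False).astype(bool) & elig).sum())
        summary[f"n_{f}"] = n
        summary[f"frac_{f}"] = n / n_elig if n_elig else 0.0
    return summary
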