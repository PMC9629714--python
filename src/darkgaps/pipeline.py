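"""Pipeline configuration, validation and one-command orchestration.

Stages run in order simulate -> reception -> classify -> allocate ->
drivers; any prefix can be skipped by supplying its outputs as inputs.  A
single global seed deterministically derives per-stage seeds (SHA-256 of
"<seed>:<stage>", truncated below 2^31) so each stage is individually
reproducible.  The manifest records output paths, SHA-256 hashes, seeds and
the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import allocation as alloc
from . import drivers_brt as brt
from . import gap_classifier as gc
from . import reception as rc
from . import synthetic as syn
from .grid import GridSpec, Raster

log = logging.getLogger("darkgaps")


def derive_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters with the published defaults: 12 h minimum gap,
    50 nmi shore filter, >10 positions/day reception, rule model 12 h/k=14,
    336 h cap, 1:1 presence/absence, 50 iterations of 75/25 CV, 400 km
    distance clip."""
    out_dir: str = "darkgaps_out"
    messages_path: str | None = None
    truth_path: str | None = None
    seed: int = 0
    # simulate
    n_vessels: int = 30
    days: int = 60
    # reception
    obs_cell_deg: float = 1.0
    pred_cell_deg: float = 0.25
    # classify
    min_gap_h: float = 12.0
    min_shore_nmi: float = 50.0
    min_reception: float = 10.0
    rule_lookback_h: int = 12
    rule_k: int = 14
    rule_reception_min: float = 10.0
    select_model: bool = False
    cv_folds: int = 5
    cv_repeats: int = 10
    # allocate
    cap_h: float = 336.0
    max_speed_knots: float = 10.0
    # drivers
    brt_iterations: int = 50
    brt_train_frac: float = 0.75
    world: syn.WorldConfig = field(default_factory=syn.WorldConfig)
    fleet: syn.FleetConfig = field(default_factory=syn.FleetConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as e:
                mark = getattr(e, "problem_mark", None)
                line = f" at line {mark.line + 1}" if mark else ""
                raise ValueError(f"cannot parse {path}{line}: {e}") from e
        world = raw.pop("world", {})
        fleet = raw.pop("fleet", {})
        if "reception_bumps" in world:
            world["reception_bumps"] = tuple(
                syn.GaussianBump(**b) for b in world["reception_bumps"])
        if "driver_specs" in world:
            world["driver_specs"] = {k: syn.DriverFieldSpec(**v)
                                     for k, v in world["driver_specs"].items()}
        if "movement" in fleet:
            fleet["movement"] = syn.MovementConfig(**fleet["movement"])
        if "disabling" in fleet:
            fleet["disabling"] = syn.DisablingModel(**fleet["disabling"])
        return cls(world=syn.WorldConfig(**world),
                   fleet=syn.FleetConfig(**fleet), **raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violation strings; empty iff the config is valid."""
    v: list[str] = []
    if config.cap_h is not None and config.cap_h <= 0:
        v.append("cap_h: must be > 0")
    if config.min_gap_h <= 0:
        v.append("min_gap_h: must be > 0")
    if config.min_shore_nmi < 0:
        v.append("min_shore_nmi: must be >= 0")
    if config.rule_k < 1:
        v.append("rule_k: must be >= 1")
    if not (0 < config.brt_train_frac < 1):
        v.append("brt_train_frac: must be in (0, 1)")
    if config.brt_iterations < 1:
        v.append("brt_iterations: must be >= 1")
    if config.max_speed_knots <= 0:
        v.append("max_speed_knots: must be > 0")
    if config.messages_path is not None and not Path(config.messages_path).exists():
        v.append(f"messages_path: file not found ({config.messages_path})")
    for name, mix in (("gear_mix", config.fleet.gear_mix),
                      ("flag_mix", config.fleet.flag_mix),
                      ("device_class_mix", config.fleet.device_class_mix)):
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            v.append(f"fleet.{name}: proportions sum to {total}, expected 1")
    if config.fleet.n_vessels < 1:
        v.append("fleet.n_vessels: must be >= 1")
    span_ok = True
    try:
        GridSpec(config.world.west, config.world.south, config.world.east,
                 config.world.north, config.world.cell_size_deg)
    except Exception as e:
        span_ok = False
        v.append(f"world: {e}")
    if span_ok and config.world.reception_background < 0:
        v.append("world.reception_background: must be >= 0")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the output manifest."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "files": {}}

    def _record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = {"seed": derive_seed(config.seed, stage)}
        for k, p in paths.items():
            manifest["files"][f"{stage}.{k}"] = {
                "path": str(p), "sha256": _sha256(Path(p))}

    # -- simulate ---------------------------------------------------------
    stage = "simulate"
    world = syn.build_world(dataclasses.replace(
        config.world, seed=derive_seed(config.seed, "world")))
    if config.messages_path:
        messages = syn.read_messages(config.messages_path)
        truth = syn.read_truth(config.truth_path) if config.truth_path else None
        log.info("loaded %d messages from %s", len(messages), config.messages_path)
    else:
        fleet = dataclasses.replace(config.fleet, n_vessels=config.n_vessels,
                                    seed=derive_seed(config.seed, stage))
        messages, truth = syn.simulate_fleet(world, fleet, config.days)
        log.info("simulated %d messages, %d planted disabling events",
                 len(messages), len(truth))
    paths = syn.write_fixture(messages, truth if truth is not None
                              else pd.DataFrame(columns=syn.TRUTH_COLUMNS), out)
    paths["shore"] = world.shore_distance_km.write_ascii(out / "shore_distance_km.asc")
    for name, r in world.drivers.items():
        paths[f"driver_{name}"] = r.write_ascii(out / f"driver_{name}.asc")
    _record(stage, paths)

    # -- reception --------------------------------------------------------
    stage = "reception"
    observed = rc.observed_reception(messages, config.obs_cell_deg)
    predicted = {dev: rc.predict_reception(g, config.pred_cell_deg)
                 for dev, g in observed.items()}
    paths = {}
    for dev in observed:
        paths[f"obs_{dev}"] = observed[dev].raster.write_ascii(
            out / f"reception_observed_{dev}.asc")
        paths[f"pred_{dev}"] = predicted[dev].raster.write_ascii(
            out / f"reception_predicted_{dev}.asc")
    _record(stage, paths)

    # -- classify ---------------------------------------------------------
    stage = "classify"
    gaps = gc.detect_gaps(messages, config.min_gap_h)
    gaps = gc.filter_gaps(gaps, world.shore_distance_km, predicted,
                          config.min_shore_nmi, config.min_reception,
                          config.min_gap_h)
    paths = {}
    if truth is not None and len(truth):
        gaps = gc.label_gaps(gaps, truth)
    if config.select_model and "truth" in gaps.columns:
        model, table, ev = gc.select_model(
            gaps, gc.default_candidate_grid(), config.cv_folds,
            config.cv_repeats, derive_seed(config.seed, stage))
        table.to_csv(out / "model_selection.csv", index=False)
        paths["model_selection"] = out / "model_selection.csv"
        log.info("selected rule model: lookback %dh, k=%d, reception>%g",
                 model.lookback_h, model.k, model.reception_min)
    else:
        model = gc.RuleModel(config.rule_lookback_h, config.rule_k,
                             config.rule_reception_min)
    gaps = gc.classify(gaps, model)
    gaps.to_csv(out / "gaps.csv", index=False)
    paths["gaps"] = out / "gaps.csv"
    if "truth" in gaps.columns:
        ev = gc.evaluate(gaps)
        with open(out / "eval.json", "w") as fh:
            json.dump({"tp": ev.tp, "fp": ev.fp, "fn": ev.fn, "tn": ev.tn,
                       "precision": ev.precision, "recall": ev.recall,
                       "fpr": ev.fpr, "f05": ev.f_beta,
                       "model": dataclasses.asdict(model)}, fh, indent=2)
        paths["eval"] = out / "eval.json"
    _record(stage, paths)

    # -- allocate ---------------------------------------------------------
    stage = "allocate"
    sus = gaps[gaps["classification"] == gc.SUSPECTED]
    grid = world.spec
    activity = alloc.activity_hours(messages, grid)
    acfg = alloc.AllocationConfig(cap_h=config.cap_h,
                                  max_speed_knots=config.max_speed_knots)
    linear = alloc.allocate_gaps(sus, grid, "linear", cap_h=config.cap_h)
    prob = alloc.allocate_gaps(sus, grid, "probabilistic", cap_h=config.cap_h,
                               config=acfg, prior=activity)
    frac = alloc.fraction_obscured(linear, activity)
    paths = {"activity": activity.write_ascii(out / "vessel_activity_h.asc"),
             "linear": linear.write_ascii(out / "disabling_time_linear_h.asc"),
             "prob": prob.write_ascii(out / "disabling_time_prob_h.asc"),
             "fraction": frac.write_ascii(out / "fraction_obscured.asc")}
    summary = alloc.summarize_disabling(gaps, messages, grid, by="gear",
                                        cap_h=config.cap_h)
    summary.to_csv(out / "table1_summary.csv", index=False)
    paths["summary"] = out / "table1_summary.csv"
    _record(stage, paths)

    # -- drivers ----------------------------------------------------------
    stage = "drivers"
    stack = brt.DriverStack.from_world(world)
    seed = derive_seed(config.seed, stage)
    paths = {}
    try:
        def factory(s: int) -> pd.DataFrame:
            return brt.build_dataset(linear, activity, stack, seed=s)

        fit = brt.fit_brt(factory(seed), seed=seed)
        report = brt.evaluate_brt(factory, n_iter=config.brt_iterations,
                                  train_frac=config.brt_train_frac, seed=seed)
        fit.relative_importance.rename_axis("driver").reset_index().to_csv(
            out / "importance.csv", index=False)
        fit.partial_dependence.to_csv(out / "pdp.csv", index=False)
        with open(out / "brt_eval.json", "w") as fh:
            json.dump(dataclasses.asdict(report), fh, indent=2)
        paths = {"importance": out / "importance.csv",
                 "pdp": out / "pdp.csv", "eval": out / "brt_eval.json"}
    except brt.DriverModelError as e:
        log.warning("driver model skipped: %s", e)
        manifest["stages"]["drivers"] = {"skipped": str(e)}
    if paths:
        _record(stage, paths)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
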