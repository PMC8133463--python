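"""Configuration-driven end-to-end runner for the synthetic climate-envelope study.

Stages: generate the synthetic world -> assemble the training set -> radial
leave-one-segment-out evaluation of every algorithm -> select algorithms by
AUC cutoff -> delta-AUC importance -> refit the selected algorithms on all
data -> current + future projections -> scenario range table. All artifacts
(CSV tables, text rasters, a JSON run manifest) land in one run directory.

One global seed fans out deterministically to per-stage seeds via
numpy's SeedSequence, so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .evaluation import (
    delta_auc_importance,
    loocv_predict,
    max_kappa_threshold,
    radial_segments,
    select_algorithms,
)
from .grids import ClimateGrid, ScenarioSpec, write_ascii_raster
from .models import ALGORITHM_IDS, AlgorithmSpec, SdmModel, fit, predict
from .occurrence import (
    assemble_training_set,
    sample_pseudo_absences,
    transect_absence_midpoints,
    write_records_csv,
    write_transects_csv,
    records_to_frame,
)
from .projection import (
    ensemble_mean_surface,
    project_surface,
    range_table_to_frame,
    scenario_range_table,
)
from .synthetic import (
    DEFAULT_GCM_IDS,
    SyntheticWorldConfig,
    default_gcm_deltas,
    generate_climate_grid,
    generate_future_grid,
    sample_presences,
    simulate_transects,
    true_occupancy,
)

logger = logging.getLogger(__name__)

_STAGES = ("climate", "presences", "transects", "pseudo_absences", "models")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic fan-out of the global seed into per-stage seeds (< 2^31)."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class RunConfig:
    """Every stage's parameters; defaults mirror the study design
    (4,764 pseudo-absences at >=10 km, five radial segments, AUC cutoff 0.6,
    all four RCPs and both horizon years)."""

    synthetic: SyntheticWorldConfig = field(default_factory=SyntheticWorldConfig)
    n_pseudo_absences: int = 4764
    min_dist_km: float = 10.0
    pseudo_region: tuple[float, float, float, float] | None = None  # default: extent
    k_segments: int = 5
    segment_offset_deg: float = 0.0
    algorithms: tuple[str, ...] = ALGORITHM_IDS
    hyperparameters: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    auc_cutoff: float = 0.6
    gcm_ids: tuple[str, ...] = DEFAULT_GCM_IDS
    rcps: tuple[float, ...] = (2.6, 4.5, 6.0, 8.5)
    years: tuple[int, ...] = (2050, 2070)
    seed: int = 0
    output_dir: str = "climenv_run"


def validate_config(raw: Mapping[str, Any] | RunConfig) -> RunConfig:
    """Normalise a raw mapping into a RunConfig, reporting every violation at once."""
    if isinstance(raw, RunConfig):
        cfg_dict = dataclasses.asdict(raw)
    else:
        cfg_dict = dict(raw)
    errors: list[str] = []

    synth_raw = cfg_dict.pop("synthetic", {})
    if isinstance(synth_raw, SyntheticWorldConfig):
        synth = synth_raw
    else:
        synth_raw = dict(synth_raw)
        for key in ("extent", "core_center"):
            if key in synth_raw and isinstance(synth_raw[key], list):
                synth_raw[key] = tuple(synth_raw[key])
        try:
            synth = SyntheticWorldConfig(**synth_raw)
        except (ConfigurationError, TypeError) as exc:
            errors.append(f"synthetic: {exc}")
            synth = SyntheticWorldConfig()

    known = {f.name for f in dataclasses.fields(RunConfig)} - {"synthetic"}
    unknown = set(cfg_dict) - known
    if unknown:
        errors.append(f"unknown config field(s): {sorted(unknown)}")
    kwargs = {k: v for k, v in cfg_dict.items() if k in known}
    for key in ("algorithms", "gcm_ids", "rcps", "years", "pseudo_region"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    cfg = RunConfig(synthetic=synth, **kwargs)

    if cfg.k_segments < 2:
        errors.append("k_segments: must be at least 2")
    if cfg.min_dist_km < 0:
        errors.append("min_dist_km: must be >= 0")
    if cfg.n_pseudo_absences < 0:
        errors.append("n_pseudo_absences: must be >= 0")
    if not (0.0 <= cfg.auc_cutoff <= 1.0):
        errors.append("auc_cutoff: must lie in [0, 1]")
    bad_alg = [a for a in cfg.algorithms if a not in ALGORITHM_IDS]
    if bad_alg:
        errors.append(f"algorithms: unknown id(s) {bad_alg}")
    bad_rcp = [r for r in cfg.rcps if float(r) not in (2.6, 4.5, 6.0, 8.5)]
    if bad_rcp:
        errors.append(f"rcps: unknown value(s) {bad_rcp}")
    bad_year = [y for y in cfg.years if int(y) not in (2050, 2070)]
    if bad_year:
        errors.append(f"years: unknown value(s) {bad_year}")
    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or TOML run configuration file."""
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        import yaml

        raw = yaml.safe_load(path.read_text()) or {}
    elif path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raise ConfigurationError(f"unsupported config format: {path.suffix!r}")
    return validate_config(raw)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _spec_for(cfg: RunConfig, alg: str, seed: int) -> AlgorithmSpec:
    return AlgorithmSpec(alg, cfg.hyperparameters.get(alg, {}), seed=seed)


def run_synthetic_study(
    config: RunConfig | Mapping[str, Any],
    upto: str = "summarize",
    write: bool = True,
) -> dict[str, Any]:
    """Execute the whole study (or a prefix of it) and return the artifacts.

    `upto` is one of synth/assemble/evaluate/importance/project/summarize;
    earlier stages are always (re)computed deterministically from the config.
    With `write=True` every completed stage's artifacts are written under
    `config.output_dir`.
    """
    order = ("synth", "assemble", "evaluate", "importance", "project", "summarize")
    if upto not in order:
        raise ConfigurationError(f"unknown stage {upto!r}; expected one of {order}")
    stop = order.index(upto)
    cfg = validate_config(config)
    seeds = stage_seeds(cfg.seed)
    out = Path(cfg.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    art: dict[str, Any] = {"config": cfg}

    # -- synth ---------------------------------------------------------------
    synth_cfg = dataclasses.replace(cfg.synthetic, seed=seeds["climate"])
    grid = generate_climate_grid(synth_cfg)
    surface = true_occupancy(grid, synth_cfg)
    presences = sample_presences(surface, synth_cfg.n_presence, seeds["presences"])
    transects = simulate_transects(
        surface, synth_cfg.n_transects, synth_cfg.transect_length_km,
        synth_cfg.detection_prob, seeds["transects"],
    )
    n_detected = sum(t.detected for t in transects)
    logger.info("synth: %d presences, %d transects (%d with detections)",
                len(presences), len(transects), n_detected)
    art.update(grid=grid, occupancy=surface, presences=presences, transects=transects)
    if write:
        grid.write_dir(out / "grid_current")
        write_ascii_raster(out / "true_occupancy.asc", grid.geometry, surface.values)
        pd.DataFrame({"lon": [p.lon for p in presences],
                      "lat": [p.lat for p in presences]}).to_csv(
            out / "presences.csv", index=False)
        write_transects_csv(transects, out / "transects.csv")
    if stop == 0:
        return art

    # -- assemble ------------------------------------------------------------
    absences = transect_absence_midpoints(transects)
    region = cfg.pseudo_region or cfg.synthetic.extent
    pseudo = sample_pseudo_absences(
        region, presences, cfg.n_pseudo_absences, cfg.min_dist_km,
        seeds["pseudo_absences"],
    )
    table = assemble_training_set(presences, absences, pseudo, grid)
    logger.info(
        "assemble: %d transect absences + %d pseudo-absences -> %d zero rows; "
        "%d rows total",
        len(absences), len(pseudo), int((table["response"] == 0).sum()), len(table),
    )
    art.update(absences=absences, pseudo_absences=pseudo, table=table)
    if write:
        write_records_csv(absences, out / "transect_absences.csv")
        write_records_csv(pseudo, out / "pseudo_absences.csv")
        table.to_csv(out / "feature_table.csv", index=False)
    if stop == 1:
        return art

    # -- evaluate ------------------------------------------------------------
    segments = radial_segments(table, cfg.k_segments, offset_deg=cfg.segment_offset_deg)
    cv_results = {}
    cv_frames = []
    for alg in cfg.algorithms:
        ev = loocv_predict(_spec_for(cfg, alg, seeds["models"]), table, segments)
        cv_results[alg] = ev
        f = ev.to_frame()
        f.insert(0, "algorithm", alg)
        cv_frames.append(f)
        logger.info("evaluate: %s pooled LOOCV AUC = %.3f", alg, ev.auc)
    cv_aucs = {a: ev.auc for a, ev in cv_results.items()}
    selected = select_algorithms(cv_aucs, cfg.auc_cutoff)
    logger.info("evaluate: selected %s (AUC > %.2f)", selected, cfg.auc_cutoff)
    art.update(segments=segments, cv_results=cv_results, cv_aucs=cv_aucs,
               selected=selected)
    if write:
        pd.concat(cv_frames).to_csv(out / "cv_predictions.csv", index=False)
        pd.DataFrame(
            {"algorithm": list(cv_aucs), "loocv_auc": list(cv_aucs.values()),
             "selected": [a in selected for a in cv_aucs]}
        ).to_csv(out / "cv_auc.csv", index=False)
    if stop == 2:
        return art

    # -- importance ----------------------------------------------------------
    importance = {}
    imp_frames = []
    for alg in selected:
        imp = delta_auc_importance(_spec_for(cfg, alg, seeds["models"]), table,
                                   segments)
        importance[alg] = imp
        f = imp.to_frame()
        f.insert(0, "algorithm", alg)
        imp_frames.append(f)
    art["importance"] = importance
    if write and imp_frames:
        pd.concat(imp_frames).to_csv(out / "variable_importance.csv", index=False)
    if stop == 3:
        return art

    # -- project -------------------------------------------------------------
    models: dict[str, SdmModel] = {}
    thresholds = {}
    for alg in selected:
        model = fit(_spec_for(cfg, alg, seeds["models"]), table)
        models[alg] = model
        p_current = predict(model, table)
        thresholds[alg] = max_kappa_threshold(table["response"].to_numpy(), p_current)
        logger.info("project: %s max-kappa threshold = %.3f (kappa %.3f)",
                    alg, thresholds[alg].threshold, thresholds[alg].kappa)
    scenario_grids = []
    for rcp in cfg.rcps:
        for year in cfg.years:
            deltas = default_gcm_deltas(float(rcp), int(year), cfg.gcm_ids)
            for gcm, delta in deltas.items():
                scen = ScenarioSpec(gcm=gcm, rcp=float(rcp), year=int(year))
                scenario_grids.append(generate_future_grid(grid, delta, scen))
    art.update(models=models, thresholds=thresholds, scenario_grids=scenario_grids)
    if write:
        pd.DataFrame(
            [
                {"algorithm": a, "threshold": t.threshold, "kappa": t.kappa,
                 "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn}
                for a, t in thresholds.items()
            ]
        ).to_csv(out / "thresholds.csv", index=False)
        for alg, model in models.items():
            model.save(out / f"model_{alg}.pkl")
    if stop == 4:
        return art

    # -- summarize -----------------------------------------------------------
    estimates = scenario_range_table(models, thresholds, scenario_grids, grid)
    range_table = range_table_to_frame(estimates)
    art.update(range_estimates=estimates, range_table=range_table)
    for e in estimates:
        logger.info("summarize: %s mean area %.0f km^2 (percent left: %s)",
                    e.scenario, e.mean_area_km2, e.percent_left)
    if write:
        range_table.to_csv(out / "range_table.csv", index=False)
        if models:
            current_surfaces = [project_surface(m, grid) for m in models.values()]
            ens = ensemble_mean_surface(current_surfaces)
            write_ascii_raster(out / "ensemble_current.asc", grid.geometry, ens.values)
            for rcp in cfg.rcps:
                for year in cfg.years:
                    members = [
                        project_surface(m, g)
                        for m in models.values()
                        for g in scenario_grids
                        if g.scenario.rcp == float(rcp)
                        and g.scenario.year == int(year)
                    ]
                    if members:
                        ens = ensemble_mean_surface(members)
                        write_ascii_raster(
                            out / f"ensemble_rcp{rcp}_{year}.asc",
                            grid.geometry, ens.values,
                        )
        manifest = {
            "package_version": __version__,
            "python": sys.version.split()[0],
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "config_hash": _config_hash(cfg),
            "config": dataclasses.asdict(cfg),
            "n_presence": len(presences),
            "n_transect_absences": len(absences),
            "n_pseudo_absences": len(pseudo),
            "cv_auc": cv_aucs,
            "selected_algorithms": selected,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return art
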