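"""End-to-end orchestration: simulate -> partition -> model -> project -> refugia.

Every stage is a pure function of its declared inputs and the run seed, so a
rerun with the same config produces bit-identical tables. Artifacts are
plain text: CSV tables, ASCII-grid rasters, JSON summaries, a YAML copy of
the resolved config and a JSON-lines log.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climatic_partition as cp
from . import ensemble_projection as ep
from . import evaluation as ev
from . import grid_io
from . import refugia as rf
from . import synthetic_world as sw
from .config import RunConfig
from .sdm_methods import FAMILIES

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_all"]


@dataclass
class PipelineResult:
    config: RunConfig
    domain: sw.DomainSpec
    cells: pd.DataFrame
    scenarios: dict
    partitions: dict  # gcm -> (DecisionTreeModel, LeafPartition)
    forest_reports: dict
    sensitivity: dict
    runs: dict  # gcm -> ModelRun
    metrics: pd.DataFrame
    selected_methods: list
    registry: pd.DataFrame
    current_consensus: dict  # category -> 2-D bool
    future_consensus: dict  # rcp -> category -> 2-D bool
    current_by_gcm: dict = field(default_factory=dict)
    future_by_gcm: dict = field(default_factory=dict)
    reports: dict = field(default_factory=dict)  # rcp -> RefugeReport
    uncertainty: dict = field(default_factory=dict)


def _to_grid(surface_vector: np.ndarray, cell_ids: np.ndarray, domain: sw.DomainSpec):
    grid = np.zeros(domain.n_cells, dtype=surface_vector.dtype)
    grid[np.asarray(cell_ids, dtype=int)] = surface_vector
    return grid.reshape(domain.shape)


def _stage(log_path: Path | None, name: str, t0: float, **counts) -> None:
    entry = {"stage": name, "wall_s": round(time.time() - t0, 3), **counts}
    logger.info("stage %s done in %.1fs %s", name, entry["wall_s"], counts)
    if log_path is not None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full pipeline under one config and seed.

    Stage order: synthesize world, per-GCM tree partition (CV-pruned) with
    forest check and anthropogenic sensitivity, per-GCM distribution models
    on the 25 % sample with 10 replicates, holdout validation and adequate-
    method selection, projection to each RCP, leaf-to-category aggregation,
    cross-GCM consensus, refuge report.
    """
    out = Path(out_dir) if out_dir is not None else None
    log_path = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        log_path = out / "log.jsonl"
        log_path.write_text("")

    syn = config.synthetic
    seed = config.seed

    # ---- simulate -------------------------------------------------------
    t0 = time.time()
    domain = sw.DomainSpec(
        syn.lat_min, syn.lat_max, syn.lon_min, syn.lon_max, syn.cell_size
    )
    rules = sw.default_rules()
    scenarios = sw.default_scenarios()
    gcms = sorted(scenarios)
    baseline = sw.generate_climate(
        domain,
        scenarios[gcms[0]]["baseline"],
        noise_sd=syn.noise_sd,
        seed=seed,
        smooth_sigma=syn.smooth_sigma,
    )
    landcover = sw.generate_landcover(baseline, rules)
    cells = sw.apply_anthropogenic(landcover, baseline, hotspots=syn.hotspots, seed=seed)
    lat2d, lon2d = domain.center_grids()
    areas2d = grid_io.cell_area_km2(lat2d, domain.cell_size)
    if out is not None:
        grid_io.write_cells(out / "cells.csv", cells)
    _stage(log_path, "simulate", t0, n_cells=len(cells))

    # ---- partition ------------------------------------------------------
    t0 = time.time()
    control = cp.TreeControl(
        min_node_size=config.partition.min_node_size,
        cv_reps=config.partition.cv_reps,
        cv_folds=config.partition.cv_folds,
        use_1se=config.partition.use_1se,
    )
    climate_vars = list(sw.BIOCLIM_VARIABLES)
    partitions: dict[str, tuple[cp.DecisionTreeModel, cp.LeafPartition]] = {}
    forest_reports: dict[str, cp.ForestReport] = {}
    for gi, gcm in enumerate(gcms):
        full = cp.fit_tree(cells, climate_vars, control, gcm_id=gcm)
        pruned = cp.prune_by_cv(full, cells, seed=seed + gi)
        partition = cp.assign_leaves(pruned, cells)
        partitions[gcm] = (pruned, partition)
        forest_reports[gcm] = cp.random_forest_check(
            cells, climate_vars, n_trees=config.partition.rf_trees, seed=seed + gi
        )
        if out is not None:
            pruned.to_json(out / f"tree_{gcm}.json")
            partition.to_csv(out / f"partition_{gcm}.csv")
    sensitivity = cp.anthropogenic_sensitivity(
        cells, climate_vars, fraction_cutoff=0.5, n_trees=200, seed=seed
    )
    _stage(
        log_path,
        "partition",
        t0,
        leaves={g: partitions[g][1].assignments["leaf_id"].nunique() for g in gcms},
    )

    # ---- model ----------------------------------------------------------
    t0 = time.time()
    runs: dict[str, ep.ModelRun] = {}
    metrics_frames = []
    for gi, gcm in enumerate(gcms):
        model, partition = partitions[gcm]
        design = ep.make_design(
            cells,
            sample_frac=config.modeling.sample_frac,
            calib_frac=config.modeling.calib_frac,
            n_reps=config.modeling.n_replicates,
            seed=seed,
        )
        run = ep.fit_all(
            cells,
            partition,
            design,
            variables=model.selected_variables(),
            methods=config.modeling.methods,
            hyperparams=config.modeling.hyperparams,
            seed=seed + gi,
            gcm_id=gcm,
        )
        runs[gcm] = run
        leaf_truth = partition.assignments.set_index("cell_id")["leaf_id"]
        table = ev.external_validate(
            run.surfaces, leaf_truth, design.holdout_ids, design.modeling_ids
        )
        table.insert(0, "gcm", gcm)
        metrics_frames.append(table)
    metrics = pd.concat(metrics_frames, ignore_index=True)
    selected = ev.select_methods(metrics, cutoff=config.modeling.cutoff)
    leaves_per_gcm = {g: runs[g].leaf_ids for g in gcms}
    slots = list(config.modeling.methods) + [
        f for f in FAMILIES if set(FAMILIES[f]) <= set(config.modeling.methods)
    ]
    registry = ep.enumerate_jobs(slots, leaves_per_gcm, config.modeling.n_replicates)
    if out is not None:
        metrics.to_csv(out / "metrics.csv", index=False)
        registry.to_csv(out / "registry.csv", index=False)
        (out / "selected_methods.json").write_text(json.dumps(selected))
    _stage(log_path, "model", t0, fit_jobs=len(registry), selected=selected)

    # ---- project --------------------------------------------------------
    t0 = time.time()
    family = config.projection.family
    current_by_gcm: dict[str, dict[str, np.ndarray]] = {}
    future_by_gcm: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    uncertainty: dict[tuple[str, str], pd.DataFrame] = {}
    for gcm in gcms:
        run = runs[gcm]
        _, partition = partitions[gcm]
        leaf_bin = {
            leaf: _to_grid(
                run.surfaces[(family, leaf)].binary,
                run.surfaces[(family, leaf)].cell_ids,
                domain,
            )
            for leaf in run.leaf_ids
            if (family, leaf) in run.surfaces
        }
        count, overlap = ev.uncertainty_map(leaf_bin, areas2d)
        uncertainty[(gcm, "baseline")] = overlap
        current_by_gcm[gcm] = ep.aggregate_leaves(leaf_bin, partition)
        future_by_gcm[gcm] = {}
        for rcp in config.projection.rcps:
            # same seed as the baseline: future = baseline + anomaly (delta
            # method), so scenario differences are exactly the shift fields
            stack = sw.generate_climate(
                domain,
                scenarios[gcm][rcp],
                noise_sd=syn.noise_sd,
                seed=seed,
                smooth_sigma=syn.smooth_sigma,
            )
            proj = ep.project(run, stack)
            leaf_bin_f = {
                leaf: _to_grid(proj[(family, leaf)].binary, proj[(family, leaf)].cell_ids, domain)
                for leaf in run.leaf_ids
                if (family, leaf) in proj
            }
            _, overlap_f = ev.uncertainty_map(leaf_bin_f, areas2d)
            uncertainty[(gcm, rcp)] = overlap_f
            future_by_gcm[gcm][rcp] = ep.aggregate_leaves(leaf_bin_f, partition)

    all_categories = sorted(
        set().union(*(set(current_by_gcm[g]) for g in gcms))
    )
    for g in gcms:  # a GCM whose tree lost a category predicts it nowhere
        for cat in all_categories:
            current_by_gcm[g].setdefault(cat, np.zeros(domain.shape, dtype=bool))
            for rcp in config.projection.rcps:
                future_by_gcm[g][rcp].setdefault(cat, np.zeros(domain.shape, dtype=bool))

    consensus_rule = config.projection.consensus
    current_consensus = ep.gcm_consensus(
        {g: current_by_gcm[g] for g in gcms}, rule=consensus_rule
    )
    future_consensus = {
        rcp: ep.gcm_consensus(
            {g: future_by_gcm[g][rcp] for g in gcms}, rule=consensus_rule
        )
        for rcp in config.projection.rcps
    }
    _stage(log_path, "project", t0, rcps=list(config.projection.rcps))

    # ---- refugia --------------------------------------------------------
    t0 = time.time()
    if config.refugia.regions == "synthetic":
        regions = sw.default_regions(domain)
    else:
        regions = rf.load_regions(config.refugia.regions)
    reports: dict[str, rf.RefugeReport] = {}
    for rcp in config.projection.rcps:
        report = rf.build_report(
            rcp,
            current_consensus,
            future_consensus[rcp],
            lat2d,
            lon2d,
            areas2d,
            regions=regions,
        )
        reports[rcp] = report
        if out is not None:
            report.table.to_csv(out / f"refuge_{rcp}.csv", index=False)
            report.by_region.to_csv(out / f"refuge_{rcp}_by_region.csv", index=False)
            for cat, m in report.refuge_maps.items():
                grid_io.write_raster(
                    out / f"refuge_{rcp}_{cat}.asc", m.astype(float), domain
                )
    if out is not None:
        summary = {
            "selected_methods": selected,
            "forest_oob_accuracy": {
                g: forest_reports[g].explained_proportion for g in gcms
            },
            "sensitivity": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in sensitivity.items()
            },
            "refuge_pct": {
                rcp: dict(
                    zip(reports[rcp].table["category"], reports[rcp].table["refuge_pct"])
                )
                for rcp in reports
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    _stage(log_path, "refugia", t0, rcps=list(reports))

    return PipelineResult(
        config=config,
        domain=domain,
        cells=cells,
        scenarios=scenarios,
        partitions=partitions,
        forest_reports=forest_reports,
        sensitivity=sensitivity,
        runs=runs,
        metrics=metrics,
        selected_methods=selected,
        registry=registry,
        current_consensus=current_consensus,
        future_consensus=future_consensus,
        current_by_gcm=current_by_gcm,
        future_by_gcm=future_by_gcm,
        reports=reports,
        uncertainty=uncertainty,
    )
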