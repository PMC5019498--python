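"""Replicate/sampling design, TSS-weighted ensembles, projection, consensus.

The modelling design mirrors the sampling scheme of the analysis: 25 % of
cells are drawn as the modelling sample; each of 10 replicates splits that
sample 75/25 into calibration/validation; every method is fitted per leaf
and replicate, replicate-averaged, thresholded at the mean calibration
prevalence, and combined into per-family ensembles weighted by
internal-validation TSS. Future climate is projection-only (no refitting);
leaves aggregate to categories by union; GCMs combine by unanimity
consensus (majority rule available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climatic_partition import LeafPartition
from .evaluation import confusion_metrics
from .sdm_methods import (
    FAMILIES,
    METHODS,
    PredictionSurface,
    SDMFit,
    TrainSet,
    binarize,
    fit_method,
    predict_suitability,
)
from .synthetic_world import ClimateStack

__all__ = [
    "ReplicateDesign",
    "ModelRun",
    "make_design",
    "enumerate_jobs",
    "fit_all",
    "tss_weighted_ensemble",
    "project",
    "aggregate_leaves",
    "gcm_consensus",
]

logger = logging.getLogger(__name__)

MIN_PRESENCES = 5


@dataclass(frozen=True)
class ReplicateDesign:
    """Modelling sample and per-replicate calibration/validation splits."""

    modeling_ids: np.ndarray
    holdout_ids: np.ndarray
    replicates: tuple[tuple[np.ndarray, np.ndarray], ...]  # (calib, valid)
    seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def make_design(
    cells: pd.DataFrame,
    sample_frac: float = 0.25,
    calib_frac: float = 0.75,
    n_reps: int = 10,
    seed: int = 0,
) -> ReplicateDesign:
    """Draw the modelling sample and replicate splits, reproducibly.

    The modelling sample is a uniform draw without replacement of
    ``round(sample_frac * n)`` cells; each replicate re-partitions it into
    ``round(calib_frac * n_sample)`` calibration cells, remainder validation.
    """
    for name, frac in (("sample_frac", sample_frac), ("calib_frac", calib_frac)):
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {frac}")
    ids = np.sort(cells["cell_id"].to_numpy())
    n = len(ids)
    rng = np.random.default_rng(seed)
    n_sample = round(sample_frac * n)
    modeling = np.sort(rng.choice(ids, size=n_sample, replace=False))
    holdout = np.setdiff1d(ids, modeling)
    n_calib = round(calib_frac * n_sample)
    replicates = []
    for _ in range(n_reps):
        perm = rng.permutation(modeling)
        replicates.append((np.sort(perm[:n_calib]), np.sort(perm[n_calib:])))
    return ReplicateDesign(
        modeling_ids=modeling,
        holdout_ids=holdout,
        replicates=tuple(replicates),
        seed=seed,
    )


def enumerate_jobs(
    method_slots: list[str],
    leaves_per_gcm: dict[str, list[int]],
    n_replicates: int,
) -> pd.DataFrame:
    """The job registry: one row per (gcm, method, leaf, replicate) fit.

    With M method slots, R replicates and L leaves in total across GCMs the
    registry holds M*R*L fit jobs and M*L replicate-averaged surfaces.
    """
    rows = [
        {"gcm": gcm, "method": m, "leaf": leaf, "replicate": r}
        for gcm in sorted(leaves_per_gcm)
        for m in method_slots
        for leaf in leaves_per_gcm[gcm]
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows, columns=["gcm", "method", "leaf", "replicate"])


@dataclass
class ModelRun:
    """All fitted models and replicate-averaged surfaces for one GCM."""

    gcm_id: str
    methods: list[str]
    families: dict[str, tuple[str, ...]]
    variables: list[str]
    design: ReplicateDesign
    partition: LeafPartition
    fits: dict[tuple[str, int, int], SDMFit] = field(default_factory=dict)
    internal_tss: pd.DataFrame | None = None
    surfaces: dict[tuple[str, int], PredictionSurface] = field(default_factory=dict)
    skipped_leaves: list[int] = field(default_factory=list)

    @property
    def leaf_ids(self) -> list[int]:
        return [lf for lf in self.partition.leaf_ids if lf not in self.skipped_leaves]

    def method_weights(self, leaf_id: int) -> dict[str, float]:
        """Mean internal-validation TSS per method, clamped at 0."""
        t = self.internal_tss
        sub = t[t["leaf"] == leaf_id].groupby("method")["tss"].mean()
        return {m: max(float(sub.get(m, np.nan)), 0.0) for m in self.methods if m in sub}


def _climate_matrix(cells: pd.DataFrame, variables: list[str]) -> tuple[np.ndarray, np.ndarray]:
    sub = cells.sort_values("cell_id")
    return sub["cell_id"].to_numpy(), sub[variables].to_numpy(dtype=float)


def _job_seed(seed: int, *key: int) -> int:
    return int(np.random.default_rng((seed, *key)).integers(2**31))


def fit_all(
    cells: pd.DataFrame,
    partition: LeafPartition,
    design: ReplicateDesign,
    variables: list[str],
    methods: list[str] | None = None,
    families: dict[str, tuple[str, ...]] | None = None,
    hyperparams: dict[str, dict] | None = None,
    seed: int = 0,
    gcm_id: str = "gcm",
) -> ModelRun:
    """Fit every (method, leaf, replicate), average, threshold, ensemble.

    Per replicate, presences = calibration cells of the leaf, absences = the
    other calibration cells; the binary threshold is the calibration
    prevalence. Leaves with fewer than 5 presences in any replicate are
    skipped with a warning. Family ensembles are TSS-weighted means of their
    member methods' replicate-averaged surfaces and are stored under the
    family name alongside the single methods.
    """
    methods = list(METHODS) if methods is None else list(methods)
    families = dict(FAMILIES) if families is None else dict(families)
    families = {f: mem for f, mem in families.items() if set(mem) & set(methods)}
    hyperparams = hyperparams or {}
    run = ModelRun(
        gcm_id=gcm_id,
        methods=methods,
        families=families,
        variables=list(variables),
        design=design,
        partition=partition,
    )
    all_ids, X_all = _climate_matrix(cells, variables)
    leaf_of = partition.assignments.set_index("cell_id")["leaf_id"]
    tss_rows = []
    raw_surfaces: dict[tuple[str, int], list[np.ndarray]] = {}
    thresholds: dict[int, list[float]] = {}

    for leaf_id in partition.leaf_ids:
        ok = True
        for r, (calib, _) in enumerate(design.replicates):
            n_pres = int((leaf_of.loc[calib] == leaf_id).sum())
            if n_pres < MIN_PRESENCES:
                logger.warning(
                    "leaf %d skipped: %d presences in replicate %d (< %d)",
                    leaf_id,
                    n_pres,
                    r,
                    MIN_PRESENCES,
                )
                run.skipped_leaves.append(leaf_id)
                ok = False
                break
        if not ok:
            continue
        for r, (calib, valid) in enumerate(design.replicates):
            train = TrainSet.from_cells(
                cells, partition.assignments, leaf_id, variables, calib
            )
            thresholds.setdefault(leaf_id, []).append(train.prevalence)
            valid_mask = np.isin(all_ids, valid)
            X_valid = X_all[valid_mask]
            truth_valid = (leaf_of.loc[all_ids[valid_mask]] == leaf_id).to_numpy()
            for mi, method in enumerate(methods):
                fit = fit_method(
                    method,
                    train,
                    hyperparams.get(method),
                    seed=_job_seed(seed, mi, leaf_id, r),
                    replicate=r,
                )
                run.fits[(method, leaf_id, r)] = fit
                suit_all = fit.predict(X_all)
                raw_surfaces.setdefault((method, leaf_id), []).append(suit_all)
                if truth_valid.any() and not truth_valid.all():
                    cm = confusion_metrics(
                        fit.predict(X_valid) >= train.prevalence, truth_valid
                    )
                    tss = cm.tss
                else:
                    tss = np.nan
                tss_rows.append(
                    {"method": method, "leaf": leaf_id, "replicate": r, "tss": tss}
                )
    run.internal_tss = pd.DataFrame(
        tss_rows, columns=["method", "leaf", "replicate", "tss"]
    )

    for (method, leaf_id), stack in raw_surfaces.items():
        avg = np.mean(stack, axis=0)
        thr = float(np.mean(thresholds[leaf_id]))
        run.surfaces[(method, leaf_id)] = binarize(
            PredictionSurface(
                cell_ids=all_ids,
                suitability=avg,
                leaf_id=leaf_id,
                method_id=method,
                gcm_id=gcm_id,
                rcp_id="baseline",
            ),
            thr,
        )
    _add_family_surfaces(run, run.surfaces)
    return run


def tss_weighted_ensemble(
    surfaces: list[PredictionSurface], tss_weights: list[float]
) -> PredictionSurface:
    """Weighted-mean suitability, weights = internal TSS clamped at 0.

    Members with non-positive weight are excluded; all-non-positive weights
    are an error (the ensemble would be undefined).
    """
    if len(surfaces) != len(tss_weights) or not surfaces:
        raise ValueError("need one weight per surface and at least one surface")
    weights = np.clip(np.asarray(tss_weights, dtype=float), 0.0, None)
    if not (weights > 0).any():
        raise ValueError("all ensemble weights are <= 0")
    ref = surfaces[0]
    combined = np.zeros(len(ref.cell_ids))
    for s, w in zip(surfaces, weights):
        if not np.array_equal(s.cell_ids, ref.cell_ids):
            raise ValueError("ensemble members cover different cells")
        combined += w * s.suitability
    combined /= weights.sum()
    return PredictionSurface(
        cell_ids=ref.cell_ids,
        suitability=combined,
        leaf_id=ref.leaf_id,
        gcm_id=ref.gcm_id,
        rcp_id=ref.rcp_id,
    )


def _add_family_surfaces(
    run: ModelRun, surfaces: dict[tuple[str, int], PredictionSurface]
) -> None:
    for family, members in run.families.items():
        for leaf_id in run.leaf_ids:
            weights = run.method_weights(leaf_id)
            member_surfaces, member_weights = [], []
            thr = None
            for m in members:
                if (m, leaf_id) in surfaces and m in weights:
                    member_surfaces.append(surfaces[(m, leaf_id)])
                    member_weights.append(weights[m])
                    thr = surfaces[(m, leaf_id)].threshold
            if not member_surfaces or not any(w > 0 for w in member_weights):
                logger.warning(
                    "family %s has no positively weighted member for leaf %d",
                    family,
                    leaf_id,
                )
                continue
            ens = tss_weighted_ensemble(member_surfaces, member_weights)
            ens.method_id = family
            surfaces[(family, leaf_id)] = binarize(ens, thr)


def project(
    run: ModelRun,
    cells_future: pd.DataFrame | ClimateStack,
    rcp_id: str | None = None,
) -> dict[tuple[str, int], PredictionSurface]:
    """Project fitted models onto a future climate — no refitting.

    Thresholds and ensemble weights are carried unchanged from calibration.
    The future stack must come from the same GCM the models were trained on.
    """
    if isinstance(cells_future, ClimateStack):
        scen = cells_future.scenario
        if scen.gcm_id != run.gcm_id:
            raise ValueError(
                f"GCM mismatch: models trained on {run.gcm_id!r}, "
                f"future stack is {scen.gcm_id!r}"
            )
        rcp_id = scen.rcp_id
        frame = cells_future.to_frame()
        ids = frame.index.to_numpy()
        X = frame[run.variables].to_numpy(dtype=float)
    else:
        ids, X = _climate_matrix(cells_future, run.variables)

    out: dict[tuple[str, int], PredictionSurface] = {}
    for leaf_id in run.leaf_ids:
        for method in run.methods:
            reps = [
                run.fits[(method, leaf_id, r)]
                for r in range(run.design.n_replicates)
                if (method, leaf_id, r) in run.fits
            ]
            if not reps:
                continue
            avg = np.mean([f.predict(X) for f in reps], axis=0)
            thr = run.surfaces[(method, leaf_id)].threshold
            out[(method, leaf_id)] = binarize(
                PredictionSurface(
                    cell_ids=ids,
                    suitability=avg,
                    leaf_id=leaf_id,
                    method_id=method,
                    gcm_id=run.gcm_id,
                    rcp_id=rcp_id,
                ),
                thr,
            )
    _add_family_surfaces(run, out)
    for s in out.values():
        s.rcp_id = rcp_id
    return out


def aggregate_leaves(
    leaf_binaries: dict[int, np.ndarray], partition: LeafPartition
) -> dict[str, np.ndarray]:
    """Category presence = cellwise union of its leaves' binary presences."""
    unmapped = set(leaf_binaries) - set(partition.leaf_category)
    if unmapped:
        raise ValueError(f"leaves without a category mapping: {sorted(unmapped)}")
    out: dict[str, np.ndarray] = {}
    for leaf_id, binary in sorted(leaf_binaries.items()):
        cat = partition.leaf_category[leaf_id]
        if cat in out:
            out[cat] = out[cat] | binary
        else:
            out[cat] = binary.copy()
    return out


def gcm_consensus(
    category_binaries: dict[str, dict[str, np.ndarray]],
    rule: str = "unanimity",
) -> dict[str, np.ndarray]:
    """Cross-GCM consensus per category.

    ``rule='unanimity'`` (default) keeps cells where every GCM predicts
    presence; ``rule='majority'`` keeps cells where more than half do.
    """
    if len(category_binaries) < 2:
        raise ValueError("consensus needs at least 2 GCMs")
    gcms = sorted(category_binaries)
    categories = set().union(*(set(category_binaries[g]) for g in gcms))
    for g in gcms:
        missing = categories - set(category_binaries[g])
        if missing:
            raise ValueError(f"GCM {g!r} lacks categories {sorted(missing)}")
    out: dict[str, np.ndarray] = {}
    for cat in sorted(categories):
        stack = np.stack([category_binaries[g][cat] for g in gcms])
        if rule == "unanimity":
            out[cat] = stack.all(axis=0)
        elif rule == "majority":
            out[cat] = stack.sum(axis=0) * 2 > len(gcms)
        else:
            raise ValueError(f"unknown consensus rule {rule!r}")
    return out
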