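"""Prediction scoring against the known distribution.

Sensitivity, specificity, TSS (sensitivity + specificity - 1) and rank-based
AUC per method x leaf; adequate-method selection by the all-metrics > cutoff
rule; and the multi-leaf-overlap uncertainty map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .sdm_methods import PredictionSurface

__all__ = [
    "EvalMetrics",
    "confusion_metrics",
    "auc",
    "external_validate",
    "select_methods",
    "uncertainty_map",
]

METRIC_COLUMNS = ("sensitivity", "specificity", "tss", "auc")


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    tss: float
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(pred_binary, truth_binary) -> EvalMetrics:
    """Standard presence/absence confusion metrics; TSS = sens + spec - 1.

    Truth must contain both classes, otherwise sensitivity or specificity is
    undefined and the call fails loudly.
    """
    pred = np.asarray(pred_binary, dtype=bool)
    truth = np.asarray(truth_binary, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth have different shapes")
    if truth.all() or not truth.any():
        raise ValueError(
            "truth is single-class; sensitivity/specificity are undefined"
        )
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    tn = int((~pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec, tss=sens + spec - 1.0
    )


def auc(scores, truth_binary) -> float:
    """Rank-based (Mann-Whitney) AUC with mid-rank tie handling."""
    truth = np.asarray(truth_binary, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(truth.astype(int), np.asarray(scores, dtype=float)))


def external_validate(
    surfaces: dict[tuple[str, int], PredictionSurface],
    leaf_truth: pd.Series,
    holdout_ids: np.ndarray,
    modeling_ids: np.ndarray,
) -> pd.DataFrame:
    """Score replicate-averaged predictions on the held-out cells.

    ``surfaces`` maps (method_id, leaf_id) to a thresholded surface covering
    all cells; ``leaf_truth`` is the tree's cell_id -> leaf_id map (the known
    distribution). The holdout must be disjoint from the modelling sample.
    Returns one row per (method, leaf) with the four metrics.
    """
    holdout_ids = np.asarray(holdout_ids)
    modeling_ids = np.asarray(modeling_ids)
    overlap = np.intersect1d(holdout_ids, modeling_ids)
    if overlap.size:
        raise ValueError(
            f"holdout overlaps the modelling sample ({overlap.size} cells, "
            f"e.g. {overlap[:5].tolist()})"
        )
    rows = []
    for (method_id, leaf_id), surface in sorted(surfaces.items()):
        if surface.threshold is None:
            raise ValueError(f"surface ({method_id}, {leaf_id}) is not thresholded")
        suit = surface.series().loc[holdout_ids].to_numpy()
        truth = (leaf_truth.loc[holdout_ids] == leaf_id).to_numpy()
        cm = confusion_metrics(suit >= surface.threshold, truth)
        rows.append(
            {
                "method": method_id,
                "leaf": leaf_id,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "tss": cm.tss,
                "auc": auc(suit, truth),
                "n": len(truth),
            }
        )
    return pd.DataFrame(rows)


def select_methods(
    metrics_table: pd.DataFrame, cutoff: float = 0.7, per_leaf: bool = True
) -> list[str]:
    """Methods whose evaluation metrics all exceed the cutoff (strict >).

    ``per_leaf=True`` (default) requires the worst leaf to pass — the
    stricter reading; ``per_leaf=False`` applies the rule to per-method
    means across leaves.
    """
    if metrics_table.empty:
        raise ValueError("metrics table is empty")
    grouped = metrics_table.groupby("method")[list(METRIC_COLUMNS)]
    summary = grouped.min() if per_leaf else grouped.mean()
    passing = summary[(summary > cutoff).all(axis=1)]
    ranked = passing.mean(axis=1).sort_values(ascending=False)
    return list(ranked.index)


def uncertainty_map(
    leaf_binaries: dict[int, np.ndarray], cell_areas: np.ndarray
) -> tuple[np.ndarray, pd.DataFrame]:
    """Multi-leaf overlap: cells where more than one leaf is predicted.

    Returns the per-cell overlap count and a per-leaf table of predicted
    area vs the area overlapping other leaves (km^2). Only one landcover can
    occupy a cell, so overlap quantifies prediction uncertainty.
    """
    shapes = {b.shape for b in leaf_binaries.values()}
    if len(shapes) > 1:
        raise ValueError(f"leaf surfaces are on different grids: {shapes}")
    if cell_areas.shape not in shapes and shapes:
        raise ValueError("cell_areas grid does not match the surfaces")
    count = np.zeros(cell_areas.shape, dtype=int)
    for b in leaf_binaries.values():
        count += b.astype(int)
    uncertain = count >= 2
    rows = []
    for leaf_id, b in sorted(leaf_binaries.items()):
        rows.append(
            {
                "leaf": leaf_id,
                "area_km2": float(cell_areas[b].sum()),
                "uncertain_area_km2": float(cell_areas[b & uncertain].sum()),
            }
        )
    return count, pd.DataFrame(rows)
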