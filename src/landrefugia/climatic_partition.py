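"""Partition grid cells into climatically homogeneous leaves.

A CART decision tree (landcover category ~ climate) is grown per GCM
baseline, pruned by repeated cross-validation, and its terminal leaves become
the modelling units ("pseudo-species"): spatially and climatically coherent
cell groups, each predicting the landcover category that best characterizes
it. A bagged random forest provides an independent efficiency check
(out-of-bag accuracy), and a sensitivity analysis tests whether
classification quality degrades with anthropogenic cover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import cart

__all__ = [
    "TreeControl",
    "DecisionTreeModel",
    "LeafPartition",
    "fit_tree",
    "prune_by_cv",
    "assign_leaves",
    "random_forest_check",
    "anthropogenic_sensitivity",
]


@dataclass(frozen=True)
class TreeControl:
    """Growth/pruning control parameters.

    ``min_node_size`` is the smallest node eligible for splitting (default
    20 cells); ``cv_reps`` repetitions of ``cv_folds``-fold cross-validation
    drive the cost-complexity selection (1-SE rule).
    """

    min_node_size: int = 20
    cv_reps: int = 200
    cv_folds: int = 10
    use_1se: bool = True


@dataclass
class DecisionTreeModel:
    """A (possibly pruned) classification tree plus its fitting context."""

    tree: cart.DecisionTree
    climate_vars: list[str]
    control: TreeControl
    gcm_id: str | None = None
    cv_info: dict = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return self.tree.n_leaves

    def selected_variables(self) -> list[str]:
        """Climate variables actually used in splits (tree-indicated)."""
        return [self.tree.feature_names[j] for j in self.tree.used_features()]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tree": self.tree.to_dict(),
            "climate_vars": self.climate_vars,
            "control": vars(self.control).copy(),
            "gcm_id": self.gcm_id,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DecisionTreeModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            tree=cart.DecisionTree.from_dict(payload["tree"]),
            climate_vars=payload["climate_vars"],
            control=TreeControl(**payload["control"]),
            gcm_id=payload.get("gcm_id"),
        )


@dataclass
class LeafPartition:
    """Cell -> leaf assignment with leaf -> predicted-category map.

    Leaves are numbered 1..L in tree-node order. ``assignments`` has columns
    cell_id, leaf_id, predicted_category, landcover; ``misclassified_share``
    gives, per original category, the share of its cells sitting in leaves
    that predict a DIFFERENT category.
    """

    assignments: pd.DataFrame
    leaf_category: dict[int, str]
    leaf_counts: dict[int, int]
    leaf_composition: dict[int, dict[str, int]]
    misclassified_share: dict[str, float]
    gcm_id: str | None = None

    @property
    def leaf_ids(self) -> list[int]:
        return sorted(self.leaf_category)

    def cells_of(self, leaf_id: int) -> np.ndarray:
        a = self.assignments
        return a.loc[a["leaf_id"] == leaf_id, "cell_id"].to_numpy()

    def overall_misclassified_share(self) -> float:
        a = self.assignments
        return float((a["predicted_category"] != a["landcover"]).mean())

    def to_csv(self, path: str | Path) -> None:
        self.assignments.to_csv(path, index=False)


def _design(cells: pd.DataFrame, climate_vars: list[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [v for v in climate_vars if v not in cells.columns]
    if missing:
        raise ValueError(f"cell table lacks climate variables: {missing}")
    sub = cells.sort_values("cell_id")
    X = sub[climate_vars].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = sub["cell_id"].to_numpy()[np.isnan(X).any(axis=1)][:10].tolist()
        raise ValueError(f"cells with missing climate values: {bad}")
    return X, sub["landcover"].to_numpy()


def fit_tree(
    cells: pd.DataFrame,
    climate_vars: list[str],
    control: TreeControl = TreeControl(),
    gcm_id: str | None = None,
) -> DecisionTreeModel:
    """Grow the full classification tree (category ~ climate).

    Deterministic given the cell table (rows are canonically ordered by
    cell_id before fitting). Single-category or constant-predictor input
    yields a root-only tree.
    """
    X, y = _design(cells, climate_vars)
    if len(y) < control.min_node_size:
        raise ValueError(
            f"need at least min_node_size={control.min_node_size} cells, got {len(y)}"
        )
    tree = cart.fit_tree(
        X, y, min_split=control.min_node_size, feature_names=list(climate_vars)
    )
    return DecisionTreeModel(tree=tree, climate_vars=list(climate_vars), control=control, gcm_id=gcm_id)


def prune_by_cv(
    model: DecisionTreeModel,
    cells: pd.DataFrame,
    n_reps: int | None = None,
    k_folds: int | None = None,
    seed: int = 0,
) -> DecisionTreeModel:
    """Cost-complexity pruning at the CV-selected size (1-SE rule).

    Repetitions reshuffle the fold assignment, so ``n_reps * k_folds``
    validation fits inform the relative-error curve. The pruned tree is a
    subtree of the full tree.
    """
    control = model.control
    n_reps = control.cv_reps if n_reps is None else n_reps
    k_folds = control.cv_folds if k_folds is None else k_folds
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X, y = _design(cells, model.climate_vars)
    pruned, info = cart.prune_select_cv(
        model.tree,
        X,
        y,
        n_reps=n_reps,
        k_folds=k_folds,
        seed=seed,
        min_split=control.min_node_size,
        use_1se=control.use_1se,
    )
    return DecisionTreeModel(
        tree=pruned,
        climate_vars=model.climate_vars,
        control=control,
        gcm_id=model.gcm_id,
        cv_info=info,
    )


def assign_leaves(model: DecisionTreeModel, cells: pd.DataFrame) -> LeafPartition:
    """Assign every cell to a leaf; leaves predict their modal category.

    Also reports the "classified differently" diagnostic: per original
    category, the share of its cells whose leaf predicts another category.
    """
    X, y = _design(cells, model.climate_vars)
    sub = cells.sort_values("cell_id")
    node_ids = model.tree.apply(X)
    leaf_nodes = model.tree.leaf_ids()
    leaf_of_node = {nid: i + 1 for i, nid in enumerate(sorted(leaf_nodes))}
    leaf_ids = np.array([leaf_of_node[nid] for nid in node_ids])

    leaf_category: dict[int, str] = {}
    leaf_counts: dict[int, int] = {}
    leaf_composition: dict[int, dict[str, int]] = {}
    for nid in sorted(leaf_nodes):
        lid = leaf_of_node[nid]
        member = node_ids == nid
        leaf_counts[lid] = int(member.sum())
        comp_labels, comp_counts = np.unique(y[member], return_counts=True)
        leaf_composition[lid] = {str(lab): int(c) for lab, c in zip(comp_labels, comp_counts)}
        if member.any():
            # modal training category; ties break toward the first label
            leaf_category[lid] = str(comp_labels[np.argmax(comp_counts)])
        else:
            leaf_category[lid] = str(
                model.tree.classes_[model.tree.nodes[nid].prediction]
            )
    predicted = np.array([leaf_category[lid] for lid in leaf_ids], dtype=object)
    assignments = pd.DataFrame(
        {
            "cell_id": sub["cell_id"].to_numpy(),
            "leaf_id": leaf_ids,
            "predicted_category": predicted,
            "landcover": y,
        }
    )
    mis = {
        str(cat): float((predicted[y == cat] != cat).mean())
        for cat in np.unique(y)
    }
    return LeafPartition(
        assignments=assignments,
        leaf_category=leaf_category,
        leaf_counts=leaf_counts,
        leaf_composition=leaf_composition,
        misclassified_share=mis,
        gcm_id=model.gcm_id,
    )


@dataclass
class ForestReport:
    """Random-forest check of the climatic classification."""

    explained_proportion: float  # out-of-bag accuracy
    per_cell: pd.DataFrame  # cell_id, correct (0/1 by OOB vote), true_class_share
    n_trees: int


def random_forest_check(
    cells: pd.DataFrame,
    climate_vars: list[str],
    n_trees: int = 500,
    seed: int = 0,
) -> ForestReport:
    """Bagged-forest validation of category ~ climate.

    ``explained_proportion`` is the out-of-bag accuracy; ``per_cell`` carries
    each cell's OOB correctness and its OOB vote share for the true category.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, y = _design(cells, climate_vars)
    sub = cells.sort_values("cell_id")
    forest = cart.fit_forest(
        X, y, n_trees=n_trees, seed=seed, feature_names=list(climate_vars)
    )
    share = forest.oob_true_class_share()
    has_vote = forest.oob_votes.sum(axis=1) > 0
    correct = np.full(len(y), np.nan)
    correct[has_vote] = (
        np.argmax(forest.oob_votes[has_vote], axis=1) == forest.y_codes[has_vote]
    ).astype(float)
    per_cell = pd.DataFrame(
        {
            "cell_id": sub["cell_id"].to_numpy(),
            "correct": correct,
            "true_class_share": share,
        }
    )
    return ForestReport(
        explained_proportion=forest.oob_accuracy(), per_cell=per_cell, n_trees=n_trees
    )


def anthropogenic_sensitivity(
    cells: pd.DataFrame,
    climate_vars: list[str],
    fraction_cutoff: float = 0.5,
    n_trees: int = 200,
    seed: int = 0,
    n_boot: int = 200,
) -> dict:
    """Does anthropogenic cover degrade the climatic classification?

    Reruns the forest classification after dropping cells above the
    anthropogenic-fraction cutoff and compares OOB accuracies; additionally
    fits a logistic regression of per-cell OOB correctness on
    anthro_fraction, reporting the slope with a bootstrap percentile
    interval. A slope interval covering 0 means classification quality is
    unrelated to anthropogenic cover.
    """
    if "anthro_fraction" not in cells.columns:
        raise ValueError("cell table lacks anthro_fraction")
    filtered = cells[cells["anthro_fraction"] <= fraction_cutoff]
    if filtered.empty:
        raise ValueError(f"no cells with anthro_fraction <= {fraction_cutoff}")

    report_all = random_forest_check(cells, climate_vars, n_trees=n_trees, seed=seed)
    report_filtered = random_forest_check(
        filtered, climate_vars, n_trees=n_trees, seed=seed
    )

    sub = cells.sort_values("cell_id")
    frac = sub["anthro_fraction"].to_numpy(dtype=float)
    correct = report_all.per_cell["correct"].to_numpy()
    ok = ~np.isnan(correct)
    frac, correct = frac[ok], correct[ok]

    def slope(f: np.ndarray, c: np.ndarray) -> float:
        if len(np.unique(c)) < 2 or np.ptp(f) == 0:
            return 0.0
        # ridge-stabilized: constructed worlds can be perfectly separable
        model = LogisticRegression(C=1e6, max_iter=1000)
        model.fit(f.reshape(-1, 1), c.astype(int))
        return float(model.coef_[0, 0])

    point = slope(frac, correct)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(frac), size=len(frac))
        boots.append(slope(frac[idx], correct[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "accuracy_all": report_all.explained_proportion,
        "accuracy_filtered": report_filtered.explained_proportion,
        "n_all": int(len(cells)),
        "n_filtered": int(len(filtered)),
        "trend_slope": point,
        "trend_ci": (float(lo), float(hi)),
    }
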