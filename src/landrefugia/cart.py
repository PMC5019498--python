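"""Classification trees (CART) with cost-complexity pruning and bagging.

Greedy binary recursive partitioning on the Gini criterion, one variable per
split. Determinism is part of the contract: split ties break toward the
smallest variable index, then the smallest threshold; modal-class ties break
toward the smallest class index. Cost-complexity (weakest-link) pruning and
repeated k-fold cross-validation with the 1-SE rule select the subtree size;
bagged trees with per-split random variable subsets provide the forest used
both as a classification check and as a distribution-model member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Node",
    "DecisionTree",
    "fit_tree",
    "cost_complexity_path",
    "prune",
    "cv_error_curve",
    "prune_select_cv",
    "BaggedForest",
    "fit_forest",
]

_EPS = 1e-12


@dataclass
class Node:
    node_id: int
    depth: int
    n: int
    class_counts: np.ndarray
    impurity: float
    prediction: int  # modal class index; ties -> smallest index
    feature: int | None = None
    threshold: float | None = None
    left: int | None = None
    right: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class DecisionTree:
    """A fitted binary classification tree.

    ``nodes[0]`` is the root; left children take ``x[feature] <= threshold``.
    """

    classes_: np.ndarray
    feature_names: list[str]
    nodes: list[Node] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return sum(1 for nd in self.nodes if nd.is_leaf)

    def leaf_ids(self) -> list[int]:
        return [nd.node_id for nd in self.nodes if nd.is_leaf]

    def used_features(self) -> list[int]:
        order: dict[int, None] = {}
        for nd in self.nodes:
            if not nd.is_leaf:
                order.setdefault(nd.feature)
        return sorted(order)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node_id reached by each row."""
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X), dtype=int)
        stack = [(0, np.arange(len(X)))]
        while stack:
            nid, idx = stack.pop()
            nd = self.nodes[nid]
            if nd.is_leaf:
                out[idx] = nid
                continue
            go_left = X[idx, nd.feature] <= nd.threshold
            stack.append((nd.left, idx[go_left]))
            stack.append((nd.right, idx[~go_left]))
        return out

    def predict_index(self, X: np.ndarray) -> np.ndarray:
        leaf = self.apply(X)
        pred = np.array([nd.prediction for nd in self.nodes])
        return pred[leaf]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_index(X)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        leaf = self.apply(X)
        prop = np.array([nd.class_counts / max(nd.n, 1) for nd in self.nodes])
        return prop[leaf]

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes_],
            "feature_names": list(self.feature_names),
            "nodes": [
                {
                    "node_id": nd.node_id,
                    "depth": nd.depth,
                    "n": int(nd.n),
                    "class_counts": [int(c) for c in nd.class_counts],
                    "impurity": float(nd.impurity),
                    "prediction": int(nd.prediction),
                    "feature": nd.feature,
                    "threshold": nd.threshold,
                    "left": nd.left,
                    "right": nd.right,
                }
                for nd in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DecisionTree":
        tree = cls(
            classes_=np.array(payload["classes"], dtype=object),
            feature_names=list(payload["feature_names"]),
        )
        for d in payload["nodes"]:
            tree.nodes.append(
                Node(
                    node_id=d["node_id"],
                    depth=d["depth"],
                    n=d["n"],
                    class_counts=np.array(d["class_counts"]),
                    impurity=d["impurity"],
                    prediction=d["prediction"],
                    feature=d["feature"],
                    threshold=d["threshold"],
                    left=d["left"],
                    right=d["right"],
                )
            )
        return tree


def _gini(counts: np.ndarray, n: int) -> float:
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    k: int,
    min_leaf: int,
    features: np.ndarray,
):
    """Best (decrease, feature, threshold) over candidate splits, or None.

    Features are scanned in ascending index order and thresholds in ascending
    value order, so equal-quality splits resolve deterministically toward the
    smallest feature index, then the smallest threshold.
    """
    n = idx.size
    parent_counts = np.bincount(y[idx], minlength=k).astype(float)
    g_parent = _gini(parent_counts, n)
    best_dec, best_feat, best_thr = 0.0, None, None
    yi = y[idx]
    for j in features:
        x = X[idx, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ys = yi[order]
        onehot = np.zeros((n, k))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        pos = np.arange(n - 1)
        valid = (xs[1:] > xs[:-1]) & (pos + 1 >= min_leaf) & (n - pos - 1 >= min_leaf)
        if not valid.any():
            continue
        pos = pos[valid]
        n_left = (pos + 1).astype(float)
        n_right = n - n_left
        left = cum[pos]
        right = parent_counts - left
        g_left = 1.0 - (left * left).sum(axis=1) / (n_left * n_left)
        g_right = 1.0 - (right * right).sum(axis=1) / (n_right * n_right)
        dec = g_parent - (n_left * g_left + n_right * g_right) / n
        i = int(np.argmax(dec))  # first max -> smallest threshold
        if dec[i] > best_dec + _EPS:
            best_dec = float(dec[i])
            best_feat = int(j)
            best_thr = float((xs[pos[i]] + xs[pos[i] + 1]) / 2.0)
    if best_feat is None:
        return None
    return best_dec, best_feat, best_thr


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    *,
    min_split: int = 20,
    min_leaf: int | None = None,
    max_depth: int | None = None,
    mtry: int | None = None,
    rng: np.random.Generator | None = None,
    feature_names: list[str] | None = None,
) -> DecisionTree:
    """Grow a full CART tree (any impurity-decreasing split is accepted).

    ``min_split`` is the smallest node that may be split; ``min_leaf``
    (default ``max(1, min_split // 3)``, the rpart convention) the smallest
    child. ``mtry`` activates per-split random feature subsets (for forests).
    Single-category input yields a root-only tree.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (cells x variables)")
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    k = len(classes)
    if min_leaf is None:
        min_leaf = max(1, min_split // 3)
    if mtry is not None and rng is None:
        rng = np.random.default_rng(0)
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(X.shape[1])]
    tree = DecisionTree(classes_=classes, feature_names=list(names))

    def new_node(idx: np.ndarray, depth: int) -> int:
        counts = np.bincount(y_codes[idx], minlength=k).astype(float)
        nd = Node(
            node_id=len(tree.nodes),
            depth=depth,
            n=idx.size,
            class_counts=counts,
            impurity=_gini(counts, idx.size),
            prediction=int(np.argmax(counts)),
        )
        tree.nodes.append(nd)
        return nd.node_id

    all_features = np.arange(X.shape[1])
    root = new_node(np.arange(len(X)), 0)
    stack = [(root, np.arange(len(X)))]
    while stack:
        nid, idx = stack.pop()
        nd = tree.nodes[nid]
        if (
            nd.n < min_split
            or nd.impurity <= _EPS
            or (max_depth is not None and nd.depth >= max_depth)
        ):
            continue
        if mtry is not None and mtry < X.shape[1]:
            features = np.sort(rng.choice(X.shape[1], size=mtry, replace=False))
        else:
            features = all_features
        found = _best_split(X, y_codes, idx, k, min_leaf, features)
        if found is None:
            continue
        _, feat, thr = found
        go_left = X[idx, feat] <= thr
        nd.feature, nd.threshold = feat, thr
        left_idx, right_idx = idx[go_left], idx[~go_left]
        nd.left = new_node(left_idx, nd.depth + 1)
        nd.right = new_node(right_idx, nd.depth + 1)
        stack.append((nd.left, left_idx))
        stack.append((nd.right, right_idx))
    return tree


def _descendant_leaf_stats(tree: DecisionTree, collapsed: set[int]):
    """Per-node (misclass_risk, n_effective_leaves) under a collapse set."""
    n_total = tree.nodes[0].n
    risk_node = {
        nd.node_id: (nd.n - nd.class_counts.max()) / n_total for nd in tree.nodes
    }
    risk_sub: dict[int, float] = {}
    leaves_sub: dict[int, int] = {}

    def visit(nid: int):
        nd = tree.nodes[nid]
        if nd.is_leaf or nid in collapsed:
            risk_sub[nid] = risk_node[nid]
            leaves_sub[nid] = 1
            return
        visit(nd.left)
        visit(nd.right)
        risk_sub[nid] = risk_sub[nd.left] + risk_sub[nd.right]
        leaves_sub[nid] = leaves_sub[nd.left] + leaves_sub[nd.right]

    visit(0)
    return risk_node, risk_sub, leaves_sub


def _weakest_links(tree: DecisionTree, collapsed: set[int]):
    """(min_g, [node_ids achieving it]) over effective internal nodes."""
    risk_node, risk_sub, leaves_sub = _descendant_leaf_stats(tree, collapsed)
    g_min, argmin = np.inf, []
    for nd in tree.nodes:
        nid = nd.node_id
        if nd.is_leaf or nid in collapsed or nid not in risk_sub:
            continue
        if leaves_sub[nid] <= 1:
            continue
        g = (risk_node[nid] - risk_sub[nid]) / (leaves_sub[nid] - 1)
        if g < g_min - _EPS:
            g_min, argmin = g, [nid]
        elif g <= g_min + _EPS:
            argmin.append(nid)
    return g_min, argmin


def cost_complexity_path(tree: DecisionTree) -> np.ndarray:
    """Ascending sequence of critical complexity parameters, starting at 0."""
    alphas = [0.0]
    collapsed: set[int] = set()
    while True:
        g_min, links = _weakest_links(tree, collapsed)
        if not links:
            break
        alphas.append(max(g_min, 0.0))
        collapsed.update(links)
    return np.unique(alphas)


def prune(tree: DecisionTree, alpha: float) -> DecisionTree:
    """Optimal subtree for complexity parameter ``alpha`` (weakest-link).

    The result is a literal subtree: node ids and split parameters are
    preserved; pruned internal nodes become leaves.
    """
    collapsed: set[int] = set()
    while True:
        g_min, links = _weakest_links(tree, collapsed)
        if not links or g_min > alpha + _EPS:
            break
        collapsed.update(links)
    # rebuild reachable nodes with collapse applied
    out = DecisionTree(classes_=tree.classes_, feature_names=list(tree.feature_names))
    id_map: dict[int, int] = {}

    def copy_node(nid: int) -> int:
        nd = tree.nodes[nid]
        new = Node(
            node_id=0,
            depth=nd.depth,
            n=nd.n,
            class_counts=nd.class_counts.copy(),
            impurity=nd.impurity,
            prediction=nd.prediction,
        )
        new.node_id = len(out.nodes)
        out.nodes.append(new)
        id_map[nid] = new.node_id
        if not nd.is_leaf and nid not in collapsed:
            new.feature, new.threshold = nd.feature, nd.threshold
            new.left = copy_node(nd.left)
            new.right = copy_node(nd.right)
        return new.node_id

    copy_node(0)
    return out


def _representative_alphas(alphas: np.ndarray) -> np.ndarray:
    """One test alpha per subtree interval (geometric midpoints, rpart-style)."""
    reps = [0.0]
    for a, b in zip(alphas[:-1], alphas[1:]):
        reps.append(float(np.sqrt(a * b)) if a > 0 else b / 2.0)
    if len(alphas) > 1:
        reps.append(float(alphas[-1]))
    return np.unique(reps)


def cv_error_curve(
    X: np.ndarray,
    y: np.ndarray,
    alphas: np.ndarray,
    *,
    n_reps: int,
    k_folds: int,
    seed: int,
    min_split: int = 20,
    min_leaf: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated relative error at each candidate alpha.

    Repeated k-fold CV: each repetition reshuffles the fold assignment. The
    error is misclassification risk relative to the root (majority-class)
    risk, the scale on which a relative error of 1 means "no better than no
    split at all". Returns (mean_rel_error, se_rel_error) per alpha.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    _, counts = np.unique(y, return_counts=True)
    root_misclass = n - counts.max()
    if root_misclass == 0:
        return np.zeros(len(alphas)), np.zeros(len(alphas))
    rng = np.random.default_rng(seed)
    per_rep = np.zeros((n_reps, len(alphas)))
    for rep in range(n_reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k_folds)
        misclass = np.zeros(len(alphas))
        for fold in folds:
            mask = np.zeros(n, dtype=bool)
            mask[fold] = True
            subtree = fit_tree(
                X[~mask], y[~mask], min_split=min_split, min_leaf=min_leaf
            )
            for ai, alpha in enumerate(alphas):
                pred = prune(subtree, alpha).predict(X[mask])
                misclass[ai] += int((pred != y[mask]).sum())
        per_rep[rep] = misclass / root_misclass
    mean = per_rep.mean(axis=0)
    if n_reps > 1:
        se = per_rep.std(axis=0, ddof=1) / np.sqrt(n_reps)
    else:
        se = np.sqrt(np.maximum(mean * (1 - mean / (n / root_misclass)), 0.0) / n)
    return mean, se


def prune_select_cv(
    tree: DecisionTree,
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_reps: int = 200,
    k_folds: int = 10,
    seed: int = 0,
    min_split: int = 20,
    min_leaf: int | None = None,
    use_1se: bool = True,
) -> tuple[DecisionTree, dict]:
    """Prune ``tree`` at the CV-selected complexity (1-SE rule by default).

    The 1-SE rule picks the largest alpha (simplest subtree) whose mean CV
    relative error is within one standard error of the minimum.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    alphas = cost_complexity_path(tree)
    reps = _representative_alphas(alphas)
    mean, se = cv_error_curve(
        X,
        y,
        reps,
        n_reps=n_reps,
        k_folds=k_folds,
        seed=seed,
        min_split=min_split,
        min_leaf=min_leaf,
    )
    best = int(np.argmin(mean))
    if use_1se:
        threshold = mean[best] + se[best]
        chosen = max(i for i in range(len(reps)) if mean[i] <= threshold + _EPS)
    else:
        chosen = best
    pruned = prune(tree, float(reps[chosen]))
    info = {
        "alphas": reps,
        "cv_rel_error": mean,
        "cv_se": se,
        "selected_alpha": float(reps[chosen]),
        "n_leaves_full": tree.n_leaves,
        "n_leaves_pruned": pruned.n_leaves,
    }
    return pruned, info


@dataclass
class BaggedForest:
    """Bootstrap-aggregated trees with out-of-bag bookkeeping."""

    trees: list[DecisionTree]
    classes_: np.ndarray
    oob_votes: np.ndarray  # (n_train, n_classes) OOB vote counts
    y_codes: np.ndarray

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_accuracy(self) -> float:
        """Out-of-bag classification accuracy over rows with >= 1 OOB vote."""
        has_vote = self.oob_votes.sum(axis=1) > 0
        if not has_vote.any():
            raise ValueError("no row has out-of-bag votes; grow more trees")
        pred = np.argmax(self.oob_votes[has_vote], axis=1)
        return float((pred == self.y_codes[has_vote]).mean())

    def oob_true_class_share(self) -> np.ndarray:
        """Per-row OOB vote share for the true class (NaN if never OOB)."""
        totals = self.oob_votes.sum(axis=1)
        share = np.full(len(self.y_codes), np.nan)
        ok = totals > 0
        share[ok] = self.oob_votes[ok, self.y_codes[ok]] / totals[ok]
        return share

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Vote fraction per class across all trees."""
        votes = np.zeros((len(X), len(self.classes_)))
        for tree in self.trees:
            local = tree.predict(X)
            for ci, c in enumerate(self.classes_):
                votes[local == c, ci] += 1
        return votes / self.n_trees

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_trees: int = 500,
    mtry: int | None = None,
    min_split: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> BaggedForest:
    """Bag ``n_trees`` bootstrap trees with random per-split variable subsets.

    ``mtry`` defaults to ``round(sqrt(p))``, the standard classification
    choice. Each tree reuses the same CART growing machinery as the single
    decision tree.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if mtry is None:
        mtry = max(1, round(np.sqrt(p)))
    classes = np.unique(y)
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code[v] for v in y])
    rng = np.random.default_rng(seed)
    trees: list[DecisionTree] = []
    oob_votes = np.zeros((n, len(classes)))
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = fit_tree(
            X[boot],
            y[boot],
            min_split=min_split,
            min_leaf=1,
            mtry=mtry,
            rng=rng,
            feature_names=feature_names,
        )
        trees.append(tree)
        if oob.size:
            pred = tree.predict(X[oob])
            for ci, c in enumerate(classes):
                oob_votes[oob[pred == c], ci] += 1
    return BaggedForest(trees=trees, classes_=classes, oob_votes=oob_votes, y_codes=y_codes)
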