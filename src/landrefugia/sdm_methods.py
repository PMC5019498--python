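"""Geographic distribution models fitted on leaf presence/absence.

Nine methods in three families, all exposing the same contract: fit on a
:class:`TrainSet` (presences = cells of one leaf, absences = sampled cells of
other leaves), predict a suitability in [0, 1] for any climate vector, and
binarize at the calibration prevalence.

Families:

* envelope/distance — ``bioclim`` (percentile envelope), ``gower``
  (range-normalized nearest-presence distance, DOMAIN-style),
  ``mahalanobis`` (distance to the presence centroid under the presence
  covariance, mapped through the chi-square survival function);
* statistical — ``glm`` (logistic, linear+quadratic), ``gam`` (additive
  logistic with per-variable spline basis, ridge chosen by CV), ``mars``
  (adaptive hinge basis grown forward, pruned by GCV, logistic link);
* machine learning — ``maxent_like`` (penalized logistic on hinge+quadratic
  features against background; simplified analogue of MaxEnt),
  ``garp_like`` (small genetic algorithm over conjunctive envelope rules;
  simplified analogue of GARP), ``rf`` (bagged CART trees, vote fraction).

``maxent_like`` and ``garp_like`` are deliberately simplified analogues of
the published desktop tools and are labelled as such everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.preprocessing import SplineTransformer

from . import cart

__all__ = [
    "METHODS",
    "FAMILIES",
    "TrainSet",
    "SDMFit",
    "PredictionSurface",
    "fit_method",
    "predict_suitability",
    "binarize",
]

METHODS: tuple[str, ...] = (
    "bioclim",
    "gower",
    "mahalanobis",
    "glm",
    "gam",
    "mars",
    "maxent_like",
    "garp_like",
    "rf",
)

FAMILIES: dict[str, tuple[str, ...]] = {
    "envelope_distance": ("bioclim", "gower", "mahalanobis"),
    "statistical": ("glm", "gam", "mars"),
    "machine_learning": ("maxent_like", "garp_like", "rf"),
}

MIN_PRESENCES = 5


@dataclass
class TrainSet:
    """Presence/absence calibration data for one leaf.

    Absences are TRUE absences (cells assigned to other leaves), not
    pseudo-absences: the full distribution of the modelling unit is known.
    ``variables`` are the tree-selected climate variables.
    """

    leaf_id: int
    variables: list[str]
    X_presence: np.ndarray
    X_absence: np.ndarray

    def __post_init__(self) -> None:
        if len(self.X_presence) < MIN_PRESENCES:
            raise ValueError(
                f"leaf {self.leaf_id}: need >= {MIN_PRESENCES} presences, "
                f"got {len(self.X_presence)}"
            )
        if len(self.X_absence) == 0:
            raise ValueError(f"leaf {self.leaf_id}: no absences")

    @property
    def prevalence(self) -> float:
        n1, n0 = len(self.X_presence), len(self.X_absence)
        return n1 / (n1 + n0)

    @property
    def X_all(self) -> np.ndarray:
        return np.vstack([self.X_presence, self.X_absence])

    @property
    def y(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.X_presence), dtype=int), np.zeros(len(self.X_absence), dtype=int)]
        )

    @classmethod
    def from_cells(
        cls,
        cells: pd.DataFrame,
        leaf_assignment: pd.DataFrame,
        leaf_id: int,
        variables: list[str],
        cell_ids: np.ndarray,
    ) -> "TrainSet":
        """Build presences/absences from the cells with the given ids."""
        sub = cells.set_index("cell_id").loc[np.asarray(cell_ids)]
        leaf_of = leaf_assignment.set_index("cell_id")["leaf_id"]
        is_presence = (leaf_of.loc[np.asarray(cell_ids)] == leaf_id).to_numpy()
        X = sub[variables].to_numpy(dtype=float)
        return cls(
            leaf_id=leaf_id,
            variables=list(variables),
            X_presence=X[is_presence],
            X_absence=X[~is_presence],
        )


@dataclass
class SDMFit:
    """A fitted distribution method for one leaf and replicate."""

    method_id: str
    leaf_id: int
    variables: list[str]
    prevalence: float
    predictor: object
    replicate: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        s = np.clip(self.predictor.predict(X), 0.0, 1.0)
        return s


@dataclass
class PredictionSurface:
    """Per-cell continuous suitability, optionally thresholded to binary."""

    cell_ids: np.ndarray
    suitability: np.ndarray
    threshold: float | None = None
    leaf_id: int | None = None
    method_id: str | None = None
    gcm_id: str | None = None
    rcp_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.suitability):
            raise ValueError("cell_ids and suitability lengths differ")
        s = np.asarray(self.suitability, dtype=float)
        if np.any((s < -1e-9) | (s > 1 + 1e-9)):
            raise ValueError("suitability outside [0, 1]")

    @property
    def binary(self) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("surface has no threshold; call binarize first")
        return self.suitability >= self.threshold

    def series(self) -> pd.Series:
        return pd.Series(self.suitability, index=self.cell_ids)


# ---------------------------------------------------------------- envelope


class _Bioclim:
    """Percentile envelope: score = 1 - 2 * max_j |pct_j - 0.5|, 0 outside."""

    def __init__(self, P: np.ndarray, trim: float = 0.0):
        if trim > 0:
            lo = np.quantile(P, trim, axis=0)
            hi = np.quantile(P, 1 - trim, axis=0)
            P = np.clip(P, lo, hi)
        self.sorted = np.sort(P, axis=0)
        self.mins = self.sorted[0]
        self.maxs = self.sorted[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = self.sorted.shape[0]
        score = np.ones(len(X))
        for j in range(self.sorted.shape[1]):
            pct = np.searchsorted(self.sorted[:, j], X[:, j], side="right") / n
            s = 1.0 - 2.0 * np.abs(pct - 0.5)
            s = np.where((X[:, j] < self.mins[j]) | (X[:, j] > self.maxs[j]), 0.0, s)
            score = np.minimum(score, s)
        return score


class _Gower:
    """1 - mean range-normalized distance to the NEAREST presence."""

    def __init__(self, P: np.ndarray):
        self.P = P
        rng = P.max(axis=0) - P.min(axis=0)
        self.range = np.where(rng > 0, rng, 1.0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # (n_query, n_presence, p) in manageable chunks
        out = np.empty(len(X))
        step = max(1, int(2e6 / max(self.P.size, 1)))
        for i in range(0, len(X), step):
            block = X[i : i + step]
            d = np.abs(block[:, None, :] - self.P[None, :, :]) / self.range
            out[i : i + step] = d.mean(axis=2).min(axis=1)
        return np.clip(1.0 - out, 0.0, 1.0)


class _Mahalanobis:
    """Chi-square survival of the squared distance to the presence centroid."""

    def __init__(self, P: np.ndarray, ridge: float = 1e-8):
        self.mean = P.mean(axis=0)
        cov = np.cov(P, rowvar=False)
        cov = np.atleast_2d(cov)
        p = cov.shape[0]
        if ridge > 0:
            cov = cov + ridge * (np.trace(cov) / p) * np.eye(p)
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError(
                "presence covariance is singular; increase ridge"
            )
        self.prec = np.linalg.inv(cov)
        self.df = p

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = X - self.mean
        d2 = np.einsum("ij,jk,ik->i", d, self.prec, d)
        return chi2.sf(d2, df=self.df)


# -------------------------------------------------------------- statistical


class _FeatureLogistic:
    """Logistic regression on an engineered feature expansion."""

    def __init__(self, expand, model, mu: np.ndarray, sd: np.ndarray):
        self.expand = expand
        self.model = model
        self.mu = mu
        self.sd = sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mu) / self.sd
        return self.model.predict_proba(self.expand(Z))[:, 1]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _fit_glm(train: TrainSet, hp: dict, seed: int) -> _FeatureLogistic:
    quadratic = hp.get("quadratic", True)

    def expand(Z: np.ndarray) -> np.ndarray:
        return np.hstack([Z, Z**2]) if quadratic else Z

    mu, sd = _standardize(train.X_all)
    model = LogisticRegression(C=hp.get("C", 1e4), max_iter=5000)
    model.fit(expand((train.X_all - mu) / sd), train.y)
    return _FeatureLogistic(expand, model, mu, sd)


def _fit_gam(train: TrainSet, hp: dict, seed: int) -> _FeatureLogistic:
    n_knots = hp.get("basis_dim", 5)
    mu, sd = _standardize(train.X_all)
    Z = (train.X_all - mu) / sd
    spline = SplineTransformer(n_knots=n_knots, degree=3, include_bias=False)
    spline.fit(Z)
    expand = spline.transform
    # ridge strength by CV on classification accuracy: the surface is used
    # through a prevalence threshold, so boundary placement matters and
    # probability calibration at the extremes does not
    model = LogisticRegressionCV(
        Cs=np.logspace(-2, 4, 7),
        cv=3,
        max_iter=2000,
        random_state=seed,
        scoring="accuracy",
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(expand(Z), train.y)
    return _FeatureLogistic(expand, model, mu, sd)


class _MarsBasis:
    """A set of hinge basis functions max(+/-(x_j - t), 0)."""

    def __init__(self, terms: list[tuple[int, float, int]]):
        self.terms = terms  # (feature, knot, sign)

    def transform(self, Z: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(Z))]
        for j, t, s in self.terms:
            cols.append(np.maximum(s * (Z[:, j] - t), 0.0))
        return np.column_stack(cols)


def _mars_gcv(sse: float, n: int, n_terms: int, penalty: float) -> float:
    # effective parameters: terms plus penalty per knot (Friedman's C(M))
    c = n_terms + penalty * max(n_terms - 1, 0) / 2.0
    denom = (1.0 - c / n) ** 2
    if denom <= 0:
        return np.inf
    return sse / n / denom


def _fit_mars(train: TrainSet, hp: dict, seed: int) -> _FeatureLogistic:
    """Forward hinge growth to max_terms, backward prune by GCV, logistic link.

    The piecewise-linear basis is selected by least squares on the 0/1
    response (fast and scale-free); the final coefficients are refitted with
    a logistic model on the selected basis.
    """
    max_terms = hp.get("max_terms", 21)
    penalty = hp.get("penalty", 3.0)
    max_knots = hp.get("max_knots", 20)
    mu, sd = _standardize(train.X_all)
    Z = (train.X_all - mu) / sd
    y = train.y.astype(float)
    n, p = Z.shape

    knots: list[list[float]] = []
    for j in range(p):
        uniq = np.unique(Z[:, j])
        if len(uniq) > max_knots:
            uniq = np.quantile(uniq, np.linspace(0.05, 0.95, max_knots))
        knots.append(list(uniq))

    terms: list[tuple[int, float, int]] = []
    basis = np.ones((n, 1))
    resid_sse = float(((y - y.mean()) ** 2).sum())
    while len(terms) < max_terms:
        best = None
        for j in range(p):
            for t in knots[j]:
                for s in (1, -1):
                    if (j, t, s) in terms:
                        continue
                    col = np.maximum(s * (Z[:, j] - t), 0.0)
                    B = np.column_stack([basis, col])
                    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
                    sse = float(((y - B @ coef) ** 2).sum())
                    if best is None or sse < best[0] - 1e-12:
                        best = (sse, j, t, s)
        if best is None or best[0] > resid_sse - 1e-10:
            break
        resid_sse, j, t, s = best
        terms.append((j, t, s))
        basis = np.column_stack([basis, np.maximum(s * (Z[:, j] - t), 0.0)])

    # backward pruning by generalized cross-validation
    def gcv_of(subset: list[tuple[int, float, int]]) -> float:
        B = _MarsBasis(subset).transform(Z)
        coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
        sse = float(((y - B @ coef) ** 2).sum())
        return _mars_gcv(sse, n, len(subset) + 1, penalty)

    current = list(terms)
    best_subset, best_gcv = list(current), gcv_of(current)
    while current:
        candidates = [
            (gcv_of(current[:i] + current[i + 1 :]), i) for i in range(len(current))
        ]
        g, i = min(candidates)
        current = current[:i] + current[i + 1 :]
        if g < best_gcv:
            best_gcv, best_subset = g, list(current)

    mars = _MarsBasis(best_subset)
    model = LogisticRegression(C=hp.get("C", 1e4), max_iter=5000)
    model.fit(mars.transform(Z), train.y)
    out = _FeatureLogistic(mars.transform, model, mu, sd)
    out.basis = mars  # selected hinge terms, inspectable
    out.forward_terms = terms
    return out


# ---------------------------------------------------------- machine learning


def _fit_maxent_like(train: TrainSet, hp: dict, seed: int) -> _FeatureLogistic:
    """Penalized logistic on hinge+quadratic features, presence vs background.

    Background = all sampled cells (presences included), weighted so the two
    classes balance. A documented simplified analogue of MaxEnt.
    """
    n_knots = hp.get("n_knots", 5)
    mu, sd = _standardize(train.X_all)
    Z = (train.X_all - mu) / sd
    p = Z.shape[1]
    knot_grid = [np.quantile(Z[:, j], np.linspace(0.1, 0.9, n_knots)) for j in range(p)]

    def expand(Zq: np.ndarray) -> np.ndarray:
        cols = [Zq, Zq**2]
        for j in range(p):
            for t in knot_grid[j]:
                cols.append(np.maximum(Zq[:, j] - t, 0.0)[:, None])
                cols.append(np.maximum(t - Zq[:, j], 0.0)[:, None])
        return np.hstack(cols)

    Zp = (train.X_presence - mu) / sd
    X_fit = np.vstack([Zp, Z])  # presences vs full background
    y_fit = np.concatenate([np.ones(len(Zp), dtype=int), np.zeros(len(Z), dtype=int)])
    model = LogisticRegression(
        C=hp.get("C", 1.0), max_iter=5000, class_weight="balanced"
    )
    model.fit(expand(X_fit), y_fit)
    return _FeatureLogistic(expand, model, mu, sd)


class _EnvelopeRuleSet:
    """Elite conjunctive interval rules; suitability = share predicting present."""

    def __init__(self, rules: np.ndarray, mu: np.ndarray, sd: np.ndarray):
        self.rules = rules  # (n_rules, p, 2) [lo, hi] in standardized space
        self.mu = mu
        self.sd = sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mu) / self.sd
        inside = (
            (Z[:, None, :] >= self.rules[None, :, :, 0])
            & (Z[:, None, :] <= self.rules[None, :, :, 1])
        ).all(axis=2)
        return inside.mean(axis=1)


def _fit_garp_like(train: TrainSet, hp: dict, seed: int) -> _EnvelopeRuleSet:
    """Small genetic algorithm over conjunctive envelope rules.

    Individuals are per-variable intervals; fitness is training TSS of the
    rule as a presence predictor. Mutation perturbs bounds, crossover mixes
    variables; the elite set forms the predictor. A documented simplified
    analogue of GARP.
    """
    pop_size = hp.get("pop_size", 40)
    n_gen = hp.get("n_generations", 30)
    n_elite = hp.get("n_elite", 5)
    rng = np.random.default_rng(seed)
    mu, sd = _standardize(train.X_all)
    Z = (train.X_all - mu) / sd
    y = train.y
    p = Z.shape[1]
    lo_all, hi_all = Z.min(axis=0) - 0.5, Z.max(axis=0) + 0.5

    def random_rule() -> np.ndarray:
        a = rng.uniform(lo_all, hi_all)
        b = rng.uniform(lo_all, hi_all)
        return np.stack([np.minimum(a, b), np.maximum(a, b)], axis=1)

    def fitness(rule: np.ndarray) -> float:
        inside = ((Z >= rule[:, 0]) & (Z <= rule[:, 1])).all(axis=1)
        tp = int((inside & (y == 1)).sum())
        fn = int((~inside & (y == 1)).sum())
        fp = int((inside & (y == 0)).sum())
        tn = int((~inside & (y == 0)).sum())
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        return sens + spec - 1.0

    pop = [random_rule() for _ in range(pop_size)]
    for _ in range(n_gen):
        scores = np.array([fitness(r) for r in pop])
        order = np.argsort(-scores)
        elite = [pop[i] for i in order[:n_elite]]
        children = list(elite)
        while len(children) < pop_size:
            a, b = rng.choice(n_elite, size=2, replace=True)
            mask = rng.random(p) < 0.5
            child = np.where(mask[:, None], elite[a], elite[b]).copy()
            jitter = rng.normal(scale=0.2, size=(p, 2)) * (rng.random((p, 1)) < 0.3)
            child = child + jitter
            child = np.stack(
                [np.minimum(child[:, 0], child[:, 1]), np.maximum(child[:, 0], child[:, 1])],
                axis=1,
            )
            children.append(child)
        pop = children
    scores = np.array([fitness(r) for r in pop])
    order = np.argsort(-scores)
    elite = np.stack([pop[i] for i in order[:n_elite]])
    return _EnvelopeRuleSet(elite, mu, sd)


class _ForestPredictor:
    def __init__(self, forest: cart.BaggedForest):
        self.forest = forest
        self.presence_col = int(np.where(forest.classes_ == 1)[0][0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict_proba(X)[:, self.presence_col]


def _fit_rf(train: TrainSet, hp: dict, seed: int) -> _ForestPredictor:
    forest = cart.fit_forest(
        train.X_all,
        train.y,
        n_trees=hp.get("n_trees", 200),
        min_split=hp.get("min_split", 5),
        seed=seed,
    )
    return _ForestPredictor(forest)


_FITTERS = {
    "bioclim": lambda tr, hp, seed: _Bioclim(tr.X_presence, trim=hp.get("trim", 0.0)),
    "gower": lambda tr, hp, seed: _Gower(tr.X_presence),
    "mahalanobis": lambda tr, hp, seed: _Mahalanobis(
        tr.X_presence, ridge=hp.get("ridge", 1e-8)
    ),
    "glm": _fit_glm,
    "gam": _fit_gam,
    "mars": _fit_mars,
    "maxent_like": _fit_maxent_like,
    "garp_like": _fit_garp_like,
    "rf": _fit_rf,
}


def fit_method(
    method_id: str,
    train: TrainSet,
    hyperparams: dict | None = None,
    seed: int = 0,
    replicate: int = 0,
) -> SDMFit:
    """Fit one distribution method on one leaf's calibration data."""
    if method_id not in _FITTERS:
        raise ValueError(f"unknown method {method_id!r}; choose from {METHODS}")
    predictor = _FITTERS[method_id](train, hyperparams or {}, seed)
    return SDMFit(
        method_id=method_id,
        leaf_id=train.leaf_id,
        variables=list(train.variables),
        prevalence=train.prevalence,
        predictor=predictor,
        replicate=replicate,
    )


def predict_suitability(fit: SDMFit, climate, cell_ids=None) -> PredictionSurface:
    """Predict the suitability surface for a fitted method.

    ``climate`` is either a ClimateStack (all cells, row-major ids) or a
    (cell_ids, X) pair already restricted to the fit's variables.
    """
    if hasattr(climate, "to_frame"):  # ClimateStack
        frame = climate.to_frame()
        missing = [v for v in fit.variables if v not in frame.columns]
        if missing:
            raise KeyError(f"climate stack lacks variables {missing}")
        X = frame[fit.variables].to_numpy(dtype=float)
        ids = frame.index.to_numpy()
        gcm = climate.scenario.gcm_id
        rcp = climate.scenario.rcp_id
    else:
        ids, X = climate
        ids = np.asarray(ids)
        gcm = rcp = None
        if cell_ids is not None:
            ids = np.asarray(cell_ids)
    return PredictionSurface(
        cell_ids=ids,
        suitability=fit.predict(X),
        leaf_id=fit.leaf_id,
        method_id=fit.method_id,
        gcm_id=gcm,
        rcp_id=rcp,
    )


def binarize(surface: PredictionSurface, threshold: float) -> PredictionSurface:
    """Attach the prevalence threshold; present iff suitability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return PredictionSurface(
        cell_ids=surface.cell_ids,
        suitability=surface.suitability,
        threshold=threshold,
        leaf_id=surface.leaf_id,
        method_id=surface.method_id,
        gcm_id=surface.gcm_id,
        rcp_id=surface.rcp_id,
    )
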