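"""Bagged regression-tree forest, written from first principles.

Each tree grows by recursive binary splitting: at a node, a random subset of
candidate features is drawn (one third of the feature count by default), and
over every candidate feature and every midpoint between consecutive distinct
sorted values the split minimising the sum of squared residuals

    SSR(s, x_i) = sum_{x_i <= s} (y - ybar_L)^2 + sum_{x_i > s} (y - ybar_R)^2

is chosen; ties go to the lowest feature index, then the smallest threshold.
A leaf predicts the mean in-bag target reaching it.  A forest averages its
trees' predictions with a (by default uniform) weight vector; the cohort-level
predictor averages one forest per leave-one-participant-out fold.

Trees are stored as flat parallel arrays (feature index, threshold, child
pointers, leaf value) so prediction is a vectorised level-by-level traversal
and serialization to JSON is direct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class ForestError(ValueError):
    pass


@dataclass(frozen=True)
class SplitCriterion:
    """The winning split at a node: feature, midpoint threshold, SSR, child means."""

    feature_index: int
    split_value: float
    ssr: float
    left_mean: float
    right_mean: float


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    candidate_features: np.ndarray | list[int],
    min_leaf: int = 1,
) -> SplitCriterion | None:
    """Exhaustive SSR-minimising split over candidate features and midpoints.

    Thresholds are midpoints between consecutive distinct sorted feature
    values, so both prospective children are non-empty; with ``min_leaf`` > 1
    only splits leaving at least that many samples on each side are
    considered.  Returns ``None`` when no candidate feature admits a valid
    split (all constant, or every split violates ``min_leaf``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ForestError("best_split needs at least 2 samples")
    candidates = sorted(int(j) for j in candidate_features)
    if not candidates:
        raise ForestError("candidate feature set is empty")

    # centring makes the prefix-sum SSR well conditioned; SSR itself is
    # translation-invariant.  Distinct features can induce the *same* row
    # bipartition (hence mathematically equal SSR), so comparisons use a
    # relative tolerance and ties resolve to the lowest feature index, then
    # the smallest threshold.
    mu = y.mean()
    yc = y - mu
    tol = 1e-10 * max(float((yc * yc).sum()), 1e-300)

    best: SplitCriterion | None = None
    for j in candidates:
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs, ys = xj[order], yc[order]
        # split after position i is valid only where the feature value changes
        change = np.flatnonzero(np.diff(xs) > 0)
        if min_leaf > 1:
            nleft = change + 1
            change = change[(nleft >= min_leaf) & (n - nleft >= min_leaf)]
        if change.size == 0:
            continue
        csum = np.cumsum(ys)
        csum2 = np.cumsum(ys * ys)
        tot, tot2 = csum[-1], csum2[-1]
        nL = change + 1
        sL, sL2 = csum[change], csum2[change]
        nR = n - nL
        sR, sR2 = tot - sL, tot2 - sL2
        ssr = (sL2 - sL * sL / nL) + (sR2 - sR * sR / nR)
        i = int(np.flatnonzero(ssr <= ssr.min() + tol)[0])  # smallest tied threshold
        if best is None or ssr[i] < best.ssr - tol:
            pos = change[i]
            best = SplitCriterion(
                feature_index=j,
                split_value=float((xs[pos] + xs[pos + 1]) / 2.0),
                ssr=float(max(ssr[i], 0.0)),
                left_mean=float(sL[i] / nL[i] + mu),
                right_mean=float(sR[i] / nR[i] + mu),
            )
    return best


@dataclass
class RegressionTree:
    """Binary regression tree in flat-array form.

    ``feature[i] == -1`` marks a leaf; then ``value[i]`` is its prediction.
    Internal nodes route rows with x[feature] <= threshold to ``left``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            active = self.feature[node] >= 0
        return self.value[node]

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.int64),
            right=np.asarray(d["right"], dtype=np.int64),
            value=np.asarray(d["value"], dtype=float),
        )


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int,
    min_leaf: int = 5,
    rng: np.random.Generator | None = None,
) -> RegressionTree:
    """Grow one tree by recursive SSR-minimising splitting.

    A node becomes a leaf when it has fewer than ``2 * min_leaf`` samples,
    its targets are constant, or no candidate feature admits a valid split.
    Candidate features are re-drawn at every node (``mtry`` without
    replacement); only splits leaving at least ``min_leaf`` samples per child
    are considered.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ForestError("cannot grow a tree on an empty sample")
    p = X.shape[1]
    if not (1 <= mtry <= p):
        raise ForestError(f"mtry must be in [1, {p}], got {mtry}")
    if rng is None:
        rng = np.random.default_rng()

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        value.append(np.nan)
        return len(feature) - 1

    def build(idx: np.ndarray, node: int) -> None:
        yn = y[idx]
        if idx.size < 2 * min_leaf or np.ptp(yn) == 0.0:
            value[node] = float(yn.mean())
            return
        cand = rng.choice(p, size=mtry, replace=False)
        crit = best_split(X[idx], yn, cand, min_leaf=min_leaf)
        if crit is None:
            value[node] = float(yn.mean())
            return
        go_left = X[idx, crit.feature_index] <= crit.split_value
        feature[node] = crit.feature_index
        threshold[node] = crit.split_value
        li, ri = new_node(), new_node()
        left[node], right[node] = li, ri
        build(idx[go_left], li)
        build(idx[~go_left], ri)

    root = new_node()
    build(np.arange(X.shape[0]), root)
    return RegressionTree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        value=np.asarray(value, dtype=float),
    )


@dataclass
class Forest:
    """Bagged ensemble of regression trees with a normalised weight vector."""

    trees: list[RegressionTree]
    tree_weights: np.ndarray
    bag_indices: list[np.ndarray]
    rng_seed: int | None = None
    y_range: tuple[float, float] = (-np.inf, np.inf)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tree_weights = np.asarray(self.tree_weights, dtype=float)
        if len(self.trees) < 1:
            raise ForestError("a forest needs at least one tree")
        if abs(self.tree_weights.sum() - 1.0) > 1e-12:
            raise ForestError("tree weights must sum to 1")
        if (self.tree_weights < 0).any():
            raise ForestError("tree weights must be non-negative")


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    mtry: int | None = None,
    min_leaf: int = 5,
    seed: int | None = None,
    bootstrap: bool = True,
    tree_weights: np.ndarray | None = None,
) -> Forest:
    """Fit a bagged forest: each tree trains on an n-with-replacement resample.

    ``mtry`` defaults to ceil(p/3) — 2 of the 6 wearable features.  Each tree
    draws its bag and all node-level candidate subsets from its own
    seed-sequence substream, so a given ``seed`` reproduces the forest exactly
    regardless of fit order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ForestError("need at least 2 training samples")
    if n_trees < 1:
        raise ForestError("n_trees must be >= 1")
    if mtry is None:
        mtry = int(np.ceil(p / 3))
    streams = np.random.SeedSequence(seed).spawn(n_trees)
    trees: list[RegressionTree] = []
    bags: list[np.ndarray] = []
    for t in range(n_trees):
        rng = np.random.default_rng(streams[t])
        bag = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        trees.append(grow_tree(X[bag], y[bag], mtry=mtry, min_leaf=min_leaf, rng=rng))
        bags.append(bag)
    if tree_weights is None:
        weights = np.full(n_trees, 1.0 / n_trees)
    else:
        weights = np.asarray(tree_weights, dtype=float)
    return Forest(
        trees=trees,
        tree_weights=weights,
        bag_indices=bags,
        rng_seed=seed,
        y_range=(float(y.min()), float(y.max())),
        params={"n_trees": n_trees, "mtry": mtry, "min_leaf": min_leaf, "bootstrap": bootstrap},
    )


def predict_forest(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Weighted average of the individual tree predictions, row by row."""
    X = np.asarray(X, dtype=float)
    p_expected = None
    for tree in forest.trees:
        used = tree.feature[tree.feature >= 0]
        if used.size:
            p_expected = max(p_expected or 0, int(used.max()) + 1)
    if p_expected is not None and X.shape[1] < p_expected:
        raise ForestError(f"feature matrix has {X.shape[1]} columns, trees use {p_expected}")
    preds = np.zeros(X.shape[0])
    for w, tree in zip(forest.tree_weights, forest.trees):
        preds += w * tree.predict(X)
    return preds


@dataclass
class ForestEnsemble:
    """One forest per leave-one-participant-out fold; predicts by plain averaging."""

    forests: list[Forest]
    fold_participant_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.forests) != len(self.fold_participant_ids):
            raise ForestError("one held-out participant id per forest required")
        if not self.forests:
            raise ForestError("empty ensemble")


def loso_cv(
    X: np.ndarray,
    y: np.ndarray,
    participant_ids: np.ndarray,
    n_trees: int = 100,
    mtry: int | None = None,
    min_leaf: int = 5,
    seed: int | None = None,
) -> tuple[ForestEnsemble, np.ndarray]:
    """Leave-one-participant-out cross-validation.

    For each participant a forest is trained with that participant's rows
    fully excluded and evaluated on them; with a 16-participant cohort this
    yields the 16-forest ensemble.  Returns the ensemble plus held-out
    predictions aligned to the input rows (each row predicted exactly once,
    by the fold that excluded it).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pids = np.asarray(participant_ids)
    unique = list(dict.fromkeys(pids.tolist()))  # first-appearance order
    if len(unique) < 2:
        raise ForestError("leave-one-participant-out needs at least 2 participants")
    streams = np.random.SeedSequence(seed).spawn(len(unique))
    forests: list[Forest] = []
    heldout = np.full(len(y), np.nan)
    for k, pid in enumerate(unique):
        test = pids == pid
        if not test.any():
            raise ForestError(f"participant {pid!r} has no rows")
        train = ~test
        fold_seed = int(streams[k].generate_state(1)[0] % (2**31))
        forest = fit_forest(
            X[train], y[train], n_trees=n_trees, mtry=mtry, min_leaf=min_leaf, seed=fold_seed
        )
        forests.append(forest)
        heldout[test] = predict_forest(forest, X[test])
    return ForestEnsemble(forests=forests, fold_participant_ids=unique), heldout


def ensemble_predict(ensemble: ForestEnsemble, X: np.ndarray) -> np.ndarray:
    """Unweighted mean of all fold forests' predictions (the final predictor)."""
    preds = np.zeros(np.asarray(X).shape[0])
    for forest in ensemble.forests:
        preds += predict_forest(forest, X)
    return preds / len(ensemble.forests)


# --- JSON round-trip -------------------------------------------------------

def forest_to_dict(forest: Forest) -> dict:
    return {
        "trees": [t.to_dict() for t in forest.trees],
        "tree_weights": forest.tree_weights.tolist(),
        "rng_seed": forest.rng_seed,
        "y_range": list(forest.y_range),
        "params": forest.params,
    }


def forest_from_dict(d: dict) -> Forest:
    trees = [RegressionTree.from_dict(t) for t in d["trees"]]
    return Forest(
        trees=trees,
        tree_weights=np.asarray(d["tree_weights"], dtype=float),
        bag_indices=[np.empty(0, dtype=np.int64)] * len(trees),
        rng_seed=d.get("rng_seed"),
        y_range=tuple(d.get("y_range", (-np.inf, np.inf))),
        params=d.get("params", {}),
    )


def save_ensemble(ensemble: ForestEnsemble, path, feature_order=None, meta=None) -> None:
    payload = {
        "format": "oxydyn-forest-ensemble",
        "version": 1,
        "feature_order": list(feature_order) if feature_order else None,
        "meta": meta or {},
        "fold_participant_ids": ensemble.fold_participant_ids,
        "forests": [forest_to_dict(f) for f in ensemble.forests],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble(path) -> tuple[ForestEnsemble, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "oxydyn-forest-ensemble":
        raise ForestError(f"{path}: not an oxydyn ensemble file")
    ensemble = ForestEnsemble(
        forests=[forest_from_dict(d) for d in payload["forests"]],
        fold_participant_ids=list(payload["fold_participant_ids"]),
    )
    return ensemble, {k: payload[k] for k in ("feature_order", "meta")}
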