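"""Fire-occurrence classifiers over seasonal soil-water features.

Two interchangeable predictors:

* :func:`apply_rules` — the fixed four-rule classifier.  Every rule keys on
  drought in the fire-year summer (severe for rules 1, 3 and 4; moderate for
  rule 2) combined with antecedent-season conditions — droughty falls and
  winters that leave fuels dry, or a favorable previous spring/winter that
  grows a flush of fine fuel which then cures.

* :class:`DecisionTree` via :func:`fit_tree` — a CART inducer: greedy binary
  recursive partitioning on Gini impurity, surrogate splits ranked by
  agreement with each primary split, cost-complexity pruning selected by
  k-fold cross-validation with the 1-SE rule, and surrogate-aware variable
  importance (a feature can matter without ever splitting a node itself).

Both emit binary fire / no-fire labels and are evaluated with the same
confusion-matrix summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import FEATURE_NAMES, SeasonalFeatures

__all__ = [
    "RuleSet",
    "apply_rules",
    "apply_rules_frame",
    "TreeNode",
    "DecisionTree",
    "fit_tree",
    "variable_importance",
    "ConfusionSummary",
    "confusion_stats",
    "rule_usage",
    "UnroutableInputError",
    "NoFirePredictionsError",
]


class UnroutableInputError(ValueError):
    """Feature vector entirely missing: neither primary nor surrogate splits apply."""


class NoFirePredictionsError(ValueError):
    """Rule-usage percentages are undefined when nothing was predicted to burn."""


# ---------------------------------------------------------------------------
# Fixed four-rule classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleSet:
    """Thresholds of the four-rule classifier.

    Only ``severe_summer`` (0.12) is an empirically identified value; the
    qualitative levels "moderate", "droughty" and "favorable" carry no
    published numbers, so their defaults are stand-ins chosen to order
    sensibly and are meant to be configured.
    """

    severe_summer: float = 0.12
    moderate_summer: float = 0.30
    droughty: float = 0.40
    favorable: float = 0.60

    def __post_init__(self) -> None:
        if not 0 < self.severe_summer < self.moderate_summer < 1:
            raise ValueError("need 0 < severe_summer < moderate_summer < 1")
        if not 0 < self.droughty < self.favorable < 1:
            raise ValueError("need 0 < droughty < favorable < 1")


def apply_rules(features: SeasonalFeatures, rules: RuleSet = RuleSet()) -> tuple[int, int | None]:
    """Classify one pixel-year with the four fixed rules, evaluated in order.

    Rule 1: severe summer drought + moderate (sub-favorable) previous spring
    + droughty current fall.  Rule 2: moderate (but not severe) summer
    drought + droughty previous fall and winter.  Rule 3: severe summer
    drought + droughty previous fall but a favorable previous winter (flash
    fuel).  Rule 4: severe summer drought + favorable previous spring.

    Returns ``(label, rule_id)`` with label 1 = fire and rule_id in 1..4 for
    the first matching rule, or ``(0, None)``.
    """
    f = features
    r = rules
    if f.summer_cur < r.severe_summer:
        if f.spring_prev < r.favorable and f.autumn_cur < r.droughty:
            return 1, 1
        if f.autumn_prev < r.droughty and f.winter_prev >= r.favorable:
            return 1, 3
        if f.spring_prev >= r.favorable:
            return 1, 4
    elif f.summer_cur < r.moderate_summer:
        if f.autumn_prev < r.droughty and f.winter_prev < r.droughty:
            return 1, 2
    return 0, None


def apply_rules_frame(features: pd.DataFrame, rules: RuleSet = RuleSet()) -> pd.DataFrame:
    """Vectorized :func:`apply_rules` over a feature table.

    ``features`` must carry the eight seasonal columns; returns a copy with
    ``pred`` (0/1) and ``rule_id`` (1-4 or <NA>) appended.  Rule precedence
    matches the scalar version (first match wins).
    """
    f = features
    r = rules
    severe = f["summer_cur"] < r.severe_summer
    rule1 = severe & (f["spring_prev"] < r.favorable) & (f["autumn_cur"] < r.droughty)
    rule2 = (
        (~severe)
        & (f["summer_cur"] < r.moderate_summer)
        & (f["autumn_prev"] < r.droughty)
        & (f["winter_prev"] < r.droughty)
    )
    rule3 = severe & (f["autumn_prev"] < r.droughty) & (f["winter_prev"] >= r.favorable)
    rule4 = severe & (f["spring_prev"] >= r.favorable)

    rule_id = np.select(
        [rule1, rule2, rule3, rule4], [1, 2, 3, 4], default=0
    )
    out = features.copy()
    out["pred"] = (rule_id > 0).astype(int)
    out["rule_id"] = pd.array(
        np.where(rule_id > 0, rule_id, np.nan), dtype="Int64"
    )
    return out


# ---------------------------------------------------------------------------
# CART: growth
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """One node of a binary classification tree.

    Internal nodes carry a primary split (feature index, threshold; values
    ``<= threshold`` go left) and up to ``n_surrogates`` surrogate splits as
    tuples ``(feature, threshold, flipped, agreement, gain)``.  ``flipped``
    means values ``<= threshold`` follow the primary split's *right* branch.
    """

    n: int
    counts: tuple[int, int]  # (class-0, class-1) sample counts
    feature: int | None = None
    threshold: float | None = None
    gain: float = 0.0  # Gini improvement of the primary split, sample-weighted
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    surrogates: list[tuple[int, float, bool, float, float]] = field(default_factory=list)
    majority_left: bool = True  # fallback direction when nothing routes

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> int:
        return int(self.counts[1] >= self.counts[0])

    @property
    def proportions(self) -> tuple[float, float]:
        return (self.counts[0] / self.n, self.counts[1] / self.n)


def _gini(counts: np.ndarray, n) -> np.ndarray:
    """Gini impurity from class-1 counts given totals n (vectorized)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n
    return 1.0 - p**2 - (1.0 - p) ** 2


def _best_split(X: np.ndarray, y: np.ndarray, min_node: int):
    """Exhaustive best Gini split over all features and midpoint thresholds.

    Returns ``(feature, threshold, gain)`` or ``None``.  Gain is the
    node-local impurity decrease (parent Gini minus child-weighted Gini).
    Ties break to the lowest feature index, then the smallest threshold.
    """
    n = len(y)
    n1 = int(y.sum())
    parent = float(_gini(np.array(n1), np.array(n)))
    best = None  # (gain, feature, threshold)
    for j in range(X.shape[1]):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ys = y[order]
        cum1 = np.cumsum(ys)
        idx = np.arange(1, n)  # split after idx samples on the left
        mids = 0.5 * (xs[:-1] + xs[1:])
        # midpoint must strictly separate its neighbors (guards float collapse
        # when adjacent values differ by one ulp)
        valid = (mids > xs[:-1]) & (mids < xs[1:])
        valid &= (idx >= min_node) & (n - idx >= min_node)
        if not valid.any():
            continue
        nl = idx[valid].astype(float)
        nr = n - nl
        c1l = cum1[:-1][valid].astype(float)
        c1r = n1 - c1l
        weighted = (nl * _gini(c1l, nl) + nr * _gini(c1r, nr)) / n
        gains = parent - weighted
        k = int(np.argmax(gains))  # first max -> smallest threshold
        gain = float(gains[k])
        pos = idx[valid][k]
        thr = mids[pos - 1]
        if best is None or gain > best[0] + 1e-12:
            best = (gain, j, float(thr))
    if best is None or best[0] <= 1e-12:
        return None
    return best[1], best[2], best[0]


def _grow(X, y, min_node: int, max_depth: int | None, depth: int = 0) -> TreeNode:
    n = len(y)
    n1 = int(y.sum())
    node = TreeNode(n=n, counts=(n - n1, n1))
    if n1 in (0, n) or n < 2 * min_node or (max_depth is not None and depth >= max_depth):
        return node
    split = _best_split(X, y, min_node)
    if split is None:
        return node
    j, thr, gain = split
    go_left = X[:, j] <= thr
    node.feature = j
    node.threshold = thr
    node.gain = gain * n  # store sample-weighted improvement for importance
    node.majority_left = bool(go_left.sum() >= (~go_left).sum())
    node.left = _grow(X[go_left], y[go_left], min_node, max_depth, depth + 1)
    node.right = _grow(X[~go_left], y[~go_left], min_node, max_depth, depth + 1)
    return node


# ---------------------------------------------------------------------------
# Surrogate splits
# ---------------------------------------------------------------------------

def _best_surrogate(x: np.ndarray, go_left: np.ndarray, y: np.ndarray):
    """Best threshold on ``x`` mimicking the primary routing ``go_left``.

    Considers both orientations.  Returns ``(threshold, flipped, agreement,
    gain)`` where gain is the sample-weighted Gini improvement the surrogate
    split itself achieves on ``y``, or ``None`` if no non-trivial split
    exists.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    gl = go_left[order].astype(float)
    ys = y[order].astype(float)
    total_left = gl.sum()
    cum_gl = np.cumsum(gl)[:-1]
    idx = np.arange(1, n).astype(float)
    mids = 0.5 * (xs[:-1] + xs[1:])
    valid = (mids > xs[:-1]) & (mids < xs[1:])
    if not valid.any():
        return None
    # agreement when (x <= t) routes left:
    agree_plain = cum_gl + ((n - idx) - (total_left - cum_gl))
    agree = np.maximum(agree_plain, n - agree_plain)
    flipped = agree_plain < (n - agree_plain)
    agree[~valid] = -1.0
    k = int(np.argmax(agree))
    if agree[k] < 0:
        return None
    thr = mids[k]
    # Gini improvement of this split on the labels:
    n1 = ys.sum()
    cum1 = np.cumsum(ys)[:-1]
    nl = idx[k]
    nr = n - nl
    parent = float(_gini(np.array(n1), np.array(float(n))))
    child = (nl * float(_gini(np.array(cum1[k]), np.array(nl)))
             + nr * float(_gini(np.array(n1 - cum1[k]), np.array(nr)))) / n
    gain = max(parent - child, 0.0) * n
    return float(thr), bool(flipped[k]), float(agree[k] / n), float(gain)


def _attach_surrogates(node: TreeNode, X: np.ndarray, y: np.ndarray, n_surrogates: int) -> None:
    """Recursively compute ranked surrogate splits for every internal node."""
    if node.is_leaf:
        return
    go_left = X[:, node.feature] <= node.threshold
    baseline = max(go_left.mean(), 1.0 - go_left.mean())
    found = []
    for j in range(X.shape[1]):
        if j == node.feature:
            continue
        res = _best_surrogate(X[:, j], go_left, y)
        if res is None:
            continue
        thr, flipped, agreement, gain = res
        if agreement > baseline + 1e-12:  # must beat the blind majority rule
            found.append((j, thr, flipped, agreement, gain))
    found.sort(key=lambda t: (-t[3], t[0]))
    node.surrogates = found[:n_surrogates]
    _attach_surrogates(node.left, X[go_left], y[go_left], n_surrogates)
    _attach_surrogates(node.right, X[~go_left], y[~go_left], n_surrogates)


# ---------------------------------------------------------------------------
# Cost-complexity pruning with k-fold cross-validation
# ---------------------------------------------------------------------------

def _subtree_stats(node: TreeNode) -> tuple[int, int]:
    """(misclassified count over the subtree's leaves, number of leaves)."""
    if node.is_leaf:
        return min(node.counts), 1
    ml, ll = _subtree_stats(node.left)
    mr, lr = _subtree_stats(node.right)
    return ml + mr, ll + lr


def _weakest_alphas(root: TreeNode, n_total: int) -> list[float]:
    """Increasing sequence of critical alphas from weakest-link pruning."""
    alphas = [0.0]

    def collect(node: TreeNode, out: list[float]):
        if node.is_leaf:
            return
        m, leaves = _subtree_stats(node)
        g = (min(node.counts) - m) / (n_total * max(leaves - 1, 1))
        out.append(g)
        collect(node.left, out)
        collect(node.right, out)

    # iteratively prune a copy
    work = _copy_tree(root)
    while not work.is_leaf:
        gs: list[float] = []
        collect(work, gs)
        gmin = min(gs)
        alphas.append(gmin)
        _prune_where_g(work, n_total, gmin)
    return sorted(set(alphas))


def _copy_tree(node: TreeNode) -> TreeNode:
    new = TreeNode(
        n=node.n,
        counts=node.counts,
        feature=node.feature,
        threshold=node.threshold,
        gain=node.gain,
        surrogates=list(node.surrogates),
        majority_left=node.majority_left,
    )
    if not node.is_leaf:
        new.left = _copy_tree(node.left)
        new.right = _copy_tree(node.right)
    return new


def _prune_where_g(node: TreeNode, n_total: int, gmin: float) -> None:
    if node.is_leaf:
        return
    _prune_where_g(node.left, n_total, gmin)
    _prune_where_g(node.right, n_total, gmin)
    m, leaves = _subtree_stats(node)
    g = (min(node.counts) - m) / (n_total * max(leaves - 1, 1))
    if g <= gmin + 1e-15:
        node.feature = None
        node.threshold = None
        node.left = None
        node.right = None
        node.surrogates = []


def _pruned_copy(root: TreeNode, alpha: float, n_total: int) -> TreeNode:
    """Smallest optimally pruned subtree for complexity penalty ``alpha``."""
    new = _copy_tree(root)

    def prune(node: TreeNode):
        if node.is_leaf:
            return
        prune(node.left)
        prune(node.right)
        m, leaves = _subtree_stats(node)
        # collapse when the leaf risk is no worse than subtree risk + penalty
        if min(node.counts) / n_total <= m / n_total + alpha * (leaves - 1) + 1e-15:
            node.feature = None
            node.threshold = None
            node.left = None
            node.right = None
            node.surrogates = []

    prune(new)
    return new


def _stats_map(node: TreeNode, memo: dict) -> tuple[int, int]:
    """Memoized (subtree misclassification count, leaf count) per node."""
    if node.is_leaf:
        memo[id(node)] = (min(node.counts), 1)
    else:
        ml, ll = _stats_map(node.left, memo)
        mr, lr = _stats_map(node.right, memo)
        memo[id(node)] = (ml + mr, ll + lr)
    return memo[id(node)]


def _predict_pruned(
    node: TreeNode,
    alpha: float,
    n_total: int,
    X: np.ndarray,
    idx: np.ndarray,
    out: np.ndarray,
    memo: dict,
) -> None:
    """Route samples through the alpha-pruned subtree without materializing it."""
    if len(idx) == 0:
        return
    if not node.is_leaf:
        m, leaves = memo[id(node)]
        collapsed = min(node.counts) / n_total <= m / n_total + alpha * (leaves - 1) + 1e-15
    else:
        collapsed = True
    if collapsed:
        out[idx] = node.prediction
        return
    left = X[idx, node.feature] <= node.threshold
    _predict_pruned(node.left, alpha, n_total, X, idx[left], out, memo)
    _predict_pruned(node.right, alpha, n_total, X, idx[~left], out, memo)


def _route(node: TreeNode, x: np.ndarray) -> int:
    while not node.is_leaf:
        v = x[node.feature]
        if not np.isnan(v):
            node = node.left if v <= node.threshold else node.right
            continue
        for j, thr, flipped, _agree, _gain in node.surrogates:
            w = x[j]
            if np.isnan(w):
                continue
            left = (w <= thr) != flipped
            node = node.left if left else node.right
            break
        else:
            if np.all(np.isnan(x)):
                raise UnroutableInputError("all feature values missing")
            node = node.left if node.majority_left else node.right
    return node.prediction


@dataclass
class DecisionTree:
    """A fitted CART classifier over the eight seasonal fASW features."""

    root: TreeNode
    feature_names: tuple[str, ...] = FEATURE_NAMES
    alpha: float = 0.0
    cv_error: float | None = None

    @property
    def n_leaves(self) -> int:
        return _subtree_stats(self.root)[1]

    @property
    def root_split(self) -> tuple[str, float] | None:
        if self.root.is_leaf:
            return None
        return self.feature_names[self.root.feature], float(self.root.threshold)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        return np.array([_route(self.root, row) for row in X], dtype=int)

    def importance(self) -> pd.Series:
        return variable_importance(self)

    # -- plain-text serialization -------------------------------------------
    def to_text(self) -> str:
        def encode(node: TreeNode) -> dict:
            d = {"n": node.n, "counts": list(node.counts)}
            if not node.is_leaf:
                d.update(
                    feature=self.feature_names[node.feature],
                    threshold=node.threshold,
                    gain=node.gain,
                    majority_left=node.majority_left,
                    surrogates=[
                        {
                            "feature": self.feature_names[j],
                            "threshold": thr,
                            "flipped": flipped,
                            "agreement": agree,
                            "gain": gain,
                        }
                        for j, thr, flipped, agree, gain in node.surrogates
                    ],
                    left=encode(node.left),
                    right=encode(node.right),
                )
            return d

        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "alpha": self.alpha,
                "cv_error": self.cv_error,
                "tree": encode(self.root),
            },
            indent=2,
        )

    @classmethod
    def from_text(cls, text: str) -> "DecisionTree":
        payload = json.loads(text)
        names = tuple(payload["feature_names"])
        index = {n: i for i, n in enumerate(names)}

        def decode(d: dict) -> TreeNode:
            node = TreeNode(n=d["n"], counts=tuple(d["counts"]))
            if "feature" in d:
                node.feature = index[d["feature"]]
                node.threshold = d["threshold"]
                node.gain = d["gain"]
                node.majority_left = d["majority_left"]
                node.surrogates = [
                    (
                        index[s["feature"]],
                        s["threshold"],
                        s["flipped"],
                        s["agreement"],
                        s["gain"],
                    )
                    for s in d["surrogates"]
                ]
                node.left = decode(d["left"])
                node.right = decode(d["right"])
            return node

        return cls(
            root=decode(payload["tree"]),
            feature_names=names,
            alpha=payload["alpha"],
            cv_error=payload["cv_error"],
        )


def _as_matrix(X, feature_names) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X[list(feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def fit_tree(
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    min_node: int = 20,
    max_depth: int | None = None,
    n_surrogates: int = 5,
    feature_names: tuple[str, ...] | None = None,
) -> DecisionTree:
    """Induce a pruned CART classifier.

    Grows the full tree by greedy Gini partitioning (children must each keep
    ``min_node`` samples), derives the weakest-link alpha sequence, estimates
    the misclassification of every candidate complexity by ``folds``-fold
    cross-validation (stratified, seeded), picks the largest alpha within one
    standard error of the CV minimum (1-SE rule), prunes, and finally attaches
    ranked surrogate splits to the surviving internal nodes.

    A single-class input yields a single-leaf tree with a warning.
    """
    if feature_names is None:
        if isinstance(X, pd.DataFrame):
            if set(FEATURE_NAMES) <= set(X.columns):
                feature_names = FEATURE_NAMES
            else:
                feature_names = tuple(X.columns)
        else:
            p = np.asarray(X).shape[1]
            feature_names = FEATURE_NAMES if p == 8 else tuple(f"x{i}" for i in range(p))
    Xm = _as_matrix(X, feature_names) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yv = np.asarray(y, dtype=int)
    if Xm.shape[0] != yv.shape[0]:
        raise ValueError("X and y length mismatch")
    n = len(yv)
    # the unpruned tree can form chains ~n/min_node deep; growth and pruning
    # recurse one frame per level, so give them headroom
    import sys

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * (n // max(min_node, 1) + 100)))
    if len(np.unique(yv)) < 2:
        warnings.warn("single-class input: returning a degenerate single-leaf tree")
        n1 = int(yv.sum())
        return DecisionTree(root=TreeNode(n=n, counts=(n - n1, n1)), feature_names=feature_names)

    full = _grow(Xm, yv, min_node, max_depth)
    alphas = _weakest_alphas(full, n)
    # evaluate at geometric midpoints of consecutive critical alphas
    grid = [0.0]
    for a, b in zip(alphas, alphas[1:]):
        grid.append(float(np.sqrt(max(a, 1e-12) * b)) if a > 0 else 0.5 * b)
    grid.append(alphas[-1] * 1.001 + 1e-12)
    grid = sorted(set(grid))

    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(yv == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds

    errors = np.zeros((len(grid), n), dtype=bool)
    for k in range(folds):
        test = np.flatnonzero(fold_of == k)
        train = np.flatnonzero(fold_of != k)
        sub = _grow(Xm[train], yv[train], min_node, max_depth)
        memo: dict = {}
        _stats_map(sub, memo)
        preds = np.empty(len(test), dtype=int)
        for gi, alpha in enumerate(grid):
            _predict_pruned(sub, alpha, len(train), Xm[test], np.arange(len(test)), preds, memo)
            errors[gi, test] = preds != yv[test]

    cv_err = errors.mean(axis=1)
    best = int(np.argmin(cv_err))
    # 1-SE rule with the SE of the CV estimate taken from fold-to-fold spread
    fold_means = np.stack(
        [errors[:, fold_of == k].mean(axis=1) for k in range(folds)], axis=1
    )
    se = float(fold_means[best].std(ddof=1) / np.sqrt(folds))
    within = np.flatnonzero(cv_err <= cv_err[best] + se)
    chosen = int(within.max())  # largest alpha (smallest tree) within 1 SE
    alpha = grid[chosen]

    pruned = _pruned_copy(full, alpha, n)
    _attach_surrogates(pruned, Xm, yv, n_surrogates)
    return DecisionTree(
        root=pruned,
        feature_names=feature_names,
        alpha=float(alpha),
        cv_error=float(cv_err[chosen]),
    )


def variable_importance(tree: DecisionTree) -> pd.Series:
    """Per-feature importance, scaled so the best feature scores 100.

    Sums each feature's sample-weighted Gini improvement over every node where
    it acts as the primary splitter, plus the improvement its surrogate split
    achieves at nodes where it mimics another feature's primary split.  A
    single-leaf tree scores all zeros.
    """
    scores = np.zeros(len(tree.feature_names))

    def walk(node: TreeNode):
        if node.is_leaf:
            return
        scores[node.feature] += node.gain
        for j, _thr, _flip, _agree, gain in node.surrogates:
            scores[j] += gain
        walk(node.left)
        walk(node.right)

    walk(tree.root)
    top = scores.max()
    if top > 0:
        scores = 100.0 * scores / top
    return pd.Series(scores, index=list(tree.feature_names))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts with overall and per-class accuracies."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def accuracy_fire_present(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def accuracy_fire_absent(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "accuracy_fire_present": self.accuracy_fire_present,
            "accuracy_fire_absent": self.accuracy_fire_absent,
        }


def confusion_stats(pred, obs) -> ConfusionSummary:
    """Confusion counts of binary predictions against observations."""
    pred = np.asarray(pred, dtype=int)
    obs = np.asarray(obs, dtype=int)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: pred {pred.shape} vs obs {obs.shape}")
    return ConfusionSummary(
        tp=int(((pred == 1) & (obs == 1)).sum()),
        fp=int(((pred == 1) & (obs == 0)).sum()),
        fn=int(((pred == 0) & (obs == 1)).sum()),
        tn=int(((pred == 0) & (obs == 0)).sum()),
    )


def rule_usage(rule_ids) -> pd.Series:
    """Percentage share of each rule among fire predictions (sums to 100).

    ``rule_ids`` holds 1-4 for fire predictions and missing/None otherwise.
    Raises :class:`NoFirePredictionsError` when no fires were predicted.
    """
    ids = pd.Series(rule_ids).dropna().astype(int)
    if len(ids) == 0:
        raise NoFirePredictionsError("no fire predictions: rule percentages undefined")
    counts = ids.value_counts().reindex([1, 2, 3, 4], fill_value=0)
    return 100.0 * counts / counts.sum()
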