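"""Unsupervised random-forest clustering of motion patterns.

The construction is the classic "addcl" contrast scheme: a synthetic class
is built by independently permuting each feature column, a random forest is
trained to separate real from synthetic rows (each split maximizes Gini
information gain over a random feature subset), and the fraction of trees
in which two real observations share a terminal leaf defines a proximity.
Observations are then partitioned by k-medoids on the dissimilarity
sqrt(1 - proximity), the cluster count is chosen with the elbow method on
the within-cluster sum of squares (WSS), and clusters are profiled as
z-value summaries per variable.

Tree growing is delegated to scikit-learn's RandomForestClassifier, which
implements exactly the max-information-gain split over ``mtry`` sampled
features; the contrast-class construction, proximity accumulation,
k-medoids partitioning and model-selection curves are implemented here.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateForestError, InvalidArgumentError


# ---------------------------------------------------------------------------
# impurity primitives
# ---------------------------------------------------------------------------

def gini_impurity(labels) -> float:
    """Gini impurity 1 - sum(p_c^2) of a label multiset."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InvalidArgumentError("labels must be non-empty")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - np.sum(p ** 2))


def information_gain(parent_labels, left_labels, right_labels) -> float:
    """Gini information gain of a binary split.

    IG = I(parent) - (N_left/N) I(left) - (N_right/N) I(right); the two
    children must exactly partition the parent multiset.  Non-negative by
    concavity of the Gini index; an empty child contributes zero gain.
    """
    parent = np.asarray(parent_labels)
    left = np.asarray(left_labels)
    right = np.asarray(right_labels)
    if Counter(left.tolist()) + Counter(right.tolist()) != Counter(parent.tolist()):
        raise InvalidArgumentError("children do not partition the parent")
    n = parent.size
    ig = gini_impurity(parent)
    for child in (left, right):
        if child.size:
            ig -= child.size / n * gini_impurity(child)
    return float(max(ig, 0.0))


# ---------------------------------------------------------------------------
# unsupervised forest and proximity
# ---------------------------------------------------------------------------

@dataclass
class ForestConfig:
    """Random-forest hyperparameters (conventional defaults, all exposed)."""

    n_trees: int = 500
    mtry: int | None = None   # default: ceil(sqrt(n_features))
    max_depth: int | None = None
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise InvalidArgumentError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise InvalidArgumentError("mtry must be >= 1")
        if self.min_leaf < 1:
            raise InvalidArgumentError("min_leaf must be >= 1")


def zscore(features: np.ndarray) -> np.ndarray:
    """Column-wise z-scores; constant columns raise (degenerate forest)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("features must be a 2-D array")
    constant = np.ptp(X, axis=0) == 0
    if np.any(constant):
        bad = int(np.flatnonzero(constant)[0])
        raise DegenerateForestError(f"feature column {bad} is constant")
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)


def fit_unsupervised_forest(features: np.ndarray, config: ForestConfig | None = None,
                            ):
    """Fit the real-vs-permuted contrast forest and return its proximity.

    Returns ``(forest, proximity)`` where ``proximity[i, j]`` is the
    fraction of trees placing real observations i and j in the same
    terminal leaf (symmetric, unit diagonal, entries in [0, 1]).
    Deterministic under ``config.seed``.
    """
    from sklearn.ensemble import RandomForestClassifier

    config = config or ForestConfig()
    X = zscore(features)
    n, k = X.shape
    if n < 2:
        raise InvalidArgumentError("need at least 2 observations")
    if config.mtry is not None and config.mtry > k:
        raise InvalidArgumentError("mtry cannot exceed the feature count")
    mtry = config.mtry or int(np.ceil(np.sqrt(k)))

    rng = np.random.default_rng(config.seed)
    synthetic = np.column_stack([rng.permutation(X[:, j]) for j in range(k)])
    X_train = np.vstack([X, synthetic])
    y_train = np.concatenate([np.zeros(n), np.ones(n)])

    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=mtry,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_leaf,
        random_state=int(rng.integers(2 ** 31)),
    )
    forest.fit(X_train, y_train)

    leaves = forest.apply(X)   # (n, n_trees), real observations only
    prox = np.zeros((n, n), dtype=float)
    for t in range(leaves.shape[1]):
        col = leaves[:, t]
        prox += col[:, None] == col[None, :]
    prox /= leaves.shape[1]
    np.fill_diagonal(prox, 1.0)
    return forest, prox


def proximity_to_dissimilarity(prox: np.ndarray) -> np.ndarray:
    """Canonical mapping sqrt(1 - proximity), clipped for numerical safety."""
    return np.sqrt(np.clip(1.0 - np.asarray(prox, dtype=float), 0.0, None))


# ---------------------------------------------------------------------------
# k-medoids on the proximity dissimilarity
# ---------------------------------------------------------------------------

def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = D[medoids]                       # (k, n)
    labels = np.argmin(sub, axis=0)
    cost = float(sub[labels, np.arange(D.shape[0])].sum())
    return labels, cost


def _pam_once(D: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    labels, cost = _assign(D, medoids)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # re-seed an empty cluster at the worst-served point
                worst = int(np.argmax(D[medoids].min(axis=0)))
                new_medoids[c] = worst
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        new_labels, new_cost = _assign(D, new_medoids)
        if new_cost >= cost - 1e-12:
            break
        medoids, labels, cost = new_medoids, new_labels, new_cost
    return medoids, labels, cost


def cluster_from_proximity(prox: np.ndarray, k: int, seed: int = 0,
                           n_restarts: int = 10,
                           exhaustive_limit: int = 2000) -> np.ndarray:
    """k-medoids partition of observations from a proximity matrix.

    Dissimilarity is sqrt(1 - proximity).  Tiny instances (few possible
    medoid sets) are solved exactly by enumeration; larger ones use seeded
    PAM-style alternation with multiple restarts.  Every observation is
    assigned to exactly one cluster.
    """
    prox = np.asarray(prox, dtype=float)
    n = prox.shape[0]
    if prox.ndim != 2 or prox.shape[1] != n:
        raise InvalidArgumentError("proximity must be square")
    if not 2 <= k < n:
        raise InvalidArgumentError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    D = proximity_to_dissimilarity(prox)

    from math import comb
    if comb(n, k) <= exhaustive_limit:
        best_cost, best_labels = np.inf, None
        for medoids in itertools.combinations(range(n), k):
            labels, cost = _assign(D, np.array(medoids))
            if cost < best_cost - 1e-12:
                best_cost, best_labels = cost, labels
        return _canonical_labels(best_labels)

    rng = np.random.default_rng(seed)
    best_cost, best_labels = np.inf, None
    for _ in range(n_restarts):
        _, labels, cost = _pam_once(D, k, rng)
        if cost < best_cost - 1e-12:
            best_cost, best_labels = cost, labels
    return _canonical_labels(best_labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters in order of first appearance (stable across runs)."""
    labels = np.asarray(labels)
    mapping = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# model selection and profiles
# ---------------------------------------------------------------------------

def _wss(Xz: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = Xz[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    wss_by_k: dict[int, float]
    aic_by_k: dict[int, float]
    bic_by_k: dict[int, float]
    r_squared: float
    profiles: "object"          # per-cluster z summaries (DataFrame)
    low_confidence: bool = False
    assignments_by_k: dict[int, np.ndarray] = field(default_factory=dict)


def _split_worst_cluster(Xz: np.ndarray, labels: np.ndarray, prox: np.ndarray,
                         seed: int) -> np.ndarray | None:
    """Refine a k-partition into k+1 by splitting the worst cluster.

    The cluster with the largest within-SS contribution is split in two,
    first by 2-medoids on its proximity block, with a feature-space 2-means
    fallback; returns None when no cluster can be split.
    """
    contrib = {c: _wss(Xz[labels == c], np.zeros(np.sum(labels == c), int))
               for c in np.unique(labels)}
    members = None
    for c in sorted(contrib, key=contrib.get, reverse=True):
        cand_members = np.flatnonzero(labels == c)
        if cand_members.size >= 2:
            members = cand_members
            break
    if members is None:
        return None
    new_label = labels.max() + 1
    if np.ptp(Xz[members], axis=0).max() == 0:
        # identical points: any bisection leaves the WSS unchanged
        trial = labels.copy()
        trial[members[: members.size // 2]] = new_label
        return trial
    candidates = []
    if members.size > 2:
        try:
            sub = cluster_from_proximity(prox[np.ix_(members, members)], 2,
                                         seed=seed)
            candidates.append(sub)
        except InvalidArgumentError:
            pass
    # deterministic 2-means fallback in feature space
    pts = Xz[members]
    far = np.argmax(np.linalg.norm(pts - pts[0], axis=1))
    centers = np.stack([pts[0], pts[far]])
    assign = np.zeros(members.size, dtype=int)
    for _ in range(50):
        d = np.linalg.norm(pts[:, None, :] - centers[None], axis=2)
        new_assign = np.argmin(d, axis=1)
        if np.array_equal(new_assign, assign) or len(set(new_assign)) < 2:
            break
        assign = new_assign
        centers = np.stack([pts[assign == 0].mean(axis=0),
                            pts[assign == 1].mean(axis=0)])
    if len(set(assign)) == 2:
        candidates.append(assign)

    best, best_w = None, np.inf
    for cand in candidates:
        if len(set(cand.tolist())) < 2:
            continue
        trial = labels.copy()
        trial[members[cand == 1]] = new_label
        w = _wss(Xz, trial)
        if w < best_w:
            best, best_w = trial, w
    return best


def elbow_select_k(features: np.ndarray, prox: np.ndarray, k_max: int = 8,
                   seed: int = 0,
                   ) -> tuple[int, dict[int, float], dict[int, float], dict[int, float], dict[int, np.ndarray], bool]:
    """Cluster for k = 2..k_max and locate the WSS elbow.

    WSS is evaluated in z-scored feature space (k = 1 gives the total sum
    of squares).  For each k the proximity k-medoids solution competes
    against a split-refinement of the previous solution, which keeps the
    reported curve non-increasing even when PAM lands in a local optimum.
    The knee is the k maximizing the second forward difference of the WSS
    curve; AIC = WSS + 2*k*p and BIC = WSS + ln(n)*k*p (p features) are
    reported alongside.  A knee whose prominence is below 25% of the total
    sum of squares sets the low-confidence flag.
    """
    if k_max < 2:
        raise InvalidArgumentError("k_max must be >= 2")
    Xz = zscore(features)
    n, p = Xz.shape
    if k_max >= n:
        raise InvalidArgumentError("k_max must be below the observation count")

    wss = {1: _wss(Xz, np.zeros(n, dtype=int))}
    assignments = {1: np.zeros(n, dtype=int)}
    for k in range(2, k_max + 1):
        labels = cluster_from_proximity(prox, k, seed=seed + k)
        w = _wss(Xz, labels)
        if w > wss[k - 1]:
            refined = _split_worst_cluster(Xz, assignments[k - 1], prox,
                                           seed=seed + 31 * k)
            if refined is not None and _wss(Xz, refined) < w:
                labels = _canonical_labels(refined)
                w = _wss(Xz, labels)
        assignments[k] = labels
        wss[k] = w
    aic = {k: w + 2.0 * k * p for k, w in wss.items()}
    bic = {k: w + np.log(n) * k * p for k, w in wss.items()}

    ks = np.arange(2, k_max)        # candidate knees need both neighbours
    if ks.size == 0:
        best_k, low_conf = 2, True
    else:
        d2 = np.array([wss[k - 1] - 2 * wss[k] + wss[k + 1] for k in ks])
        best_k = int(ks[int(np.argmax(d2))])
        low_conf = bool(d2.max() < 0.25 * wss[1])
    assignments.pop(1)
    return best_k, wss, aic, bic, assignments, low_conf


def cluster_profiles(features: np.ndarray, assignments: np.ndarray,
                     variable_names: list[str] | None = None):
    """Per-cluster z-value summaries and the solution's R-squared.

    Features are standardized over all observations; for every cluster and
    variable the mean z, its spread and the cluster size are reported --
    the quantities a ridge-line cluster plot displays.  Returns
    ``(profiles_dataframe, r_squared)`` with R^2 = 1 - WSS/TSS.
    """
    import pandas as pd

    Xz = zscore(features)
    labels = np.asarray(assignments)
    if labels.shape[0] != Xz.shape[0]:
        raise InvalidArgumentError("assignments must match the observation count")
    uniq = np.unique(labels)
    names = variable_names or [f"x{j + 1}" for j in range(Xz.shape[1])]

    rows = []
    for c in uniq:
        pts = Xz[labels == c]
        if pts.size == 0:
            raise InvalidArgumentError(f"cluster {c} is empty")
        for j, name in enumerate(names):
            rows.append({
                "cluster": int(c), "variable": name, "n": pts.shape[0],
                "mean_z": float(pts[:, j].mean()),
                "sd_z": float(pts[:, j].std(ddof=1)) if pts.shape[0] > 1 else 0.0,
                "q25_z": float(np.percentile(pts[:, j], 25)),
                "q75_z": float(np.percentile(pts[:, j], 75)),
            })
    tss = float((Xz ** 2).sum())
    r2 = 1.0 - _wss(Xz, labels) / tss if tss > 0 else 0.0
    return pd.DataFrame(rows), float(r2)


def cluster_motion_patterns(features: np.ndarray,
                            variable_names: list[str] | None = None,
                            forest_config: ForestConfig | None = None,
                            k_max: int = 8, seed: int = 0) -> ClusterSolution:
    """End-to-end pattern identification for one condition (side x phase)."""
    forest_config = forest_config or ForestConfig(seed=seed)
    _, prox = fit_unsupervised_forest(features, forest_config)
    k, wss, aic, bic, by_k, low_conf = elbow_select_k(
        features, prox, k_max=k_max, seed=seed)
    labels = by_k[k]
    profiles, r2 = cluster_profiles(features, labels, variable_names)
    return ClusterSolution(k=k, assignments=labels, wss_by_k=wss,
                           aic_by_k=aic, bic_by_k=bic, r_squared=r2,
                           profiles=profiles, low_confidence=low_conf,
                           assignments_by_k=by_k)
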