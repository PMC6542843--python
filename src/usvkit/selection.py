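"""Feature ranking with four algorithms and a perturbation-voting protocol.

Four rankers over the design matrix: Gram-Schmidt orthogonalization (greedy
forward selection by squared correlation with the class indicators in the
null space of the already-selected features), minimum-redundancy
maximum-relevance (mutual-information difference criterion on discretized
features), SIMBA (margin-based feature weighting by stochastic ascent of the
hypothesis margin under a weighted Euclidean metric), and random-forest
permutation importance (mean decrease in out-of-bag accuracy).

Stability is assessed by ranking many stratified 90 % subsamples of the data
and aggregating the per-run orders with Borda voting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

METHODS = ("gso", "mrmr", "simba", "rf_accuracy")


@dataclass
class FeatureRanking:
    """A permutation of feature indices in descending order of merit."""

    order: np.ndarray
    scores: np.ndarray
    method: str
    runs: int = 1
    feature_names: list[str] | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.asarray(self.order)
        m = len(order)
        if sorted(order.tolist()) != list(range(m)):
            raise ValueError("order must be a permutation of the feature indices")
        self.order = order

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _one_hot(y) -> np.ndarray:
    classes = sorted(set(y))
    idx = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(y), len(classes)))
    for i, c in enumerate(y):
        Y[i, idx[c]] = 1.0
    return Y


# ---------------------------------------------------------------------------
# Gram-Schmidt orthogonalization
# ---------------------------------------------------------------------------

def gso_rank(X: np.ndarray, y, k: int | None = None) -> FeatureRanking:
    """Greedy forward ranking by orthogonalized correlation with the classes.

    At each step the candidate whose residual (projection onto the orthogonal
    complement of the selected set) has the largest sum of squared cosines
    with the residualized one-hot class indicators is selected, and its
    direction is deflated from every remaining candidate and from the target.
    Zero-variance residuals (e.g. duplicates of selected features) score 0.
    """
    Xr = _standardize(X).copy()
    Yr = _one_hot(y)
    Yr = Yr - Yr.mean(axis=0)
    n, m = Xr.shape
    k = m if k is None else min(k, m)
    order: list[int] = []
    scores = np.zeros(m)
    remaining = np.ones(m, dtype=bool)
    tol = 1e-10 * n
    for _ in range(k):
        xnorm2 = np.einsum("ij,ij->j", Xr, Xr)
        ynorm2 = np.einsum("ij,ij->j", Yr, Yr)
        cross = Xr.T @ Yr  # m x n_classes
        valid_y = ynorm2 > tol
        with np.errstate(divide="ignore", invalid="ignore"):
            merit = np.where(
                xnorm2[:, None] > tol,
                cross**2 / np.maximum(xnorm2[:, None], tol),
                0.0,
            )
        merit = merit[:, valid_y] / ynorm2[valid_y]
        merit = merit.sum(axis=1)
        merit[~remaining] = -np.inf
        best = int(np.argmax(merit))
        order.append(best)
        scores[best] = merit[best]
        remaining[best] = False
        if xnorm2[best] > tol:
            u = Xr[:, best] / np.sqrt(xnorm2[best])
            Xr -= np.outer(u, u @ Xr)
            Yr -= np.outer(u, u @ Yr)
    order.extend(np.flatnonzero(remaining).tolist())
    return FeatureRanking(order=np.array(order), scores=scores, method="gso")


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def _discretize(X: np.ndarray) -> np.ndarray:
    """Three levels per feature at mean +/- one standard deviation."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    D = np.ones_like(X, dtype=np.int64)
    D[X < mu - sd] = 0
    D[X > mu + sd] = 2
    return D


def _mi_bits(a: np.ndarray, b: np.ndarray, na: int, nb: int) -> float:
    """Mutual information in bits from empirical joint frequencies."""
    n = len(a)
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(pa, pb)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mrmr_rank(X: np.ndarray, y, k: int | None = None) -> FeatureRanking:
    """Minimum-redundancy maximum-relevance ranking (difference criterion).

    Features are discretized to three levels at mean +/- sd; the first pick
    maximizes I(f; y) and each subsequent pick maximizes
    I(f; y) - mean over selected s of I(f; s), with mutual information in
    bits from empirical joint frequencies.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    k = m if k is None else min(k, m)
    D = _discretize(X)
    classes = sorted(set(y))
    yc = np.array([classes.index(c) for c in y])
    nc = len(classes)
    rel = np.array([_mi_bits(D[:, j], yc, 3, nc) for j in range(m)])

    order: list[int] = []
    scores = np.zeros(m)
    remaining = np.ones(m, dtype=bool)
    red_sum = np.zeros(m)
    for step in range(k):
        if step == 0:
            crit = rel.copy()
        else:
            crit = rel - red_sum / step
        crit[~remaining] = -np.inf
        best = int(np.argmax(crit))
        order.append(best)
        scores[best] = crit[best]
        remaining[best] = False
        if step < k - 1:
            for j in np.flatnonzero(remaining):
                red_sum[j] += _mi_bits(D[:, j], D[:, best], 3, 3)
    order.extend(np.flatnonzero(remaining).tolist())
    return FeatureRanking(order=np.array(order), scores=scores, method="mrmr")


# ---------------------------------------------------------------------------
# SIMBA
# ---------------------------------------------------------------------------

def simba_rank(
    X: np.ndarray,
    y,
    k: int | None = None,
    rng: np.random.Generator | None = None,
    passes: int = 5,
) -> FeatureRanking:
    """Margin-based feature weighting by stochastic hypothesis-margin ascent.

    Maintains signed weights (initialised to 1).  For each sample, the
    nearest hit H (same class) and nearest miss M (other class) are found
    under the w**2-weighted Euclidean distance and the weights ascend the
    hypothesis-margin gradient
    ``dw_i = 0.5 * ((x_i - M_i)^2 / ||x - M||_w - (x_i - H_i)^2 / ||x - H||_w) * w_i``.
    The metric depends on w only through w**2, so weight signs are
    irrelevant to the objective; weights are kept signed rather than clipped
    at zero (a clip would freeze a feature forever after one overshooting
    step, since the update is multiplicative in w).  Weights are rescaled to
    max |w| = 1 after each pass; final merit is w**2 / max(w**2).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    Xs = _standardize(X)
    n, m = Xs.shape
    classes = sorted(set(y))
    yc = np.array([classes.index(c) for c in y])
    w = np.ones(m)
    skipped = 0
    eps = 1e-12
    for _ in range(passes):
        for i in rng.permutation(n):
            w2 = w**2
            diff = Xs - Xs[i]
            d2 = (diff**2) @ w2
            d2[i] = np.inf
            same = yc == yc[i]
            same[i] = False
            if not same.any():
                skipped += 1
                continue
            hit = int(np.argmin(np.where(same, d2, np.inf)))
            miss = int(np.argmin(np.where(~same, d2, np.inf)))
            dh = max(np.sqrt(d2[hit]), eps)
            dm = max(np.sqrt(d2[miss]), eps)
            w = w + 0.5 * (diff[miss] ** 2 / dm - diff[hit] ** 2 / dh) * w
        peak = np.abs(w).max()
        if peak > 0:
            w /= peak
    if skipped:
        logger.warning("SIMBA skipped %d single-sample-class updates", skipped)
    merit = w**2
    if merit.max() > 0:
        merit = merit / merit.max()
    order = np.argsort(-merit, kind="stable")
    return FeatureRanking(
        order=order, scores=merit, method="simba", extras={"skipped": skipped}
    )


# ---------------------------------------------------------------------------
# Random-forest permutation importance
# ---------------------------------------------------------------------------

def rf_importance_rank(
    X: np.ndarray,
    y,
    rng: np.random.Generator | None = None,
    n_trees: int = 500,
) -> FeatureRanking:
    """Rank by mean decrease in out-of-bag accuracy under permutation.

    Fits a random forest (Gini splits, bootstrap resampling, sqrt(M)
    candidate features per split) and, per tree, measures the drop in
    accuracy on that tree's out-of-bag samples when each feature column is
    permuted.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = np.ascontiguousarray(X, dtype=np.float32)
    n, m = X.shape
    classes = sorted(set(y))
    yc = np.array([classes.index(c) for c in y])
    seed = int(rng.integers(0, 2**31 - 1))
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max(1, round(np.sqrt(m))),
        min_samples_leaf=1,
        bootstrap=True,
        oob_score=False,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, yc)
    drops = np.zeros(m)
    counts = np.zeros(m)
    for tree, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samples, assume_unique=False)
        if len(oob) == 0:
            continue
        Xo = X[oob].copy()
        n_oob = len(oob)

        def tree_acc(mat: np.ndarray) -> np.ndarray:
            votes = tree.tree_.predict(mat).reshape(len(mat), -1)
            pred = votes.argmax(axis=1)
            return pred.reshape(-1, n_oob) == yc[oob]

        base = float(tree_acc(Xo).mean())
        # evaluate all feature permutations in one batched prediction
        XP = np.broadcast_to(Xo, (m, n_oob, m)).copy()
        for j in range(m):
            XP[j, :, j] = Xo[rng.permutation(n_oob), j]
        acc = tree_acc(XP.reshape(m * n_oob, m)).mean(axis=1)
        drops += base - acc
        counts += 1
    importance = drops / np.maximum(counts, 1)
    order = np.argsort(-importance, kind="stable")
    return FeatureRanking(order=order, scores=importance, method="rf_accuracy")


# ---------------------------------------------------------------------------
# Stability voting
# ---------------------------------------------------------------------------

def stability_vote(per_run_rankings: list[FeatureRanking]) -> FeatureRanking:
    """Consensus ranking by ascending Borda score.

    The Borda score of a feature is the sum over runs of its (0-based) rank
    position; ties break by earlier mean first-selection position, then by
    feature index.
    """
    if not per_run_rankings:
        raise ValueError("no rankings to aggregate")
    m = len(per_run_rankings[0].order)
    if any(len(r.order) != m for r in per_run_rankings):
        raise ValueError("all rankings must cover the same number of features")
    positions = np.empty((len(per_run_rankings), m))
    for i, r in enumerate(per_run_rankings):
        positions[i, r.order] = np.arange(m)
    borda = positions.sum(axis=0)
    mean_pos = positions.mean(axis=0)
    order = np.lexsort((np.arange(m), mean_pos, borda))
    return FeatureRanking(
        order=order,
        scores=-borda,
        method=per_run_rankings[0].method,
        runs=len(per_run_rankings),
        extras={"borda": borda.tolist()},
    )


def _rank_once(
    method: str, X: np.ndarray, y, rng: np.random.Generator, **kwargs
) -> FeatureRanking:
    if method == "gso":
        return gso_rank(X, y, **kwargs)
    if method == "mrmr":
        return mrmr_rank(X, y, **kwargs)
    if method == "simba":
        return simba_rank(X, y, rng=rng, **kwargs)
    if method == "rf_accuracy":
        return rf_importance_rank(X, y, rng=rng, **kwargs)
    raise ValueError(f"unknown feature-selection method {method!r}")


def stability_protocol(
    X: np.ndarray,
    y,
    method: str,
    runs: int = 100,
    rng: np.random.Generator | int | None = None,
    subsample_frac: float = 0.9,
    **kwargs,
) -> FeatureRanking:
    """Rank features on ``runs`` stratified 90 % subsamples and Borda-vote.

    Each run draws, per class, 90 % of the samples without replacement (so
    every perturbed dataset retains all classes), ranks all features on the
    subsample, and the per-run orders are aggregated by
    :func:`stability_vote`.  Fully reproducible from the supplied rng/seed.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    y_arr = np.asarray(y)
    classes = sorted(set(y_arr.tolist()))
    rankings = []
    for _ in range(runs):
        keep = []
        for c in classes:
            idx = np.flatnonzero(y_arr == c)
            n_keep = max(1, int(round(subsample_frac * len(idx))))
            keep.append(rng.choice(idx, size=n_keep, replace=False))
        sel = np.sort(np.concatenate(keep))
        rankings.append(_rank_once(method, X[sel], y_arr[sel].tolist(), rng, **kwargs))
    consensus = stability_vote(rankings)
    consensus.runs = runs
    return consensus
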