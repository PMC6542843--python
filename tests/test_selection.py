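"""Feature ranking algorithms against brute-force oracles, and Borda voting."""

import numpy as np
import pytest

from usvkit import (
    FeatureRanking,
    gso_rank,
    mrmr_rank,
    rf_importance_rank,
    simba_rank,
    stability_protocol,
    stability_vote,
)
from usvkit.selection import _discretize


def _labels(n_per_class: int, classes=("a", "b")) -> list[str]:
    out = []
    for c in classes:
        out.extend([c] * n_per_class)
    return out


def test_ranking_validates_permutation():
    with pytest.raises(ValueError, match="permutation"):
        FeatureRanking(order=np.array([0, 0, 2]), scores=np.zeros(3), method="gso")


# --- GSO -------------------------------------------------------------------

def test_gso_indicator_feature_first(rng):
    y = _labels(15)
    x1 = np.array([1.0 if c == "a" else -1.0 for c in y])
    X = np.column_stack([rng.normal(size=30), x1, rng.normal(size=30)])
    assert gso_rank(X, y).order[0] == 1


def test_gso_duplicate_residual_zero(rng):
    y = _labels(15)
    x1 = np.array([1.0 if c == "a" else -1.0 for c in y]) + 0.1 * rng.normal(size=30)
    X = np.column_stack([x1, x1.copy(), rng.normal(size=30)])
    rk = gso_rank(X, y)
    assert rk.order[0] == 0
    # the duplicate is annihilated by the null-space projection
    assert rk.scores[1] == pytest.approx(0.0, abs=1e-9)
    assert rk.order[1] == 2


def _gso_oracle(X, y):
    """Naive per-step re-scoring: full least-squares residualization each step."""
    X = np.asarray(X, dtype=float)
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    classes = sorted(set(y))
    Y = np.zeros((len(y), len(classes)))
    for i, c in enumerate(y):
        Y[i, classes.index(c)] = 1.0
    Y = Y - Y.mean(axis=0)
    selected: list[int] = []
    m = Xs.shape[1]
    while len(selected) < m:
        best, best_merit = None, -np.inf
        for j in range(m):
            if j in selected:
                continue
            if selected:
                B = Xs[:, selected]
                proj = B @ np.linalg.lstsq(B, Xs[:, j], rcond=None)[0]
                xr = Xs[:, j] - proj
                Yr = Y - B @ np.linalg.lstsq(B, Y, rcond=None)[0]
            else:
                xr, Yr = Xs[:, j], Y
            xn = xr @ xr
            merit = 0.0
            if xn > 1e-10 * len(y):
                for c in range(Yr.shape[1]):
                    yn = Yr[:, c] @ Yr[:, c]
                    if yn > 1e-10 * len(y):
                        merit += (xr @ Yr[:, c]) ** 2 / (xn * yn)
            if merit > best_merit:
                best, best_merit = j, merit
        selected.append(best)
    return selected


@pytest.mark.parametrize("seed", range(5))
def test_gso_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    y = _labels(10, classes=("a", "b", "c"))
    X = rng.normal(size=(30, 5))
    X[:, 0] += np.array([{"a": 2.0, "b": 0.0, "c": -2.0}[c] for c in y])
    X[:, 3] += np.array([{"a": 0.0, "b": 1.5, "c": 0.0}[c] for c in y])
    assert gso_rank(X, y).order.tolist() == _gso_oracle(X, y)


# --- mRMR ------------------------------------------------------------------

def _mi_oracle(a, b):
    """Independent MI implementation (natural counts, log2)."""
    n = len(a)
    mi = 0.0
    for va in np.unique(a):
        for vb in np.unique(b):
            pab = np.mean((a == va) & (b == vb))
            if pab > 0:
                mi += pab * np.log2(pab / (np.mean(a == va) * np.mean(b == vb)))
    return mi


def _mrmr_oracle(X, y):
    D = _discretize(np.asarray(X, dtype=float))
    classes = sorted(set(y))
    yc = np.array([classes.index(c) for c in y])
    m = D.shape[1]
    rel = [_mi_oracle(D[:, j], yc) for j in range(m)]
    selected: list[int] = []
    while len(selected) < m:
        best, best_crit = None, -np.inf
        for j in range(m):
            if j in selected:
                continue
            red = (
                np.mean([_mi_oracle(D[:, j], D[:, s]) for s in selected])
                if selected
                else 0.0
            )
            crit = rel[j] - red
            if crit > best_crit:
                best, best_crit = j, crit
        selected.append(best)
    return selected


def test_mrmr_first_pick_is_max_relevance(rng):
    y = _labels(20, classes=("a", "b", "c"))
    X = rng.normal(size=(60, 4))
    X[:, 2] += 3.0 * np.array([{"a": -1, "b": 0, "c": 1}[c] for c in y])
    rk = mrmr_rank(X, y)
    D = _discretize(X)
    yc = np.array([("a", "b", "c").index(c) for c in y])
    rels = [_mi_oracle(D[:, j], yc) for j in range(4)]
    assert rk.order[0] == int(np.argmax(rels)) == 2


def test_mrmr_redundancy_penalizes_duplicate(rng):
    # A strong, A' its noisy duplicate, B weaker but independent:
    # step 2 must pick B when I(B;y) > I(A';y) - I(A';A)
    y = _labels(30)
    sig = np.array([1.0 if c == "a" else -1.0 for c in y])
    A = sig + 0.1 * rng.normal(size=60)
    A2 = A + 0.05 * rng.normal(size=60)
    B = sig + 1.2 * rng.normal(size=60)
    X = np.column_stack([A, A2, B])
    rk = mrmr_rank(X, y)
    assert rk.order[0] == 0
    assert rk.order[1] == 2


@pytest.mark.parametrize("seed", range(5))
def test_mrmr_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    y = _labels(13, classes=("a", "b", "c"))
    X = rng.normal(size=(39, 6))
    X[:, 1] += np.array([{"a": 2.0, "b": 0.0, "c": -2.0}[c] for c in y])
    X[:, 4] += np.array([{"a": 0.0, "b": 2.0, "c": 0.0}[c] for c in y])
    assert mrmr_rank(X, y).order.tolist() == _mrmr_oracle(X, y)


# --- SIMBA -----------------------------------------------------------------

def test_simba_recovers_separating_feature():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        y = _labels(20)
        X = rng.normal(size=(40, 10))
        X[:, 0] = np.array([4.0 if c == "a" else -4.0 for c in y]) + 0.3 * rng.normal(
            size=40
        )
        rk = simba_rank(X, y, rng=np.random.default_rng(seed + 1))
        hits += rk.order[0] == 0
    assert hits >= 95


def test_simba_duplicate_columns_equal_weights(rng):
    y = _labels(20)
    sig = np.array([2.0 if c == "a" else -2.0 for c in y]) + 0.2 * rng.normal(size=40)
    X = np.column_stack([sig, sig.copy(), rng.normal(size=40)])
    rk = simba_rank(X, y, rng=np.random.default_rng(5))
    assert rk.scores[0] == pytest.approx(rk.scores[1], rel=1e-9)


def test_simba_zero_variance_feature_not_promoted(rng):
    y = _labels(20)
    sig = np.array([3.0 if c == "a" else -3.0 for c in y]) + 0.2 * rng.normal(size=40)
    X = np.column_stack([sig, np.full(40, 7.0)])
    rk = simba_rank(X, y, rng=np.random.default_rng(6))
    assert rk.order[0] == 0
    assert rk.scores[1] < rk.scores[0]


def test_simba_deterministic_given_rng():
    y = _labels(15)
    X = np.random.default_rng(0).normal(size=(30, 6))
    a = simba_rank(X, y, rng=np.random.default_rng(9))
    b = simba_rank(X, y, rng=np.random.default_rng(9))
    assert np.array_equal(a.order, b.order)
    assert np.allclose(a.scores, b.scores)


# --- RF permutation importance ---------------------------------------------

def test_rf_importance_finds_determining_feature():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y = _labels(20)
        X = rng.normal(size=(40, 5))
        X[:, 2] = np.array([3.0 if c == "a" else -3.0 for c in y])
        rk = rf_importance_rank(X, y, rng=np.random.default_rng(seed), n_trees=100)
        hits += rk.order[0] == 2
    assert hits >= 19


def test_rf_importance_null_under_label_permutation(rng):
    y = list(rng.permutation(_labels(20)))
    X = rng.normal(size=(40, 5))
    rk = rf_importance_rank(X, y, rng=np.random.default_rng(0), n_trees=100)
    assert np.all(np.abs(rk.scores) < 0.05)


def test_rf_importance_duplicated_informative_pair(rng):
    y = _labels(20)
    sig = np.array([3.0 if c == "a" else -3.0 for c in y])
    X = np.column_stack([sig, sig.copy(), rng.normal(size=(40, 3))])
    rk = rf_importance_rank(X, y, rng=np.random.default_rng(2), n_trees=200)
    assert rk.scores[0] + rk.scores[1] > max(rk.scores[2:])


# --- Borda voting ----------------------------------------------------------

def _mk(order):
    order = np.asarray(order)
    return FeatureRanking(order=order, scores=np.zeros(len(order)), method="gso")


def test_vote_unanimity():
    rk = stability_vote([_mk([2, 0, 1])] * 100)
    assert rk.order.tolist() == [2, 0, 1]


def test_vote_hand_example():
    # runs [f0,f1,f2] and [f0,f2,f1]: f1 vs f2 tie on Borda and mean
    # position, broken by feature index
    rk = stability_vote([_mk([0, 1, 2]), _mk([0, 2, 1])])
    assert rk.order.tolist() == [0, 1, 2]


def _borda_oracle(orders):
    m = len(orders[0])
    score = {j: 0.0 for j in range(m)}
    for o in orders:
        for pos, j in enumerate(o):
            score[j] += pos
    return sorted(range(m), key=lambda j: (score[j], score[j] / len(orders), j))


@pytest.mark.parametrize("seed", range(10))
def test_vote_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    orders = [rng.permutation(4).tolist() for _ in range(3)]
    rk = stability_vote([_mk(o) for o in orders])
    assert rk.order.tolist() == _borda_oracle(orders)


def test_vote_rejects_inconsistent_m():
    with pytest.raises(ValueError, match="same number"):
        stability_vote([_mk([0, 1, 2]), _mk([0, 1])])


# --- stability protocol ----------------------------------------------------

def test_protocol_single_run_equals_direct_ranking(rng):
    y = _labels(20, classes=("a", "b", "c"))
    X = np.random.default_rng(3).normal(size=(60, 5))
    consensus = stability_protocol(X, y, "gso", runs=1, rng=42)
    # replicate the protocol's subsample draw with the same seed
    g = np.random.default_rng(42)
    y_arr = np.asarray(y)
    keep = []
    for c in sorted(set(y)):
        idx = np.flatnonzero(y_arr == c)
        keep.append(g.choice(idx, size=int(round(0.9 * len(idx))), replace=False))
    sel = np.sort(np.concatenate(keep))
    direct = gso_rank(X[sel], [y[i] for i in sel])
    assert consensus.order.tolist() == direct.order.tolist()


def test_protocol_deterministic(full_dm):
    a = stability_protocol(full_dm.X, full_dm.y, "gso", runs=5, rng=7)
    b = stability_protocol(full_dm.X, full_dm.y, "gso", runs=5, rng=7)
    assert np.array_equal(a.order, b.order)


def test_protocol_unknown_method():
    with pytest.raises(ValueError, match="unknown feature-selection"):
        stability_protocol(np.zeros((20, 3)), _labels(10), "magic", runs=1, rng=0)


def test_all_methods_return_valid_permutations(small_dm):
    m = small_dm.X.shape[1]
    for method in ("gso", "mrmr", "simba", "rf_accuracy"):
        rk = stability_protocol(small_dm.X, small_dm.y, method, runs=2, rng=1)
        assert sorted(rk.order.tolist()) == list(range(m))


def test_consensus_top8_overlap_across_methods(full_dm):
    """The four consensus rankings share at least one top-8 feature."""
    tops = []
    for method, runs in (("gso", 25), ("mrmr", 25), ("simba", 25), ("rf_accuracy", 10)):
        rk = stability_protocol(full_dm.X, full_dm.y, method, runs=runs, rng=2)
        tops.append(set(rk.top(8).tolist()))
    common = set.intersection(*tops)
    assert common, f"no overlap across methods: {tops}"
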