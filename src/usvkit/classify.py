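"""Supervised call-type classification and its validation protocol.

Random forests (500 Gini trees, bootstrap resampling, sqrt(M) candidate
features per split) and RBF-kernel SVMs (one-against-one multiclass, with
penalty and kernel-width hyperparameters tuned on a 2-power grid by an inner
10-fold cross-validation on the training partition only) are validated by
stratified 10-fold cross-validation repeated many times; per-repetition
accuracy is pooled over the 10 held-out folds and results are summarised as
mean +/- standard deviation together with a pooled confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .selection import FeatureRanking
from .synth import CATEGORIES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFParams:
    n_trees: int = 500
    n_candidate_features: int | None = None  # None -> round(sqrt(M))
    min_node_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class SVMParams:
    penalty_exponents: tuple[int, ...] = tuple(range(-5, 16, 2))  # 2^-5 .. 2^15
    width_exponents: tuple[int, ...] = tuple(range(-15, 4, 2))  # 2^-15 .. 2^3
    inner_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.penalty_exponents or not self.width_exponents:
            raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class CVResult:
    per_repetition_accuracy: np.ndarray
    confusion: np.ndarray
    labels: list[str]
    protocol: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repetition_accuracy))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_repetition_accuracy, ddof=1)) if len(
            self.per_repetition_accuracy
        ) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "per_repetition_accuracy": self.per_repetition_accuracy.tolist(),
            "confusion": self.confusion.tolist(),
            "labels": self.labels,
            "protocol": self.protocol,
        }


def train_rf(X: np.ndarray, y, params: RFParams) -> RandomForestClassifier:
    """Fit a random forest; prediction is by majority vote over the trees."""
    if len(set(y)) < 2:
        raise ValueError("training labels contain a single class")
    m = X.shape[1]
    mtry = params.n_candidate_features or max(1, round(np.sqrt(m)))
    clf = RandomForestClassifier(
        n_estimators=params.n_trees,
        criterion="gini",
        max_features=min(mtry, m),
        min_samples_leaf=params.min_node_size,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def train_svm(
    X: np.ndarray,
    y,
    params: SVMParams,
    rng: np.random.Generator | None = None,
) -> GridSearchCV:
    """Grid-searched RBF SVM (one-against-one) tuned by inner k-fold CV.

    ``X`` must already be standardized with training-partition statistics.
    The kernel-width grid is applied to the RBF gamma coefficient in
    exp(-gamma * ||u - v||^2).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    y_arr = np.asarray(y)
    _, counts = np.unique(y_arr, return_counts=True)
    folds = int(min(params.inner_folds, counts.min()))
    if folds < params.inner_folds:
        logger.warning(
            "reducing inner CV folds from %d to %d (smallest class has %d samples)",
            params.inner_folds,
            folds,
            counts.min(),
        )
    folds = max(folds, 2)
    grid = {
        "C": [2.0**e for e in params.penalty_exponents],
        "gamma": [2.0**e for e in params.width_exponents],
    }
    inner = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1))
    )
    search = GridSearchCV(
        SVC(kernel="rbf", decision_function_shape="ovo"),
        grid,
        scoring="accuracy",
        cv=inner,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y_arr)
    return search


def _fit_predict(model_spec, X_tr, y_tr, X_te, rng) -> np.ndarray:
    if isinstance(model_spec, RFParams):
        spec = RFParams(
            n_trees=model_spec.n_trees,
            n_candidate_features=model_spec.n_candidate_features,
            min_node_size=model_spec.min_node_size,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        clf = train_rf(X_tr, y_tr, spec)
        return clf.predict(X_te)
    if isinstance(model_spec, SVMParams):
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        clf = train_svm((X_tr - mu) / sd, y_tr, model_spec, rng=rng)
        return clf.predict((X_te - mu) / sd)
    raise TypeError(f"unsupported model spec {type(model_spec).__name__}")


def cross_validate(
    X: np.ndarray,
    y,
    model_spec: RFParams | SVMParams,
    folds: int = 10,
    repetitions: int = 100,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold cross-validation.

    Per repetition the data are shuffled into ``folds`` stratified folds,
    each held out once; the repetition's accuracy pools correct predictions
    over all folds.  Standardization and hyperparameter tuning (for SVMs)
    happen inside the training partition only.  The confusion matrix pools
    all repetitions (rows = truth, columns = predicted).
    """
    X = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    labels = sorted(set(y_arr.tolist()))
    label_pos = {c: i for i, c in enumerate(labels)}
    classes, counts = np.unique(y_arr, return_counts=True)
    low = counts < folds
    if low.any():
        raise ValueError(
            f"class(es) {classes[low].tolist()} have fewer samples than "
            f"{folds} folds; stratification impossible"
        )
    rng = np.random.default_rng(seed)
    accs = np.empty(repetitions)
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for rep in range(repetitions):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1))
        )
        correct = 0
        for tr, te in skf.split(X, y_arr):
            pred = _fit_predict(model_spec, X[tr], y_arr[tr], X[te], rng)
            correct += int(np.sum(pred == y_arr[te]))
            for t, p in zip(y_arr[te], pred):
                confusion[label_pos[t], label_pos[p]] += 1
        accs[rep] = correct / len(y_arr)
    return CVResult(
        per_repetition_accuracy=accs,
        confusion=confusion,
        labels=labels,
        protocol={
            "folds": folds,
            "repetitions": repetitions,
            "seed": seed,
            "model": type(model_spec).__name__,
        },
    )


def accuracy_vs_k(
    X: np.ndarray,
    y,
    ranking: FeatureRanking,
    k_max: int = 15,
    model_spec: RFParams | SVMParams | None = None,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
) -> list[tuple[int, float, float]]:
    """Cross-validated accuracy using the top-k ranked features, k = 1..k_max.

    Returns a list of ``(k, mean, sd)`` triples.
    """
    if k_max > X.shape[1]:
        raise ValueError(f"k_max={k_max} exceeds the {X.shape[1]} available features")
    if model_spec is None:
        model_spec = RFParams()
    curve = []
    for k in range(1, k_max + 1):
        cols = ranking.top(k)
        res = cross_validate(
            X[:, cols], y, model_spec, folds=folds, repetitions=repetitions, seed=seed
        )
        curve.append((k, res.mean, res.sd))
    return curve


def confusion_matrix(truth, predicted, labels: list[str] | None = None) -> np.ndarray:
    """Count matrix with rows = truth, columns = predicted.

    Defaults to the nine call-type labels; any label outside the label set is
    rejected.
    """
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if labels is None:
        labels = list(CATEGORIES)
    pos = {c: i for i, c in enumerate(labels)}
    out = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in pos or p not in pos:
            bad = t if t not in pos else p
            raise ValueError(f"label {bad!r} outside the known classes {labels}")
        out[pos[t], pos[p]] += 1
    return out
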