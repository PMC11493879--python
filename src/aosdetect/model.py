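"""Imbalance-corrected, AUROC-optimized stenosis classification.

The cohort design matrix is split 75/25 with stratification, the minority
class is oversampled to parity with SMOTE, features are min-max normalized
on the balanced training set, and five classifier families (logistic
regression, k-nearest neighbours, decision tree, support vector machine,
random forest) are grid-searched under stratified 4-fold cross-validation
scored by AUROC.  The best model is evaluated on the held-out test set with
a full confusion matrix and a Mann-Whitney AUROC.

``AoSDetector`` packages the SMOTE -> scaling -> grid-search stages as a
scikit-learn classifier so it composes with sklearn tooling.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0


def stratified_split(
    X: np.ndarray, y: np.ndarray, spec: SplitSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Return (train_idx, test_idx) for a stratified 75/25 partition.

    Test size is ``ceil((1 - f) * n)``; per-class training counts follow
    largest-remainder rounding of the class frequencies, so 101 + 48
    patients split into 75 + 36 training and 38 test patients.
    """
    spec = spec or SplitSpec()
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    n = len(y)
    n_test = math.ceil((1.0 - spec.train_fraction) * n)
    n_train = n - n_test

    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])

    # largest-remainder allocation of training slots across classes
    exact = {c: np.sum(y == c) * n_train / n for c in classes}
    alloc = {c: int(math.floor(v)) for c, v in exact.items()}
    short = n_train - sum(alloc.values())
    for c in sorted(classes, key=lambda c: exact[c] - alloc[c], reverse=True)[:short]:
        alloc[c] += 1

    train_idx, test_idx = [], []
    for c in classes:
        members = np.flatnonzero(y == c)
        perm = rng.permutation(members)
        train_idx.extend(perm[: alloc[c]])
        test_idx.extend(perm[alloc[c]:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Minority Over-sampling to class parity.

    New minority samples are ``x_i + lambda * (x_nn - x_i)`` with
    ``lambda ~ U[0, 1]`` and ``x_nn`` one of the k nearest minority
    neighbours (Euclidean).  Originals are retained; the minority count is
    raised to match the majority count exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    Xm = X[y == minority]
    if n_min <= k:
        k = int(n_min) - 1
        warnings.warn(f"minority class smaller than k+1; reducing k to {k}")
        log.warning("SMOTE: reduced k to %d for a minority of %d", k, n_min)
    if k < 1:
        raise ValueError("minority class too small for SMOTE")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    X_new = Xm[base] + lam[:, None] * (Xm[neigh[base, pick]] - Xm[base])
    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def fit_normalizer(X_train: np.ndarray) -> MinMaxScaler:
    """Fit a column-wise min-max transform on the (balanced) training set.

    Constant columns map to 0 (with a warning); the same affine map is
    applied to test data, whose values may leave [0, 1].
    """
    X_train = np.asarray(X_train, dtype=float)
    const = np.flatnonzero(X_train.max(axis=0) == X_train.min(axis=0))
    if const.size:
        warnings.warn(f"{const.size} constant training columns map to 0")
    return MinMaxScaler().fit(X_train)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

#: family order follows the published listing; used for deterministic tie-breaks
def default_family_grids(seed: int = 0) -> list[tuple[str, BaseEstimator, list[dict]]]:
    return [
        # LogisticRegression defaults to an L2 penalty with a fitted intercept
        ("logistic-regression",
         LogisticRegression(max_iter=500, fit_intercept=True),
         list(ParameterGrid({"C": [0.01, 0.1, 1.0, 10.0, 100.0]}))),
        ("k-nearest-neighbours",
         KNeighborsClassifier(),
         list(ParameterGrid({"n_neighbors": [3, 5, 7, 11]}))),
        ("decision-tree",
         DecisionTreeClassifier(random_state=seed),
         list(ParameterGrid({"max_depth": [2, 3, 5, None]}))),
        ("support-vector-machine",
         SVC(probability=True, random_state=seed),
         list(ParameterGrid({"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]}))),
        ("random-forest",
         RandomForestClassifier(random_state=seed, n_jobs=1),
         list(ParameterGrid({"n_estimators": [100, 500], "max_depth": [None, 5]}))),
    ]


@dataclass
class CvCandidate:
    family: str
    params: dict
    mean_auroc: float
    sd_auroc: float


@dataclass
class GridSearchResult:
    classifier: BaseEstimator
    family: str
    params: dict
    mean_auroc: float
    sd_auroc: float
    report: list[CvCandidate] = field(default_factory=list)


def grid_search_train(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    cv_folds: int = 4,
    families: list[tuple[str, BaseEstimator, list[dict]]] | None = None,
) -> GridSearchResult:
    """Stratified 4-fold CV grid search over all families, scored by AUROC.

    Ties are broken by listing order (simpler family first, then the
    earlier grid point, i.e. smaller C / fewer neighbours / shallower
    depth), so results are deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    for i, (_, test) in enumerate(folds):
        if np.unique(y[test]).size < 2:
            raise ValueError(f"cross-validation fold {i} contains a single class")

    report: list[CvCandidate] = []
    best: CvCandidate | None = None
    best_est = None
    for family, proto, grid in families or default_family_grids(seed):
        for params in grid:
            est = clone(proto).set_params(**params)
            scores = []
            try:
                for train, test in folds:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", FutureWarning)
                        m = clone(est).fit(X[train], y[train])
                    scores.append(mann_whitney_auroc(y[test], _scores(m, X[test])))
            except ValueError as exc:
                # candidate infeasible at this sample size (e.g. more
                # neighbours than fold members); exclude it
                log.debug("skipping %s %s: %s", family, params, exc)
                report.append(CvCandidate(family, dict(params),
                                          float("nan"), float("nan")))
                continue
            cand = CvCandidate(family, dict(params),
                               float(np.mean(scores)), float(np.std(scores)))
            report.append(cand)
            if best is None or cand.mean_auroc > best.mean_auroc:
                best, best_est = cand, est
    if best is None:
        raise ValueError("no feasible grid candidate for this training set")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        final = clone(best_est).fit(X, y)
    log.info("grid search winner: %s %s (CV AUROC %.3f +- %.3f)",
             best.family, best.params, best.mean_auroc, best.sd_auroc)
    return GridSearchResult(
        classifier=final, family=best.family, params=best.params,
        mean_auroc=best.mean_auroc, sd_auroc=best.sd_auroc, report=report,
    )


def _scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def mann_whitney_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC by the Mann-Whitney U formulation (ties counted one half)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == np.max(y_true) if y_true.dtype != bool else y_true
    n_pos = int(np.sum(pos))
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: test set contains a single class")
    ranks = rankdata(scores)
    u = np.sum(ranks[pos]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix, derived diagnostic metrics and AUROC."""

    tp: int
    fp: int
    tn: int
    fn: int
    auroc: float
    roc_points: tuple = ()

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else math.nan  # undefined on an empty cell

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn,
                           self.tp + self.tn + self.fp + self.fn)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def rounded(self) -> dict[str, float]:
        """Metrics at the 2-decimal reporting precision."""
        return {
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
            "accuracy": round(self.accuracy, 2),
            "ppv": round(self.ppv, 2),
            "npv": round(self.npv, 2),
            "auroc": round(self.auroc, 2),
        }

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": {"tp": self.tp, "fp": self.fp,
                                 "tn": self.tn, "fn": self.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "auroc": self.auroc,
        }


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int,
                        auroc: float = float("nan")) -> EvaluationReport:
    """Build a report directly from confusion-matrix counts."""
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn, auroc=auroc)


def evaluate(
    classifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Test-set evaluation: Mann-Whitney AUROC plus the confusion matrix at
    the given probability threshold."""
    scores = _scores(classifier, np.asarray(X_test, dtype=float))
    y_test = np.asarray(y_test)
    auroc = mann_whitney_auroc(y_test, scores)
    pred = (scores >= threshold).astype(int)
    pos = y_test == 1
    tp = int(np.sum(pred[pos] == 1))
    fn = int(np.sum(pred[pos] == 0))
    tn = int(np.sum(pred[~pos] == 0))
    fp = int(np.sum(pred[~pos] == 1))
    # ROC points for export (threshold sweep over unique scores)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(y_test[order] == 1)
    fps = np.cumsum(y_test[order] == 0)
    n_pos, n_neg = tps[-1], fps[-1]
    roc = tuple(zip((fps / n_neg).tolist(), (tps / n_pos).tolist()))
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn, auroc=auroc, roc_points=roc)


# ---------------------------------------------------------------------------
# sklearn-style wrapper
# ---------------------------------------------------------------------------

class AoSDetector(BaseEstimator, ClassifierMixin):
    """SMOTE-balanced, min-max-normalized, grid-searched stenosis classifier.

    Parameters
    ----------
    smote_k : int
        Neighbour count for minority oversampling.
    cv_folds : int
        Stratified cross-validation folds for the grid search.
    threshold : float
        Probability threshold for :meth:`predict`.
    random_state : int
        Seeds SMOTE draws, CV fold assignment and stochastic learners.

    Attributes (after fit)
    ----------------------
    scaler_ : MinMaxScaler fitted on the balanced training set.
    search_ : GridSearchResult with the CV report.
    classifier_ : the refitted winning classifier.
    """

    def __init__(self, smote_k: int = 5, cv_folds: int = 4,
                 threshold: float = 0.5, random_state: int = 0):
        self.smote_k = smote_k
        self.cv_folds = cv_folds
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        Xb, yb = smote_oversample(X, y, k=self.smote_k, seed=self.random_state)
        self.scaler_ = fit_normalizer(Xb)
        Xs = self.scaler_.transform(Xb)
        self.search_ = grid_search_train(
            Xs, yb, seed=self.random_state, cv_folds=self.cv_folds
        )
        self.classifier_ = self.search_.classifier
        return self

    def predict_proba(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.classifier_.predict_proba(Xs)

    def decision_scores(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return _scores(self.classifier_, Xs)

    def predict(self, X):
        return (self.decision_scores(X) >= self.threshold).astype(int)

    def evaluate(self, X, y) -> EvaluationReport:
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return evaluate(self.classifier_, Xs, y, threshold=self.threshold)
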