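"""One-against-one RBF-SVM classification with exposed votes and decision values.

The quadratic-program solver itself is scikit-learn's libsvm binding; this
module owns everything around it: grid-search tuning, per-fold feature
standardization, and the vote / pairwise decision-value bookkeeping on
which the misclassification analysis rests.

Sign convention (fixed throughout the package): for a class pair (i, j)
with i < j, a positive decision value favors the lower-indexed class i.
libsvm follows this convention internally for its K >= 3 one-vs-one
decision values; scikit-learn's two-class special case reports the
opposite sign, which is normalized here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["SVMConfig", "PredictionRecord", "OneVsOneSVM", "tune_hyperparameters"]

#: libsvm-style default grids (log2-spaced, step 4x).
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class SVMConfig:
    """Hyperparameters and tuning protocol for the one-vs-one RBF SVM."""

    C: float = 1.0
    gamma: float = 0.1
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    n_folds: int = 5
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class PredictionRecord:
    """Votes and pairwise decision values for one test item.

    ``votes`` has one entry per class (1..K order) and sums to K(K-1)/2;
    ``pair_dv`` maps each pair (i, j), i < j, to its decision value under
    the positive-favors-i convention. ``predicted_class`` is the vote
    argmax with ties broken toward the lowest class index.
    """

    id: str | None
    predicted_class: int
    votes: np.ndarray
    pair_dv: dict[tuple[int, int], float]


class OneVsOneSVM:
    """K(K-1)/2 soft-margin RBF binary classifiers with vote aggregation.

    Features are z-scored with training-set statistics when
    ``standardize`` is on; the fitted scaler is kept on the model so the
    exact same shift/scale is applied at prediction time (no test-set
    leakage).
    """

    def __init__(self, C: float, gamma: float, standardize: bool = True):
        if C <= 0 or gamma <= 0:
            raise ValueError("C and gamma must be positive")
        self.C = C
        self.gamma = gamma
        self.standardize = standardize
        self.scaler_: StandardScaler | None = None
        self.svc_: SVC | None = None
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsOneSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        self.classes_ = classes
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        self.svc_ = SVC(
            kernel="rbf",
            C=self.C,
            gamma=self.gamma,
            decision_function_shape="ovo",
            cache_size=200,
        ).fit(X, y)
        return self

    @property
    def n_classes(self) -> int:
        self._check_fitted()
        return int(self.classes_.size)

    @property
    def n_binary_classifiers(self) -> int:
        k = self.n_classes
        return k * (k - 1) // 2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Class-label pairs (i, j), i < j, in decision-value column order."""
        self._check_fitted()
        labels = [int(c) for c in self.classes_]
        return list(itertools.combinations(labels, 2))

    def _check_fitted(self) -> None:
        if self.svc_ is None:
            raise RuntimeError("model is not fitted")

    def pairwise_decision_values(self, X: np.ndarray) -> np.ndarray:
        """(n_items, K(K-1)/2) decision values, positive favoring the
        lower-indexed class of each pair."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.svc_.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the "
                f"fitted model ({self.svc_.n_features_in_})"
            )
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        dv = self.svc_.decision_function(X)
        if self.n_classes == 2:
            # sklearn's binary special case: positive favors classes_[1]
            dv = -np.atleast_2d(dv).reshape(-1, 1)
        return dv

    def predict_votes_dv(self, X: np.ndarray, ids=None) -> list[PredictionRecord]:
        """Votes, pairwise decision values and the voted class per item.

        Each pair classifier casts one vote: for pair (i, j) the vote goes
        to i when its decision value is >= 0, else to j (an exact-zero tie
        favors the lower index). The predicted class is the vote argmax,
        ties toward the lowest class index.
        """
        dv = self.pairwise_decision_values(X)
        pairs = self.pairs
        labels = [int(c) for c in self.classes_]
        label_pos = {c: p for p, c in enumerate(labels)}
        if ids is None:
            ids = [None] * dv.shape[0]
        records: list[PredictionRecord] = []
        for row, item_id in zip(dv, ids):
            votes = np.zeros(len(labels), dtype=int)
            for (i, j), value in zip(pairs, row):
                votes[label_pos[i if value >= 0 else j]] += 1
            predicted = labels[int(np.argmax(votes))]  # argmax ties -> lowest index
            records.append(
                PredictionRecord(
                    id=item_id,
                    predicted_class=predicted,
                    votes=votes,
                    pair_dv=dict(zip(pairs, (float(v) for v in row))),
                )
            )
        return records

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([r.predicted_class for r in self.predict_votes_dv(X)])


@dataclass
class TuningResult:
    C_opt: float
    gamma_opt: float
    cv_accuracy: float
    grid_scores: dict[tuple[float, float], float] = field(repr=False, default_factory=dict)


def tune_hyperparameters(X: np.ndarray, y: np.ndarray, config: SVMConfig) -> TuningResult:
    """Grid search for (C, gamma) maximizing mean stratified-CV accuracy.

    Folds are fixed once (seeded) and shared by every grid point, so the
    search is deterministic; ties are broken toward smaller C, then
    smaller gamma.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; need >= n_folds={config.n_folds}"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))

    best: tuple[float, float] | None = None
    best_acc = -np.inf
    scores: dict[tuple[float, float], float] = {}
    for C in sorted(config.C_grid):
        for gamma in sorted(config.gamma_grid):
            fold_acc = []
            for train, test in folds:
                model = OneVsOneSVM(C, gamma, config.standardize).fit(X[train], y[train])
                fold_acc.append(float(np.mean(model.predict(X[test]) == y[test])))
            acc = float(np.mean(fold_acc))
            scores[(C, gamma)] = acc
            if acc > best_acc:  # strict: earlier (smaller C, gamma) wins ties
                best_acc = acc
                best = (C, gamma)
    return TuningResult(C_opt=best[0], gamma_opt=best[1], cv_accuracy=best_acc, grid_scores=scores)
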