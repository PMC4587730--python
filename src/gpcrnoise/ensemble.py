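"""Ensemble-based noise detection (noise-rank filter).

An independent cross-check on the SVM-based candidate shortlist: a roster
of heterogeneous classifiers (naive Bayes, random forest, RBF-SVM,
multi-layer perceptron) is evaluated by a single shared stratified CV, and
each sequence is flagged per classifier that misclassified it as a test
item. The noise-rank score weights the failing classifiers (defaults
MLP=3, SVM=2, NB=1, RF=1); candidates are the sequences failed by all
roster members (consensus) or by at least ``min_failures`` of them
(majority). An overlap report quantifies the agreement between two
detection methods' candidate sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["EnsembleConfig", "run_ensemble", "noise_rank", "select_by_failures", "overlap_report"]

DEFAULT_WEIGHTS = {"MLP": 3, "SVM": 2, "NB": 1, "RF": 1}


@dataclass
class EnsembleConfig:
    roster: tuple[str, ...] = ("NB", "RF", "SVM", "MLP")
    weights: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    n_folds: int = 5
    min_failures: int = 3
    seed: int = 0
    svm_C: float = 1.0
    svm_gamma: float | str = "scale"
    rf_trees: int = 500
    mlp_max_iter: int = 300

    def __post_init__(self) -> None:
        for kind in self.roster:
            if kind not in ("NB", "RF", "SVM", "MLP"):
                raise ValueError(f"unknown roster member {kind!r}")
            if self.weights.get(kind, 0) <= 0:
                raise ValueError(f"roster member {kind!r} needs a positive weight")
        if not (1 <= self.min_failures <= len(self.roster)):
            raise ValueError("min_failures must be between 1 and the roster size")


def _make_classifier(kind: str, config: EnsembleConfig, n_features: int):
    if kind == "NB":
        return make_pipeline(StandardScaler(), GaussianNB())
    if kind == "RF":
        return RandomForestClassifier(n_estimators=config.rf_trees, random_state=config.seed)
    if kind == "SVM":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=config.svm_C, gamma=config.svm_gamma)
        )
    if kind == "MLP":
        width = min(100, 2 * n_features)
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(width,),
                solver="lbfgs",  # reliable on the small-sample sizes used here
                max_iter=config.mlp_max_iter,
                random_state=config.seed,
            ),
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


def run_ensemble(
    X: np.ndarray, y: np.ndarray, ids: list[str], config: EnsembleConfig
) -> pd.DataFrame:
    """Per-sequence misclassification flags, one boolean column per
    roster classifier, all evaluated on the same stratified CV split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; need >= n_folds={config.n_folds}"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))

    flags = pd.DataFrame(False, index=pd.Index(ids, name="id"), columns=list(config.roster))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for kind in config.roster:
            wrong = np.zeros(len(y), dtype=bool)
            for train, test in folds:
                clf = _make_classifier(kind, config, X.shape[1])
                clf.fit(X[train], y[train])
                wrong[test] = clf.predict(X[test]) != y[test]
            flags[kind] = wrong
    return flags


def noise_rank(flags: pd.DataFrame, weights: dict[str, int] | None = None) -> pd.DataFrame:
    """Rank sequences by the weighted number of failing classifiers.

    Sorted by weighted score descending, ties by failure count descending
    then id ascending.
    """
    weights = weights or DEFAULT_WEIGHTS
    missing = [c for c in flags.columns if c not in weights]
    if missing:
        raise ValueError(f"no weight given for classifier(s) {missing}")
    w = np.array([weights[c] for c in flags.columns])
    rank = pd.DataFrame(
        {
            "failure_count": flags.to_numpy().sum(axis=1),
            "weighted_score": flags.to_numpy() @ w,
        },
        index=flags.index,
    )
    return rank.sort_values(
        by=["weighted_score", "failure_count", "id"],
        ascending=[False, False, True],
        kind="mergesort",
    )


def select_by_failures(flags: pd.DataFrame, min_failures: int) -> list[str]:
    """Ids failed by at least ``min_failures`` classifiers (consensus when
    min_failures equals the roster size)."""
    counts = flags.sum(axis=1)
    return list(flags.index[counts >= min_failures])


def overlap_report(set_a, set_b) -> dict:
    """Agreement between two candidate id sets, percentages as integers."""
    a, b = set(set_a), set(set_b)
    common = a & b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_common": len(common),
        "pct_of_a": round(100 * len(common) / len(a)) if a else 0,
        "pct_of_b": round(100 * len(common) / len(b)) if b else 0,
    }
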