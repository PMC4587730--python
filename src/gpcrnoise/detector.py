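"""Systematic SVM-based misclassification analysis for label-noise detection.

The procedure has three steps:

1. Repeated cross-validated classification. The dataset is reshuffled
   ``n_iterations`` times (default 100); each time a stratified 5-fold CV
   classifies every sequence exactly once as a test item, using a
   one-vs-one RBF-SVM with the tuned gamma and with C jittered across a
   small range of multipliers around its tuned optimum, fold by fold.
   Each sequence accumulates an error rate ER_s (percent of test
   occasions misclassified); sequences with ER_s >= e (default 75%,
   inclusive) form the frequently-misclassified subset.
2. Voting-ratio analysis. For each frequent misclassification, R_s =
   VT_s / VP_s, where VT_s and VP_s are the one-vs-one votes accumulated
   over all test occasions by the true-label class and by the most
   frequently predicted class. R_s <= theta_R (default 0.5) marks a
   consistent ("large") error.
3. Cumulative decision values. CDV_s sums, over all test occasions, the
   decision value of the single pairwise classifier confronting the true
   class i with the most-predicted class j. Under the positive-favors-
   lower-index convention, a consistently preferred j yields a large
   positive CDV_s when i > j and a large negative one when i < j;
   |CDV_s| >= theta_CDV (default 60 per 100 iterations) marks a large
   error.

The final candidate shortlist is the union of the step-2 and step-3
"large" sets within the frequently-misclassified subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .metrics import confusion, multiclass_metrics
from .svm import OneVsOneSVM, SVMConfig, tune_hyperparameters

__all__ = [
    "DetectorConfig",
    "ErrorProfile",
    "NoiseCandidate",
    "DetectionResult",
    "profile_errors",
    "select_frequent",
    "voting_ratio",
    "cumulative_dv",
    "classify_magnitude",
    "detect_candidates",
]


@dataclass
class DetectorConfig:
    """Thresholds and protocol for the three-step analysis.

    ``theta_CDV`` is calibrated for 100 iterations; because the CDV is an
    un-normalized sum, the effective threshold scales linearly when
    ``n_iterations`` differs from 100. ``C_jitter`` multipliers are cycled
    across the CV folds so each iteration uses slightly different SVM
    models near the tuned C optimum.
    """

    n_iterations: int = 100
    n_folds: int = 5
    e_threshold: float = 75.0
    theta_R: float = 0.5
    theta_CDV: float = 60.0
    C_jitter: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)
    standardize: bool = True
    votes_misclassified_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.e_threshold <= 100):
            raise ValueError("e_threshold must be in (0, 100]")
        if self.theta_R <= 0:
            raise ValueError("theta_R must be positive")
        if self.theta_CDV < 0:
            raise ValueError("theta_CDV must be non-negative")
        if self.n_iterations < 1 or self.n_folds < 2:
            raise ValueError("n_iterations >= 1 and n_folds >= 2 required")
        if not self.C_jitter or any(m <= 0 for m in self.C_jitter):
            raise ValueError("C_jitter must be non-empty positive multipliers")

    @property
    def theta_CDV_effective(self) -> float:
        return self.theta_CDV * self.n_iterations / 100.0


@dataclass
class ErrorProfile:
    """Per-sequence misclassification bookkeeping across all iterations.

    Each sequence is a test item exactly once per iteration, so the logs
    have one row per iteration: ``pred_log[k]`` is the voted class on the
    iteration-k test occasion, ``votes_log[k, c-1]`` the one-vs-one votes
    class c received on that occasion, and ``dv_true[k, c-1]`` the
    decision value of the pair classifier confronting the true class with
    class c (canonical sign: positive favors the lower class index).
    """

    id: str
    true_class: int
    n_iterations: int
    er: float
    pred_log: np.ndarray
    votes_log: np.ndarray
    dv_true: np.ndarray

    @property
    def misclassified_mask(self) -> np.ndarray:
        return self.pred_log != self.true_class

    @property
    def n_misclassified(self) -> int:
        return int(self.misclassified_mask.sum())

    @property
    def assigned_counts(self) -> np.ndarray:
        """Per-class counts of misclassified test occasions."""
        k = self.votes_log.shape[1]
        wrong = self.pred_log[self.misclassified_mask]
        return np.bincount(wrong - 1, minlength=k).astype(np.int64)

    @property
    def votes_by_class(self) -> np.ndarray:
        """One-vs-one votes accumulated per class over ALL test occasions."""
        return self.votes_log.sum(axis=0)

    @property
    def votes_true(self) -> int:
        return int(self.votes_by_class[self.true_class - 1])


@dataclass
class NoiseCandidate:
    """A shortlisted sequence with the evidence behind its selection."""

    id: str
    true_class: int
    predicted_class: int
    er: float
    r: float
    cdv: float
    large_r: bool
    large_cdv: bool

    @property
    def magnitude(self) -> str:
        return "large" if (self.large_r or self.large_cdv) else "small"


def profile_errors(
    X: np.ndarray,
    y: np.ndarray,
    ids: list[str],
    C_opt: float,
    gamma_opt: float,
    config: DetectorConfig,
) -> tuple[list[ErrorProfile], pd.DataFrame]:
    """Step 1: repeated stratified-CV classification with jittered C.

    Returns one :class:`ErrorProfile` per sequence (dataset order) plus a
    per-iteration table of overall accuracy and multi-class MCC — the
    distributions usually summarized as box plots when reporting the
    classifier itself.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if len(ids) != n:
        raise ValueError("ids and y must align")
    k_classes = int(y.max())
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; need >= n_folds={config.n_folds}"
        )

    votes_log = np.zeros((n, config.n_iterations, k_classes), dtype=np.int16)
    pred_log = np.zeros((n, config.n_iterations), dtype=np.int16)
    dv_true = np.zeros((n, config.n_iterations, k_classes))
    acc_series = np.empty(config.n_iterations)
    mcc_series = np.empty(config.n_iterations)

    jitter = config.C_jitter
    for it in range(config.n_iterations):
        fold_seed = (config.seed + 1_000_003 * it) % (2**31)
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=fold_seed)
        for fold_idx, (train, test) in enumerate(skf.split(X, y)):
            c_fold = C_opt * jitter[fold_idx % len(jitter)]
            model = OneVsOneSVM(c_fold, gamma_opt, config.standardize).fit(X[train], y[train])
            records = model.predict_votes_dv(X[test])
            for local, s in enumerate(test):
                rec = records[local]
                pred_log[s, it] = rec.predicted_class
                # model votes are over model.classes_; map into 1..K slots
                for pos, cls in enumerate(model.classes_):
                    votes_log[s, it, int(cls) - 1] += rec.votes[pos]
                true = int(y[s])
                for (i, j), value in rec.pair_dv.items():
                    if i == true:
                        dv_true[s, it, j - 1] = value
                    elif j == true:
                        dv_true[s, it, i - 1] = value
        cm = confusion(y, pred_log[:, it], k_classes)
        res = multiclass_metrics(cm)
        acc_series[it] = res["accuracy_overall"]
        mcc_series[it] = res["mcc_multiclass"]

    profiles = [
        ErrorProfile(
            id=ids[s],
            true_class=int(y[s]),
            n_iterations=config.n_iterations,
            er=100.0 * float(np.sum(pred_log[s] != y[s])) / config.n_iterations,
            pred_log=pred_log[s].astype(int),
            votes_log=votes_log[s].astype(np.int64),
            dv_true=dv_true[s],
        )
        for s in range(n)
    ]
    iteration_metrics = pd.DataFrame(
        {
            "iteration": np.arange(1, config.n_iterations + 1),
            "accuracy_overall": acc_series,
            "mcc_multiclass": mcc_series,
        }
    )
    return profiles, iteration_metrics


def select_frequent(profiles: list[ErrorProfile], e_threshold: float) -> list[ErrorProfile]:
    """Sequences misclassified on at least ``e_threshold`` percent of test
    occasions (boundary inclusive); input order preserved."""
    return [p for p in profiles if p.er >= e_threshold]


def voting_ratio(profile: ErrorProfile, misclassified_only: bool = False) -> dict:
    """Step 2: R_s = VT_s / VP_s for one frequently misclassified sequence.

    The most-predicted class is the argmax of the misclassification
    assignment counts (ties toward the lowest class index). By default VT
    and VP accumulate votes over ALL test occasions; with
    ``misclassified_only`` they count only misclassified occasions (a
    sensitivity-analysis variant).
    """
    if profile.n_misclassified == 0:
        raise ValueError(
            f"sequence {profile.id!r} was never misclassified; most-predicted class undefined"
        )
    predicted = int(np.argmax(profile.assigned_counts)) + 1  # ties -> lowest index
    if misclassified_only:
        totals = profile.votes_log[profile.misclassified_mask].sum(axis=0)
    else:
        totals = profile.votes_by_class
    vt = int(totals[profile.true_class - 1])
    vp = int(totals[predicted - 1])
    if vp == 0:
        raise ValueError(f"sequence {profile.id!r}: most-predicted class received no votes")
    return {"VT": vt, "VP": vp, "R": vt / vp, "predicted_class": predicted}


def cumulative_dv(profile: ErrorProfile, predicted_class: int) -> float:
    """Step 3: CDV_s summed over all test occasions for the single pair
    classifier confronting the true class with ``predicted_class``.

    The canonical sign convention (positive favors the lower class index)
    makes the result directly interpretable: a consistently preferred
    predicted class j gives a large positive CDV when true i > j and a
    large negative one when i < j.
    """
    if predicted_class == profile.true_class:
        raise ValueError("predicted class equals the true class; no pair classifier exists")
    return float(profile.dv_true[:, predicted_class - 1].sum())


def classify_magnitude(r: float, cdv: float, config: DetectorConfig) -> dict:
    """Combine the step-2 and step-3 thresholds into an error magnitude."""
    large_r = r <= config.theta_R
    large_cdv = abs(cdv) >= config.theta_CDV_effective
    return {
        "large_R": large_r,
        "large_CDV": large_cdv,
        "magnitude": "large" if (large_r or large_cdv) else "small",
    }


@dataclass
class DetectionResult:
    """End-to-end output of the three-step analysis."""

    candidates: list[NoiseCandidate]
    frequent: list[NoiseCandidate]
    profiles: list[ErrorProfile]
    iteration_metrics: pd.DataFrame
    C_opt: float
    gamma_opt: float

    def candidates_frame(self) -> pd.DataFrame:
        return _as_frame(self.candidates)

    def frequent_frame(self) -> pd.DataFrame:
        return _as_frame(self.frequent)

    def profiles_frame(self) -> pd.DataFrame:
        """Per-sequence misclassification statistics (all sequences)."""
        k = self.profiles[0].assigned_counts.size if self.profiles else 0
        rows = []
        for p in self.profiles:
            row = {"id": p.id, "ER": p.er, "true_class": p.true_class}
            for c in range(1, k + 1):
                row[f"miscls_as_{c}"] = int(p.assigned_counts[c - 1])
            row["VT"] = p.votes_true
            rows.append(row)
        return pd.DataFrame(rows)


def _as_frame(candidates: list[NoiseCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "true_class": c.true_class,
                "predicted_class": c.predicted_class,
                "ER": c.er,
                "R": c.r,
                "CDV": c.cdv,
                "large_R": c.large_r,
                "large_CDV": c.large_cdv,
                "magnitude": c.magnitude,
            }
            for c in candidates
        ],
        columns=[
            "id",
            "true_class",
            "predicted_class",
            "ER",
            "R",
            "CDV",
            "large_R",
            "large_CDV",
            "magnitude",
        ],
    )


def detect_candidates(
    X: np.ndarray,
    y: np.ndarray,
    ids: list[str],
    config: DetectorConfig,
    C_opt: float | None = None,
    gamma_opt: float | None = None,
    svm_config: SVMConfig | None = None,
) -> DetectionResult:
    """Run the three-step analysis end to end.

    If C/gamma are not supplied they are grid-search tuned first (using
    ``svm_config``, or a default configuration seeded from the detector
    seed). The returned shortlist contains the frequently misclassified
    sequences whose error magnitude is "large" by either the voting-ratio
    or the cumulative-decision-value criterion; ``frequent`` additionally
    retains the small-magnitude ones for reporting.
    """
    if C_opt is None or gamma_opt is None:
        cfg = svm_config or SVMConfig(
            n_folds=config.n_folds, standardize=config.standardize, seed=config.seed
        )
        tuned = tune_hyperparameters(X, y, cfg)
        C_opt, gamma_opt = tuned.C_opt, tuned.gamma_opt

    profiles, iteration_metrics = profile_errors(X, y, ids, C_opt, gamma_opt, config)
    frequent_profiles = select_frequent(profiles, config.e_threshold)

    frequent: list[NoiseCandidate] = []
    for p in frequent_profiles:
        vr = voting_ratio(p, misclassified_only=config.votes_misclassified_only)
        cdv = cumulative_dv(p, vr["predicted_class"])
        mag = classify_magnitude(vr["R"], cdv, config)
        frequent.append(
            NoiseCandidate(
                id=p.id,
                true_class=p.true_class,
                predicted_class=vr["predicted_class"],
                er=p.er,
                r=vr["R"],
                cdv=cdv,
                large_r=mag["large_R"],
                large_cdv=mag["large_CDV"],
            )
        )
    shortlist = [c for c in frequent if c.magnitude == "large"]
    return DetectionResult(
        candidates=shortlist,
        frequent=frequent,
        profiles=profiles,
        iteration_metrics=iteration_metrics,
        C_opt=C_opt,
        gamma_opt=gamma_opt,
    )
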