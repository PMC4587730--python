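"""Shared fixtures: Gaussian feature blobs and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from gpcrnoise.detector import ErrorProfile
from gpcrnoise.simulate import GeneratorConfig, generate_dataset


def make_blobs(
    n_classes: int, per_class: int, spread: float = 0.3, dim: int = 2, seed: int = 0
):
    """Well-separated Gaussian clusters with 1-based integer labels."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 10, size=(n_classes, dim))
    X = np.vstack(
        [centers[k] + rng.normal(0, spread, size=(per_class, dim)) for k in range(n_classes)]
    )
    y = np.repeat(np.arange(1, n_classes + 1), per_class)
    return X, y


def make_profile(
    true_class: int,
    pred_log: np.ndarray,
    votes_log: np.ndarray,
    dv_true: np.ndarray | None = None,
    rec_id: str = "seq",
) -> ErrorProfile:
    """Assemble an ErrorProfile from explicit per-iteration logs."""
    pred_log = np.asarray(pred_log, dtype=int)
    votes_log = np.asarray(votes_log, dtype=np.int64)
    n_iter = pred_log.size
    if dv_true is None:
        dv_true = np.zeros((n_iter, votes_log.shape[1]))
    return ErrorProfile(
        id=rec_id,
        true_class=true_class,
        n_iterations=n_iter,
        er=100.0 * float(np.sum(pred_log != true_class)) / n_iter,
        pred_log=pred_log,
        votes_log=votes_log,
        dv_true=np.asarray(dv_true, dtype=float),
    )


@pytest.fixture(scope="session")
def blobs7():
    return make_blobs(7, 10, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Clean 4-class synthetic dataset, desk-scale for fast SVM tests."""
    config = GeneratorConfig(
        class_names=("A", "B", "C", "D"),
        class_sizes=(12, 12, 12, 12),
        length_range=(40, 80),
        noise_rate=0.0,
        seed=7,
    )
    dataset, truth = generate_dataset(config)
    return dataset, truth, config
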