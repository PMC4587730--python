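"""End-to-end orchestration: transform -> tune -> detect -> (ensemble) -> report.

``run_pipeline`` executes the full analysis for one or more sequence
transformations and writes all artifacts into a single output directory:

- ``candidates_<method>.tsv``      shortlisted label-noise candidates
- ``frequent_<method>.tsv``        all frequently misclassified sequences
- ``profiles_<method>.tsv``        per-sequence misclassification statistics
- ``iteration_metrics_<method>.tsv`` per-iteration accuracy / multi-class MCC
- ``noise_rank.tsv`` / ``overlap.tsv`` when the ensemble filter is enabled
- ``intersection.tsv``             cross-transform agreement (multi-transform
  runs only); agreement across transformations strengthens the evidence
  that a sequence is mislabeled rather than merely hard to represent
- ``manifest.json``                config snapshot, seeds, input checksums

Runs are idempotent for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .detector import DetectorConfig, detect_candidates
from .ensemble import EnsembleConfig, noise_rank, overlap_report, run_ensemble, select_by_failures
from .seq_io import LabeledDataset
from .svm import SVMConfig, tune_hyperparameters
from .transforms import transform_dataset

__all__ = ["run_pipeline"]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def run_pipeline(
    dataset: LabeledDataset,
    out_dir: str | Path,
    transforms: tuple[str, ...] = ("acc",),
    detector_config: DetectorConfig | None = None,
    svm_config: SVMConfig | None = None,
    ensemble_config: EnsembleConfig | None = None,
    with_ensemble: bool = False,
    acc_lag: int | None = None,
    pdbt_lag: int | None = None,
    input_files: dict[str, str | Path] | None = None,
) -> Path:
    """Run the systematic misclassification analysis end to end.

    Returns the output directory. With several ``transforms``, a
    per-transform candidate set is produced plus the intersection table of
    sequences frequently misclassified under every transformation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    detector_config = detector_config or DetectorConfig()
    svm_config = svm_config or SVMConfig(
        n_folds=detector_config.n_folds,
        standardize=detector_config.standardize,
        seed=detector_config.seed,
    )

    y = dataset.label_indices()
    ids = dataset.ids
    frequent_sets: dict[str, set[str]] = {}
    tuned_points: dict[str, dict] = {}
    first_result = None

    for method in transforms:
        lag = acc_lag if method == "acc" else pdbt_lag if method == "pdbt" else None
        fm = transform_dataset(dataset, method, max_lag=lag)
        tuned = tune_hyperparameters(fm.X, y, svm_config)
        result = detect_candidates(
            fm.X, y, ids, detector_config, C_opt=tuned.C_opt, gamma_opt=tuned.gamma_opt
        )
        if first_result is None:
            first_result = (method, fm, result)
        tuned_points[method] = {
            "C_opt": tuned.C_opt,
            "gamma_opt": tuned.gamma_opt,
            "cv_accuracy": tuned.cv_accuracy,
        }
        result.candidates_frame().to_csv(out / f"candidates_{method}.tsv", sep="\t", index=False)
        result.frequent_frame().to_csv(out / f"frequent_{method}.tsv", sep="\t", index=False)
        result.profiles_frame().to_csv(out / f"profiles_{method}.tsv", sep="\t", index=False)
        result.iteration_metrics.to_csv(
            out / f"iteration_metrics_{method}.tsv", sep="\t", index=False
        )
        frequent_sets[method] = {c.id for c in result.frequent}

    if len(transforms) > 1:
        common = set.intersection(*frequent_sets.values())
        pd.DataFrame(
            {
                "id": sorted(common),
                "n_transforms": len(transforms),
            }
        ).to_csv(out / "intersection.tsv", sep="\t", index=False)

    if with_ensemble:
        method, fm, result = first_result
        ens_cfg = ensemble_config or EnsembleConfig(
            seed=detector_config.seed,
            svm_C=tuned_points[method]["C_opt"],
            svm_gamma=tuned_points[method]["gamma_opt"],
        )
        flags = run_ensemble(fm.X, y, ids, ens_cfg)
        rank = noise_rank(flags, ens_cfg.weights)
        rank.to_csv(out / "noise_rank.tsv", sep="\t")
        ens_ids = select_by_failures(flags, ens_cfg.min_failures)
        svm_ids = [c.id for c in result.frequent]
        report = overlap_report(svm_ids, ens_ids)
        report["consensus_n"] = len(select_by_failures(flags, len(ens_cfg.roster)))
        pd.DataFrame([report]).to_csv(out / "overlap.tsv", sep="\t", index=False)

    manifest = {
        "software": {"name": "gpcrnoise", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "n_records": len(dataset),
        "classes": dataset.classes,
        "transforms": list(transforms),
        "tuned": tuned_points,
        "detector_config": _config_dict(detector_config),
        "svm_config": _config_dict(svm_config),
        "input_checksums": {
            name: _checksum(Path(p)) for name, p in (input_files or {}).items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return out
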