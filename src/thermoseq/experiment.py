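"""End-to-end orchestration of the two experimental designs.

``run_experiment`` takes a labeled dataset through preprocessing
(length-percentile filter, greedy redundancy reduction), split construction
(nested CV or species holdout), per-family hyperparameter optimization on
the inner folds, retraining of the winning configuration, and evaluation on
the held-out partitions — writing metric reports, trial logs, ROC points,
predictions and the length/OGT bin tables into one output directory.
Any species or record leakage between training and test partitions aborts
the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, hpo, models, splits
from .descriptors import featurize_dataset
from .embed import get_embedder
from .io import Dataset, read_fasta_with_metadata, validate_alphabet, write_predictions

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "predict"]

_FEATURE_FAMILIES = {"elastic_net", "svm", "random_forest", "xgboost", "mlp"}


@dataclass
class ExperimentConfig:
    design: str = "nested_cv"  # nested_cv | species_holdout
    families: list[str] = field(default_factory=lambda: ["elastic_net"])
    embedder: str = "mock"
    embed_dim: int = 64
    n_trials: int = 20
    outer_folds: int = 3
    inner_folds: int = 5
    holdout_species: list[str] = field(default_factory=list)
    length_filter: bool = True
    redundancy_reduction: bool = False
    identity_threshold: float = 0.40
    relatedness_max_identity: float = 0.50
    seed: int = 0
    out_dir: str = "experiment_out"

    def __post_init__(self):
        if self.design not in ("nested_cv", "species_holdout"):
            raise ValueError(f"unknown design {self.design!r}")
        unknown = set(self.families) - set(models.FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _family_inputs(family: str, ds: Dataset, ids: list[str], features: pd.DataFrame):
    sub = ds.subset(ids)
    y = np.asarray(sub.labels, dtype=int)
    if family in _FEATURE_FAMILIES:
        return features.loc[sub.ids].to_numpy(), y
    return sub.sequences, y


def _assert_no_leakage(train_ids, test_ids, what: str) -> None:
    leak = set(train_ids) & set(test_ids)
    if leak:
        raise RuntimeError(f"leakage between training and {what}: {sorted(leak)[:5]}")


def _evaluate(model, X, y) -> tuple[evaluation.MetricReport, np.ndarray]:
    scores = models.predict_proba(model, X)
    preds = (scores >= 0.5).astype(int)
    counts = evaluation.confusion(y, preds)
    auc = None
    if len(np.unique(y)) == 2:
        _, auc = evaluation.roc_auc(y, scores)
    return evaluation.metrics(counts, auc=auc), scores


def run_experiment(cfg: ExperimentConfig, ds: Dataset) -> pd.DataFrame:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(json.dumps(cfg.__dict__, indent=2, default=str))

    ds = validate_alphabet(ds)
    if cfg.length_filter:
        ds = splits.length_percentile_filter(ds)
    if cfg.redundancy_reduction:
        ds = splits.reduce_redundancy(ds, cfg.identity_threshold)

    features = featurize_dataset(ds) if set(cfg.families) & _FEATURE_FAMILIES else None
    fixed_by_family = {}
    if "prolatherm" in cfg.families:
        fixed_by_family["prolatherm"] = {
            "embedder": get_embedder(cfg.embedder, seed=cfg.seed, d=cfg.embed_dim)
        }

    report_rows = []
    if cfg.design == "nested_cv":
        plan = splits.nested_cv_plan(ds, cfg.outer_folds, cfg.inner_folds, cfg.seed)
        plan.to_tsv(out_dir / "split_plan.tsv")
        for family in cfg.families:
            fold_metrics = []
            for k in range(cfg.outer_folds):
                test_ids = plan.outer_test_ids(k)
                train_ids = plan.outer_train_ids(k)
                _assert_no_leakage(train_ids, test_ids, f"outer fold {k}")
                fold_data = []
                for j in range(cfg.inner_folds):
                    val_ids = plan.inner_fold_ids(k, j)
                    tr_ids = [rid for rid in train_ids if rid not in set(val_ids)]
                    fold_data.append(
                        _family_inputs(family, ds, tr_ids, features)
                        + _family_inputs(family, ds, val_ids, features)
                    )
                best, history = hpo.optimize(
                    family, models.SEARCH_SPACES[family], fold_data,
                    n_trials=cfg.n_trials, seed=cfg.seed,
                    fixed_params=fixed_by_family.get(family),
                )
                hpo.trials_to_tsv(history, out_dir / f"trials_{family}_outer{k}.tsv")
                X_all, y_all = _family_inputs(family, ds, train_ids, features)
                model = hpo.retrain_best(
                    best, family, X_all, y_all, seed=cfg.seed,
                    fixed_params=fixed_by_family.get(family),
                )
                X_test, y_test = _family_inputs(family, ds, test_ids, features)
                report, scores = _evaluate(model, X_test, y_test)
                fold_metrics.append(report.to_dict())
                write_predictions(
                    ds.subset(test_ids), scores, out_dir / f"preds_{family}_outer{k}.tsv"
                )
            frame = pd.DataFrame(fold_metrics)
            row = {"family": family}
            for metric in frame.columns:
                row[metric] = f"{frame[metric].mean():.3f} +- {frame[metric].std(ddof=0):.3f}"
            report_rows.append(row)
    else:
        holdout = set(cfg.holdout_species)
        plan = splits.species_holdout_plan(ds, holdout, cfg.inner_folds, cfg.seed)
        plan.to_tsv(out_dir / "split_plan.tsv")
        cv_ids = plan.cv_ids()
        test1_ids = plan.holdout_ids()
        _assert_no_leakage(cv_ids, test1_ids, "test1")
        test1 = ds.subset(test1_ids)
        train_ds = ds.subset(cv_ids)
        test2 = splits.relatedness_filter(test1, train_ds, cfg.relatedness_max_identity)
        for family in cfg.families:
            fold_data = []
            for j in range(cfg.inner_folds):
                val_ids = plan.inner_fold_ids(None, j)
                tr_ids = [rid for rid in cv_ids if rid not in set(val_ids)]
                fold_data.append(
                    _family_inputs(family, ds, tr_ids, features)
                    + _family_inputs(family, ds, val_ids, features)
                )
            best, history = hpo.optimize(
                family, models.SEARCH_SPACES[family], fold_data,
                n_trials=cfg.n_trials, seed=cfg.seed,
                fixed_params=fixed_by_family.get(family),
            )
            hpo.trials_to_tsv(history, out_dir / f"trials_{family}.tsv")
            X_all, y_all = _family_inputs(family, ds, cv_ids, features)
            model = hpo.retrain_best(
                best, family, X_all, y_all, seed=cfg.seed,
                fixed_params=fixed_by_family.get(family),
            )
            row = {"family": family}
            for tag, part in (("test1", test1), ("test2", test2)):
                X_test, y_test = _family_inputs(family, ds, part.ids, features)
                report, scores = _evaluate(model, X_test, y_test)
                for metric, value in report.to_dict().items():
                    row.setdefault(metric, {})
                    row[metric][tag] = value
                write_predictions(part, scores, out_dir / f"preds_{family}_{tag}.tsv")
                if tag == "test1":
                    preds = (scores >= 0.5).astype(int)
                    evaluation.bin_by_length(part, preds).to_csv(
                        out_dir / f"length_bins_{family}.tsv", sep="\t", index=False
                    )
                    evaluation.bin_by_ogt(part, preds, [60, 70, 80, 90]).to_csv(
                        out_dir / f"ogt_bins_{family}.tsv", sep="\t", index=False
                    )
                    curve, _ = evaluation.roc_auc(y_test, scores)
                    curve.to_csv(out_dir / f"roc_{family}.tsv", sep="\t", index=False)
            # Table-4-style layout: test1 value with bracketed test2 value
            row = {
                "family": family,
                **{
                    m: f"{v['test1']:.3f} [{v['test2']:.3f}]"
                    for m, v in row.items()
                    if m != "family" and isinstance(v, dict)
                },
            }
            report_rows.append(row)

    report = pd.DataFrame(report_rows)
    report.to_csv(out_dir / "report.tsv", sep="\t", index=False)
    return report


def predict(fasta_path: str | Path, model_dir: str | Path, out_path: str | Path,
            meta_path: str | Path | None = None, embedder=None) -> pd.DataFrame:
    """Score a FASTA file with a saved checkpoint and write predictions TSV."""
    from Bio import SeqIO

    from .io import ProteinRecord

    if meta_path is not None:
        ds = read_fasta_with_metadata(fasta_path, meta_path)
    else:
        ds = Dataset(
            [
                ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
                for rec in SeqIO.parse(str(fasta_path), "fasta")
            ]
        )
    ds = validate_alphabet(ds)
    model, spec = models.load_model(model_dir)
    family = spec["family"]
    if family == "prolatherm" and getattr(model, "embedder", None) is None:
        if embedder is None:
            raise ValueError(
                "this checkpoint needs a per-residue embedding provider; pass embedder="
            )
        model.embedder = embedder
    if family in _FEATURE_FAMILIES:
        X = featurize_dataset(ds).to_numpy()
    else:
        X = ds.sequences
    scores = models.predict_proba(model, X)
    write_predictions(ds, scores, out_path)
    from .io import read_predictions

    return read_predictions(out_path)
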