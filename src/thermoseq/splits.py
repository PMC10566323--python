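"""Length filtering, homology-aware redundancy reduction and data splitting.

Two experimental designs are supported:

* ``nested_cv`` — class-stratified 3-outer / 5-inner nested cross-validation
  for unbiased generalization estimates;
* ``species_holdout`` — a held-out test partition containing only proteins
  from species absent from every training/validation fold, guarding against
  species-circularity bias, with an optional relatedness-filtered subset
  (maximum identity to any training sequence below 50%).

Sequence identity is computed from an optimal Needleman–Wunsch global
alignment (match +1, mismatch 0, linear gap −1), identity = matches /
alignment columns. Redundancy reduction is a transparent greedy incremental
clustering over that kernel (length-descending, ties by id), returning the
cluster seeds as representatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from sklearn.model_selection import StratifiedKFold

from .io import Dataset

__all__ = [
    "SplitPlan",
    "IdentityResult",
    "length_percentile_filter",
    "pairwise_identity",
    "max_identity_against",
    "reduce_redundancy",
    "stratified_kfold",
    "nested_cv_plan",
    "species_holdout_plan",
    "relatedness_filter",
]


# ---------------------------------------------------------------------------
# identity kernel
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _aligner()


@dataclass(frozen=True)
class IdentityResult:
    query_id: str
    best_hit_id: str
    identity: float


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity of two sequences, in [0, 1].

    Identity = matched columns / total alignment columns of one optimal
    global alignment; symmetric by construction of the scoring scheme.
    """
    if not a or not b:
        raise ValueError("pairwise_identity: empty sequence")
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


def max_identity_against(query: str, references: list[str]) -> float:
    """Maximum pairwise identity of ``query`` against a list of sequences."""
    return max(pairwise_identity(query, ref) for ref in references)


# ---------------------------------------------------------------------------
# length filtering
# ---------------------------------------------------------------------------

def nearest_rank(values, pct: float):
    """Nearest-rank percentile: the ceil(pct/100 * n)-th order statistic."""
    ordered = sorted(values)
    n = len(ordered)
    rank = max(1, math.ceil(pct / 100.0 * n))
    return ordered[min(rank, n) - 1]


def length_percentile_filter(ds: Dataset, lo_pct: float = 5, hi_pct: float = 95) -> Dataset:
    """Drop sequences shorter than the lo_pct-th or longer than the hi_pct-th
    length percentile (nearest-rank percentiles of the dataset's lengths)."""
    if lo_pct >= hi_pct:
        raise ValueError(f"lo_pct ({lo_pct}) must be < hi_pct ({hi_pct})")
    if len(ds) == 0:
        raise ValueError("length_percentile_filter: empty dataset")
    lengths = [len(rec) for rec in ds]
    lo = nearest_rank(lengths, lo_pct) if lo_pct > 0 else min(lengths)
    hi = nearest_rank(lengths, hi_pct)
    kept = [rec for rec in ds if lo <= len(rec) <= hi]
    return Dataset(kept, provenance=ds.provenance)


# ---------------------------------------------------------------------------
# redundancy reduction
# ---------------------------------------------------------------------------

def reduce_redundancy(ds: Dataset, threshold: float = 0.40) -> Dataset:
    """Greedy incremental clustering at a global-identity threshold.

    Records are visited length-descending (ties by id). Each record joins the
    first existing cluster whose representative (seed) has identity >= the
    threshold, else it opens a new cluster. One representative per cluster is
    returned, in the original dataset order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(ds.records, key=lambda r: (-len(r), r.id))
    representatives: list = []
    for rec in order:
        for rep in representatives:
            if pairwise_identity(rec.sequence, rep.sequence) >= threshold:
                break
        else:
            representatives.append(rec)
    keep = {rep.id for rep in representatives}
    return Dataset([rec for rec in ds if rec.id in keep], provenance=ds.provenance)


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Fold/partition assignment for one experimental design.

    ``assignment`` maps record id → {level: partition tag}. Levels:

    * nested_cv: ``outer`` → ``outer<k>`` (the record's outer *test* fold)
      and ``inner:outer<k>`` → ``inner<j>`` for every outer fold k in which
      the record is training data.
    * species_holdout: ``outer`` → ``test1`` or ``cv``; for cv records,
      ``inner`` → ``inner<j>``.
    """

    design: str
    outer_folds: int
    inner_folds: int
    seed: int
    assignment: dict[str, dict[str, str]] = field(default_factory=dict)

    # -- queries ------------------------------------------------------------
    def ids_with(self, level: str, tag: str) -> list[str]:
        return [rid for rid, lv in self.assignment.items() if lv.get(level) == tag]

    def outer_test_ids(self, k: int) -> list[str]:
        return self.ids_with("outer", f"outer{k}")

    def outer_train_ids(self, k: int) -> list[str]:
        tag = f"outer{k}"
        return [rid for rid, lv in self.assignment.items() if "outer" in lv and lv["outer"] != tag]

    def inner_fold_ids(self, k: int | None, j: int) -> list[str]:
        level = "inner" if k is None else f"inner:outer{k}"
        return self.ids_with(level, f"inner{j}")

    def holdout_ids(self) -> list[str]:
        return self.ids_with("outer", "test1")

    def cv_ids(self) -> list[str]:
        return self.ids_with("outer", "cv")

    # -- serialization ------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"id": rid, "level": level, "partition": tag}
            for rid, levels in self.assignment.items()
            for level, tag in levels.items()
        ]
        header = (
            f"# design={self.design} outer_folds={self.outer_folds} "
            f"inner_folds={self.inner_folds} seed={self.seed}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SplitPlan":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
            meta = dict(tok.split("=") for tok in header.split())
            df = pd.read_csv(fh, sep="\t", dtype=str)
        plan = cls(
            design=meta["design"],
            outer_folds=int(meta["outer_folds"]),
            inner_folds=int(meta["inner_folds"]),
            seed=int(meta["seed"]),
        )
        for _, row in df.iterrows():
            plan.assignment.setdefault(row["id"], {})[row["level"]] = row["partition"]
        return plan


def _check_labels(ds: Dataset) -> np.ndarray:
    labels = ds.labels
    if any(lab is None for lab in labels):
        missing = [rid for rid, lab in zip(ds.ids, labels) if lab is None]
        raise ValueError(f"records without labels cannot be split: {missing[:5]}")
    return np.asarray(labels, dtype=int)


def _stratified_fold_tags(ids: list[str], labels: np.ndarray, k: int, seed: int) -> dict[str, str]:
    """Map id → ``inner<j>`` fold tag using a seeded class-stratified split."""
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present for a stratified split")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tags: dict[str, str] = {}
    for j, (_, test_idx) in enumerate(skf.split(np.zeros(len(ids)), labels)):
        for i in test_idx:
            tags[ids[i]] = f"inner{j}"
    return tags


def stratified_kfold(ds: Dataset, k: int, seed: int) -> SplitPlan:
    """Class-stratified k-fold plan (per-fold class counts within 1 of ideal)."""
    labels = _check_labels(ds)
    tags = _stratified_fold_tags(ds.ids, labels, k, seed)
    plan = SplitPlan(design="species_holdout", outer_folds=0, inner_folds=k, seed=seed)
    for rid in ds.ids:
        plan.assignment[rid] = {"outer": "cv", "inner": tags[rid]}
    return plan


def nested_cv_plan(ds: Dataset, outer: int = 3, inner: int = 5, seed: int = 0) -> SplitPlan:
    """Nested cross-validation: class-stratified outer folds, each outer
    training set re-split into class-stratified inner folds."""
    labels = _check_labels(ds)
    ids = ds.ids
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    if outer > counts.min():
        raise ValueError(f"outer={outer} exceeds the smaller class size {counts.min()}")
    plan = SplitPlan(design="nested_cv", outer_folds=outer, inner_folds=inner, seed=seed)
    skf = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
    for rid in ids:
        plan.assignment[rid] = {}
    folds = list(skf.split(np.zeros(len(ids)), labels))
    for k, (train_idx, test_idx) in enumerate(folds):
        for i in test_idx:
            plan.assignment[ids[i]]["outer"] = f"outer{k}"
        train_ids = [ids[i] for i in train_idx]
        train_labels = labels[train_idx]
        # derived seed keeps inner folds independent across outer folds
        tags = _stratified_fold_tags(train_ids, train_labels, inner, seed * 1000 + k + 1)
        for rid in train_ids:
            plan.assignment[rid][f"inner:outer{k}"] = tags[rid]
    return plan


def species_holdout_plan(
    ds: Dataset, holdout_species: set[str], inner: int = 5, seed: int = 0
) -> SplitPlan:
    """Species-disjoint holdout: all records of the holdout species go to
    partition ``test1``; the rest is split into class-stratified CV folds."""
    labels = _check_labels(ds)
    holdout_species = set(holdout_species)
    unknown = holdout_species - ds.species_set
    if unknown:
        raise ValueError(f"holdout species not in dataset: {sorted(unknown)}")
    rest_ids, rest_labels, test_ids = [], [], []
    for rid, rec, lab in zip(ds.ids, ds.records, labels):
        if rec.species in holdout_species:
            test_ids.append(rid)
        else:
            rest_ids.append(rid)
            rest_labels.append(lab)
    rest_labels = np.asarray(rest_labels, dtype=int)
    if len(rest_ids) == 0 or np.bincount(rest_labels, minlength=2).min() == 0:
        raise ValueError("holdout species cover an entire class; nothing left to train on")
    plan = SplitPlan(design="species_holdout", outer_folds=0, inner_folds=inner, seed=seed)
    tags = _stratified_fold_tags(rest_ids, rest_labels, inner, seed)
    for rid in test_ids:
        plan.assignment[rid] = {"outer": "test1"}
    for rid in rest_ids:
        plan.assignment[rid] = {"outer": "cv", "inner": tags[rid]}
    # species-disjointness invariant, asserted on every generated plan
    test_species = {ds[rid].species for rid in test_ids}
    cv_species = {ds[rid].species for rid in rest_ids}
    assert not (test_species & cv_species), "species leak between test1 and CV partitions"
    return plan


def relatedness_filter(test: Dataset, train: Dataset, max_identity: float = 0.50) -> Dataset:
    """Keep test records whose maximum identity to every training sequence is
    strictly below ``max_identity`` (the evolutionary less-related subset)."""
    if len(test) == 0 or len(train) == 0:
        raise ValueError("relatedness_filter: empty dataset")
    train_seqs = train.sequences
    kept = [
        rec for rec in test if max_identity_against(rec.sequence, train_seqs) < max_identity
    ]
    return Dataset(kept, provenance=test.provenance)
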