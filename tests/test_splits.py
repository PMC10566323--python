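import numpy as np
import pytest

from thermoseq.io import Dataset, ProteinRecord, read_fasta_with_metadata
from thermoseq.splits import (
    length_percentile_filter,
    nested_cv_plan,
    pairwise_identity,
    reduce_redundancy,
    relatedness_filter,
    species_holdout_plan,
    stratified_kfold,
)


def _mk(records):
    return Dataset(records)


def _rec(rid, seq, species="sp", label=0):
    return ProteinRecord(id=rid, sequence=seq, species=species, ogt=None, label=label)


# ---------------------------------------------------------------------------
# identity kernel
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("AAAA", "AAAA", 1.0),
        ("AAAA", "TTTT", 0.0),
        ("ACDEFG", "ACDEFA", 5 / 6),  # hand alignment: 5 matches over 6 columns
    ],
)
def test_pairwise_identity_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)
    assert pairwise_identity(b, a) == pytest.approx(expected)  # symmetry


def test_pairwise_identity_empty_sequence():
    with pytest.raises(ValueError):
        pairwise_identity("", "ACD")


# ---------------------------------------------------------------------------
# length filter
# ---------------------------------------------------------------------------

def test_length_filter_nearest_rank():
    # lengths 1..100: 5th/95th nearest-rank percentiles are 5 and 95
    ds = _mk([_rec(f"r{i}", "A" * i) for i in range(1, 101)])
    kept = length_percentile_filter(ds)
    lengths = [len(r) for r in kept]
    assert len(kept) == 91
    assert min(lengths) == 5 and max(lengths) == 95


def test_length_filter_degenerate_and_identity():
    same = _mk([_rec(f"r{i}", "ACDEF") for i in range(10)])
    assert len(length_percentile_filter(same)) == 10
    mixed = _mk([_rec(f"r{i}", "A" * (i + 1)) for i in range(10)])
    assert len(length_percentile_filter(mixed, 0, 100)) == 10
    with pytest.raises(ValueError):
        length_percentile_filter(mixed, 50, 50)


# ---------------------------------------------------------------------------
# redundancy reduction
# ---------------------------------------------------------------------------

def test_reduce_redundancy_collapses_duplicates():
    ds = _mk([_rec("a", "ACDEFGHIKL"), _rec("b", "ACDEFGHIKL")])
    assert len(reduce_redundancy(ds)) == 1


def test_reduce_redundancy_keeps_unrelated():
    ds = _mk([_rec("a", "AAAAAAAAAA"), _rec("b", "TTTTTTTTTT")])
    assert len(reduce_redundancy(ds, 0.40)) == 2


def test_reduce_redundancy_two_planted_clusters():
    # 5 copies of X and 2 copies of unrelated Y -> exactly 2 representatives,
    # matching a brute-force all-pairs identity matrix + greedy assignment
    x, y = "ACDEFGHIKLMNPQRSTVWY", "WWWWWWWWWWGGGGGGGGGG"
    ds = _mk([_rec(f"x{i}", x) for i in range(5)] + [_rec(f"y{i}", y) for i in range(2)])
    reps = reduce_redundancy(ds, 0.40)
    assert len(reps) == 2
    assert {r.sequence for r in reps} == {x, y}


def test_reduce_redundancy_no_similar_representatives(golden_dir):
    ds = read_fasta_with_metadata(golden_dir / "redundancy.fasta", golden_dir / "redundancy.tsv")
    reps = reduce_redundancy(ds, 0.40)
    assert sum(r.species == "Clusterus_plantus" for r in reps) == 1  # planted 5-cluster
    seqs = reps.sequences
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            assert pairwise_identity(seqs[i], seqs[j]) < 0.40


def test_reduce_redundancy_threshold_validated(small_labeled_ds):
    with pytest.raises(ValueError):
        reduce_redundancy(small_labeled_ds, 1.5)


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------

def _label_ds(n_pos, n_neg, length=40):
    rng = np.random.RandomState(5)
    recs = []
    for i in range(n_pos + n_neg):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        recs.append(_rec(f"r{i}", seq, species=f"s{i % 7}", label=int(i < n_pos)))
    return _mk(recs)


def test_stratified_kfold_exact_counts():
    ds = _label_ds(10, 20)
    plan = stratified_kfold(ds, 5, seed=1)
    for j in range(5):
        fold = ds.subset(plan.inner_fold_ids(None, j))
        assert fold.class_counts() == {0: 4, 1: 2}


def test_stratified_kfold_pigeonhole():
    ds = _label_ds(11, 20)
    plan = stratified_kfold(ds, 5, seed=1)
    pos_counts = sorted(
        ds.subset(plan.inner_fold_ids(None, j)).class_counts()[1] for j in range(5)
    )
    assert pos_counts == [2, 2, 2, 2, 3]


def test_stratified_kfold_deterministic():
    ds = _label_ds(10, 20)
    a = stratified_kfold(ds, 5, seed=9).assignment
    b = stratified_kfold(ds, 5, seed=9).assignment
    assert a == b


def test_stratified_kfold_requires_labels(small_labeled_ds):
    unlabeled = Dataset([_rec("u", "ACDEF", label=None)] + small_labeled_ds.records)
    with pytest.raises(ValueError, match="label"):
        stratified_kfold(unlabeled, 2, seed=0)


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

def test_nested_cv_partition_properties():
    ds = _label_ds(12, 18)
    plan = nested_cv_plan(ds, outer=3, inner=5, seed=2)
    outer_folds = [set(plan.outer_test_ids(k)) for k in range(3)]
    assert sum(len(f) for f in outer_folds) == 30
    assert set().union(*outer_folds) == set(ds.ids)
    for i in range(3):
        for j in range(i + 1, 3):
            assert not outer_folds[i] & outer_folds[j]
    # inner folds of outer fold k never contain outer-test-k records and
    # partition the outer training set
    for k in range(3):
        inner_ids = set()
        for j in range(5):
            fold = set(plan.inner_fold_ids(k, j))
            assert not fold & outer_folds[k]
            assert not fold & inner_ids
            inner_ids |= fold
        assert inner_ids == set(ds.ids) - outer_folds[k]


# ---------------------------------------------------------------------------
# species holdout
# ---------------------------------------------------------------------------

def test_species_holdout_disjoint(small_labeled_ds):
    plan = species_holdout_plan(small_labeled_ds, {"species_2", "species_4"}, inner=2, seed=0)
    test_species = {small_labeled_ds[rid].species for rid in plan.holdout_ids()}
    cv_species = {small_labeled_ds[rid].species for rid in plan.cv_ids()}
    assert test_species == {"species_2", "species_4"}
    assert not test_species & cv_species
    assert len(plan.holdout_ids()) == 10  # 5 proteins per species


def test_species_holdout_empty_equals_kfold(small_labeled_ds):
    plan = species_holdout_plan(small_labeled_ds, set(), inner=3, seed=4)
    ref = stratified_kfold(small_labeled_ds, 3, seed=4)
    assert plan.holdout_ids() == []
    assert plan.assignment == ref.assignment


def test_species_holdout_whole_class_is_error(small_labeled_ds):
    with pytest.raises(ValueError, match="class"):
        species_holdout_plan(
            small_labeled_ds, {"species_0", "species_1", "species_2"}, inner=2, seed=0
        )


# ---------------------------------------------------------------------------
# relatedness filter
# ---------------------------------------------------------------------------

def test_relatedness_filter_drops_identical_keeps_unrelated():
    train = _mk([_rec("t0", "ACDEFGHIKLMNPQRSTVWY")])
    test = _mk(
        [
            _rec("same", "ACDEFGHIKLMNPQRSTVWY"),
            _rec("far", "GGGGGGGGGGGGGGGGGGGG"),
        ]
    )
    kept = relatedness_filter(test, train, 0.50)
    assert kept.ids == ["far"]


def test_relatedness_filter_matches_bruteforce(golden_dir):
    train = read_fasta_with_metadata(
        golden_dir / "holdout_train.fasta", golden_dir / "holdout_train.tsv"
    )
    test = read_fasta_with_metadata(
        golden_dir / "holdout_test.fasta", golden_dir / "holdout_test.tsv"
    )
    kept = relatedness_filter(test, train, 0.50)
    # exhaustive pairwise oracle
    expect = [
        rec.id
        for rec in test
        if max(pairwise_identity(rec.sequence, t) for t in train.sequences) < 0.50
    ]
    assert kept.ids == expect
    # the planted homologs must be exactly the removed records
    removed = set(test.ids) - set(kept.ids)
    assert {"homolog|H0", "homolog|H1"} <= removed


def test_relatedness_filter_monotone(golden_dir):
    train = read_fasta_with_metadata(
        golden_dir / "holdout_train.fasta", golden_dir / "holdout_train.tsv"
    )
    test = read_fasta_with_metadata(
        golden_dir / "holdout_test.fasta", golden_dir / "holdout_test.tsv"
    )
    sizes = [len(relatedness_filter(test, train, t)) for t in (0.3, 0.5, 0.9)]
    assert sizes == sorted(sizes)
    assert set(relatedness_filter(test, train, 0.3).ids) <= set(test.ids)
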