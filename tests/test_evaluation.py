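import math

import numpy as np
import pytest

from thermoseq.evaluation import (
    ConfusionCounts,
    bin_by_length,
    bin_by_ogt,
    confusion,
    metrics,
    percent_improvement,
    roc_auc,
)
from thermoseq.io import Dataset, ProteinRecord


def test_confusion_examples():
    c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
    assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)
    c = confusion([1, 0], [0, 1])
    assert (c.fp, c.fn) == (1, 1)
    with pytest.raises(ValueError):
        confusion([1, 0], [1])


def test_confusion_cells_partition(rng):
    labels = rng.randint(0, 2, 1000)
    preds = rng.randint(0, 2, 1000)
    c = confusion(labels, preds)
    assert c.n_s == 1000


def test_metrics_species_holdout_confusion_table():
    """345 thermophilic / 224 nonthermophilic test proteins with 1 false
    positive and 45 false negatives."""
    rep = metrics(ConfusionCounts(tp=300, tn=223, fp=1, fn=45))
    assert round(rep.mcc, 3) == 0.847
    assert round(rep.precision, 3) == 0.997
    assert round(rep.recall, 3) == 0.870
    assert round(rep.accuracy, 3) == 0.919
    assert round(rep.specificity, 3) == 0.996
    assert round(rep.bacc, 3) == 0.933
    assert round(rep.f1, 3) == 0.929


def test_metrics_shortest_length_bin():
    rep = metrics(ConfusionCounts(tp=70, tn=39, fp=0, fn=11))
    assert round(rep.mcc, 3) == 0.821


def test_metrics_perfect_predictor():
    rep = metrics(ConfusionCounts(tp=7, tn=5, fp=0, fn=0))
    for value in rep.to_dict().values():
        assert value == 1.0
    assert rep.degenerate == ()


def test_metrics_degenerate_flagged():
    rep = metrics(ConfusionCounts(tp=0, tn=4, fp=0, fn=0))
    assert rep.precision == 0.0 and "precision" in rep.degenerate
    assert rep.mcc == 0.0 and "mcc" in rep.degenerate


def test_bacc_internal_consistency(rng):
    for _ in range(50):
        cells = rng.randint(0, 30, 4)
        if cells.sum() == 0:
            continue
        rep = metrics(ConfusionCounts(*map(int, cells)))
        assert rep.bacc == pytest.approx((rep.recall + rep.specificity) / 2)


def test_metrics_order_independence(rng):
    labels = rng.randint(0, 2, 200)
    preds = rng.randint(0, 2, 200)
    perm = rng.permutation(200)
    assert metrics(confusion(labels, preds)) == metrics(confusion(labels[perm], preds[perm]))


def test_random_predictor_mcc_near_zero(rng):
    n = 1000
    vals = []
    labels = rng.randint(0, 2, n)
    for _ in range(200):
        preds = rng.randint(0, 2, n)
        vals.append(metrics(confusion(labels, preds)).mcc)
    assert abs(np.mean(vals)) < 3 / math.sqrt(n)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_auc_extremes():
    labels = [0, 0, 1, 1]
    _, auc = roc_auc(labels, [0.1, 0.2, 0.8, 0.9])
    assert auc == 1.0
    _, auc_tied = roc_auc(labels, [0.5, 0.5, 0.5, 0.5])
    assert auc_tied == 0.5
    with pytest.raises(ValueError):
        roc_auc([1, 1], [0.2, 0.8])


def test_roc_auc_hand_computation():
    # manual threshold sweep over 6 records
    labels = np.array([1, 1, 1, 0, 0, 0])
    scores = np.array([0.9, 0.7, 0.4, 0.6, 0.3, 0.1])
    _, auc = roc_auc(labels, scores)
    # thresholds: tp/fp trajectory gives area 2/3 + ... compute pairwise:
    # AUC = P(score_pos > score_neg) with ties at 0.5; pairs: 9 total,
    # favorable: (0.9,{0.6,0.3,0.1}) 3 + (0.7,{...}) 3 + (0.4,{0.3,0.1}) 2 = 8
    assert auc == pytest.approx(8 / 9)


def test_roc_auc_monotone_transform_invariant(rng):
    labels = rng.randint(0, 2, 100)
    labels[:5] = 1
    labels[5:10] = 0
    scores = rng.random_sample(100)
    _, a1 = roc_auc(labels, scores)
    _, a2 = roc_auc(labels, scores ** 3)
    assert a1 == pytest.approx(a2)


# ---------------------------------------------------------------------------
# binned analyses
# ---------------------------------------------------------------------------

def _binned_ds():
    rng = np.random.RandomState(0)
    recs = []
    for i, length in enumerate(np.linspace(82, 712, 40).astype(int)):
        label = int(i % 2 == 0)
        recs.append(
            ProteinRecord(
                id=f"r{i}",
                sequence="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length)),
                species=f"s{i % 6}",
                ogt=float(60 + (i % 4) * 10 + 2) if label else 25.0,
                label=label,
            )
        )
    return Dataset(recs)


def test_length_bin_edges_span_observed_range():
    ds = _binned_ds()
    preds = np.asarray(ds.labels, dtype=int)
    table = bin_by_length(ds, preds, n_bins=5)
    np.testing.assert_allclose(table["bin_low"], [82, 208, 334, 460, 586])
    np.testing.assert_allclose(table["bin_high"], [208, 334, 460, 586, 712])
    # partition conservation
    assert table["tp"].sum() == 20
    assert (table["n_thermo"] + table["n_nonthermo"]).sum() == 40


def test_length_single_bin_equals_global():
    ds = _binned_ds()
    preds = 1 - np.asarray(ds.labels, dtype=int)
    table = bin_by_length(ds, preds, n_bins=1)
    c = confusion(ds.labels, preds)
    assert table.loc[0, ["tp", "tn", "fp", "fn"]].tolist() == [c.tp, c.tn, c.fp, c.fn]


def test_ogt_bins_count_species_and_errors():
    ds = _binned_ds()
    preds = np.asarray(ds.labels, dtype=int).copy()
    preds[0] = 0  # one false negative (record 0 is thermophilic)
    table = bin_by_ogt(ds, preds, [60, 70, 80, 90])
    assert len(table) == 4
    assert table["fn"].sum() == 1
    assert table["tp"].sum() == 19
    # nonthermophilic records (OGT 25) fall outside all bins
    assert table["n_proteins"].sum() == 20
    # empty-bin behaviour: a range above every OGT yields zeros
    empty = bin_by_ogt(ds, preds, [200])
    assert empty.loc[0, "n_proteins"] == 0 and empty.loc[0, "tp"] == 0


def test_percent_improvement_arithmetic():
    assert percent_improvement(0.933, 0.790) == pytest.approx(18.1, abs=0.05)
    assert percent_improvement(0.847, 0.772) == pytest.approx(9.7, abs=0.05)
    with pytest.raises(ValueError):
        percent_improvement(1.0, 0.0)
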