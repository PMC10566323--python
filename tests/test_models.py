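import numpy as np
import pytest

from thermoseq import models
from thermoseq.embed import MockEmbedder
from thermoseq.models import (
    LSTMModel,
    MLPEmbeddingModel,
    PooledEmbeddingClassifier,
    TransformerModel,
    build_model,
    cross_entropy,
    validate_hyperparams,
)


@pytest.fixture(scope="module")
def tiny_seq_data(separable_ds):
    y = np.asarray(separable_ds.labels, dtype=int)
    return separable_ds.sequences[:60], y[:60]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def test_cross_entropy_examples():
    assert cross_entropy([1], [0.5]) == pytest.approx(np.log(2), abs=1e-6)
    assert cross_entropy([1], [1 - 1e-15]) == pytest.approx(0.0, abs=1e-9)
    assert cross_entropy([1, 0], [0.9, 0.2]) == pytest.approx(
        -(np.log(0.9) + np.log(0.8)) / 2, abs=1e-9
    )
    with pytest.raises(ValueError):
        cross_entropy([1, 0], [0.5])


# ---------------------------------------------------------------------------
# construction / registry
# ---------------------------------------------------------------------------

def test_build_model_families():
    for family in models.FAMILIES:
        model = build_model(family)
        assert hasattr(model, "fit") and hasattr(model, "predict_proba")
    with pytest.raises(ValueError, match="unknown model family"):
        build_model("perceptron_9000")


def test_hyperparams_validated_against_space():
    validate_hyperparams("svm", {"kernel": "rbf", "C": 1.0})
    with pytest.raises(ValueError):
        validate_hyperparams("svm", {"kernel": "sigmoid"})
    with pytest.raises(ValueError):
        validate_hyperparams("elastic_net", {"C": 1e9})
    with pytest.raises(ValueError):
        validate_hyperparams("lstm", {"made_up": 1})


def test_head_parameter_count():
    # FC d->d/2 (+bias), BN gamma/beta, FC d/2->2 (+bias)
    d = 64
    model = PooledEmbeddingClassifier(embedder=MockEmbedder(d=d, seed=0), max_epochs=2,
                                      early_stop_patience=1, seed=0)
    model.fit(["ACDEFGHIKL"] * 8 + ["KKKKKKKKKK"] * 8, [0] * 8 + [1] * 8)
    expected = d * (d // 2) + d // 2 + 2 * (d // 2) + (d // 2) * 2 + 2
    assert model.network_.n_parameters() == expected


def test_shared_head_across_families(tiny_seq_data):
    """The classifier head is the same component (identical parameter shapes)
    for the pooled-embedding, recurrent and transformer families."""
    X, y = tiny_seq_data
    kw = dict(max_epochs=2, early_stop_patience=1, seed=0)
    lstm = LSTMModel(embed_dim=8, hidden=8, bidirectional=True, **kw).fit(X[:20], y[:20])
    trans = TransformerModel(embed_dim=16, n_layers=1, n_heads=2, ff_dim=16, **kw).fit(
        X[:20], y[:20]
    )
    emb = MLPEmbeddingModel(embed_dim=16, **kw).fit(X[:20], y[:20])
    heads = [lstm.network_.head, trans.network_.head, emb.network_.head]
    assert all(type(h).__name__ == "HeadClassifier" for h in heads)
    for h, width in zip(heads, [16, 16, 16]):
        assert h.fc1.W.shape == (width, width // 2)
        assert h.fc_out.W.shape == (width // 2, 2)


def test_bilstm_last_state_width(tiny_seq_data):
    X, y = tiny_seq_data
    m = LSTMModel(embed_dim=8, hidden=10, bidirectional=True, max_epochs=2,
                  early_stop_patience=1, seed=0).fit(X[:20], y[:20])
    assert m.network_.head.fc1.W.shape[0] == 20  # 2 x hidden size


# ---------------------------------------------------------------------------
# probability interface
# ---------------------------------------------------------------------------

def test_predict_proba_softmax_properties(tiny_seq_data):
    X, y = tiny_seq_data
    m = MLPEmbeddingModel(embed_dim=8, max_epochs=3, early_stop_patience=1, seed=0)
    m.fit(X[:30], y[:30])
    probs = m.predict_proba(X[:10])
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert ((probs >= 0) & (probs <= 1)).all()
    pos = models.predict_proba(m, X[:10])
    np.testing.assert_allclose(pos, probs[:, 1])


def test_input_kind_mismatch_errors(tiny_seq_data):
    X, y = tiny_seq_data
    with pytest.raises(TypeError, match="feature matrix"):
        models.ElasticNetModel().fit(X, y)  # sequences into a feature model
    with pytest.raises(TypeError, match="sequences"):
        LSTMModel().fit(np.random.rand(10, 5), np.zeros(10, dtype=int))


# ---------------------------------------------------------------------------
# training loop contracts
# ---------------------------------------------------------------------------

def test_training_deterministic_same_seed(tiny_seq_data):
    X, y = tiny_seq_data
    kw = dict(embedder=MockEmbedder(d=16, seed=1), max_epochs=6, early_stop_patience=2, seed=4)
    m1 = PooledEmbeddingClassifier(**kw).fit(X, y)
    m2 = PooledEmbeddingClassifier(**kw).fit(X, y)
    assert m1.training_log_.equals(m2.training_log_)
    np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))


def test_training_reduces_loss_on_separable_features(rng):
    n = 120
    X = rng.standard_normal((n, 5))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += 2 * (y - 0.5)  # widen the margin
    m = models.MLPModel(hidden=16, n_layers=1, max_epochs=50, early_stop_patience=10, seed=0)
    m.fit(X, y)
    log = m.training_log_
    assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]
    assert m.best_val_loss_ < np.log(2)


def test_early_stopping_disabled_runs_all_epochs(tiny_seq_data):
    X, y = tiny_seq_data
    m = MLPEmbeddingModel(embed_dim=8, max_epochs=5, early_stop_patience=0, seed=0)
    m.fit(X[:30], y[:30])
    assert len(m.training_log_) == 5


def test_padding_never_changes_predictions(tiny_seq_data):
    """A record's score is identical whether predicted alone or in a padded
    batch with much longer sequences."""
    X, y = tiny_seq_data
    kw = dict(max_epochs=2, early_stop_patience=1, seed=0)
    for m in (
        MLPEmbeddingModel(embed_dim=8, **kw),
        LSTMModel(embed_dim=8, hidden=8, bidirectional=True, **kw),
        TransformerModel(embed_dim=16, n_heads=2, pool_stride=4, **kw),
        TransformerModel(embed_dim=16, n_heads=2, sparse=True, window=8, n_global=2, **kw),
    ):
        m.fit(X[:24], y[:24])
        short = min(X[:24], key=len)
        longest = max(X[:24], key=len)
        alone = m.predict_proba([short])[0, 1]
        batched = m.predict_proba([short, longest])[0, 1]
        assert alone == pytest.approx(batched, abs=1e-9)


def test_prolatherm_requires_embedder_for_sequences(tiny_seq_data):
    X, y = tiny_seq_data
    with pytest.raises(ValueError, match="provider"):
        PooledEmbeddingClassifier(embedder=None).fit(X, y)


def test_prolatherm_accepts_precomputed_pooled_matrix(rng):
    X = rng.standard_normal((40, 12))
    y = (X[:, 0] > 0).astype(int)
    m = PooledEmbeddingClassifier(max_epochs=5, early_stop_patience=2, seed=0).fit(X, y)
    assert m.predict_proba(X).shape == (40, 2)


def test_save_load_roundtrip(tmp_path, rng):
    X = rng.standard_normal((50, 6))
    y = (X.sum(axis=1) > 0).astype(int)
    m = models.ElasticNetModel(C=0.5, seed=0).fit(X, y)
    models.save_model(m, "elastic_net", tmp_path / "ckpt")
    loaded, spec = models.load_model(tmp_path / "ckpt")
    assert spec["family"] == "elastic_net"
    np.testing.assert_allclose(loaded.predict_proba(X), m.predict_proba(X))
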