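"""The classifier zoo: feature-based, hybrid and sequence-based families.

Thirteen families share the scikit-learn estimator interface
(``fit(X, y)``, ``predict``, ``predict_proba``, ``get_params``):

===================  =====================================================
family               input kind / architecture
===================  =====================================================
elastic_net          599-feature matrix → logistic regression, L1+L2 penalty
svm                  feature matrix → SVM (linear / RBF / polynomial kernel)
random_forest        feature matrix → bagged decision trees
xgboost              feature matrix → gradient-boosted trees
mlp                  feature matrix → FC stack with BN + dropout per layer
mlp_embedding        sequence → lookup embedding → mean pool → shared head
lstm / bilstm        sequence → lookup embedding → (bi)LSTM → last state → head
lstm_basicdesc /     sequence → 6-property residue encoding → FC expansion
bilstm_basicdesc       layers → (bi)LSTM → last state → head
transformer          sequence → lookup + positional embedding → stride
                       average pre-pooling → pre-LN transformer blocks →
                       mean pool → head
sparse_transformer   same without pre-pooling; sliding-window attention
                       plus g global tokens
prolatherm           per-residue language-model embedding → mean pool → head
===================  =====================================================

The classification head (FC d→d/2 + ReLU + batch norm, dropout, FC output)
is one shared component (:class:`~thermoseq._nn.HeadClassifier`) across the
embedding, recurrent and transformer families. Neural families minimize the
cross-entropy loss with Adam, reduce the learning rate on a validation-loss
plateau, use early stopping, and restore the best-validation-loss epoch.
All training is deterministic under a fixed seed. The decision threshold is
0.5 with the boundary assigned to the positive (thermophilic) class.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import _nn as nn
from ._autodiff import Tensor, softmax
from ._nn import TrainingConfig  # noqa: F401  (public re-export)
from .descriptors import ordinal_encode, residue_encoding
from .embed import EmbeddingMatrix, mean_pool

__all__ = [
    "TrainingConfig",
    "cross_entropy",
    "build_model",
    "validate_hyperparams",
    "predict_proba",
    "train",
    "save_model",
    "load_model",
    "SEARCH_SPACES",
    "FAMILIES",
    "ElasticNetModel",
    "SVMModel",
    "RandomForestModel",
    "XGBoostModel",
    "MLPModel",
    "MLPEmbeddingModel",
    "LSTMModel",
    "BasicDescLSTMModel",
    "TransformerModel",
    "PooledEmbeddingClassifier",
]


def cross_entropy(labels, probs, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy between 0/1 labels and probabilities."""
    labels = np.asarray(labels, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {probs.shape} probabilities")
    probs = np.clip(probs, eps, 1 - eps)
    return float(-np.mean(labels * np.log(probs) + (1 - labels) * np.log(1 - probs)))


# ---------------------------------------------------------------------------
# input-kind validation
# ---------------------------------------------------------------------------

def _describe_kind(X) -> str:
    arr = np.asarray(X, dtype=object) if not isinstance(X, np.ndarray) else X
    if arr.ndim == 2:
        return "numeric feature/embedding matrix"
    if arr.ndim == 1 and len(arr) and isinstance(arr.ravel()[0], str):
        return "amino-acid sequences"
    return f"array of shape {arr.shape}"


def _as_feature_matrix(X, who: str) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    arr = np.asarray(X)
    if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.number):
        raise TypeError(
            f"{who} expects a numeric feature matrix, got {_describe_kind(X)}"
        )
    return arr.astype(float)


def _as_sequences(X, who: str) -> list[str]:
    if isinstance(X, np.ndarray) and X.ndim == 2 and np.issubdtype(X.dtype, np.number):
        raise TypeError(f"{who} expects amino-acid sequences, got numeric feature matrix")
    seqs = list(X)
    if not seqs or not all(isinstance(s, str) for s in seqs):
        raise TypeError(f"{who} expects amino-acid sequences, got {_describe_kind(X)}")
    return seqs


# ---------------------------------------------------------------------------
# feature-based families (delegating to scikit-learn / xgboost)
# ---------------------------------------------------------------------------

class _FeatureModelBase(BaseEstimator, ClassifierMixin):
    def _make(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y):
        X = _as_feature_matrix(X, type(self).__name__)
        y = np.asarray(y, dtype=int)
        self.estimator_ = self._make()
        self.estimator_.fit(X, y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = _as_feature_matrix(X, type(self).__name__)
        return self.estimator_.predict_proba(X)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class ElasticNetModel(_FeatureModelBase):
    """Logistic regression with a mixed L1/L2 (elastic-net) penalty."""

    def __init__(self, C=1.0, l1_ratio=0.5, max_iter=5000, seed=0):
        self.C = C
        self.l1_ratio = l1_ratio
        self.max_iter = max_iter
        self.seed = seed

    def _make(self):
        return LogisticRegression(
            solver="saga",
            C=self.C,
            l1_ratio=self.l1_ratio,
            max_iter=self.max_iter,
            random_state=self.seed,
        )


class SVMModel(_FeatureModelBase):
    """Support vector machine with linear / RBF / polynomial kernels."""

    def __init__(self, kernel="rbf", C=1.0, gamma="scale", degree=3, coef0=0.0, seed=0):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.seed = seed

    def _make(self):
        return SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
            degree=self.degree,
            coef0=self.coef0,
            probability=True,
            random_state=self.seed,
        )


class RandomForestModel(_FeatureModelBase):
    def __init__(self, n_estimators=300, max_depth=None, max_features="sqrt", seed=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.seed = seed

    def _make(self):
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        )


class XGBoostModel(_FeatureModelBase):
    def __init__(
        self,
        n_estimators=300,
        max_depth=6,
        learning_rate=0.1,
        subsample=1.0,
        colsample_bytree=1.0,
        reg_lambda=1.0,
        seed=0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.reg_lambda = reg_lambda
        self.seed = seed

    def _make(self):
        return XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            reg_lambda=self.reg_lambda,
            random_state=self.seed,
            n_jobs=1,
            eval_metric="logloss",
        )


# ---------------------------------------------------------------------------
# neural base: shared Adam training loop
# ---------------------------------------------------------------------------

class _NeuralBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the autodiff-backed families.

    Subclasses implement ``_prepare`` (raw inputs → per-record internal
    representation), ``_build`` (construct the network from a seeded RNG)
    and ``_forward`` (batch of prepared records → two-logit Tensor).
    """

    # ---- subclass hooks ---------------------------------------------------
    def _prepare(self, X) -> list:
        raise NotImplementedError

    def _build(self, rng: np.random.RandomState, prepared: list) -> nn.Module:
        raise NotImplementedError

    def _forward(self, net: nn.Module, batch: list, training: bool) -> Tensor:
        raise NotImplementedError

    # ---- training ---------------------------------------------------------
    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            batch_size=getattr(self, "batch_size", 32),
            max_epochs=getattr(self, "max_epochs", 200),
            early_stop_patience=getattr(self, "early_stop_patience", 10),
            lr=getattr(self, "lr", 1e-3),
            seed=getattr(self, "seed", 0),
        )

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y, dtype=int)
        prepared = self._prepare(X)
        if len(prepared) != len(y):
            raise ValueError(f"{len(prepared)} inputs vs {len(y)} labels")
        cfg = self._config()

        if X_val is None:
            idx = np.arange(len(y))
            try:
                tr_idx, va_idx = train_test_split(
                    idx, test_size=max(0.1, 2 / len(y)), stratify=y, random_state=cfg.seed
                )
            except ValueError:
                tr_idx, va_idx = train_test_split(idx, test_size=0.1, random_state=cfg.seed)
            train_data = [prepared[i] for i in tr_idx]
            train_y = y[tr_idx]
            val_data = [prepared[i] for i in va_idx]
            val_y = y[va_idx]
        else:
            train_data, train_y = prepared, y
            val_data = self._prepare(X_val)
            val_y = np.asarray(y_val, dtype=int)
        if len(np.unique(val_y)) < 2:
            warnings.warn("validation set contains a single class; early stopping on loss only")

        rng = np.random.RandomState(cfg.seed)
        self._dropout_rng = np.random.RandomState(cfg.seed + 7)
        net = self._build(rng, train_data)
        opt = nn.Adam(net.parameters(), lr=cfg.lr)

        shuffler = np.random.RandomState(cfg.seed + 1)
        best_loss = np.inf
        best_state = nn.get_state(net)
        since_best = 0
        since_plateau = 0
        log = []
        for epoch in range(cfg.max_epochs):
            order = shuffler.permutation(len(train_y))
            train_losses = []
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                logits = self._forward(net, [train_data[i] for i in sel], training=True)
                loss = nn.logits_cross_entropy(logits, train_y[sel])
                opt.zero_grad()
                loss.backward()
                opt.step()
                train_losses.append(float(loss.data))
            val_loss = self._eval_loss(net, val_data, val_y, cfg.batch_size)
            log.append(
                {
                    "epoch": epoch,
                    "lr": opt.lr,
                    "train_loss": float(np.mean(train_losses)),
                    "val_loss": val_loss,
                }
            )
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best_state = nn.get_state(net)
                since_best = 0
                since_plateau = 0
            else:
                since_best += 1
                since_plateau += 1
            if since_plateau > cfg.lr_plateau_patience:
                opt.lr = max(opt.lr * cfg.lr_plateau_factor, cfg.min_lr)
                since_plateau = 0
            if cfg.early_stop_patience > 0 and since_best >= cfg.early_stop_patience:
                break
        nn.set_state(net, best_state)
        self.network_ = net
        self.classes_ = np.array([0, 1])
        self.best_val_loss_ = best_loss
        self.training_log_ = pd.DataFrame(log)
        return self

    def _eval_loss(self, net, data: list, y: np.ndarray, batch_size: int) -> float:
        losses, counts = [], []
        for start in range(0, len(y), batch_size):
            batch = data[start : start + batch_size]
            logits = self._forward(net, batch, training=False)
            loss = nn.logits_cross_entropy(logits, y[start : start + batch_size])
            losses.append(float(loss.data))
            counts.append(len(batch))
        return float(np.average(losses, weights=counts))

    def decision_logits(self, X) -> np.ndarray:
        prepared = self._prepare(X)
        out = []
        batch_size = getattr(self, "batch_size", 32)
        for start in range(0, len(prepared), batch_size):
            logits = self._forward(
                self.network_, prepared[start : start + batch_size], training=False
            )
            out.append(logits.data)
        return np.vstack(out)

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_logits(X)
        probs = softmax(Tensor(logits), axis=-1).data
        return probs

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# feature-matrix MLP
# ---------------------------------------------------------------------------

class _MLPNet(nn.Module):
    def __init__(self, n_in, hidden, n_layers, dropout, activation, rng, drop_rng):
        dims = [n_in] + [hidden] * n_layers
        self.layers = [nn.Linear(a, b, rng) for a, b in zip(dims, dims[1:])]
        self.bns = [nn.BatchNorm1d(hidden) for _ in range(n_layers)]
        self.drops = [nn.Dropout(dropout, drop_rng) for _ in range(n_layers)]
        self.activation = activation
        self.out = nn.Linear(dims[-1], 2, rng)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        for lin, bn, drop in zip(self.layers, self.bns, self.drops):
            x = lin.forward(x)
            x = x.relu() if self.activation == "relu" else x.tanh()
            x = bn.forward(x, training)
            x = drop.forward(x, training)
        return self.out.forward(x)


class MLPModel(_NeuralBase):
    """Fully connected stack (BN + dropout per layer) on the feature matrix."""

    def __init__(
        self,
        hidden=128,
        n_layers=2,
        dropout=0.2,
        activation="relu",
        lr=1e-3,
        batch_size=32,
        max_epochs=200,
        early_stop_patience=10,
        seed=0,
    ):
        self.hidden = hidden
        self.n_layers = n_layers
        self.dropout = dropout
        self.activation = activation
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.seed = seed

    def _prepare(self, X):
        return list(_as_feature_matrix(X, "MLPModel"))

    def _build(self, rng, prepared):
        return _MLPNet(
            len(prepared[0]), self.hidden, self.n_layers, self.dropout,
            self.activation, rng, self._dropout_rng,
        )

    def _forward(self, net, batch, training):
        return net.forward(Tensor(np.vstack(batch)), training)


# ---------------------------------------------------------------------------
# pooled language-model embedding head ("prolatherm" family)
# ---------------------------------------------------------------------------

class _HeadNet(nn.Module):
    def __init__(self, d, dropout, first_fc, rng, drop_rng):
        self.head = nn.HeadClassifier(d, dropout, rng, first_fc=first_fc)
        self.head.drop.rng = drop_rng

    def forward(self, x: Tensor, training: bool) -> Tensor:
        return self.head.forward(x, training)


class PooledEmbeddingClassifier(_NeuralBase):
    """Language-model-embedding thermophilicity head.

    A frozen per-residue embedding provider yields an l x d matrix per
    protein; dropout (training only) is applied to the residue rows before
    average pooling over the length, and the pooled d-vector feeds the shared
    head (FC d→d/2 + ReLU + BN, dropout, FC output). Only the head trains —
    no gradient flows into the provider. Inputs may alternatively be
    precomputed pooled d-vectors (2-D numeric matrix).
    """

    def __init__(
        self,
        embedder=None,
        dropout=0.2,
        lr=1e-3,
        batch_size=32,
        max_epochs=200,
        early_stop_patience=10,
        seed=0,
    ):
        self.embedder = embedder
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.seed = seed

    def _prepare(self, X):
        if isinstance(X, np.ndarray) and X.ndim == 2 and np.issubdtype(X.dtype, np.number):
            return [row[None, :] for row in X.astype(float)]  # already pooled
        seqs = _as_sequences(X, "PooledEmbeddingClassifier")
        if self.embedder is None:
            raise ValueError(
                "PooledEmbeddingClassifier needs an embedding provider to process "
                "raw sequences; pass embedder= or precomputed pooled vectors"
            )
        out = []
        for s in seqs:
            phi = self.embedder.embed(s)
            out.append(phi.values if isinstance(phi, EmbeddingMatrix) else np.asarray(phi))
        return out

    def _build(self, rng, prepared):
        d = prepared[0].shape[1]
        return _HeadNet(d, self.dropout, True, rng, self._dropout_rng)

    def _pool(self, batch: list, training: bool) -> np.ndarray:
        pooled = np.empty((len(batch), batch[0].shape[1]))
        for i, phi in enumerate(batch):
            if training and self.dropout > 0:
                keep = (self._dropout_rng.random_sample(phi.shape) >= self.dropout) / (
                    1 - self.dropout
                )
                phi = phi * keep
            pooled[i] = mean_pool(phi)
        return pooled

    def _forward(self, net, batch, training):
        return net.forward(Tensor(self._pool(batch, training)), training)


# ---------------------------------------------------------------------------
# sequence batching helpers
# ---------------------------------------------------------------------------

def _pad_ordinals(codes: list[np.ndarray], multiple: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad ordinal code arrays with 0 (the reserved padding index)."""
    lengths = np.array([len(c) for c in codes])
    T = int(lengths.max())
    if multiple > 1:
        T = int(np.ceil(T / multiple) * multiple)
    out = np.zeros((len(codes), T), dtype=np.int64)
    for i, c in enumerate(codes):
        out[i, : len(c)] = c
    return out, lengths


def _masked_mean_pool(x: Tensor, lengths: np.ndarray) -> Tensor:
    B, T, _ = x.shape
    mask = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
    summed = (x * Tensor(mask[:, :, None])).sum(axis=1)
    return summed * Tensor(1.0 / lengths[:, None])


def _reverse_indices(lengths: np.ndarray, T: int) -> np.ndarray:
    """Per-row time indices that reverse each sequence within its length."""
    idx = np.tile(np.arange(T), (len(lengths), 1))
    for i, L in enumerate(lengths):
        idx[i, :L] = L - 1 - np.arange(L)
    return idx


class _BiLSTMStack(nn.Module):
    """Stacked (optionally bidirectional) LSTM over padded batches.

    Padding safety: the forward direction is causal so states at the last
    valid position ignore padding; the backward direction runs on per-row
    reversed sequences so its "last" state likewise sits at a valid position.
    """

    def __init__(self, n_in, hidden, n_layers, bidirectional, dropout, rng, drop_rng):
        self.bidirectional = bidirectional
        self.hidden = hidden
        dims = [n_in] + [hidden * (2 if bidirectional else 1)] * n_layers
        self.fwd = [nn.LSTM(dims[i], hidden, rng) for i in range(n_layers)]
        self.bwd = [nn.LSTM(dims[i], hidden, rng) for i in range(n_layers)] if bidirectional else []
        self.drops = [nn.Dropout(dropout, drop_rng) for _ in range(n_layers)]

    def last_state(self, x: Tensor, lengths: np.ndarray, training: bool) -> Tensor:
        B, T, _ = x.shape
        rows = np.arange(B)
        rev = _reverse_indices(lengths, T)
        for layer_idx in range(len(self.fwd)):
            hs_f = self.fwd[layer_idx].forward(x)
            if self.bidirectional:
                x_rev = x[rows[:, None], rev]
                hs_b_rev = self.bwd[layer_idx].forward(x_rev)
                hs_b = hs_b_rev[rows[:, None], rev]  # align back to input order
                x = nn.concat([hs_f, hs_b], axis=-1)
            else:
                x = hs_f
            x = self.drops[layer_idx].forward(x, training)
            last_f = hs_f[rows, lengths - 1]
            if self.bidirectional:
                last_b = hs_b_rev[rows, lengths - 1]
                last = nn.concat([last_f, last_b], axis=-1)
            else:
                last = last_f
        return last


# ---------------------------------------------------------------------------
# purely sequence-based families
# ---------------------------------------------------------------------------

class _MLPEmbeddingNet(nn.Module):
    def __init__(self, embed_dim, dropout, use_first_fc, rng, drop_rng):
        self.embedding = nn.Embedding(21, embed_dim, rng)  # index 0 = padding
        self.head = nn.HeadClassifier(embed_dim, dropout, rng, first_fc=use_first_fc)
        self.head.drop.rng = drop_rng

    def forward(self, codes, lengths, training):
        pooled = _masked_mean_pool(self.embedding.forward(codes), lengths)
        return self.head.forward(pooled, training)


class MLPEmbeddingModel(_NeuralBase):
    """Lookup embedding → mean pool over length → shared head.

    The first FC layer of the head is optional (a tuned choice); pooling
    happens before it.
    """

    def __init__(
        self,
        embed_dim=64,
        use_first_fc=True,
        dropout=0.2,
        lr=1e-3,
        batch_size=32,
        max_epochs=200,
        early_stop_patience=10,
        seed=0,
    ):
        self.embed_dim = embed_dim
        self.use_first_fc = use_first_fc
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.seed = seed

    def _prepare(self, X):
        return [ordinal_encode(s) for s in _as_sequences(X, "MLPEmbeddingModel")]

    def _build(self, rng, prepared):
        return _MLPEmbeddingNet(
            self.embed_dim, self.dropout, self.use_first_fc, rng, self._dropout_rng
        )

    def _forward(self, net, batch, training):
        codes, lengths = _pad_ordinals(batch)
        return net.forward(codes, lengths, training)


class _LSTMNet(nn.Module):
    def __init__(self, n_in, embed_dim, hidden, n_layers, bidirectional, dropout,
                 rng, drop_rng, embed_tokens=True):
        self.embed_tokens = embed_tokens
        if embed_tokens:
            self.embedding = nn.Embedding(21, embed_dim, rng)
            n_in = embed_dim
        self.stack = _BiLSTMStack(n_in, hidden, n_layers, bidirectional, dropout, rng, drop_rng)
        self.head = nn.HeadClassifier(hidden * (2 if bidirectional else 1), dropout, rng)
        self.head.drop.rng = drop_rng

    def forward(self, x, lengths, training):
        if self.embed_tokens:
            x = self.embedding.forward(x)
        last = self.stack.last_state(x, lengths, training)
        return self.head.forward(last, training)


class LSTMModel(_NeuralBase):
    """Lookup embedding → (bi)LSTM stack → last hidden state → shared head."""

    def __init__(
        self,
        embed_dim=32,
        hidden=48,
        n_layers=1,
        bidirectional=False,
        dropout=0.2,
        lr=1e-3,
        batch_size=32,
        max_epochs=200,
        early_stop_patience=10,
        seed=0,
    ):
        self.embed_dim = embed_dim
        self.hidden = hidden
        self.n_layers = n_layers
        self.bidirectional = bidirectional
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.seed = seed

    def _prepare(self, X):
        return [ordinal_encode(s) for s in _as_sequences(X, "LSTMModel")]

    def _build(self, rng, prepared):
        return _LSTMNet(
            None, self.embed_dim, self.hidden, self.n_layers, self.bidirectional,
            self.dropout, rng, self._dropout_rng, embed_tokens=True,
        )

    def _forward(self, net, batch, training):
        codes, lengths = _pad_ordinals(batch)
        return net.forward(codes, lengths, training)


class _BasicDescNet(nn.Module):
    """FC dimensionality-expansion layers over the 6-property residue
    encoding, then a (bi)LSTM stack and the shared head."""

    def __init__(self, expansion_dims, hidden, n_layers, bidirectional, dropout, rng, drop_rng):
        dims = [6] + list(expansion_dims)
        self.expand = [nn.Linear(a, b, rng) for a, b in zip(dims, dims[1:])]
        self.expand_drop = nn.Dropout(dropout, drop_rng)
        self.stack = _BiLSTMStack(dims[-1], hidden, n_layers, bidirectional, dropout, rng, drop_rng)
        self.head = nn.HeadClassifier(hidden * (2 if bidirectional else 1), dropout, rng)
        self.head.drop.rng = drop_rng

    def forward(self, x: Tensor, lengths, training):
        B, T, _ = x.shape
        flat = x.reshape(B * T, x.shape[2])
        for lin in self.expand:
            flat = self.expand_drop.forward(lin.forward(flat).relu(), training)
        x = flat.reshape(B, T, flat.shape[-1])
        last = self.stack.last_state(x, lengths, training)
        return self.head.forward(last, training)


class BasicDescLSTMModel(_NeuralBase):
    """Hybrid family: physicochemical residue encoding feeds the recurrence."""

    def __init__(
        self,
        expansion_dims=(16, 32),
        hidden=48,
        n_layers=1,
        bidirectional=False,
        dropout=0.2,
        lr=1e-3,
        batch_size=32,
        max_epochs=200,
        early_stop_patience=10,
        seed=0,
    ):
        self.expansion_dims = expansion_dims
        self.hidden = hidden
        self.n_layers = n_layers
        self.bidirectional = bidirectional
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.seed = seed

    def _prepare(self, X):
        return [residue_encoding(s) for s in _as_sequences(X, "BasicDescLSTMModel")]

    def _build(self, rng, prepared):
        return _BasicDescNet(
            self.expansion_dims, self.hidden, self.n_layers, self.bidirectional,
            self.dropout, rng, self._dropout_rng,
        )

    def _forward(self, net, batch, training):
        lengths = np.array([m.shape[0] for m in batch])
        T = int(lengths.max())
        x = np.zeros((len(batch), T, 6))
        for i, m in enumerate(batch):
            x[i, : m.shape[0]] = m
        return net.forward(Tensor(x), lengths, training)


class _TransformerNet(nn.Module):
    def __init__(self, embed_dim, n_layers, n_heads, ff_dim, pool_stride, dropout,
                 sparse, window, n_global, max_len, rng, drop_rng):
        self.embedding = nn.Embedding(21, embed_dim, rng)
        self.positional = nn.Embedding(max_len, embed_dim, rng)
        self.blocks = [
            nn.TransformerBlock(embed_dim, n_heads, ff_dim, dropout, rng) for _ in range(n_layers)
        ]
        for blk in self.blocks:
            blk.drop.rng = drop_rng
        self.head = nn.HeadClassifier(embed_dim, dropout, rng)
        self.head.drop.rng = drop_rng
        self.pool_stride = pool_stride
        self.sparse = sparse
        self.window = window
        self.n_global = n_global

    def _attention_mask(self, lengths: np.ndarray, T: int) -> np.ndarray:
        valid = np.arange(T)[None, :] < lengths[:, None]  # (B, T)
        mask = np.where(valid[:, None, None, :], 0.0, -1e9)  # keys only
        if self.sparse:
            i = np.arange(T)[:, None]
            j = np.arange(T)[None, :]
            allowed = (np.abs(i - j) <= self.window) | (i < self.n_global) | (j < self.n_global)
            mask = mask + np.where(allowed[None, None, :, :], 0.0, -1e9)
        return mask

    def forward(self, codes: np.ndarray, lengths: np.ndarray, training: bool) -> Tensor:
        B, T = codes.shape
        x = self.embedding.forward(codes) + self.positional.forward(
            np.tile(np.arange(T), (B, 1))
        )
        if self.pool_stride > 1:
            s = self.pool_stride
            valid = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
            x = x * Tensor(valid[:, :, None])
            Tp = T // s
            counts = valid.reshape(B, Tp, s).sum(axis=2)
            x = x.reshape(B, Tp, s, x.shape[-1]).sum(axis=2) * Tensor(
                1.0 / np.maximum(counts, 1.0)[:, :, None]
            )
            lengths = np.maximum((counts > 0).sum(axis=1), 1).astype(int)
            T = Tp
        mask = self._attention_mask(lengths, T)
        for blk in self.blocks:
            x = blk.forward(x, mask, training)
        pooled = _masked_mean_pool(x, lengths)
        return self.head.forward(pooled, training)


class TransformerModel(_NeuralBase):
    """Pre-layer-norm transformer classifier over learned token embeddings.

    With ``sparse=False`` a stride-``pool_stride`` average pooling shortens
    the sequence before the attention blocks (the full-attention variant);
    with ``sparse=True`` no pre-pooling is applied and attention is
    restricted to a sliding window plus ``n_global`` global tokens.
    """

    def __init__(
        self,
        embed_dim=32,
        n_layers=1,
        n_heads=4,
        ff_dim=64,
        pool_stride=4,
        dropout=0.1,
        sparse=False,
        window=16,
        n_global=4,
        max_len=1024,
        lr=1e-3,
        batch_size=32,
        max_epochs=200,
        early_stop_patience=10,
        seed=0,
    ):
        self.embed_dim = embed_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ff_dim = ff_dim
        self.pool_stride = pool_stride
        self.dropout = dropout
        self.sparse = sparse
        self.window = window
        self.n_global = n_global
        self.max_len = max_len
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.seed = seed

    def _prepare(self, X):
        return [ordinal_encode(s) for s in _as_sequences(X, "TransformerModel")]

    def _build(self, rng, prepared):
        stride = 1 if self.sparse else self.pool_stride
        return _TransformerNet(
            self.embed_dim, self.n_layers, self.n_heads, self.ff_dim, stride,
            self.dropout, self.sparse, self.window, self.n_global, self.max_len,
            rng, self._dropout_rng,
        )

    def _forward(self, net, batch, training):
        stride = 1 if self.sparse else self.pool_stride
        codes, lengths = _pad_ordinals(batch, multiple=max(stride, 1))
        return net.forward(codes, lengths, training)


# ---------------------------------------------------------------------------
# family registry, search spaces, validation
# ---------------------------------------------------------------------------

_NEURAL_COMMON = {
    "lr": ("log", 1e-4, 1e-2),
    "dropout": ("uniform", 0.0, 0.5),
    "batch_size": ("cat", [16, 32, 64]),
}

SEARCH_SPACES: dict[str, dict] = {
    "elastic_net": {"C": ("log", 1e-3, 1e2), "l1_ratio": ("uniform", 0.0, 1.0)},
    "svm": {
        "kernel": ("cat", ["linear", "rbf", "poly"]),
        "C": ("log", 1e-2, 1e2),
        "gamma": ("log", 1e-4, 1.0),
        "degree": ("int", 2, 4),
    },
    "random_forest": {
        "n_estimators": ("int", 100, 800),
        "max_depth": ("int", 3, 25),
        "max_features": ("cat", ["sqrt", "log2", 0.3]),
    },
    "xgboost": {
        "n_estimators": ("int", 100, 800),
        "max_depth": ("int", 2, 10),
        "learning_rate": ("log", 1e-3, 0.3),
        "subsample": ("uniform", 0.5, 1.0),
        "colsample_bytree": ("uniform", 0.5, 1.0),
        "reg_lambda": ("log", 1e-3, 10.0),
    },
    "mlp": {
        **_NEURAL_COMMON,
        "hidden": ("cat", [64, 128, 256]),
        "n_layers": ("int", 1, 3),
        "activation": ("cat", ["relu", "tanh"]),
    },
    "mlp_embedding": {
        **_NEURAL_COMMON,
        "embed_dim": ("cat", [32, 64, 128]),
        "use_first_fc": ("cat", [True, False]),
    },
    "lstm": {**_NEURAL_COMMON, "embed_dim": ("cat", [16, 32, 64]),
             "hidden": ("cat", [32, 48, 64]), "n_layers": ("int", 1, 2)},
    "bilstm": {**_NEURAL_COMMON, "embed_dim": ("cat", [16, 32, 64]),
               "hidden": ("cat", [32, 48, 64]), "n_layers": ("int", 1, 2)},
    "lstm_basicdesc": {**_NEURAL_COMMON, "expansion_dims": ("cat", [(16,), (16, 32), (32, 64)]),
                       "hidden": ("cat", [32, 48, 64]), "n_layers": ("int", 1, 2)},
    "bilstm_basicdesc": {**_NEURAL_COMMON, "expansion_dims": ("cat", [(16,), (16, 32), (32, 64)]),
                         "hidden": ("cat", [32, 48, 64]), "n_layers": ("int", 1, 2)},
    "transformer": {**_NEURAL_COMMON, "embed_dim": ("cat", [32, 64]),
                    "n_layers": ("int", 1, 3), "n_heads": ("cat", [2, 4]),
                    "ff_dim": ("cat", [64, 128]), "pool_stride": ("cat", [1, 2, 4, 8])},
    "sparse_transformer": {**_NEURAL_COMMON, "embed_dim": ("cat", [32, 64]),
                           "n_layers": ("int", 1, 3), "n_heads": ("cat", [2, 4]),
                           "ff_dim": ("cat", [64, 128]), "window": ("cat", [8, 16, 32]),
                           "n_global": ("cat", [1, 4, 8])},
    "prolatherm": {**_NEURAL_COMMON},
}

_FAMILY_CLASSES = {
    "elastic_net": (ElasticNetModel, {}),
    "svm": (SVMModel, {}),
    "random_forest": (RandomForestModel, {}),
    "xgboost": (XGBoostModel, {}),
    "mlp": (MLPModel, {}),
    "mlp_embedding": (MLPEmbeddingModel, {}),
    "lstm": (LSTMModel, {"bidirectional": False}),
    "bilstm": (LSTMModel, {"bidirectional": True}),
    "lstm_basicdesc": (BasicDescLSTMModel, {"bidirectional": False}),
    "bilstm_basicdesc": (BasicDescLSTMModel, {"bidirectional": True}),
    "transformer": (TransformerModel, {"sparse": False}),
    "sparse_transformer": (TransformerModel, {"sparse": True}),
    "prolatherm": (PooledEmbeddingClassifier, {}),
}

FAMILIES = tuple(_FAMILY_CLASSES)

# constructor keys that are training plumbing, not searched hyperparameters
_EXTRA_KEYS = {
    "seed", "max_epochs", "early_stop_patience", "max_iter", "coef0", "embedder",
    "max_len", "batch_size", "val_fraction",
}


def validate_hyperparams(family: str, params: dict) -> None:
    """Check a parameter map against the family's declared search space."""
    if family not in SEARCH_SPACES:
        raise ValueError(f"unknown model family {family!r}; known: {sorted(SEARCH_SPACES)}")
    space = SEARCH_SPACES[family]
    for name, value in params.items():
        if name in _EXTRA_KEYS:
            continue
        if name not in space:
            raise ValueError(f"hyperparameter {name!r} not in {family}'s search space")
        kind, *args = space[name]
        if kind == "cat":
            if value not in args[0]:
                raise ValueError(f"{family}.{name}={value!r} not among {args[0]}")
        elif kind == "int":
            lo, hi = args
            if not (isinstance(value, (int, np.integer)) and lo <= value <= hi):
                raise ValueError(f"{family}.{name}={value!r} outside integer range [{lo}, {hi}]")
        else:  # log / uniform
            lo, hi = args
            if not (lo <= float(value) <= hi):
                raise ValueError(f"{family}.{name}={value!r} outside range [{lo}, {hi}]")


def build_model(family: str, **hyperparams):
    """Construct an untrained estimator of the given family."""
    if family not in _FAMILY_CLASSES:
        raise ValueError(f"unknown model family {family!r}; known: {sorted(_FAMILY_CLASSES)}")
    validate_hyperparams(family, hyperparams)
    cls, fixed = _FAMILY_CLASSES[family]
    return cls(**{**fixed, **hyperparams})


def train(model, X_train, y_train, X_val=None, y_val=None):
    """Fit an estimator, passing an explicit validation set when supported."""
    if isinstance(model, _NeuralBase):
        return model.fit(X_train, y_train, X_val=X_val, y_val=y_val)
    return model.fit(X_train, y_train)


def predict_proba(model, X) -> np.ndarray:
    """Positive-class (thermophilic) probability per record."""
    return model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# checkpoints: directory {spec.json, params.bin, training_log.tsv}
# ---------------------------------------------------------------------------

def save_model(model, family: str, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = {k: v for k, v in model.get_params().items() if k != "embedder"}
    spec = {"family": family, "hyperparams": json.loads(json.dumps(params, default=str))}
    (out_dir / "spec.json").write_text(json.dumps(spec, indent=2))
    joblib.dump(model, out_dir / "params.bin")
    log = getattr(model, "training_log_", None)
    if log is not None:
        log.to_csv(out_dir / "training_log.tsv", sep="\t", index=False)
    return out_dir


def load_model(model_dir: str | Path):
    model_dir = Path(model_dir)
    spec = json.loads((model_dir / "spec.json").read_text())
    model = joblib.load(model_dir / "params.bin")
    return model, spec
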