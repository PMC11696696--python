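"""Duplex off-target classifiers: contextual (transformer-encoder embedding
+ BiLSTM) and static (word embedding + BiLSTM).

Both variants read the stack-encoded token sequence of an sgRNA-DNA duplex
and emit the probability that the duplex is a cleaved off-target site.  The
contextual variant passes token + learned positional embeddings through a
stack of self-attention encoder blocks before the recurrent layer, so a
doublet's representation depends on its neighbours and its position; the
static variant feeds the fixed per-token embeddings straight to the BiLSTM.
The BiLSTM's concatenated final hidden states (h_T forward ; h_T backward)
feed two ReLU dense layers and a single sigmoid output.

The public surface is a scikit-learn estimator, `CrisprDuplexClassifier`,
plus thin functional wrappers (`build_model`, `train`, `predict`).
Training is end-to-end supervised from scratch — no masked-token
pretraining — minimising binary cross-entropy with Adam and keeping the
weights of the epoch with the best validation PR-AUC.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from .encoding import DUPLEX_LENGTH

VARIANTS = ("contextual", "static")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``embed_dim`` (d), ``n_layers`` (L) and ``n_heads`` (H) follow the
    published defaults d=64, L=6, H=8; d must be divisible by H for the
    contextual variant.  The sequence length is fixed at 23 - k + 1 by the
    encoding order.  ``pos_weight`` optionally up-weights the positive
    class in the loss (1.0 = no reweighting).
    """

    variant: str = "contextual"
    k: int = 2
    embed_dim: int = 64
    n_layers: int = 6
    n_heads: int = 8
    lstm_units: int = 32
    dense_units: tuple[int, int] = (128, 64)
    dropout: float = 0.1
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 10
    pos_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.k not in (1, 2, 3):
            raise ValueError(f"encoding order k must be 1, 2 or 3, got {self.k}")
        if self.variant == "contextual" and self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} must be divisible by n_heads {self.n_heads}"
            )
        if len(tuple(self.dense_units)) != 2:
            raise ValueError("dense_units must list exactly two layer widths")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0,1), got {self.dropout}")

    @property
    def seq_len(self) -> int:
        return DUPLEX_LENGTH - self.k + 1

    @property
    def vocab_size(self) -> int:
        return 4 ** (2 * self.k)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dense_units"] = list(self.dense_units)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["dense_units"] = tuple(d["dense_units"])
        return cls(**d)


class _DuplexNet(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.token_emb = nn.Embedding(cfg.vocab_size, cfg.embed_dim, rng)
        self.blocks: list[nn.EncoderBlock] = []
        if cfg.variant == "contextual":
            self.pos_emb = nn.Tensor(
                rng.normal(0.0, 0.02, size=(cfg.seq_len, cfg.embed_dim)),
                requires_grad=True,
            )
            self.blocks = [
                nn.EncoderBlock(cfg.embed_dim, cfg.n_heads, rng) for _ in range(cfg.n_layers)
            ]
        self.lstm = nn.BiLSTM(cfg.embed_dim, cfg.lstm_units, rng)
        d1, d2 = cfg.dense_units
        self.dense1 = nn.Linear(2 * cfg.lstm_units, d1, rng)
        self.dense2 = nn.Linear(d1, d2, rng)
        self.out = nn.Linear(d2, 1, rng)
        self.drop = nn.Dropout(cfg.dropout)

    def embed(self, X: np.ndarray) -> nn.Tensor:
        """Per-token representations, shape (batch, seq_len, embed_dim)."""
        h = self.token_emb(X)
        if self.cfg.variant == "contextual":
            h = h + self.pos_emb
            for block in self.blocks:
                h = block(h)
        return h

    def logits(self, X: np.ndarray, rng: np.random.Generator | None = None,
               training: bool = False) -> nn.Tensor:
        h = self.embed(X)
        if training:
            h = self.drop(h, rng, training)
        h = self.lstm(h)
        h = self.dense1(h).relu()
        if training:
            h = self.drop(h, rng, training)
        h = self.dense2(h).relu()
        return self.out(h)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class CrisprDuplexClassifier(BaseEstimator, ClassifierMixin):
    """Off-target activity classifier over stack-encoded duplex tokens.

    Parameters mirror :class:`ModelConfig`.  ``fit`` accepts the integer
    token matrix X of shape (n_pairs, 23 - k + 1) and binary y; a held-out
    validation set (for checkpoint selection) is either passed explicitly
    via ``validation_data`` or carved out of the training data
    (``validation_fraction``, stratified).

    Examples
    --------
    >>> clf = CrisprDuplexClassifier(n_layers=2, n_heads=2, embed_dim=16)
    >>> clf.fit(X_train, y_train)          # doctest: +SKIP
    >>> proba = clf.predict_proba(X_val)   # doctest: +SKIP
    """

    def __init__(
        self,
        variant: str = "contextual",
        k: int = 2,
        embed_dim: int = 64,
        n_layers: int = 6,
        n_heads: int = 8,
        lstm_units: int = 32,
        dense_units: tuple[int, int] = (128, 64),
        dropout: float = 0.1,
        learning_rate: float = 1e-4,
        batch_size: int = 64,
        epochs: int = 10,
        pos_weight: float = 1.0,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.variant = variant
        self.k = k
        self.embed_dim = embed_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.lstm_units = lstm_units
        self.dense_units = dense_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.pos_weight = pos_weight
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _config(self) -> ModelConfig:
        return ModelConfig(
            variant=self.variant,
            k=self.k,
            embed_dim=self.embed_dim,
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            lstm_units=self.lstm_units,
            dense_units=tuple(self.dense_units),
            dropout=self.dropout,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            pos_weight=self.pos_weight,
            seed=self.random_state,
        )

    def _validate_X(self, X: np.ndarray, cfg: ModelConfig) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or (X.shape[0] > 0 and X.shape[1] != cfg.seq_len):
            raise ValueError(
                f"X must have shape (n, {cfg.seq_len}) for k={cfg.k}, got {X.shape}"
            )
        if not np.issubdtype(X.dtype, np.integer):
            Xi = X.astype(np.int64)
            if not np.array_equal(Xi, X):
                raise ValueError("X must contain integer token indices")
            X = Xi
        if X.size and (X.min() < 0 or X.max() >= cfg.vocab_size):
            raise ValueError(f"token indices must lie in [0, {cfg.vocab_size})")
        return X

    def fit(self, X, y, validation_data: tuple | None = None):
        cfg = self._config()
        X = self._validate_X(X, cfg)
        y = np.asarray(y).astype(np.int64).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training set must contain both classes")

        if validation_data is not None:
            X_tr, y_tr = X, y
            X_val = self._validate_X(np.asarray(validation_data[0]), cfg)
            y_val = np.asarray(validation_data[1]).astype(np.int64).ravel()
        else:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X,
                y,
                test_size=self.validation_fraction,
                stratify=y,
                random_state=cfg.seed,
            )

        rng = np.random.default_rng(cfg.seed)
        net = _DuplexNet(cfg, rng)
        opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)

        sample_w = np.where(y_tr == 1, cfg.pos_weight, 1.0)
        log_rows = []
        best_pr = -np.inf
        best_weights = [p.data.copy() for p in net.parameters()]
        best_epoch = 0
        n = X_tr.shape[0]

        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = net.logits(X_tr[idx], rng=rng, training=True)
                loss = _weighted_bce(logits, y_tr[idx], sample_w[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce the learning rate or check the input encoding"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            val_scores = _predict_net(net, X_val)
            val_roc = roc_auc_score(y_val, val_scores) if np.unique(y_val).size > 1 else np.nan
            val_pr = average_precision_score(y_val, val_scores) if y_val.sum() else np.nan
            log_rows.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(losses)),
                    "val_roc_auc": float(val_roc),
                    "val_pr_auc": float(val_pr),
                }
            )
            if np.isfinite(val_pr) and val_pr > best_pr:
                best_pr = val_pr
                best_weights = [p.data.copy() for p in net.parameters()]
                best_epoch = epoch

        net.load_arrays(best_weights)
        self.network_ = net
        self.config_ = cfg
        self.training_log_ = pd.DataFrame(log_rows)
        self.best_epoch_ = best_epoch
        self.n_parameters_ = net.n_parameters()
        self.n_features_in_ = cfg.seq_len
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._validate_X(X, self.config_)
        p1 = _predict_net(self.network_, X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def embed(self, X) -> np.ndarray:
        """Per-token contextual representations, shape (n, seq_len, d)."""
        check_is_fitted(self, "network_")
        X = self._validate_X(X, self.config_)
        return self.network_.embed(X).data

    # -- checkpointing -------------------------------------------------

    def save(self, directory) -> None:
        """Write a checkpoint directory: ``config.json`` + ``weights.npz``."""
        check_is_fitted(self, "network_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(self.config_.to_dict(), indent=2))
        arrays = {f"w{i}": a for i, a in enumerate(self.network_.state_arrays())}
        np.savez(directory / "weights.npz", **arrays)
        self.training_log_.to_csv(directory / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "CrisprDuplexClassifier":
        directory = Path(directory)
        cfg = ModelConfig.from_dict(json.loads((directory / "config.json").read_text()))
        est = cls(
            variant=cfg.variant,
            k=cfg.k,
            embed_dim=cfg.embed_dim,
            n_layers=cfg.n_layers,
            n_heads=cfg.n_heads,
            lstm_units=cfg.lstm_units,
            dense_units=cfg.dense_units,
            dropout=cfg.dropout,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            pos_weight=cfg.pos_weight,
            random_state=cfg.seed,
        )
        net = _DuplexNet(cfg, np.random.default_rng(cfg.seed))
        with np.load(directory / "weights.npz") as data:
            net.load_arrays([data[f"w{i}"] for i in range(len(data.files))])
        est.network_ = net
        est.config_ = cfg
        log_path = directory / "training_log.csv"
        est.training_log_ = pd.read_csv(log_path) if log_path.exists() else pd.DataFrame()
        est.classes_ = np.array([0, 1])
        est.n_parameters_ = net.n_parameters()
        est.n_features_in_ = cfg.seq_len
        return est


def _weighted_bce(logits: nn.Tensor, y: np.ndarray, w: np.ndarray) -> nn.Tensor:
    if np.all(w == 1.0):
        return nn.bce_with_logits(logits, y)
    z = logits.data
    yv = np.asarray(y, dtype=np.float64).reshape(z.shape)
    wv = np.asarray(w, dtype=np.float64).reshape(z.shape)
    loss = wv * (np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - yv * z)
    out_data = np.array(loss.sum() / wv.sum())
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def backward(g):
        if logits.requires_grad:
            logits._accum(g * wv * (sig - yv) / wv.sum())

    return logits._child(out_data, (logits,), backward)


def _predict_net(net: _DuplexNet, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    if X.shape[0] == 0:
        return np.empty(0)
    out = []
    for start in range(0, X.shape[0], batch_size):
        logits = net.logits(X[start : start + batch_size], training=False)
        out.append(1.0 / (1.0 + np.exp(-logits.data.ravel())))
    return np.concatenate(out)


# -- thin functional wrappers ------------------------------------------


def build_model(cfg: ModelConfig) -> CrisprDuplexClassifier:
    """Instantiate an (unfitted) classifier from a :class:`ModelConfig`."""
    return CrisprDuplexClassifier(
        variant=cfg.variant,
        k=cfg.k,
        embed_dim=cfg.embed_dim,
        n_layers=cfg.n_layers,
        n_heads=cfg.n_heads,
        lstm_units=cfg.lstm_units,
        dense_units=cfg.dense_units,
        dropout=cfg.dropout,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        pos_weight=cfg.pos_weight,
        random_state=cfg.seed,
    )


def train(
    model: CrisprDuplexClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> CrisprDuplexClassifier:
    """Fit ``model``; when a validation set is given it drives checkpoint
    selection (best validation PR-AUC), otherwise one is carved out."""
    val = (X_val, y_val) if X_val is not None else None
    return model.fit(X_train, y_train, validation_data=val)


def predict(model: CrisprDuplexClassifier, X: np.ndarray) -> np.ndarray:
    """Positive-class probabilities, order preserved."""
    return model.predict_proba(X)[:, 1]
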