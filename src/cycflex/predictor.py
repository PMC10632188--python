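"""Sequence→cyclizability scoring.

Two predictor realizations behind one contract: a trainable convolutional/
recurrent regressor and a linear dinucleotide surrogate.  All downstream
analyses consume predictors through :func:`rc_averaged_predict`, which reports
the mean of the forward and reverse-complement scores and is therefore exactly
reverse-complement symmetric.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from cycflex._network import Adam, SequenceRegressor
from cycflex.sequence_io import (
    PROBE_LEN,
    LoopSeqRecord,
    encode,
    one_hot,
    revcomp,
    strip_adapters,
)

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


@runtime_checkable
class CyclizabilityPredictor(Protocol):
    """Deterministic map from a 50-base window to a real score."""

    kind: str

    def score_raw(self, seq: str) -> float: ...

    def score_raw_batch(self, seqs: Sequence[str]) -> np.ndarray: ...


@dataclass
class LinearDinucModel:
    """Additive dinucleotide-step model: b + Σ_i w[seq_i seq_{i+1}].

    Serves both as a testing surrogate predictor and as the ground truth of
    the synthetic data generators.
    """

    w: np.ndarray  # 16 weights indexed 4*code(first) + code(second)
    b: float = 0.0
    kind: str = field(default="linear", init=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.shape != (16,):
            raise ValueError("w must have 16 entries (AA..TT)")
        if not (np.isfinite(self.w).all() and np.isfinite(self.b)):
            raise ValueError("model parameters must be finite")

    @classmethod
    def from_dict(cls, weights: dict[str, float], b: float = 0.0
                  ) -> "LinearDinucModel":
        w = np.zeros(16)
        for dn, val in weights.items():
            w[DINUCLEOTIDES.index(dn)] = val
        return cls(w=w, b=b)

    @classmethod
    def random_symmetric(cls, rng: np.random.Generator, scale: float = 0.05,
                         b: float = 0.0) -> "LinearDinucModel":
        """Random weights with w[d] = w[revcomp(d)] so rc-averaging is exact."""
        w = np.zeros(16)
        for i, dn in enumerate(DINUCLEOTIDES):
            j = DINUCLEOTIDES.index(revcomp(dn))
            if i <= j:
                val = rng.normal(0.0, scale)
                w[i] = val
                w[j] = val
        return cls(w=w, b=b)

    def score_raw(self, seq: str) -> float:
        if len(seq) < 2:
            raise ValueError("need sequence length >= 2")
        codes = encode(seq)
        steps = 4 * codes[:-1] + codes[1:]
        return float(self.b + self.w[steps].sum())

    def score_raw_batch(self, seqs: Sequence[str]) -> np.ndarray:
        if not len(seqs):
            return np.empty(0)
        lengths = {len(s) for s in seqs}
        if len(lengths) == 1:
            # equal-length fast path: one vectorized pass
            joined = "".join(seqs)
            codes = encode(joined).reshape(len(seqs), lengths.pop())
            return self.score_encoded_batch(codes)
        return np.array([self.score_raw(s) for s in seqs])

    def score_encoded_batch(self, codes: np.ndarray) -> np.ndarray:
        """Score an (N, L) integer-encoded batch (vectorized fast path)."""
        steps = 4 * codes[:, :-1] + codes[:, 1:]
        return self.b + self.w[steps].sum(axis=1)

    def to_dict(self) -> dict:
        return {"kind": "linear",
                "w": dict(zip(DINUCLEOTIDES, self.w.tolist())),
                "b": self.b}


@dataclass(frozen=True)
class NeuralNetConfig:
    """Hyperparameters of the convolutional/recurrent regressor."""

    conv_blocks: tuple = ((64, 8, 2), (32, 4, 2))  # (filters, kernel, pool)
    lstm_units: int = 64
    dropout: float = 0.2
    dense_units: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 50
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for name in ("lstm_units", "dense_units", "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for F, K, P in self.conv_blocks:
            if min(F, K, P) < 1:
                raise ValueError("conv block sizes must be >= 1")


@dataclass(frozen=True)
class TrainReport:
    n_train: int
    n_test: int
    loss_curve: tuple  # per-epoch training MSE
    test_pearson_r: float | None  # None when undefined (constant targets)
    test_median_abs_distance: float
    seed: int


class NeuralPredictor:
    """Trained convolutional/recurrent cyclizability regressor."""

    kind = "neural"

    def __init__(self, net: SequenceRegressor, y_mean: float, y_std: float,
                 config: NeuralNetConfig | None = None):
        self.net = net
        self.y_mean = y_mean
        self.y_std = y_std
        self.config = config

    def _forward(self, X: np.ndarray) -> np.ndarray:
        preds, _ = self.net.forward(X, train=False)
        return preds * self.y_std + self.y_mean

    def score_raw(self, seq: str) -> float:
        return float(self.score_raw_batch([seq])[0])

    def score_raw_batch(self, seqs: Sequence[str]) -> np.ndarray:
        if not len(seqs):
            return np.empty(0)
        X = np.stack([one_hot(s) for s in seqs])
        out = np.empty(len(seqs))
        for i in range(0, len(seqs), 4096):
            out[i:i + 4096] = self._forward(X[i:i + 4096])
        return out

    def save(self, path: str | Path) -> None:
        state = {
            "kind": "neural",
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "config": None if self.config is None else {
                "conv_blocks": [list(cb) for cb in self.config.conv_blocks],
                "lstm_units": self.config.lstm_units,
                "dropout": self.config.dropout,
                "dense_units": self.config.dense_units,
                "learning_rate": self.config.learning_rate,
                "batch_size": self.config.batch_size,
                "max_epochs": self.config.max_epochs,
                "early_stop_patience": self.config.early_stop_patience,
                "seed": self.config.seed,
            },
            "network": self.net.state_dict(),
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path: str | Path) -> "NeuralPredictor":
        state = json.loads(Path(path).read_text())
        cfg = None
        if state.get("config"):
            c = dict(state["config"])
            c["conv_blocks"] = tuple(tuple(cb) for cb in c["conv_blocks"])
            cfg = NeuralNetConfig(**c)
        return cls(SequenceRegressor.from_state_dict(state["network"]),
                   y_mean=state["y_mean"], y_std=state["y_std"], config=cfg)


def save_predictor(p: CyclizabilityPredictor, path: str | Path) -> None:
    if isinstance(p, NeuralPredictor):
        p.save(path)
    elif isinstance(p, LinearDinucModel):
        Path(path).write_text(json.dumps(p.to_dict()))
    else:
        raise TypeError(f"cannot serialize predictor of type {type(p)!r}")


def load_predictor(path: str | Path) -> CyclizabilityPredictor:
    state = json.loads(Path(path).read_text())
    if state.get("kind") == "linear":
        return LinearDinucModel.from_dict(state["w"], b=state.get("b", 0.0))
    return NeuralPredictor.load(path)


def linear_dinuc_score(model: LinearDinucModel, seq: str) -> float:
    """Score of ``seq`` under a linear dinucleotide model."""
    return model.score_raw(seq)


def rc_averaged_predict(p: CyclizabilityPredictor, seq: str) -> float:
    """Mean of forward and reverse-complement raw scores."""
    return (p.score_raw(seq) + p.score_raw(revcomp(seq))) / 2.0


def rc_averaged_predict_batch(p: CyclizabilityPredictor,
                              seqs: Sequence[str]) -> np.ndarray:
    if not len(seqs):
        return np.empty(0)
    fwd = p.score_raw_batch(seqs)
    rev = p.score_raw_batch([revcomp(s) for s in seqs])
    return (fwd + rev) / 2.0


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_neural(library: Sequence[LoopSeqRecord],
                 cfg: NeuralNetConfig = NeuralNetConfig(),
                 split: float = 0.7
                 ) -> tuple[NeuralPredictor, TrainReport]:
    """Train the convolutional/recurrent regressor on a loop-seq library.

    The library is partitioned into train/test with a seeded uniform random
    split; the model minimizes MSE via Adam.  Targets are standardized on the
    train split internally (inverted at prediction time).  Early stopping
    monitors a 10% validation carve-out of the train split and restores the
    best weights.
    """
    if len(library) < 100:
        raise ValueError("library must contain at least 100 records")
    y = np.array([r.c0 for r in library], dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValueError("non-finite c0 in library")
    probes = [strip_adapters(r) for r in library]
    if any(len(s) != PROBE_LEN for s in probes):
        raise ValueError("all probes must have length 50")
    X = np.stack([one_hot(s) for s in probes])

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(library))
    n_train = int(round(split * len(library)))
    tr_idx, te_idx = perm[:n_train], perm[n_train:]
    n_val = max(1, int(round(0.1 * n_train)))
    val_idx, fit_idx = tr_idx[:n_val], tr_idx[n_val:]

    y_mean = float(y[tr_idx].mean())
    y_std = float(y[tr_idx].std())
    degenerate = bool(np.all(y[tr_idx] == y[tr_idx][0]))
    if degenerate:
        y_mean = float(y[tr_idx][0])
        y_std = 1.0
    ys = (y - y_mean) / y_std

    net = SequenceRegressor(PROBE_LEN, cfg.conv_blocks, cfg.lstm_units,
                            cfg.dense_units, cfg.dropout, seed=cfg.seed)
    opt = Adam(net.params, lr=cfg.learning_rate)
    drop_rng = np.random.default_rng(cfg.seed + 1)

    Xf, yf = X[fit_idx], ys[fit_idx]
    Xv, yv = X[val_idx], ys[val_idx]
    best_val = math.inf
    best_params = {k: v.copy() for k, v in net.params.items()}
    patience_left = cfg.early_stop_patience
    loss_curve = []
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(yf))
        epoch_loss = 0.0
        for i in range(0, len(yf), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            xb, yb = Xf[sel], yf[sel]
            preds, cache = net.forward(xb, train=True, drop_rng=drop_rng)
            err = preds - yb
            epoch_loss += float((err ** 2).sum())
            grads = net.backward(2.0 * err / len(yb), cache)
            opt.step(net.params, grads)
        loss_curve.append(epoch_loss / len(yf))
        val_pred, _ = net.forward(Xv, train=False)
        val_mse = float(((val_pred - yv) ** 2).mean())
        if val_mse < best_val - 1e-9:
            best_val = val_mse
            best_params = {k: v.copy() for k, v in net.params.items()}
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    net.params = best_params

    predictor = NeuralPredictor(net, y_mean=y_mean, y_std=y_std, config=cfg)
    test_lib = [LoopSeqRecord(seq=probes[i], c0=y[i]) for i in te_idx]
    r, mad = evaluate(predictor, test_lib)
    if degenerate:
        r = None
    return predictor, TrainReport(
        n_train=n_train, n_test=len(te_idx), loss_curve=tuple(loss_curve),
        test_pearson_r=r, test_median_abs_distance=mad, seed=cfg.seed)


def evaluate(p: CyclizabilityPredictor, library: Sequence[LoopSeqRecord]
             ) -> tuple[float | None, float]:
    """Pearson r and median |pred − c0| of rc-averaged predictions.

    Returns ``r = None`` (with a warning) when either predictions or targets
    are constant, making the correlation undefined.
    """
    if not library:
        raise ValueError("library is empty")
    probes = [strip_adapters(r) for r in library]
    y = np.array([r.c0 for r in library])
    preds = rc_averaged_predict_batch(p, probes)
    mad = float(np.median(np.abs(preds - y)))
    if len(y) < 2 or np.ptp(preds) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("Pearson r undefined: constant predictions or targets")
        return None, mad
    r = float(np.corrcoef(preds, y)[0, 1])
    return r, mad
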