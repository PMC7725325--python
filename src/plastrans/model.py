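"""The fragment transmissibility classifier: build, train, score, persist.

The classifier scores a DNA fragment with a value in (0, 1); higher means
more likely derived from a transmissible (conjugative or mobilizable)
plasmid.  Fragments longer than the 400 bp training window are scored by a
non-overlapping 400 bp scan window, the sequence score being the unweighted
mean of the window scores.  With an uncertainty threshold ``t``, scores in
``|score - 0.5| < t`` are labelled uncertain; otherwise a score strictly
above 0.5 is transmissible, anything else non-transmissible.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import network
from .network import Batch, PlasTransNet, Adam, bce_with_logits, encode_batch
from .simulator import Fragment, TRANSMISSIBLE, NON_TRANSMISSIBLE

__all__ = [
    "ModelConfig",
    "PredictionRecord",
    "TrainedModel",
    "build_model",
    "train_model",
    "score_window",
    "score_sequence",
    "classify_score",
    "save_model",
    "load_model",
]

UNCERTAIN = "uncertain"
_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Architecture defaults follow the published design: two convolutional
    branches of 512 kernels of length 6 with ReLU, global average pooling,
    concatenation to a 1024-dimensional merged vector, and a batch
    normalization / dense / batch normalization head before the logistic
    output.  Training hyperparameters (batch size, epochs, patience,
    learning rate, validation split) are package defaults.
    """

    triplet_kernels: int = 512
    base_kernels: int = 512
    kernel_len: int = 6
    hidden_dim: int = 1024
    n_head_blocks: int = 1
    max_len: int = 400
    min_len: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 50
    early_stop_patience: int = 5
    validation_frac: float = 0.1
    seed: int = 0

    @property
    def merged_dim(self) -> int:
        return self.triplet_kernels + self.base_kernels

    def validate(self) -> None:
        if self.triplet_kernels < 1 or self.base_kernels < 1:
            raise ValueError("kernel counts must be positive")
        if self.kernel_len < 1:
            raise ValueError("kernel_len must be positive")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if not 0.0 <= self.validation_frac < 1.0:
            raise ValueError("validation_frac must be in [0, 1)")


@dataclass
class PredictionRecord:
    """Per-sequence prediction: mean score, window scores, decision label."""

    sequence_id: str
    score: float
    window_scores: list[float]
    label: str
    threshold_t: float


@dataclass
class TrainedModel:
    """A network plus the configuration it was built with."""

    net: PlasTransNet
    config: ModelConfig
    history: dict[str, list[float]] = field(default_factory=dict)

    def score_batch(self, sequences: list[str]) -> np.ndarray:
        batch = encode_batch(sequences, self.config.max_len, self.config.kernel_len)
        return self.net.predict_proba(batch)


def build_model(config: ModelConfig | None = None) -> TrainedModel:
    """Instantiate an untrained classifier from a configuration."""
    config = config or ModelConfig()
    config.validate()
    net = PlasTransNet(
        triplet_kernels=config.triplet_kernels,
        base_kernels=config.base_kernels,
        kernel_len=config.kernel_len,
        hidden_dim=config.hidden_dim,
        n_head_blocks=config.n_head_blocks,
        seed=config.seed,
    )
    return TrainedModel(net=net, config=config)


def _labels_to_binary(fragments: list[Fragment]) -> np.ndarray:
    mapping = {TRANSMISSIBLE: 1.0, NON_TRANSMISSIBLE: 0.0}
    try:
        return np.array([mapping[f.label] for f in fragments])
    except KeyError as exc:
        raise ValueError(f"unknown fragment label: {exc.args[0]!r}") from None


def _masked_auc(scores: np.ndarray, y: np.ndarray) -> float:
    from .evaluation import auc

    return auc(scores.tolist(), y.astype(int).tolist())


def train_model(model: TrainedModel, train_fragments: list[Fragment],
                config: ModelConfig | None = None) -> TrainedModel:
    """Train on labeled fragments; returns the model at its best-validation epoch.

    Binary cross-entropy, Adam optimizer, deterministic under the config
    seed (weight init, shuffling and the validation split all derive from
    it).  ``model.history`` records per-epoch train/validation loss and
    validation AUC.
    """
    cfg = config or model.config
    if not train_fragments:
        raise ValueError("no training fragments")
    bad = [f.fragment_id or i for i, f in enumerate(train_fragments)
           if not cfg.min_len <= len(f.sequence) <= cfg.max_len]
    if bad:
        raise ValueError(
            f"{len(bad)} fragments outside [{cfg.min_len}, {cfg.max_len}] bp: "
            f"{bad[:5]}{'...' if len(bad) > 5 else ''}"
        )
    y = _labels_to_binary(train_fragments)
    if y.min() == y.max():
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(cfg.seed + 1)
    batch = encode_batch([f.sequence for f in train_fragments], cfg.max_len, cfg.kernel_len)
    n = len(train_fragments)
    perm = rng.permutation(n)
    n_val = int(round(n * cfg.validation_frac))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    def take(idx: np.ndarray) -> Batch:
        return Batch(batch.trip_idx[idx], batch.trip_mask[idx],
                     batch.base_idx[idx], batch.base_mask[idx], batch.lengths[idx])

    opt = Adam(model.net, lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_auc": []}
    best_val = np.inf
    best_state = {k: v.copy() for k, v in model.net.state_arrays().items()}
    patience = 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for s in range(0, order.size, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            mb = take(idx)
            logits = model.net.forward_logits(mb, train=True)
            loss, dlogits = bce_with_logits(logits, y[idx])
            grads = model.net.backward(dlogits)
            losses.append(loss)
            opt.step(grads)
        history["train_loss"].append(float(np.mean(losses)))
        if n_val:
            val_logits = model.net.forward_logits(take(val_idx), train=False)
            val_loss, _ = bce_with_logits(val_logits, y[val_idx])
            val_scores = 1.0 / (1.0 + np.exp(-val_logits))
            val_auc = (_masked_auc(val_scores, y[val_idx])
                       if y[val_idx].min() != y[val_idx].max() else float("nan"))
        else:
            val_loss, val_auc = history["train_loss"][-1], float("nan")
        history["val_loss"].append(float(val_loss))
        history["val_auc"].append(float(val_auc))
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.net.state_arrays().items()}
            patience = 0
        else:
            patience += 1
            if patience >= cfg.early_stop_patience:
                break
    model.net.load_state_arrays(best_state)
    model.history = history
    return model


def score_window(model: TrainedModel, sequence: str) -> float:
    """Score one window (min_len..max_len bp) through the network."""
    cfg = model.config
    if not cfg.min_len <= len(sequence) <= cfg.max_len:
        raise ValueError(
            f"window length {len(sequence)} outside [{cfg.min_len}, {cfg.max_len}] bp"
        )
    return float(model.score_batch([sequence])[0])


def split_windows(sequence: str, window: int = 400, min_len: int = 100) -> list[str]:
    """Non-overlapping scan windows left to right; a trailing remainder of at
    least ``min_len`` bp is kept as a short window, shorter remainders dropped."""
    if len(sequence) < min_len:
        raise ValueError(f"sequence of {len(sequence)} bp is below the {min_len} bp minimum")
    out = []
    for start in range(0, len(sequence), window):
        piece = sequence[start : start + window]
        if len(piece) >= min_len:
            out.append(piece)
    return out


def score_sequence(model: TrainedModel, sequence: str, sequence_id: str = "",
                   t: float = 0.0) -> PredictionRecord:
    """Scan-window scoring of a sequence of any length >= min_len.

    The sequence score is the unweighted mean of the per-window scores and
    the label follows :func:`classify_score` at threshold ``t``.
    """
    cfg = model.config
    windows = split_windows(sequence, cfg.max_len, cfg.min_len)
    scores = model.score_batch(windows).astype(np.float64)
    mean_score = float(np.mean(scores))
    return PredictionRecord(
        sequence_id=sequence_id, score=mean_score,
        window_scores=[float(s) for s in scores],
        label=classify_score(mean_score, t), threshold_t=t,
    )


def classify_score(score: float, t: float) -> str:
    """Decision rule: uncertain within ``|score-0.5| < t``; else transmissible
    iff score is strictly above 0.5 (exactly 0.5 is non-transmissible)."""
    if not 0.0 <= t < 0.5:
        raise ValueError(f"threshold t must be in [0, 0.5), got {t}")
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must be in [0, 1], got {score}")
    if abs(score - 0.5) < t:
        return UNCERTAIN
    return TRANSMISSIBLE if score > 0.5 else NON_TRANSMISSIBLE


def save_model(model: TrainedModel, path: str) -> None:
    """Persist config + all parameters and normalization statistics (npz)."""
    meta = {"format_version": _FORMAT_VERSION, "config": asdict(model.config)}
    arrays = {f"param/{k}": v for k, v in model.net.state_arrays().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str) -> TrainedModel:
    """Load a persisted model; identical scores on any probe batch."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != _FORMAT_VERSION:
                raise ValueError(
                    f"model artifact format {meta.get('format_version')} is not "
                    f"supported (expected {_FORMAT_VERSION})"
                )
            state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    except (OSError, ValueError, KeyError) as exc:
        if isinstance(exc, ValueError) and "format" in str(exc):
            raise
        raise ValueError(f"cannot read model artifact {path!r}: {exc}") from exc
    config = ModelConfig(**meta["config"])
    model = build_model(config)
    model.net.load_state_arrays(state)
    return model
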