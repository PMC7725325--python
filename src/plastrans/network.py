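"""Numpy implementation of the two-branch convolutional classifier.

Both network inputs are one-hot sequences (64-bit triplet rows, 4-bit base
rows), so a 1-D convolution over them is an embedding sum: with integer
symbol indices ``s_t`` the feature map is

    z[t, k] = b[k] + sum_{d=0}^{klen-1} W[d, s_{t+d}, k]

which this module evaluates by table lookup instead of dense matmul.  An
extra vocabulary row pinned at zero represents padding and ambiguous
symbols (the all-zero one-hot row).  Each branch applies ReLU and a masked
global average pool over the valid convolution windows; the pooling mask
excludes padding and any window that would straddle two segments of the
connected input (frame boundaries of the six-frame triplet sequence, the
strand boundary of the dual-strand base sequence).  Keeping kernels within
segments makes the pooled features — and hence the score — exactly
invariant under reverse complement, which only permutes the segments.

The pooled branch vectors are concatenated and passed through batch
normalization / dense / batch normalization blocks to a single logistic
output.  Training is by Adam on binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix

from .encoding import triplet_frame_lengths

__all__ = ["Batch", "encode_batch", "PlasTransNet", "Adam"]

TRIPLET_VOCAB = 64
BASE_VOCAB = 4

_BASE_LUT = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


@dataclass
class Batch:
    """Index-encoded fragment batch with pooling masks.

    ``trip_idx``: (B, Tt) triplet indices, 64 = padding/ambiguous;
    ``base_idx``: (B, 2*max_len) base indices, 4 = padding/ambiguous;
    masks are (B, T - klen + 1) booleans over valid convolution windows.
    """

    trip_idx: np.ndarray
    trip_mask: np.ndarray
    base_idx: np.ndarray
    base_mask: np.ndarray
    lengths: np.ndarray


def _strand_indices(seq: str) -> tuple[np.ndarray, np.ndarray]:
    fwd = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    rev = np.where(fwd < 4, 3 - fwd, 4)[::-1]
    return fwd, rev


def _frame_codons(strand: np.ndarray, offset: int) -> np.ndarray:
    n = (strand.size - offset) // 3
    if n == 0:
        return np.empty(0, dtype=np.int64)
    a = strand[offset : offset + 3 * n : 3]
    b = strand[offset + 1 : offset + 1 + 3 * n : 3]
    c = strand[offset + 2 : offset + 2 + 3 * n : 3]
    codons = a * 16 + b * 4 + c
    codons[(a > 3) | (b > 3) | (c > 3)] = TRIPLET_VOCAB
    return codons


def _segment_mask(total_windows: int, seg_lengths: list[int], klen: int) -> np.ndarray:
    mask = np.zeros(total_windows, dtype=bool)
    pos = 0
    for seg in seg_lengths:
        if seg >= klen:
            mask[pos : pos + seg - klen + 1] = True
        pos += seg
    return mask


def encode_batch(sequences: list[str], max_len: int, klen: int = 6) -> Batch:
    """Encode fragments into padded index arrays and segment-aware masks."""
    B = len(sequences)
    t_rows = sum(triplet_frame_lengths(max_len))
    trip_idx = np.full((B, t_rows), TRIPLET_VOCAB, dtype=np.int64)
    trip_mask = np.zeros((B, t_rows - klen + 1), dtype=bool)
    base_idx = np.full((B, 2 * max_len), BASE_VOCAB, dtype=np.int64)
    base_mask = np.zeros((B, 2 * max_len - klen + 1), dtype=bool)
    lengths = np.zeros(B, dtype=np.int64)
    for i, seq in enumerate(sequences):
        L = len(seq)
        if L > max_len:
            raise ValueError(f"sequence of {L} bp exceeds max_len={max_len}")
        fwd, rev = _strand_indices(seq)
        codons = np.concatenate(
            [_frame_codons(s, o) for s in (fwd, rev) for o in range(3)]
        )
        trip_idx[i, : codons.size] = codons
        trip_mask[i] = _segment_mask(t_rows - klen + 1, triplet_frame_lengths(L), klen)
        base_idx[i, :L] = fwd
        base_idx[i, L : 2 * L] = rev
        base_mask[i] = _segment_mask(2 * max_len - klen + 1, [L, L], klen)
        lengths[i] = L
    return Batch(trip_idx, trip_mask, base_idx, base_mask, lengths)


def save_batch(batch: Batch, path: str) -> None:
    """Serialize an encoded batch to npz for training caches."""
    np.savez_compressed(path, trip_idx=batch.trip_idx, trip_mask=batch.trip_mask,
                        base_idx=batch.base_idx, base_mask=batch.base_mask,
                        lengths=batch.lengths)


def load_batch(path: str) -> Batch:
    with np.load(path) as data:
        return Batch(data["trip_idx"], data["trip_mask"],
                     data["base_idx"], data["base_mask"], data["lengths"])


def batch_from_onehot(triplet_matrices: list[np.ndarray], base_matrices: list[np.ndarray],
                      lengths: list[int], klen: int = 6) -> Batch:
    """Build a :class:`Batch` from one-hot matrix pairs (all-zero rows -> pad index)."""
    def to_idx(mats: list[np.ndarray], vocab: int) -> np.ndarray:
        stacked = np.stack(mats)
        idx = stacked.argmax(axis=2).astype(np.int64)
        idx[stacked.sum(axis=2) == 0] = vocab
        return idx

    trip_idx = to_idx(triplet_matrices, TRIPLET_VOCAB)
    base_idx = to_idx(base_matrices, BASE_VOCAB)
    t_windows = trip_idx.shape[1] - klen + 1
    b_windows = base_idx.shape[1] - klen + 1
    trip_mask = np.stack([
        _segment_mask(t_windows, triplet_frame_lengths(L), klen) for L in lengths
    ])
    base_mask = np.stack([_segment_mask(b_windows, [L, L], klen) for L in lengths])
    return Batch(trip_idx, trip_mask, base_idx, base_mask,
                 np.asarray(lengths, dtype=np.int64))


class _ConvPoolBranch:
    """Embedding-form 1-D convolution + ReLU + masked global average pooling."""

    def __init__(self, vocab: int, kernels: int, klen: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (klen * vocab))
        self.W = (rng.standard_normal((klen, vocab + 1, kernels)) * scale).astype(np.float32)
        self.W[:, vocab, :] = 0.0  # padding/ambiguous row stays zero
        self.b = np.zeros(kernels, dtype=np.float32)
        self.vocab, self.klen = vocab, klen
        self._cache: tuple | None = None

    def forward(self, idx: np.ndarray, mask: np.ndarray, train: bool) -> np.ndarray:
        B, T = idx.shape
        Tout = T - self.klen + 1
        z = np.broadcast_to(self.b, (B, Tout, self.b.size)).copy()
        for d in range(self.klen):
            z += self.W[d][idx[:, d : d + Tout]]
        np.maximum(z, 0.0, out=z)
        n_valid = mask.sum(axis=1).astype(np.float32)
        inv = (1.0 / np.maximum(n_valid, 1.0)).astype(np.float32)
        pooled = np.einsum("btk,bt->bk", z, mask.astype(np.float32)) * inv[:, None]
        if train:
            self._cache = (idx, mask, z, inv)
        return pooled

    def backward(self, dpooled: np.ndarray) -> dict[str, np.ndarray]:
        idx, mask, z, inv = self._cache
        B, Tout, K = z.shape
        dz = (mask.astype(np.float32) * inv[:, None])[:, :, None] * dpooled[:, None, :]
        dz *= z > 0
        db = dz.sum(axis=(0, 1))
        dz_flat = dz.reshape(B * Tout, K)
        dW = np.zeros_like(self.W)
        N = B * Tout
        indptr = np.arange(N + 1)
        data = np.ones(N, dtype=np.float32)
        for d in range(self.klen):
            cols = idx[:, d : d + Tout].reshape(N)
            S = csr_matrix((data, cols, indptr), shape=(N, self.vocab + 1))
            dW[d] = S.T @ dz_flat
        dW[:, self.vocab, :] = 0.0
        self._cache = None
        return {"W": dW, "b": db}

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}


class _BatchNorm:
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim, dtype=np.float32)
        self.beta = np.zeros(dim, dtype=np.float32)
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        xhat, inv_std = self._cache
        B = dy.shape[0]
        dgamma = (dy * xhat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        dx = inv_std / B * (B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        self._cache = None
        return dx.astype(np.float32), {"gamma": dgamma, "beta": dbeta}

    def params(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    def stats(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, relu: bool):
        scale = np.sqrt((2.0 if relu else 1.0) / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.relu = relu
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = x @ self.W + self.b
        if self.relu:
            y = np.maximum(y, 0.0)
        if train:
            self._cache = (x, y)
        return y

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        x, y = self._cache
        if self.relu:
            dy = dy * (y > 0)
        grads = {"W": x.T @ dy, "b": dy.sum(axis=0)}
        self._cache = None
        return (dy @ self.W.T).astype(np.float32), grads

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}


class PlasTransNet:
    """Two-branch convolutional network over index-encoded fragment batches."""

    def __init__(self, triplet_kernels: int, base_kernels: int, kernel_len: int,
                 hidden_dim: int, n_head_blocks: int, seed: int):
        rng = np.random.default_rng(seed)
        self.kernel_len = kernel_len
        self.triplet_branch = _ConvPoolBranch(TRIPLET_VOCAB, triplet_kernels, kernel_len, rng)
        self.base_branch = _ConvPoolBranch(BASE_VOCAB, base_kernels, kernel_len, rng)
        self.merged_dim = triplet_kernels + base_kernels
        self.head: list = []
        d = self.merged_dim
        for _ in range(n_head_blocks):
            self.head.append(_BatchNorm(d))
            self.head.append(_Dense(d, hidden_dim, rng, relu=True))
            self.head.append(_BatchNorm(hidden_dim))
            d = hidden_dim
        self.out = _Dense(d, 1, rng, relu=False)

    # --- forward / backward -------------------------------------------------

    def forward_logits(self, batch: Batch, train: bool = False) -> np.ndarray:
        pt = self.triplet_branch.forward(batch.trip_idx, batch.trip_mask, train)
        pb = self.base_branch.forward(batch.base_idx, batch.base_mask, train)
        h = np.concatenate([pt, pb], axis=1)
        for layer in self.head:
            h = layer.forward(h, train)
        return self.out.forward(h, train)[:, 0]

    def predict_proba(self, batch: Batch) -> np.ndarray:
        z = self.forward_logits(batch, train=False)
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, dlogits: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        grads: dict[str, dict[str, np.ndarray]] = {}
        dh, grads["out"] = self.out.backward(dlogits[:, None].astype(np.float32))
        for li in range(len(self.head) - 1, -1, -1):
            dh, grads[f"head{li}"] = self.head[li].backward(dh)
        k = self.triplet_branch.b.size
        grads["triplet"] = self.triplet_branch.backward(dh[:, :k])
        grads["base"] = self.base_branch.backward(dh[:, k:])
        return grads

    # --- parameter access ---------------------------------------------------

    def param_groups(self) -> dict[str, dict[str, np.ndarray]]:
        groups = {"triplet": self.triplet_branch.params(),
                  "base": self.base_branch.params()}
        for li, layer in enumerate(self.head):
            groups[f"head{li}"] = layer.params()
        groups["out"] = self.out.params()
        return groups

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array map of all parameters and batch-norm statistics."""
        out = {}
        for gname, group in self.param_groups().items():
            for pname, arr in group.items():
                out[f"{gname}.{pname}"] = arr
        for li, layer in enumerate(self.head):
            if isinstance(layer, _BatchNorm):
                for sname, arr in layer.stats().items():
                    out[f"head{li}.{sname}"] = arr
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(state):
            raise ValueError("model state does not match architecture")
        for name, arr in own.items():
            if arr.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            arr[...] = state[name]


class Adam:
    """Adaptive-moment optimizer over a model's parameter groups."""

    def __init__(self, model: PlasTransNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {g: {p: np.zeros_like(a) for p, a in gr.items()}
                  for g, gr in model.param_groups().items()}
        self.v = {g: {p: np.zeros_like(a) for p, a in gr.items()}
                  for g, gr in model.param_groups().items()}

    def step(self, grads: dict[str, dict[str, np.ndarray]]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for gname, group in self.model.param_groups().items():
            for pname, param in group.items():
                g = grads[gname][pname].astype(np.float32)
                m = self.m[gname][pname]
                v = self.v[gname][pname]
                m += (1 - self.beta1) * (g - m)
                v += (1 - self.beta2) * (g * g - v)
                param -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z, y = logits.astype(np.float64), labels.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, ((p - y) / z.size).astype(np.float32)
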