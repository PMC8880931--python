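"""Normalized temperature-scaled cross-entropy (NT-Xent) over patient
pairs.

For a batch of N patients contributing 2N projections z_1..z_2N with
cosine similarity ``sim``, the per-pair loss is

    l(i, j) = -log  exp(sim(z_i, z_j) / tau)
                    / sum_{k != i} exp(sim(z_i, z_k) / tau)

and the batch loss is the sum of l(p1, p2) over the N patients. This is
the asymmetric form (one anchor per patient); a ``symmetric`` switch
adds l(p2, p1) per patient, matching the SimCLR convention.

All similarity computations are log-sum-exp stabilized, and projection
norms are floored at a small epsilon so a ReLU head that momentarily
outputs a zero vector does not abort training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import PairingError, ZeroVectorError

NORM_EPS = 1e-12


@dataclass(frozen=True)
class LossConfig:
    temperature: float = 0.1
    symmetric: bool = False

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Inner product of the unit-normalized vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine similarity undefined for zero vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _normalize_rows(Z: np.ndarray) -> tuple:
    Z = np.asarray(Z, dtype=np.float64)
    norms = np.maximum(np.linalg.norm(Z, axis=1, keepdims=True), NORM_EPS)
    return Z / norms, norms


def _check_pairing(pair_index: np.ndarray, m: int) -> np.ndarray:
    pair_index = np.asarray(pair_index, dtype=int)
    if pair_index.ndim != 2 or pair_index.shape[1] != 2:
        raise PairingError(f"pair_index must be (N, 2), got {pair_index.shape}")
    flat = pair_index.ravel()
    if sorted(flat.tolist()) != list(range(m)):
        raise PairingError(
            f"pair_index must partition positions 0..{m - 1} exactly once")
    return pair_index


def pair_loss(i: int, j: int, projections: np.ndarray,
              config: LossConfig | None = None) -> float:
    """l(i, j) for anchor i with positive j over a (2N, d) projection batch."""
    config = config or LossConfig()
    if i == j:
        raise PairingError("anchor and positive must differ (i != j)")
    Zh, _ = _normalize_rows(projections)
    m = Zh.shape[0]
    s = (Zh @ Zh[i]) / config.temperature
    mask = np.arange(m) != i
    return float(logsumexp(s[mask]) - s[j])


def batch_loss(projections: np.ndarray, pair_index,
               config: LossConfig | None = None) -> float:
    """Sum of per-patient pair losses over the batch."""
    loss, _ = batch_loss_and_grad(projections, pair_index, config)
    return loss


def batch_loss_and_grad(projections: np.ndarray, pair_index,
                        config: LossConfig | None = None) -> tuple:
    """Batch NT-Xent loss and its gradient w.r.t. the raw projections.

    Vectorized over anchors; the gradient flows through the cosine
    normalization (norms floored at ``NORM_EPS``).
    """
    config = config or LossConfig()
    Z = np.asarray(projections, dtype=np.float64)
    m = Z.shape[0]
    pair_index = _check_pairing(pair_index, m)
    Zh, norms = _normalize_rows(Z)
    tau = config.temperature

    anchors = [(int(p1), int(p2)) for p1, p2 in pair_index]
    if config.symmetric:
        anchors += [(int(p2), int(p1)) for p1, p2 in pair_index]

    S = (Zh @ Zh.T) / tau
    total = 0.0
    G = np.zeros((m, m))          # dL/dS (scaled similarities)
    off = ~np.eye(m, dtype=bool)
    for i, j in anchors:
        row = S[i][off[i]]
        lse = logsumexp(row)
        total += lse - S[i, j]
        q = np.exp(S[i] - lse)
        q[i] = 0.0
        G[i] += q
        G[i, j] -= 1.0
    G /= tau

    dZh = (G + G.T) @ Zh
    dZ = (dZh - Zh * np.sum(dZh * Zh, axis=1, keepdims=True)) / norms
    return float(total), dZ
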