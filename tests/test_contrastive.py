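"""NT-Xent loss: worked examples, scalar oracle equivalence, invariants."""

import math

import numpy as np
import pytest

from pclr.contrastive import (LossConfig, batch_loss, batch_loss_and_grad,
                              cosine_similarity, pair_loss)
from pclr.errors import PairingError, ZeroVectorError

RNG = np.random.default_rng(2024)


def scalar_oracle(Z, pair_index, tau, symmetric=False):
    """Naive double-loop evaluation of the printed loss formula."""
    Z = np.asarray(Z, dtype=np.float64)
    m = Z.shape[0]

    def sim(a, b):
        return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))

    def ell(i, j):
        num = math.exp(sim(Z[i], Z[j]) / tau)
        den = sum(math.exp(sim(Z[i], Z[k]) / tau)
                  for k in range(m) if k != i)
        return -math.log(num / den)

    total = 0.0
    for p1, p2 in pair_index:
        total += ell(p1, p2)
        if symmetric:
            total += ell(p2, p1)
    return total


def random_batch(n_patients, width, rng):
    Z = rng.normal(size=(2 * n_patients, width))
    order = rng.permutation(2 * n_patients)
    pair_index = order.reshape(n_patients, 2)
    return Z, pair_index


def test_cosine_similarity_basics():
    v = np.array([0.3, -2.0, 1.1])
    assert cosine_similarity(v, v) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_similarity([1, 1], [-1, -1]) == pytest.approx(-1.0)
    with pytest.raises(ZeroVectorError):
        cosine_similarity([0, 0], [1, 0])
    with pytest.raises(ValueError):
        cosine_similarity([1, 0], [1, 0, 0])


def test_single_pair_batch_loss_is_zero():
    """N = 1: the denominator's only term is the numerator."""
    Z = RNG.normal(size=(2, 6))
    assert pair_loss(0, 1, Z) == pytest.approx(0.0, abs=1e-12)
    assert batch_loss(Z, [(0, 1)]) == pytest.approx(0.0, abs=1e-12)


def test_identical_projections_give_log3():
    """N = 2, tau = 1, all projections equal: softmax uniform over 3."""
    Z = np.tile([0.5, 0.5], (4, 1))
    cfg = LossConfig(temperature=1.0)
    assert pair_loss(0, 1, Z, cfg) == pytest.approx(math.log(3.0))
    assert batch_loss(Z, [(0, 1), (2, 3)], cfg) == pytest.approx(
        2 * math.log(3.0))


def test_orthogonal_pairs_at_low_temperature():
    """Well-separated pairs at tau = 0.1: loss log(1 + 2 e^-10)."""
    Z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    cfg = LossConfig(temperature=0.1)
    expected = math.log(1.0 + 2.0 * math.exp(-10.0))
    assert pair_loss(0, 1, Z, cfg) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(9.08e-5, rel=1e-2)


def test_vectorized_matches_scalar_oracle():
    """100 random batches (N <= 8, width <= 16) to 1e-10 relative."""
    rng = np.random.default_rng(77)
    for trial in range(100):
        n = int(rng.integers(1, 9))
        w = int(rng.integers(2, 17))
        tau = float(rng.uniform(0.05, 2.0))
        sym = bool(rng.integers(0, 2))
        Z, pi = random_batch(n, w, rng)
        got = batch_loss(Z, pi, LossConfig(temperature=tau, symmetric=sym))
        want = scalar_oracle(Z, pi, tau, symmetric=sym)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-12), trial


def test_monotone_in_positive_similarity():
    """Raising sim(z_p1, z_p2), all else fixed, strictly lowers the loss."""
    others = RNG.normal(size=(6, 4))
    anchor = np.array([1.0, 0.0, 0.0, 0.0])
    losses = []
    for angle in np.linspace(1.4, 0.1, 8):
        pos = np.array([math.cos(angle), math.sin(angle), 0.0, 0.0])
        Z = np.vstack([anchor, pos, others])
        losses.append(pair_loss(0, 1, Z, LossConfig(temperature=0.5)))
    assert all(a > b for a, b in zip(losses, losses[1:]))


def test_infinite_temperature_limit():
    """tau -> inf flattens the softmax: loss -> log(2N - 1)."""
    Z, pi = random_batch(4, 6, np.random.default_rng(5))
    cfg = LossConfig(temperature=1e6)
    for p1, p2 in pi:
        assert pair_loss(int(p1), int(p2), Z, cfg) == pytest.approx(
            math.log(7.0), rel=1e-4)


def test_scale_invariance():
    Z, pi = random_batch(3, 5, np.random.default_rng(6))
    base = batch_loss(Z, pi)
    Z2 = Z.copy()
    Z2[2] *= 37.5
    assert batch_loss(Z2, pi) == pytest.approx(base, rel=1e-12)


def test_patient_order_permutation_invariance():
    Z, pi = random_batch(4, 5, np.random.default_rng(8))
    assert batch_loss(Z, pi[::-1]) == pytest.approx(batch_loss(Z, pi),
                                                    rel=1e-12)


def test_gradient_matches_finite_differences():
    Z, pi = random_batch(3, 4, np.random.default_rng(9))
    for cfg in (LossConfig(), LossConfig(temperature=0.7, symmetric=True)):
        _, dZ = batch_loss_and_grad(Z, pi, cfg)
        eps = 1e-6
        num = np.zeros_like(Z)
        for a in range(Z.shape[0]):
            for b in range(Z.shape[1]):
                Zp, Zm = Z.copy(), Z.copy()
                Zp[a, b] += eps
                Zm[a, b] -= eps
                num[a, b] = (batch_loss(Zp, pi, cfg)
                             - batch_loss(Zm, pi, cfg)) / (2 * eps)
        assert np.abs(num - dZ).max() / np.abs(num).max() < 1e-6


def test_named_errors():
    Z = RNG.normal(size=(4, 3))
    with pytest.raises(PairingError):
        pair_loss(1, 1, Z)
    with pytest.raises(PairingError):
        batch_loss(Z, [(0, 1)])                 # 4 tensors, 1 pair
    with pytest.raises(PairingError):
        batch_loss(Z, [(0, 1), (1, 2)])         # position reused
    with pytest.raises(ValueError):
        LossConfig(temperature=0.0)
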