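"""Vector quantization: nearest-neighbour oracle, tie rule, loss contracts, EMA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vqradiomics.vq import (
    Codebook,
    ema_update,
    latent_loss,
    latent_loss_grads,
    vector_quantize,
)


def _brute_force_indices(latent, vectors):
    """Exhaustive double-loop nearest-neighbour assignment."""
    d, w, h = latent.shape
    out = np.zeros((w, h), dtype=int)
    for i in range(w):
        for j in range(h):
            dists = [np.linalg.norm(latent[:, i, j] - vectors[k]) ** 2
                     for k in range(vectors.shape[0])]
            out[i, j] = int(np.argmin(dists))
    return out


def test_exact_codeword_maps_to_itself(rng):
    cb = Codebook.random(8, 4, rng, dtype=np.float64)
    latent = np.tile(cb.vectors[3][:, None, None], (1, 2, 2))
    q = vector_quantize(latent, cb)
    assert np.all(q.indices == 3)
    np.testing.assert_array_equal(q.values, latent)


def test_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(30):
        k = int(rng.integers(2, 9))
        d = int(rng.integers(1, 5))
        cb = Codebook.random(k, d, rng, dtype=np.float64)
        latent = rng.standard_normal((d, 5, 5))
        q = vector_quantize(latent, cb, count_usage=False)
        np.testing.assert_array_equal(q.indices, _brute_force_indices(latent, cb.vectors))
        np.testing.assert_array_equal(q.values, cb.vectors[q.indices].transpose(2, 0, 1))


def test_tie_breaks_to_lower_index():
    vectors = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
    cb = Codebook(vectors=vectors)
    latent = np.zeros((2, 1, 1))  # equidistant from codewords 0 and 1
    assert vector_quantize(latent, cb).indices[0, 0] == 0


def test_quantization_idempotent(rng):
    cb = Codebook.random(8, 4, rng, dtype=np.float64)
    latent = rng.standard_normal((4, 6, 6))
    q1 = vector_quantize(latent, cb, count_usage=False)
    q2 = vector_quantize(q1.values, cb, count_usage=False)
    np.testing.assert_array_equal(q1.indices, q2.indices)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    seed=st.integers(0, 2**16),
    k=st.integers(2, 12),
    d=st.integers(1, 6),
    w=st.integers(1, 5),
    h=st.integers(1, 5),
)
def test_quantization_properties(seed, k, d, w, h):
    """Indices are valid, values are exact codebook rows, and re-quantizing
    quantized values is the identity — for arbitrary small instances."""
    gen = np.random.default_rng(seed)
    cb = Codebook.random(k, d, gen, dtype=np.float64)
    latent = gen.standard_normal((d, w, h))
    q = vector_quantize(latent, cb, count_usage=False)
    assert q.indices.min() >= 0 and q.indices.max() < k
    np.testing.assert_array_equal(q.values, cb.vectors[q.indices].transpose(2, 0, 1))
    q2 = vector_quantize(q.values, cb, count_usage=False)
    np.testing.assert_array_equal(q.indices, q2.indices)


def test_usage_counts_and_input_validation(rng):
    cb = Codebook.random(4, 2, rng)
    latent = rng.standard_normal((2, 3, 3))
    vector_quantize(latent, cb)
    assert cb.usage_counts.sum() == 9
    bad = latent.copy()
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        vector_quantize(bad, cb)


def test_codebook_validation():
    with pytest.raises(ValueError):
        Codebook(vectors=np.zeros((1, 4)))  # K < 2
    with pytest.raises(ValueError):
        Codebook(vectors=np.full((4, 2), np.inf))
    with pytest.raises(ValueError):
        Codebook(vectors=np.zeros((4, 2)), update_mode="ema", ema_decay=1.5)


def test_latent_loss_arithmetic():
    cb = Codebook(vectors=np.array([[0.0], [5.0]]))
    latent = np.ones((1, 1, 1))
    q = vector_quantize(latent, cb, count_usage=False)
    loss = latent_loss(latent, q, beta=0.25)
    assert loss.codebook_term == pytest.approx(1.0)
    assert loss.commitment_term == pytest.approx(0.25)
    assert loss.total == pytest.approx(1.25)
    # zero when the latent equals its assigned codewords
    zero = latent_loss(q.values, q, beta=0.25)
    assert zero.total == 0.0
    with pytest.raises(ValueError):
        latent_loss(latent, q, beta=-1.0)


def test_latent_loss_gradient_routing(rng):
    """Finite differences: the commitment gradient reaches only the latent;
    perturbing a codeword changes only the codebook-term gradient."""
    cb = Codebook.random(4, 3, rng, dtype=np.float64)
    latent = rng.standard_normal((3, 2, 2))
    beta = 0.25
    q = vector_quantize(latent, cb, count_usage=False)
    d_ze, d_cb = latent_loss_grads(latent, q, beta, cb.K)

    eps = 1e-6
    # commitment term = beta * mean((ze - e)^2) with assignments held fixed
    def commit(z):
        return beta * np.mean((z - q.values) ** 2)

    num = np.zeros_like(latent)
    for idx in np.ndindex(*latent.shape):
        z1, z2 = latent.copy(), latent.copy()
        z1[idx] += eps
        z2[idx] -= eps
        num[idx] = (commit(z1) - commit(z2)) / (2 * eps)
    np.testing.assert_allclose(d_ze, num, atol=1e-8)

    # codebook term = mean((e - sg[ze])^2) over assigned positions
    def codebook_term(vectors):
        vals = vectors[q.indices].transpose(2, 0, 1)
        return np.mean((vals - latent) ** 2)

    for k in range(cb.K):
        for d in range(cb.D):
            v1, v2 = cb.vectors.copy(), cb.vectors.copy()
            v1[k, d] += eps
            v2[k, d] -= eps
            g = (codebook_term(v1) - codebook_term(v2)) / (2 * eps)
            assert abs(g - d_cb[k, d]) < 1e-8


def test_ema_fixed_point():
    """Constant latents assigned to one codeword pull it onto them."""
    cb = Codebook(vectors=np.array([[10.0, 10.0], [5.0, -5.0]]), update_mode="ema",
                  ema_decay=0.5)
    target = np.array([1.0, 2.0])
    latent = np.tile(target[:, None, None], (1, 3, 3))
    for _ in range(40):
        q = vector_quantize(latent, cb, count_usage=False)
        ema_update(cb, latent, q.indices)
    np.testing.assert_allclose(cb.vectors[q.indices[0, 0]], target, atol=1e-3)


def test_ema_unassigned_codeword_stays():
    cb = Codebook(vectors=np.array([[0.0, 0.0], [3.0, 4.0]]), update_mode="ema",
                  ema_decay=0.9)
    latent = np.zeros((2, 2, 2))
    before = cb.vectors[1].copy()
    ema_update(cb, latent, np.zeros((2, 2), dtype=int))
    np.testing.assert_allclose(cb.vectors[1], before, atol=1e-3)


def test_ema_single_step_matches_hand_computation():
    gamma = 0.8
    cb = Codebook(vectors=np.array([[1.0], [2.0]]), update_mode="ema", ema_decay=gamma)
    latent = np.array([[[3.0, 5.0]]])  # D=1, two positions, both -> codeword 0
    assignments = np.zeros((1, 2), dtype=int)
    # hand-rolled accumulators (initialized at N=1, m=initial vectors)
    n = gamma * np.array([1.0, 1.0]) + (1 - gamma) * np.array([2.0, 0.0])
    m = gamma * np.array([[1.0], [2.0]]) + (1 - gamma) * np.array([[8.0], [0.0]])
    total = n.sum()
    smoothed = (n + cb.ema_eps) / (total + 2 * cb.ema_eps) * total
    expected = m / smoothed[:, None]
    ema_update(cb, latent, assignments)
    np.testing.assert_allclose(cb.vectors, expected, rtol=1e-12)
    with pytest.raises(ValueError):
        ema_update(Codebook(vectors=np.zeros((2, 1))), latent, assignments)
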