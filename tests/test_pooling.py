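"""Pooling model: forward pass, loss terms, gradients, training."""

import itertools

import numpy as np
import pytest
from scipy import sparse

from nichetraj.niche import normalize_adjacency
from nichetraj.pooling import (
    PoolingModel,
    TrainingConfig,
    _selu,
    cluster_assign,
    collapse_regularization,
    gcn_forward,
    modularity_loss,
    purity_loss,
    total_loss_and_grads,
    train,
)

from .conftest import random_adjacency, random_row_stochastic


def make_model(rng, m=4, h=3, k=3, beta=1.0):
    return PoolingModel.init(m, h, k, beta, rng)


# ---------------------------------------------------------------- forward


def test_forward_isolated_nodes_reduce_to_mlp(rng):
    """With no edges, each row is encoded independently: X2=selu(selu(V W1) W2)."""
    v = np.eye(4)
    model = make_model(rng, m=4)
    empty = sparse.csr_matrix((4, 4))
    x2 = gcn_forward(v, empty, model)
    expected = _selu(_selu(v @ model.W1) @ model.W2)
    np.testing.assert_allclose(x2, expected, rtol=1e-12)


def test_forward_identical_rows_stay_identical(rng):
    v = np.tile(np.array([0.2, 0.3, 0.5]), (5, 1))
    a = normalize_adjacency(random_adjacency(rng, 5, p=1.0))  # complete graph
    model = make_model(rng, m=3)
    x2 = gcn_forward(v, a, model)
    np.testing.assert_allclose(x2, np.tile(x2[0], (5, 1)), rtol=1e-10)


def test_forward_matches_dense_matrix_oracle(rng):
    n, m = 10, 4
    a = random_adjacency(rng, n)
    a_norm = normalize_adjacency(a)
    v = random_row_stochastic(rng, n, m)
    model = make_model(rng, m=m)
    x2 = gcn_forward(v, a_norm, model)
    s = a_norm.toarray() + np.eye(n)
    expected = _selu(s @ _selu(s @ v @ model.W1) @ model.W2)
    np.testing.assert_allclose(x2, expected, rtol=1e-10)


def test_forward_shape_mismatch_raises(rng):
    model = make_model(rng, m=4)
    with pytest.raises(ValueError, match="features"):
        gcn_forward(np.ones((5, 3)), sparse.identity(5), model)


def test_cluster_assign_rows_sum_to_one_and_limits(rng):
    model = make_model(rng, m=4, k=5)
    x2 = rng.normal(size=(20, 3))
    c = cluster_assign(x2, model)
    np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-9)
    # zero logits -> uniform rows
    zero_model = PoolingModel(model.W1, model.W2, np.zeros_like(model.WC), 1.0)
    np.testing.assert_allclose(cluster_assign(x2, zero_model), 0.2, atol=1e-12)


# ------------------------------------------------------------------ losses


def modularity_oracle(c, a, denominator="nodes"):
    """Direct double-sum evaluation of -Tr(C^T B C)/2N."""
    a = a.toarray()
    n = a.shape[0]
    scale = n if denominator == "nodes" else a.sum() / 2.0
    d = a.sum(axis=1)
    b = a - np.outer(d, d) / (2.0 * scale)
    return -np.trace(c.T @ b @ c) / (2.0 * scale)


def purity_oracle(c, v):
    n, m = v.shape
    k = c.shape[1]
    v_star = np.zeros((k, m))
    for kk in range(k):
        if c[:, kk].sum() > 0:
            v_star[kk] = (c[:, kk][:, None] * v).sum(0) / c[:, kk].sum()
    total = 0.0
    for j in range(n):
        for mm in range(m):
            total += (v[j, mm] - sum(c[j, kk] * v_star[kk, mm] for kk in range(k))) ** 2
    return total / (n * m)


def collapse_oracle(c):
    n, k = c.shape
    return np.sqrt(k) / (n * (np.sqrt(k) - 1.0)) * np.sqrt(
        sum(c[:, kk].sum() ** 2 for kk in range(k))
    )


@pytest.mark.parametrize("denominator", ["nodes", "edges"])
def test_losses_match_direct_summation_oracles(rng, denominator):
    for _ in range(20):
        n, k, m = 12, 3, 4
        a = random_adjacency(rng, n)
        c = random_row_stochastic(rng, n, k)
        v = random_row_stochastic(rng, n, m)
        assert modularity_loss(c, a, denominator) == pytest.approx(
            modularity_oracle(c, a, denominator), rel=1e-8
        )
        assert purity_loss(c, v) == pytest.approx(purity_oracle(c, v), rel=1e-8)
        assert collapse_regularization(c) == pytest.approx(
            collapse_oracle(c), rel=1e-8
        )


def test_modularity_uniform_assignment_closed_form(rng):
    """Uniform C collapses Tr(C^T B C) to sum(B)/K, for both conventions."""
    n, k = 10, 4
    a = random_adjacency(rng, n)
    c = np.full((n, k), 1.0 / k)
    d = np.asarray(a.sum(axis=1)).ravel()
    for denom, scale in [("nodes", float(n)), ("edges", a.sum() / 2.0)]:
        b_sum = a.sum() - (d.sum() ** 2) / (2.0 * scale)
        assert modularity_loss(c, a, denom) == pytest.approx(
            -b_sum / (2.0 * scale * k), rel=1e-10
        )


def test_modularity_prefers_true_blocks_over_swapped():
    blocks = sparse.block_diag(
        [np.ones((4, 4)) - np.eye(4), np.ones((4, 4)) - np.eye(4)], format="csr"
    )
    good = np.repeat(np.eye(2), 4, axis=0)
    bad = np.vstack(
        [np.tile([1.0, 0.0], (2, 1)), np.tile([0.0, 1.0], (2, 1))] * 2
    )
    assert modularity_loss(good, blocks) < modularity_loss(bad, blocks)


def test_purity_zero_for_homogeneous_compositions(rng):
    v = np.tile([0.25, 0.25, 0.5], (8, 1))
    c = random_row_stochastic(rng, 8, 3)
    assert purity_loss(c, v) == pytest.approx(0.0, abs=1e-15)


def test_purity_zero_for_hard_match_of_two_groups():
    v = np.vstack([np.tile([1.0, 0.0], (4, 1)), np.tile([0.0, 1.0], (4, 1))])
    c = np.repeat(np.eye(2), 4, axis=0)
    assert purity_loss(c, v) == pytest.approx(0.0, abs=1e-15)


def test_collapse_balanced_and_collapsed_extremes():
    n, k = 12, 4
    balanced = np.full((n, k), 1.0 / k)
    assert collapse_regularization(balanced) == pytest.approx(
        1.0 / (np.sqrt(k) - 1.0), rel=1e-12
    )
    collapsed = np.zeros((n, k))
    collapsed[:, 0] = 1.0
    assert collapse_regularization(collapsed) == pytest.approx(
        np.sqrt(k) / (np.sqrt(k) - 1.0), rel=1e-12
    )
    assert collapse_regularization(balanced) < collapse_regularization(collapsed)


def test_losses_permutation_equivariant(rng):
    """Relabeling niches and clusters consistently leaves all terms unchanged."""
    n, k, m = 10, 3, 4
    a = random_adjacency(rng, n)
    c = random_row_stochastic(rng, n, k)
    v = random_row_stochastic(rng, n, m)
    perm_n = rng.permutation(n)
    perm_k = rng.permutation(k)
    a_p = sparse.csr_matrix(a.toarray()[np.ix_(perm_n, perm_n)])
    c_p = c[np.ix_(perm_n, perm_k)]
    v_p = v[perm_n]
    assert modularity_loss(c, a) == pytest.approx(modularity_loss(c_p, a_p), rel=1e-10)
    assert purity_loss(c, v) == pytest.approx(purity_loss(c_p, v_p), rel=1e-10)
    assert collapse_regularization(c) == pytest.approx(
        collapse_regularization(c_p), rel=1e-10
    )


# --------------------------------------------------------------- gradients


def test_analytic_gradients_match_finite_differences(rng):
    """Central finite differences over every weight of every layer."""
    n, m, h, k = 8, 3, 2, 3
    a = random_adjacency(rng, n)
    a_norm = normalize_adjacency(a)
    v = random_row_stochastic(rng, n, m)
    model = make_model(rng, m=m, h=h, k=k, beta=0.7)
    config = TrainingConfig(lambda_m=0.3, lambda_p=300.0, lambda_r=0.1)
    _, _, grads = total_loss_and_grads(v, a, a_norm, model, config)

    eps = 1e-6
    for p_idx, param in enumerate(model.params()):
        numeric = np.zeros_like(param)
        for idx in np.ndindex(param.shape):
            orig = param[idx]
            param[idx] = orig + eps
            up, _, _ = total_loss_and_grads(v, a, a_norm, model, config)
            param[idx] = orig - eps
            down, _, _ = total_loss_and_grads(v, a, a_norm, model, config)
            param[idx] = orig
            numeric[idx] = (up - down) / (2.0 * eps)
        np.testing.assert_allclose(
            grads[p_idx], numeric, rtol=1e-4, atol=1e-7,
            err_msg=f"gradient mismatch in parameter {p_idx}",
        )


# ---------------------------------------------------------------- training


def two_block_graphs():
    """Two spatial blocks with distinct compositions as one NicheGraph-like."""
    from dataclasses import dataclass

    @dataclass
    class G:
        adjacency: sparse.csr_matrix
        composition: np.ndarray
        sample: str = "s0"

    a = sparse.block_diag(
        [np.ones((5, 5)) - np.eye(5), np.ones((5, 5)) - np.eye(5)], format="csr"
    )
    v = np.vstack([np.tile([0.9, 0.1], (5, 1)), np.tile([0.1, 0.9], (5, 1))])
    return [G(adjacency=a, composition=v)]


def exhaustive_two_partition_modularity(a):
    """Best hard 2-partition modularity by enumerating all assignments."""
    n = a.shape[0]
    best = -np.inf
    for bits in itertools.product([0, 1], repeat=n):
        c = np.eye(2)[list(bits)]
        best = max(best, -modularity_loss(c, a))
    return best


def test_training_recovers_two_blocks_and_near_optimal_modularity():
    graphs = two_block_graphs()
    config = TrainingConfig(max_epochs=400, seed=0)
    model, history = train(graphs, n_clusters=2, hidden_dim=4, beta=1.0, config=config)
    assert history["total"][-1] < history["total"][0]
    from nichetraj.pooling import assign_all

    c = assign_all(graphs, model)[0]
    hard = c.argmax(axis=1)
    assert len(set(hard[:5])) == 1 and len(set(hard[5:])) == 1
    assert hard[0] != hard[5]
    c_hard = np.eye(2)[hard]
    achieved = -modularity_loss(c_hard, graphs[0].adjacency)
    optimum = exhaustive_two_partition_modularity(graphs[0].adjacency)
    assert achieved >= 0.95 * optimum


def test_training_is_seed_reproducible():
    graphs = two_block_graphs()
    config = TrainingConfig(max_epochs=50, seed=42)
    m1, h1 = train(graphs, n_clusters=2, config=config)
    m2, h2 = train(graphs, n_clusters=2, config=config)
    for p1, p2 in zip(m1.params(), m2.params()):
        np.testing.assert_array_equal(p1, p2)
    assert h1["total"] == h2["total"]


def test_training_loss_decreases_in_moving_average():
    graphs = two_block_graphs()
    config = TrainingConfig(max_epochs=300, seed=1)
    _, history = train(graphs, n_clusters=2, config=config)
    total = np.array(history["total"])
    head = total[:30].mean()
    tail = total[-30:].mean()
    assert tail < head


def test_train_validates_inputs():
    with pytest.raises(ValueError, match="at least one"):
        train([], n_clusters=2)
    with pytest.raises(ValueError):
        TrainingConfig(lambda_m=-1.0)
    with pytest.raises(ValueError):
        TrainingConfig(max_epochs=0)
    with pytest.raises(ValueError):
        TrainingConfig(modularity_denominator="typo")
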