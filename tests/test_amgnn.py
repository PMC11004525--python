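"""Graph predictor: adjacency primitives, forward contracts, gradients,
episodic training and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aecopd import amgnn as ag


# ---------------------------------------------------------------------------
# constraint matrix

def test_constraint_matrix_hand_example():
    """3 patients, one factor, values [0,1,2] -> min-max similarity."""
    E = ag.constraint_matrix(np.array([[0.0], [1.0], [2.0]]), [1.0])
    expected = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.5], [0.0, 0.5, 1.0]])
    assert np.allclose(E, expected)


def test_constraint_matrix_constant_factor_gives_ones():
    E = ag.constraint_matrix(np.full((4, 1), 3.7), [1.0])
    assert np.allclose(E, 1.0)


def test_constraint_matrix_weighted_sum_linearity(rng):
    r1 = rng.normal(size=(6, 1))
    R = np.hstack([r1, np.full((6, 1), 2.0)])  # factor 2 constant
    E = ag.constraint_matrix(R, [0.5, 0.5])
    S1 = ag.constraint_matrix(r1, [1.0])
    assert np.allclose(E, 0.5 * S1 + 0.5 * np.ones((6, 6)))


def test_constraint_matrix_rejects_negative_weights():
    with pytest.raises(ag.AMGNNError, match="nonnegative"):
        ag.constraint_matrix(np.zeros((3, 2)), [0.5, -0.5])


@settings(deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_constraint_matrix_matches_pairwise_loop(seed):
    rng = np.random.default_rng(seed)
    R = rng.normal(size=(10, 3))
    w = rng.dirichlet(np.ones(3))
    E = ag.constraint_matrix(R, w)
    n = 10
    brute = np.zeros((n, n))
    for f in range(3):
        D = np.array([[abs(R[i, f] - R[j, f]) for j in range(n)] for i in range(n)])
        S = np.ones((n, n)) if D.max() == 0 else 1 - D / D.max()
        brute += w[f] * S
    assert np.allclose(E, brute)
    assert np.allclose(E, E.T)
    assert np.allclose(np.diag(E), 1.0)
    assert E.min() >= -1e-12 and E.max() <= 1 + 1e-12


# ---------------------------------------------------------------------------
# pairwise differences

def test_pairwise_differences_small_cases(rng):
    assert np.allclose(
        ag.pairwise_differences(np.array([[3.0], [5.0]])),
        np.array([[[0.0], [2.0]], [[2.0], [0.0]]]),
    )
    X = np.tile(rng.normal(size=4), (5, 1))
    assert np.allclose(ag.pairwise_differences(X), 0.0)
    X = rng.normal(size=(8, 3))
    T = ag.pairwise_differences(X)
    for i in range(8):
        for j in range(8):
            assert np.allclose(T[i, j], np.abs(X[i] - X[j]))
    assert np.allclose(T, T.transpose(1, 0, 2))


# ---------------------------------------------------------------------------
# episodes

def _toy_nodes(n=30, f_sel=5, k=2, seed=0):
    rng = np.random.default_rng(seed)
    node = rng.normal(size=(n, f_sel + k))
    labels = np.tile([0, 1], n // 2)
    return node, labels, f_sel, k


def test_default_episode_has_21_nodes():
    node, labels, f_sel, k = _toy_nodes()
    ep = ag.sample_episode(node, labels, f_sel, k, np.random.default_rng(0), m=10)
    assert ep.n_nodes == 21
    assert len(ep.support_indices[0]) == len(ep.support_indices[1]) == 10
    assert ep.node_labels[ep.query_index] == -1


def test_minimal_episode_m1():
    node, labels, f_sel, k = _toy_nodes()
    ep = ag.sample_episode(node, labels, f_sel, k, np.random.default_rng(0), m=1)
    assert ep.n_nodes == 3


def test_episode_sampling_determinism():
    node, labels, f_sel, k = _toy_nodes()
    a = ag.sample_episode(node, labels, f_sel, k, np.random.default_rng(9), m=5)
    b = ag.sample_episode(node, labels, f_sel, k, np.random.default_rng(9), m=5)
    assert np.array_equal(a.rows, b.rows)


def test_episode_error_suggests_smaller_m():
    node, labels, f_sel, k = _toy_nodes(n=10)
    with pytest.raises(ag.AMGNNError, match="smaller m"):
        ag.sample_episode(node, labels, f_sel, k, np.random.default_rng(0), m=8)


# ---------------------------------------------------------------------------
# forward contracts

def _toy_model_and_episode(seed=0, m=3):
    node, labels, f_sel, k = _toy_nodes(seed=seed)
    cfg = ag.AMGNNConfig(edge_net_hidden=8, gnn_hidden=4, m_support=m, seed=seed)
    rng = np.random.default_rng(seed)
    params = ag._init_params(f_sel, k, cfg, rng)
    # non-degenerate head so outputs depend on everything
    params["f2_W"] = rng.normal(scale=0.3, size=params["f2_W"].shape)
    params["f2_b"] = rng.normal(scale=0.3, size=2)
    ep = ag.sample_episode(node, labels, f_sel, k, rng, m=m)
    return params, cfg, ep


def test_softmax_rows_sum_to_one():
    params, cfg, ep = _toy_model_and_episode()
    probs = ag.forward(params, ep, cfg)
    assert probs.shape == (ep.n_nodes, 2)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert (probs >= 0).all()


def test_permutation_equivariance():
    params, cfg, ep = _toy_model_and_episode(seed=3)
    probs = ag.forward(params, ep, cfg)
    rng = np.random.default_rng(5)
    perm = rng.permutation(ep.n_nodes)
    ep_p = ag.Episode(
        node_features=ep.node_features[perm],
        node_labels=ep.node_labels[perm],
        support_indices=ep.support_indices,
        query_index=int(np.flatnonzero(perm == ep.query_index)[0]),
        query_label=ep.query_label,
        f_sel=ep.f_sel,
        k=ep.k,
    )
    probs_p = ag.forward(params, ep_p, cfg)
    assert np.allclose(probs_p, probs[perm], atol=1e-10)


def test_identity_graph_is_local():
    """With all off-diagonal constraints zero, each node's output depends
    only on its own features."""
    params, cfg, ep = _toy_model_and_episode(seed=4)
    E = np.eye(ep.n_nodes)
    probs, _ = ag._forward_cache(params, ep, E)
    q = ep.query_index
    perturbed = ep.node_features.copy()
    perturbed[np.arange(ep.n_nodes) != q] += 10.0
    ep2 = ag.Episode(perturbed, ep.node_labels, ep.support_indices, q,
                     ep.query_label, ep.f_sel, ep.k)
    probs2, _ = ag._forward_cache(params, ep2, E)
    assert np.allclose(probs2[q], probs[q], atol=1e-12)


def test_adjacency_invariants():
    params, cfg, ep = _toy_model_and_episode(seed=6)
    E = ag.constraint_matrix(ep.node_features[:, ep.f_sel:], cfg.weights_for(ep.k))
    _, cache = ag._forward_cache(params, ep, E)
    for blk in (cache["b1"], cache["b2"]):
        P = blk["P"]
        pre = P - np.eye(ep.n_nodes)  # before self-loops
        assert (pre >= -1e-12).all()
        assert np.allclose(np.diag(pre), 0.0)
        assert np.allclose(blk["A"].sum(axis=1), 1.0)


def test_dimension_mismatch_raises():
    params, cfg, ep = _toy_model_and_episode()
    bad = ag.Episode(ep.node_features[:, :-1], ep.node_labels,
                     ep.support_indices, ep.query_index, ep.query_label,
                     ep.f_sel - 1, ep.k)
    with pytest.raises(ag.AMGNNError, match="selected features"):
        ag.forward(params, bad, cfg)


# ---------------------------------------------------------------------------
# gradients

def test_backprop_matches_finite_differences():
    """Analytic gradient vs central differences on a 5-node episode."""
    node, labels, f_sel, k = _toy_nodes(n=12, seed=1)
    cfg = ag.AMGNNConfig(edge_net_hidden=6, gnn_hidden=3, m_support=2, seed=1)
    rng = np.random.default_rng(1)
    params = ag._init_params(f_sel, k, cfg, rng)
    params["f2_W"] = rng.normal(scale=0.4, size=params["f2_W"].shape)
    params["f2_b"] = rng.normal(scale=0.4, size=2)
    params["f1_W"][f_sel + k:, :] = rng.normal(scale=0.4, size=(2, 3))
    ep = ag.sample_episode(node, labels, f_sel, k, rng, m=2)
    assert ep.n_nodes == 5
    E = ag.constraint_matrix(ep.node_features[:, f_sel:], cfg.weights_for(k))
    _, grads, _ = ag.loss_and_grads(params, ep, E)
    check_rng = np.random.default_rng(7)
    for name, arr in params.items():
        flat_idx = (
            [()] if arr.ndim == 0
            else [np.unravel_index(i, arr.shape)
                  for i in check_rng.choice(arr.size, size=min(4, arr.size),
                                            replace=False)]
        )
        for idx in flat_idx:
            eps = 1e-6

            def loss_at(v):
                p2 = {k2: v2.copy() for k2, v2 in params.items()}
                if p2[name].ndim:
                    p2[name][idx] = v
                else:
                    p2[name] = np.asarray(v)
                l, _, _ = ag.loss_and_grads(p2, ep, E)
                return l

            base = arr[idx] if arr.ndim else float(arr)
            num = (loss_at(base + eps) - loss_at(base - eps)) / (2 * eps)
            ana = grads[name][idx] if arr.ndim else float(grads[name])
            denom = max(abs(num) + abs(ana), 1e-6)
            assert abs(num - ana) / denom < 1e-4, (name, idx)


# ---------------------------------------------------------------------------
# training and prediction

def test_zero_episodes_returns_initialized_model(selected):
    X, y, risk, _ = selected
    cfg = ag.AMGNNConfig(n_episodes=0, seed=5)
    model = ag.train(X, y, risk, cfg)
    fresh = ag._init_params(model.f_sel, model.k, cfg, np.random.default_rng(5))
    for name in fresh:
        assert np.array_equal(model.params[name], fresh[name])
    assert len(model.loss_trace) == 0


def test_training_is_deterministic(selected):
    X, y, risk, _ = selected
    cfg = ag.AMGNNConfig(n_episodes=30, seed=2)
    m1 = ag.train(X, y, risk, cfg)
    m2 = ag.train(X, y, risk, cfg)
    for name in m1.params:
        assert np.array_equal(m1.params[name], m2.params[name])
    assert np.array_equal(m1.loss_trace, m2.loss_trace)


def test_label_symmetry(selected):
    """Swapping the class labels everywhere swaps the output columns."""
    X, y, risk, _ = selected
    cfg = ag.AMGNNConfig(n_episodes=40, seed=7)
    m1 = ag.train(X, y, risk, cfg)
    m2 = ag.train(X, 1 - y, risk, cfg)
    p1, _ = ag.predict(m1, X[:8], seed=3)
    p2, _ = ag.predict(m2, X[:8], seed=3)
    assert np.allclose(p1, p2[:, ::-1], atol=1e-10)


def test_training_learns_separable_cohort(selected):
    X, y, risk, _ = selected
    cfg = ag.AMGNNConfig(n_episodes=1000, seed=0)
    model = ag.train(X, y, risk, cfg)
    assert model.query_correct_trace[-200:].mean() >= 0.95
    assert model.loss_trace[-50:].mean() < model.loss_trace[:50].mean()


def test_predict_contracts(selected):
    X, y, risk, _ = selected
    cfg = ag.AMGNNConfig(n_episodes=600, seed=1)
    model = ag.train(X, y, risk, cfg)
    probs, classes = ag.predict(model, X[:15], repeats=5, seed=4)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert set(classes) <= {0, 1}
    # query identical to a class-1 training patient -> predicted class 1
    one_row = X[np.flatnonzero(y == 1)[0]][None, :]
    _, c = ag.predict(model, one_row, repeats=10, seed=5)
    assert c[0] == 1
    # determinism
    p2, _ = ag.predict(model, X[:15], repeats=5, seed=4)
    assert np.array_equal(probs, p2)


def test_predict_single_repeat_reduces_to_one_forward(selected):
    X, y, risk, _ = selected
    cfg = ag.AMGNNConfig(n_episodes=50, seed=1)
    model = ag.train(X, y, risk, cfg)
    probs, _ = ag.predict(model, X[:1], repeats=1, seed=9)
    # replicate the single episode by hand with the same generator
    rng = np.random.default_rng(9)
    ep = ag.sample_episode(model.support_features, model.support_labels,
                           model.f_sel, model.k, rng, m=model.config.m_support)
    feats = ep.node_features.copy()
    Xq = (X[:1] - model.mu) / model.sd
    feats[ep.query_index] = ag._node_matrix(Xq, model.risk_indices)[0]
    ep_q = ag.Episode(feats, ep.node_labels, ep.support_indices,
                      ep.query_index, -1, model.f_sel, model.k)
    E = ag.constraint_matrix(feats[:, model.f_sel:],
                             model.config.weights_for(model.k))
    manual, _ = ag._forward_cache(model.params, ep_q, E)
    assert np.allclose(probs[0], manual[ep.query_index], atol=1e-12)


def test_config_validation():
    with pytest.raises(ag.AMGNNError, match="two"):
        ag.AMGNNConfig(n_layers=3)
    with pytest.raises(ag.AMGNNError, match="nonnegative"):
        ag.AMGNNConfig(risk_factor_weights=(-0.5, 1.5))
    cfg = ag.AMGNNConfig(risk_factor_weights=(2.0, 2.0))
    assert np.allclose(cfg.weights_for(2), [0.5, 0.5])
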