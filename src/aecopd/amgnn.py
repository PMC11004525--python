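"""Auto-metric graph neural network with episodic meta-learning.

The predictor classifies one unknown patient (the query) from a small graph of
labeled support patients.  Each episode is a graph of N = 2m + 1 nodes
(m support patients per class plus the query, default m = 10, N = 21).  Node
features are the Lasso-selected columns, the k risk-factor columns appended
again as flagged channels, and a one-hot class channel (query = (1/2, 1/2)).

Edges are built in two parts:

* an *edge constraint matrix* E from risk-factor differences: per factor f,
  D_f[i,j] = |r_if - r_jf| is turned into the min-max similarity
  S_f = 1 - D_f / max(D_f), and E = sum_f w_f S_f with nonnegative weights;
* a *learned edge weight matrix* W: a per-pair MLP (equivalent to stacked 1x1
  convolutions over the N x N grid) applied to the absolute feature
  differences |x_i - x_j|, with a final sigmoid.

The adjacency is A = rownorm(W o E + I) (diagonal of W o E zeroed first).
Two aggregation + fully connected layers follow; the second layer recomputes
W from the hidden representations (the auto-metric step) while E stays fixed.
A softmax head gives class probabilities; training minimizes cross-entropy on
the query node with Adam, carrying parameters from episode to episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .selection import RiskFactorSet, SelectionResult
from .feature_table import FeatureTable

__all__ = [
    "AMGNNConfig",
    "Episode",
    "TrainedAMGNN",
    "constraint_matrix",
    "pairwise_differences",
    "sample_episode",
    "forward",
    "train",
    "predict",
    "train_on_table",
    "predict_on_table",
]


class AMGNNError(ValueError):
    pass


@dataclass
class AMGNNConfig:
    edge_net_hidden: int = 64
    gnn_hidden: int = 32
    n_layers: int = 2
    learning_rate: float = 1e-3
    n_episodes: int = 2000
    m_support: int = 10
    risk_factor_weights: Optional[Sequence[float]] = None  # None -> equal, sum 1
    seed: int = 0

    def __post_init__(self):
        if self.n_layers != 2:
            raise AMGNNError("the predictor uses exactly two aggregation+FC layers")
        if self.risk_factor_weights is not None:
            w = np.asarray(self.risk_factor_weights, dtype=float)
            if (w < 0).any():
                raise AMGNNError("risk_factor_weights must be nonnegative")
            s = w.sum()
            if s <= 0:
                raise AMGNNError("risk_factor_weights must not all be zero")
            self.risk_factor_weights = tuple(w / s)

    def weights_for(self, k: int) -> np.ndarray:
        if self.risk_factor_weights is None:
            return np.full(k, 1.0 / k)
        w = np.asarray(self.risk_factor_weights, dtype=float)
        if len(w) != k:
            raise AMGNNError(f"risk_factor_weights has length {len(w)}, expected {k}")
        return w


@dataclass
class Episode:
    """One support/query graph.

    ``node_features`` holds the selected-feature columns followed by the k
    risk-factor columns; the class channel is appended inside the forward pass
    from ``node_labels`` (-1 marks the masked query).
    """

    node_features: np.ndarray      # N x (f_sel + k)
    node_labels: np.ndarray        # length N; query entry = -1
    support_indices: Dict[int, np.ndarray]
    query_index: int
    query_label: int               # ground truth when known, else -1
    f_sel: int
    k: int
    rows: np.ndarray = None        # source row indices (bookkeeping)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


@dataclass
class TrainedAMGNN:
    params: Dict[str, np.ndarray]
    config: AMGNNConfig
    f_sel: int
    k: int
    risk_indices: np.ndarray       # columns of the selected matrix used as risk factors
    mu: np.ndarray                 # standardization of the selected matrix
    sd: np.ndarray
    support_features: np.ndarray   # standardized training pool, n x (f_sel + k)
    support_labels: np.ndarray
    loss_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    query_correct_trace: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# graph construction primitives

def constraint_matrix(risk_values: np.ndarray, weights: Sequence[float]) -> np.ndarray:
    """Edge constraint E from per-patient risk-factor values.

    Per factor f: D_f[i,j] = |r_if - r_jf|, S_f = 1 - D_f / max(D_f) (all ones
    when the factor is constant); E = sum_f w_f S_f.  With weights summing to
    one, E is symmetric with unit diagonal and entries in [0, 1].
    """
    R = np.atleast_2d(np.asarray(risk_values, dtype=float))
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise AMGNNError("constraint weights must be nonnegative")
    if R.shape[1] != len(w):
        raise AMGNNError("one weight per risk factor required")
    n = R.shape[0]
    E = np.zeros((n, n))
    for f in range(R.shape[1]):
        D = np.abs(R[:, f][:, None] - R[:, f][None, :])
        dmax = D.max()
        S = np.ones((n, n)) if dmax == 0 else 1.0 - D / dmax
        E += w[f] * S
    return E


def pairwise_differences(features: np.ndarray) -> np.ndarray:
    """Absolute pairwise difference tensor T[i, j, :] = |x_i - x_j|."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    return np.abs(X[:, None, :] - X[None, :, :])


# ---------------------------------------------------------------------------
# episode sampling

def _node_matrix(X_sel_std: np.ndarray, risk_indices: np.ndarray) -> np.ndarray:
    """Selected features with the risk-factor columns appended as flagged channels."""
    return np.hstack([X_sel_std, X_sel_std[:, np.asarray(risk_indices, dtype=int)]])


def sample_episode(
    node_features: np.ndarray,
    labels: np.ndarray,
    f_sel: int,
    k: int,
    rng: np.random.Generator,
    m: int = 10,
    query_row: Optional[int] = None,
) -> Episode:
    """Sample one N = 2m + 1 node episode.

    A single label-independent permutation of the pool drives the draw: the
    first m rows of each class (in permutation order) become the support set;
    the query is the supplied row, or the first remaining row otherwise.  This
    makes the sampled graph invariant under a global relabeling of the two
    classes, which the trainer's label-symmetry property relies on.
    """
    labels = np.asarray(labels, dtype=int)
    pool = np.arange(len(labels))
    if query_row is not None:
        pool = pool[pool != query_row]
    for c in (0, 1):
        if np.count_nonzero(labels[pool] == c) < m:
            raise AMGNNError(
                f"class {c} has fewer than m={m} support rows available; "
                "use a smaller m"
            )
    perm = rng.permutation(pool)
    taken = {0: 0, 1: 0}
    nodes, remaining = [], []
    for r in perm:
        c = labels[r]
        if taken[c] < m:
            taken[c] += 1
            nodes.append(r)
        else:
            remaining.append(int(r))
    query = query_row
    if query is None:
        if not remaining:
            raise AMGNNError("no row left to serve as query; reduce m")
        query = remaining[rng.integers(len(remaining))]
    rows = np.array(nodes + [query], dtype=int)
    node_labels = labels[rows].copy()
    qlab = int(node_labels[-1]) if query_row is None else int(labels[query])
    node_labels[-1] = -1
    positions = {c: np.flatnonzero(labels[rows[:-1]] == c) for c in (0, 1)}
    return Episode(
        node_features=node_features[rows],
        node_labels=node_labels,
        support_indices=positions,
        query_index=len(rows) - 1,
        query_label=qlab,
        f_sel=f_sel,
        k=k,
        rows=rows,
    )


# ---------------------------------------------------------------------------
# parameters, forward, backward

def _init_params(f_sel: int, k: int, cfg: AMGNNConfig, rng: np.random.Generator):
    """Uniform fan-in initialization.

    The final classifier layer and the class-channel input rows start at zero,
    which keeps the parameter state invariant under swapping the two classes.
    """
    he, fh = cfg.edge_net_hidden, cfg.gnn_hidden
    f_node = f_sel + k + 2  # + one-hot class channel

    def u(shape, fan_in):
        b = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-b, b, size=shape)

    p = {
        "e1_W1": u((f_sel, he), f_sel),
        "e1_b1": u((he,), f_sel),
        "e1_w2": u((he,), he),
        "e1_b2": u((), he),
        "f1_W": u((f_node, fh), f_node),
        "f1_b": u((fh,), f_node),
        "e2_W1": u((fh, he), fh),
        "e2_b1": u((he,), fh),
        "e2_w2": u((he,), he),
        "e2_b2": u((), he),
        "f2_W": np.zeros((fh, 2)),
        "f2_b": np.zeros(2),
    }
    p["f1_W"][f_sel + k:, :] = 0.0  # class channels
    return p


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _edge_block(D, W1, b1, w2, b2, E):
    """Per-pair MLP -> sigmoid edge weights -> constrained, normalized adjacency."""
    Z = D @ W1 + b1
    Ah = np.tanh(Z)
    u = Ah @ w2 + b2
    W = _sigmoid(u)
    M = W * E
    np.fill_diagonal(M, 0.0)
    P = M + np.eye(M.shape[0])
    rs = P.sum(axis=1)
    A = P / rs[:, None]
    return {"Z": Z, "Ah": Ah, "u": u, "W": W, "P": P, "rs": rs, "A": A}


def _label_channels(node_labels: np.ndarray) -> np.ndarray:
    L = np.full((len(node_labels), 2), 0.5)
    for i, c in enumerate(node_labels):
        if c >= 0:
            L[i] = 0.0
            L[i, c] = 1.0
    return L


def _forward_cache(params, episode: Episode, E: np.ndarray):
    V = np.hstack([episode.node_features, _label_channels(episode.node_labels)])
    S = episode.node_features[:, : episode.f_sel]
    D1 = pairwise_differences(S)
    b1 = _edge_block(
        D1, params["e1_W1"], params["e1_b1"], params["e1_w2"], params["e1_b2"], E
    )
    G1 = b1["A"] @ V
    Q1 = G1 @ params["f1_W"] + params["f1_b"]
    H = np.tanh(Q1)
    D2 = pairwise_differences(H)
    b2 = _edge_block(
        D2, params["e2_W1"], params["e2_b1"], params["e2_w2"], params["e2_b2"], E
    )
    G2 = b2["A"] @ H
    logits = G2 @ params["f2_W"] + params["f2_b"]
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    return probs, {
        "V": V, "D1": D1, "b1": b1, "G1": G1, "H": H,
        "D2": D2, "b2": b2, "G2": G2, "probs": probs, "E": E,
    }


def forward(model_or_params, episode: Episode, config: Optional[AMGNNConfig] = None):
    """Class-probability matrix (N x 2); rows sum to one."""
    if isinstance(model_or_params, TrainedAMGNN):
        params, cfg = model_or_params.params, model_or_params.config
    else:
        params, cfg = model_or_params, config or AMGNNConfig()
    if params["e1_W1"].shape[0] != episode.f_sel:
        raise AMGNNError(
            f"model expects {params['e1_W1'].shape[0]} selected features, "
            f"episode has {episode.f_sel}"
        )
    E = constraint_matrix(
        episode.node_features[:, episode.f_sel:], cfg.weights_for(episode.k)
    )
    probs, _ = _forward_cache(params, episode, E)
    return probs


def _rownorm_backward(dA, A, rs):
    """Backprop through A = P / rowsum(P)."""
    return (dA - (dA * A).sum(axis=1, keepdims=True)) / rs[:, None]


def _edge_block_backward(dA, blk, D, W1, w2, E):
    dP = _rownorm_backward(dA, blk["A"], blk["rs"])
    dM = dP.copy()
    np.fill_diagonal(dM, 0.0)
    dW = dM * E
    du = dW * blk["W"] * (1.0 - blk["W"])
    g_w2 = (blk["Ah"] * du[:, :, None]).sum(axis=(0, 1))
    g_b2 = du.sum()
    dAh = du[:, :, None] * w2
    dZ = dAh * (1.0 - blk["Ah"] ** 2)
    g_W1 = np.tensordot(D, dZ, axes=([0, 1], [0, 1]))
    g_b1 = dZ.sum(axis=(0, 1))
    dD = dZ @ W1.T
    return dD, {"W1": g_W1, "b1": g_b1, "w2": g_w2, "b2": g_b2}


def _abs_diff_backward(dD, X):
    """Backprop through D[i,j] = |x_i - x_j| to the rows of X."""
    SG = np.sign(X[:, None, :] - X[None, :, :])
    T = dD * SG
    return T.sum(axis=1) - T.sum(axis=0)


def loss_and_grads(params, episode: Episode, E: np.ndarray, weight: float = 1.0):
    """(Weighted) cross-entropy on the query node and analytic gradients.

    ``weight`` rescales the query loss; the trainer passes the inverse query
    class frequency so that the minority class is not under-represented in
    the episodic objective.
    """
    probs, c = _forward_cache(params, episode, E)
    q, y = episode.query_index, episode.query_label
    if y not in (0, 1):
        raise AMGNNError("episode query_label must be known (0/1) for training")
    loss = -weight * np.log(max(probs[q, y], 1e-300))

    N = episode.n_nodes
    dL = np.zeros((N, 2))
    dL[q] = weight * probs[q]
    dL[q, y] -= weight

    g = {}
    g["f2_W"] = c["G2"].T @ dL
    g["f2_b"] = dL.sum(axis=0)
    dG2 = dL @ params["f2_W"].T
    dA2 = dG2 @ c["H"].T
    dH = c["b2"]["A"].T @ dG2
    dD2, ge2 = _edge_block_backward(
        dA2, c["b2"], c["D2"], params["e2_W1"], params["e2_w2"], E
    )
    for k_, v in ge2.items():
        g[f"e2_{k_}"] = v
    dH += _abs_diff_backward(dD2, c["H"])
    dQ1 = dH * (1.0 - c["H"] ** 2)
    g["f1_W"] = c["G1"].T @ dQ1
    g["f1_b"] = dQ1.sum(axis=0)
    dG1 = dQ1 @ params["f1_W"].T
    dA1 = dG1 @ c["V"].T
    dD1, ge1 = _edge_block_backward(
        dA1, c["b1"], c["D1"], params["e1_W1"], params["e1_w2"], E
    )
    for k_, v in ge1.items():
        g[f"e1_{k_}"] = v
    return loss, g, probs


# ---------------------------------------------------------------------------
# training and prediction

class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k_, gk in grads.items():
            self.m[k_] = self.b1 * self.m[k_] + (1 - self.b1) * gk
            self.v[k_] = self.b2 * self.v[k_] + (1 - self.b2) * gk ** 2
            mh = self.m[k_] / (1 - self.b1 ** self.t)
            vh = self.v[k_] / (1 - self.b2 ** self.t)
            params[k_] = params[k_] - self.lr * mh / (np.sqrt(vh) + self.eps)


def train(
    X_sel: np.ndarray,
    y: np.ndarray,
    risk_factors: RiskFactorSet,
    config: Optional[AMGNNConfig] = None,
) -> TrainedAMGNN:
    """Episodic meta-learning on a selected-feature matrix.

    Columns are standardized with the training statistics (stored in the model
    for prediction).  For each of ``config.n_episodes`` iterations an episode
    is sampled, the query cross-entropy is backpropagated, and one Adam step
    taken; parameters persist across episodes.
    """
    cfg = config or AMGNNConfig()
    X_sel = np.atleast_2d(np.asarray(X_sel, dtype=float))
    y = np.asarray(y, dtype=int)
    if X_sel.shape[1] == 0:
        raise AMGNNError("selected-feature matrix has no columns")
    mu = X_sel.mean(axis=0)
    sd = X_sel.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X_sel - mu) / sd
    risk_idx = np.asarray(risk_factors.factor_indices, dtype=int)
    node = _node_matrix(Xs, risk_idx)
    f_sel, k = Xs.shape[1], len(risk_idx)

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(f_sel, k, cfg, rng)
    opt = _Adam(params, cfg.learning_rate)
    w = cfg.weights_for(k)
    # inverse-frequency weights: queries follow the cohort's class ratio, so
    # the episodic loss re-balances the two classes
    counts = np.bincount(y, minlength=2)
    class_w = len(y) / (2.0 * np.maximum(counts, 1))
    losses, correct = [], []
    for _ in range(cfg.n_episodes):
        ep = sample_episode(node, y, f_sel, k, rng, m=cfg.m_support)
        E = constraint_matrix(ep.node_features[:, f_sel:], w)
        loss, grads, probs = loss_and_grads(
            params, ep, E, weight=class_w[ep.query_label]
        )
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at episode {len(losses)}; "
                "lower the learning rate or check the inputs"
            )
        pred = 0 if probs[ep.query_index, 0] >= probs[ep.query_index, 1] else 1
        losses.append(loss)
        correct.append(pred == ep.query_label)
        opt.step(params, grads)
    return TrainedAMGNN(
        params=params,
        config=cfg,
        f_sel=f_sel,
        k=k,
        risk_indices=risk_idx,
        mu=mu,
        sd=sd,
        support_features=node,
        support_labels=y.copy(),
        loss_trace=np.array(losses),
        query_correct_trace=np.array(correct, dtype=bool),
    )


def predict(
    model: TrainedAMGNN,
    X_query: np.ndarray,
    repeats: int = 10,
    seed: int = 0,
):
    """Average query-node probabilities over ``repeats`` resampled episodes.

    ``X_query`` is a rows x selected-features matrix on the raw scale of the
    training matrix.  Returns ``(probs, classes)``; ties at 0.5 classify as
    class 0 (stable).
    """
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    if X_query.shape[1] != model.f_sel:
        raise AMGNNError(
            f"query matrix has {X_query.shape[1]} columns, model expects {model.f_sel}"
        )
    Xq = (X_query - model.mu) / model.sd
    nodes_q = _node_matrix(Xq, model.risk_indices)
    rng = np.random.default_rng(seed)
    w = model.config.weights_for(model.k)
    m = model.config.m_support
    pool_feats = model.support_features
    pool_labels = model.support_labels
    out = np.zeros((X_query.shape[0], 2))
    for i in range(X_query.shape[0]):
        acc = np.zeros(2)
        for _ in range(repeats):
            ep = sample_episode(pool_feats, pool_labels, model.f_sel, model.k, rng, m=m)
            # replace the sampled training query node by the external query
            feats = ep.node_features.copy()
            feats[ep.query_index] = nodes_q[i]
            ep_q = Episode(
                node_features=feats,
                node_labels=ep.node_labels,
                support_indices=ep.support_indices,
                query_index=ep.query_index,
                query_label=-1,
                f_sel=model.f_sel,
                k=model.k,
            )
            E = constraint_matrix(feats[:, model.f_sel:], w)
            probs, _ = _forward_cache(model.params, ep_q, E)
            acc += probs[ep.query_index]
        out[i] = acc / repeats
    classes = (out[:, 1] > out[:, 0]).astype(int)
    return out, classes


# ---------------------------------------------------------------------------
# table-level wrappers

def train_on_table(
    table: FeatureTable,
    selection: SelectionResult,
    risk_factors: RiskFactorSet,
    config: Optional[AMGNNConfig] = None,
    train_rows: Optional[Sequence[int]] = None,
) -> TrainedAMGNN:
    rows = np.arange(table.n_patients) if train_rows is None else np.asarray(train_rows)
    X = table.values[np.ix_(rows, selection.selected_indices)]
    return train(X, table.labels[rows], risk_factors, config)


def predict_on_table(
    model: TrainedAMGNN,
    table: FeatureTable,
    selection: SelectionResult,
    query_rows: Sequence[int],
    repeats: int = 10,
    seed: int = 0,
):
    rows = np.asarray(query_rows, dtype=int)
    X = table.values[np.ix_(rows, selection.selected_indices)]
    return predict(model, X, repeats=repeats, seed=seed)
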