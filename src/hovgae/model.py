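"""Higher-order variational graph auto-encoder for PPI link prediction.

The encoder stacks higher-order graph convolutions (personalized-PageRank
propagation followed by a learned linear map and ReLU) and ends in two
parallel linear heads producing per-node Gaussian parameters mu and
log sigma.  A latent embedding Z is sampled with the reparameterization
trick and decoded by an inner product: p(a_ij = 1) = sigmoid(z_i . z_j).

Training minimizes

    L = balanced reconstruction cross-entropy + KL(q(Z) || N(0, I)) + v * L2,

full-batch, with Adam.  The reconstruction term reweights positive and
negative entries by 1/d and 1/(1-d) (d = density of the target adjacency)
so that the sparse positive class is not drowned out.  The model is
topology-only: node features are the identity matrix, so the first
propagation input is I and propagate(I) can be precomputed once.

All gradients are computed by hand-written backpropagation (the
propagation operator is linear and self-adjoint, which makes its adjoint
free); correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .graph import Graph, normalize_adjacency
from .heuristics import ScoreTable, top_t_l3_candidates, expand_adjacency, _pair_indices
from .propagation import PropagationConfig, propagate

__all__ = [
    "EncoderParams",
    "LatentEmbedding",
    "TrainConfig",
    "identity_features",
    "encode",
    "reparameterize",
    "decode",
    "balanced_reconstruction_loss",
    "kl_loss",
    "l2_reg",
    "total_loss",
    "train",
    "predict_scores",
    "HOVGAEModel",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------- containers


@dataclass
class EncoderParams:
    """Trainable weights: shared hidden layers plus parallel mu / log-sigma heads."""

    hidden: list[np.ndarray]
    W_mu: np.ndarray
    W_logsigma: np.ndarray
    dropout: float = 0.5
    v: float = 1e-5

    @property
    def weights(self) -> list[np.ndarray]:
        return [*self.hidden, self.W_mu, self.W_logsigma]

    @property
    def f(self) -> int:
        return self.W_mu.shape[1]


@dataclass
class LatentEmbedding:
    """Per-node Gaussian parameters and a sampled embedding of width f."""

    mu: np.ndarray
    log_sigma: np.ndarray
    Z: np.ndarray

    @property
    def f(self) -> int:
        return self.mu.shape[1]


@dataclass
class TrainConfig:
    """Hyper-parameters of a training run.

    ``layer_widths`` gives hidden widths then embedding width f; the
    defaults are a 3-layer encoder 256-128-64.  ``cotrain_t`` > 0 switches
    on A^3 co-training: the t strongest non-edges by raw 3-hop walk count
    are added to the reconstruction target (and only there, unless
    ``cotrain_in_propagation`` is set).
    """

    learning_rate: float = 0.01
    max_iters: int = 300
    early_stop_window: int = 2
    min_iters: int = 10
    seed: int = 0
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    cotrain_t: int = 0
    cotrain_in_propagation: bool = False
    layer_widths: tuple[int, ...] = (256, 128, 64)
    dropout: float = 0.5
    v: float = 1e-5
    include_diagonal: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_iters <= 0:
            raise ValueError("learning_rate and max_iters must be positive")
        if len(self.layer_widths) < 2:
            raise ValueError("need at least one hidden layer plus the embedding width")


# ------------------------------------------------------------- model pieces


def identity_features(n: int) -> sp.csr_matrix:
    """Sparse n x n identity used as the (featureless) node input matrix."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sp.identity(n, format="csr")


def glorot_init(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def embedding_init(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance uniform init for the first (embedding-lookup) layer.

    With identity node features the first weight matrix is a per-node
    embedding table: each one-hot input row selects one row of W.  Glorot's
    fan-in term assumes n unit-variance input coordinates, but a one-hot
    row carries unit total energy, so Glorot shrinks the first layer by
    ~1/sqrt(n) and starves deep encoders of signal.  Embedding tables are
    conventionally initialized at unit scale instead.
    """
    return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=shape)


def init_params(n: int, cfg: TrainConfig, rng: np.random.Generator) -> EncoderParams:
    widths = [n, *cfg.layer_widths]
    hidden = [
        embedding_init((widths[0], widths[1]), rng) if i == 0
        else glorot_init((widths[i], widths[i + 1]), rng)
        for i in range(len(widths) - 2)
    ]
    f = widths[-1]
    W_mu = glorot_init((widths[-2], f), rng)
    W_ls = glorot_init((widths[-2], f), rng)
    return EncoderParams(hidden=hidden, W_mu=W_mu, W_logsigma=W_ls, dropout=cfg.dropout, v=cfg.v)


def encode(
    X,
    A_norm: sp.spmatrix,
    params: EncoderParams,
    cfg: PropagationConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the encoder: shared ReLU hidden layers, linear mu / log-sigma heads.

    Dropout (inverted, rate ``params.dropout``) is applied to hidden
    activations only, and only when ``training`` is set.
    """
    mu, log_sigma, _ = _forward(X, A_norm, params, cfg, training=training, rng=rng)[:3]
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(log_sigma))):
        raise FloatingPointError("non-finite encoder output")
    return mu, log_sigma


def reparameterize(mu: np.ndarray, log_sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Z = mu + exp(log_sigma) * eps with eps ~ N(0, I)."""
    if mu.shape != log_sigma.shape:
        raise ValueError("mu and log_sigma shapes differ")
    eps = rng.standard_normal(mu.shape)
    return mu + np.exp(log_sigma) * eps


def decode(Z: np.ndarray) -> np.ndarray:
    """Edge-probability matrix sigmoid(Z Z^T); symmetric by construction."""
    return _sigmoid(Z @ Z.T)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def balanced_reconstruction_loss(
    logits: np.ndarray,
    target: np.ndarray,
    d: float,
) -> float:
    """Class-balanced cross-entropy between logits and a binary target matrix.

    Positive entries are weighted 1/d and negative entries 1/(1-d), so the
    two classes contribute equally despite the extreme sparsity of PPI
    adjacencies.  Computed stably from logits via softplus; the sum runs
    over every (ordered) entry of the target, diagonal included when the
    caller put self-loops there.
    """
    if not (0.0 < d < 1.0):
        raise ValueError(f"density d must be in (0, 1), got {d}")
    w_pos = target / d
    w_neg = (1.0 - target) / (1.0 - d)
    return float(np.sum(w_pos * _softplus(-logits) + w_neg * _softplus(logits)))


def _balanced_loss_grad(logits: np.ndarray, target: np.ndarray, d: float) -> np.ndarray:
    s = _sigmoid(logits)
    return (target / d) * (s - 1.0) + ((1.0 - target) / (1.0 - d)) * s


def kl_loss(mu: np.ndarray, log_sigma: np.ndarray) -> float:
    """KL divergence of the factorized Gaussian posterior from N(0, I)."""
    if mu.shape != log_sigma.shape:
        raise ValueError("mu and log_sigma shapes differ")
    sigma2 = np.exp(2.0 * log_sigma)
    return float(0.5 * np.sum(mu**2 + sigma2 - 2.0 * log_sigma - 1.0))


def l2_reg(params: EncoderParams) -> float:
    """Half the summed squared Frobenius norms of all weight matrices."""
    return float(0.5 * sum(np.sum(W**2) for W in params.weights))


def total_loss(recon: float, kl: float, reg: float, v: float) -> float:
    """Total minimization objective: recon + kl + v * reg."""
    return recon + kl + v * reg


# ------------------------------------------------------ forward / backward


def _forward(
    X,
    A_norm: sp.spmatrix,
    params: EncoderParams,
    cfg: PropagationConfig,
    training: bool,
    rng: np.random.Generator | None,
    P0: np.ndarray | None = None,
):
    """Encoder forward pass; returns (mu, log_sigma, cache) for backprop.

    ``P0`` optionally caches propagate(X) (constant across iterations when
    X is the identity).  The cache stores, per layer, the dropout mask, the
    propagated input P_l and the post-activation H_l.
    """
    if P0 is None:
        P0 = np.asarray(propagate(X.toarray() if sp.issparse(X) else X, A_norm, cfg))
    masks: list[np.ndarray | None] = [None]  # no dropout on the input features
    Ps: list[np.ndarray] = [P0]
    Hs: list[np.ndarray] = []
    H = np.maximum(P0 @ params.hidden[0], 0.0)
    Hs.append(H)
    for W in params.hidden[1:]:
        H, mask = _dropout(H, params.dropout, training, rng)
        masks.append(mask)
        P = propagate(H, A_norm, cfg)
        Ps.append(P)
        H = np.maximum(P @ W, 0.0)
        Hs.append(H)
    H, mask = _dropout(Hs[-1], params.dropout, training, rng)
    masks.append(mask)
    P_last = propagate(H, A_norm, cfg)
    Ps.append(P_last)
    mu = P_last @ params.W_mu
    log_sigma = P_last @ params.W_logsigma
    cache = {"masks": masks, "Ps": Ps, "Hs": Hs}
    return mu, log_sigma, cache


def _dropout(H, rate, training, rng):
    if training and rate > 0.0:
        mask = (rng.random(H.shape) >= rate) / (1.0 - rate)
        return H * mask, mask
    return H, None


def loss_and_grads(
    params: EncoderParams,
    A_norm: sp.spmatrix,
    cfg: PropagationConfig,
    target: np.ndarray,
    d: float,
    eps: np.ndarray,
    P0: np.ndarray,
    training: bool = True,
    rng: np.random.Generator | None = None,
):
    """One full forward/backward pass with a fixed noise draw eps.

    Returns (loss components dict, gradient list aligned with
    ``params.weights``).  Exposing eps explicitly keeps the pass
    deterministic for finite-difference verification.
    """
    mu, log_sigma, cache = _forward(
        None, A_norm, params, cfg, training=training, rng=rng, P0=P0
    )
    sigma = np.exp(log_sigma)
    Z = mu + sigma * eps
    logits = Z @ Z.T
    recon = balanced_reconstruction_loss(logits, target, d)
    kl = kl_loss(mu, log_sigma)
    reg = l2_reg(params)
    loss = total_loss(recon, kl, reg, params.v)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")

    # --- backward ---
    G = _balanced_loss_grad(logits, target, d)
    dZ = (G + G.T) @ Z
    dmu = dZ + mu  # KL: d/dmu = mu
    dlog_sigma = dZ * sigma * eps + (sigma**2 - 1.0)  # KL: d/dlogsig = sig^2 - 1

    P_last = cache["Ps"][-1]
    grads_mu = P_last.T @ dmu
    grads_ls = P_last.T @ dlog_sigma
    dP_last = dmu @ params.W_mu.T + dlog_sigma @ params.W_logsigma.T
    # propagation operator is self-adjoint (polynomial in symmetric A_norm)
    dH = propagate(dP_last, A_norm, cfg)
    mask = cache["masks"][-1]
    if mask is not None:
        dH = dH * mask

    grads_hidden: list[np.ndarray] = []
    for l in range(len(params.hidden) - 1, -1, -1):
        H_l = cache["Hs"][l]
        P_l = cache["Ps"][l]
        dM = dH * (H_l > 0)
        grads_hidden.append(P_l.T @ dM)
        if l > 0:
            dH = propagate(dM @ params.hidden[l].T, A_norm, cfg)
            m = cache["masks"][l]
            if m is not None:
                dH = dH * m
    grads_hidden.reverse()

    grads = [*grads_hidden, grads_mu, grads_ls]
    grads = [g + params.v * W for g, W in zip(grads, params.weights)]
    components = {"recon": recon, "kl": kl, "reg": reg, "total": loss}
    return components, grads, (mu, log_sigma, Z)


class _Adam:
    """Minimal Adam optimizer over a list of ndarray parameters."""

    def __init__(self, shapes, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, weights, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for W, g, m, v in zip(weights, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            W -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ----------------------------------------------------------------- training


#: smoothing factor of the exponentially averaged validation loss used by
#: early stopping (time constant of about three iterations)
_VAL_EMA = 0.7


def _validation_loss(mu: np.ndarray, val_pos, val_neg) -> float:
    """Mean cross-entropy of deterministic mu-based scores on held-out pairs."""
    pairs = list(val_pos) + list(val_neg)
    y = np.array([1.0] * len(val_pos) + [0.0] * len(val_neg))
    logits = np.array([mu[i] @ mu[j] for i, j in pairs])
    return float(np.mean(y * _softplus(-logits) + (1.0 - y) * _softplus(logits)))


def train(
    train_graph: Graph,
    cfg: TrainConfig,
    val_pos=None,
    val_neg=None,
) -> tuple[EncoderParams, LatentEmbedding, list[dict]]:
    """Fit the model on a training graph by full-batch Adam.

    Weights are Glorot-initialized from ``cfg.seed``.  With co-training
    enabled the reconstruction target is the A^3-expanded adjacency while
    propagation stays on the original training graph (the default reading;
    ``cotrain_in_propagation`` flips propagation onto the expanded graph
    too).  Training stops at ``max_iters`` or when the validation loss has
    failed to decrease for ``early_stop_window`` consecutive iterations.

    Returns the fitted parameters, a deterministic mu-based embedding for
    inference (Z = mu), and a per-iteration loss trace.
    """
    if train_graph.n < 1 or train_graph.n_edges < 1:
        raise ValueError("training graph must have at least one edge")
    rng = np.random.default_rng(cfg.seed)
    n = train_graph.n

    target_graph = train_graph
    if cfg.cotrain_t > 0:
        extra = top_t_l3_candidates(train_graph, cfg.cotrain_t)
        target_graph = expand_adjacency(train_graph, extra)
    prop_graph = target_graph if (cfg.cotrain_t > 0 and cfg.cotrain_in_propagation) else train_graph

    A_norm = normalize_adjacency(prop_graph)
    target = target_graph.A.toarray().astype(float)
    if cfg.include_diagonal:
        np.fill_diagonal(target, 1.0)
        d = (target_graph.A.nnz + n) / float(n) ** 2
    else:
        d = target_graph.A.nnz / float(n) ** 2
    if not (0.0 < d < 1.0):
        raise ValueError(f"degenerate target density d={d}")

    params = init_params(n, cfg, rng)
    X = identity_features(n)
    P0 = np.asarray(propagate(X.toarray(), A_norm, cfg.propagation))
    opt = _Adam([W.shape for W in params.weights], lr=cfg.learning_rate)

    trace: list[dict] = []
    prev_val = np.inf
    best_ema = np.inf
    best_weights = None
    ema = None
    stall = 0
    use_val = val_pos is not None and val_neg is not None
    for it in range(cfg.max_iters):
        eps = rng.standard_normal((n, params.f))
        comps, grads, (mu, log_sigma, _) = loss_and_grads(
            params, A_norm, cfg.propagation, target, d, eps, P0, training=True, rng=rng
        )
        opt.step(params.weights, grads)
        rec = {"iter": it, **comps}
        if use_val:
            mu_eval, _ = encode(X, A_norm, params, cfg.propagation, training=False)
            rec["val_loss"] = _validation_loss(mu_eval, val_pos, val_neg)
            # dropout + reparameterization noise makes the raw per-iteration
            # validation loss jitter, so the stopping rule (no decrease for
            # early_stop_window consecutive iterations) is applied to an
            # exponentially smoothed loss; stopping is armed only after a
            # short warm-up because the first Adam steps overshoot
            ema = rec["val_loss"] if ema is None else _VAL_EMA * ema + (1.0 - _VAL_EMA) * rec["val_loss"]
            stall = stall + 1 if ema >= prev_val - 1e-12 else 0
            prev_val = ema
            if ema < best_ema:
                best_ema = ema
                best_weights = [W.copy() for W in params.weights]
        trace.append(rec)
        if use_val and it + 1 >= cfg.min_iters and stall >= cfg.early_stop_window:
            break
    if use_val and best_weights is not None:
        # classic early stopping returns the best model seen, not the last
        for W, Wb in zip(params.weights, best_weights):
            W[...] = Wb

    mu, log_sigma = encode(X, A_norm, params, cfg.propagation, training=False)
    embedding = LatentEmbedding(mu=mu, log_sigma=log_sigma, Z=mu.copy())
    return params, embedding, trace


def predict_scores(embedding: LatentEmbedding, pairs, g: Graph) -> ScoreTable:
    """Score queried pairs with sigmoid(mu_i . mu_j) (deterministic inference)."""
    idx = _pair_indices(g, pairs)
    mu = embedding.mu
    scores = [float(_sigmoid(np.array(mu[i] @ mu[j]))) for i, j in idx]
    entries = []
    for (i, j), s in zip(idx, scores):
        if j < i:
            i, j = j, i
        entries.append((g.node_ids[i], g.node_ids[j], s))
    return ScoreTable(entries=entries, method="hovgae")


# --------------------------------------------------------------- high level


class HOVGAEModel:
    """fit/score wrapper tying a training run to its graph's label map."""

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.graph: Graph | None = None
        self.embedding: LatentEmbedding | None = None
        self.params: EncoderParams | None = None
        self.trace: list[dict] = []

    def fit(self, g: Graph, val_pos=None, val_neg=None) -> "HOVGAEModel":
        self.graph = g
        self.params, self.embedding, self.trace = train(g, self.cfg, val_pos, val_neg)
        return self

    def score_pairs(self, pairs) -> np.ndarray:
        if self.embedding is None:
            raise RuntimeError("model not fitted")
        idx = _pair_indices(self.graph, pairs)
        mu = self.embedding.mu
        logits = np.array([mu[i] @ mu[j] for i, j in idx])
        return _sigmoid(logits)


def save_checkpoint(path, model: HOVGAEModel) -> None:
    """Single-archive checkpoint: node-label map, config, weight matrices (v1)."""
    meta = {
        "format_version": 1,
        "node_ids": model.graph.node_ids,
        "config": {
            **{k: v for k, v in asdict(model.cfg).items() if k != "propagation"},
            "propagation": asdict(model.cfg.propagation),
        },
        "n_hidden": len(model.params.hidden),
    }
    edges = np.array(sorted(model.graph.edge_set()), dtype=np.int64).reshape(-1, 2)
    arrays = {f"hidden_{i}": W for i, W in enumerate(model.params.hidden)}
    arrays["edges"] = edges
    arrays["W_mu"] = model.params.W_mu
    arrays["W_logsigma"] = model.params.W_logsigma
    arrays["mu"] = model.embedding.mu
    arrays["log_sigma"] = model.embedding.log_sigma
    # np.savez appends ".npz" to bare paths, which breaks atomic
    # temp-then-rename writes; an open handle is used verbatim
    with open(path, "wb") as fh:
        np.savez(fh, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> HOVGAEModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg_d = dict(meta["config"])
        cfg_d["propagation"] = PropagationConfig(**cfg_d["propagation"])
        cfg_d["layer_widths"] = tuple(cfg_d["layer_widths"])
        cfg = TrainConfig(**cfg_d)
        model = HOVGAEModel(cfg)
        hidden = [np.array(data[f"hidden_{i}"]) for i in range(meta["n_hidden"])]
        model.params = EncoderParams(
            hidden=hidden,
            W_mu=np.array(data["W_mu"]),
            W_logsigma=np.array(data["W_logsigma"]),
            dropout=cfg.dropout,
            v=cfg.v,
        )
        mu = np.array(data["mu"])
        model.embedding = LatentEmbedding(
            mu=mu, log_sigma=np.array(data["log_sigma"]), Z=mu.copy()
        )
        node_ids = list(meta["node_ids"])
        edges = [tuple(e) for e in np.array(data["edges"]).reshape(-1, 2)]
        model.graph = Graph.from_edges(node_ids, edges)
    return model
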