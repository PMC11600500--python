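"""Locality-aware invariant point attention network for RNA quality scoring.

The scorer embeds per-nucleotide features and per-edge pair features, runs
a stack of invariant point attention (IPA) layers whose attention is
restricted to each nucleotide's k nearest neighbours and biased by the
edge embeddings, and maps the final representation through a linear layer
plus a two-layer MLP with a logistic output to a predicted per-nucleotide
lDDT (pNuL) in (0, 1). The molecule-level score (pMoL) is the arithmetic
mean of pNuL.

Attention logits for head ``h`` over the neighbourhood N(i) are

    w_L * ( q_i . k_j / sqrt(c/H)  +  b_ij  -  gamma_h * w_C / 2 *
            sum_p || T_i o q_p_i - T_j o k_p_j ||^2 )

with w_L = sqrt(1/3), w_C = sqrt(2 / (9 Q)) and gamma_h a learned per-head
scalar (unit at initialisation). Query/key/value points live in each
nucleotide's local frame and are compared in the global frame; outputs are
mapped back through T_i^{-1}, which makes every layer — and hence the whole
network — invariant to global rotations and translations of the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, einsum, softmax, layer_norm, concatenate
from .features import (
    DEFAULT_K,
    N_NODE_FEATURES,
    RBF_COUNT,
    edge_features,
    knn_graph,
    nucleotide_features,
)
from .frames import frames_from_structure, stack_frames

_NORM_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the published model)."""

    n_layers: int = 4
    n_heads: int = 4
    hidden: int = 128
    n_query_points: int = 8
    n_value_points: int = 4
    K: int = DEFAULT_K
    rbf_count: int = RBF_COUNT
    dropout: float = 0.1

    def __post_init__(self):
        for name, v in asdict(self).items():
            if name != "dropout" and v <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.hidden % self.n_heads:
            raise ValueError("hidden width must be divisible by n_heads")

    @property
    def head_width(self) -> int:
        return self.hidden // self.n_heads

    @property
    def n_pair_features(self) -> int:
        return 5 + 9 * self.rbf_count

    @property
    def concat_width(self) -> int:
        H, c, V = self.n_heads, self.hidden, self.n_value_points
        return H * self.head_width + H * c + H * V * 3 + H * V

    @property
    def w_L(self) -> float:
        return float(np.sqrt(1.0 / 3.0))

    @property
    def w_C(self) -> float:
        return float(np.sqrt(2.0 / (9.0 * self.n_query_points)))


@dataclass(frozen=True)
class QualityPrediction:
    """pNuL vector in (0,1) and its mean, pMoL."""

    pnul: np.ndarray
    pmol: float


def init_model(config: ModelConfig, seed: int) -> dict[str, Tensor]:
    """Deterministically seeded parameter set; same seed, same bits."""
    rng = np.random.default_rng(seed)
    H, c, ch = config.n_heads, config.hidden, config.head_width
    Q, V = config.n_query_points, config.n_value_points

    def lin(name, fan_in, fan_out, params):
        params[f"{name}_W"] = ad.parameter(rng.normal(0.0, 1.0 / np.sqrt(fan_in), (fan_in, fan_out)))
        params[f"{name}_b"] = ad.parameter(np.zeros(fan_out))

    p: dict[str, Tensor] = {}
    lin("node_proj", N_NODE_FEATURES, c, p)
    lin("pair_proj", config.n_pair_features, c, p)
    for l in range(config.n_layers):
        pre = f"l{l}."
        for nm, fo in (("q", H * ch), ("k", H * ch), ("v", H * ch),
                       ("qp", H * Q * 3), ("kp", H * Q * 3), ("vp", H * V * 3)):
            p[f"{pre}{nm}_W"] = ad.parameter(rng.normal(0.0, 1.0 / np.sqrt(c), (c, fo)))
        lin(f"{pre}bias", c, H, p)
        # plain learned per-head point weighting, unit at init; an all-zero
        # parameter set therefore collapses to exactly uniform attention
        p[f"{pre}gamma"] = ad.parameter(np.ones(H))
        lin(f"{pre}out", config.concat_width, c, p)
        p[f"{pre}ln_g"] = ad.parameter(np.ones(c))
        p[f"{pre}ln_b"] = ad.parameter(np.zeros(c))
    lin("final", c, c, p)
    lin("mlp1", c, c, p)
    lin("mlp2", c, 1, p)
    return p


def parameter_count(config: ModelConfig) -> int:
    """Total scalar parameters — a pure function of the config (K-independent)."""
    return sum(t.data.size for t in init_model(config, 0).values())


def _linear(x: Tensor, params, name: str) -> Tensor:
    sub = "".join(chr(ord("i") + n) for n in range(x.ndim - 1))
    out = einsum(f"{sub}a,ab->{sub}b", x, params[f"{name}_W"])
    bias = params.get(f"{name}_b")  # q/k/v and point maps are bias-free
    return out if bias is None else out + bias


def _to_global(R: Tensor, t: Tensor, pts: Tensor) -> Tensor:
    """Apply per-nucleotide frames to local points, shape (L, H, P, 3)."""
    return einsum("lxy,lhpy->lhpx", R, pts) + t.reshape(t.shape[0], 1, 1, 3)


def attention_weights(params, layer: int, config: ModelConfig,
                      s: Tensor, e: Tensor, R: Tensor, t: Tensor,
                      neighbors: np.ndarray) -> Tensor:
    """Attention weights a_ij^h over each neighbourhood, shape (L, k, H).

    Rows are normalised by a softmax over the k locality edges; with
    all-zero projections and unit gammas acting on zero points the weights
    are exactly uniform 1/|N(i)|.
    """
    L = s.shape[0]
    H, ch = config.n_heads, config.head_width
    Q = config.n_query_points
    q = _linear(s, params, f"l{layer}.q").reshape(L, H, ch)
    k = _linear(s, params, f"l{layer}.k").reshape(L, H, ch)
    qp = _to_global(R, t, _linear(s, params, f"l{layer}.qp").reshape(L, H, Q, 3))
    kp = _to_global(R, t, _linear(s, params, f"l{layer}.kp").reshape(L, H, Q, 3))

    k_nbr = k[neighbors]                      # (L, k, H, ch)
    qk = einsum("lhc,lmhc->lmh", q, k_nbr) * (1.0 / np.sqrt(ch))
    bias = _linear(e, params, f"l{layer}.bias")  # (L, k, H)
    kp_nbr = kp[neighbors]                    # (L, k, H, Q, 3)
    diff = qp.reshape(L, 1, H, Q, 3) - kp_nbr
    sq = (diff * diff).sum(axis=-1).sum(axis=-1)  # (L, k, H)
    gamma = params[f"l{layer}.gamma"]
    logits = (qk + bias - sq * gamma * (config.w_C / 2.0)) * config.w_L
    return softmax(logits, axis=1)


def ipa_layer(params, layer: int, config: ModelConfig,
              s: Tensor, e: Tensor, R: Tensor, t: Tensor,
              neighbors: np.ndarray, dropout_mask: np.ndarray | None = None) -> Tensor:
    """One IPA update: attention outputs (scalar, pair, point, point-norm)
    concatenated, projected, added residually and layer-normalised."""
    L = s.shape[0]
    H, c, ch = config.n_heads, config.hidden, config.head_width
    V = config.n_value_points

    a = attention_weights(params, layer, config, s, e, R, t, neighbors)
    v = _linear(s, params, f"l{layer}.v").reshape(L, H, ch)
    vp = _to_global(R, t, _linear(s, params, f"l{layer}.vp").reshape(L, H, V, 3))

    o = einsum("lmh,lmhc->lhc", a, v[neighbors])
    oe = einsum("lmh,lmc->lhc", a, e)
    op_g = einsum("lmh,lmhvx->lhvx", a, vp[neighbors])
    # back to the local frame: R_i^T (o_g - t_i)
    op = einsum("lyx,lhvy->lhvx", R, op_g - t.reshape(L, 1, 1, 3))
    norms = ((op * op).sum(axis=-1) + _NORM_EPS).sqrt()

    update = _linear(
        concatenate([o.reshape(L, H * ch), oe.reshape(L, H * c),
                     op.reshape(L, H * V * 3), norms.reshape(L, H * V)], axis=-1),
        params, f"l{layer}.out",
    )
    if dropout_mask is not None:
        update = update * Tensor(dropout_mask)
    return layer_norm(s + update, params[f"l{layer}.ln_g"], params[f"l{layer}.ln_b"])


def forward(params, config: ModelConfig, node_feats: np.ndarray, edge_feats: np.ndarray,
            neighbors: np.ndarray, R: np.ndarray, t: np.ndarray,
            rng: np.random.Generator | None = None) -> Tensor:
    """Full network pass returning the pNuL Tensor of shape (L,).

    ``rng`` enables dropout (training); ``None`` runs deterministic inference.
    """
    s = _linear(Tensor(node_feats), params, "node_proj")
    e = _linear(Tensor(edge_feats), params, "pair_proj")
    Rt, tt = Tensor(R), Tensor(t)
    p = config.dropout
    for l in range(config.n_layers):
        mask = None
        if rng is not None and p > 0:
            mask = (rng.random((s.shape[0], config.hidden)) >= p) / (1.0 - p)
        s = ipa_layer(params, l, config, s, e, Rt, tt, neighbors, mask)
    h = _linear(s, params, "final").relu()
    h = _linear(h, params, "mlp1").relu()
    logits = _linear(h, params, "mlp2")
    return logits.sigmoid().reshape(-1)


def structure_inputs(structure, config: ModelConfig):
    """Features, locality graph and stacked frames for one structure."""
    node = nucleotide_features(structure)
    graph = knn_graph(structure, config.K)
    edge = edge_features(structure, graph)
    R, t = stack_frames(frames_from_structure(structure))
    return node, edge, graph.neighbors, R, t


def predict(structure, params, config: ModelConfig) -> QualityPrediction:
    """Score one structure: per-nucleotide pNuL and their mean, pMoL."""
    node, edge, nbr, R, t = structure_inputs(structure, config)
    pnul = forward(params, config, node, edge, nbr, R, t, rng=None).data
    return QualityPrediction(pnul=pnul, pmol=float(pnul.mean()))


# ---- serialisation -----------------------------------------------------------

def save_params(params: dict[str, Tensor], config: ModelConfig, path, seed: int | None = None) -> None:
    """Serialise weights with the config (and seed, if given) recorded."""
    meta = {"config": asdict(config), "seed": seed}
    np.savez(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **{k: v.data for k, v in params.items()})


def load_params(path) -> tuple[dict[str, Tensor], ModelConfig, int | None]:
    with np.load(str(path)) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        params = {k: ad.parameter(zf[k]) for k in zf.files if k != "__meta__"}
    return params, ModelConfig(**meta["config"]), meta["seed"]
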