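"""Multi-head graph-attention regression network, implemented in NumPy.

The model maps a protein graph (binary adjacency ``A`` with self-loops) and
node features ``H`` (L x F) to a scalar solubility ``S``:

* per head k, a shared linear map ``W_k`` projects features to F' dimensions;
  attention logits ``e_ij = LeakyReLU(a_k^T [W_k h_i || W_k h_j])`` are
  computed for neighbors ``j`` of ``i`` (the 2F'-vector ``a_k`` is stored as
  its source/destination halves), masked by ``A`` and softmax-normalized per
  row into coefficients ``alpha_ij``;
* node updates ``h'_i = sigma(sum_j alpha_ij W_k h_j)`` are concatenated over
  the K heads (width K*F' = hidden_channels) and fed to the next layer;
* after the last attention layer the node vectors are mean-pooled and a
  single-layer perceptron produces ``S = ReLU(w . pooled + b)``.

Both the forward pass and its analytic gradients are written out by hand;
training (see :mod:`solugat.train`) runs Adam on these gradients.  The
softmax uses per-row max subtraction so long proteins cannot overflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .graphs import ProteinGraph

__all__ = [
    "GATModelConfig", "GATLayerParams", "GATParams", "init_params",
    "attention_coefficients", "gat_layer_forward", "multi_head_forward",
    "readout_pool", "mlp_predict", "model_forward", "forward_batch",
    "backward_batch", "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration and parameters
# ---------------------------------------------------------------------------

@dataclass
class GATModelConfig:
    """Architecture hyperparameters.

    ``hidden_channels`` is the concatenated multi-head width K*F', so the
    per-head width is ``hidden_channels // heads``.  Defaults follow the
    tuned setting: two attention layers, 16 heads, 1024 hidden channels,
    LeakyReLU slope 0.2 in the attention logits, ELU between layers, mean
    pooling over nodes.
    """

    in_features: int = 1300
    num_layers: int = 2
    heads: int = 16
    hidden_channels: int = 1024
    leaky_slope: float = 0.2
    activation: str = "elu"
    pooling: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_channels % self.heads != 0:
            raise ValueError(
                f"hidden_channels ({self.hidden_channels}) must be divisible "
                f"by heads ({self.heads})"
            )
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must be in (0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.pooling not in ("mean", "sum"):
            raise ValueError(f"unknown pooling {self.pooling!r}")

    @property
    def head_dim(self) -> int:
        return self.hidden_channels // self.heads


@dataclass
class GATLayerParams:
    """One attention layer: per-head projection ``W`` (K, F', F_in) and the
    attention vector split into source/destination halves (K, F') each."""

    W: np.ndarray
    a_src: np.ndarray
    a_dst: np.ndarray

    @property
    def heads(self) -> int:
        return self.W.shape[0]

    @property
    def head_dim(self) -> int:
        return self.W.shape[1]

    @property
    def in_features(self) -> int:
        return self.W.shape[2]


@dataclass
class GATParams:
    """All learnable tensors: attention layers plus the MLP readout."""

    layers: list[GATLayerParams]
    w_mlp: np.ndarray          # (hidden_channels,)
    b_mlp: np.ndarray          # scalar, stored 0-d for the optimizer

    def as_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for l, layer in enumerate(self.layers):
            out[f"layer{l}/W"] = layer.W
            out[f"layer{l}/a_src"] = layer.a_src
            out[f"layer{l}/a_dst"] = layer.a_dst
        out["mlp/w"] = self.w_mlp
        out["mlp/b"] = self.b_mlp
        return out

    def copy(self) -> "GATParams":
        return GATParams(
            layers=[GATLayerParams(l.W.copy(), l.a_src.copy(), l.a_dst.copy())
                    for l in self.layers],
            w_mlp=self.w_mlp.copy(), b_mlp=self.b_mlp.copy(),
        )

    def n_parameters(self) -> int:
        return sum(v.size for v in self.as_dict().values())


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: GATModelConfig, seed: int | None = None) -> GATParams:
    """Glorot-uniform initialization of the attention layers from a fixed seed.

    The readout perceptron starts at ``w = 0, b = 0.5`` so every initial
    prediction sits at the middle of the solubility range: a ReLU output
    head that starts (or is pushed) below zero on all samples receives no
    gradient at all, and a centered start keeps it in its active region.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layers = []
    fin = config.in_features
    K, fp = config.heads, config.head_dim
    for _ in range(config.num_layers):
        W = _glorot(rng, (K, fp, fin), fin, fp)
        a_src = _glorot(rng, (K, fp), 2 * fp, 1)
        a_dst = _glorot(rng, (K, fp), 2 * fp, 1)
        layers.append(GATLayerParams(W=W, a_src=a_src, a_dst=a_dst))
        fin = K * fp
    w_mlp = np.zeros(config.hidden_channels)
    return GATParams(layers=layers, w_mlp=w_mlp, b_mlp=np.array(0.5))


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _elu(x):
    # expm1 only sees the non-positive branch (np.where evaluates both)
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))

def _elu_deriv(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))

def _relu(x):
    return np.maximum(x, 0.0)

def _relu_deriv(x):
    return (x > 0).astype(np.float64)

def _identity(x):
    return x

def _one(x):
    return np.ones_like(x)

_ACTIVATIONS = {
    "elu": (_elu, _elu_deriv),
    "relu": (_relu, _relu_deriv),
    "identity": (_identity, _one),
}


def _as_adjacency(graph) -> np.ndarray:
    A = graph.A if isinstance(graph, ProteinGraph) else np.asarray(graph)
    return A.astype(bool)


# ---------------------------------------------------------------------------
# single-graph operations (spec surface)
# ---------------------------------------------------------------------------

def attention_coefficients(H: np.ndarray, layer: GATLayerParams, graph,
                           leaky_slope: float = 0.2) -> np.ndarray:
    """Masked, softmax-normalized attention coefficients, shape (K, L, L).

    ``alpha[k, i, j]`` is node j's weight in node i's neighborhood for head
    k; entries outside the neighborhood (A[i,j] = 0) are exactly zero and
    every row sums to one (the self-loop guarantees a non-empty neighborhood).
    """
    mask = _as_adjacency(graph)
    Z = np.einsum("lf,kpf->lkp", np.asarray(H, dtype=np.float64), layer.W)
    alpha, _, _ = _attention_from_Z(Z, mask, layer, leaky_slope)
    return alpha


def _attention_from_Z(Z, mask, layer, slope):
    """Z: (L, K, F') -> (alpha (K,L,L), raw logits (K,L,L), Z)."""
    s_src = np.einsum("lkp,kp->lk", Z, layer.a_src)   # (L, K)
    s_dst = np.einsum("lkp,kp->lk", Z, layer.a_dst)
    raw = s_src.T[:, :, None] + s_dst.T[:, None, :]   # (K, L, L)
    lk = np.where(raw > 0, raw, slope * raw)
    logits = np.where(mask[None, :, :], lk, -np.inf)
    mx = logits.max(axis=2, keepdims=True)
    ex = np.exp(logits - mx)
    alpha = ex / ex.sum(axis=2, keepdims=True)
    return alpha, raw, Z


def multi_head_forward(H: np.ndarray, layer: GATLayerParams, graph,
                       leaky_slope: float = 0.2,
                       activation: str = "elu") -> np.ndarray:
    """One multi-head attention layer; output (L, K*F'), head blocks in order."""
    mask = _as_adjacency(graph)
    act, _ = _ACTIVATIONS[activation]
    Z = np.einsum("lf,kpf->lkp", np.asarray(H, dtype=np.float64), layer.W)
    alpha, _, _ = _attention_from_Z(Z, mask, layer, leaky_slope)
    M = np.einsum("kij,jkp->ikp", alpha, Z)
    L = Z.shape[0]
    return act(M.reshape(L, -1))


def gat_layer_forward(H: np.ndarray, layer: GATLayerParams, graph,
                      leaky_slope: float = 0.2,
                      activation: str = "elu") -> np.ndarray:
    """Single-head view: per-head outputs stacked as (L, K, F').

    With K = 1 this is the plain attention update
    ``h'_i = sigma(sum_j alpha_ij W h_j)``.
    """
    L = np.asarray(H).shape[0]
    out = multi_head_forward(H, layer, graph, leaky_slope, activation)
    return out.reshape(L, layer.heads, layer.head_dim)


def readout_pool(H_nodes: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Permutation-invariant graph readout over node vectors."""
    H_nodes = np.asarray(H_nodes, dtype=np.float64)
    if H_nodes.shape[0] < 1:
        raise ValueError("cannot pool an empty node set")
    if mode == "mean":
        return H_nodes.mean(axis=0)
    if mode == "sum":
        return H_nodes.sum(axis=0)
    raise ValueError(f"unknown pooling {mode!r}")


def mlp_predict(pooled: np.ndarray, w_mlp: np.ndarray, b_mlp: float) -> float:
    """Readout perceptron ``S = ReLU(w . pooled + b)``."""
    pooled = np.asarray(pooled, dtype=np.float64)
    if pooled.shape != np.asarray(w_mlp).shape:
        raise ValueError(
            f"pooled vector ({pooled.shape}) and w_mlp "
            f"({np.asarray(w_mlp).shape}) dimensions differ"
        )
    return float(max(0.0, float(np.dot(w_mlp, pooled)) + float(b_mlp)))


def model_forward(graph, H: np.ndarray, params: GATParams,
                  config: GATModelConfig) -> float:
    """Full forward pass for one protein: stacked attention layers, pooling,
    MLP readout.  Deterministic given parameters."""
    S, _, _ = forward_batch([(graph, H)], params, config)
    return float(S[0])


# ---------------------------------------------------------------------------
# batched forward / backward (training path)
# ---------------------------------------------------------------------------

def forward_batch(batch, params: GATParams, config: GATModelConfig,
                  want_cache: bool = False):
    """Forward pass over a list of ``(graph, H)`` pairs.

    Node features of all graphs are stacked so each layer's projection is a
    single matrix product; attention itself is evaluated per graph (the
    adjacency is graph-local).  Returns ``(S, cache, node_states)`` where
    ``S`` is the (B,) prediction vector and ``node_states`` the final
    per-node hidden matrix (rows grouped by graph).  ``cache`` is None unless
    ``want_cache`` (it is consumed by :func:`backward_batch`).
    """
    act, _ = _ACTIVATIONS[config.activation]
    masks = [_as_adjacency(g) for g, _ in batch]
    sizes = [m.shape[0] for m in masks]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    Hcat = np.vstack([np.asarray(H, dtype=np.float64) for _, H in batch])
    if Hcat.shape[1] != params.layers[0].in_features:
        raise ValueError(
            f"feature width {Hcat.shape[1]} does not match layer-0 "
            f"parameters ({params.layers[0].in_features})"
        )

    layer_caches = []
    for layer in params.layers:
        K, fp = layer.heads, layer.head_dim
        W_flat = layer.W.reshape(K * fp, -1).T          # (F_in, K*F')
        Zflat = Hcat @ W_flat                           # (N, K*F')
        Z = Zflat.reshape(-1, K, fp)
        per_graph = []
        M = np.empty_like(Z)
        for g, (lo, hi) in enumerate(zip(offsets[:-1], offsets[1:])):
            Zg = Z[lo:hi]
            alpha, raw, _ = _attention_from_Z(Zg, masks[g], layer,
                                              config.leaky_slope)
            M[lo:hi] = np.einsum("kij,jkp->ikp", alpha, Zg)
            per_graph.append((alpha, raw))
        pre = M.reshape(M.shape[0], -1)                 # (N, K*F')
        Hout = act(pre)
        if not np.all(np.isfinite(Hout)):
            raise FloatingPointError(
                "non-finite intermediate in attention layer"
            )
        layer_caches.append({"Hin": Hcat, "Z": Z, "per_graph": per_graph,
                             "pre": pre, "W_flat": W_flat, "layer": layer})
        Hcat = Hout

    # pooling + MLP
    pool_div = np.array(sizes, dtype=np.float64)
    P = np.vstack([
        Hcat[lo:hi].sum(axis=0) for lo, hi in zip(offsets[:-1], offsets[1:])
    ])
    if config.pooling == "mean":
        P = P / pool_div[:, None]
    u = P @ params.w_mlp + float(params.b_mlp)
    S = np.maximum(u, 0.0)

    cache = None
    if want_cache:
        cache = {"layers": layer_caches, "masks": masks, "offsets": offsets,
                 "sizes": sizes, "P": P, "u": u, "H_last": Hcat,
                 "params": params, "config": config}
    return S, cache, Hcat


def backward_batch(cache, dS: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic gradients of ``sum_b dS[b] * S_b`` w.r.t. every parameter.

    Mirrors :func:`forward_batch` in reverse: ReLU head, pooling, then per
    layer the activation, the neighborhood aggregation, the masked softmax,
    the LeakyReLU logits and the shared projection.
    """
    params: GATParams = cache["params"]
    config: GATModelConfig = cache["config"]
    _, dact = _ACTIVATIONS[config.activation]
    offsets, sizes = cache["offsets"], cache["sizes"]
    slope = config.leaky_slope

    grads: dict[str, np.ndarray] = {}
    du = np.asarray(dS, dtype=np.float64) * (cache["u"] > 0)
    grads["mlp/w"] = cache["P"].T @ du
    grads["mlp/b"] = np.array(du.sum())
    dP = du[:, None] * params.w_mlp[None, :]

    dH = np.empty_like(cache["H_last"])
    for g, (lo, hi) in enumerate(zip(offsets[:-1], offsets[1:])):
        row = dP[g]
        if config.pooling == "mean":
            row = row / sizes[g]
        dH[lo:hi] = row

    for l in range(len(params.layers) - 1, -1, -1):
        lc = cache["layers"][l]
        layer: GATLayerParams = lc["layer"]
        K, fp = layer.heads, layer.head_dim
        dpre = dH * dact(lc["pre"])                    # (N, K*F')
        dM = dpre.reshape(-1, K, fp)
        Z = lc["Z"]
        dZ = np.empty_like(Z)
        da_src = np.zeros_like(layer.a_src)
        da_dst = np.zeros_like(layer.a_dst)
        for g, (lo, hi) in enumerate(zip(offsets[:-1], offsets[1:])):
            alpha, raw = lc["per_graph"][g]
            Zg, dMg = Z[lo:hi], dM[lo:hi]
            dalpha = np.einsum("ikp,jkp->kij", dMg, Zg)
            dZg = np.einsum("kij,ikp->jkp", alpha, dMg)
            # softmax backward (rows); alpha is zero off-neighborhood so dE is too
            dE = alpha * (dalpha - (alpha * dalpha).sum(axis=2, keepdims=True))
            draw = dE * np.where(raw > 0, 1.0, slope)
            ds_src = draw.sum(axis=2).T                # (L, K)
            ds_dst = draw.sum(axis=1).T
            da_src += np.einsum("lk,lkp->kp", ds_src, Zg)
            da_dst += np.einsum("lk,lkp->kp", ds_dst, Zg)
            dZg = dZg + ds_src[:, :, None] * layer.a_src[None] \
                      + ds_dst[:, :, None] * layer.a_dst[None]
            dZ[lo:hi] = dZg
        dZflat = dZ.reshape(dZ.shape[0], -1)
        grads[f"layer{l}/W"] = (lc["Hin"].T @ dZflat).T.reshape(K, fp, -1)
        grads[f"layer{l}/a_src"] = da_src
        grads[f"layer{l}/a_dst"] = da_dst
        dH = dZflat @ lc["W_flat"].T
    return grads


# ---------------------------------------------------------------------------
# checkpoint container
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: GATParams, config: GATModelConfig,
                    feature_mode: str = "esm+blosum",
                    extra: dict | None = None) -> None:
    """Write config + all weight tensors to an ``.npz`` container.

    float64 tensors are stored losslessly, so reload is bit-exact.
    """
    meta = {"config": asdict(config), "feature_mode": feature_mode,
            "extra": extra or {}}
    arrays = {k.replace("/", "__"): v for k, v in params.as_dict().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path):
    """Read back ``(params, config, meta)`` from :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(str(data["__meta__"]))
        config = GATModelConfig(**meta["config"])
        layers = []
        for l in range(config.num_layers):
            layers.append(GATLayerParams(
                W=data[f"layer{l}__W"],
                a_src=data[f"layer{l}__a_src"],
                a_dst=data[f"layer{l}__a_dst"],
            ))
        params = GATParams(layers=layers, w_mlp=data["mlp__w"],
                           b_mlp=np.array(data["mlp__b"]))
    return params, config, meta
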