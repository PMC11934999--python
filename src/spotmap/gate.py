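"""Graph attention autoencoder (GATE) producing node embeddings.

The encoder stacks L attention layers. In layer k the edge weight from a
node i to a neighbor j is

    r_ij = sigmoid(v_s' sigma(W h_i) + v_t' sigma(W h_j))

normalized over the neighborhood A_i (which includes i) by a softmax to
give attention coefficients alpha_ij, and the new representation is the
attention-weighted sum h_i <- sum_j alpha_ij sigma(W h_j). The decoder
mirrors the encoder with transpose-tied weight matrices and its own
attention vectors, reconstructing the normalized expression profile; the
training objective is the summed squared reconstruction error. The output
of the last encoder layer is the embedding Z.

Cells and spots are embedded by two GATEs with identical layer widths so
that per-node embeddings are comparable in dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Adam, Tensor
from .io import ExpressionMatrix, ValidationError
from .graph import AdjacencyGraph

__all__ = [
    "GateConfig",
    "GateParams",
    "Embedding",
    "attention_coefficients",
    "gate_forward",
    "train_gate",
]

_ACTIVATIONS = {
    "elu": lambda t: t.elu(),
    "identity": lambda t: t,
    "sigmoid": lambda t: t.sigmoid(),
}


@dataclass
class GateConfig:
    """Architecture and optimization settings for one GATE."""

    dims: tuple[int, ...] = (512, 30)
    epochs: int = 500
    lr: float = 1e-4
    seed: int = 0
    activation: str = "elu"
    dtype: type = np.float32


@dataclass
class GateParams:
    """Trainable parameters; decoder weights are the encoder's transposed."""

    dims: list[int]
    W: list[Tensor]
    enc_vs: list[Tensor]
    enc_vt: list[Tensor]
    dec_vs: list[Tensor]
    dec_vt: list[Tensor]
    activation: str = "elu"

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.enc_vs, *self.enc_vt, *self.dec_vs, *self.dec_vt]


@dataclass
class Embedding:
    """Final node embedding Z, one row per cell or spot."""

    Z: np.ndarray
    modality: str
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if not np.isfinite(self.Z).all():
            raise ValidationError("non-finite embedding")


def init_gate_params(in_dim: int, config: GateConfig) -> GateParams:
    """Glorot-uniform initialization, reproducible from the config seed."""
    rng = np.random.default_rng(config.seed)
    dims = [in_dim, *config.dims]
    W, evs, evt, dvs, dvt = [], [], [], [], []
    for k in range(1, len(dims)):
        d_in, d_out = dims[k - 1], dims[k]
        lim = np.sqrt(6.0 / (d_in + d_out))
        W.append(Tensor(rng.uniform(-lim, lim, (d_out, d_in)).astype(config.dtype),
                        requires_grad=True))
        lim_v = np.sqrt(6.0 / (d_out + 1))
        lim_u = np.sqrt(6.0 / (d_in + 1))
        evs.append(Tensor(rng.uniform(-lim_v, lim_v, d_out).astype(config.dtype), requires_grad=True))
        evt.append(Tensor(rng.uniform(-lim_v, lim_v, d_out).astype(config.dtype), requires_grad=True))
        dvs.append(Tensor(rng.uniform(-lim_u, lim_u, d_in).astype(config.dtype), requires_grad=True))
        dvt.append(Tensor(rng.uniform(-lim_u, lim_u, d_in).astype(config.dtype), requires_grad=True))
    return GateParams(dims, W, evs, evt, dvs, dvt, activation=config.activation)


class _AggStruct:
    """Precomputed sparse structure of one graph's edge list.

    Edges come grouped by query node (``src`` non-decreasing), so the
    attention matrix P with P[i, j] = alpha_ij is a CSR whose indptr and
    indices are fixed; only the data (the alphas) changes per iteration.
    The transposed pattern is precomputed for the backward pass.
    """

    def __init__(self, graph: AdjacencyGraph):
        from scipy.sparse import csr_matrix

        self._csr = csr_matrix
        self.n_nodes = graph.n_nodes
        self.src, self.dst = graph.edge_arrays()
        counts = np.array([len(nb) for nb in graph.neighbors])
        self.indptr = np.concatenate([[0], np.cumsum(counts)])
        self.perm = np.argsort(self.dst, kind="stable")
        t_counts = np.bincount(self.dst, minlength=self.n_nodes)
        self.t_indptr = np.concatenate([[0], np.cumsum(t_counts)])
        self.t_indices = self.src[self.perm]

    def matrix(self, alpha: np.ndarray):
        return self._csr((alpha, self.dst, self.indptr),
                         shape=(self.n_nodes, self.n_nodes))

    def matrix_t(self, alpha: np.ndarray):
        return self._csr((alpha[self.perm], self.t_indices, self.t_indptr),
                         shape=(self.n_nodes, self.n_nodes))


def _aggregate(S: Tensor, alpha: Tensor, agg: _AggStruct) -> Tensor:
    """out[i] = sum over edges (i -> j) of alpha_e * S[j], as one fused op."""
    out_data = agg.matrix(alpha.data) @ S.data

    def backward(g):
        d_alpha = np.einsum("ed,ed->e", g[agg.src], S.data[agg.dst])
        d_S = agg.matrix_t(alpha.data) @ g
        return (d_S, d_alpha)

    out = Tensor(out_data)
    out.requires_grad = S.requires_grad or alpha.requires_grad
    if out.requires_grad:
        out._parents = (S, alpha)
        out._backward = backward
    return out


def _edge_softmax(r: Tensor, agg: _AggStruct) -> Tensor:
    """Softmax of per-edge scores within each query node's neighborhood."""
    shift = np.full(agg.n_nodes, -np.inf, dtype=r.data.dtype)
    np.maximum.at(shift, agg.src, r.data)  # detached max-shift for stability
    e = (r - Tensor(shift[agg.src])).exp()
    denom = e.segment_sum(agg.src, agg.n_nodes)
    return e / denom.gather_rows(agg.src)


def _attention_layer(H: Tensor, agg: _AggStruct, W: Tensor, vs: Tensor, vt: Tensor,
                     act) -> tuple[Tensor, Tensor]:
    """One attention aggregation; returns (new representation, edge alphas)."""
    S = act(H @ W.T)
    s = S @ vs
    t = S @ vt
    r = (s.gather_rows(agg.src) + t.gather_rows(agg.dst)).sigmoid()
    alpha = _edge_softmax(r, agg)
    H_new = _aggregate(S, alpha, agg)
    return H_new, alpha


def attention_coefficients(h_prev: np.ndarray, graph: AdjacencyGraph, W: np.ndarray,
                           v_s: np.ndarray, v_t: np.ndarray,
                           activation: str = "elu") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-edge attention weights for one layer, on plain arrays.

    Returns (src, dst, alpha) aligned with ``graph.edge_arrays()``; for each
    query node i the alphas over A_i sum to 1.
    """
    act = _ACTIVATIONS[activation]
    agg = _AggStruct(graph)
    _, alpha = _attention_layer(Tensor(np.asarray(h_prev, dtype=float)), agg,
                                Tensor(np.asarray(W, dtype=float)),
                                Tensor(np.asarray(v_s, dtype=float)),
                                Tensor(np.asarray(v_t, dtype=float)), act)
    return agg.src, agg.dst, alpha.data


def _forward(X: Tensor, graph: AdjacencyGraph | _AggStruct, params: GateParams,
             direction: str) -> Tensor:
    act = _ACTIVATIONS[params.activation]
    agg = graph if isinstance(graph, _AggStruct) else _AggStruct(graph)
    H = X
    if direction == "encode":
        for k in range(params.n_layers):
            H, _ = _attention_layer(H, agg, params.W[k],
                                    params.enc_vs[k], params.enc_vt[k], act)
        return H
    if direction == "decode":
        for k in reversed(range(params.n_layers)):
            H, _ = _attention_layer(H, agg, params.W[k].T,
                                    params.dec_vs[k], params.dec_vt[k], act)
        return H
    raise ValueError("direction must be 'encode' or 'decode'")


def gate_forward(X: np.ndarray, graph: AdjacencyGraph, params: GateParams,
                 direction: str = "encode") -> np.ndarray:
    """Run the encoder (expression -> Z) or decoder (Z -> reconstruction)."""
    X = np.asarray(X, dtype=float)
    expected = params.dims[0] if direction == "encode" else params.dims[-1]
    if X.shape[1] != expected:
        raise ValidationError(
            f"{direction} input has {X.shape[1]} features, expected {expected}"
        )
    if X.shape[0] != graph.n_nodes:
        raise ValidationError("row count does not match the graph")
    return _forward(Tensor(X), graph, params, direction).data


def train_gate(E: ExpressionMatrix, graph: AdjacencyGraph,
               config: GateConfig | None = None) -> tuple[GateParams, Embedding, list[float]]:
    """Train one GATE by reconstruction; returns (params, embedding, losses).

    ``losses[0]`` is the pre-training loss; training is reproducible from
    ``config.seed`` and the final loss never exceeds the initial one (the
    best-seen parameters are kept).
    """
    if E.layer != "cpm_log2":
        raise ValidationError("GATE training expects the normalized layer")
    if graph.n_nodes != E.n_rows:
        raise ValidationError("graph size does not match the expression matrix")
    config = config or GateConfig()
    params = init_gate_params(E.n_genes, config)
    X = Tensor(E.values.astype(config.dtype))
    agg = _AggStruct(graph)
    opt = Adam(params.parameters(), lr=config.lr)

    def loss_tensor() -> Tensor:
        Z = _forward(X, agg, params, "encode")
        Xhat = _forward(Z, agg, params, "decode")
        diff = X - Xhat
        return (diff * diff).sum()

    losses = [float(loss_tensor().data)]
    best = ([p.data.copy() for p in params.parameters()], losses[0])
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss = loss_tensor()
        val = float(loss.data)
        if not np.isfinite(val):
            raise ValidationError(f"non-finite reconstruction loss at epoch {epoch}")
        loss.backward()
        opt.step()
        losses.append(val)
        if val < best[1]:
            best = ([p.data.copy() for p in params.parameters()], val)
    final = float(loss_tensor().data)
    losses.append(final)
    if final > best[1]:
        for p, b in zip(params.parameters(), best[0]):
            p.data = b
        losses[-1] = best[1]
    Z = _forward(X, agg, params, "encode").data.astype(float)
    return params, Embedding(Z, E.modality, list(E.row_ids)), losses
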