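"""Learned cell-to-spot mapping matrix and assignment extraction.

The mapping matrix M (m cells x w spots, row-stochastic via a row softmax
of free logits) is fitted with Adam to minimize the three-term objective

    L = sum_ij KL(C_i || S_j) M_ij          (expression similarity)
      + sum_ij D_ij M_ij                    (embedding similarity)
      + lambda * (1/w) * sum_j |N_j - sum_i M_ij|   (cell quantity)

where KL is the Kullback-Leibler divergence between the gene-probability
profiles of cell i and spot j, D_ij = 1 - PCC(Z_i^sc, Z_j^st) is the
Pearson distance between embeddings, and N_j is the expected number of
cells in spot j. lambda defaults to 0.1.

Two extraction modes read assignments off the fitted M: "regular" fills
each spot j with its N_j highest-scoring cells (a cell may serve several
spots, or none), and "greedy" sends every cell to its single
highest-scoring spot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor
from .abundance import CellsPerSpot
from .gate import Embedding
from .io import CellAnnotation, ExpressionMatrix, ValidationError

__all__ = [
    "CostMatrices",
    "MappingMatrix",
    "MappingResult",
    "MappingConfig",
    "kl_cost_matrix",
    "pearson_distance_matrix",
    "init_mapping",
    "mapping_loss",
    "optimize_mapping",
    "extract_regular",
    "extract_greedy",
    "spot_celltype_proportions",
]

logger = logging.getLogger(__name__)

KL_EPS = 1e-10  # smoothing added to profiles before renormalization


@dataclass
class CostMatrices:
    """Precomputed m x w cost terms of the mapping objective."""

    kl: np.ndarray
    pearson: np.ndarray

    def __post_init__(self):
        self.kl = np.asarray(self.kl, dtype=float)
        self.pearson = np.asarray(self.pearson, dtype=float)
        if self.kl.shape != self.pearson.shape:
            raise ValidationError("cost matrices must share a shape")
        if not (np.isfinite(self.kl).all() and np.isfinite(self.pearson).all()):
            raise ValidationError("non-finite cost entries")
        if (self.kl < -1e-12).any():
            raise ValidationError("negative KL cost")
        if (self.pearson < -1e-9).any() or (self.pearson > 2 + 1e-9).any():
            raise ValidationError("Pearson distance outside [0, 2]")

    @property
    def total(self) -> np.ndarray:
        return self.kl + self.pearson


@dataclass
class MappingMatrix:
    """Free logits and their row-softmax M (each row sums to 1)."""

    logits: np.ndarray

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=float)
        if self.logits.ndim != 2:
            raise ValidationError("logits must be 2-D")
        if not np.isfinite(self.logits).all():
            raise ValidationError("non-finite logits")

    @property
    def M(self) -> np.ndarray:
        z = self.logits - self.logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    @property
    def shape(self):
        return self.logits.shape


@dataclass
class MappingResult:
    """Explicit (cell_id, spot_id, score) assignments."""

    assignments: pd.DataFrame
    mode: str

    def __post_init__(self):
        required = {"cell_id", "spot_id", "score"}
        if not required.issubset(self.assignments.columns):
            raise ValidationError(f"assignments need columns {sorted(required)}")
        if self.mode not in ("regular", "greedy"):
            raise ValidationError(f"unknown mapping mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class MappingConfig:
    """Optimizer settings for the mapping objective."""

    lam: float = 0.1
    epochs: int = 1000
    lr: float = 0.01
    seed: int = 0
    jitter_sd: float = 0.01


# ---------------------------------------------------------------------------
# cost matrices
# ---------------------------------------------------------------------------

def _to_prob(values: np.ndarray, eps: float) -> np.ndarray:
    p = values + eps
    return p / p.sum(axis=1, keepdims=True)


def kl_cost_matrix(C: ExpressionMatrix, S: ExpressionMatrix, eps: float = KL_EPS) -> np.ndarray:
    """KL(cell || spot) over gene distributions, for every cell/spot pair.

    Rows of the normalized matrices are eps-smoothed and renormalized to
    probability vectors p_i, q_j; kl_ij = sum_g p_i(g) ln(p_i(g)/q_j(g)).
    """
    if C.gene_ids != S.gene_ids:
        raise ValidationError("KL cost requires matched gene columns")
    if C.layer != "cpm_log2" or S.layer != "cpm_log2":
        raise ValidationError("KL cost expects the normalized layer")
    P = _to_prob(C.values, eps)
    Q = _to_prob(S.values, eps)
    self_term = (P * np.log(P)).sum(axis=1)
    cross = P @ np.log(Q).T
    return np.maximum(self_term[:, None] - cross, 0.0)


def pearson_distance_matrix(Z_sc: Embedding, Z_st: Embedding) -> np.ndarray:
    """D_ij = 1 - Pearson correlation between embedding rows; D in [0, 2]."""
    A, B = Z_sc.Z, Z_st.Z
    if A.shape[1] != B.shape[1]:
        raise ValidationError("embeddings must share their dimension")
    if A.shape[1] < 2:
        raise ValidationError("Pearson distance needs embedding dimension >= 2")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    a_norm = np.linalg.norm(Ac, axis=1)
    b_norm = np.linalg.norm(Bc, axis=1)
    zero_a, zero_b = a_norm == 0, b_norm == 0
    if zero_a.any() or zero_b.any():
        logger.warning("zero-variance embedding rows; their Pearson distance set to 1")
    corr = (Ac @ Bc.T) / np.outer(np.where(zero_a, 1.0, a_norm), np.where(zero_b, 1.0, b_norm))
    corr[zero_a, :] = 0.0
    corr[:, zero_b] = 0.0
    return np.clip(1.0 - corr, 0.0, 2.0)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def init_mapping(N: CellsPerSpot, m: int, seed: int = 0,
                 jitter_sd: float = 0.01) -> MappingMatrix:
    """Logits at log cell-count proportions plus a small seeded jitter.

    With zero jitter every row of M equals N / sum(N), so the initial
    column masses already reflect the estimated cells per spot.
    """
    rng = np.random.default_rng(seed)
    base = np.log(N.counts / N.counts.sum())
    logits = np.tile(base, (m, 1))
    if jitter_sd > 0:
        logits = logits + rng.normal(0.0, jitter_sd, logits.shape)
    return MappingMatrix(logits)


def mapping_loss(M: np.ndarray, costs: CostMatrices, N: CellsPerSpot, lam: float) -> float:
    """The exact three-term objective evaluated at a row-stochastic M."""
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise ValidationError("non-finite mapping matrix")
    if M.shape != costs.kl.shape:
        raise ValidationError("mapping matrix shape does not match costs")
    w = M.shape[1]
    if len(N.counts) != w:
        raise ValidationError("cells-per-spot length does not match M columns")
    term12 = float((costs.total * M).sum())
    term3 = float(lam * np.abs(N.counts - M.sum(axis=0)).sum() / w)
    return term12 + term3


def optimize_mapping(costs: CostMatrices, N: CellsPerSpot,
                     config: MappingConfig | None = None,
                     init: MappingMatrix | None = None,
                     ) -> tuple[MappingMatrix, list[float]]:
    """Fit the mapping matrix with Adam; returns (matrix, loss history).

    The final loss never exceeds the initial loss: the best-seen logits
    are kept.
    """
    config = config or MappingConfig()
    m, w = costs.kl.shape
    if init is None:
        init = init_mapping(N, m, seed=config.seed, jitter_sd=config.jitter_sd)
    logits = Tensor(init.logits.copy(), requires_grad=True)
    cost_t = Tensor(costs.total)
    n_t = Tensor(N.counts.astype(float))
    opt = Adam([logits], lr=config.lr)

    def loss_tensor() -> Tensor:
        M = logits.softmax_rows()
        quantity = (n_t - M.sum(axis=0)).abs().sum() * (config.lam / w)
        return (cost_t * M).sum() + quantity

    history = [float(loss_tensor().data)]
    best = (logits.data.copy(), history[0])
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss = loss_tensor()
        val = float(loss.data)
        if not np.isfinite(val):
            raise ValidationError(f"mapping loss diverged at epoch {epoch}")
        loss.backward()
        opt.step()
        history.append(val)
        if val < best[1]:
            best = (logits.data.copy(), val)
    final = float(loss_tensor().data)
    history.append(final)
    if final > best[1]:
        logits.data = best[0]
        history[-1] = best[1]
    return MappingMatrix(logits.data), history


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_regular(mapping: MappingMatrix, N: CellsPerSpot,
                    cell_ids: list[str], spot_ids: list[str] | None = None) -> MappingResult:
    """Fill each spot j with its N_j highest-scoring cells.

    Selection is per spot and independent, so a cell may be mapped to
    several spots while another is never used. Ties go to the lower cell
    index.
    """
    M = mapping.M
    m, w = M.shape
    spot_ids = list(spot_ids) if spot_ids is not None else list(N.spot_ids)
    if len(N.counts) != w or len(spot_ids) != w:
        raise ValidationError("spot bookkeeping does not match M columns")
    if len(cell_ids) != m:
        raise ValidationError("cell_ids length does not match M rows")
    if (N.counts > m).any():
        raise ValidationError("a spot requests more cells than exist")
    rows = []
    for j in range(w):
        order = np.argsort(-M[:, j], kind="stable")[: N.counts[j]]
        for i in order:
            rows.append((cell_ids[i], spot_ids[j], M[i, j]))
    df = pd.DataFrame(rows, columns=["cell_id", "spot_id", "score"])
    return MappingResult(df, mode="regular")


def extract_greedy(mapping: MappingMatrix, cell_ids: list[str],
                   spot_ids: list[str]) -> MappingResult:
    """Send every cell to its single highest-scoring spot (ties: lower index)."""
    M = mapping.M
    if len(cell_ids) != M.shape[0] or len(spot_ids) != M.shape[1]:
        raise ValidationError("id lists do not match M")
    best = M.argmax(axis=1)
    df = pd.DataFrame({
        "cell_id": list(cell_ids),
        "spot_id": [spot_ids[j] for j in best],
        "score": M[np.arange(M.shape[0]), best],
    })
    return MappingResult(df, mode="greedy")


def spot_celltype_proportions(result: MappingResult, ann: CellAnnotation,
                              spot_ids: list[str] | None = None) -> pd.DataFrame:
    """Cell-type proportion per spot from the mapped cells.

    Rows are spots, columns cell types; occupied spots sum to 1, spots with
    no mapped cells (possible in greedy mode) get an all-zero row.
    """
    types = ann.labels
    counts = {}
    for cell, spot in zip(result.assignments["cell_id"], result.assignments["spot_id"]):
        t = ann.type_of(cell)
        counts.setdefault(spot, {}).setdefault(t, 0)
        counts[spot][t] += 1
    if spot_ids is None:
        spot_ids = sorted(counts)
    table = pd.DataFrame(0.0, index=pd.Index(spot_ids, name="spot_id"), columns=types)
    for spot in spot_ids:
        per = counts.get(spot)
        if not per:
            continue
        total = sum(per.values())
        for t, c in per.items():
            table.loc[spot, t] = c / total
    return table
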