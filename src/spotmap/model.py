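"""Model/Results interface tying the whole pipeline together.

:class:`CellToSpotModel` is constructed from a raw-count single-cell
matrix, a raw-count spot matrix and the spot coordinates; ``fit()`` runs
preprocessing, cell-count estimation, graph construction, GATE training
and the mapping-matrix optimization, and returns a
:class:`CellToSpotResults` carrying the fitted mapping matrix plus
diagnostics. Assignments, per-spot cell-type proportions, evaluation
against a ground truth, and plotting all hang off the results object.

A typical session::

    model = CellToSpotModel(sc_counts, st_counts, geometry, annotation=ann)
    res = model.fit(seed=0)
    print(res.summary())
    regular = res.regular()          # fill each spot with its N_j cells
    greedy = res.greedy()            # place every cell somewhere
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import io as smio
from .abundance import CellsPerSpot, constant_cells_per_spot, estimate_cells_per_spot_umi
from .gate import Embedding, GateConfig, train_gate
from .graph import build_expression_knn_graph, build_spatial_graph
from .io import CellAnnotation, ExpressionMatrix, SpotGeometry, ValidationError
from .mapping import (
    CostMatrices,
    MappingConfig,
    MappingMatrix,
    MappingResult,
    extract_greedy,
    extract_regular,
    kl_cost_matrix,
    optimize_mapping,
    pearson_distance_matrix,
    spot_celltype_proportions,
)
from .metrics import EvaluationReport, celltype_error_rate, ploc, pmap, proportion_pcc

__all__ = ["MapperConfig", "CellToSpotModel", "CellToSpotResults"]

logger = logging.getLogger(__name__)


@dataclass
class MapperConfig:
    """All tunable settings of the pipeline, with the method's defaults."""

    mean_cells_per_spot: float = 5.0
    lam: float = 0.1
    k_expression: int = 15
    k_spatial: int = 6
    gate: GateConfig = field(default_factory=GateConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    seed: int = 0

    def seeded(self, seed: int | None) -> "MapperConfig":
        """Derive per-stage seeds from one master seed."""
        if seed is None:
            seed = self.seed
        seed = int(seed) % (2**31 - 10)
        return dc_replace(
            self,
            seed=seed,
            gate=dc_replace(self.gate, seed=seed + 1),
            mapping=dc_replace(self.mapping, seed=seed + 2),
        )


class CellToSpotModel:
    """Single-cell-to-spot mapping model.

    Parameters
    ----------
    sc_counts, st_counts : ExpressionMatrix
        Raw counts (cells x genes and spots x genes).
    geometry : SpotGeometry
        Spot coordinates, matched to ``st_counts`` rows.
    annotation : CellAnnotation, optional
        Cell-type labels; only used for proportion summaries and
        evaluation, never by the fit itself.
    cells_per_spot : CellsPerSpot, optional
        Externally determined counts (e.g. nucleus segmentation); when
        absent the two-anchor UMI rule is used.
    config : MapperConfig, optional
    """

    def __init__(self, sc_counts: ExpressionMatrix, st_counts: ExpressionMatrix,
                 geometry: SpotGeometry, annotation: CellAnnotation | None = None,
                 cells_per_spot: CellsPerSpot | None = None,
                 config: MapperConfig | None = None):
        if sc_counts.layer != "raw_counts" or st_counts.layer != "raw_counts":
            raise ValidationError("the model is built from raw counts")
        self.sc_counts = sc_counts
        self.st_counts = st_counts
        self.geometry = geometry.match(st_counts)
        self.annotation = annotation
        self.cells_per_spot = cells_per_spot
        self.config = config or MapperConfig()

    @classmethod
    def from_files(cls, sc_path, st_path, coords_path, sc_format: str = "csv",
                   st_format: str = "csv", annotation: CellAnnotation | None = None,
                   config: MapperConfig | None = None) -> "CellToSpotModel":
        sc = smio.read_expression(sc_path, sc_format, modality="sc")
        st = smio.read_expression(st_path, st_format, modality="st")
        geom = smio.read_coordinates(coords_path)
        return cls(sc, st, geom, annotation=annotation, config=config)

    # -- pipeline stages ------------------------------------------------------
    def preprocess(self):
        """Rare-gene filter per matrix, common genes, CPM+log2 per row."""
        sc_f = smio.filter_rare_genes(self.sc_counts)
        st_f = smio.filter_rare_genes(self.st_counts)
        sc_raw, st_raw = smio.intersect_genes(sc_f, st_f)
        return sc_raw, st_raw, smio.normalize_cpm_log2(sc_raw), smio.normalize_cpm_log2(st_raw)

    def fit(self, seed: int | None = None, st_embedding: Embedding | None = None
            ) -> "CellToSpotResults":
        """Run the full pipeline and return the fitted results.

        ``st_embedding`` lets callers reuse a spot embedding across
        repeated fits against the same ST data.
        """
        cfg = self.config.seeded(seed)
        timings: dict[str, float] = {}

        t0 = time.perf_counter()
        sc_raw, st_raw, sc_norm, st_norm = self.preprocess()
        timings["preprocess"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        if self.cells_per_spot is not None:
            N = self.cells_per_spot
        else:
            try:
                N = estimate_cells_per_spot_umi(st_raw, cfg.mean_cells_per_spot)
            except ValidationError:
                logger.warning("degenerate UMI anchors; falling back to a constant count")
                N = constant_cells_per_spot(st_raw.row_ids,
                                            max(1, round(cfg.mean_cells_per_spot)))
        timings["cells_per_spot"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        k_expr = min(cfg.k_expression, sc_norm.n_rows - 1)
        k_spat = min(cfg.k_spatial, st_norm.n_rows - 1)
        sc_graph = build_expression_knn_graph(sc_norm, k=max(k_expr, 1) if sc_norm.n_rows > 1 else 0)
        st_graph = build_spatial_graph(self.geometry, k=max(k_spat, 0))
        timings["graphs"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        _, z_sc, sc_losses = train_gate(sc_norm, sc_graph, cfg.gate)
        if st_embedding is None:
            _, z_st, st_losses = train_gate(st_norm, st_graph, cfg.gate)
        else:
            z_st, st_losses = st_embedding, []
        timings["gate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        costs = CostMatrices(kl_cost_matrix(sc_norm, st_norm),
                             pearson_distance_matrix(z_sc, z_st))
        mapping, history = optimize_mapping(
            costs, N, dc_replace(cfg.mapping, lam=cfg.lam))
        timings["mapping"] = time.perf_counter() - t0

        return CellToSpotResults(
            model=self, config=cfg, mapping=mapping, cells_per_spot=N,
            costs=costs, sc_embedding=z_sc, st_embedding=z_st,
            loss_history=history, gate_losses={"sc": sc_losses, "st": st_losses},
            cell_ids=list(sc_norm.row_ids), spot_ids=list(st_norm.row_ids),
            n_genes=sc_norm.n_genes, timings=timings,
        )


@dataclass
class CellToSpotResults:
    """Fitted mapping matrix with extraction, evaluation and diagnostics."""

    model: CellToSpotModel
    config: MapperConfig
    mapping: MappingMatrix
    cells_per_spot: CellsPerSpot
    costs: CostMatrices
    sc_embedding: Embedding
    st_embedding: Embedding
    loss_history: list[float]
    gate_losses: dict[str, list[float]]
    cell_ids: list[str]
    spot_ids: list[str]
    n_genes: int = 0
    timings: dict[str, float] = field(default_factory=dict)

    # -- extraction -----------------------------------------------------------
    def regular(self) -> MappingResult:
        return extract_regular(self.mapping, self.cells_per_spot,
                               self.cell_ids, self.spot_ids)

    def greedy(self) -> MappingResult:
        return extract_greedy(self.mapping, self.cell_ids, self.spot_ids)

    def proportions(self, mode: str = "regular") -> pd.DataFrame:
        if self.model.annotation is None:
            raise ValidationError("cell-type proportions need an annotation")
        result = self.regular() if mode == "regular" else self.greedy()
        return spot_celltype_proportions(result, self.model.annotation, self.spot_ids)

    def assigned_coordinates(self, mode: str = "greedy") -> pd.DataFrame:
        """Coordinates of each assignment's spot (cell placements)."""
        result = self.regular() if mode == "regular" else self.greedy()
        geom = self.model.geometry
        pos = {s: i for i, s in enumerate(geom.spot_ids)}
        idx = [pos[s] for s in result.assignments["spot_id"]]
        out = result.assignments.copy()
        out["x"] = geom.coords[idx, 0]
        out["y"] = geom.coords[idx, 1]
        return out

    # -- diagnostics ----------------------------------------------------------
    @property
    def quantity_gap(self) -> float:
        """Mean absolute gap between column masses of M and N."""
        M = self.mapping.M
        return float(np.abs(self.cells_per_spot.counts - M.sum(axis=0)).mean())

    def evaluate(self, truth: pd.DataFrame,
                 true_proportions: pd.DataFrame | None = None) -> EvaluationReport:
        """Score both extraction modes against a cell -> spot truth table."""
        if self.model.annotation is None:
            raise ValidationError("evaluation needs a cell annotation")
        ann = self.model.annotation
        report = EvaluationReport(
            per_type_pmap=pmap(self.regular(), truth, ann),
            error_rate=celltype_error_rate(self.regular(), truth, ann),
            per_type_ploc=ploc(self.greedy(), truth, ann),
        )
        if true_proportions is not None:
            pred = self.proportions("regular").loc[true_proportions.index,
                                                   true_proportions.columns]
            per_spot, mean = proportion_pcc(pred, true_proportions)
            report.proportion_pcc_per_spot = per_spot
            report.proportion_pcc_mean = mean
        return report

    def summary(self) -> str:
        m, w = self.mapping.shape
        lines = [
            "Cell-to-spot mapping results",
            "=" * 44,
            f"cells (m):                 {m}",
            f"spots (w):                 {w}",
            f"genes after preprocessing: {self.n_genes}",
            f"embedding dimension:       {self.sc_embedding.Z.shape[1]}",
            f"expected cells (sum N_j):  {self.cells_per_spot.total}",
            f"lambda (quantity weight):  {self.config.lam}",
            f"initial mapping loss:      {self.loss_history[0]:.4f}",
            f"final mapping loss:        {self.loss_history[-1]:.4f}",
            f"mean |N_j - column mass|:  {self.quantity_gap:.4f}",
        ]
        if self.gate_losses["sc"]:
            lines.append(f"sc GATE loss (init->final): "
                         f"{self.gate_losses['sc'][0]:.1f} -> {self.gate_losses['sc'][-1]:.1f}")
        if self.gate_losses["st"]:
            lines.append(f"st GATE loss (init->final): "
                         f"{self.gate_losses['st'][0]:.1f} -> {self.gate_losses['st'][-1]:.1f}")
        return "\n".join(lines)

    def plot_assignments(self, mode: str = "greedy", ax=None):
        """Scatter the assigned spot coordinates, colored by cell type."""
        import matplotlib.pyplot as plt

        coords = self.assigned_coordinates(mode)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        if self.model.annotation is not None:
            types = [self.model.annotation.type_of(c) for c in coords["cell_id"]]
            for t in sorted(set(types)):
                mask = [tt == t for tt in types]
                ax.scatter(coords.loc[mask, "x"], coords.loc[mask, "y"], s=8, label=t)
            ax.legend(fontsize=6, markerscale=1.5)
        else:
            ax.scatter(coords["x"], coords["y"], s=8)
        ax.set_title(f"{mode} mapping ({len(coords)} assignments)")
        ax.set_aspect("equal")
        return ax
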