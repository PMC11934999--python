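"""Ground-truthed synthetic data for testing the mapper end to end.

Three stages emulate how bead-resolution spatial data (Slide-seq-like,
one cell per bead with coordinates and type labels) is turned into a
multi-cell-per-spot benchmark:

1. :func:`generate_synthetic_tissue` draws an annotated tissue: each cell
   type has a negative-binomial expression program with a block of
   elevated marker genes, and cells of a type occupy a coherent spatial
   patch (or a gradient along x).
2. :func:`bin_cells_to_spots` lays a square grid over the tissue and sums
   the member cells' counts per occupied bin, searching the bin side so
   the realized mean cells per spot hits a target (5, 15 or 30 are the
   conventional resolutions); the cell -> spot table is the ground truth
   that the mapping metrics consume.
3. :func:`perturb_expression` mimics cross-platform technical variation:
   per cell, a fixed fraction pt of genes is chosen at random and each
   chosen count x is replaced by x * 2**z with z ~ Normal(0, 1), then
   re-rounded to a non-negative integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellAnnotation, ExpressionMatrix, SpotGeometry, ValidationError

__all__ = [
    "SyntheticTissue",
    "SimulatedST",
    "generate_synthetic_tissue",
    "bin_cells_to_spots",
    "perturb_expression",
]


@dataclass
class SyntheticTissue:
    """Annotated single cells with coordinates and their generating programs."""

    cells: ExpressionMatrix
    annotation: CellAnnotation
    coords: np.ndarray
    type_programs: pd.DataFrame
    seed: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.cells.n_rows, 2):
            raise ValidationError("one (x, y) coordinate per cell required")
        if set(self.annotation.cell_ids) != set(self.cells.row_ids):
            raise ValidationError("annotation does not cover the cells")


@dataclass
class SimulatedST:
    """Binned spots with geometry and the cell -> spot ground truth."""

    spots: ExpressionMatrix
    geometry: SpotGeometry
    truth: pd.DataFrame  # columns cell_id, spot_id
    mean_cells_per_spot: float

    def __post_init__(self):
        if list(self.truth.columns[:2]) != ["cell_id", "spot_id"]:
            raise ValidationError("truth table needs columns cell_id, spot_id")
        if self.truth["cell_id"].duplicated().any():
            raise ValidationError("a cell is assigned to more than one spot")


def generate_synthetic_tissue(n_types: int = 8, cells_per_type: int = 200,
                              n_genes: int = 400, n_markers_per_type: int = 12,
                              spatial_layout: str = "patches",
                              marker_fold: float = 6.0,
                              library_size: float = 2000.0,
                              dispersion: float = 0.3,
                              patch_sd: float = 0.35,
                              seed: int = 0) -> SyntheticTissue:
    """Draw an annotated tissue with typed expression programs and patches.

    Each type's program is a shared lognormal gene baseline with its own
    marker block multiplied by ``marker_fold``, scaled to ``library_size``
    expected counts per cell; counts are gamma-Poisson (negative binomial)
    with the given dispersion and a lognormal per-cell size factor.
    ``patches`` places type centers on a grid over the unit square with
    Gaussian scatter (sd = patch_sd * center spacing); ``gradient`` orders
    types along x.
    """
    if n_types < 1 or cells_per_type < 1 or n_genes < 1:
        raise ValidationError("sizes must be positive")
    if n_markers_per_type * n_types > n_genes:
        raise ValidationError("marker blocks exceed the gene panel")
    if spatial_layout not in ("patches", "gradient"):
        raise ValidationError(f"unknown layout {spatial_layout!r}")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    types = [f"type{t:02d}" for t in range(n_types)]

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    programs = np.tile(base, (n_types, 1))
    for t in range(n_types):
        block = slice(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        programs[t, block] *= marker_fold
    programs *= library_size / programs.sum(axis=1, keepdims=True)

    n_cells = n_types * cells_per_type
    type_idx = np.repeat(np.arange(n_types), cells_per_type)
    size_factors = rng.lognormal(mean=0.0, sigma=0.25, size=n_cells)
    mu = programs[type_idx] * size_factors[:, None]
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    if spatial_layout == "patches":
        side = int(np.ceil(np.sqrt(n_types)))
        centers = np.array([((t % side + 0.5) / side, (t // side + 0.5) / side)
                            for t in range(n_types)])
        spacing = 1.0 / side
        coords = centers[type_idx] + rng.normal(0.0, patch_sd * spacing, (n_cells, 2))
    else:
        x = (type_idx + rng.uniform(0, 1, n_cells)) / n_types
        y = rng.uniform(0, 1, n_cells)
        coords = np.column_stack([x, y])

    cell_ids = [f"cell{c:05d}" for c in range(n_cells)]
    cells = ExpressionMatrix(counts, cell_ids, gene_ids, layer="raw_counts", modality="sc")
    ann = CellAnnotation(cell_ids, [types[t] for t in type_idx])
    progs = pd.DataFrame(programs, index=types, columns=gene_ids)
    return SyntheticTissue(cells, ann, coords, progs, seed)


def _bin_assignments(coords: np.ndarray, side: float) -> np.ndarray:
    origin = coords.min(axis=0)
    return np.floor((coords - origin) / side).astype(int)


def bin_cells_to_spots(tissue: SyntheticTissue, target_mean_cells: float,
                       tolerance: float = 0.1) -> SimulatedST:
    """Sum located cells into square-grid spots at a target mean occupancy.

    The bin side is searched (log-spaced scan refined by bisection) so the
    realized mean cells per occupied bin is within ``tolerance`` (10%) of
    the target; spot expression is the exact sum of member raw counts and
    the spot coordinate is the bin center.
    """
    n_cells = tissue.cells.n_rows
    if target_mean_cells < 1:
        raise ValidationError("target mean cells per spot must be >= 1")
    if target_mean_cells > n_cells:
        raise ValidationError("target exceeds the number of cells")
    coords = tissue.coords
    span = float(max(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]))) or 1.0

    def realized(side: float) -> float:
        bins = _bin_assignments(coords, side)
        n_occupied = len(np.unique(bins, axis=0))
        return n_cells / n_occupied

    lo, hi = span / (2.0 * np.sqrt(n_cells)), 2.0 * span
    best_side, best_err = None, np.inf
    for side in np.geomspace(lo, hi, 80):
        err = abs(realized(side) - target_mean_cells)
        if err < best_err:
            best_side, best_err = side, err
    # bisection refinement around the best scan point (mean is ~monotone in side)
    lo2, hi2 = best_side / 1.3, best_side * 1.3
    for _ in range(40):
        mid = 0.5 * (lo2 + hi2)
        if realized(mid) < target_mean_cells:
            lo2 = mid
        else:
            hi2 = mid
        if abs(realized(mid) - target_mean_cells) < best_err:
            best_side, best_err = mid, abs(realized(mid) - target_mean_cells)
    mean = realized(best_side)
    if abs(mean - target_mean_cells) > tolerance * target_mean_cells:
        raise ValidationError(
            f"could not reach mean {target_mean_cells} cells/spot "
            f"(best realized {mean:.2f}); adjust the tissue size"
        )

    bins = _bin_assignments(coords, best_side)
    origin = coords.min(axis=0)
    keys = [tuple(b) for b in bins]
    uniq = sorted(set(keys))
    spot_of_bin = {b: f"spot{i:04d}" for i, b in enumerate(uniq)}
    spot_ids = [spot_of_bin[b] for b in uniq]
    spot_index = {s: i for i, s in enumerate(spot_ids)}

    values = np.zeros((len(uniq), tissue.cells.n_genes))
    for c, b in enumerate(keys):
        values[spot_index[spot_of_bin[b]]] += tissue.cells.values[c]
    centers = np.array([(origin + (np.array(b) + 0.5) * best_side) for b in uniq])
    truth = pd.DataFrame({
        "cell_id": tissue.cells.row_ids,
        "spot_id": [spot_of_bin[b] for b in keys],
    })
    spots = ExpressionMatrix(values, spot_ids, list(tissue.cells.gene_ids),
                             layer="raw_counts", modality="st")
    return SimulatedST(spots, SpotGeometry(spot_ids, centers), truth, mean)


def perturb_expression(E: ExpressionMatrix, pt: float, seed: int = 0) -> ExpressionMatrix:
    """Multiply a random pt-fraction of each cell's genes by 2**Normal(0,1).

    Exactly floor(pt * g) genes are drawn per cell without replacement;
    perturbed counts are rounded to the nearest non-negative integer.
    """
    if E.layer != "raw_counts":
        raise ValidationError("perturbation applies to raw counts")
    if not 0.0 <= pt <= 1.0:
        raise ValidationError("pt must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = E.n_genes
    k = int(np.floor(pt * g))
    values = E.values.copy()
    if k > 0:
        for c in range(E.n_rows):
            idx = rng.choice(g, size=k, replace=False)
            z = rng.normal(0.0, 1.0, size=k)
            values[c, idx] = np.maximum(np.rint(values[c, idx] * np.exp2(z)), 0.0)
    return ExpressionMatrix(values, list(E.row_ids), list(E.gene_ids),
                            layer="raw_counts", modality=E.modality)
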