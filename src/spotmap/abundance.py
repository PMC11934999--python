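"""Expected number of cells per spot.

Spot-level UMI totals are a reasonable proxy for the number of cells a
capture spot covers. The estimator normalizes per-spot totals to counts per
million and log2-transforms them, then fits a line through two anchor
spots: the spot with the minimum nonzero normalized total is assumed to
hold one cell, and the spot at the median normalized total is assumed to
hold the platform's mean cells per spot (default 5, typical for 10x
Visium). Alternatively, nucleus counts from external H&E segmentation can
be supplied directly, or a constant can be used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "CellsPerSpot",
    "estimate_cells_per_spot_umi",
    "cells_per_spot_from_counts",
    "constant_cells_per_spot",
]

logger = logging.getLogger(__name__)


@dataclass
class CellsPerSpot:
    """Positive integer cell count per spot; N = [n1..nw]."""

    spot_ids: list[str]
    counts: np.ndarray
    source: str = "umi_linear"

    def __post_init__(self):
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) != len(self.spot_ids):
            raise ValidationError("counts must align with spot_ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("cell counts must be integers")
            self.counts = np.round(self.counts).astype(int)
        if (self.counts < 1).any():
            raise ValidationError("every spot must hold at least one cell")
        if self.source not in ("umi_linear", "nucleus_counts", "constant"):
            raise ValidationError(f"unknown source tag {self.source!r}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def estimate_cells_per_spot_umi(S_raw: ExpressionMatrix, mean_cells: float = 5.0) -> CellsPerSpot:
    """Two-anchor linear estimate of cells per spot from UMI totals.

    u_j = log2(1 + 1e6 * T_j / sum_k T_k) with T_j the raw UMI total of
    spot j; the line passes through (u_min, 1) and (u_median, mean_cells);
    predictions are rounded half-up and clipped to >= 1.
    """
    if S_raw.layer != "raw_counts":
        raise ValidationError("cell-count estimation expects raw counts")
    if mean_cells <= 0:
        raise ValidationError("mean_cells must be positive")
    totals = S_raw.values.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(S_raw.row_ids, totals) if t <= 0]
        raise ValidationError(f"spots with zero UMI total: {bad[:10]}")
    u = np.log2(1.0 + 1e6 * totals / totals.sum())
    u_min = u[u > 0].min()
    u_med = float(np.median(u))
    if np.isclose(u_min, u_med):
        raise ValidationError(
            "degenerate anchors (minimum equals median normalized UMI); "
            "use constant_cells_per_spot instead"
        )
    slope = (mean_cells - 1.0) / (u_med - u_min)
    est = 1.0 + slope * (u - u_min)
    counts = np.maximum(_round_half_up(est), 1.0).astype(int)
    return CellsPerSpot(list(S_raw.row_ids), counts, source="umi_linear")


def cells_per_spot_from_counts(table: pd.DataFrame, spot_ids: list[str]) -> CellsPerSpot:
    """Adopt externally measured nucleus counts (CSV columns spot_id,count).

    Zero counts are raised to 1 (every spot must be mappable); missing
    spots are an error.
    """
    if not {"spot_id", "count"}.issubset(table.columns):
        raise ValidationError("nucleus-count table needs columns spot_id,count")
    lookup = dict(zip(table["spot_id"].astype(str), table["count"]))
    counts = []
    for s in spot_ids:
        if s not in lookup:
            raise ValidationError(f"no nucleus count for spot {s!r}")
        c = lookup[s]
        if float(c) != int(c):
            raise ValidationError(f"non-integer nucleus count {c!r} for spot {s!r}")
        c = int(c)
        if c < 0:
            raise ValidationError(f"negative nucleus count for spot {s!r}")
        if c == 0:
            logger.warning("spot %s has zero nuclei; raising to 1", s)
            c = 1
        counts.append(c)
    return CellsPerSpot(list(spot_ids), np.array(counts), source="nucleus_counts")


def constant_cells_per_spot(spot_ids: list[str], n: int) -> CellsPerSpot:
    """Assume a constant number of cells in every spot."""
    if int(n) != n or n < 1:
        raise ValidationError("constant cell count must be an integer >= 1")
    return CellsPerSpot(list(spot_ids), np.full(len(spot_ids), int(n)), source="constant")
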