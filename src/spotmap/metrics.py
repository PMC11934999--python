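"""Assessment metrics for cell-to-spot mapping against a known truth.

* ``pmap`` — single-cell mapping precision for regular mapping: per cell
  type, the fraction of assignments placed on the exact ground-truth spot
  (Pmap = N_T / N_map).
* ``celltype_error_rate`` — per-spot cell-type misclassification: the
  minimal number of label mismatches between the predicted and true type
  multisets of each spot, summed and divided by the number of cells.
* ``ploc`` — location precision for greedy mapping: per type, the
  fraction of cells sent to their true spot (Ploc = N_t / N_ct).
* ``proportion_pcc`` — per-spot Pearson correlation between predicted and
  true cell-type proportions.
* ``k_distance`` — mean Euclidean distance from each query point to its k
  nearest reference points (spatial proximity of one population to
  another, e.g. T cells to tumor cells).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import CellAnnotation, ValidationError
from .mapping import MappingResult

__all__ = [
    "EvaluationReport",
    "pmap",
    "celltype_error_rate",
    "ploc",
    "proportion_pcc",
    "k_distance",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Bundle of the mapping metrics for one run."""

    per_type_pmap: pd.Series | None = None
    error_rate: float | None = None
    per_type_ploc: pd.Series | None = None
    proportion_pcc_per_spot: pd.Series | None = None
    proportion_pcc_mean: float | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.per_type_pmap is not None:
            out["pmap"] = {k: (None if pd.isna(v) else float(v))
                           for k, v in self.per_type_pmap.items()}
            out["pmap_median"] = float(self.per_type_pmap.dropna().median())
        if self.error_rate is not None:
            out["error_rate"] = float(self.error_rate)
        if self.per_type_ploc is not None:
            out["ploc"] = {k: (None if pd.isna(v) else float(v))
                           for k, v in self.per_type_ploc.items()}
            out["ploc_median"] = float(self.per_type_ploc.dropna().median())
        if self.proportion_pcc_mean is not None:
            out["proportion_pcc_mean"] = float(self.proportion_pcc_mean)
        return out


def _truth_lookup(truth: pd.DataFrame) -> dict[str, str]:
    return dict(zip(truth["cell_id"].astype(str), truth["spot_id"].astype(str)))


def pmap(result: MappingResult, truth: pd.DataFrame, ann: CellAnnotation) -> pd.Series:
    """Per-type fraction of regular assignments on the exact truth spot."""
    if result.mode != "regular":
        raise ValidationError("Pmap is defined for regular mapping results")
    lookup = _truth_lookup(truth)
    correct: Counter = Counter()
    mapped: Counter = Counter()
    for cell, spot in zip(result.assignments["cell_id"], result.assignments["spot_id"]):
        if cell not in lookup:
            continue
        t = ann.type_of(cell)
        mapped[t] += 1
        if lookup[cell] == spot:
            correct[t] += 1
    values = {t: (correct[t] / mapped[t] if mapped[t] else np.nan) for t in ann.labels}
    return pd.Series(values, name="pmap").sort_index()


def celltype_error_rate(result: MappingResult, truth: pd.DataFrame,
                        ann: CellAnnotation, truth_ann: CellAnnotation | None = None) -> float:
    """Fraction of cells whose per-spot type label cannot be matched.

    Per spot, predicted and true type multisets are compared; the minimal
    number of mismatches is n - sum_t min(pred_t, true_t) on the common
    cardinality, with any cardinality excess counted as errors.
    """
    truth_ann = truth_ann or ann
    true_comp: dict[str, Counter] = {}
    for cell, spot in zip(truth["cell_id"].astype(str), truth["spot_id"].astype(str)):
        true_comp.setdefault(spot, Counter())[truth_ann.type_of(cell)] += 1
    pred_comp: dict[str, Counter] = {}
    for cell, spot in zip(result.assignments["cell_id"], result.assignments["spot_id"]):
        pred_comp.setdefault(spot, Counter())[ann.type_of(cell)] += 1
    n_cells = int(sum(sum(c.values()) for c in true_comp.values()))
    if n_cells == 0:
        raise ValidationError("empty ground truth")
    n_error = 0
    n_card_mismatch = 0
    for spot, true_counter in true_comp.items():
        pred_counter = pred_comp.get(spot, Counter())
        n_true = sum(true_counter.values())
        n_pred = sum(pred_counter.values())
        if n_pred != n_true:
            n_card_mismatch += 1
        overlap = sum((true_counter & pred_counter).values())
        n_error += min(n_true, n_pred) - min(overlap, min(n_true, n_pred))
        n_error += max(0, n_true - n_pred)  # cells never filled count as errors
    if n_card_mismatch:
        logger.warning("%d spots had predicted/true cell-count mismatches; "
                       "excess counted as errors", n_card_mismatch)
    return n_error / n_cells


def ploc(result: MappingResult, truth: pd.DataFrame, ann: CellAnnotation) -> pd.Series:
    """Per-type fraction of greedily placed cells on their true spot."""
    if result.mode != "greedy":
        raise ValidationError("Ploc is defined for greedy mapping results")
    lookup = _truth_lookup(truth)
    correct: Counter = Counter()
    total: Counter = Counter()
    for cell, spot in zip(result.assignments["cell_id"], result.assignments["spot_id"]):
        if cell not in lookup:
            raise ValidationError(f"cell {cell!r} has no ground-truth spot")
        t = ann.type_of(cell)
        total[t] += 1
        if lookup[cell] == spot:
            correct[t] += 1
    values = {t: (correct[t] / total[t] if total[t] else np.nan) for t in ann.labels}
    return pd.Series(values, name="ploc").sort_index()


def proportion_pcc(pred: pd.DataFrame, true: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-spot Pearson correlation of predicted vs true type proportions."""
    if list(pred.columns) != list(true.columns):
        raise ValidationError("proportion tables must share their type columns")
    if list(pred.index) != list(true.index):
        raise ValidationError("proportion tables must share their spots")
    P = pred.to_numpy(dtype=float)
    T = true.to_numpy(dtype=float)
    Pc = P - P.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    p_norm = np.linalg.norm(Pc, axis=1)
    t_norm = np.linalg.norm(Tc, axis=1)
    degenerate = (p_norm == 0) | (t_norm == 0)
    if degenerate.any():
        logger.warning("%d spots have zero-variance proportions; PCC undefined there",
                       int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (Pc * Tc).sum(axis=1) / (p_norm * t_norm)
    pcc[degenerate] = np.nan
    series = pd.Series(pcc, index=pred.index, name="pcc")
    return series, float(series.dropna().mean())


def k_distance(query_coords: np.ndarray, reference_coords: np.ndarray,
               k: int = 5) -> np.ndarray:
    """Mean Euclidean distance from each query to its k nearest references."""
    query_coords = np.atleast_2d(np.asarray(query_coords, dtype=float))
    reference_coords = np.atleast_2d(np.asarray(reference_coords, dtype=float))
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > reference_coords.shape[0]:
        raise ValidationError(
            f"k={k} exceeds the {reference_coords.shape[0]} reference points"
        )
    tree = cKDTree(reference_coords)
    dists, _ = tree.query(query_coords, k=k)
    dists = np.asarray(dists, dtype=float)
    if dists.ndim == 1:  # k == 1
        dists = dists[:, None]
    return dists.mean(axis=1)
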