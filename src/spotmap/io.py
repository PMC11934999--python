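"""Expression-matrix containers, readers/writers, and preprocessing.

The two matrices the mapper consumes are a single-cell matrix ``C`` (m cells
x g genes) and a spot matrix ``S`` (w spots x g genes), both raw counts on
input. Preprocessing removes genes detected in at most one row, restricts
both matrices to their common genes, and normalizes each row to counts per
million followed by log2(1 + x) — after which the two modalities are
directly comparable.

Supported on-disk dialects: a MatrixMarket triplet directory
(matrix.mtx + barcodes.tsv + features.tsv), a dense CSV (header row of gene
ids, first column row ids), and h5ad (counts in ``X``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SpotGeometry",
    "CellAnnotation",
    "ValidationError",
    "read_expression",
    "write_expression",
    "read_coordinates",
    "write_coordinates",
    "filter_rare_genes",
    "normalize_cpm_log2",
    "intersect_genes",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Non-negative (rows x genes) matrix with ids and a layer tag.

    Parameters
    ----------
    values : ndarray
        Dense non-negative matrix, one row per cell or spot.
    row_ids, gene_ids : list of str
        Unique barcodes / gene identifiers.
    layer : {"raw_counts", "cpm_log2"}
        Whether the values are raw counts or CPM+log2-normalized.
    modality : {"sc", "st"}
    """

    values: np.ndarray
    row_ids: list[str]
    gene_ids: list[str]
    layer: str = "raw_counts"
    modality: str = "sc"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.validate()

    def validate(self):
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if g == 0:
            raise ValidationError("expression matrix has zero genes")
        if len(self.row_ids) != n:
            raise ValidationError(f"{len(self.row_ids)} row ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if len(set(self.row_ids)) != n:
            raise ValidationError("duplicated row ids")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicated gene ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite expression values")
        if (self.values < 0).any():
            raise ValidationError("negative expression values")
        if self.layer not in ("raw_counts", "cpm_log2"):
            raise ValidationError(f"unknown layer tag {self.layer!r}")
        if self.modality not in ("sc", "st"):
            raise ValidationError(f"unknown modality tag {self.modality!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.gene_ids)


@dataclass
class SpotGeometry:
    """Per-spot 2-D coordinates, aligned one-to-one with the ST matrix rows."""

    spot_ids: list[str]
    coords: np.ndarray

    def __post_init__(self):
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be (n_spots, 2)")
        if len(self.spot_ids) != self.coords.shape[0]:
            raise ValidationError("spot_ids length mismatch with coords")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValidationError("duplicated spot ids")

    def match(self, st: ExpressionMatrix) -> "SpotGeometry":
        """Reorder to match the row order of an ST expression matrix."""
        if set(self.spot_ids) != set(st.row_ids):
            raise ValidationError("geometry spot ids do not match ST matrix rows")
        pos = {s: i for i, s in enumerate(self.spot_ids)}
        order = [pos[s] for s in st.row_ids]
        return SpotGeometry(list(st.row_ids), self.coords[order])


@dataclass
class CellAnnotation:
    """Cell-type label per cell. Labels are free strings, non-empty."""

    cell_ids: list[str]
    cell_type: list[str]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cell_type = [str(t) for t in self.cell_type]
        if len(self.cell_ids) != len(self.cell_type):
            raise ValidationError("cell_ids and cell_type lengths differ")
        if any(t == "" for t in self.cell_type):
            raise ValidationError("empty cell-type label")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicated cell ids in annotation")
        self._index = dict(zip(self.cell_ids, self.cell_type))

    def type_of(self, cell_id: str) -> str:
        try:
            return self._index[cell_id]
        except KeyError:
            raise ValidationError(f"cell {cell_id!r} has no annotation") from None

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.cell_type))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, format: str, layer: str = "raw_counts",
                    modality: str = "sc") -> ExpressionMatrix:
    """Read an expression matrix from ``mtx_dir``, ``csv`` or ``h5ad``.

    MTX directories follow the CellRanger triplet convention with genes as
    features (matrix is genes x barcodes on disk, transposed on read).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)),
                                list(df.columns.astype(str)), layer=layer, modality=modality)
    if format == "mtx_dir":
        from scipy.io import mmread

        mat = mmread(path / "matrix.mtx")
        barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].astype(str).tolist()
        features = pd.read_csv(path / "features.tsv", header=None, sep="\t")[0].astype(str).tolist()
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float).T
        return ExpressionMatrix(values, barcodes, features, layer=layer, modality=modality)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return ExpressionMatrix(np.asarray(X, dtype=float),
                                list(adata.obs_names), list(adata.var_names),
                                layer=layer, modality=modality)
    raise ValueError(f"unknown format {format!r}")


def write_expression(E: ExpressionMatrix, path, format: str) -> None:
    """Write a matrix so that :func:`read_expression` round-trips it."""
    path = Path(path)
    if format == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        E.to_frame().to_csv(path)
        return
    if format == "mtx_dir":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), csr_matrix(E.values.T))
        pd.Series(E.row_ids).to_csv(path / "barcodes.tsv", index=False, header=False)
        pd.Series(E.gene_ids).to_csv(path / "features.tsv", index=False, header=False)
        return
    if format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(X=E.values.copy(),
                           obs=pd.DataFrame(index=pd.Index(E.row_ids)),
                           var=pd.DataFrame(index=pd.Index(E.gene_ids)))
        path.parent.mkdir(parents=True, exist_ok=True)
        adata.write_h5ad(path)
        return
    raise ValueError(f"unknown format {format!r}")


def read_coordinates(path) -> SpotGeometry:
    """Read spot coordinates from a CSV with columns spot_id,x,y."""
    df = pd.read_csv(path)
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValidationError(f"coordinate file must have columns {sorted(required)}")
    return SpotGeometry(list(df["spot_id"].astype(str)), df[["x", "y"]].to_numpy(dtype=float))


def write_coordinates(G: SpotGeometry, path) -> None:
    pd.DataFrame({"spot_id": G.spot_ids, "x": G.coords[:, 0], "y": G.coords[:, 1]}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_rare_genes(E: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes detected in no more than one row (cell or spot)."""
    if E.layer != "raw_counts":
        raise ValidationError("gene filtering expects raw counts")
    prevalence = (E.values > 0).sum(axis=0)
    keep = prevalence >= 2
    if not keep.any():
        raise ValidationError(
            "no gene is detected in at least 2 rows; inputs look incompatible"
        )
    return replace(
        E,
        values=E.values[:, keep],
        gene_ids=[g for g, k in zip(E.gene_ids, keep) if k],
    )


def normalize_cpm_log2(E: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each row to one million total counts, then log2(1 + x)."""
    if E.layer != "raw_counts":
        raise ValidationError("normalization expects raw counts")
    totals = E.values.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = [r for r, z in zip(E.row_ids, zero) if z]
        raise ValidationError(f"all-zero rows cannot be CPM-normalized: {bad[:10]}")
    cpm = E.values * (1e6 / totals[:, None])
    return replace(E, values=np.log2(1.0 + cpm), layer="cpm_log2")


def intersect_genes(C: ExpressionMatrix, S: ExpressionMatrix):
    """Restrict both matrices to their shared genes, lexicographic order."""
    common = sorted(set(C.gene_ids) & set(S.gene_ids))
    if not common:
        raise ValidationError("no genes shared between the two matrices")
    c_pos = {g: i for i, g in enumerate(C.gene_ids)}
    s_pos = {g: i for i, g in enumerate(S.gene_ids)}
    c_idx = [c_pos[g] for g in common]
    s_idx = [s_pos[g] for g in common]
    return (
        replace(C, values=C.values[:, c_idx], gene_ids=list(common)),
        replace(S, values=S.values[:, s_idx], gene_ids=list(common)),
    )
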