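"""Core containers and file I/O for the deconvolution pipeline.

Three containers move through every stage:

* :class:`ExpressionMatrix` — a genes x columns matrix of expression values,
  where columns are either bulk samples or single cells.  The internal
  orientation is always genes x columns; readers convert at the boundary.
* :class:`CellLabelTable` — per-cell metadata (sample of origin, cluster
  assignment, QC covariates), carried as a pandas DataFrame indexed by cell id.
* :class:`CompositionMatrix` — samples x cell-types proportion matrices, used
  both for gold standards and for solver estimates.

Supported on-disk formats are dense TSV/CSV matrices, MatrixMarket triplets
with sidecar features/barcodes files (the common 10x export layout), and TSV
label/composition tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("squidecon")

#: unit tags for which negative values are tolerated
_SIGNED_UNITS = {"lognorm", "arbitrary"}

VALID_UNIT_TAGS = {"counts", "TPM", "TMM", "lognorm", "arbitrary"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups.index[:10]))}")


@dataclass
class ExpressionMatrix:
    """A genes x columns expression matrix with string identifiers.

    ``values`` may be a dense ndarray or a scipy sparse matrix; both are
    accepted everywhere downstream.  ``unit_tag`` records the measurement
    scale; negative entries are only legal for ``lognorm``/``arbitrary``
    (transformed bulk profiles may dip below zero).
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    column_ids: list[str]
    unit_tag: str = "counts"

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if self.unit_tag not in VALID_UNIT_TAGS:
            raise ValueError(f"unknown unit_tag {self.unit_tag!r}")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.column_ids, "column ids")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        dense = self.to_dense(copy=False)
        if not np.all(np.isfinite(dense)):
            raise ValueError("expression values must be finite")
        if self.unit_tag not in _SIGNED_UNITS and dense.min(initial=0) < 0:
            raise ValueError(f"negative values not allowed for unit_tag={self.unit_tag}")

    # -- basic accessors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_dense(self, copy: bool = True) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        arr = np.asarray(self.values, dtype=float)
        return arr.copy() if copy else arr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.gene_ids, columns=self.column_ids)

    # -- subsetting ------------------------------------------------------
    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index().get_indexer(list(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not present: {missing[:10]}")
        vals = self.values[idx, :] if not sp.issparse(self.values) else self.values.tocsr()[idx, :]
        return ExpressionMatrix(vals, list(genes), list(self.column_ids), self.unit_tag)

    def subset_columns(self, columns: Sequence[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.column_ids).get_indexer(list(columns))
        if (idx < 0).any():
            missing = [c for c, i in zip(columns, idx) if i < 0]
            raise KeyError(f"columns not present: {missing[:10]}")
        vals = self.values[:, idx] if not sp.issparse(self.values) else self.values.tocsc()[:, idx]
        return ExpressionMatrix(vals, list(self.gene_ids), list(columns), self.unit_tag)

    def with_values(self, values, unit_tag: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values, list(self.gene_ids), list(self.column_ids), unit_tag or self.unit_tag
        )


@dataclass
class CellLabelTable:
    """Per-cell metadata: sample of origin, cluster, and QC covariates.

    Backed by a DataFrame indexed by unique cell id with columns
    ``sample_id``, ``cluster_id`` (``"unassigned"`` allowed),
    ``mito_fraction`` and ``ribo_fraction`` (fractions in [0, 1]; NaN when
    unknown — QC then derives them from gene-name prefixes).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "cluster_id")

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "cell_id" in t.columns:
            t = t.set_index("cell_id")
        t.index = t.index.astype(str)
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].unique()
            raise ValueError(f"duplicate cell ids: {list(dup[:10])}")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"label table missing required column {col!r}")
            if t[col].isna().any():
                raise ValueError(f"label table column {col!r} contains missing values")
            t[col] = t[col].astype(str)
        for col in ("mito_fraction", "ribo_fraction"):
            if col not in t.columns:
                t[col] = np.nan
            vals = t[col].to_numpy(dtype=float)
            bad = vals[~np.isnan(vals)]
            if len(bad) and (bad.min() < 0 or bad.max() > 1):
                raise ValueError(f"{col} must lie in [0, 1]")
        self.table = t

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, cell_ids: Sequence[str]) -> "CellLabelTable":
        return CellLabelTable(self.table.loc[list(cell_ids)].copy())

    def with_clusters(self, mapping: dict[str, str]) -> "CellLabelTable":
        t = self.table.copy()
        t["cluster_id"] = t["cluster_id"].map(lambda c: mapping.get(c, c))
        return CellLabelTable(t)


@dataclass
class CompositionMatrix:
    """Samples x cell-types proportions (gold standard or solver estimate)."""

    values: np.ndarray
    sample_ids: list[str]
    celltype_ids: list[str]
    kind: str = "estimate"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.celltype_ids = [str(c) for c in self.celltype_ids]
        if self.kind not in ("gold_standard", "estimate"):
            raise ValueError(f"unknown kind {self.kind!r}")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.celltype_ids, "celltype ids")
        if self.values.shape != (len(self.sample_ids), len(self.celltype_ids)):
            raise ValueError("composition shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("composition values must be finite")
        if self.kind == "gold_standard" and len(self.sample_ids):
            if self.values.min(initial=0) < 0:
                raise ValueError("gold-standard proportions must be non-negative")
            sums = self.values.sum(axis=1)
            if np.abs(sums - 1.0).max(initial=0) > 1e-6:
                raise ValueError("gold-standard rows must sum to 1 within 1e-6")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.celltype_ids)

    def align(self, sample_ids: Sequence[str], celltype_ids: Sequence[str]) -> "CompositionMatrix":
        frame = self.to_frame().loc[list(sample_ids), list(celltype_ids)]
        return CompositionMatrix(frame.to_numpy(), list(sample_ids), list(celltype_ids), self.kind)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dense_matrix(
    path: str | Path,
    orientation: str = "genes_by_columns",
    unit_tag: str = "counts",
) -> ExpressionMatrix:
    """Read a dense TSV/CSV matrix with a header row and id first column.

    ``orientation`` states how the file is laid out; the result is always
    genes x columns.  Delimiter is sniffed from the extension ('.csv' means
    comma, anything else tab).  Numbers must use dot decimals.
    """
    if orientation not in ("genes_by_columns", "columns_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    frame.index = frame.index.astype(str)

    def _dup_err(ids, what):
        counts = pd.Series(ids).value_counts()
        dups = counts[counts > 1]
        if len(dups):
            raise ValueError(
                f"{path}: duplicate {what}: {', '.join(map(str, dups.index[:10]))}"
            )

    _dup_err(frame.index, "row ids")
    _dup_err(frame.columns, "column ids")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for j in range(raw.shape[1]):
        col = pd.to_numeric(pd.Series(raw[:, j]), errors="coerce")
        bad = np.nonzero(col.isna().to_numpy() & (raw[:, j] != "nan"))[0]
        if len(bad):
            r = bad[0]
            raise ValueError(
                f"{path}: non-numeric value {raw[r, j]!r} at row {frame.index[r]!r}, "
                f"column {frame.columns[j]!r}"
            )
        values[:, j] = col.to_numpy(dtype=float)
    if orientation == "columns_by_genes":
        values = values.T
        gene_ids, column_ids = list(frame.columns), list(frame.index)
    else:
        gene_ids, column_ids = list(frame.index), list(frame.columns)
    return ExpressionMatrix(values, gene_ids, column_ids, unit_tag)


def write_dense_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write an ExpressionMatrix as TSV (genes as rows) at full precision."""
    mat.to_frame().to_csv(Path(path), sep="\t", float_format="%.17g")


def _read_id_lines(path: Path) -> list[str]:
    """First whitespace-separated token per line (10x features have 3 columns)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0].split(" ")[0] if ("\t" in line or " " in line) else line)
    return ids


def read_mtx_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate matrix with features/barcodes sidecars.

    The MTX header's dimensions must match the sidecar line counts; MTX
    coordinates are 1-based in the file and converted to the internal
    0-based convention by the parser.
    """
    mat = scipy.io.mmread(str(matrix_path))
    genes = _read_id_lines(Path(features_path))
    cells = _read_id_lines(Path(barcodes_path))
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"MTX header declares shape {mat.shape} but features/barcodes files "
            f"have {len(genes)}/{len(cells)} lines"
        )
    return ExpressionMatrix(sp.csr_matrix(mat), genes, cells, "counts")


def write_mtx_triplet(
    mat: ExpressionMatrix, matrix_path: str | Path, features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    values = mat.values if sp.issparse(mat.values) else sp.coo_matrix(mat.values)
    scipy.io.mmwrite(str(matrix_path), values)
    Path(features_path).write_text("".join(g + "\n" for g in mat.gene_ids))
    Path(barcodes_path).write_text("".join(c + "\n" for c in mat.column_ids))


def read_labels(path: str | Path) -> CellLabelTable:
    """Read a per-cell label table (TSV, cell ids in the first column)."""
    t = pd.read_csv(Path(path), sep="\t", index_col=0)
    t.index.name = "cell_id"
    return CellLabelTable(t)


def write_labels(labels: CellLabelTable, path: str | Path) -> None:
    t = labels.table.copy()
    t.index.name = "cell_id"
    t.to_csv(Path(path), sep="\t")


def read_composition(path: str | Path, kind: str = "estimate") -> CompositionMatrix:
    """Read a samples x cell-types TSV proportion table."""
    frame = pd.read_csv(Path(path), sep="\t", index_col=0, float_precision="round_trip")
    return CompositionMatrix(
        frame.to_numpy(dtype=float), list(frame.index.astype(str)),
        list(frame.columns.astype(str)), kind,
    )


def write_composition(comp: CompositionMatrix, path: str | Path) -> None:
    """Write a CompositionMatrix as TSV at full double precision.

    Written files round-trip through :func:`read_composition` to within
    1e-12 (in practice bit-exactly, via repr-faithful formatting).
    """
    comp.to_frame().to_csv(Path(path), sep="\t", float_format="%.17g")


def setup_logging(level: str = "INFO") -> None:
    """Configure stderr logging for the package (used by the CLI)."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
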