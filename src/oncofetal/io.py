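"""Readers, writers and the shared data carriers.

Single-cell counts travel as a :class:`CellDataset`: a dense cells × genes
UMI count matrix plus per-cell metadata (sample, liver phenotype, cell type,
cluster) and an optional per-gene genomic position table used by the CNV
stage.  Two on-disk dialects are supported: a 10x-style MatrixMarket triplet
directory (``matrix.mtx`` with genes in rows, ``barcodes.tsv``,
``features.tsv``) and a dense TSV with cells in rows.

All expression-based stages consume a :class:`NormalizedMatrix` produced by
:func:`normalize_log_cp10k` — counts scaled to 10,000 per cell, then
``log1p`` (natural log).  This is the single preprocessing convention of the
package.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("oncofetal")

PHENOTYPES = ("fetal", "normal", "adjacent", "tumor_HCC", "tumor_HB", "tumor_ICC")
TUMOR_PHENOTYPES = ("tumor_HCC", "tumor_HB", "tumor_ICC")

REQUIRED_META_COLUMNS = ("sample_id", "phenotype", "cell_type")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the declared dialect."""


class ValidationError(ValueError):
    """Raised when parsed inputs violate a dataset invariant."""


def chromosome_sort_key(chrom: str) -> tuple:
    """Total order on chromosome names: natural-numeric first, then lexicographic.

    ``chr2`` sorts before ``chr10``; purely alphabetic names (``chrX``,
    ``chrM``) come after all numeric ones, in lexicographic order.
    """
    name = str(chrom)
    stripped = re.sub(r"^(chr|Chr|CHR)", "", name)
    if stripped.isdigit():
        return (0, int(stripped), "")
    return (1, 0, name)


@dataclass
class CellDataset:
    """Cells × genes UMI counts with aligned cell metadata and gene positions.

    counts : (n_cells, n_genes) non-negative integer array
    cell_ids, gene_ids : unique identifiers, aligned to the matrix axes
    cell_meta : indexed by cell_id; requires sample_id, phenotype, cell_type
        columns; cluster is optional
    gene_pos : optional, indexed by gene_id with chrom, start, end
        (1-based inclusive base pairs)
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    gene_pos: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"id lengths ({len(self.cell_ids)}, {len(self.gene_ids)}) do not "
                f"match matrix shape {self.counts.shape}"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if np.any(self.counts < 0):
            raise ValidationError("negative entries in count matrix")
        missing_cols = [c for c in REQUIRED_META_COLUMNS if c not in self.cell_meta.columns]
        if missing_cols:
            raise ValidationError(f"cell metadata missing required columns: {missing_cols}")
        meta_cells = set(self.cell_meta.index.astype(str))
        orphans = [c for c in self.cell_ids if c not in meta_cells]
        if orphans:
            raise ValidationError(
                f"{len(orphans)} cells in matrix absent from metadata, "
                f"e.g. {orphans[:5]}"
            )
        # align metadata rows to matrix order
        self.cell_meta = self.cell_meta.loc[self.cell_ids]
        if self.gene_pos is not None:
            for col in ("chrom", "start", "end"):
                if col not in self.gene_pos.columns:
                    raise ValidationError(f"gene_pos missing column {col!r}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass
class NormalizedMatrix:
    """Log-scale normalized expression (cells × genes), same axes as its source."""

    values: np.ndarray
    norm_method: str = "log_cp10k"
    scale_factor: float = 1e4
    zero_cells: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("normalized matrix contains non-finite values")
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")


def normalize_log_cp10k(ds: CellDataset, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Counts-per-10K + log1p (natural log) normalization.

    Cells with zero total count are kept as all-zero rows and flagged in
    ``zero_cells`` (they are excluded from scoring denominators downstream).
    """
    counts = ds.counts.astype(float)
    totals = counts.sum(axis=1)
    zero_cells = totals == 0
    if zero_cells.all():
        raise ValidationError("all cells have zero total count")
    if zero_cells.any():
        logger.warning("%d cells with zero total count kept as all-zero rows", zero_cells.sum())
    safe = np.where(zero_cells, 1.0, totals)
    values = np.log1p(counts / safe[:, None] * scale_factor)
    return NormalizedMatrix(values=values, scale_factor=scale_factor, zero_cells=zero_cells)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_mtx_dir(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    mtx_path = os.path.join(path, "matrix.mtx")
    bc_path = os.path.join(path, "barcodes.tsv")
    ft_path = os.path.join(path, "features.tsv")
    for p in (mtx_path, bc_path, ft_path):
        if not os.path.exists(p):
            raise FormatError(f"MTX triplet incomplete: missing {os.path.basename(p)}")
    try:
        mat = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise FormatError(f"malformed MTX file {mtx_path}: {exc}") from exc
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(ft_path, sep="\t", header=None)[0].astype(str).tolist()
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    # 10x convention: features (genes) in rows, barcodes (cells) in columns
    if dense.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix shape {dense.shape} does not match features×barcodes "
            f"({len(features)}, {len(barcodes)})"
        )
    return dense.T, barcodes, features


def _read_dense_tsv(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.shape[1] == 0:
        raise FormatError(f"dense TSV {path} has no gene columns")
    return df.to_numpy(), df.index.astype(str).tolist(), df.columns.astype(str).tolist()


def read_gene_positions(path: str) -> pd.DataFrame:
    """Gene-position TSV with columns gene_id, chrom, start, end (1-based inclusive)."""
    pos = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in pos.columns:
            raise ValidationError(f"gene position table missing column {col!r}")
    return pos.set_index("gene_id")


def read_cell_dataset(
    matrix_path: str,
    meta_path: str,
    gene_pos_path: str | None = None,
) -> CellDataset:
    """Load a CellDataset from disk.

    ``matrix_path`` is either an MTX triplet directory or a dense TSV (cells
    in rows).  Cells present in the matrix but absent from metadata are an
    error; metadata rows without a matrix cell are dropped with a warning.
    """
    if os.path.isdir(matrix_path):
        counts, cell_ids, gene_ids = _read_mtx_dir(matrix_path)
    else:
        counts, cell_ids, gene_ids = _read_dense_tsv(matrix_path)
    if np.any(counts != np.round(counts)):
        logger.warning("count matrix contains non-integer values; truncating")
    counts = np.asarray(np.round(counts), dtype=np.int64)

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise ValidationError("metadata TSV missing cell_id column")
    if meta["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id rows in metadata")
    meta = meta.set_index("cell_id")
    extra = meta.index.difference(cell_ids)
    if len(extra):
        logger.warning("dropping %d metadata rows without a matrix cell", len(extra))
        meta = meta.drop(index=extra)

    gene_pos = read_gene_positions(gene_pos_path) if gene_pos_path else None
    if gene_pos is not None:
        gene_pos = gene_pos.loc[gene_pos.index.intersection(gene_ids)]
        gene_pos["start"] = gene_pos["start"].astype(int)
        gene_pos["end"] = gene_pos["end"].astype(int)

    return CellDataset(
        counts=counts, cell_ids=cell_ids, gene_ids=gene_ids,
        cell_meta=meta, gene_pos=gene_pos,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cell_dataset(ds: CellDataset, out_dir: str, dialect: str = "mtx") -> None:
    """Write a CellDataset: matrix (chosen dialect) + metadata + positions."""
    os.makedirs(out_dir, exist_ok=True)
    if dialect == "mtx":
        mtx_dir = os.path.join(out_dir, "matrix")
        os.makedirs(mtx_dir, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(ds.counts.T)  # genes × cells on disk
        scipy.io.mmwrite(os.path.join(mtx_dir, "matrix.mtx"), sparse, field="integer")
        pd.Series(ds.cell_ids).to_csv(
            os.path.join(mtx_dir, "barcodes.tsv"), sep="\t", header=False, index=False)
        pd.Series(ds.gene_ids).to_csv(
            os.path.join(mtx_dir, "features.tsv"), sep="\t", header=False, index=False)
    elif dialect == "dense":
        pd.DataFrame(ds.counts, index=ds.cell_ids, columns=ds.gene_ids).to_csv(
            os.path.join(out_dir, "counts.tsv"), sep="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = ds.cell_meta.copy()
    meta.index.name = "cell_id"
    meta.to_csv(os.path.join(out_dir, "cell_meta.tsv"), sep="\t")
    if ds.gene_pos is not None:
        pos = ds.gene_pos.copy()
        pos.index.name = "gene_id"
        pos.to_csv(os.path.join(out_dir, "gene_pos.tsv"), sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a GMT file into {set name: gene list}; description column ignored."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")
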