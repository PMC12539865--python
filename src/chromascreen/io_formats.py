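"""On-disk formats for the pipeline: contact matrices, tracks, genes, tables.

All genomic coordinates are 0-based half-open internally. GFF-like input
(1-based inclusive) is converted at the boundary. Files are tab-delimited
text; lines starting with '#' are comments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed file content (bad indices, wrong column count, unparsable)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinTable:
    """Fixed-resolution binning of one chromosome.

    Bin ``i`` spans ``[i*resolution, min((i+1)*resolution, chrom_length))``,
    0-based half-open; bins are contiguous, non-overlapping and sorted.
    """

    chrom: str
    resolution: int
    chrom_length: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValidationError(f"resolution must be positive, got {self.resolution}")
        if self.chrom_length <= 0:
            raise ValidationError(f"chrom_length must be positive, got {self.chrom_length}")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.chrom_length / self.resolution)

    def bin_start(self, i: int) -> int:
        return i * self.resolution

    def bin_end(self, i: int) -> int:
        return min((i + 1) * self.resolution, self.chrom_length)

    def bin_of(self, pos: int) -> int:
        """Bin index containing position ``pos`` (0-based)."""
        if not 0 <= pos < self.chrom_length:
            raise ValidationError(
                f"position {pos} outside chromosome {self.chrom} [0, {self.chrom_length})"
            )
        return pos // self.resolution


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact counts."""

    bin_table: BinTable
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        n = self.bin_table.n_bins
        if c.shape != (n, n):
            raise ValidationError(f"counts shape {c.shape} != ({n}, {n})")
        if not np.all(np.isfinite(c)):
            raise ValidationError("counts contain non-finite values")
        if np.any(c < 0):
            raise ValidationError("counts contain negative values")
        if not np.allclose(c, c.T, rtol=0, atol=1e-8):
            raise ValidationError("counts matrix is not symmetric")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.bin_table.n_bins


@dataclass(frozen=True)
class Gene:
    """Gene interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

def _data_lines(path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_contact_matrix(path, format: str, bin_table: BinTable) -> ContactMatrix:
    """Read a contact matrix from COO triplets or a dense text matrix.

    COO rows are ``bin_i<TAB>bin_j<TAB>count``; each unordered pair may be
    given once (it is mirrored) and duplicate pairs are summed. Dense input
    must already be symmetric.
    """
    n = bin_table.n_bins
    if format == "coo":
        m = np.zeros((n, n))
        for lineno, line in _data_lines(path):
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if i < 0 or j < 0 or i >= n or j >= n:
                raise FormatError(f"{path}:{lineno}: bin index out of range for n_bins={n}")
            if c < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {c}")
            m[i, j] += c
        counts = m + m.T - np.diag(np.diag(m))
        return ContactMatrix(bin_table, counts)
    elif format == "dense":
        counts = np.loadtxt(path, comments="#", ndmin=2)
        if counts.shape != (n, n):
            raise FormatError(f"{path}: dense matrix shape {counts.shape} != ({n}, {n})")
        return ContactMatrix(bin_table, counts)
    raise ValueError(f"unknown contact matrix format {format!r}")


def write_contact_matrix(cm: ContactMatrix, path, format: str = "coo") -> None:
    """Write a contact matrix; COO emits the upper triangle incl. diagonal."""
    if format == "coo":
        iu, ju = np.triu_indices(cm.n_bins)
        vals = cm.counts[iu, ju]
        nz = vals != 0
        with open(path, "w") as fh:
            fh.write(f"# chrom={cm.bin_table.chrom} resolution={cm.bin_table.resolution}\n")
            for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
                fh.write(f"{i}\t{j}\t{v:.10g}\n")
    elif format == "dense":
        write_dense_matrix(cm.counts, path)
    else:
        raise ValueError(f"unknown contact matrix format {format!r}")


def write_dense_matrix(values: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), delimiter="\t", fmt="%.10g")


def read_dense_matrix(path) -> np.ndarray:
    return np.loadtxt(path, comments="#", ndmin=2)


# ---------------------------------------------------------------------------
# Per-bin tracks (bedGraph)
# ---------------------------------------------------------------------------

def write_track(values: Sequence[float], bin_table: BinTable, path) -> None:
    """Write one value per bin as bedGraph; NaN written literally as 'nan'."""
    values = np.asarray(values, dtype=float)
    if len(values) != bin_table.n_bins:
        raise ValidationError(
            f"track length {len(values)} != n_bins {bin_table.n_bins}"
        )
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            sv = "nan" if not np.isfinite(v) else f"{v:.6g}"
            fh.write(f"{bin_table.chrom}\t{bin_table.bin_start(i)}\t{bin_table.bin_end(i)}\t{sv}\n")


def read_track(path, bin_table: BinTable) -> np.ndarray:
    values = np.full(bin_table.n_bins, np.nan)
    seen = 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom, start, end, val = parts
        if chrom != bin_table.chrom:
            raise FormatError(
                f"{path}:{lineno}: chrom {chrom!r} != bin table chrom {bin_table.chrom!r}"
            )
        i = int(start) // bin_table.resolution
        if i >= bin_table.n_bins or int(start) != bin_table.bin_start(i) or int(end) != bin_table.bin_end(i):
            raise FormatError(f"{path}:{lineno}: interval does not match bin table")
        values[i] = float(val)
        seen += 1
    if seen != bin_table.n_bins:
        raise ValidationError(f"{path}: {seen} bins read, expected {bin_table.n_bins}")
    return values


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

def read_genes(path, format: str = "bed") -> list[Gene]:
    """Read gene intervals from BED (>=4 cols) or a GFF-like 9-column file.

    GFF-like coordinates (1-based inclusive) are converted to 0-based
    half-open. Input order is preserved.
    """
    genes: list[Gene] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if format == "bed":
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >=4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 else "."
        elif format == "gff_like":
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: GFF-like needs 9 columns")
            chrom = parts[0]
            start, end = int(parts[3]) - 1, int(parts[4])
            strand = parts[6] if parts[6] in {"+", "-"} else "."
            name = None
            for attr in parts[8].split(";"):
                attr = attr.strip()
                if attr.startswith("ID="):
                    name = attr[3:]
                    break
            if name is None:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
        else:
            raise ValueError(f"unknown gene format {format!r}")
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: start >= end after conversion")
        genes.append(Gene(name, chrom, start, end, strand))
    return genes


def write_genes(genes: Iterable[Gene], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Expression, gene lists, tables
# ---------------------------------------------------------------------------

def read_sample_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with at least sample/group/stage columns."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str})
    for col in ("sample", "group", "stage"):
        if col not in meta.columns:
            raise FormatError(f"{path}: missing required metadata column {col!r}")
    if meta["sample"].duplicated().any():
        raise ValidationError(f"{path}: duplicated sample ids")
    return meta.set_index("sample", drop=False)


def read_expression(path, metadata_path=None):
    """Read a genes x samples count TSV into an ExpressionMatrix.

    First column is gene_id; remaining columns are numeric counts. Duplicated
    gene rows are deduplicated if identical and rejected on conflict.
    """
    from .coexpression import ExpressionMatrix  # avoids import cycle at module load

    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    # locate the first non-numeric cell for a useful error message
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in expression table")
    if df.index.duplicated().any():
        dup = df[df.index.duplicated(keep=False)]
        for gid, grp in dup.groupby(level=0):
            if not (grp.nunique() <= 1).all():
                raise ValidationError(f"{path}: conflicting duplicate rows for gene {gid!r}")
        df = df[~df.index.duplicated(keep="first")]
    meta = read_sample_metadata(metadata_path) if metadata_path is not None else None
    if meta is not None:
        missing = [s for s in df.columns if s not in meta.index]
        if missing:
            raise ValidationError(f"{path}: samples missing from metadata: {missing}")
        meta = meta.loc[list(df.columns)]
    return ExpressionMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        metadata=meta,
    )


def write_expression(expr, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_list(path) -> set[str]:
    ids: set[str] = set()
    for _, line in _data_lines(path):
        ids.add(line.split()[0])
    return ids


def write_gene_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(f"{gid}\n")


def write_table(rows, path) -> None:
    """Write rows (DataFrame or list of dicts) as a TSV with header."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
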