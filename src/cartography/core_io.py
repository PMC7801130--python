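"""Containers and readers/writers for the standard formats the pipeline touches.

The central in-memory objects are :class:`CountMatrix` (sparse gene x cell UMI
counts with per-cell metadata), :class:`ExprMatrix` (normalized expression or
residuals on the same axes) and :class:`GeneSet` (a named list of gene
symbols).  On-disk formats are the 10X Genomics MatrixMarket triplet layout
(v2 ``genes.tsv`` and v3 ``features.tsv.gz`` dialects, gzip handled
transparently) and tab-separated GMT gene-set files.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: feature id of the CAR transcript pseudo-feature (counts mapped to the
#: region upstream of the 3'LTR polyadenylation site of the CAR vector).
CAR_FEATURE_ID = "CAR-3LTR"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(ValueError):
    """Files parsed individually but are mutually inconsistent."""


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class GeneSet:
    """A named list of gene symbols (signature or pathway term)."""

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError(f"gene set {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with axis labels and metadata.

    ``cell_meta`` is indexed by barcode and carries at least ``donor``,
    ``condition`` and ``sample_id`` when produced by the simulator or read
    with metadata.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_names) != n_genes:
            raise IntegrityError(
                f"gene annotation length {len(self.gene_ids)} does not match "
                f"matrix rows {n_genes}"
            )
        if len(self.barcodes) != n_cells:
            raise IntegrityError(
                f"barcode count {len(self.barcodes)} does not match matrix "
                f"columns {n_cells}"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("counts contain negative entries")
        if len(set(self.gene_ids)) != n_genes:
            raise IntegrityError("gene_ids are not unique")
        if len(set(self.barcodes)) != n_cells:
            raise IntegrityError("barcodes are not unique")
        if len(self.cell_meta) != n_cells or not (
            self.cell_meta.index.to_numpy(dtype=object) == self.barcodes
        ).all():
            raise IntegrityError("cell_meta must have exactly one row per barcode")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise KeyError(f"gene id {gene_id!r} not present")
        return int(idx[0])

    def resolve_symbols(self, symbols: Sequence[str], missing: str = "drop") -> list[str]:
        """Map gene symbols to gene ids; error on ambiguous symbols.

        ``missing``: ``"drop"`` silently skips absent symbols, ``"error"``
        raises.
        """
        by_symbol: dict[str, list[str]] = {}
        for gid, name in zip(self.gene_ids, self.gene_names):
            by_symbol.setdefault(name, []).append(gid)
        out = []
        for s in symbols:
            hits = by_symbol.get(s, [])
            if len(hits) > 1:
                raise IntegrityError(f"gene symbol {s!r} is ambiguous: {hits}")
            if not hits:
                if missing == "error":
                    raise KeyError(f"gene symbol {s!r} not present")
                continue
            out.append(hits[0])
        return out

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            gene_names=self.gene_names,
            barcodes=self.barcodes[idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            gene_names=self.gene_names[idx],
            barcodes=self.barcodes,
            cell_meta=self.cell_meta,
        )


@dataclass
class ExprMatrix:
    """Real-valued genes x cells expression (normalized or residuals).

    ``transform_log`` records the ordered list of transforms applied so the
    provenance of the values is explicit (e.g. ``["cp10k", "log1p"]``).
    """

    values: "sp.spmatrix | np.ndarray"
    gene_ids: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.barcodes) != n_cells:
            raise IntegrityError("axis labels do not match value matrix shape")
        if len(self.cell_meta) != n_cells:
            raise IntegrityError("cell_meta must have one row per cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise KeyError(f"gene id {gene_id!r} not present")
        return int(idx[0])

    def subset_genes(self, idx: np.ndarray) -> "ExprMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        vals = self.values[idx, :] if sp.issparse(self.values) else self.values[idx, :]
        return ExprMatrix(
            values=vals,
            gene_ids=self.gene_ids[idx],
            gene_names=self.gene_names[idx],
            barcodes=self.barcodes,
            cell_meta=self.cell_meta,
            transform_log=list(self.transform_log) + ["subset_genes"],
        )

    def subset_cells(self, idx: np.ndarray) -> "ExprMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExprMatrix(
            values=self.values[:, idx],
            gene_ids=self.gene_ids,
            gene_names=self.gene_names,
            barcodes=self.barcodes[idx],
            cell_meta=self.cell_meta.iloc[idx],
            transform_log=list(self.transform_log) + ["subset_cells"],
        )


# ---------------------------------------------------------------------------
# 10X MatrixMarket directories
# ---------------------------------------------------------------------------

def _find_file(directory: Path, names: Sequence[str]) -> Path | None:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    return None


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_lines(path: Path) -> list[list[str]]:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def read_10x_mtx(directory: "str | os.PathLike") -> CountMatrix:
    """Read a 10X-style directory (v2 ``genes.tsv`` or v3 ``features.tsv.gz``).

    Also loads an optional ``cell_meta.tsv(.gz)`` (barcode-indexed) written by
    :func:`write_10x_mtx`.
    """
    directory = Path(directory)
    mtx = _find_file(directory, ["matrix.mtx", "matrix.mtx.gz"])
    if mtx is None:
        raise FormatError(f"missing matrix.mtx(.gz) in {directory}")
    feat = _find_file(
        directory, ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"]
    )
    if feat is None:
        raise FormatError(f"missing features.tsv(.gz) / genes.tsv(.gz) in {directory}")
    bc = _find_file(directory, ["barcodes.tsv", "barcodes.tsv.gz"])
    if bc is None:
        raise FormatError(f"missing barcodes.tsv(.gz) in {directory}")

    if mtx.suffix == ".gz":
        with gzip.open(mtx, "rb") as fh:
            mat = scipy.io.mmread(fh)
    else:
        mat = scipy.io.mmread(mtx)
    mat = sp.csr_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{mtx} contains non-integer counts")
    mat = mat.astype(np.int64)

    feat_rows = _read_tsv_lines(feat)
    if any(len(r) < 2 for r in feat_rows):
        raise FormatError(f"{feat}: feature lines need at least 2 columns")
    gene_ids = np.array([r[0] for r in feat_rows], dtype=object)
    gene_names = np.array([r[1] for r in feat_rows], dtype=object)
    barcodes = np.array([r[0] for r in _read_tsv_lines(bc)], dtype=object)

    if mat.shape[0] != len(gene_ids):
        raise IntegrityError(
            f"matrix declares {mat.shape[0]} genes but {feat.name} has {len(gene_ids)}"
        )
    if mat.shape[1] != len(barcodes):
        raise IntegrityError(
            f"matrix declares {mat.shape[1]} cells but {bc.name} has {len(barcodes)}"
        )

    meta_path = _find_file(directory, ["cell_meta.tsv", "cell_meta.tsv.gz"])
    meta = None
    if meta_path is not None and len(barcodes):
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta = meta.loc[barcodes]
    return CountMatrix(mat, gene_ids, gene_names, barcodes, meta)


def write_10x_mtx(m: CountMatrix, directory: "str | os.PathLike") -> Path:
    """Write a CountMatrix as a v3-style plain-text 10X directory.

    The round trip ``read_10x_mtx(write_10x_mtx(m))`` reproduces counts,
    gene ids and barcodes exactly.  Cell metadata, if any, is written as
    ``cell_meta.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(m.counts)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), coo, field="integer")
    with open(directory / "features.tsv", "w") as fh:
        for gid, name in zip(m.gene_ids, m.gene_names):
            fh.write(f"{gid}\t{name}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for b in m.barcodes:
            fh.write(f"{b}\n")
    if m.cell_meta.shape[1]:
        m.cell_meta.to_csv(directory / "cell_meta.tsv", sep="\t")
    return directory


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: "str | os.PathLike") -> list[GeneSet]:
    """Parse a tab-separated GMT file into a list of GeneSets.

    Duplicate symbols within a line are deduplicated (order preserved) with a
    logged warning; a line with fewer than 3 fields is a format error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g)
            if len(seen) != len(genes):
                logger.warning(
                    "%s:%d: %d duplicate symbols in set %s deduplicated",
                    path, lineno, len(genes) - len(seen), name,
                )
            sets.append(GeneSet(name=name, genes=list(seen), description=desc))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: "str | os.PathLike") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
    return path


def packaged_gmt(name: str) -> Path:
    """Path to a GMT file shipped under ``cartography/data``."""
    return Path(__file__).parent / "data" / name
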