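"""Reading and writing 10x-style count directories and related side files.

The on-disk convention follows CellRanger's triplet layout: a MatrixMarket
``matrix.mtx`` (genes as rows, droplets as columns, 1-based coordinates),
``barcodes.tsv`` with one droplet barcode per line, and ``features.tsv`` (or
the older ``genes.tsv``) with gene ids and display symbols.  All three files
may be gzip-compressed.  In memory counts are held 0-based in a
:class:`DropletMatrix`.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("soupclean")

__all__ = [
    "DropletMatrix",
    "ClusterAssignment",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_clusters",
    "read_gene_list",
]


class MalformedDirectoryError(ValueError):
    """A 10x count directory is missing files or contains invalid content."""


@dataclass
class DropletMatrix:
    """Sparse gene x droplet UMI count matrix with names attached.

    Parameters
    ----------
    counts
        Non-negative count matrix, genes as rows and droplets as columns.
        Stored as CSC sparse for fast per-droplet (column) access.
    gene_ids
        Unique gene identifiers (e.g. Ensembl ids), one per row.
    gene_symbols
        Display symbols, one per row; duplicates allowed (HGNC symbols are
        not unique in real annotations).
    barcodes
        Unique droplet barcodes, one per column.
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.barcodes = [str(b) for b in self.barcodes]
        n_genes, n_drops = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.gene_symbols) != n_genes:
            raise ValueError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} rows"
            )
        if len(self.barcodes) != n_drops:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {n_drops} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            dups = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene ids: {sorted(dups)[:5]}")
        if len(set(self.barcodes)) != n_drops:
            dups = _duplicates(self.barcodes)
            raise ValueError(f"duplicate barcodes: {sorted(dups)[:5]}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[1]

    def droplet_totals(self) -> np.ndarray:
        """Total UMIs per droplet (N_c), dense 1-D array."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        """Total UMIs per gene across all droplets, dense 1-D array."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    # -- subsetting -----------------------------------------------------
    def subset_droplets(self, index: Sequence[int] | np.ndarray) -> "DropletMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return DropletMatrix(
            counts=self.counts[:, index],
            gene_ids=list(self.gene_ids),
            gene_symbols=list(self.gene_symbols),
            barcodes=[self.barcodes[i] for i in index],
        )

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Resolve gene names to row indices.

        Symbols are matched first; names not found as a symbol fall back to
        the gene-id column.  A symbol shared by several rows resolves to all
        of them (logged), since ambient-RNA gene sets are named by symbol.
        """
        by_symbol: dict[str, list[int]] = {}
        for i, s in enumerate(self.gene_symbols):
            by_symbol.setdefault(s, []).append(i)
        by_id = {g: i for i, g in enumerate(self.gene_ids)}
        out: list[int] = []
        missing: list[str] = []
        for name in genes:
            rows = by_symbol.get(name)
            if rows is not None:
                if len(rows) > 1:
                    logger.info(
                        "symbol %s matches %d rows; using all", name, len(rows)
                    )
                out.extend(rows)
            elif name in by_id:
                out.append(by_id[name])
            else:
                missing.append(name)
        if missing:
            logger.warning("genes not found in matrix: %s", missing[:10])
        return np.unique(out)


@dataclass
class ClusterAssignment:
    """Barcode -> cluster label map over the filtered (cell) droplets."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for bc, lab in self.mapping.items():
            if not str(lab):
                raise ValueError(f"empty cluster label for barcode {bc}")
        self.mapping = {str(b): str(l) for b, l in self.mapping.items()}

    def labels_for(self, barcodes: Sequence[str], strict: bool = True) -> np.ndarray:
        missing = [b for b in barcodes if b not in self.mapping]
        if missing and strict:
            raise ValueError(
                f"{len(missing)} cells lack a cluster assignment: {missing[:5]}"
            )
        return np.array([self.mapping.get(b, "") for b in barcodes], dtype=object)

    @property
    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.mapping.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def _find_file(path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = path / name
            if p.is_file():
                return p
    raise MalformedDirectoryError(
        f"malformed 10x directory {path}: none of {list(stems)} present"
    )


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, dtype=str, **kw)


def read_mtx_dir(path: str | os.PathLike) -> DropletMatrix:
    """Read a 10x-style MatrixMarket triplet directory.

    Accepts both 2-column (id, symbol) and 3-column CellRanger features
    files; ``genes.tsv`` and ``features.tsv`` are both recognised, plain or
    gzipped.  Rows follow the features file, columns the barcodes file.
    """
    path = Path(path)
    if not path.is_dir():
        raise MalformedDirectoryError(f"malformed 10x directory: {path} is not a directory")
    mtx = _find_file(path, ["matrix.mtx"])
    bc_file = _find_file(path, ["barcodes.tsv"])
    feat_file = _find_file(path, ["features.tsv", "genes.tsv"])

    mat = scipy.io.mmread(str(mtx))
    mat = sp.csc_matrix(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
            raise ValueError(f"non-integer values in {mtx}")
        mat = mat.astype(np.int64)

    barcodes = _read_tsv(bc_file)[0].tolist()
    feats = _read_tsv(feat_file)
    gene_ids = feats[0].tolist()
    gene_symbols = (feats[1] if feats.shape[1] > 1 else feats[0]).tolist()
    return DropletMatrix(mat, gene_ids, gene_symbols, barcodes)


def write_mtx_dir(
    m: DropletMatrix,
    path: str | os.PathLike,
    gzipped: bool = False,
    round_to_int: bool = False,
) -> None:
    """Write a DropletMatrix as a 10x triplet directory.

    Corrected matrices are generally fractional; unless ``round_to_int`` is
    set (or the data are already integral) a ``real``-field MatrixMarket
    file is written.  Entries are emitted in column-major order so output is
    byte-stable for a given matrix.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = m.counts.tocoo()
    data = counts.data
    if round_to_int:
        data = np.floor(data + 0.5)
    integral = data.size == 0 or bool(np.all(data == np.round(data)))

    order = np.lexsort((counts.row, counts.col))
    rows, cols, vals = counts.row[order], counts.col[order], data[order]

    opener = gzip.open if gzipped else open
    suffix = ".gz" if gzipped else ""
    fieldtype = "integer" if integral else "real"
    with opener(path / f"matrix.mtx{suffix}", "wt") as fh:
        fh.write(f"%%MatrixMarket matrix coordinate {fieldtype} general\n%\n")
        fh.write(f"{m.n_genes} {m.n_droplets} {len(vals)}\n")
        for r, c, v in zip(rows, cols, vals):
            if integral:
                fh.write(f"{r + 1} {c + 1} {int(round(v))}\n")
            else:
                fh.write(f"{r + 1} {c + 1} {v:.6g}\n")
    with opener(path / f"barcodes.tsv{suffix}", "wt") as fh:
        fh.write("".join(b + "\n" for b in m.barcodes))
    with opener(path / f"features.tsv{suffix}", "wt") as fh:
        for gid, sym in zip(m.gene_ids, m.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")


def read_clusters(
    path: str | os.PathLike,
    cells: DropletMatrix,
    strict: bool = False,
) -> ClusterAssignment:
    """Read a two-column (barcode, cluster) TSV, with or without header.

    Barcodes absent from ``cells`` are dropped with a warning.  With
    ``strict`` an error is raised if any cell of ``cells`` is unassigned.
    """
    df = _read_tsv(Path(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    # tolerate a header row: drop it if its barcode is not in the matrix and
    # looks like a label
    known = set(cells.barcodes)
    first = df.iloc[0, 0]
    if first not in known and df.shape[0] > 1 and first.lower() in (
        "barcode", "cell", "cell_id", "barcodes",
    ):
        df = df.iloc[1:]
    mapping: dict[str, str] = {}
    unknown: list[str] = []
    for bc, lab in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if bc in mapping:
            raise ValueError(f"barcode {bc} assigned twice in {path}")
        if bc in known:
            mapping[bc] = lab
        else:
            unknown.append(bc)
    if unknown:
        logger.warning(
            "%d cluster barcodes absent from matrix, dropped: %s",
            len(unknown), unknown[:5],
        )
    missing = [b for b in cells.barcodes if b not in mapping]
    if missing and strict:
        raise ValueError(
            f"{len(missing)} cells without cluster assignment: {missing[:5]}"
        )
    return ClusterAssignment(mapping)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read a gene list: one symbol per line, '#' starts a comment."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            name = line.split("#", 1)[0].strip()
            if name:
                out.append(name)
    return out
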