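"""Ambient-expression ("soup") profile estimation and diagnostics.

Empty droplets — those whose total UMI count falls at or below a small
threshold — contain no cell, so everything they captured is cell-free
ambient mRNA.  Pooling their counts gives the per-gene soup composition

    b_g = sum_d n_{g,d} / sum_d sum_g n_{g,d}

over the selected droplets.  The diagnostics here quantify how soup-like
the cell population is (correlation of the aggregate cell profile with the
soup) and how soup-enriched individual cells are for a given gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator

from .io import DropletMatrix

__all__ = [
    "SoupProfile",
    "SoupProfileEstimator",
    "estimate_soup",
    "soup_cell_correlation",
    "soup_fraction_per_cell",
]


@dataclass
class SoupProfile:
    """Per-gene ambient expression fractions with their provenance.

    Attributes
    ----------
    fractions
        b_g, one entry per gene of the source matrix; sums to 1.
    counts
        Raw per-gene soup counts the fractions were computed from.
    umi_threshold
        Droplet-total UMI cutoff used to call a droplet empty.
    total_soup_umis
        Denominator of the fraction: total counts in selected droplets.
    n_droplets_used
        Number of droplets at or below the threshold (zero-count droplets
        included; they contribute nothing).
    """

    fractions: np.ndarray
    counts: np.ndarray
    umi_threshold: int
    total_soup_umis: int
    n_droplets_used: int

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.fractions < 0):
            raise ValueError("negative soup fractions")
        if self.total_soup_umis > 0:
            s = self.fractions.sum()
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"soup fractions sum to {s}, expected 1")


class SoupProfileEstimator(BaseEstimator):
    """Estimate the soup composition from the empty droplets of a raw matrix.

    Parameters
    ----------
    umi_threshold : int, default 10
        Droplets whose total UMIs do not exceed (``inclusive``) or are
        strictly below (``inclusive=False``) this value are treated as
        empty.  Values below ~100 all give near-identical profiles on real
        channels; 10 is the conservative default.
    inclusive : bool, default True
        Whether the threshold comparison is ``<=`` (default) or ``<``.

    Attributes
    ----------
    fractions_ : ndarray of shape (n_genes,)
        Estimated b_g.
    total_soup_umis_ : int
    n_droplets_used_ : int
    profile_ : SoupProfile
        The same information bundled for downstream use.
    """

    def __init__(self, umi_threshold: int = 10, inclusive: bool = True):
        self.umi_threshold = umi_threshold
        self.inclusive = inclusive

    def fit(self, X: DropletMatrix, y=None) -> "SoupProfileEstimator":
        """Fit on the *raw* (cells + empty droplets) matrix."""
        counts = X.counts if isinstance(X, DropletMatrix) else sp.csc_matrix(X)
        totals = np.asarray(counts.sum(axis=0)).ravel()
        if self.inclusive:
            empty = totals <= self.umi_threshold
        else:
            empty = totals < self.umi_threshold
        n_used = int(empty.sum())
        if n_used == 0 or totals[empty].sum() == 0:
            raise ValueError(
                f"no empty droplets below threshold {self.umi_threshold} "
                "with at least one UMI"
            )
        soup_counts = np.asarray(counts[:, empty].sum(axis=1)).ravel()
        total = soup_counts.sum()
        self.counts_ = soup_counts.astype(float)
        self.fractions_ = soup_counts / total
        self.total_soup_umis_ = int(total)
        self.n_droplets_used_ = n_used
        self.profile_ = SoupProfile(
            fractions=self.fractions_,
            counts=self.counts_,
            umi_threshold=self.umi_threshold,
            total_soup_umis=self.total_soup_umis_,
            n_droplets_used=self.n_droplets_used_,
        )
        return self


def estimate_soup(
    raw: DropletMatrix, umi_threshold: int = 10, inclusive: bool = True
) -> SoupProfile:
    """Estimate the ambient profile from empty droplets of the raw matrix."""
    est = SoupProfileEstimator(umi_threshold=umi_threshold, inclusive=inclusive)
    return est.fit(raw).profile_


def _subsample_counts(vec: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample an integer count vector to ``target`` total without
    replacement over unit counts (multivariate hypergeometric)."""
    vec = np.asarray(np.round(vec), dtype=np.int64)
    total = int(vec.sum())
    if target >= total:
        return vec
    return rng.multivariate_hypergeometric(vec, target)


def soup_cell_correlation(
    cells: DropletMatrix,
    soup: SoupProfile,
    trim_quantile: float = 0.99,
    seed: int = 0,
) -> float:
    """Pearson correlation between soup and aggregate-cell count profiles.

    All cell counts are pooled into one per-gene profile, genes above the
    ``trim_quantile`` of that aggregate are removed (the handful of
    extremely expressed genes otherwise dominate), and the deeper of the
    two count vectors is subsampled without replacement down to the
    shallower one's total so sampling noise is matched.
    """
    agg = cells.gene_totals().astype(np.int64)
    soup_counts = np.round(soup.counts).astype(np.int64)
    cutoff = np.quantile(agg, trim_quantile)
    keep = agg <= cutoff
    if keep.sum() < 3:
        raise ValueError("fewer than 3 genes remain after quantile trimming")
    agg, soup_counts = agg[keep], soup_counts[keep]

    rng = np.random.default_rng(seed)
    target = int(min(agg.sum(), soup_counts.sum()))
    agg = _subsample_counts(agg, target, rng)
    soup_counts = _subsample_counts(soup_counts, target, rng)
    r, _ = pearsonr(agg, soup_counts)
    return float(r)


def soup_fraction_per_cell(
    cells: DropletMatrix,
    soup: SoupProfile,
    gene_set: list[str] | np.ndarray,
) -> np.ndarray:
    """Per-cell expression of a gene set relative to its soup expression.

    Returns (sum_{g in G} n_{g,c} / N_c) / (sum_{g in G} b_g) per cell.  A
    value near 1 means the cell expresses the set at exactly the ambient
    rate (pure contamination); values far above 1 flag endogenous
    expression.  Cells with zero total counts yield NaN.
    """
    idx = _resolve_gene_set(cells, gene_set)
    b = soup.fractions[idx].sum()
    if b <= 0:
        raise ValueError("gene set absent from soup")
    totals = cells.droplet_totals().astype(float)
    gs_counts = np.asarray(cells.counts[idx, :].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(totals > 0, gs_counts / totals, np.nan)
    return frac / b


def _resolve_gene_set(cells: DropletMatrix, gene_set) -> np.ndarray:
    """Gene names -> row indices; integer arrays pass through."""
    arr = np.asarray(gene_set)
    if arr.dtype.kind in "iu":
        idx = arr
    else:
        idx = cells.gene_indices([str(g) for g in arr])
    if idx.size == 0:
        raise ValueError("gene set matches no genes in the matrix")
    return idx
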