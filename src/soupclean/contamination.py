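"""Contamination-fraction (rho) estimation.

The observed counts of a droplet containing a cell decompose additively,
``n_{g,c} = m_{g,c} + o_{g,c}``, into endogenous counts m and ambient
counts ``o_{g,c} = N_c * rho_c * b_g``.  If a gene set G is known to be
endogenously silent in a cell (m = 0 for all g in G), the contamination
fraction of that cell is identified directly:

    rho_c = sum_{g in G} n_{g,c} / (N_c * sum_{g in G} b_g)

Two estimators are provided.  :class:`GeneSetContamination` takes a
user-supplied negative-marker gene set (e.g. haemoglobin genes outside red
blood cells), screens out cells that endogenously express the set with a
Poisson test against the strongest possible ambient null, and pools the
remaining cells.  :class:`AutoContamination` discovers cluster markers by
tf-idf, treats each marker as silent outside its own cluster, derives one
rho estimate per marker and reports the mode of their weighted density —
bad markers scatter, good markers pile up at the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator

from .io import ClusterAssignment, DropletMatrix
from .profile import SoupProfile, _resolve_gene_set

logger = logging.getLogger("soupclean")

__all__ = [
    "ContaminationEstimate",
    "NonExpressionMask",
    "GeneSetContamination",
    "AutoContamination",
    "non_expressing_cells",
    "estimate_rho_gene_set",
    "rank_estimation_genes",
    "auto_estimate_rho",
]


@dataclass
class ContaminationEstimate:
    """A global contamination fraction with its supporting evidence.

    ``rho_per_cell`` replicates the global value per cell: a single channel
    is assumed to have one contamination level, individual-cell differences
    being dominated by capture-efficiency noise.
    """

    rho_global: float
    method: str  # "manual_gene_set" | "automated" | "fixed"
    rho_per_cell: np.ndarray | None = None
    per_marker_estimates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "clusters_used", "rho_estimate", "weight"]
        )
    )
    n_cells_used: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_global <= 1.0:
            raise ValueError(f"rho_global {self.rho_global} outside [0, 1]")
        if self.method == "fixed" and len(self.per_marker_estimates):
            raise ValueError("fixed estimates carry no per-marker table")

    @classmethod
    def fixed(cls, rho: float) -> "ContaminationEstimate":
        return cls(rho_global=float(rho), method="fixed")

    def per_cell(self, n_cells: int) -> np.ndarray:
        if self.rho_per_cell is not None and len(self.rho_per_cell) == n_cells:
            return np.asarray(self.rho_per_cell, dtype=float)
        return np.full(n_cells, self.rho_global)


@dataclass
class NonExpressionMask:
    """Which cells may be assumed endogenously silent for a gene set.

    ``endogenous`` marks cells whose gene-set counts exceed what pure
    ambient contamination could supply (Poisson test, BH-adjusted).
    ``usable`` additionally excludes every cell sharing a cluster with an
    endogenously-expressing cell: clusters are transcriptionally coherent,
    so one confident detection taints its whole cluster.
    """

    usable: np.ndarray
    endogenous: np.ndarray
    p_values: np.ndarray
    fdr_threshold: float


def _poisson_endogenous(
    gs_counts: np.ndarray,
    totals: np.ndarray,
    soup_frac: float,
    fdr: float,
    maximum_contamination: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag cells whose gene-set counts are implausible under pure soup.

    Null per cell: counts ~ Poisson(maximum_contamination * N_c * B); the
    upper-tail p-value P(X >= observed) is BH-corrected across cells.
    """
    lam = maximum_contamination * totals * soup_frac
    pvals = stats.poisson.sf(gs_counts - 1, lam)
    pvals = np.where(gs_counts <= 0, 1.0, pvals)
    qvals = stats.false_discovery_control(pvals)
    return qvals <= fdr, pvals


def non_expressing_cells(
    cells: DropletMatrix,
    soup: SoupProfile,
    gene_set,
    clusters: ClusterAssignment | None = None,
    fdr: float = 0.05,
    maximum_contamination: float = 1.0,
) -> NonExpressionMask:
    """Determine the cells for which the gene set can be assumed silent.

    A cell is flagged *endogenously expressing* when its gene-set count is
    significantly larger than achievable even if the cell were nothing but
    contamination (``maximum_contamination=1``).  With clusters supplied,
    any cluster containing a flagged cell is excluded wholesale.
    """
    idx = _resolve_gene_set(cells, gene_set)
    B = float(soup.fractions[idx].sum())
    if B <= 0:
        raise ValueError("gene set absent from soup")
    totals = cells.droplet_totals().astype(float)
    gs_counts = np.asarray(cells.counts[idx, :].sum(axis=0)).ravel()
    endog, pvals = _poisson_endogenous(
        gs_counts, totals, B, fdr, maximum_contamination
    )
    if clusters is not None:
        labels = clusters.labels_for(cells.barcodes, strict=True)
        bad_clusters = set(labels[endog])
        usable = np.array([lab not in bad_clusters for lab in labels])
    else:
        usable = ~endog
    return NonExpressionMask(
        usable=usable, endogenous=endog, p_values=pvals, fdr_threshold=fdr
    )


class GeneSetContamination(BaseEstimator):
    """Contamination fraction from a negative-marker gene set.

    Parameters
    ----------
    gene_set : sequence of str or int
        Genes assumed silent outside the cell types that express them
        (symbols, ids or row indices).
    fdr : float, default 0.05
        Benjamini-Hochberg threshold for the endogenous-expression screen.
    maximum_contamination : float, default 1.0
        Contamination level of the screening null; 1.0 is the most
        permissive "cell is nothing but soup" null.
    summary : {"pooled", "median"}, default "pooled"
        Pool counts across usable cells (weighting cells by N_c * B) or
        take the median of per-cell estimates.

    Attributes
    ----------
    rho_ : float
    rho_per_usable_cell_ : ndarray
    mask_ : NonExpressionMask
    estimate_ : ContaminationEstimate
    """

    def __init__(
        self,
        gene_set,
        fdr: float = 0.05,
        maximum_contamination: float = 1.0,
        summary: str = "pooled",
    ):
        self.gene_set = gene_set
        self.fdr = fdr
        self.maximum_contamination = maximum_contamination
        self.summary = summary

    def fit(
        self,
        X: DropletMatrix,
        y=None,
        *,
        soup: SoupProfile,
        clusters: ClusterAssignment | None = None,
    ) -> "GeneSetContamination":
        mask = non_expressing_cells(
            X, soup, self.gene_set, clusters,
            fdr=self.fdr, maximum_contamination=self.maximum_contamination,
        )
        if not mask.usable.any():
            raise ValueError("no cells satisfy the m=0 assumption")
        idx = _resolve_gene_set(X, self.gene_set)
        B = float(soup.fractions[idx].sum())
        totals = X.droplet_totals().astype(float)
        gs_counts = np.asarray(X.counts[idx, :].sum(axis=0)).ravel()

        use = mask.usable & (totals > 0)
        per_cell = gs_counts[use] / (totals[use] * B)
        n_over = int((per_cell > 1).sum())
        if n_over:
            logger.warning(
                "%d per-cell rho estimates exceeded 1 and were clipped", n_over
            )
        per_cell_clipped = np.clip(per_cell, 0.0, 1.0)

        if self.summary == "median":
            rho = float(np.median(per_cell_clipped))
        else:
            rho = float(gs_counts[use].sum() / (totals[use].sum() * B))
        rho = min(max(rho, 0.0), 1.0)

        self.mask_ = mask
        self.rho_ = rho
        self.rho_per_usable_cell_ = per_cell_clipped
        self.n_cells_used_ = int(use.sum())
        table = pd.DataFrame(
            {
                "gene": ["<gene set>"],
                "clusters_used": ["<usable cells>"],
                "rho_estimate": [rho],
                "weight": [float(gs_counts[use].sum())],
            }
        )
        self.estimate_ = ContaminationEstimate(
            rho_global=rho,
            method="manual_gene_set",
            rho_per_cell=np.full(X.n_droplets, rho),
            per_marker_estimates=table,
            n_cells_used=self.n_cells_used_,
        )
        return self


def estimate_rho_gene_set(
    cells: DropletMatrix,
    soup: SoupProfile,
    gene_set,
    mask: NonExpressionMask,
) -> ContaminationEstimate:
    """Pooled rho over the cells a precomputed mask declares usable."""
    if not mask.usable.any():
        raise ValueError("no cells satisfy the m=0 assumption")
    idx = _resolve_gene_set(cells, gene_set)
    B = float(soup.fractions[idx].sum())
    if B <= 0:
        raise ValueError("gene set absent from soup")
    totals = cells.droplet_totals().astype(float)
    gs_counts = np.asarray(cells.counts[idx, :].sum(axis=0)).ravel()
    use = mask.usable & (totals > 0)
    per_cell = gs_counts[use] / (totals[use] * B)
    if (per_cell > 1).any():
        logger.warning(
            "%d per-cell rho estimates exceeded 1 and were clipped",
            int((per_cell > 1).sum()),
        )
    rho = float(np.clip(gs_counts[use].sum() / (totals[use].sum() * B), 0, 1))
    return ContaminationEstimate(
        rho_global=rho,
        method="manual_gene_set",
        rho_per_cell=np.full(cells.n_droplets, rho),
        per_marker_estimates=pd.DataFrame(
            {
                "gene": ["<gene set>"],
                "clusters_used": ["<usable cells>"],
                "rho_estimate": [rho],
                "weight": [float(gs_counts[use].sum())],
            }
        ),
        n_cells_used=int(use.sum()),
    )


def rank_estimation_genes(
    cells: DropletMatrix,
    soup: SoupProfile,
    top_n: int = 500,
    pseudo_fraction_scale: float = 0.1,
) -> pd.DataFrame:
    """Rank soup-abundant genes by bimodality of cell/soup expression ratio.

    Good genes for manual contamination estimation are abundant in the
    ambient background yet expressed endogenously by only a subset of
    cells, so the per-cell log-ratio

        r_{g,c} = log10( (n_{g,c}/N_c) / b_g )

    is bimodal: a contamination peak near log10(rho) and an endogenous peak
    above 0.  Zero counts enter with the pseudo-fraction 0.1/N_c.  The
    bimodality score is the sample bimodality coefficient
    (skewness^2 + 1) / kurtosis, which exceeds 5/9 for distributions more
    bimodal than the uniform.

    Returns a DataFrame (gene, soup_fraction, bimodality_score) sorted by
    descending score.
    """
    if top_n < 1:
        raise ValueError("top_n must be at least 1")
    b = soup.fractions
    candidates = np.argsort(-b, kind="stable")[: min(top_n, int((b > 0).sum()))]
    totals = cells.droplet_totals().astype(float)
    pos = totals > 0
    if not pos.any():
        raise ValueError("no cells with nonzero counts")

    sub = np.asarray(cells.counts[candidates, :][:, pos].todense(), dtype=float)
    n_pos = totals[pos]
    frac = sub / n_pos
    pseudo = pseudo_fraction_scale / n_pos
    frac = np.where(sub > 0, frac, pseudo)
    r = np.log10(frac / b[candidates, None])

    skew = stats.skew(r, axis=1)
    kurt = stats.kurtosis(r, axis=1, fisher=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (skew**2 + 1.0) / kurt
    score = np.where(np.isfinite(score), score, 0.0)

    out = pd.DataFrame(
        {
            "gene": [cells.gene_symbols[i] for i in candidates],
            "gene_id": [cells.gene_ids[i] for i in candidates],
            "soup_fraction": b[candidates],
            "bimodality_score": score,
        }
    )
    return out.sort_values(
        "bimodality_score", ascending=False, kind="stable"
    ).reset_index(drop=True)


def _tfidf_markers(
    cells: DropletMatrix,
    labels: np.ndarray,
    tfidf_min: float,
) -> pd.DataFrame:
    """Cluster markers by tf-idf on detection.

    tf: fraction of cells in the cluster detecting the gene (count > 0);
    idf: log of total cells over cells detecting the gene anywhere.  A gene
    is a marker of the cluster where its detection rate is highest when
    tf * idf clears ``tfidf_min``.
    """
    detected = (cells.counts > 0).astype(np.int64)
    n_cells = cells.n_droplets
    det_total = np.asarray(detected.sum(axis=1)).ravel().astype(float)
    uniq = np.unique(labels)
    tf = np.zeros((cells.n_genes, len(uniq)))
    for j, lab in enumerate(uniq):
        members = labels == lab
        tf[:, j] = np.asarray(
            detected[:, np.flatnonzero(members)].sum(axis=1)
        ).ravel() / members.sum()
    with np.errstate(divide="ignore"):
        idf = np.log(n_cells / det_total)
    idf = np.where(det_total > 0, idf, 0.0)
    best = tf.argmax(axis=1)
    tfidf = tf[np.arange(cells.n_genes), best] * idf
    keep = tfidf >= tfidf_min
    return pd.DataFrame(
        {
            "gene_row": np.flatnonzero(keep),
            "cluster": uniq[best[keep]],
            "tf": tf[keep, best[keep]],
            "tfidf": tfidf[keep],
        }
    )


class AutoContamination(BaseEstimator):
    """Fully automated contamination estimation from cluster markers.

    Each strong, soup-detectable cluster marker yields an independent rho
    estimate by assuming it is endogenously silent in every other cluster
    (after the Poisson endogenous-expression screen).  Estimates from poor
    markers scatter; estimates from genuinely private markers concentrate
    at the true contamination level, so the mode of their soup-count
    weighted kernel density is returned as the channel estimate.

    Parameters
    ----------
    tfidf_min : float, default 1.0
        Minimum tf-idf marker specificity score.  If no gene passes, the
        cutoff is relaxed in steps of 0.25 down to ``tfidf_floor`` (with a
        logged warning) before giving up: heavily contaminated channels
        depress every gene's idf because ambient counts make markers
        detectable everywhere.
    soup_quantile : float, default 0.90
        A marker must sit above this quantile of nonzero soup fractions —
        an estimate needs the gene to be visible in the soup at all.
    fdr : float, default 0.05
        FDR of the per-marker endogenous-expression screen.
    grid_size : int, default 512
        Resolution of the density-mode grid over [0, 1].
    """

    def __init__(
        self,
        tfidf_min: float = 1.0,
        soup_quantile: float = 0.90,
        fdr: float = 0.05,
        grid_size: int = 512,
        tfidf_floor: float = 0.25,
    ):
        self.tfidf_min = tfidf_min
        self.soup_quantile = soup_quantile
        self.fdr = fdr
        self.grid_size = grid_size
        self.tfidf_floor = tfidf_floor

    def fit(
        self,
        X: DropletMatrix,
        y=None,
        *,
        soup: SoupProfile,
        clusters: ClusterAssignment,
    ) -> "AutoContamination":
        labels = clusters.labels_for(X.barcodes, strict=True)
        if len(np.unique(labels)) < 2:
            raise ValueError("automated estimation needs at least 2 clusters")
        b = soup.fractions
        b_cut = np.quantile(b[b > 0], self.soup_quantile)
        cutoff = self.tfidf_min
        while True:
            markers = _tfidf_markers(X, labels, cutoff)
            markers = markers[b[markers["gene_row"].to_numpy()] >= b_cut]
            if not markers.empty:
                break
            if cutoff - 0.25 < self.tfidf_floor - 1e-9:
                raise ValueError(
                    "no marker gene passed the specificity and soup filters; "
                    "supply a manual gene set instead"
                )
            cutoff -= 0.25
            logger.warning(
                "no marker passed tf-idf >= %.2f; relaxing cutoff to %.2f",
                cutoff + 0.25, cutoff,
            )
        self.tfidf_used_ = cutoff

        totals = X.droplet_totals().astype(float)
        counts = sp.csr_matrix(X.counts)
        rows, est_rows = [], []
        for g, sub in markers.groupby("gene_row", sort=True):
            g = int(g)
            marker_clusters = set(sub["cluster"])
            bg = float(b[g])
            gene_counts = np.asarray(counts[g, :].todense()).ravel()
            endog, _ = _poisson_endogenous(
                gene_counts, totals, bg, self.fdr, maximum_contamination=1.0
            )
            bad_clusters = marker_clusters | set(labels[endog])
            use = np.array([lab not in bad_clusters for lab in labels])
            use &= totals > 0
            if not use.any():
                continue
            rho_g = gene_counts[use].sum() / (totals[use].sum() * bg)
            weight = float(soup.counts[g])
            rows.append((g, rho_g, weight, use.sum(), marker_clusters))
            est_rows.append(
                {
                    "gene": X.gene_symbols[g],
                    "clusters_used": ",".join(
                        sorted(set(np.unique(labels)) - bad_clusters)
                    ),
                    "rho_estimate": float(rho_g),
                    "weight": weight,
                }
            )
        if not rows:
            raise ValueError(
                "no usable cells remained for any marker; "
                "supply a manual gene set instead"
            )
        estimates = np.array([r[1] for r in rows])
        weights = np.array([r[2] for r in rows])
        rho = _weighted_density_mode(
            np.clip(estimates, 0.0, 1.0), weights, self.grid_size
        )
        if rho == 0.0 and np.all(estimates <= 0):
            logger.warning("all per-marker estimates are 0; returning rho=0")

        self.per_marker_estimates_ = pd.DataFrame(est_rows)
        self.rho_ = float(rho)
        self.n_markers_used_ = len(rows)
        self.estimate_ = ContaminationEstimate(
            rho_global=self.rho_,
            method="automated",
            rho_per_cell=np.full(X.n_droplets, self.rho_),
            per_marker_estimates=self.per_marker_estimates_,
            n_cells_used=int(max(r[3] for r in rows)),
        )
        return self


def _weighted_density_mode(
    estimates: np.ndarray, weights: np.ndarray, grid_size: int = 512
) -> float:
    """Mode of a weighted Gaussian KDE on a fixed grid over [0, 1].

    Silverman bandwidth; degenerate inputs (a single estimate, zero spread
    or zero weight) fall back to the weighted mean.
    """
    if weights.sum() <= 0:
        weights = np.ones_like(estimates)
    if len(estimates) < 2 or np.ptp(estimates) < 1e-12:
        return float(np.average(estimates, weights=weights))
    try:
        kde = stats.gaussian_kde(estimates, bw_method="silverman", weights=weights)
    except np.linalg.LinAlgError:
        return float(np.average(estimates, weights=weights))
    grid = np.linspace(0.0, 1.0, grid_size)
    return float(grid[np.argmax(kde(grid))])


def auto_estimate_rho(
    cells: DropletMatrix,
    soup: SoupProfile,
    clusters: ClusterAssignment,
    tfidf_min: float = 1.0,
    soup_quantile: float = 0.90,
    fdr: float = 0.05,
) -> ContaminationEstimate:
    """Automated marker-based rho estimate (see :class:`AutoContamination`)."""
    est = AutoContamination(
        tfidf_min=tfidf_min, soup_quantile=soup_quantile, fdr=fdr
    )
    return est.fit(cells, soup=soup, clusters=clusters).estimate_
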