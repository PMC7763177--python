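"""Background-count removal.

Given the soup profile b and a contamination fraction rho, the expected
ambient counts in cell c are ``o_{g,c} = N_c * rho_c * b_g`` and the naive
corrected counts are ``m = n - N rho b``.  Naive subtraction can go
negative wherever the expectation exceeds the observation, so the actual
correction removes a fixed per-unit total ``T = round(rho * N)`` by
maximizing the multinomial likelihood of the removed counts under the
soup composition subject to 0 <= o <= n: a capped water-filling in which
removal is spread across genes essentially in proportion to their soup
fraction (with a half-count digamma correction that matters only for
small counts), genes whose share exceeds their observed count are capped
there, and the excess spills over the remaining genes.

When cluster assignments are available the correction is performed on
cluster-aggregated counts — pooling defeats sparsity, since a single
observed count cannot be classified as soup or signal on its own — and
the removed counts are then redistributed to member cells per gene in
proportion to each cell's observed counts of that gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .contamination import (
    AutoContamination,
    ContaminationEstimate,
    GeneSetContamination,
)
from .io import ClusterAssignment, DropletMatrix
from .profile import SoupProfile, SoupProfileEstimator

__all__ = [
    "CorrectionResult",
    "SoupCorrector",
    "expected_soup_counts",
    "subtract_naive",
    "correct_counts",
    "removal_summary",
]


@dataclass
class CorrectionResult:
    """Corrected and removed counts with per-cell bookkeeping.

    Invariants: ``corrected + removed`` reproduces the input counts
    elementwise, and ``0 <= corrected <= input``.  Cells (or clusters)
    whose removable counts (genes with soup support) fall short of the
    removal target are listed in ``infeasible_cells`` with everything
    removable removed.
    """

    corrected: sp.spmatrix
    removed: sp.spmatrix
    target_removed_per_cell: np.ndarray
    infeasible_cells: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    gene_symbols: list[str] = field(default_factory=list)
    barcodes: list[str] = field(default_factory=list)

    def as_droplet_matrix(self) -> DropletMatrix:
        """Corrected counts wrapped back into a DropletMatrix."""
        m = DropletMatrix.__new__(DropletMatrix)
        m.counts = sp.csc_matrix(self.corrected)
        m.gene_ids = list(self.gene_ids)
        m.gene_symbols = list(self.gene_symbols)
        m.barcodes = list(self.barcodes)
        return m


def expected_soup_counts(
    cell_totals: np.ndarray, rho: float | np.ndarray, soup: SoupProfile
) -> np.ndarray:
    """Expected ambient counts o_{g,c} = N_c * rho_c * b_g (dense)."""
    cell_totals = np.asarray(cell_totals, dtype=float)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), cell_totals.shape)
    if np.any(rho < 0):
        raise ValueError("negative contamination fraction")
    return np.outer(soup.fractions, cell_totals * rho)


def subtract_naive(
    cells: DropletMatrix,
    rho: ContaminationEstimate | float,
    soup: SoupProfile,
    clip: bool = True,
) -> np.ndarray:
    """Naive corrected counts m = n - N_c rho_c b_g (dense, fractional)."""
    if isinstance(rho, ContaminationEstimate):
        rho_c = rho.per_cell(cells.n_droplets)
    else:
        rho_c = np.full(cells.n_droplets, float(rho))
    expected = expected_soup_counts(cells.droplet_totals(), rho_c, soup)
    m = np.asarray(cells.counts.todense(), dtype=float) - expected
    return np.clip(m, 0.0, None) if clip else m


def _capped_removal(
    n: np.ndarray, b: np.ndarray, target: float
) -> tuple[np.ndarray, bool]:
    """Remove ``target`` counts from ``n`` according to the soup profile b.

    The removal vector o maximizes the multinomial removal log-likelihood
    sum_g [o_g log b_g - log Gamma(o_g + 1)] subject to sum o = target and
    0 <= o_g <= n_g.  The KKT conditions give a water-filling solution
    which, with the standard approximation psi(x + 1) ~ log(x + 1/2),
    is piecewise linear in the water level C:

        o_g = clip(C * b_g - 1/2, 0, n_g),

    C chosen by bisection so the total matches, then the uncapped genes
    rescaled so it matches exactly.  For large targets this approaches
    plain proportional allocation (o_g ~ target * b_g) with genes capped
    at their observed counts; the half-count shift keeps small units
    within one count of the exact integer optimum.  Genes with b == 0 are
    never touched.  Returns (removed vector, infeasible flag).
    """
    o = np.zeros_like(n, dtype=float)
    active = (b > 0) & (n > 0)
    removable = n[active].sum()
    if removable <= target:
        o[active] = n[active]
        return o, removable < target - 1e-9
    if target <= 0:
        return o, False

    bb = b[active]
    caps = n[active]
    lo, hi = 0.0, float(((caps + 0.5) / bb).max()) + 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.clip(mid * bb - 0.5, 0.0, caps).sum() < target:
            lo = mid
        else:
            hi = mid
    alloc = np.clip(hi * bb - 0.5, 0.0, caps)
    # polish: rescale the uncapped genes so the total is exact
    uncapped = alloc < caps - 1e-9
    residual = target - alloc[~uncapped].sum()
    s = alloc[uncapped].sum()
    if s > 0:
        alloc[uncapped] *= residual / s
    o[np.flatnonzero(active)] = np.minimum(alloc, caps)
    return o, False


def _stochastic_round_unit(
    o_entries: np.ndarray, caps: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Round removal amounts to integers, preserving the unit total.

    Floor every entry, then add back the rounded total shortfall one count
    at a time, sampled without replacement with probability proportional
    to the fractional parts, never exceeding the per-entry cap.
    """
    floors = np.floor(o_entries)
    frac = o_entries - floors
    shortfall = int(round(o_entries.sum() - floors.sum()))
    if shortfall > 0:
        eligible = np.flatnonzero((floors + 1 <= caps) & (frac > 1e-12))
        if eligible.size:
            k = min(shortfall, eligible.size)
            p = frac[eligible] / frac[eligible].sum()
            chosen = rng.choice(eligible, size=k, replace=False, p=p)
            floors[chosen] += 1
    return floors


def correct_counts(
    cells: DropletMatrix,
    soup: SoupProfile,
    rho: ContaminationEstimate | float,
    clusters: ClusterAssignment | None = None,
    round_to_int: bool = False,
    seed: int = 0,
) -> CorrectionResult:
    """Remove the expected soup contribution from every cell.

    Correction units are clusters when ``clusters`` is given, individual
    cells otherwise.  Per unit the removal target is ``round(rho * N)``
    (half-up) and is allocated by capped proportional removal; cluster
    removals are redistributed to member cells per gene proportionally to
    each cell's observed counts of that gene.  With ``round_to_int`` the
    fractional removals are stochastically rounded (seeded) preserving
    each unit's removed total.
    """
    if isinstance(rho, ContaminationEstimate):
        rho_c = rho.per_cell(cells.n_droplets)
    else:
        rho_c = np.full(cells.n_droplets, float(rho))
    if np.any(rho_c < 0) or np.any(rho_c > 1):
        raise ValueError("contamination fraction outside [0, 1]")

    counts = sp.csc_matrix(cells.counts).astype(float)
    totals = cells.droplet_totals().astype(float)
    b = soup.fractions
    rng = np.random.default_rng(seed)

    if clusters is not None:
        labels = clusters.labels_for(cells.barcodes, strict=True)
        units = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    else:
        units = [np.array([c]) for c in range(cells.n_droplets)]

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    infeasible: list[str] = []
    target_per_cell = np.zeros(cells.n_droplets)

    for members in units:
        n_u = np.asarray(counts[:, members].sum(axis=1)).ravel()
        weight = (totals[members] * rho_c[members]).sum()
        target = float(np.floor(weight + 0.5))
        n_unit_total = totals[members].sum()
        target_per_cell[members] = (
            target * totals[members] / n_unit_total if n_unit_total > 0 else 0.0
        )
        if target <= 0:
            continue
        o_u, infeas = _capped_removal(n_u, b, target)
        if infeas:
            infeasible.extend(cells.barcodes[c] for c in members)
        hit = np.flatnonzero(o_u > 0)
        if hit.size == 0:
            continue
        sub = np.asarray(counts[hit, :][:, members].todense(), dtype=float)
        gene_tot = sub.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            share = sub * (o_u[hit] / gene_tot)[:, None]
        share = np.nan_to_num(share)
        if round_to_int:
            flat = _stochastic_round_unit(share.ravel(), sub.ravel(), rng)
            share = flat.reshape(share.shape)
        nz = share > 0
        gi, ci = np.nonzero(nz)
        rows.append(hit[gi])
        cols.append(members[ci])
        vals.append(share[nz])

    if rows:
        removed = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=counts.shape,
        ).tocsc()
    else:
        removed = sp.csc_matrix(counts.shape)
    corrected = (counts - removed).tocsc()
    corrected.eliminate_zeros()
    # guard against -0.0 / tiny negatives from float subtraction
    corrected.data = np.where(
        np.abs(corrected.data) < 1e-9, 0.0, corrected.data
    )
    corrected.eliminate_zeros()
    return CorrectionResult(
        corrected=corrected,
        removed=removed,
        target_removed_per_cell=target_per_cell,
        infeasible_cells=infeasible,
        gene_ids=list(cells.gene_ids),
        gene_symbols=list(cells.gene_symbols),
        barcodes=list(cells.barcodes),
    )


def removal_summary(result: CorrectionResult) -> dict:
    """Per-gene and per-cell removal fractions and the global rate.

    Returns a dict with a per-gene DataFrame (gene, total_before,
    total_removed, fraction_removed), a per-cell DataFrame (barcode,
    total_before, total_removed, fraction_removed) and the scalar
    ``global_fraction_removed`` = total removed / total counts.
    """
    removed = result.removed
    original = result.corrected + removed
    gene_before = np.asarray(original.sum(axis=1)).ravel()
    gene_removed = np.asarray(removed.sum(axis=1)).ravel()
    cell_before = np.asarray(original.sum(axis=0)).ravel()
    cell_removed = np.asarray(removed.sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        gene_frac = np.where(gene_before > 0, gene_removed / gene_before, 0.0)
        cell_frac = np.where(cell_before > 0, cell_removed / cell_before, 0.0)
    total = cell_before.sum()
    return {
        "per_gene": pd.DataFrame(
            {
                "gene": result.gene_symbols or np.arange(len(gene_before)),
                "total_before": gene_before,
                "total_removed": gene_removed,
                "fraction_removed": gene_frac,
            }
        ),
        "per_cell": pd.DataFrame(
            {
                "barcode": result.barcodes or np.arange(len(cell_before)),
                "total_before": cell_before,
                "total_removed": cell_removed,
                "fraction_removed": cell_frac,
            }
        ),
        "global_fraction_removed": float(cell_removed.sum() / total)
        if total > 0
        else 0.0,
    }


class SoupCorrector(BaseEstimator, TransformerMixin):
    """End-to-end ambient RNA removal as a transformer.

    ``fit`` estimates the soup profile from the raw (cells + empties)
    matrix and the contamination fraction from the filtered cells;
    ``transform`` removes the estimated background.

    Parameters
    ----------
    contamination : "auto", float, or ContaminationEstimate, default "auto"
        How to obtain rho.  "auto" runs the marker-based automated
        estimator (requires clusters); a float fixes rho directly; a
        ready-made estimate is used as is.  Ignored when ``gene_set`` is
        given.
    gene_set : sequence of str, optional
        Negative-marker genes for manual estimation.
    umi_threshold : int, default 10
        Empty-droplet UMI cutoff for the soup profile.
    inclusive : bool, default True
        Threshold comparison for empties (``<=`` vs ``<``).
    fdr : float, default 0.05
        FDR of the Poisson endogenous-expression screen.
    round_to_int : bool, default False
        Emit stochastically rounded integer counts.
    random_state : int, default 0
        Seed for stochastic rounding.

    Attributes
    ----------
    soup_profile_ : SoupProfile
    contamination_ : ContaminationEstimate
    rho_ : float
    """

    def __init__(
        self,
        contamination="auto",
        gene_set=None,
        umi_threshold: int = 10,
        inclusive: bool = True,
        fdr: float = 0.05,
        round_to_int: bool = False,
        random_state: int = 0,
    ):
        self.contamination = contamination
        self.gene_set = gene_set
        self.umi_threshold = umi_threshold
        self.inclusive = inclusive
        self.fdr = fdr
        self.round_to_int = round_to_int
        self.random_state = random_state

    def fit(
        self,
        X: DropletMatrix,
        y=None,
        *,
        cells: DropletMatrix | None = None,
        clusters: ClusterAssignment | None = None,
    ) -> "SoupCorrector":
        """Fit on the raw matrix ``X``; ``cells`` is the filtered matrix
        (required unless rho is fixed)."""
        self.soup_profile_ = (
            SoupProfileEstimator(self.umi_threshold, self.inclusive)
            .fit(X)
            .profile_
        )
        self.clusters_ = clusters
        if isinstance(self.contamination, ContaminationEstimate):
            self.contamination_ = self.contamination
        elif isinstance(self.contamination, (int, float)):
            self.contamination_ = ContaminationEstimate.fixed(
                float(self.contamination)
            )
        elif self.gene_set is not None:
            if cells is None:
                raise ValueError("gene-set estimation requires `cells`")
            est = GeneSetContamination(self.gene_set, fdr=self.fdr)
            est.fit(cells, soup=self.soup_profile_, clusters=clusters)
            self.contamination_ = est.estimate_
        elif self.contamination == "auto":
            if cells is None or clusters is None:
                raise ValueError(
                    "automated estimation requires `cells` and `clusters`"
                )
            est = AutoContamination(fdr=self.fdr)
            est.fit(cells, soup=self.soup_profile_, clusters=clusters)
            self.contamination_ = est.estimate_
        else:
            raise ValueError(f"unrecognised contamination: {self.contamination!r}")
        self.rho_ = self.contamination_.rho_global
        return self

    def correct(
        self,
        cells: DropletMatrix,
        clusters: ClusterAssignment | None = None,
    ) -> CorrectionResult:
        """Full correction result (corrected + removed + diagnostics)."""
        return correct_counts(
            cells,
            self.soup_profile_,
            self.contamination_,
            clusters=clusters if clusters is not None else self.clusters_,
            round_to_int=self.round_to_int,
            seed=self.random_state,
        )

    def transform(self, X: DropletMatrix) -> DropletMatrix:
        """Corrected counts as a DropletMatrix."""
        return self.correct(X).as_droplet_matrix()
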