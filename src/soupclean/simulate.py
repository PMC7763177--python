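"""Synthetic droplet channels with known ground truth.

A channel is simulated from the same generative model the correction
assumes: each cell type has a gene expression profile, the ambient soup is
the UMI-weighted mean of the cell-type profiles (cell-free mRNA samples
the cells of the channel approximately uniformly), and each cell's
observed counts are an endogenous multinomial draw from its type profile
plus a soup multinomial draw from the ambient profile, mixed at the
contamination fraction rho.  Empty droplets are small pure-soup draws.

Cell-type profiles combine a shared baseline with per-type *private*
marker blocks (exactly zero in every other type), so negative-marker gene
sets with genuinely zero endogenous expression exist by construction and
estimator accuracy can be scored against the generating rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import ClusterAssignment, DropletMatrix

__all__ = ["CellTypeSpec", "ChannelTruth", "simulate_channel", "species_mix_fixture"]


@dataclass
class CellTypeSpec:
    """One simulated cell type.

    ``profile`` may be given explicitly (must sum to 1); otherwise it is
    drawn from ``profile_seed``: private markers receive ``marker_weight``
    of the type's expression, the shared remainder is a common Dirichlet
    baseline.
    """

    name: str
    n_cells: int
    mean_umis: float
    profile_seed: int = 0
    profile: np.ndarray | None = None


@dataclass
class ChannelTruth:
    """Ground truth of a simulated channel."""

    profiles: dict[str, np.ndarray]
    soup_fractions: np.ndarray
    rho_true: np.ndarray
    cell_types: np.ndarray
    endogenous_counts: sp.spmatrix
    soup_counts: sp.spmatrix
    marker_genes: dict[str, list[int]] = field(default_factory=dict)


def _make_profiles(
    n_genes: int,
    specs: list[CellTypeSpec],
    n_markers: int,
    marker_weight: float,
    baseline_seed: int,
) -> tuple[dict[str, np.ndarray], dict[str, list[int]]]:
    """Per-type profiles: disjoint private marker blocks + shared baseline."""
    k = len(specs)
    if any(s.profile is not None for s in specs):
        profiles = {}
        for s in specs:
            p = np.asarray(s.profile, dtype=float)
            if p.shape != (n_genes,) or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
                raise ValueError(f"invalid profile for cell type {s.name}")
            profiles[s.name] = p
        return profiles, {}
    if k * n_markers > n_genes:
        raise ValueError("not enough genes for the requested marker blocks")
    shared = np.zeros(n_genes)
    shared_idx = np.arange(k * n_markers, n_genes)
    rng = np.random.default_rng(baseline_seed)
    shared[shared_idx] = rng.dirichlet(np.ones(len(shared_idx)))
    profiles: dict[str, np.ndarray] = {}
    markers: dict[str, list[int]] = {}
    for j, s in enumerate(specs):
        block = np.arange(j * n_markers, (j + 1) * n_markers)
        prof = (1.0 - marker_weight) * shared
        type_rng = np.random.default_rng(s.profile_seed)
        prof[block] = marker_weight * type_rng.dirichlet(np.ones(n_markers) * 5.0)
        profiles[s.name] = prof / prof.sum()
        markers[s.name] = block.tolist()
    return profiles, markers


def simulate_channel(
    n_genes: int,
    cell_type_spec: list[CellTypeSpec],
    rho: float | np.ndarray,
    n_empty: int = 10000,
    empty_umi_range: tuple[int, int] = (1, 10),
    seed: int = 0,
    n_markers_per_type: int = 25,
    marker_weight: float = 0.25,
    umi_sigma: float = 0.5,
) -> tuple[DropletMatrix, DropletMatrix, ClusterAssignment, ChannelTruth]:
    """Simulate one droplet channel.

    Parameters
    ----------
    n_genes : int
        Genome size.
    cell_type_spec : list of CellTypeSpec
        Cell types with their sizes and mean depths.
    rho : float or per-cell array
        Contamination fraction; a scalar applies to every cell.
    n_empty : int, default 2000
        Number of empty (pure soup) droplets in the raw matrix.
    empty_umi_range : (int, int), default (1, 10)
        Inclusive uniform range of empty-droplet totals; the default keeps
        them under the standard soup UMI threshold.
    seed : int
        Seed controlling every draw; fixed seed -> bit-identical output.
    n_markers_per_type, marker_weight
        Size and expression share of each type's private marker block.
    umi_sigma : float, default 0.5
        Log-normal sigma of per-cell depth, emulating the wide
        capture-efficiency spread of droplet experiments.

    Returns
    -------
    raw : DropletMatrix        cells and empty droplets
    filtered : DropletMatrix   cells only
    clusters : ClusterAssignment   one cluster per cell type
    truth : ChannelTruth
    """
    rng = np.random.default_rng(seed)
    profiles, markers = _make_profiles(
        n_genes, cell_type_spec, n_markers_per_type, marker_weight,
        baseline_seed=seed + 1,
    )
    n_cells = sum(s.n_cells for s in cell_type_spec)
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), (n_cells,)).copy()
    if (rho_arr < 0).any() or (rho_arr > 1).any():
        raise ValueError("rho outside [0, 1]")

    # soup = expected-UMI-weighted mean of type profiles
    weights = np.array([s.n_cells * s.mean_umis for s in cell_type_spec], float)
    weights /= weights.sum()
    soup = np.zeros(n_genes)
    for w, s in zip(weights, cell_type_spec):
        soup += w * profiles[s.name]
    soup /= soup.sum()

    endo_cols, soup_cols, labels = [], [], []
    for s in cell_type_spec:
        p = profiles[s.name]
        mu = np.log(s.mean_umis) - 0.5 * umi_sigma**2
        totals = np.maximum(
            1, np.round(rng.lognormal(mu, umi_sigma, s.n_cells))
        ).astype(np.int64)
        for i in range(s.n_cells):
            n_endo = int(round((1.0 - rho_arr[len(labels)]) * totals[i]))
            n_soup = int(totals[i]) - n_endo
            endo_cols.append(rng.multinomial(n_endo, p))
            soup_cols.append(rng.multinomial(n_soup, soup))
            labels.append(s.name)
    endo = sp.csc_matrix(np.column_stack(endo_cols))
    soup_mat = sp.csc_matrix(np.column_stack(soup_cols))
    observed = (endo + soup_mat).tocsc()

    empty_totals = rng.integers(
        empty_umi_range[0], empty_umi_range[1] + 1, size=n_empty
    )
    if n_empty:
        # batch the multinomial draws by total for speed
        empty_arr = np.zeros((n_genes, n_empty), dtype=np.int64)
        for t in np.unique(empty_totals):
            cols = np.flatnonzero(empty_totals == t)
            empty_arr[:, cols] = rng.multinomial(int(t), soup, size=cols.size).T
        empties = sp.csc_matrix(empty_arr)
    else:
        empties = sp.csc_matrix((n_genes, 0))

    gene_ids = [f"ENSG{i:08d}" for i in range(n_genes)]
    gene_symbols = [f"GENE{i}" for i in range(n_genes)]
    cell_barcodes = [f"CELL-{i:06d}" for i in range(n_cells)]
    empty_barcodes = [f"EMPTY-{i:06d}" for i in range(n_empty)]

    filtered = DropletMatrix(observed, gene_ids, gene_symbols, cell_barcodes)
    raw = DropletMatrix(
        sp.hstack([observed, empties]).tocsc(),
        gene_ids, gene_symbols, cell_barcodes + empty_barcodes,
    )
    clusters = ClusterAssignment(dict(zip(cell_barcodes, labels)))
    truth = ChannelTruth(
        profiles=profiles,
        soup_fractions=soup,
        rho_true=rho_arr,
        cell_types=np.array(labels, dtype=object),
        endogenous_counts=endo,
        soup_counts=soup_mat,
        marker_genes=markers,
    )
    return raw, filtered, clusters, truth


def species_mix_fixture(
    n_genes_per_block: int = 50,
    n_cells_per_block: int = 100,
    rho: float = 0.02,
    seed: int = 0,
    mean_umis: float = 2000.0,
    n_empty: int = 10000,
) -> tuple[DropletMatrix, DropletMatrix, ClusterAssignment, ChannelTruth]:
    """Two cell types with fully disjoint gene blocks (barnyard design).

    Mimics a human/mouse cell-line mixture: every cross-block count in a
    cell is ground-truth contamination, so per-cell contamination can be
    measured exactly.  With equal block depths half the soup belongs to
    the other block, making the expected cross-block fraction per cell
    rho / 2.
    """
    n_genes = 2 * n_genes_per_block
    rng = np.random.default_rng(seed + 7)
    prof_a = np.zeros(n_genes)
    prof_b = np.zeros(n_genes)
    prof_a[:n_genes_per_block] = rng.dirichlet(np.ones(n_genes_per_block) * 5.0)
    prof_b[n_genes_per_block:] = rng.dirichlet(np.ones(n_genes_per_block) * 5.0)
    specs = [
        CellTypeSpec("speciesA", n_cells_per_block, mean_umis, profile=prof_a),
        CellTypeSpec("speciesB", n_cells_per_block, mean_umis, profile=prof_b),
    ]
    raw, filtered, clusters, truth = simulate_channel(
        n_genes, specs, rho=rho, n_empty=n_empty, seed=seed
    )
    truth.marker_genes = {
        "speciesA": list(range(n_genes_per_block)),
        "speciesB": list(range(n_genes_per_block, n_genes)),
    }
    return raw, filtered, clusters, truth
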