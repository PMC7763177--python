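# Methods

## Model and assumptions

A droplet channel is modelled as follows. Each cell-containing droplet
yields `n_gc = m_gc + o_gc` observed UMIs of gene *g*: endogenous counts
*m* plus ambient ("soup") counts *o*. Two assumptions make the problem
tractable:

1. **Constant soup composition.** The relative abundance of genes in the
   ambient material is the same for every droplet in a channel, so
   `o_gc = N_c ρ_c b_g` with a single per-gene profile `b_g`
   (`Σ_g b_g = 1`). This is supported empirically by the high correlation
   between the pooled empty-droplet profile and the aggregate cell
   profile — the soup is approximately a uniform sample of the cells in
   the channel — and can be checked per dataset with
   `soup_cell_correlation`.
2. **Constant contamination fraction.** ρ is taken as a single
   channel-level value. Cell-to-cell variation in ρ exists (smaller
   cells are relatively more contaminated) but is dominated by the
   order-of-magnitude spread in capture efficiency; cluster-level
   correction with per-gene redistribution (below) reintroduces most of
   the per-cell adaptivity that matters in practice.

## Soup profile estimation

Droplets whose total UMI count is at or below `umi_threshold` (default
10) are declared empty and their counts pooled:
`b_g = Σ_d n_gd / Σ_dg n_gd`. Any threshold below ~100 gives nearly the
same profile on realistic channels; 10 is conservative and is applied
inclusively (`≤`), matching how empty droplets are described in
composition analyses; a `strict` flag switches to `<`. Zero-count
droplets are selected but contribute nothing. The estimator refuses to
run if no qualifying droplet holds a single UMI.

Two diagnostics accompany the profile:

- `soup_cell_correlation`: Pearson correlation between the soup counts
  and the aggregated cell counts after (a) dropping genes above the 99th
  quantile of aggregate expression, whose extreme abundance would
  otherwise dominate the statistic, and (b) subsampling the deeper count
  vector without replacement (multivariate hypergeometric, seeded) to
  the shallower one's total so both sides carry equal sampling noise.
  Real channels typically score 0.7–0.96.
- `soup_fraction_per_cell`: per-cell expression of a gene set relative
  to its soup rate, `(Σ_G n_gc / N_c) / Σ_G b_g`. Values near 1 flag
  pure contamination; values ≫ 1 flag endogenous expression (e.g. red
  blood cells for haemoglobin sets).

## Contamination estimation

### Gene-set (manual) estimator

Given genes G assumed endogenously silent in at least some cells, the
cells for which the assumption is safe are found by a one-sided Poisson
test: under the most permissive null — the cell is *nothing but* soup —
the gene-set count is Poisson with mean `maximum_contamination · N_c ·
B`, `B = Σ_G b_g`. Upper-tail p-values are Benjamini–Hochberg corrected
across cells (FDR 0.05 by default); rejected cells endogenously express
G. Because clusters are transcriptionally coherent, one confident
detection taints its cluster: every cell sharing a cluster with a
rejected cell is excluded. Over the remaining cells,
`ρ = Σ_c Σ_G n_gc / Σ_c (N_c B)` — the count-weighted pooled estimate
(a `median` summary over per-cell estimates is available; pooled is the
default because it weights cells by their information content). Raw
per-cell values above 1 (possible for tiny droplets) are clipped with a
warning.

### Candidate-gene ranking

When no gene set is known a priori, `rank_estimation_genes` ranks the
500 most soup-abundant genes by how bimodal their per-cell log-ratio
`r_gc = log10((n_gc/N_c)/b_g)` is (zeros enter with pseudo-fraction
`0.1/N_c`). Ideal estimation genes show a contamination peak near
`log10 ρ` plus a separated endogenous peak above 0. Bimodality is scored
with the sample bimodality coefficient `(skew² + 1)/kurtosis`, which
exceeds 5/9 for distributions more bimodal than the uniform — chosen
because it is deterministic, moment-based and cheap; any reasonable
bimodality statistic would order the same genes similarly.

### Automated estimator

Markers of each cluster are found by tf-idf on detection: `tf` is the
fraction of the cluster's cells with a nonzero count, `idf = log(total
cells / cells detecting the gene anywhere)`; a gene is a marker of the
cluster maximizing its `tf` when `tf·idf ≥ 1.0`. If nothing passes —
heavy contamination depresses every `idf` because soup makes abundant
genes detectable everywhere — the cutoff relaxes in steps of 0.25 down
to 0.25 before giving up. Markers must additionally sit above the 90th
percentile of nonzero `b_g`: a marker invisible in the soup carries no
information about ρ. Each surviving marker is assumed silent in all
other clusters (after the same Poisson screen) and yields one pooled ρ
estimate. Good markers pile up at the true ρ while violated-assumption
markers scatter upward with no preferred value, so the final estimate is
the mode of a Gaussian KDE over the per-marker estimates (Silverman
bandwidth, weighted by each marker's soup counts, argmax on a 512-point
grid over [0, 1] for determinism). Fewer than two distinct estimates
fall back to their weighted mean.

## Correction

Naive subtraction `m = n − N ρ b` is exact in expectation but can go
negative; the implemented correction instead removes a fixed total
`T = round(ρ N)` (half-up, for determinism) per correction unit by
maximizing the multinomial log-likelihood of the removed counts,
`Σ_g o_g log b_g − log Γ(o_g+1)`, subject to `Σ o_g = T` and
`0 ≤ o_g ≤ n_g`. The KKT conditions give a water-filling solution; with
the standard approximation `ψ(x+1) ≈ log(x+½)` it is piecewise linear
in the water level C:

    o_g = clip(C·b_g − ½, 0, n_g)

C is found by bisection (60 iterations) and the uncapped genes rescaled
so the total is exact to 1e-9. The half-count shift matters only at
small counts, where it keeps the solution within one count per gene of
the exact integer optimum (verified against brute-force enumeration);
at large counts the allocation converges to proportional removal
`T·b_g` with caps, i.e. to the naive subtraction whenever no cap binds
(totals agree exactly; per-gene values differ by at most the half-count
shift). Genes with `b_g = 0` are never touched. A unit whose removable
counts fall short of T is flagged infeasible and stripped of everything
removable.

With cluster assignments, correction runs on cluster-aggregated counts —
pooling defeats sparsity, since a single observed count is otherwise
unclassifiable as soup or signal — and each gene's removed total is
redistributed to member cells in proportion to their observed counts of
that gene. Proportional-to-observed redistribution (rather than
proportional to cell size) guarantees `0 ≤ m_gc ≤ n_gc` cell by cell,
coincides with size-proportionality when expression is homogeneous
across the cluster, and automatically removes more from the cells that
actually carry the contaminating counts.

`round_to_int` produces integer output by seeded stochastic rounding:
floor every removal, then add back the unit's rounded shortfall one
count at a time, sampling entries without replacement with probability
proportional to their fractional parts, never exceeding an entry's
observed count. Off by default; fractional corrected counts are valid
input for standard downstream tools.

Invariants maintained exactly: `corrected + removed = original`;
`0 ≤ corrected ≤ original`; removal is elementwise monotone in ρ;
ρ = 0 is the identity.

## Synthetic channels

`simulate_channel` instantiates the generative model itself: per-type
expression profiles, soup equal to the expected-UMI-weighted mean of the
profiles, per-cell depth `N_c` log-normal (σ = 0.5, emulating the wide
capture-efficiency spread of droplet assays), endogenous counts
multinomial from the type profile at `round((1−ρ)N_c)`, soup counts
multinomial from `b` for the remainder, and empty droplets as pure-soup
draws with uniform totals in [1, 10].

Default study conditions, fixed once: 2,000 genes; four cell types of
125 cells at mean depth 1,000; 25 *private* marker genes per type
(exactly zero in every other type's profile) carrying 25% of the type's
expression, the shared remainder drawn from a flat Dirichlet; 10,000
empty droplets (≈ 55,000 soup UMIs, the depth of a realistically
sequenced channel at desk scale — a much shallower soup makes `b_g`
noise, not estimator bias, the dominant error term). The private blocks
make exact negative-marker gene sets available by construction, so
estimator error can be scored against the generating ρ.
`species_mix_fixture` builds the barnyard special case: two types on
fully disjoint gene blocks, where every cross-block count is
ground-truth contamination.

What the simulator does *not* emulate — and hence what passing tests do
not establish about real data: doublets, per-cell variation in ρ beyond
depth effects, soup composition drift away from the cell-weighted mean
(a perturbation dial exists via explicit profiles), gene-length or GC
capture biases, imperfect clustering (simulated clusters are the true
cell types), and annotation ambiguity (duplicate symbols).

Measured under these conditions (20 channels, ρ ∈ {0.02, 0.05, 0.1,
0.2}): manual-estimator mean |ρ̂ − ρ| ≈ 0.002–0.003, automated ≈
0.003–0.01; the barnyard fixture's cross-block expression drops by a
factor of 20–70 after correction while own-block counts track the true
endogenous counts to ≈ 0.2%. `scripts/acceptance.py` recomputes all of
these for any seed.

## Numerical and design choices

- Empty-droplet threshold comparison: inclusive `≤ 10` by default;
  strict `<` available. The two differ only through droplets with
  exactly 10 UMIs and are practically indistinguishable.
- BH correction via `scipy.stats.false_discovery_control`.
- `maximum_contamination = 1` in the Poisson screen is deliberately the
  weakest null; it only excludes cells that *cannot* be explained as
  pure soup, erring toward keeping the m = 0 assumption safe.
- KDE mode on a fixed 512-point grid rather than numerical optimization:
  determinism beats the third decimal of the mode.
- Removal target rounding happens per correction unit (cell or
  cluster), before allocation.
- Ties in stochastic rounding are resolved by the seeded generator;
  everything else in the pipeline is deterministic given its inputs.
- MatrixMarket output is written in column-major nonzero order with a
  fixed float format, so equal matrices produce byte-identical files.

## Limitations

- A raw (unfiltered) matrix containing empty droplets is required; the
  clustering-only setting without empties is out of scope.
- ρ is global per channel; the per-cell shrinkage estimator of the
  hierarchical-Bayes variety is not implemented.
- The Poisson screen assumes gene-set counts are independent across the
  set given `N_c`; strongly co-regulated sets violate this mildly.
- tf-idf marker discovery needs at least two clusters and honest
  cluster labels; with a single cluster or label noise, supply a manual
  gene set or a fixed ρ.
- At contamination rates approaching the expression level of every
  marker (ρ ≳ 0.3), marker detection degrades and the automated
  estimator loses its anchor; the manual path remains usable.
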