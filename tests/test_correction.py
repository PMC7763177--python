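import itertools
import math

import numpy as np
import pytest
import scipy.sparse as sp

import soupclean as scn
from soupclean.correction import _capped_removal
from conftest import make_matrix, soup_from_fractions


def brute_force_removal(n, b, target):
    """Independent oracle: enumerate all integer removal vectors o with
    sum(o) = target, 0 <= o <= n, and maximize the multinomial removal
    log-likelihood sum o_g log b_g - log o_g!."""
    best, best_ll = None, -np.inf
    for o in itertools.product(*[range(int(x) + 1) for x in n]):
        if sum(o) != target:
            continue
        ll, ok = 0.0, True
        for og, bg in zip(o, b):
            if og > 0:
                if bg == 0:
                    ok = False
                    break
                ll += og * math.log(bg) - math.lgamma(og + 1)
        if ok and ll > best_ll:
            best_ll, best = ll, np.array(o, dtype=float)
    return best


class TestExpectedSoupCounts:
    def test_direct_arithmetic(self):
        soup = soup_from_fractions([0.02, 0.98])
        o = scn.expected_soup_counts(np.array([100]), 0.05, soup)
        assert o[0, 0] == pytest.approx(0.1)

    def test_zero_rho_gives_zero_matrix(self):
        soup = soup_from_fractions([0.3, 0.7])
        assert not scn.expected_soup_counts(np.array([50, 80]), 0.0, soup).any()

    def test_column_sums_are_n_rho(self):
        soup = soup_from_fractions([0.2, 0.3, 0.5])
        o = scn.expected_soup_counts(np.array([100, 40]), np.array([0.1, 0.5]), soup)
        np.testing.assert_allclose(o.sum(axis=0), [10.0, 20.0])

    def test_negative_rho_rejected(self):
        soup = soup_from_fractions([1.0])
        with pytest.raises(ValueError, match="negative"):
            scn.expected_soup_counts(np.array([10]), -0.1, soup)


class TestSubtractNaive:
    def test_direct_arithmetic(self):
        soup = soup_from_fractions([0.02, 0.98])
        cells = make_matrix([[10], [90]])
        m = scn.subtract_naive(cells, 0.05, soup)
        assert m[0, 0] == pytest.approx(10 - 100 * 0.05 * 0.02)  # 9.9

    def test_clip_prevents_negative(self):
        soup = soup_from_fractions([0.5, 0.5])
        cells = make_matrix([[0], [100]])
        m = scn.subtract_naive(cells, 0.5, soup, clip=True)
        assert m[0, 0] == 0.0
        unclipped = scn.subtract_naive(cells, 0.5, soup, clip=False)
        assert unclipped[0, 0] < 0

    def test_close_to_constrained_removal_when_no_caps_bind(self):
        # generous counts everywhere: constrained removal stays within a
        # count of naive subtraction (half-count shift per gene at most)
        soup = soup_from_fractions([0.4, 0.35, 0.25])
        cells = make_matrix([[400], [350], [250]])
        naive = scn.subtract_naive(cells, 0.1, soup)
        res = scn.correct_counts(cells, soup, 0.1)
        corrected = np.asarray(res.corrected.todense())
        assert np.abs(corrected - naive).max() <= 1.0
        # removal totals agree exactly with rho * N
        assert res.removed.sum() == pytest.approx(100.0)


class TestCappedRemoval:
    def test_symmetric_uncapped_unit(self):
        o, infeasible = _capped_removal(
            np.array([10.0, 10.0]), np.array([0.5, 0.5]), 10
        )
        np.testing.assert_allclose(o, [5.0, 5.0])
        assert not infeasible

    def test_capped_unit_spills_to_other_gene(self):
        o, infeasible = _capped_removal(
            np.array([1.0, 19.0]), np.array([0.5, 0.5]), 10
        )
        np.testing.assert_allclose(o, [1.0, 9.0])
        assert not infeasible

    def test_zero_soup_genes_never_touched(self):
        o, _ = _capped_removal(np.array([5.0, 5.0]), np.array([0.0, 1.0]), 4)
        assert o[0] == 0.0 and o[1] == pytest.approx(4.0)

    def test_infeasible_unit_removes_all_removable(self):
        o, infeasible = _capped_removal(
            np.array([5.0, 5.0]), np.array([1.0, 0.0]), 9
        )
        assert infeasible
        np.testing.assert_allclose(o, [5.0, 0.0])

    def test_matches_bruteforce_on_random_small_units(self):
        rng = np.random.default_rng(123)
        compared = 0
        for _ in range(300):
            k = int(rng.integers(2, 7))
            n = rng.integers(0, 8, size=k).astype(float)
            b = rng.dirichlet(np.ones(k) * float(rng.choice([0.5, 1.0, 3.0])))
            removable = n[b > 0].sum()
            if removable < 1 or n.sum() > 30:
                continue
            target = int(rng.integers(1, min(removable, 30) + 1))
            o, infeasible = _capped_removal(n, b, target)
            oracle = brute_force_removal(n, b, target)
            if oracle is None or infeasible:
                continue
            compared += 1
            assert np.abs(o - oracle).max() <= 1.0 + 1e-9
        assert compared >= 100


class TestCorrectCounts:
    def test_identity_at_zero_rho(self, channel):
        _, filtered, _, _ = channel
        soup = soup_from_fractions(np.ones(filtered.n_genes) / filtered.n_genes)
        res = scn.correct_counts(filtered, soup, 0.0)
        assert (res.corrected != filtered.counts).nnz == 0
        assert res.removed.nnz == 0

    def test_conservation_and_bounds(self, channel, channel_soup):
        _, filtered, clusters, _ = channel
        res = scn.correct_counts(filtered, channel_soup, 0.1, clusters=clusters)
        resid = res.corrected + res.removed - filtered.counts
        assert abs(resid).max() < 1e-9 if resid.nnz else True
        assert res.corrected.data.min() >= 0
        assert res.removed.data.min() >= 0
        # removed never exceeds observed
        diff = filtered.counts - res.removed
        assert diff.min() > -1e-9

    def test_per_unit_total_is_rounded_target(self):
        soup = soup_from_fractions([0.5, 0.5])
        cells = make_matrix([[40], [60]])
        res = scn.correct_counts(cells, soup, 0.11)
        assert res.removed.sum() == pytest.approx(round(0.11 * 100))

    def test_cluster_removal_lands_on_observing_cell(self):
        # soup-only gene observed in one of two same-size cells: its
        # removed counts must come from that cell only
        soup = soup_from_fractions([0.5, 0.25, 0.25])
        counts = np.array([[4, 0], [0, 4], [96, 96]])
        cells = make_matrix(counts, barcode_prefix="d")
        clusters = scn.ClusterAssignment({"d0": "c", "d1": "c"})
        res = scn.correct_counts(cells, soup, 0.04, clusters=clusters)
        removed = np.asarray(res.removed.todense())
        assert removed[0, 1] == 0.0  # cell d1 never observed gene 0
        assert removed[1, 0] == 0.0
        assert removed[0, 0] > 0

    def test_monotone_in_rho(self):
        rng = np.random.default_rng(7)
        cells = make_matrix(rng.integers(0, 30, size=(10, 5)))
        soup = soup_from_fractions(rng.dirichlet(np.ones(10)))
        r1 = scn.correct_counts(cells, soup, 0.05)
        r2 = scn.correct_counts(cells, soup, 0.15)
        d = np.asarray((r2.removed - r1.removed).todense())
        assert d.min() >= -1e-9

    def test_rho_above_one_rejected(self):
        cells = make_matrix([[10]])
        soup = soup_from_fractions([1.0])
        with pytest.raises(ValueError, match="outside"):
            scn.correct_counts(cells, soup, 1.2)

    def test_missing_cluster_label_rejected(self):
        cells = make_matrix([[10, 10]], barcode_prefix="d")
        soup = soup_from_fractions([1.0])
        clusters = scn.ClusterAssignment({"d0": "c"})
        with pytest.raises(ValueError, match="cluster"):
            scn.correct_counts(cells, soup, 0.1, clusters=clusters)

    def test_infeasible_cell_flagged(self):
        soup = soup_from_fractions([1.0, 0.0])
        cells = make_matrix([[1], [99]], barcode_prefix="d")
        res = scn.correct_counts(cells, soup, 0.5)
        assert res.infeasible_cells == ["d0"]
        assert res.removed.sum() == 1.0


class TestIntegerRounding:
    def test_rounded_output_is_integral_and_bounded(self, channel, channel_soup):
        _, filtered, clusters, _ = channel
        res = scn.correct_counts(
            filtered, channel_soup, 0.1, clusters=clusters,
            round_to_int=True, seed=5,
        )
        assert np.all(res.removed.data == np.round(res.removed.data))
        assert np.all(res.corrected.data == np.round(res.corrected.data))
        assert res.corrected.data.min() >= 0

    def test_seeded_rounding_is_reproducible(self, channel, channel_soup):
        _, filtered, clusters, _ = channel
        kw = dict(clusters=clusters, round_to_int=True, seed=5)
        a = scn.correct_counts(filtered, channel_soup, 0.1, **kw)
        b = scn.correct_counts(filtered, channel_soup, 0.1, **kw)
        assert (a.corrected != b.corrected).nnz == 0


class TestRemovalSummary:
    def test_zero_rho_all_fractions_zero(self):
        cells = make_matrix([[3], [7]])
        soup = soup_from_fractions([0.5, 0.5])
        summary = scn.removal_summary(scn.correct_counts(cells, soup, 0.0))
        assert summary["global_fraction_removed"] == 0.0
        assert (summary["per_gene"]["fraction_removed"] == 0).all()

    def test_per_cell_fraction_matches_rho(self):
        soup = soup_from_fractions([0.5, 0.5])
        cells = make_matrix([[100], [100]])
        summary = scn.removal_summary(scn.correct_counts(cells, soup, 0.1))
        assert summary["per_cell"]["fraction_removed"][0] == pytest.approx(
            0.1, abs=1 / 200
        )

    def test_species_mix_asymmetry(self, species):
        # cross-block genes lose essentially everything, own markers little
        raw, filtered, clusters, truth = species
        soup = scn.estimate_soup(raw)
        res = scn.correct_counts(filtered, soup, 0.02, clusters=clusters)
        per_gene = scn.removal_summary(res)["per_gene"]
        # per-cluster cross fraction: block A genes within speciesB cells
        removed = np.asarray(res.removed.todense())
        original = np.asarray(filtered.counts.todense())
        labels = clusters.labels_for(filtered.barcodes)
        blockA = np.array(truth.marker_genes["speciesA"])
        in_b = labels == "speciesB"
        cross_removed_frac = (
            removed[blockA][:, in_b].sum() / original[blockA][:, in_b].sum()
        )
        own_removed_frac = (
            removed[blockA][:, ~in_b].sum() / original[blockA][:, ~in_b].sum()
        )
        assert cross_removed_frac > 0.8
        assert own_removed_frac < 0.05


class TestSoupCorrectorEstimator:
    def test_fit_transform_roundtrip(self, channel):
        raw, filtered, clusters, _ = channel
        corr = scn.SoupCorrector(contamination="auto")
        corr.fit(raw, cells=filtered, clusters=clusters)
        assert 0.05 < corr.rho_ < 0.15
        out = corr.transform(filtered)
        assert out.counts.shape == filtered.counts.shape
        assert out.counts.sum() < filtered.counts.sum()

    def test_fixed_rho_needs_no_cells(self, channel):
        raw, filtered, _, _ = channel
        corr = scn.SoupCorrector(contamination=0.0).fit(raw)
        out = corr.transform(filtered)
        assert (out.counts != filtered.counts).nnz == 0

    def test_get_params_round_trip(self):
        corr = scn.SoupCorrector(umi_threshold=7)
        params = corr.get_params()
        assert params["umi_threshold"] == 7
        corr.set_params(umi_threshold=12)
        assert corr.umi_threshold == 12
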