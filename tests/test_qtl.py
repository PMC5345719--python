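"""Multiple-imputation draws, LOD scans, thresholds, intervals, effects."""

import numpy as np
import pytest

from f2gbs.model import GeneticMap
from f2gbs.qtl import (GenotypeDraws, bayes_credible_interval,
                       conditional_genotype_draws, permutation_threshold,
                       qtl_effects, scan, scan_single_qtl, variance_explained,
                       _conditional_probs)
from f2gbs.simulate import F2SimConfig, QTLSpec, sim_f2, sim_map

from conftest import abh_from_rows


def _map_1chrom(positions, chrom="1"):
    return GeneticMap(chromosomes={
        chrom: [(f"m{j}", float(p)) for j, p in enumerate(positions)]})


class TestConditionalDraws:
    def test_observed_marker_reproduced_in_every_draw(self, rng):
        g = abh_from_rows(["ABH"], units="cM", positions=[0, 10, 20])
        gmap = _map_1chrom([0, 10, 20])
        draws = conditional_genotype_draws(g, gmap, step_cM=1, n_draws=20, seed=rng)
        for mid, expected in zip(["m0", "m1", "m2"], [0, 2, 1]):
            col = draws.marker_col[mid]
            assert np.all(draws.draws[0, col, :] == expected)

    def test_midpoint_between_close_equal_flanks(self):
        # exact Markov conditional: P(A at midpoint | A...A, 2 cM apart) > 0.96
        p = _conditional_probs(np.array([1.0]), np.array([0.0, 2.0]),
                               np.array([0, 0]))
        assert p[0, 0] > 0.96

    def test_midpoint_between_opposite_homozygotes_favours_het(self):
        p = _conditional_probs(np.array([5.0]), np.array([0.0, 10.0]),
                               np.array([0, 2]))
        assert p[0, 1] == max(p[0])

    def test_no_information_gives_mendelian_prior(self):
        p = _conditional_probs(np.array([3.0]), np.array([]), np.array([]))
        assert p[0].tolist() == [0.25, 0.5, 0.25]

    def test_missing_markers_skipped_in_conditioning(self, rng):
        g = abh_from_rows(["ANA"], units="cM", positions=[0, 5, 10])
        gmap = _map_1chrom([0, 5, 10])
        draws = conditional_genotype_draws(g, gmap, step_cM=5, n_draws=400, seed=rng)
        col = draws.marker_col["m1"]
        frac_a = np.mean(draws.draws[0, col, :] == 0)
        # exact conditional P(A | flanks A at 5 cM each side) ~ 0.995
        assert frac_a > 0.95

    def test_draws_reproducible_given_seed(self):
        g = abh_from_rows(["AB", "HB"], units="cM", positions=[0, 30])
        gmap = _map_1chrom([0, 30])
        d1 = conditional_genotype_draws(g, gmap, seed=77)
        d2 = conditional_genotype_draws(g, gmap, seed=77)
        assert np.array_equal(d1.draws, d2.draws)


def _single_marker_draws(genos, n_draws=1):
    codes = np.array([{"A": 0, "H": 1, "B": 2}[c] for c in genos], dtype=np.int8)
    draws = np.repeat(codes[:, None, None], n_draws, axis=2)
    return GenotypeDraws(
        individuals=[f"i{k}" for k in range(len(genos))],
        grid_chrom=np.array(["1"]),
        grid_cM=np.array([0.0]),
        draws=draws,
        marker_col={"m0": 0},
    )


class TestScan:
    def test_hand_computed_lod_single_marker(self):
        # 6 individuals, one marker, one draw: LOD = (n/2) log10(RSS0/RSS1)
        genos = "AABBHH"
        y = np.array([1.0, 1.2, 3.0, 2.8, 2.0, 2.2])
        draws = _single_marker_draws(genos)
        lod = scan_single_qtl(y, draws)
        xa = np.array([-1, -1, 1, 1, 0, 0], float)
        xd = np.array([0, 0, 0, 0, 1, 1], float)
        X = np.column_stack([np.ones(6), xa, xd])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = np.sum((y - X @ beta) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        assert lod[0] == pytest.approx(3.0 * np.log10(rss0 / rss1), rel=1e-9)

    def test_affine_phenotype_invariance(self, rng):
        genos = "".join(rng.choice(list("ABH"), 40))
        y = rng.normal(size=40)
        draws = _single_marker_draws(genos, n_draws=3)
        lod1 = scan_single_qtl(y, draws)
        lod2 = scan_single_qtl(5.0 * y - 3.0, draws)
        assert np.allclose(lod1, lod2)

    def test_combined_lod_reduces_to_single_draw(self, rng):
        genos = "".join(rng.choice(list("ABH"), 30))
        y = rng.normal(size=30)
        d1 = _single_marker_draws(genos, n_draws=1)
        d4 = _single_marker_draws(genos, n_draws=4)  # identical draws
        assert scan_single_qtl(y, d1)[0] == pytest.approx(
            scan_single_qtl(y, d4)[0])

    def test_constant_phenotype_rejected(self):
        draws = _single_marker_draws("ABH")
        with pytest.raises(ValueError, match="constant"):
            scan_single_qtl(np.ones(3), draws)

    def test_noiseless_additive_signal_peaks_at_causal_marker(self):
        for seed in range(3):
            cfg = F2SimConfig(chr_lengths_cM=(100.0,), n_markers=21,
                              n_individuals=150, seed=60 + seed,
                              qtl=(QTLSpec("1", 50.0, 1.0, 0.0),),
                              residual_sd=1.0)
            gmap = sim_map(cfg)
            g, _, tq = sim_f2(gmap, cfg)
            y = tq["1@50"].to_numpy().astype(float) - 1.0  # exact additive code
            draws = conditional_genotype_draws(g, gmap, step_cM=2,
                                               n_draws=4, seed=seed)
            lod = scan_single_qtl(y + 1e-6 * np.random.default_rng(seed).normal(size=len(y)), draws)
            peak_cm = draws.grid_cM[int(np.argmax(lod))]
            far = np.abs(draws.grid_cM - 50.0) > 20.0
            assert abs(peak_cm - 50.0) <= 20.0
            assert lod.max() > lod[far].max()


class TestPermutationThreshold:
    def _setup(self, rng, n=120):
        cfg = F2SimConfig(chr_lengths_cM=(80.0, 80.0), n_markers=16,
                          n_individuals=n, seed=5)
        gmap = sim_map(cfg)
        g, _, _ = sim_f2(gmap, cfg)
        draws = conditional_genotype_draws(g, gmap, step_cM=4, n_draws=2, seed=rng)
        y = rng.normal(size=n)
        return y, draws

    def test_alpha_one_gives_minimum_of_null_distribution(self, rng):
        y, draws = self._setup(rng)
        thr, dist = permutation_threshold(y, draws, n_perm=50, alpha=1.0,
                                          seed=rng, return_distribution=True)
        assert thr == pytest.approx(dist.min())

    def test_threshold_stable_across_seeds(self, rng):
        y, draws = self._setup(rng)
        t1 = permutation_threshold(y, draws, n_perm=400, alpha=0.05, seed=1)
        t2 = permutation_threshold(y, draws, n_perm=400, alpha=0.05, seed=2)
        assert abs(t1 - t2) < 0.3

    def test_null_max_lod_mostly_below_threshold(self, rng):
        # phenotype independent of genotype: genome-wide max exceeds the
        # 5% threshold in about 5% of replicates
        y, draws = self._setup(rng)
        thr = permutation_threshold(y, draws, n_perm=200, alpha=0.05, seed=3)
        exceed = 0
        reps = 40
        for _ in range(reps):
            y2 = rng.normal(size=len(y))
            exceed += scan_single_qtl(y2, draws).max() >= thr
        assert exceed <= reps * 0.05 + 3 * np.sqrt(reps * 0.05 * 0.95) + 1


class TestBayesInterval:
    def test_single_point_spike(self):
        grid = np.arange(0, 101, 1.0)
        lod = np.zeros(101)
        lod[40] = 8.0
        left, right = bayes_credible_interval(grid, lod, 0.95)
        assert right - left <= 2.0
        assert left <= 40 <= right

    def test_flat_profile_covers_95_percent_centred(self):
        grid = np.arange(0, 101, 1.0)
        left, right = bayes_credible_interval(grid, np.zeros(101), 0.95)
        assert (right - left) == pytest.approx(95, abs=1.5)
        assert abs((left + right) / 2 - 50) <= 1.5

    def test_gaussian_bump_matches_numeric_oracle(self):
        grid = np.arange(0, 200.5, 0.5)
        lod = 6.0 * np.exp(-0.5 * ((grid - 80) / 7.0) ** 2)
        left, right = bayes_credible_interval(grid, lod, 0.95)
        # oracle: smallest symmetric interval holding 95% of 10^lod area
        w = 10.0 ** lod
        w /= np.trapezoid(w, grid)
        half = 0.0
        while True:
            half += 0.5
            sel = np.abs(grid - 80) <= half
            if np.trapezoid(w[sel], grid[sel]) >= 0.95:
                break
        assert left == pytest.approx(80 - half, abs=1.0)
        assert right == pytest.approx(80 + half, abs=1.0)

    def test_interval_contains_peak_and_covers_prob(self, rng):
        for _ in range(20):
            grid = np.arange(0, 60, 1.0)
            lod = np.abs(rng.normal(0, 1.5, len(grid)))
            left, right = bayes_credible_interval(grid, lod, 0.9)
            peak = grid[int(np.argmax(lod))]
            assert left <= peak <= right
            w = 10.0 ** (lod - lod.max())
            sel = (grid >= left) & (grid <= right)
            assert np.trapezoid(w[sel], grid[sel]) / np.trapezoid(w, grid) >= 0.9 - 1e-9


class TestEffectsAndVariance:
    def test_effects_arithmetic(self):
        y = np.array([10.0, 10.0, 12.0, 12.0, 8.0, 8.0])
        g = np.array(list("AAHHBB"))
        add, dom = qtl_effects(y, g)
        assert add == pytest.approx(-1.0)
        assert dom == pytest.approx(3.0)

    def test_no_effect_when_means_equal(self):
        y = np.ones(6) * 4.2
        add, dom = qtl_effects(y, np.array(list("AAHHBB")))
        assert add == 0.0 and dom == 0.0

    def test_missing_class_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            qtl_effects(np.arange(4.0), np.array(list("AABB")))

    def test_variance_explained_extremes(self, rng):
        g = np.array(list("AHB" * 40))
        x = np.array([{"A": -1.0, "H": 0.0, "B": 1.0}[c] for c in g])
        assert variance_explained(x * 2 + 1, g) == pytest.approx(100.0)
        y = rng.normal(size=len(g))
        assert variance_explained(y, g) < 15.0

    def test_simulated_effect_recovery(self, rng):
        a_true, d_true = 0.5, 0.25
        cfg = F2SimConfig(chr_lengths_cM=(100.0,), n_markers=11,
                          n_individuals=600, seed=71,
                          qtl=(QTLSpec("1", 50.0, a_true, d_true),))
        gmap = sim_map(cfg)
        g, y, tq = sim_f2(gmap, cfg)
        geno = tq["1@50"].to_numpy()
        add, dom = qtl_effects(y, geno)
        nA = np.sum(geno == 0); nH = np.sum(geno == 1); nB = np.sum(geno == 2)
        se_add = 0.5 * np.sqrt(1 / nA + 1 / nB)
        se_dom = np.sqrt(1 / nH + 0.25 * (1 / nA + 1 / nB))
        assert abs(add - a_true) < 3 * se_add
        assert abs(dom - d_true) < 3 * se_dom


class TestFullScan:
    def test_strong_qtl_detected_with_interval_and_effects(self):
        cfg = F2SimConfig(chr_lengths_cM=(100.0, 100.0), n_markers=30,
                          n_individuals=250, seed=81,
                          qtl=(QTLSpec("1", 40.0, 0.8, 0.2),))
        gmap = sim_map(cfg)
        g, y, _ = sim_f2(gmap, cfg)
        res = scan(g, gmap, y, step_cM=2, n_draws=4, n_perm=100, seed=82)
        assert len(res.peaks) >= 1
        top = max(res.peaks, key=lambda p: p.lod)
        assert top.chromosome == "1"
        assert top.interval_cM[0] <= top.position_cM <= top.interval_cM[1]
        assert abs(top.position_cM - 40.0) < 15.0
        assert top.lod >= res.threshold
        assert 0 < top.percent_variance < 100
        assert top.additive_effect > 0  # B (parent-2) allele increases trait

    def test_phenotype_dict_aligned_by_individual(self):
        cfg = F2SimConfig(chr_lengths_cM=(60.0,), n_markers=6,
                          n_individuals=40, seed=91)
        gmap = sim_map(cfg)
        g, y, _ = sim_f2(gmap, cfg)
        pheno = {ind: val for ind, val in zip(g.individuals, y)}
        res = scan(g, gmap, pheno, step_cM=5, n_draws=2, n_perm=20, seed=92)
        assert res.lod.shape == res.grid_cM.shape
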