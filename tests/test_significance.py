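import numpy as np
import pytest
from scipy.stats import chisquare

import divergescan as dv
from divergescan.divergence import DivergenceScore
from divergescan.significance import (
    RandomizationConfig,
    adjust_bh,
    choose_count_levels,
    fit_null_model,
    p_values,
    randomized_divergences,
    sample_detection_indices,
)


class TestCountLevels:
    def test_endpoints_and_count(self):
        nd = np.concatenate([[10], np.random.default_rng(0).integers(10, 5001, 200), [5000]])
        levels = choose_count_levels(10000, nd, 20)
        assert levels[0] == 10 and levels[-1] == 5000
        assert len(levels) == 20
        assert np.all(np.diff(levels) > 0)

    def test_single_distinct_count(self):
        levels = choose_count_levels(1000, np.full(30, 50), 20)
        np.testing.assert_array_equal(levels, [50])

    def test_levels_respect_cell_bounds(self):
        levels = choose_count_levels(100, np.array([1, 99]), 20)
        assert levels.min() >= 1 and levels.max() <= 99


class TestRandomizedDivergences:
    def test_deterministic_given_seed(self, density_setup):
        det, emb, grid, dm, q = density_setup
        cfg = RandomizationConfig(seed=3)
        out1 = randomized_divergences(40, dm, q, cfg, np.random.default_rng(3))
        out2 = randomized_divergences(40, dm, q, cfg, np.random.default_rng(3))
        assert out1 == out2

    def test_spread_is_positive(self, density_setup):
        det, emb, grid, dm, q = density_setup
        cfg = RandomizationConfig(seed=0)
        for level in (10, 50, 150):
            _, sd = randomized_divergences(level, dm, q, cfg, np.random.default_rng(0))
            assert sd > 1e-6

    def test_uniform_weights_sample_uniformly(self):
        """Selection frequencies under uniform weights pass a chi-square test."""
        rng = np.random.default_rng(0)
        n_cells, level, n_draws = 40, 10, 1000
        idx = sample_detection_indices(level, n_cells, n_draws, rng,
                                       weights=np.full(n_cells, 1 / n_cells))
        freq = np.bincount(idx.ravel(), minlength=n_cells)
        assert chisquare(freq).pvalue > 0.01

    def test_weighted_sampling_tracks_weights(self):
        """A cell with 3x weight is selected about 3x as often (small draws)."""
        rng = np.random.default_rng(1)
        n_cells = 100
        w = np.ones(n_cells)
        w[0] = 3.0
        w /= w.sum()
        idx = sample_detection_indices(2, n_cells, 20000, rng, weights=w)
        freq = np.bincount(idx.ravel(), minlength=n_cells)
        ratio = freq[0] / freq[1:].mean()
        assert 2.5 < ratio < 3.5


class TestNullModelFit:
    def test_saturated_fit_interpolates(self):
        rng = np.random.default_rng(2)
        levels = np.array([10, 30, 90, 270, 800, 2000, 5000])
        means = rng.normal(size=7)
        sds = rng.uniform(0.1, 0.5, 7)
        model = fit_null_model(levels, means, sds, spline_df=6)  # 7 params = n_levels
        x = np.log(levels.astype(float))
        np.testing.assert_allclose(model.mean_curve(x), means, atol=1e-8)
        np.testing.assert_allclose(model.sd_curve(x), sds, atol=1e-8)

    def test_constant_means_give_constant_curve(self):
        levels = np.geomspace(10, 1000, 12).astype(int)
        model = fit_null_model(levels, np.full(12, -3.0), np.full(12, 0.2), 6)
        xs = np.log(np.array([15.0, 100.0, 900.0]))
        np.testing.assert_allclose(model.mean_curve(xs), -3.0, atol=1e-8)

    def test_clamped_extrapolation(self):
        rng = np.random.default_rng(3)
        levels = np.geomspace(10, 1000, 10).astype(int)
        model = fit_null_model(levels, rng.normal(size=10), rng.uniform(0.1, 1, 10), 6)
        lo, hi = model.fit_domain
        assert model.mean_curve(lo - 5.0) == pytest.approx(float(model.mean_curve(lo)))
        assert model.mean_curve(hi + 5.0) == pytest.approx(float(model.mean_curve(hi)))

    def test_few_levels_fall_back_to_constant(self):
        model = fit_null_model([10, 100], [-2.0, -4.0], [0.1, 0.3], 6)
        assert model.mean_curve(np.log(50.0)) == pytest.approx(-3.0)

    def test_spline_tracks_held_out_levels(self, density_setup):
        """Fitted curves predict empirical moments at levels left out of the fit."""
        det, emb, grid, dm, q = density_setup
        cfg = RandomizationConfig(n_randomizations=400, seed=0)
        rng = np.random.default_rng(0)
        levels = np.unique(np.geomspace(10, 140, 30).astype(int))
        moments = [randomized_divergences(int(l), dm, q, cfg, rng) for l in levels]
        means = np.array([m for m, _ in moments])
        sds = np.array([s for _, s in moments])
        # interior levels only: the clamped curve is not defined to
        # extrapolate beyond the fitted count range
        held = np.arange(len(levels)) % 3 == 1
        held[0] = held[-1] = False
        model = fit_null_model(levels[~held], means[~held], sds[~held], 6)
        ok = 0
        for lv, mu, sd in zip(levels[held], means[held], sds[held]):
            pred = float(model.mean_curve(np.log(float(lv))))
            ok += abs(pred - mu) < 2 * sd / np.sqrt(cfg.n_randomizations)
        assert ok >= 0.9 * held.sum()


class TestPValues:
    def _model(self, mean=-3.0, sd=0.5):
        const = lambda v: lambda xs: np.full_like(np.asarray(xs, dtype=float), v)
        return dv.NullModel(const(mean), const(sd), (0.0, 10.0),
                            np.array([10]), np.array([mean]), np.array([sd]))

    def _scores(self, ln_dkl, n_detected=50):
        return [DivergenceScore(f"g{i}", float(np.exp(v)), n_detected)
                for i, v in enumerate(np.atleast_1d(ln_dkl))]

    @pytest.mark.parametrize("z,expected_log10p,tol", [
        (0.0, np.log10(0.5), 1e-9),       # at the null median
        (1.6449, -1.3010, 5e-4),          # p ~ 0.05
        (-3.0, np.log10(0.99865), 1e-4),  # deep in the left tail, p ~ 1
    ])
    def test_normal_tail_conversion(self, z, expected_log10p, tol):
        model = self._model(mean=-3.0, sd=0.5)
        res = p_values(self._scores([-3.0 + z * 0.5]), model)
        assert res["log10_pval"][0] == pytest.approx(expected_log10p, abs=tol)

    def test_extreme_gene_does_not_underflow(self):
        model = self._model()
        res = p_values(self._scores([40.0]), model)
        assert np.isfinite(res["log10_pval"][0])
        assert res["log10_pval"][0] < -300

    def test_larger_dkl_more_significant_at_equal_count(self):
        model = self._model()
        res = p_values(self._scores([-2.0, -1.0, -3.0]), model).set_index("gene")
        assert res.loc["g1", "log10_pval"] < res.loc["g0", "log10_pval"]
        assert res.loc["g0", "log10_pval"] < res.loc["g2", "log10_pval"]

    def test_rank_ties_broken_by_dkl(self):
        # two genes with identical p (same z) get ranks ordered by d_kl
        model = self._model()
        scores = [DivergenceScore("lo", np.exp(-2.0), 50),
                  DivergenceScore("hi", np.exp(-2.0), 50)]
        scores[1].d_kl *= 1.0  # identical
        res = p_values(scores, model)
        assert sorted(res["rank"]) == [1, 2]

    def test_adjusted_never_smaller_than_raw(self, density_setup):
        det, emb, grid, dm, q = density_setup
        res = dv.run_from_detection(det, emb, method="2d", grid_points=36,
                                    seed=0, scale_coords=False)
        assert np.all(res["log10_pval_adj"] >= res["log10_pval"] - 1e-12)


class TestAdjustBH:
    def test_step_up_worked_example(self):
        # p = (.01, .02, .03, .04): all adjust to .04 under the step-up rule
        adj = adjust_bh(np.log10([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(10 ** adj, 0.04, rtol=1e-10)

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.array([-2.5])), [-2.5])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(adjust_bh(np.zeros(5)), 0.0)

    def test_matches_statsmodels_on_moderate_pvalues(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 200)
        expected = multipletests(p, method="fdr_bh")[1]
        got = 10 ** adjust_bh(np.log10(p))
        np.testing.assert_allclose(got, expected, rtol=1e-9)


class TestNullCalibration:
    def test_false_positive_rate_near_alpha(self):
        """Uniform random detection on a uniform 2D blob: ~5% of genes at p<0.05."""
        fracs = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            n_cells, n_genes = 800, 150
            cells = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
            emb = dv.EmbeddingCoordinates(cells, rng.uniform(0, 1, (n_cells, 2)))
            counts = np.round(np.geomspace(10, n_cells // 2, n_genes)).astype(int)
            det = np.zeros((n_genes, n_cells), dtype=bool)
            for g, c in enumerate(counts):
                det[g, rng.choice(n_cells, c, replace=False)] = True
            dmat = dv.DetectionMatrix(
                np.array([f"g{i}" for i in range(n_genes)], dtype=object), cells, det)
            res = dv.run_from_detection(dmat, emb, method="2d", seed=seed)
            fracs.append(float((res["log10_pval"] < np.log10(0.05)).mean()))
        assert 0.02 <= np.mean(fracs) <= 0.08
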