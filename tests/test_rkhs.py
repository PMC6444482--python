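import numpy as np
import pandas as pd
import pytest

from sirekit.data import align_phenotypes
from sirekit.grm import build_kernel, whole_genome_kernel
from sirekit.qc import dedupe_records
from sirekit.rkhs import (
    McmcConfig,
    RKHSRegression,
    add_fixed_markers,
    geweke_diagnostic,
)
from sirekit.simulate import SimulationConfig, simulate_dataset


class TestMcmcConfig:
    def test_production_schedule_retains_14000(self):
        cfg = McmcConfig.full_schedule()
        assert cfg.n_iter == 100_000 and cfg.burn_in == 30_000 and cfg.thin == 5
        assert cfg.n_retained == 14_000

    @pytest.mark.parametrize(
        "n_iter,burn,thin,expected",
        [(1000, 200, 2, 400), (1001, 200, 2, 400), (3000, 800, 3, 733)],
    )
    def test_retained_count_floor(self, n_iter, burn, thin, expected):
        assert McmcConfig(n_iter=n_iter, burn_in=burn, thin=thin).n_retained == expected

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)
        with pytest.raises(ValueError):
            McmcConfig(prior_df=0)


@pytest.fixture(scope="module")
def tiny_fit_inputs():
    cfg = SimulationConfig(n_individuals=120, n_snps=300, n_dominance_qtl=0, seed=55)
    g, _, pheno, truth = simulate_dataset(cfg)
    y, X, _ = align_phenotypes(g, dedupe_records(pheno))
    K = whole_genome_kernel(g)
    return g, y, X, K


class TestGibbsSampler:
    def test_fixed_variance_posterior_mean_equals_blup(self, tiny_fit_inputs):
        """With variances held fixed, the posterior mean of g converges to
        the closed-form BLUP g = K sg2 V^-1 (y - X beta_gls)."""
        _, y, X, K = tiny_fit_inputs
        n = len(y)
        sg2, se2 = 1.4, 2.6
        V = sg2 * K.values + se2 * np.eye(n)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        g_blup = sg2 * K.values @ Vi @ (y - X @ beta)

        fit = RKHSRegression(y, X, [K], fix_variances=([sg2], se2)).fit(
            McmcConfig(n_iter=9000, burn_in=1000, thin=1, seed=3)
        )
        rms = np.sqrt(np.mean((fit.g_mean[0] - g_blup) ** 2))
        assert rms < 0.05 * g_blup.std()
        assert np.corrcoef(fit.g_mean[0], g_blup)[0, 1] > 0.999
        # fixed variances are echoed back unchanged in every sample
        assert (fit.var_samples["sigma2_e"] == se2).all()

    def test_zero_genetic_variance_reduces_to_ols_fit(self, tiny_fit_inputs):
        _, y, X, K = tiny_fit_inputs
        fit = RKHSRegression(y, X, [K], fix_variances=([0.0], 2.0)).fit(
            McmcConfig(n_iter=4000, burn_in=500, thin=1, seed=4)
        )
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.b_mean, beta_ols, atol=0.15)
        np.testing.assert_allclose(fit.predicted, X @ beta_ols, atol=0.3)
        assert np.abs(fit.g_mean).max() == 0.0

    def test_same_seed_bit_identical_chains(self, tiny_fit_inputs):
        _, y, X, K = tiny_fit_inputs
        cfg = McmcConfig(n_iter=400, burn_in=100, thin=2, seed=9)
        a = RKHSRegression(y, X, [K]).fit(cfg)
        b = RKHSRegression(y, X, [K]).fit(cfg)
        pd.testing.assert_frame_equal(a.var_samples, b.var_samples)
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_duplicated_kernel_matches_single(self, tiny_fit_inputs):
        """Two copies of the same kernel split the genetic variance; the
        predictions and the summed variance match the single-kernel fit."""
        _, y, X, K = tiny_fit_inputs
        cfg = McmcConfig(n_iter=4000, burn_in=1000, thin=2, seed=5)
        one = RKHSRegression(y, X, [K]).fit(cfg)
        two = RKHSRegression(y, X, [K, K]).fit(cfg)
        assert np.corrcoef(one.predicted, two.predicted)[0, 1] > 0.99
        sum_two = two.var_samples.iloc[:, :2].sum(axis=1).mean()
        sum_one = one.var_samples.iloc[:, 0].mean()
        assert sum_two == pytest.approx(sum_one, rel=0.3)

    def test_h2_recovery_single_kernel(self, tiny_fit_inputs):
        _, y, X, K = tiny_fit_inputs
        fit = RKHSRegression(y, X, [K]).fit(
            McmcConfig(n_iter=3000, burn_in=800, thin=2, seed=6)
        )
        # n=120 gives a wide but informative posterior around the true 0.30
        assert 0.05 < fit.h2_posterior_mean < 0.6

    def test_masked_phenotypes_are_ignored_in_training(self, tiny_fit_inputs):
        _, y, X, K = tiny_fit_inputs
        mask = np.zeros(len(y), dtype=bool)
        mask[:30] = True
        y_corrupt = y.copy()
        y_corrupt[:30] = 999.0  # masked values must not matter
        cfg = McmcConfig(n_iter=1500, burn_in=400, thin=2, seed=7)
        a = RKHSRegression(y, X, [K], missing_mask=mask).fit(cfg)
        b = RKHSRegression(y_corrupt, X, [K], missing_mask=mask).fit(cfg)
        np.testing.assert_allclose(a.predicted, b.predicted, atol=1e-10)

    def test_rejects_bad_inputs(self, tiny_fit_inputs):
        _, y, X, K = tiny_fit_inputs
        with pytest.raises(ValueError):
            RKHSRegression(y, X, [])
        with pytest.raises(ValueError):
            RKHSRegression(y[:-1], X[:-1], [K])
        with pytest.raises(ValueError):
            RKHSRegression(y, X, [K], missing_mask=np.ones(len(y), dtype=bool)).fit(
                McmcConfig(n_iter=200, burn_in=50)
            )


class TestAddFixedMarkers:
    def test_appends_carrier_columns(self, small_dataset, small_aligned):
        _, genotypes, _, _, truth = small_dataset
        y, X, names = small_aligned
        X2, kept, names2 = add_fixed_markers(
            X, genotypes, truth.dominance_qtl_ids, names
        )
        assert X2.shape[1] == X.shape[1] + 5
        assert kept == list(truth.dominance_qtl_ids)
        assert set(np.unique(X2[:, X.shape[1]:])) <= {0.0, 1.0}

    def test_empty_list_is_noop(self, small_dataset, small_aligned):
        _, genotypes, _, _, _ = small_dataset
        y, X, _ = small_aligned
        X2, kept, _ = add_fixed_markers(X, genotypes, [])
        assert X2 is X and kept == []

    def test_collinear_marker_dropped(self, small_dataset, small_aligned):
        _, genotypes, _, _, truth = small_dataset
        y, X, _ = small_aligned
        snp = truth.dominance_qtl_ids[0]
        X2, kept, _ = add_fixed_markers(X, genotypes, [snp, snp])
        assert kept == [snp]
        assert X2.shape[1] == X.shape[1] + 1


class TestGeweke:
    def test_iid_chains_rarely_flagged(self, rng):
        flags = 0
        for _ in range(100):
            z = geweke_diagnostic(rng.standard_normal(1000))
            flags += abs(z) >= 2
        assert flags <= 5

    def test_step_change_detected(self, rng):
        x = np.concatenate([rng.standard_normal(500), rng.standard_normal(500) + 3])
        assert abs(geweke_diagnostic(x)) > 4

    def test_constant_chain_is_zero(self):
        assert geweke_diagnostic(np.full(500, 2.5)) == 0.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(np.arange(50.0))
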