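"""The eight multi-trait association tests: examples, calibration, equivalences."""

import numpy as np
import pytest
from scipy import stats

import pleiosim as ps
from pleiosim import DegenerateInputError, ParameterError, UnivariateSummary
from pleiosim.datagen import _mvn_factor
from pleiosim.methods import _shet_statistic, fit_shet_null, read_summary, write_summary


def make_summary(z, corr):
    """Summary object from Wald statistics alone (unit SEs)."""
    z = np.asarray(z, dtype=float)
    return UnivariateSummary(beta=z.copy(), se=np.ones_like(z), z=z,
                             p=2 * stats.norm.sf(np.abs(z)),
                             trait_corr=np.atleast_2d(np.asarray(corr, dtype=float)))


def null_z_draws(c, n_draws, seed):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_draws, c.shape[0])) @ _mvn_factor(c).T


class TestUnivariateScan:
    def test_null_pvalues_uniform(self):
        ps_all = []
        for i in range(2_000):
            ds = ps.simulate_dataset([0.0, 0.0], np.eye(2), n=300, maf=0.3,
                                     seed=5_000 + i)
            ps_all.append(ps.univariate_scan(ds).p)
        flat = np.concatenate(ps_all)
        assert stats.kstest(flat, "uniform").pvalue > 1e-4

    def test_power_matches_noncentral_approximation(self):
        # K = 1: Wald z is ~N(sqrt(n*ve), 1), giving closed-form power
        n, v, alpha = 2_000, 0.01, 0.05
        ncp = np.sqrt(n * v / (1 - v))
        zcrit = stats.norm.isf(alpha / 2)
        expected = stats.norm.sf(zcrit - ncp) + stats.norm.cdf(-zcrit - ncp)
        hits = 0
        reps = 500
        for i in range(reps):
            ds = ps.simulate_dataset([v], np.eye(1), n=n, maf=0.3, seed=9_000 + i)
            hits += ps.univariate_scan(ds).p[0] < alpha
        se = np.sqrt(expected * (1 - expected) / reps)
        assert hits / reps == pytest.approx(expected, abs=3.5 * se)

    def test_binary_trait_null_calibration(self):
        pvals = []
        for i in range(300):
            ds = ps.simulate_dataset([0.0], np.eye(1), n=400, maf=0.3, seed=20_000 + i)
            ds = ps.dichotomize_dataset(ds, ps.LiabilityConfig(prevalence=(0.5,)))
            pvals.append(ps.univariate_scan(ds).p[0])
        assert stats.kstest(pvals, "uniform").pvalue > 1e-4

    def test_constant_genotype_rejected(self):
        ds = ps.simulate_dataset([0.0], np.eye(1), n=100, maf=1e-6, seed=1)
        with pytest.raises(DegenerateInputError):
            ps.univariate_scan(ds)


class TestNyholtMeff:
    def test_independent_traits(self):
        assert ps.nyholt_meff(np.eye(2)) == pytest.approx(2.0)

    def test_perfectly_correlated(self):
        assert ps.nyholt_meff(ps.equicorrelation(2, 1.0)) == pytest.approx(1.0)

    def test_half_correlated_pair(self):
        # eigenvalues 1.5 and 0.5 -> Meff = 1.75
        assert ps.nyholt_meff(ps.equicorrelation(2, 0.5)) == pytest.approx(1.75)


class TestMinP:
    def test_sidak_example(self):
        res = ps.minp_test(make_summary([stats.norm.isf(0.005), 0.6], np.eye(2)))
        assert res.pvalue == pytest.approx(1 - 0.99**2, rel=1e-6)

    def test_single_effective_test_passthrough(self):
        s = make_summary([2.0], np.eye(1))
        assert ps.minp_test(s).pvalue == pytest.approx(s.p[0])

    def test_boundary(self):
        assert ps.minp_test(make_summary([0.0, 0.0], np.eye(2))).pvalue == 1.0


class TestTATES:
    def test_reduces_to_simes_for_independent_traits(self):
        z = np.array([2.5, 1.0, 0.3, 1.7])
        s = make_summary(z, np.eye(4))
        res = ps.tates_test(s, pcorr=np.eye(4))
        p_sorted = np.sort(s.p)
        simes = (4 * p_sorted / np.arange(1, 5)).min()
        assert res.pvalue == pytest.approx(simes, rel=1e-9)

    def test_single_trait_passthrough(self):
        s = make_summary([1.3], np.eye(1))
        assert ps.tates_test(s).pvalue == pytest.approx(s.p[0])

    def test_null_rejection_rate(self):
        c = ps.equicorrelation(4, 0.5)
        ctx = ps.build_context(c, methods=("TATES",))
        z = null_z_draws(c, 10_000, seed=1)
        hits = sum(ps.tates_test(make_summary(zi, c), pcorr=ctx.pcorr).pvalue < 0.05
                   for zi in z)
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert hits / 10_000 == pytest.approx(0.05, abs=3 * se)


class TestSHom:
    def test_single_trait_squared_wald(self):
        res = ps.shom_test(make_summary([2.0], np.eye(1)))
        assert res.statistic == pytest.approx(4.0)
        assert res.pvalue == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_homogeneous_effects_add(self):
        assert ps.shom_test(make_summary([2.0, 2.0], np.eye(2))).statistic == \
            pytest.approx(8.0)

    def test_opposite_effects_cancel(self):
        res = ps.shom_test(make_summary([2.0, -2.0], np.eye(2)))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)


class TestSHet:
    def test_single_trait_chi_square(self):
        res = ps.shet_test(make_summary([2.0], np.eye(1)))
        assert res.statistic == pytest.approx(4.0)
        assert res.pvalue == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_dominates_all_trait_statistic(self):
        c = ps.equicorrelation(3, 0.2)
        rng = np.random.default_rng(2)
        null = fit_shet_null(c, n_sims=2_000, seed=3)
        for zi in null_z_draws(c, 50, seed=4):
            s = make_summary(zi, c)
            shom_like = ps.shom_test(s, null_corr=c).statistic
            assert _shet_statistic(zi, c) >= shom_like - 1e-10

    def test_null_rejection_rate(self):
        c = ps.equicorrelation(4, 0.3)
        null = fit_shet_null(c, n_sims=100_000, seed=5)
        z = null_z_draws(c, 10_000, seed=6)
        hits = sum(ps.shet_test(make_summary(zi, c), null_corr=c, null=null).pvalue < 0.05
                   for zi in z)
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert hits / 10_000 == pytest.approx(0.05, abs=3 * se)

    def test_small_null_sims_warns(self):
        with pytest.warns(UserWarning):
            ps.shet_test(make_summary([1.0, 0.5], np.eye(2)), null_sims=500, seed=1)


class TestManovaCca:
    def test_single_trait_collapses_to_regression_f(self):
        ds = ps.simulate_dataset([0.01], np.eye(1), n=500, maf=0.3, seed=30)
        g = ds.genotypes.astype(float)
        y = ds.phenotypes[:, 0]
        r = np.corrcoef(g, y)[0, 1]
        f = r**2 / (1 - r**2) * (ds.n - 2)
        p_reg = stats.f.sf(f, 1, ds.n - 2)
        assert ps.manova_test(ds).pvalue == pytest.approx(p_reg, rel=1e-9)
        assert ps.cca_test(ds).pvalue == pytest.approx(p_reg, rel=1e-9)

    def test_manova_equals_cca(self, random_datasets):
        for ds in random_datasets:
            pm = ps.manova_test(ds).pvalue
            pc = ps.cca_test(ds).pvalue
            assert abs(pm - pc) < 1e-10

    def test_manova_null_uniform(self):
        pvals = [ps.manova_test(ps.simulate_dataset(
            [0.0, 0.0], ps.equicorrelation(2, 0.5), n=300, maf=0.3, seed=40_000 + i
        )).pvalue for i in range(1_000)]
        assert stats.kstest(pvals, "uniform").pvalue > 1e-4

    def test_canonical_correlation_bounded(self, quad_dataset):
        res = ps.cca_test(quad_dataset)
        assert res.statistic >= 0.0


class TestCombinedPC:
    def test_single_trait_equals_squared_wald(self):
        ds = ps.simulate_dataset([0.01], np.eye(1), n=500, maf=0.3, seed=31)
        z = ps.univariate_scan(ds).z[0]
        assert ps.combined_pc_test(ds).statistic == pytest.approx(z**2, rel=1e-9)

    def test_uncorrelated_traits_sum_of_chi_squares(self):
        ds = ps.simulate_dataset([0.005, 0.005, 0.005], np.eye(3), n=20_000,
                                 maf=0.3, seed=32)
        z = ps.univariate_scan(ds).z
        assert ps.combined_pc_test(ds).statistic == pytest.approx(
            (z**2).sum(), rel=0.05)

    def test_close_to_cca_for_small_effects(self, random_datasets):
        ratios = []
        for ds in random_datasets:
            p1 = ps.combined_pc_test(ds).pvalue
            p2 = ps.cca_test(ds).pvalue
            ratios.append(abs(np.log10(p1 / p2)))
        assert np.median(ratios) < 0.2


class TestMultiPhen:
    def test_cross_check_against_statsmodels_ordinal(self, pair_dataset, quad_dataset):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        for ds in (pair_dataset, quad_dataset):
            res = ps.multiphen_test(ds)
            sm_fit = OrderedModel(ds.genotypes, ds.phenotypes,
                                  distr="logit").fit(method="bfgs", disp=0)
            lrt_sm = 2 * (sm_fit.llf - sm_fit.llnull)
            assert res.statistic == pytest.approx(lrt_sm, rel=1e-4, abs=1e-4)

    def test_null_rejection_rate(self):
        hits = 0
        reps = 2_000
        for i in range(reps):
            ds = ps.simulate_dataset([0.0, 0.0], ps.equicorrelation(2, 0.5),
                                     n=400, maf=0.3, seed=50_000 + i)
            hits += ps.multiphen_test(ds).pvalue < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps == pytest.approx(0.05, abs=3.5 * se)

    def test_binary_trait_smoke(self):
        ds = ps.simulate_dataset([0.005], np.eye(1), n=500, maf=0.3, seed=33)
        ds = ps.dichotomize_dataset(ds, ps.LiabilityConfig(prevalence=(0.4,)))
        res = ps.multiphen_test(ds)
        assert 0.0 < res.pvalue <= 1.0

    def test_single_level_genotype_rejected(self):
        ds = ps.simulate_dataset([0.0], np.eye(1), n=100, maf=1e-6, seed=34)
        with pytest.raises(DegenerateInputError):
            ps.multiphen_test(ds)


class TestSharedProperties:
    def test_permutation_invariance(self, quad_dataset):
        from dataclasses import replace

        perm = np.array([3, 0, 2, 1])
        permuted = replace(quad_dataset,
                           phenotypes=quad_dataset.phenotypes[:, perm],
                           effects=quad_dataset.effects[perm],
                           correlation=quad_dataset.correlation[np.ix_(perm, perm)])
        for name in ps.METHOD_NAMES:
            p0 = ps.run_method(name, quad_dataset).pvalue
            p1 = ps.run_method(name, permuted).pvalue
            # TATES/SHet null references are Monte-Carlo estimates, so their
            # invariance holds only to within Monte-Carlo error
            rel = 2e-2 if name in ("TATES", "SHet") else 1e-6
            assert p1 == pytest.approx(p0, rel=rel), name

    def test_median_p_decreases_with_effect(self):
        medians = {name: [] for name in ps.METHOD_NAMES}
        for v in (0.0, 0.003, 0.015):
            pvals = {name: [] for name in ps.METHOD_NAMES}
            for i in range(40):
                ds = ps.simulate_dataset([v, v], np.eye(2), n=2_000, maf=0.3,
                                         seed=60_000 + i)
                summary = ps.univariate_scan(ds)
                for name in ps.METHOD_NAMES:
                    pvals[name].append(ps.run_method(name, ds, summary=summary).pvalue)
            for name in ps.METHOD_NAMES:
                medians[name].append(np.median(pvals[name]))
        for name, med in medians.items():
            assert med[0] > med[1] > med[2], name

    def test_unknown_method_rejected(self, pair_dataset):
        with pytest.raises(ParameterError):
            ps.run_method("BIMBAM", pair_dataset)


class TestSummaryIO:
    def test_round_trip(self, tmp_path, pair_dataset):
        s = ps.univariate_scan(pair_dataset)
        path = tmp_path / "summary.tsv"
        write_summary(s, path)
        back = read_summary(path, s.trait_corr)
        assert np.allclose(back.z, s.z)
        assert np.allclose(back.p, s.p)
        assert ps.shom_test(back).pvalue == pytest.approx(ps.shom_test(s).pvalue)
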