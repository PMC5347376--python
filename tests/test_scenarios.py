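"""Scenario families S1-S4b: grids, sampling, effect-reflecting correlations."""

import numpy as np
import pandas as pd
import pytest

import pleiosim as ps
from pleiosim import MatrixStructureError, ParameterError
from pleiosim.fixtures import toy_beta_table
from pleiosim.scenarios import correlation_grid, write_beta_table


class TestEffectVectorLibrary:
    def test_two_trait_vectors(self):
        lib = ps.effect_vector_library(2)
        assert np.allclose(lib["v1"], [0.005, 0.005])
        # v2: 0.5% variance in trait 1 and 0.1% in trait 2
        assert np.allclose(lib["v2"], [0.005, 0.001])
        assert np.allclose(lib["v3"], [0.005, 0.0])

    def test_quarter_construction_k4(self):
        lib = ps.table2_vectors(4)
        assert np.allclose(lib["v1"], [0.005] * 4)
        assert np.allclose(lib["v10"], [0.005, 0.001, 0.0, 0.0])

    def test_quarter_construction_k8_v5(self):
        # for 8 traits v5 puts 0.5% on 6 traits and 0.1% on 2
        v5 = ps.table2_vectors(8)["v5"]
        assert (v5 == 0.005).sum() == 6
        assert (v5 == 0.001).sum() == 2

    def test_quarter_construction_k20_v8(self):
        # for 20 traits v8: 0.5% on 10, 0.1% on 5, no effect on 5
        v8 = ps.table2_vectors(20)["v8"]
        assert (v8 == 0.005).sum() == 10
        assert (v8 == 0.001).sum() == 5
        assert (v8 == 0.0).sum() == 5

    def test_k_not_divisible_by_four(self):
        with pytest.raises(ParameterError):
            ps.table2_vectors(6)


class TestS1Grid:
    def test_pair_grid_size(self):
        # 19 correlation points x 3 effect vectors
        points = ps.s1_grid(2)
        assert len(points) == 57
        assert len(correlation_grid()) == 19

    def test_k4_truncation(self):
        rs = sorted({pt.r for pt in ps.s1_grid(4)})
        assert min(rs) == pytest.approx(-0.3)
        assert max(rs) == pytest.approx(0.9)

    def test_all_points_positive_definite(self):
        for k in (2, 4, 8):
            assert all(ps.is_positive_definite(pt.c) for pt in ps.s1_grid(k))

    def test_bad_step(self):
        with pytest.raises(ParameterError):
            ps.s1_grid(2, step=0.0)


class TestS2Uniform:
    def test_pd_contract_and_effect_bounds(self):
        for k in (2, 3, 4, 5):
            v, c = ps.s2_sample(k, seed=k)
            assert ps.is_positive_definite(c)
            assert np.all((v >= 0) & (v <= 0.005))

    def test_mean_sampled_effect(self):
        # effects are uniform on [0, 0.5%] so the mean is 0.25%
        draws = np.array([ps.s2_sample(4, seed=1000 + i)[0] for i in range(500)])
        se = 0.005 / np.sqrt(12 * draws.size)
        assert draws.mean() == pytest.approx(0.0025, abs=3 * se)


class TestS3Reflection:
    @pytest.mark.parametrize("v, expected", [
        ((0.005, 0.005), 0.6),    # equal effects
        ((0.005, 0.001), 0.2),    # different nonzero effects
        ((0.005, 0.0), 0.05),     # only one trait affected
    ])
    def test_pairwise_rules(self, v, expected):
        c = ps.s3_correlations(v)
        assert c[0, 1] == pytest.approx(expected)

    def test_permutation_equivariance(self):
        v = np.array([0.005, 0.001, 0.0, 0.005])
        perm = np.array([2, 0, 3, 1])
        c = ps.s3_correlations(v)
        cp = ps.s3_correlations(v[perm])
        assert np.allclose(cp, c[np.ix_(perm, perm)])

    def test_non_pd_surfaces(self):
        # wildly non-PD hand-tuned parameters must raise, not be repaired
        with pytest.raises(MatrixStructureError):
            ps.s3_correlations([0.005, 0.001, 0.002], equal=0.9, different=-0.9,
                               single=0.9)


class TestS4aMixture:
    def test_pd_contract(self):
        mix = ps.CorrelationMixture(weights=(0.6, 0.4), means=(0.1, 0.4),
                                    sds=(0.1, 0.15))
        c = ps.s4a_sample(4, mix, seed=1)
        assert ps.is_positive_definite(c)

    def test_degenerate_mixture_gives_identity(self):
        mix = ps.CorrelationMixture(weights=(1.0,), means=(0.0,), sds=(1e-9,))
        c = ps.s4a_sample(3, mix, seed=2)
        assert np.allclose(c, np.eye(3), atol=1e-7)

    def test_sampled_density_matches_mixture(self):
        from scipy import stats

        mix = ps.CorrelationMixture(weights=(0.5, 0.5), means=(-0.2, 0.3),
                                    sds=(0.1, 0.1))
        rng = np.random.default_rng(3)
        draws = mix.sample(10_000, rng)
        cdf = lambda x: (0.5 * stats.norm.cdf(x, -0.2, 0.1)
                         + 0.5 * stats.norm.cdf(x, 0.3, 0.1))
        assert stats.kstest(draws, cdf).pvalue > 1e-4

    def test_invalid_weights(self):
        with pytest.raises(ParameterError):
            ps.CorrelationMixture(weights=(0.5, 0.4), means=(0, 0), sds=(1, 1))


class TestS4bTransform:
    def _table(self, rows, traits=("t1", "t2")):
        betas = pd.DataFrame(rows, columns=traits,
                             index=[f"rs{i}" for i in range(len(rows))])
        idx = pd.Series([traits[0]] * len(rows), index=betas.index)
        return ps.BetaTable(betas=betas, index_trait=idx)

    def test_max_effect_and_ratio_preserved(self):
        table = self._table([[0.3, 0.1]])
        eff = ps.s4b_transform(table, target_max_v=0.005, maf=0.3)
        assert eff.iloc[0, 0] == pytest.approx(0.005, abs=1e-12)
        b1 = ps.variance_to_coefficient(eff.iloc[0, 0], 0.3)
        b2 = ps.variance_to_coefficient(eff.iloc[0, 1], 0.3)
        assert b1 / b2 == pytest.approx(3.0, rel=1e-9)

    def test_single_nonzero_beta(self):
        eff = ps.s4b_transform(self._table([[0.0, 0.2]]), 0.005, 0.3)
        assert eff.iloc[0, 1] == pytest.approx(0.005, abs=1e-12)
        assert eff.iloc[0, 0] == 0.0

    def test_idempotent_on_own_output(self):
        table = self._table([[0.3, 0.1], [0.05, 0.2]])
        eff1 = ps.s4b_transform(table, 0.005, 0.3)
        scaled = table.betas.copy()
        for snp in scaled.index:
            scaled.loc[snp] = [
                np.sign(b) * ps.variance_to_coefficient(v, 0.3)
                for b, v in zip(table.betas.loc[snp], eff1.loc[snp])
            ]
        table2 = ps.BetaTable(betas=scaled, index_trait=table.index_trait)
        eff2 = ps.s4b_transform(table2, 0.005, 0.3)
        assert np.allclose(eff1.to_numpy(), eff2.to_numpy(), atol=1e-12)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ParameterError):
            self._table([[0.0, 0.0]])


class TestCapSnpsPerTrait:
    def test_cap_applies(self):
        rng = np.random.default_rng(0)
        betas = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"],
                             index=[f"rs{i}" for i in range(30)])
        table = ps.BetaTable(betas=betas,
                             index_trait=pd.Series(["a"] * 30, index=betas.index))
        capped = ps.cap_snps_per_trait(table, cap=20)
        assert len(capped) == 20
        # keeps the strongest index-trait coefficients
        kept = set(capped.betas.index)
        strongest = set(betas["a"].abs().sort_values(ascending=False).index[:20])
        assert kept == strongest

    def test_noop_below_cap(self):
        table = toy_beta_table(7)
        capped = ps.cap_snps_per_trait(table, cap=20)
        assert list(capped.betas.index) == list(table.betas.index)

    def test_row_count_identity(self):
        table = toy_beta_table(7, n_snps=40)
        cap = 2
        capped = ps.cap_snps_per_trait(table, cap=cap)
        expected = sum(min(cnt, cap) for cnt in table.index_trait.value_counts())
        assert len(capped) == expected


class TestSubsetsAndIO:
    def test_subset_counts(self):
        assert len(ps.enumerate_trait_subsets(12, 2)) == 66
        assert len(ps.enumerate_trait_subsets(12, 12)) == 1
        assert ps.enumerate_trait_subsets(4, 2) == [
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

    def test_beta_table_round_trip(self, tmp_path):
        table = toy_beta_table(7)
        path = tmp_path / "betas.tsv"
        write_beta_table(table, path)
        back = ps.read_beta_table(path)
        assert np.allclose(back.betas.to_numpy(), table.betas.to_numpy())
        assert list(back.index_trait) == list(table.index_trait)

    def test_bundled_table_loads(self):
        from pleiosim.fixtures import bundled_beta_table_path

        table = ps.read_beta_table(bundled_beta_table_path())
        assert len(table) == 20
        assert len(table.traits) == 12
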