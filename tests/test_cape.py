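import numpy as np
import pandas as pd
import pytest

import capescan as cs
from capescan import cape
from conftest import make_pair_fit


class TestEnumeratePairs:
    def test_small_counts(self, dominant_matrix):
        enum = cs.enumerate_pairs(dominant_matrix.marker_ids[:4],
                                  dominant_matrix, ld_max=1.0)
        assert enum.n_possible == 6
        assert len(enum.pairs) == 6

    def test_identical_columns_excluded(self):
        rng = np.random.default_rng(0)
        col = (rng.random(100) < 0.5).astype(float)
        other = (rng.random(100) < 0.5).astype(float)
        g = cs.GenotypeMatrix(np.column_stack([col, col, other]),
                              coding=cs.DOMINANT,
                              marker_ids=["a", "a_dup", "b"])
        enum = cs.enumerate_pairs(["a", "a_dup", "b"], g, ld_max=0.5)
        assert enum.n_possible == 3
        assert enum.n_excluded_ld >= 1
        assert ("a", "a_dup") not in enum.pair_ids

    def test_covariate_joins_pool(self, null_cohort):
        _, genotypes, traits = null_cohort
        g = cs.dominant_code(genotypes)
        enum = cs.enumerate_pairs(g.marker_ids, g,
                                  covariates=traits.covariates[["sex"]],
                                  ld_max=1.01)
        assert enum.n_possible == 51 * 50 // 2
        assert any("sex" in pair for pair in enum.pair_ids)


class TestScans:
    def test_singlescan_matches_closed_form(self, dominant_matrix):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(dominant_matrix.n_individuals)
        res = cs.singlescan(dominant_matrix, y)
        x = dominant_matrix.values[:, 0]
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.iloc[0]["beta"] == pytest.approx(slope, abs=1e-12)

    def test_singlescan_planted_effect_detected(self):
        rng = np.random.default_rng(2)
        x = (rng.random(416) < 0.4).astype(float)
        g = cs.GenotypeMatrix(x[:, None], coding=cs.DOMINANT,
                              marker_ids=["hit"])
        y = x + rng.standard_normal(416)
        res = cs.singlescan(g, y)
        assert res.iloc[0]["p"] < 1e-10

    def test_singlescan_monomorphic_not_estimable(self):
        g = cs.GenotypeMatrix(np.zeros((50, 1)), coding=cs.DOMINANT)
        res = cs.singlescan(g, np.random.default_rng(3).standard_normal(50))
        assert not res.iloc[0]["estimable"]

    def test_pairscan_noiseless_recovery(self):
        rng = np.random.default_rng(4)
        fit = make_pair_fit(rng, n=500, b_int=(0.7, -0.4),
                            mains=((1.0, 0.3), (0.2, 0.9)), noise_sd=0.0)
        assert fit.estimable
        np.testing.assert_allclose(fit.beta[0], [0, 1.0, 0.3, 0.7], atol=1e-8)
        np.testing.assert_allclose(fit.beta[1], [0, 0.2, 0.9, -0.4], atol=1e-8)

    def test_pairscan_with_sex_in_pair_has_no_duplicate_column(self):
        rng = np.random.default_rng(5)
        sex = (rng.random(300) < 0.1).astype(float)
        x = (rng.random(300) < 0.4).astype(float)
        y = rng.standard_normal((300, 2))
        # sex is a member of the pair: passing it again as covariate must
        # not create a rank-deficient double column
        fit = cs.pairscan(x, sex, y, markers=("snp", "sex"))
        assert fit.estimable

    def test_pairscan_insufficient_df_not_estimable(self):
        y = np.random.default_rng(6).standard_normal((5, 2))
        cov = pd.DataFrame({"sex": [0.0, 1, 0, 1, 0]})
        fit = cs.pairscan(np.array([0, 1, 0, 1, 1.0]),
                          np.array([0, 0, 1, 1, 1.0]), y, covariates=cov)
        assert not fit.estimable


class TestDeltaM:
    def test_identity_system_solves_directly(self):
        # M = I, interaction vector (0.2, -0.1): delta equals the vector,
        # verified by 2x2 inversion by hand
        beta = np.array([[0.0, 1.0, 0.0, 0.2], [0.0, 0.0, 1.0, -0.1]])
        fit = cape.PairScanFit("a", "b", beta, np.zeros((2, 4, 4)), 100, True)
        d = cs.solve_deltas(fit)
        assert d.delta1 == pytest.approx(0.2, abs=1e-12)
        assert d.delta2 == pytest.approx(-0.1, abs=1e-12)

    def test_zero_interactions_give_zero_deltas(self):
        beta = np.array([[0.0, 0.8, 0.1, 0.0], [0.0, 0.2, 0.9, 0.0]])
        fit = cape.PairScanFit("a", "b", beta, np.zeros((2, 4, 4)), 100, True)
        d = cs.solve_deltas(fit)
        assert d.delta1 == 0.0 and d.delta2 == 0.0

    def test_singular_main_effect_matrix_flagged(self):
        beta = np.array([[0.0, 1.0, 2.0, 0.3], [0.0, 0.5, 1.0, 0.1]])
        fit = cape.PairScanFit("a", "b", beta, np.zeros((2, 4, 4)), 100, True)
        d = cs.solve_deltas(fit)
        assert not d.estimable

    def test_m_closed_form(self):
        m = cs.compute_m(cape.DeltaPair(0.2, -0.1, np.zeros((2, 2)), True))
        assert m.m12 == pytest.approx(0.2 / 0.9, abs=1e-12)
        assert m.m21 == pytest.approx(-0.1 / 1.2, abs=1e-12)
        z = cs.compute_m(cape.DeltaPair(0.0, 0.0, np.zeros((2, 2)), True))
        assert z.m12 == 0.0 and z.m21 == 0.0

    def test_m_singular_denominator_flagged(self):
        m = cs.compute_m(cape.DeltaPair(0.5, -1.0, np.zeros((2, 2)), True))
        assert np.isnan(m.m12)
        assert np.isfinite(m.m21)

    def test_self_consistency_of_coupled_equations(self):
        rng = np.random.default_rng(7)
        theta = rng.standard_normal((5000, 6))
        deltas = cape._deltas_from_theta(theta)
        m = cape._m_from_deltas(deltas)
        ok = np.isfinite(deltas).all(axis=1) & np.isfinite(m).all(axis=1)
        d1, d2 = deltas[ok, 0], deltas[ok, 1]
        m12, m21 = m[ok, 0], m[ok, 1]
        assert np.max(np.abs(d1 - m12 * (1 + d2))) < 1e-10
        assert np.max(np.abs(d2 - m21 * (1 + d1))) < 1e-10

    def test_swap_relabels_deltas_and_m(self):
        rng = np.random.default_rng(8)
        fit = make_pair_fit(rng, n=800)
        swapped = cape.PairScanFit(
            fit.marker2, fit.marker1,
            fit.beta[:, [0, 2, 1, 3]],
            fit.cov[:, [0, 2, 1, 3]][:, :, [0, 2, 1, 3]],
            fit.n, fit.estimable)
        d = cs.solve_deltas(fit)
        ds = cs.solve_deltas(swapped)
        assert d.delta1 == pytest.approx(ds.delta2, abs=1e-12)
        assert d.delta2 == pytest.approx(ds.delta1, abs=1e-12)
        m, ms = cs.compute_m(d), cs.compute_m(ds)
        assert m.m12 == pytest.approx(ms.m21, abs=1e-12)


class TestErrorPropagation:
    def test_zero_covariance_gives_zero_se(self):
        beta = np.array([[0.0, 1.0, 0.2, 0.3], [0.0, 0.2, 1.0, -0.2]])
        fit = cape.PairScanFit("a", "b", beta, np.zeros((2, 4, 4)), 100, True)
        se = cs.propagate_errors(fit, cs.solve_deltas(fit))
        assert se[0] == pytest.approx(0.0, abs=1e-12)
        assert se[1] == pytest.approx(0.0, abs=1e-12)

    def test_non_psd_covariance_rejected(self):
        beta = np.array([[0.0, 1.0, 0.2, 0.3], [0.0, 0.2, 1.0, -0.2]])
        cov = np.zeros((2, 4, 4))
        cov[0] = -np.eye(4)
        fit = cape.PairScanFit("a", "b", beta, cov, 100, True)
        with pytest.raises(ValueError, match="positive semidefinite"):
            cs.propagate_errors(fit, cape.DeltaPair(0.1, 0.1,
                                                    np.zeros((2, 2)), True))

    def test_se_scales_with_noise(self):
        # doubling the residual SD doubles SE(m) in the linear regime
        ses = []
        for sd in (1.0, 2.0):
            rng = np.random.default_rng(9)
            acc = []
            for _ in range(100):
                fit = make_pair_fit(rng, n=2000, b_int=(0.3, -0.2),
                                    mains=((2.0, 0.4), (0.4, 2.0)),
                                    noise_sd=sd)
                acc.append(cs.propagate_errors(fit, cs.solve_deltas(fit)))
            ses.append(np.nanmean(acc, axis=0))
        ratio = ses[1] / ses[0]
        assert np.all(np.abs(ratio - 2.0) < 0.3)

    def test_planted_direction_dominates(self):
        # one-directional planted influence: the suppressed marker's
        # direction carries the larger |standardized m| in >= 90% of
        # replicates
        rng = np.random.default_rng(10)
        wins = 0
        for _ in range(20):
            n = 1000
            x1 = (rng.random(n) < 0.45).astype(float)
            x2 = (rng.random(n) < 0.45).astype(float)
            et1 = 0.3 * x1 + 1.0 * x2 - 0.75 * x1 * x2 \
                + rng.standard_normal(n)
            et2 = 1.0 * x1 + 0.3 * x2 - 0.225 * x1 * x2 \
                + rng.standard_normal(n)
            fit = cs.pairscan(x1, x2, np.column_stack([et1, et2]))
            res = cape.influence_batch(fit.beta[None], fit.cov[None],
                                       np.array([True]))
            s = np.abs(res["stat"][0])
            wins += s[1] > s[0]
        assert wins >= 18
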