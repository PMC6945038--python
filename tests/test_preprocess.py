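import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import capescan as cs


class TestMafFilter:
    def test_threshold_boundary_kept(self):
        rng = np.random.default_rng(0)
        mafs = np.array([0.05, 0.10, 0.25])
        values = rng.binomial(2, mafs[None, :], size=(4000, 3)).astype(float)
        g = cs.GenotypeMatrix(values, coding=cs.DOSAGE,
                              marker_ids=["lo", "edge", "hi"])
        # force exact empirical frequencies for determinism at the boundary
        g.values[:, 1] = 0
        g.values[: int(0.10 * 2 * 4000), 1] = 1  # allele freq exactly 0.10
        kept = cs.maf_filter(g, 0.1)
        assert list(kept.marker_ids) == ["edge", "hi"]

    def test_zero_threshold_drops_monomorphic_only(self):
        values = np.array([[0, 1, 2], [0, 1, 0], [0, 0, 1]], dtype=float)
        g = cs.GenotypeMatrix(values, marker_ids=["mono", "a", "b"])
        kept = cs.maf_filter(g, 0.0)
        assert list(kept.marker_ids) == ["a", "b"]

    def test_against_allele_counting_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 3, size=(80, 50)).astype(float)
        g = cs.GenotypeMatrix(values)
        kept = set(cs.maf_filter(g, 0.3).marker_ids)
        expected = set()
        for j in range(50):
            count1 = sum(values[:, j])          # allele-1 copies
            f = count1 / (2 * 80)
            if min(f, 1 - f) >= 0.3:
                expected.add(g.marker_ids[j])
        assert kept == expected

    def test_missingness_policy(self):
        values = np.full((100, 2), 1.0)
        values[:10, 0] = np.nan
        g = cs.GenotypeMatrix(values, marker_ids=["gappy", "full"])
        kept = cs.maf_filter(g, 0.0, max_missing=0.05)
        assert list(kept.marker_ids) == ["full"]
        with pytest.raises(ValueError, match="gappy"):
            cs.maf_filter(g, 0.0, max_missing=0.05, drop_high_missing=False)


class TestDominantCoding:
    def test_quoted_coding_rule(self):
        # dosages (0,1,2,0) with allele 1 minor -> (0,1,1,0)
        col = np.array([[0.0], [1.0], [2.0], [0.0]])
        g = cs.GenotypeMatrix(np.hstack([col, np.zeros((4, 1))]))
        coded = cs.dominant_code(g)
        np.testing.assert_array_equal(coded.values[:, 0], [0, 1, 1, 0])
        assert coded.coding == cs.DOMINANT

    def test_homozygous_major_column_all_zero(self):
        # allele 1 is the major allele here, so dosage 2 is homozygous major
        values = np.array([[2.0], [2.0], [2.0], [1.0]])
        coded = cs.dominant_code(cs.GenotypeMatrix(values))
        np.testing.assert_array_equal(coded.values[:, 0], [0, 0, 0, 1])

    def test_idempotent_with_warning(self, dominant_matrix):
        with pytest.warns(UserWarning, match="already dominant"):
            again = cs.dominant_code(dominant_matrix)
        np.testing.assert_array_equal(again.values, dominant_matrix.values)

    def test_commutes_with_maf_filter(self):
        rng = np.random.default_rng(2)
        values = rng.binomial(2, rng.uniform(0.05, 0.5, 30)[None, :],
                              size=(500, 30)).astype(float)
        g = cs.GenotypeMatrix(values)
        a = cs.dominant_code(cs.maf_filter(g, 0.1))
        b = cs.dominant_code(g).select_markers(
            np.flatnonzero(cs.compute_maf(g) >= 0.1))
        np.testing.assert_array_equal(a.values, b.values)


class TestRankZ:
    def test_moments_near_standard_normal(self):
        rng = np.random.default_rng(3)
        z = cs.rank_z(rng.standard_normal(1000))
        assert abs(z.mean()) < 0.05
        assert abs(z.std(ddof=1) - 1) < 0.05

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=60,
                    unique=True))
    def test_order_preserving(self, values):
        x = np.asarray(values)
        z = cs.rank_z(x)
        order = np.argsort(x)
        assert np.all(np.diff(z[order]) > 0)

    @given(st.lists(st.integers(-10_000, 10_000), min_size=5, max_size=40,
                    unique=True))
    def test_invariant_under_monotone_transform(self, values):
        # spacing >= 1e-2 keeps exp() from collapsing distinct inputs
        x = np.asarray(values, dtype=float) / 100.0
        np.testing.assert_allclose(cs.rank_z(x), cs.rank_z(np.exp(x / 100)),
                                   atol=1e-12)

    def test_ties_share_output(self):
        z = cs.rank_z([1.0, 2.0, 2.0, 3.0])
        assert z[1] == z[2]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            cs.rank_z([1.0, 2.0])
        with pytest.raises(ValueError, match="all-equal"):
            cs.rank_z([5.0, 5.0, 5.0, 5.0])

    def test_blom_offset_available(self):
        x = np.arange(10.0)
        assert not np.allclose(cs.rank_z(x), cs.rank_z(x, offset="blom"))


def _table(frame, kinds, covariates=None):
    return cs.TraitTable(frame, kinds=kinds, covariates=covariates)


class TestTraitAssociations:
    def test_pooled_t_matches_hand_computation(self):
        # groups (1,2,3) vs (2,4,6): pooled variance 2.5,
        # t = -2 / sqrt(2.5 * (1/3 + 1/3)) = -2 sqrt(3/5)
        frame = pd.DataFrame({"flag": [1, 1, 1, 0, 0, 0],
                              "y": [1.0, 2.0, 3.0, 2.0, 4.0, 6.0]})
        t = _table(frame, {"flag": cs.BINARY, "y": cs.QUANTITATIVE})
        res = cs.trait_association_tests(t)
        row = res.t_tests.iloc[0]
        assert row["t"] == pytest.approx(-2.0 * np.sqrt(3.0 / 5.0), abs=1e-12)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(400):
            frame = pd.DataFrame({"flag": rng.integers(0, 2, 40).astype(float),
                                  "y": rng.standard_normal(40)})
            t = _table(frame, {"flag": cs.BINARY, "y": cs.QUANTITATIVE})
            row = cs.trait_association_tests(t).t_tests.iloc[0]
            if row["estimable"]:
                pvals.append(row["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.standard_normal(50),
                            rng.standard_normal(50) + 5.0])
        frame = pd.DataFrame({"flag": np.repeat([0.0, 1.0], 50), "y": y})
        t = _table(frame, {"flag": cs.BINARY, "y": cs.QUANTITATIVE})
        assert cs.trait_association_tests(t).t_tests.iloc[0]["p"] < 1e-10

    def test_crossing_interaction_detected(self):
        # effect of f1 is +1 SD when f2=0 and -1 SD when f2=1
        rng = np.random.default_rng(6)
        f1 = rng.integers(0, 2, 400).astype(float)
        f2 = rng.integers(0, 2, 400).astype(float)
        y = f1 - 2.0 * f1 * f2 + rng.standard_normal(400)
        frame = pd.DataFrame({"f1": f1, "f2": f2, "y": y})
        t = _table(frame, {"f1": cs.BINARY, "f2": cs.BINARY,
                           "y": cs.QUANTITATIVE})
        res = cs.trait_association_tests(t)
        assert res.interactions.iloc[0]["p_interaction"] < 0.05

    def test_tiny_group_not_estimable(self):
        frame = pd.DataFrame({"flag": [1.0, 0, 0, 0, 0, 0],
                              "y": [1.0, 2, 3, 4, 5, 6]})
        t = _table(frame, {"flag": cs.BINARY, "y": cs.QUANTITATIVE})
        assert not cs.trait_association_tests(t).t_tests.iloc[0]["estimable"]

    def test_sex_covariate_used_as_factor(self, null_cohort):
        _, _, traits = null_cohort
        res = cs.trait_association_tests(traits)
        assert "sex" in set(res.t_tests["factor"])


class TestQQInflation:
    def test_null_lambda_near_one(self):
        rng = np.random.default_rng(7)
        diag = cs.qq_inflation(rng.uniform(size=100_000))
        assert 0.97 <= diag.lambda_gc <= 1.03

    def test_constructed_inflation_recovered(self):
        rng = np.random.default_rng(8)
        chi2 = 1.3 * rng.chisquare(1, size=100_000)
        diag = cs.qq_inflation(stats.chi2.sf(chi2, 1))
        assert abs(diag.lambda_gc - 1.3) < 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            cs.qq_inflation([])
        with pytest.raises(ValueError, match="0, 1"):
            cs.qq_inflation([0.5, 0.0])
        with pytest.raises(ValueError, match="0, 1"):
            cs.qq_inflation([0.5, 1.5])
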