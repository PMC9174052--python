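"""Cross-participant statistics: preprocessing, Pearson scan, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qsmpipe import (
    ParameterError,
    group_difference_map,
    pearson_assoc,
    phenome_scan,
    preprocess_idp_vector,
    regress_confounds,
    significance_thresholds,
    voxelwise_assoc,
)


class TestPreprocess:
    def test_zero_mad_skips_outlier_step(self):
        x = np.zeros(100)
        x[-1] = 10.0
        with pytest.warns(UserWarning):
            out = preprocess_idp_vector(x)
        assert np.isfinite(out).all()  # nothing removed

    def test_ten_mad_outlier_removed_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        x2 = np.append(x, med + 10 * mad)
        out = preprocess_idp_vector(x2)
        assert np.isnan(out[-1])
        assert np.isfinite(out[:-1]).all()

    def test_output_is_permutation_of_normal_quantiles(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=57)  # distinct, no 6xMAD outliers possible
        out = preprocess_idp_vector(x)
        m = len(x)
        q = stats.norm.ppf((np.arange(1, m + 1) - 0.5) / m)
        q = (q - q.mean()) / q.std()
        np.testing.assert_allclose(np.sort(out), q, atol=1e-10)
        assert abs(out.mean()) < 1e-10
        # rank-based: any monotone rescaling of the input gives the same output
        out2 = preprocess_idp_vector(1000.0 + 3.0 * x)
        np.testing.assert_allclose(out, out2, atol=1e-12)

    def test_gaussian_moments(self):
        rng = np.random.default_rng(2)
        for m in (100, 500):
            out = preprocess_idp_vector(rng.exponential(size=m))
            v = out[np.isfinite(out)]
            assert abs(v.mean()) < 1e-10
            assert abs(v.std() - 1.0) < 1e-3


class TestRegressConfounds:
    def test_exact_linear_gives_zero(self):
        rng = np.random.default_rng(3)
        C = rng.normal(size=(50, 3))
        Y = C @ np.array([1.0, -2.0, 0.5]) + 4.0
        res = regress_confounds(Y, C)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_intercept_only_centers(self):
        y = np.arange(20.0)
        res = regress_confounds(y, np.ones((20, 0)))
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-10)

    def test_residuals_orthogonal(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(200, 4))
        C = rng.normal(size=(200, 3))
        res = regress_confounds(Y, C)
        for j in range(4):
            for k in range(3):
                assert abs(np.corrcoef(res[:, j], C[:, k])[0, 1]) < 1e-8

    def test_rank_deficient_confounds_warn(self):
        rng = np.random.default_rng(5)
        C = rng.normal(size=(30, 2))
        C = np.column_stack([C, C[:, 0] * 2.0])
        with pytest.warns(UserWarning):
            res = regress_confounds(rng.normal(size=30), C)
        assert np.isfinite(res).all()


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r = pearson_assoc(x, x)
        assert r.r == pytest.approx(1.0)
        assert r.p > 0 and np.isfinite(r.neglog10p)

    def test_orthogonalized_vectors_r_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        y = y - x * (x @ y) / (x @ x)
        x, y = x - x.mean(), y - y.mean()
        y = y - x * (x @ y) / (x @ x)
        res = pearson_assoc(x, y)
        assert abs(res.r) < 1e-10
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_five_point_oracle(self):
        # frozen from direct computation: r = 10/sqrt(148), two-sided t-test
        res = pearson_assoc([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert res.r == pytest.approx(10.0 / np.sqrt(148.0), abs=1e-12)
        assert res.p == pytest.approx(0.08770664700806553, abs=1e-10)
        assert res.n == 5

    def test_pairwise_complete_and_zero_variance(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6])
        y = np.array([2.0, 4, 6, 8, np.nan, 12])
        res = pearson_assoc(x, y)
        assert res.n == 4
        assert pearson_assoc(np.ones(10), np.arange(10.0)) is None

    def test_type_one_error_control(self):
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(1000):
            x = rng.standard_normal(500)
            y = rng.standard_normal(500)
            if pearson_assoc(x, y).p < 0.05:
                hits += 1
        assert 0.035 <= hits / 1000 <= 0.065


class TestThresholds:
    def test_phenome_bonferroni(self):
        t = significance_thresholds(alpha=0.05, m_tests=629_460)
        assert round(t.bonferroni_neglog10, 2) == 7.10

    def test_gwas_bonferroni(self):
        t = significance_thresholds(m_tests=1, n_gwas=36)
        assert round(t.gwas_neglog10, 2) == 9.06

    def test_single_test(self):
        t = significance_thresholds(alpha=0.05, m_tests=1)
        assert t.bonferroni_neglog10 == pytest.approx(-np.log10(0.05), abs=1e-9)

    def test_bonferroni_monotone_in_m(self):
        ts = [significance_thresholds(m_tests=m).bonferroni_neglog10
              for m in (10, 1000, 10**6)]
        assert ts[0] < ts[1] < ts[2]

    def test_bh_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        t = significance_thresholds(m_tests=4, p_values=p, fdr_q=0.05)
        np.testing.assert_array_equal(t.fdr_reject, [True, True, True, False])
        assert t.fdr_neglog10 == pytest.approx(-np.log10(0.03))

    def test_bh_rejects_superset_of_bonferroni(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(1e-6, 1e-3, 20), rng.uniform(0, 1, 200)])
        t = significance_thresholds(alpha=0.05, m_tests=len(p), p_values=p, fdr_q=0.05)
        bonf = p < 0.05 / len(p)
        assert np.all(t.fdr_reject[bonf])


class TestPhenomeScan:
    def test_min_n_and_planted_effect(self):
        rng = np.random.default_rng(8)
        n = 120
        idps = pd.DataFrame({"idp_a": rng.normal(size=n)},
                            index=[f"s{i}" for i in range(n)])
        phen = pd.DataFrame(
            {
                "linked": idps["idp_a"] * 0.8 + rng.normal(scale=0.5, size=n),
                "noise": rng.normal(size=n),
                "sparse": np.where(np.arange(n) < 30, rng.normal(size=n), np.nan),
            },
            index=idps.index,
        )
        res = phenome_scan(idps, phen, min_n=40)
        assert set(res["phenotype"]) == {"linked", "noise"}  # sparse dropped
        linked = res[res["phenotype"] == "linked"].iloc[0]
        noise = res[res["phenotype"] == "noise"].iloc[0]
        assert linked["r"] > 0.6 and linked["neglog10p"] > 7
        assert abs(noise["r"]) < 0.3

    def test_affine_invariance_of_pipeline(self):
        rng = np.random.default_rng(9)
        n = 80
        idps = pd.DataFrame({"a": rng.gamma(2, size=n)}, index=range(n))
        phen = pd.DataFrame({"p": rng.normal(size=n)}, index=range(n))
        conf = pd.DataFrame({"c": rng.normal(size=n)}, index=range(n))
        r1 = phenome_scan(idps, phen, conf)
        r2 = phenome_scan(idps * 13.0 + 5.0, phen, conf)
        assert r1.loc[0, "r"] == pytest.approx(r2.loc[0, "r"], abs=1e-12)


class TestVoxelwiseAndGroupMaps:
    def test_identical_vector_gives_r_one(self):
        rng = np.random.default_rng(10)
        n = 60
        chi = rng.normal(size=(3, 3, 2, n))
        ph = preprocess_idp_vector(chi[1, 1, 1].copy())
        rmap = voxelwise_assoc(chi, ph)
        assert rmap[1, 1, 1] == pytest.approx(1.0, abs=1e-9)

    def test_permuted_phenotype_consistent_with_null(self):
        rng = np.random.default_rng(11)
        n = 100
        chi = rng.normal(size=(4, 4, 3, n))
        ph = rng.permutation(chi[0, 0, 0])
        rmap = voxelwise_assoc(chi, ph)
        assert np.nanmax(np.abs(rmap[1:])) < 4.0 / np.sqrt(n)

    def test_planted_effect_localizes(self):
        rng = np.random.default_rng(12)
        n = 80
        chi = rng.normal(size=(6, 6, 4, n))
        ph = rng.normal(size=n)
        roi = np.zeros((6, 6, 4), bool)
        roi[1:3, 1:3, 1:3] = True
        chi[roi] += 2.0 * ph
        rmap = voxelwise_assoc(chi, ph)
        flat = np.abs(rmap).ravel()
        top = np.argsort(flat)[-max(1, flat.size // 100 * 1):]
        top_k = np.argsort(flat)[-roi.sum():]
        in_roi = roi.ravel()[top_k].mean()
        assert in_roi >= 0.9

    def test_group_difference(self):
        rng = np.random.default_rng(13)
        chi = rng.normal(size=(4, 4, 2, 30))
        # duplicated groups -> zero map
        chi2 = np.concatenate([chi, chi], axis=-1)
        d = group_difference_map(chi2, np.arange(30), np.arange(30, 60))
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        # constant offset added to group A appears in the map
        chi2[..., :30] += 5.0
        d2 = group_difference_map(chi2, np.arange(30), np.arange(30, 60))
        np.testing.assert_allclose(d2, 5.0, atol=1e-12)
        with pytest.raises(ParameterError):
            group_difference_map(chi2, np.arange(5), np.arange(3, 8))

    def test_planted_aging_contrast_sign(self):
        rng = np.random.default_rng(14)
        n = 40
        base = rng.normal(size=(5, 5, 3))
        ages = np.linspace(48, 80, n)
        chi = np.stack([base + 0.5 * (a - 60) + rng.normal(scale=2.0, size=base.shape)
                        for a in ages], axis=-1)
        old = np.where(ages > 75)[0]
        young = np.where(ages < 52)[0]
        d = group_difference_map(chi, old, young)
        assert (d > 0).mean() >= 0.95
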