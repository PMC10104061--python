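"""Normalisation chain and exon-level effect estimation."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from qtlcanvas.coords import GenomicInterval
from qtlcanvas.traits import (
    TraitError,
    TraitMatrix,
    bh_fdr,
    effects_to_frame,
    exon_effects,
    inverse_normal,
    regress_out_covariates,
    usage_matrix,
)


def _iv(i):
    return GenomicInterval("chr1", 100 * i, 100 * i + 50)


class TestUsageMatrix:
    def test_divides_by_group_total(self):
        tm = TraitMatrix(
            ["t1", "t2", "t3"], ["s1"], np.array([[2.0], [3.0], [5.0]]),
            {"t1": "g", "t2": "g", "t3": "g"},
        )
        out = usage_matrix(tm)
        assert out.values[:, 0].tolist() == [0.2, 0.3, 0.5]

    def test_single_trait_group_is_one(self):
        tm = TraitMatrix(["t"], ["s1", "s2"], np.array([[4.0, 7.0]]), {"t": "g"})
        assert usage_matrix(tm).values.tolist() == [[1.0, 1.0]]

    def test_zero_sum_group_gives_missing(self):
        tm = TraitMatrix(
            ["t1", "t2"], ["s1", "s2"], np.array([[0.0, 1.0], [0.0, 3.0]]),
            {"t1": "g", "t2": "g"},
        )
        out = usage_matrix(tm)
        assert np.isnan(out.values[:, 0]).all()
        assert out.values[:, 1].tolist() == [0.25, 0.75]

    def test_group_sums_equal_one(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2, 1, (12, 6))
        tm = TraitMatrix(
            [f"t{i}" for i in range(12)], [f"s{j}" for j in range(6)], vals,
            {f"t{i}": f"g{i % 3}" for i in range(12)},
        )
        out = usage_matrix(tm)
        for g in range(3):
            rows = [i for i in range(12) if i % 3 == g]
            assert np.allclose(out.values[rows].sum(axis=0), 1.0, atol=1e-12)


class TestInverseNormal:
    def test_three_value_quantiles(self):
        out = inverse_normal(np.array([5.0, 1.0, 9.0]))
        assert out == pytest.approx([0.0, -0.9674, 0.9674], abs=1e-4)

    def test_constant_input_all_zero(self):
        assert np.allclose(inverse_normal(np.full(5, 3.3)), 0.0)

    def test_missing_preserved_and_excluded_from_n(self):
        out = inverse_normal(np.array([1.0, np.nan, 2.0]))
        assert np.isnan(out[1])
        # n=2: quantiles at 0.25 and 0.75
        assert out[[0, 2]] == pytest.approx(stats.norm.ppf([0.25, 0.75]))

    def test_monotone_in_monotone_out(self):
        x = np.array([0.1, 5.0, 2.0, 7.0])
        out = inverse_normal(x)
        assert (np.argsort(out) == np.argsort(x)).all()

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 5000))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        assert np.allclose(inverse_normal(x), inverse_normal(np.exp(x) + 7))


class TestRegressOutCovariates:
    def test_intercept_only_centres(self):
        y = np.array([[1.0, 2.0, 3.0]])
        out = regress_out_covariates(y, None)
        assert np.allclose(out, [[-1, 0, 1]])

    def test_exact_linear_gives_zero_residuals(self):
        c = np.arange(10.0)
        y = (2 + 3 * c)[None, :]
        assert np.allclose(regress_out_covariates(y, c[:, None]), 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(5, 50))
        c = rng.normal(size=(50, 3))
        res = regress_out_covariates(y, c)
        corr = np.corrcoef(np.vstack([res, c.T]))[:5, 5:]
        assert np.abs(corr).max() < 1e-8

    def test_collinear_design_rejected(self):
        c = np.ones((10, 2))
        with pytest.raises(TraitError):
            regress_out_covariates(np.random.default_rng(0).normal(size=(1, 10)), c)


class TestExonEffects:
    def test_noise_free_recovers_beta_exactly(self):
        d = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        y = (0.5 * d)[None, :]
        eff = exon_effects(y, ["e1"], [_iv(0)], d, pre_transform=False)[0]
        assert eff.beta == pytest.approx(0.5, abs=1e-12)
        assert eff.se == pytest.approx(0.0, abs=1e-10)
        assert eff.ci_low <= eff.beta <= eff.ci_high

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        n = 80
        d = rng.choice([0, 1, 2], n).astype(float)
        covs = rng.normal(size=(n, 2))
        y = 0.4 * d + covs @ [0.3, -0.2] + rng.normal(size=n)
        eff = exon_effects(y[None, :], ["e1"], [_iv(0)], d, covs,
                           pre_transform=False)[0]
        X = sm.add_constant(np.column_stack([d, covs]))
        fit = sm.OLS(y, X).fit()
        assert eff.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert eff.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert eff.p == pytest.approx(fit.pvalues[1], abs=1e-10)
        lo, hi = fit.conf_int()[1]
        assert (eff.ci_low, eff.ci_high) == pytest.approx((lo, hi), abs=1e-10)

    def test_monomorphic_variant_rejected(self):
        with pytest.raises(TraitError, match="monomorphic"):
            exon_effects(np.zeros((1, 5)), ["e"], [_iv(0)], np.ones(5))

    def test_null_type_one_error_calibrated(self):
        """Null rejection rate at |t| > t_crit(0.05) is 0.05 +/- 0.02."""
        rng = np.random.default_rng(42)
        n, n_exons = 200, 1000
        d = rng.choice([0, 1, 2], n, p=[0.49, 0.42, 0.09]).astype(float)
        y = rng.normal(size=(n_exons, n))
        effs = exon_effects(y, [f"e{i}" for i in range(n_exons)],
                            [_iv(i) for i in range(n_exons)], d)
        frac = np.mean([e.p < 0.05 for e in effs])
        assert abs(frac - 0.05) <= 0.02

    def test_effects_frame_columns(self):
        d = np.array([0.0, 1.0, 2.0, 1.0])
        effs = exon_effects((0.3 * d)[None, :], ["e1"], [_iv(0)], d,
                            pre_transform=False)
        df = effects_to_frame(effs)
        assert list(df.columns) == [
            "exon_id", "chrom", "start", "end", "beta", "se",
            "ci_low", "ci_high", "p", "q", "significant",
        ]


def brute_force_bh(p):
    """Step-up enumeration: q_i = min over j with p_(j) >= p_(i) of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return np.minimum(q, 1.0)


class TestBhFdr:
    def test_hand_example(self):
        assert bh_fdr(np.array([0.01, 0.02, 0.03])) == pytest.approx([0.03] * 3)

    def test_degenerate_cases(self):
        assert bh_fdr(np.array([1.0, 1.0])).tolist() == [1.0, 1.0]
        assert bh_fdr(np.array([0.2])).tolist() == [0.2]

    def test_rejects_out_of_range(self):
        with pytest.raises(TraitError):
            bh_fdr(np.array([0.5, 1.5]))

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 100_000), m=st.integers(1, 12))
    def test_agrees_with_brute_force(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m)
        assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)
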