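"""Unit and property tests for the region-level test statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gcalpha.stats import (
    BinomialSite,
    EffectEstimate,
    binomial_calpha,
    binomial_variance_term,
    burden_scores,
    burden_test,
    gaussian_calpha,
    gaussian_calpha_from_summary,
)
from conftest import make_region


def _effects(betas, ses):
    return [
        EffectEstimate(f"v{i}", float(b), float(s))
        for i, (b, s) in enumerate(zip(betas, ses))
    ]


class TestGaussianCalpha:
    @pytest.mark.parametrize(
        "betas, ses, S, c, z",
        [
            ((2.0, -2.0), (1.0, 1.0), 6.0, 4.0, 3.0),
            ((0.0,) * 10, (1.0,) * 10, -10.0, 20.0, -10.0 / np.sqrt(20.0)),
        ],
    )
    def test_closed_form(self, betas, ses, S, c, z):
        res = gaussian_calpha(_effects(betas, ses))
        assert res.S == pytest.approx(S)
        assert res.c == pytest.approx(c)
        assert res.z == pytest.approx(z)
        assert res.p_asymptotic == pytest.approx(sps.norm.sf(z))

    def test_error_paths(self):
        with pytest.raises(ValueError, match="no variants"):
            gaussian_calpha([])
        with pytest.raises(ValueError, match="v1"):
            gaussian_calpha(
                [EffectEstimate("v0", 1, 1), EffectEstimate("v1", 1, 0)]
            )
        with pytest.raises(ValueError, match="non-converged.*vbad"):
            gaussian_calpha([EffectEstimate("vbad", 1, 1, converged=False)])

    @given(
        t=st.floats(0.1, 10.0),
        betas=st.lists(st.floats(-3, 3), min_size=2, max_size=8),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_equivariance(self, t, betas):
        """z is invariant when all betas and ses scale by a common t > 0."""
        ses = [0.5 + 0.1 * i for i in range(len(betas))]
        base = gaussian_calpha(_effects(betas, ses))
        scaled = gaussian_calpha(
            _effects([t * b for b in betas], [t * s for s in ses])
        )
        assert scaled.z == pytest.approx(base.z, rel=1e-9)
        assert scaled.S == pytest.approx(t**2 * base.S, rel=1e-9)
        assert scaled.c == pytest.approx(t**4 * base.c, rel=1e-9)

    def test_variant_order_invariance(self, rng):
        betas, ses = rng.normal(size=9), rng.uniform(0.2, 1.0, size=9)
        a = gaussian_calpha(_effects(betas, ses))
        order = rng.permutation(9)
        b = gaussian_calpha(_effects(betas[order], ses[order]))
        assert b.z == pytest.approx(a.z)

    def test_null_moments_monte_carlo(self, rng):
        """Under beta_k ~ N(0, se_k^2), z has mean ~0 and variance ~1."""
        K, draws = 50, 100_000
        se = rng.uniform(0.1, 1.0, size=K)
        betas = rng.normal(0.0, se, size=(draws, K))
        S = np.sum(betas**2 - se**2, axis=1)
        c = 2.0 * np.sum(se**4)
        z = S / np.sqrt(c)
        # spot-check the vectorized oracle against the API on one draw
        api = gaussian_calpha(_effects(betas[0], se))
        assert api.z == pytest.approx(z[0], rel=1e-10)
        assert abs(z.mean()) < 0.02
        assert abs(z.var() - 1.0) < 0.05

    def test_mixture_inflates_statistic(self, rng):
        """Bi-directional effects drive S positive, increasingly so in delta."""
        K, draws, se = 40, 4000, 0.3
        mean_S = []
        for delta in (0.0, 0.3, 0.6):
            signs = rng.choice([-1.0, 1.0], size=(draws, K))
            betas = rng.normal(delta * signs, se)
            mean_S.append(np.mean(np.sum(betas**2 - se**2, axis=1)))
        assert mean_S[0] == pytest.approx(0.0, abs=0.5)
        assert mean_S[0] < mean_S[1] < mean_S[2]


class TestSummaryMode:
    def test_two_variant_table(self):
        tab = pd.DataFrame(
            {"variant_id": ["a", "b"], "beta": [2.0, -2.0], "se": [1.0, 1.0]}
        )
        res = gaussian_calpha_from_summary(tab)
        assert res.z == pytest.approx(3.0)
        assert res.p_asymptotic == pytest.approx(0.00135, abs=5e-6)
        assert res.uncalibrated
        assert res.p_permutation is None

    def test_single_null_row_boundary(self):
        tab = pd.DataFrame({"variant_id": ["a"], "beta": [1.0], "se": [1.0]})
        res = gaussian_calpha_from_summary(tab)
        assert res.S == pytest.approx(0.0)
        assert res.z == pytest.approx(0.0)
        assert res.p_asymptotic == pytest.approx(0.5)

    def test_bad_rows_reported(self):
        tab = pd.DataFrame(
            {"variant_id": list("abc"), "beta": [1.0, np.nan, 2.0], "se": [1, 1, -1]}
        )
        with pytest.raises(ValueError, match=r"rows \[1, 2\]"):
            gaussian_calpha_from_summary(tab)

    def test_null_normality_improves_with_k(self, rng):
        """The null z approaches N(0,1) as K grows: KS distance shrinks.

        At small K the statistic inherits visible chi-square skewness
        (which is why permutation calibration exists); the distance to the
        standard normal must decrease monotonically over K = 10, 50, 200.
        """
        draws = 4000
        dists = []
        for K in (10, 50, 200):
            se = rng.uniform(0.1, 1.0, size=K)
            betas = rng.normal(0.0, se, size=(draws, K))
            z = np.sum(betas**2 - se**2, axis=1) / np.sqrt(2 * np.sum(se**4))
            dists.append(sps.kstest(z, "norm").statistic)
        assert dists[0] > dists[1] > dists[2]
        assert dists[2] < 0.03


class TestBinomialCalpha:
    def test_single_site_enumeration(self):
        res = binomial_calpha([BinomialSite(2, 2)], p0=0.5)
        assert res.S == pytest.approx(0.5)
        assert res.c == pytest.approx(0.25)
        assert res.z == pytest.approx(1.0)

    def test_observed_at_expectation(self):
        res = binomial_calpha([BinomialSite(2, 4), BinomialSite(2, 2)], p0=0.5)
        # first site contributes (2-2)^2 - 1 = -1
        site1 = (2 - 4 * 0.5) ** 2 - 4 * 0.5 * 0.5
        assert site1 == pytest.approx(-1.0)

    def test_singletons_uninformative(self):
        assert binomial_variance_term(1, 0.5) == pytest.approx(0.0, abs=1e-15)
        with pytest.raises(ValueError, match="degenerate"):
            binomial_calpha([BinomialSite(1, 1), BinomialSite(0, 1)], p0=0.5)

    def test_p0_bounds(self):
        with pytest.raises(ValueError):
            binomial_calpha([BinomialSite(1, 2)], p0=0.0)

    @pytest.mark.parametrize("p0", [0.1, 0.3, 0.5, 0.77])
    def test_variance_term_matches_central_moments(self, p0):
        """Enumeration equals mu4 - mu2^2 of Binomial(n, p0) for all n <= 30."""
        q = 1.0 - p0
        for n in range(1, 31):
            mu2 = n * p0 * q
            mu4 = n * p0 * q * (1.0 + 3.0 * (n - 2) * p0 * q)
            assert binomial_variance_term(n, p0) == pytest.approx(
                mu4 - mu2**2, abs=1e-12, rel=1e-12
            )


class TestBurden:
    def test_carrier_proportion_examples(self):
        region = make_region([[1.0, 0.0], [1.0, 2.0], [0.0, 0.0]], oriented=False)
        scores = burden_scores(region)
        assert scores[0] == pytest.approx(0.5)  # het + hom-major
        assert scores[1] == pytest.approx(1.0)  # carries at all variants
        assert scores[2] == pytest.approx(0.0)

    def test_missing_handling(self):
        region = make_region(
            [[1.0, np.nan], [np.nan, np.nan]], oriented=False
        )
        with pytest.warns(UserWarning, match="all genotypes missing"):
            scores = burden_scores(region)
        assert scores[0] == pytest.approx(1.0)  # 1 carrier / 1 observed
        assert np.isnan(scores[1])

    def test_matches_loop_oracle(self, rng):
        dose = rng.integers(0, 3, size=(6, 4)).astype(float)
        region = make_region(dose, oriented=False)
        scores = burden_scores(region)
        for i in range(6):
            carriers = sum(1 for j in range(4) if dose[i, j] >= 1)
            assert scores[i] == pytest.approx(carriers / 4)

    def test_constant_score_error(self):
        with pytest.raises(ValueError, match="no burden variation"):
            burden_test(np.ones(10), np.arange(10.0))

    def test_exact_linear_fit(self, rng):
        scores = np.array([0.0, 0.25, 0.5, 0.75, 1.0] * 4)
        resid = rng.normal(size=20)
        resid -= resid.mean()
        sc = scores - scores.mean()
        resid -= sc * (resid @ sc) / (sc @ sc)  # orthogonal to score
        beta, se, p = burden_test(scores, 3.0 * scores + resid)
        assert beta == pytest.approx(3.0, abs=1e-10)

    def test_matches_normal_equations(self, rng):
        scores = rng.uniform(size=30)
        cov = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        beta, se, p = burden_test(scores, y, covariates=cov)
        X = np.column_stack([np.ones(30), scores, cov])
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert beta == pytest.approx(ref[1], abs=1e-8)

    def test_binary_trait_logistic(self, rng):
        scores = rng.uniform(size=200)
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-(scores - 0.5)))).astype(float)
        beta, se, p = burden_test(scores, y, trait_type="binary")
        assert np.isfinite(beta) and se > 0 and 0 <= p <= 1
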