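"""Growth-curve fits, RGR, PCA trait axes, SMA scaling, kinship GLS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slowfast.traits import (
    fit_logistic_growth,
    gls_kinship_fit,
    logistic,
    pca_axis,
    rgr_at_inflection,
    sma_fit,
)


DAYS = np.arange(1, 31, dtype=float)


class TestGrowth:
    def test_noiseless_logistic_recovered_exactly(self):
        areas = logistic(DAYS, 2000.0, 0.25, 20.0)
        fit = fit_logistic_growth(DAYS, areas)
        assert fit.converged
        assert fit.K == pytest.approx(2000.0, rel=1e-6)
        assert fit.r == pytest.approx(0.25, rel=1e-6)
        assert fit.t0 == pytest.approx(20.0, rel=1e-6)

    def test_monotone_linear_series_flagged(self):
        fit = fit_logistic_growth(DAYS, 10.0 * DAYS)
        assert not fit.converged

    def test_rgr_is_half_the_logistic_rate(self):
        areas = logistic(DAYS, 1500.0, 0.2, 15.0)
        fit = fit_logistic_growth(DAYS, areas)
        assert rgr_at_inflection(fit) == pytest.approx(0.1, rel=1e-9)

    def test_rgr_matches_finite_difference_oracle(self):
        K, r, t0 = 1800.0, 0.31, 14.0
        fit = fit_logistic_growth(DAYS, logistic(DAYS, K, r, t0))
        h = 1e-6
        dadt = (logistic(t0 + h, K, r, t0) - logistic(t0 - h, K, r, t0)) / (2 * h)
        rgr_numeric = dadt / logistic(np.array([t0]), K, r, t0)[0]
        assert rgr_at_inflection(fit) == pytest.approx(rgr_numeric, abs=1e-8)

    def test_unconverged_fit_refuses_rgr(self):
        fit = fit_logistic_growth(DAYS, 10.0 * DAYS)
        with pytest.raises(ValueError, match="converge"):
            rgr_at_inflection(fit)

    @pytest.mark.parametrize("scale", [0.1, 7.3])
    def test_rgr_invariant_to_area_rescaling(self, scale, rng):
        areas = logistic(DAYS, 2000.0, 0.25, 16.0) + rng.normal(0, 20.0, DAYS.size)
        areas = np.maximum(areas, 1.0)
        r1 = rgr_at_inflection(fit_logistic_growth(DAYS, areas))
        r2 = rgr_at_inflection(fit_logistic_growth(DAYS, scale * areas))
        assert r2 == pytest.approx(r1, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_logistic_growth(DAYS[:4], logistic(DAYS[:4], 100, 0.2, 2))


def latent_trait_frame(rng, n=200):
    latent = rng.normal(0, 1, n)
    def trait(load, noise):
        return 10 ** (0.15 * (load * latent + noise * rng.normal(0, 1, n)))
    return pd.DataFrame(
        {
            "A_mass": trait(-1.0, 0.4),
            "LMA": trait(1.0, 0.4),
            "LLS": trait(0.8, 0.5),
        },
        index=[f"g{i}" for i in range(n)],
    )


class TestPcaAxis:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(0, 1, 50)
        wide = pd.DataFrame({"LMA": 10 ** x, "LLS": 10 ** (2 * x + 1)},
                            index=[f"g{i}" for i in range(50)])
        ax = pca_axis(wide, ["LMA", "LLS"], axis_name="LES")
        assert ax.var_explained == pytest.approx(1.0, abs=1e-12)
        assert abs(ax.loadings["LMA"]) == pytest.approx(abs(ax.loadings["LLS"]), abs=1e-12)

    def test_independent_traits_var_explained_near_one_over_p(self, rng):
        n, p = 4000, 4
        wide = pd.DataFrame(
            10 ** rng.normal(0, 0.2, (n, p)),
            columns=[f"tr{j}" for j in range(p)],
            index=[f"g{i}" for i in range(n)],
        )
        ax = pca_axis(wide, list(wide.columns))
        assert ax.var_explained == pytest.approx(1 / p, abs=0.03)

    def test_orientation_lma_positive_amass_negative(self, rng):
        wide = latent_trait_frame(rng)
        ax = pca_axis(wide, ["A_mass", "LMA", "LLS"], axis_name="LES")
        assert ax.loadings["LMA"] > 0
        assert ax.loadings["A_mass"] < 0  # acquisitive end scores low
        assert ax.loadings.pow(2).sum() == pytest.approx(1.0, abs=1e-12)

    def test_scores_invariant_to_trait_reordering(self, rng):
        wide = latent_trait_frame(rng)
        a = pca_axis(wide, ["A_mass", "LMA", "LLS"])
        b = pca_axis(wide, ["LLS", "A_mass", "LMA"])
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)

    def test_constant_trait_rejected(self, rng):
        wide = latent_trait_frame(rng)
        wide["flat"] = 2.0
        with pytest.raises(ValueError, match="flat"):
            pca_axis(wide, ["LMA", "flat"])


class TestSma:
    def test_slope_is_signed_sd_ratio(self, rng):
        x = rng.normal(0, 1, 400)
        y = -0.5 * 2.0 * x + np.sqrt(1 - 0.25) * 2.0 * rng.normal(0, 1, 400)
        f = sma_fit(x, y)
        assert f.r < 0
        assert f.slope == pytest.approx(-y.std(ddof=1) / x.std(ddof=1), abs=1e-12)

    def test_identity_line_degenerate_ci(self, rng):
        x = rng.normal(0, 1, 30)
        f = sma_fit(x, x)
        assert f.slope == pytest.approx(1.0, abs=1e-12)
        assert f.slope_ci == pytest.approx((1.0, 1.0), abs=1e-9)
        assert not f.slope_differs_from_1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), flip=st.booleans())
    def test_symmetry_of_xy_and_yx_slopes(self, seed, flip):
        r = np.random.default_rng(seed)
        x = r.normal(0, 1 + r.random(), 50)
        y = (-1 if flip else 1) * 0.7 * x + r.normal(0, 0.5, 50)
        bxy = sma_fit(x, y).slope
        byx = sma_fit(y, x).slope
        assert abs(bxy * byx) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sma_fit(np.ones(10), np.arange(10.0))


class TestGlsKinship:
    def test_identity_kinship_equals_ols(self, rng):
        x = rng.normal(0, 1, 80)
        y = 1.3 * x + rng.normal(0, 0.5, 80)
        f = gls_kinship_fit(y, x, np.eye(80))
        assert f.slope == pytest.approx(f.ols_slope, abs=1e-8)
        assert not f.differs_from_ols

    def test_block_kinship_matches_direct_gls_algebra(self, rng):
        # two related groups with confounded means; oracle = explicit
        # (X' V^-1 X)^-1 X' V^-1 y with the same nugget
        n = 40
        block = np.kron(np.eye(2), np.full((n // 2, n // 2), 0.9))
        np.fill_diagonal(block, 1.0)
        group = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        x = rng.normal(0, 1, n) + 3 * group
        y = 0.5 * x + 2 * group + rng.normal(0, 0.3, n)
        f = gls_kinship_fit(y, x, block, nugget=1e-6)

        V = block + 1e-6 * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert f.slope == pytest.approx(beta[1], rel=1e-6)
        # GLS discounts the between-group contrast, moving the slope toward
        # the within-group value 0.5 relative to OLS
        assert abs(f.slope - 0.5) < abs(f.ols_slope - 0.5)

    def test_no_confounding_slopes_agree(self, rng):
        agree = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            K = np.kron(np.eye(5), np.full((10, 10), 0.5))
            np.fill_diagonal(K, 1.0)
            x = r.normal(0, 1, 50)
            y = 0.8 * x + r.normal(0, 0.5, 50)
            f = gls_kinship_fit(y, x, K)
            agree += not f.differs_from_ols
        assert agree >= 18  # >= 90% of seeds

    def test_mismatched_kinship_rejected(self, rng):
        with pytest.raises(ValueError, match="sample size"):
            gls_kinship_fit(rng.normal(size=5), rng.normal(size=5), np.eye(4))
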