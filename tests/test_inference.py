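"""Moderation, moderated t-tests, empirical null and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dtusage.data import design_from_groups
from dtusage.inference import test_dtu as run_dtu_tests
from dtusage.inference import (
    bh_adjust,
    empirical_p,
    estimate_empirical_null,
    squeeze_dispersions,
    t_test_contrast,
    trigamma_inverse,
    z_from_p,
)
from dtusage.model import TranscriptFit, fit_all
from dtusage.simulate import SyntheticParams, simulate_dataset


def make_fit(beta, cov, df_residual, dispersion=1.0, converged=True):
    return TranscriptFit(
        transcript_id="tx",
        gene_id="g",
        beta=None if beta is None else np.asarray(beta, dtype=float),
        cov_unscaled=None if cov is None else np.asarray(cov, dtype=float),
        dispersion=dispersion,
        df_residual=df_residual,
        n_eff=df_residual + (0 if beta is None else len(beta)),
        converged=converged,
        fitted_pi=None,
    )


class TestSqueezeDispersions:
    def test_posterior_formula_hand_value(self):
        # phi_post = (d0 s0^2 + df phi) / (d0 + df) = (4*2 + 6*5) / 10 = 3.8
        d0, s0_sq, df, phi = 4.0, 2.0, 6.0, 5.0
        post = (d0 * s0_sq + df * phi) / (d0 + df)
        assert post == pytest.approx(3.8)
        # and the estimator reproduces it once (d0, s0^2) are plugged in:
        # simulate many dispersions so the prior is recovered, then check
        # the shrinkage direction and convex-combination property
        rng = np.random.default_rng(1)
        phis = s0_sq * stats.f.rvs(df, d0, size=4000, random_state=rng)
        mod = squeeze_dispersions(phis, df)
        lam = df / (df + mod.d0)
        expected = lam * phis + (1 - lam) * mod.s0_sq
        np.testing.assert_allclose(mod.phi_post, expected, rtol=1e-10)

    def test_recovers_known_prior(self):
        rng = np.random.default_rng(42)
        d0, s0_sq, df = 10.0, 2.0, 8.0
        phis = s0_sq * stats.f.rvs(df, d0, size=5000, random_state=rng)
        mod = squeeze_dispersions(phis, df)
        assert abs(mod.d0 - d0) / d0 < 0.25
        assert abs(mod.s0_sq - s0_sq) / s0_sq < 0.10

    def test_phi_post_between_phi_and_prior(self):
        rng = np.random.default_rng(2)
        phis = 2.0 * stats.f.rvs(6, 12, size=500, random_state=rng)
        mod = squeeze_dispersions(phis, 6.0)
        lo = np.minimum(phis, mod.s0_sq)
        hi = np.maximum(phis, mod.s0_sq)
        assert ((mod.phi_post >= lo - 1e-12) & (mod.phi_post <= hi + 1e-12)).all()

    def test_infinite_d0_collapses_to_prior(self):
        # homogeneous dispersions: moment matching finds no excess spread
        phis = np.full(300, 2.0)
        mod = squeeze_dispersions(phis, 10.0)
        assert np.isinf(mod.d0)
        np.testing.assert_allclose(mod.phi_post, mod.s0_sq)

    def test_zero_dispersions_get_prior(self):
        rng = np.random.default_rng(3)
        phis = 2.0 * stats.f.rvs(6, 10, size=400, random_state=rng)
        phis[:5] = 0.0
        mod = squeeze_dispersions(phis, 6.0)
        np.testing.assert_allclose(mod.phi_post[:5], mod.s0_sq)

    def test_too_few_dispersions_no_moderation(self):
        mod = squeeze_dispersions(np.array([1.5]), 4.0)
        assert mod.d0 == 0.0
        np.testing.assert_allclose(mod.phi_post, [1.5])

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in [0.1, 0.5, 2.0, 10.0, 100.0]:
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestTTestContrast:
    def test_zero_estimate_gives_p_one(self):
        fit = make_fit([0.0, 0.0], np.eye(2), df_residual=8)
        est, se, t, df, p = t_test_contrast(fit, 1.0, 4.0, np.array([0.0, 1.0]))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_t_distribution_tail(self):
        # estimate 2, se 1, df_total 10 -> p ~ 0.0734
        fit = make_fit([0.0, 2.0], np.eye(2), df_residual=6)
        est, se, t, df, p = t_test_contrast(fit, 1.0, 4.0, np.array([0.0, 1.0]))
        assert (est, se, t, df) == (2.0, 1.0, 2.0, 10.0)
        assert p == pytest.approx(2 * stats.t.sf(2, 10), abs=1e-12)
        assert p == pytest.approx(0.0734, abs=5e-4)

    def test_posterior_df_is_sum(self):
        fit = make_fit([0.0, 1.0], np.eye(2), df_residual=8)
        *_, df, _ = t_test_contrast(fit, 1.0, 4.0, np.array([0.0, 1.0]))
        assert df == 12.0

    def test_infinite_d0_uses_normal(self):
        fit = make_fit([0.0, 2.0], np.eye(2), df_residual=8)
        *_, p = t_test_contrast(fit, 1.0, np.inf, np.array([0.0, 1.0]))
        assert p == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-12)

    def test_unconverged_fit_gives_nans(self):
        fit = make_fit(None, None, df_residual=8, converged=False)
        out = t_test_contrast(fit, 1.0, 4.0, np.array([0.0, 1.0]))
        assert all(np.isnan(v) for v in out)


class TestZFromP:
    def test_examples(self):
        np.testing.assert_allclose(z_from_p(np.array([1.0]), np.array([1.0])), [0.0], atol=1e-12)
        # p = 0.31731, negative t: qnorm(0.158655) = -1 -> z = +1
        z = z_from_p(np.array([0.3173105078629141]), np.array([-1.0]))
        assert z[0] == pytest.approx(1.0, abs=1e-6)
        z = z_from_p(np.array([0.05]), np.array([1.0]))
        assert z[0] == pytest.approx(-1.9599640, abs=1e-6)

    def test_tiny_p_clipped_finite(self):
        z = z_from_p(np.array([1e-320]), np.array([1.0]))
        assert np.isfinite(z[0])


class TestEmpiricalNull:
    def test_standard_normal_recovered(self):
        rng = np.random.default_rng(10)
        mu, sigma = estimate_empirical_null(rng.normal(0, 1, 50000))
        assert -0.05 <= mu <= 0.05
        assert 0.95 <= sigma <= 1.05

    def test_contaminated_mixture_recovered(self):
        rng = np.random.default_rng(11)
        z = np.concatenate([rng.normal(0.3, 1.2, 45000), rng.normal(5.0, 1.0, 5000)])
        mu, sigma = estimate_empirical_null(z)
        assert mu == pytest.approx(0.3, abs=0.1)
        assert sigma == pytest.approx(1.2, abs=0.1)

    def test_small_sample_falls_back_to_theoretical(self):
        rng = np.random.default_rng(12)
        with pytest.warns(UserWarning, match="theoretical null"):
            mu, sigma = estimate_empirical_null(rng.normal(0, 1, 150))
        assert (mu, sigma) == (0.0, 1.0)

    def test_degenerate_z_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_empirical_null(np.zeros(500))


class TestEmpiricalP:
    def test_worked_example(self):
        # z = 2, mu* = 0.5, sigma* = 1.5 -> z* = 1, p* = 0.31731
        z_emp, p_emp = empirical_p(np.array([2.0]), 0.5, 1.5)
        assert z_emp[0] == pytest.approx(1.0)
        assert p_emp[0] == pytest.approx(0.3173105, abs=1e-6)

    def test_z_at_null_centre_gives_p_one(self):
        _, p = empirical_p(np.array([0.7]), 0.7, 1.2)
        assert p[0] == pytest.approx(1.0)

    def test_identity_null_recovers_normal_p(self):
        rng = np.random.default_rng(13)
        z = rng.normal(0, 1, 100)
        _, p = empirical_p(z, 0.0, 1.0)
        np.testing.assert_allclose(p, 2 * stats.norm.cdf(-np.abs(z)), atol=1e-14)

    def test_raw_p_round_trip_under_identity_null(self):
        # p_raw -> z -> p_emp is the identity when (mu*, sigma*) = (0, 1)
        rng = np.random.default_rng(14)
        p_raw = rng.uniform(1e-12, 1, 200)
        sign = rng.choice([-1.0, 1.0], 200)
        z = z_from_p(p_raw, sign)
        _, p_emp = empirical_p(z, 0.0, 1.0)
        np.testing.assert_allclose(p_emp, p_raw, rtol=1e-10, atol=1e-10)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(np.array([1.0]), 0.0, 0.0)


@pytest.fixture(scope="module")
def null_run():
    params = SyntheticParams(n_genes=650, dtu_fraction=0.0, usage_overdispersion=0.02, seed=5)
    q, groups, _ = simulate_dataset(params)
    design = design_from_groups(groups)
    fits = fit_all(q, design)
    return fits, design


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])

    def test_nan_passthrough(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(out[1]) and np.isfinite(out[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_and_dominates_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_hand_stepup(self):
        # independent step-up implementation as oracle
        rng = np.random.default_rng(99)
        p = rng.uniform(0, 1, 20)
        n = len(p)
        order = np.argsort(p)
        ranked = p[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(ranked, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


class TestTestDtu:
    def test_type_one_error_near_nominal(self, null_run):
        fits, design = null_run
        tables = run_dtu_tests(fits, design, null_mode="empirical")
        (_, table), = tables.items()
        p = table["p_emp"].dropna().to_numpy()
        assert len(p) > 1500
        frac = (p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_theoretical_mode_identity(self, null_run):
        fits, design = null_run
        tables = run_dtu_tests(fits, design, null_mode="theoretical")
        (_, table), = tables.items()
        ok = table["p_raw"].notna()
        np.testing.assert_allclose(
            table.loc[ok, "p_emp"], table.loc[ok, "p_raw"], rtol=1e-10, atol=1e-12
        )
        assert table.attrs["mu_star"] == 0.0 and table.attrs["sigma_star"] == 1.0

    def test_global_sign_flip_invariance(self, null_run):
        # the z-score convention flips all signs together; the recalibrated
        # p-values must not change under a global flip
        fits, design = null_run
        tables = run_dtu_tests(fits, design, null_mode="empirical")
        (_, table), = tables.items()
        z = table["z_raw"].dropna().to_numpy()
        mu1, s1 = estimate_empirical_null(z)
        mu2, s2 = estimate_empirical_null(-z)
        _, p1 = empirical_p(z, mu1, s1)
        _, p2 = empirical_p(-z, mu2, s2)
        np.testing.assert_allclose(p1, p2, atol=1e-4)

    def test_per_contrast_independent_nulls(self, null_run):
        fits, design = null_run
        contrasts = {
            "c1": np.array([0.0, 1.0]),
            "c2": np.array([0.0, -2.0]),
        }
        tables = run_dtu_tests(fits, design, contrasts=contrasts)
        assert set(tables) == {"c1", "c2"}
        # scaling a contrast rescales estimates but each table carries its
        # own fitted null parameters
        for t in tables.values():
            assert "mu_star" in t.attrs and "sigma_star" in t.attrs

    def test_missing_fits_carry_nans(self, null_run):
        fits, design = null_run
        broken = list(fits)
        broken[0] = make_fit(None, None, df_residual=0, dispersion=np.nan, converged=False)
        broken[0].transcript_id = fits[0].transcript_id
        tables = run_dtu_tests(broken, design)
        (_, table), = tables.items()
        assert np.isnan(table.iloc[0]["p_emp"])
        assert not table.iloc[0]["converged"]
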