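"""Model-core oracles: closed forms, dense-covariance AR(1), density sums."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from fplocal import model as mdl
from fplocal.datatypes import (
    GlobalParameters,
    LevelPriors,
    PopulationParameters,
    SurveyObservation,
    Trajectories,
)


def _flat_gp(tau=0.0, bias=0.0, beta=1.0, rho=0.9, sigma=0.1,
             tau_mismatch=0.0) -> GlobalParameters:
    """A fully controlled fixture for oracle tests."""
    lp = LevelPriors(
        mu_logit_Ptilde=0.5, sd_logit_Ptilde=1.0,
        mu_log_pace_P=np.log(0.08), sd_log_pace_P=0.4,
        mu_Omega_P=2000.0, sd_Omega_P=8.0,
        mu_logit_Rtilde=1.0, sd_logit_Rtilde=1.0,
        mu_log_pace_R=np.log(0.06), sd_log_pace_R=0.4,
        mu_Omega_R=1995.0, sd_Omega_R=8.0,
        mu_alpha=-1.0, sd_alpha=0.5,
    )
    comps = {"modern": bias, "traditional": bias, "unmet": bias}
    return GlobalParameters(
        levels={34: lp}, beta=beta,
        rho_P=rho, sigma_P=sigma, rho_R=rho, sigma_R=sigma, rho_Z=rho, sigma_Z=sigma,
        bias={s: ({"modern": 0.0, "traditional": 0.0, "unmet": 0.0} if s == "DHS" else dict(comps))
              for s in ("DHS", "MICS", "NATIONAL", "OTHER")},
        tau={s: {"modern": tau, "traditional": tau, "unmet": tau}
             for s in ("DHS", "MICS", "NATIONAL", "OTHER")},
        tau_mismatch=tau_mismatch,
    )


def _params(grid, eps=0.0, Ptilde=0.8, Omega_P=2000.0, pace_P=0.1,
            Rtilde=0.9, Omega_R=1995.0, pace_R=0.08, alpha=-1.0):
    n = len(grid)
    e = np.full(n, eps, dtype=float)
    return PopulationParameters(Ptilde=Ptilde, Omega_P=Omega_P, pace_P=pace_P,
                                Rtilde=Rtilde, Omega_R=Omega_R, pace_R=pace_R,
                                alpha=alpha, eps_P=e.copy(), eps_R=e.copy(), eps_Z=e.copy())


class TestSystematicCurve:
    def test_midpoint_is_half_asymptote(self):
        assert mdl.systematic_curve(2000.0, 0.8, 2000.0, 0.1) == pytest.approx(0.4)

    def test_closed_form_value(self):
        # 0.8 / (1 + e^-1), frozen from direct evaluation
        assert mdl.systematic_curve(2010, 0.8, 2000, 0.1) == pytest.approx(0.5848468629040039, abs=1e-12)

    def test_monotone_increasing_with_vanishing_left_tail(self):
        t = np.linspace(1800, 2100, 400)
        y = mdl.systematic_curve(t, 0.7, 1990, 0.06)
        assert np.all(np.diff(y) > 0)
        assert y[0] < 1e-4 and y[-1] < 0.7

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            mdl.systematic_curve(2000, 1.2, 2000, 0.1)
        with pytest.raises(ValueError):
            mdl.systematic_curve(2000, 0.5, 2000, -0.1)


class TestLogitTransform:
    def test_half_maps_to_zero_and_round_trip(self):
        assert mdl.logit_transform(0.5) == 0.0
        assert mdl.inv_logit(mdl.logit_transform(0.3)) == pytest.approx(0.3, abs=1e-12)

    def test_clamping_rule(self):
        y, clamped = mdl.clamp_proportion(1.0)
        assert y == 0.999 and clamped
        y, clamped = mdl.clamp_proportion(0.0)
        assert y == 0.001 and clamped
        y, clamped = mdl.clamp_proportion(0.4)
        assert y == 0.4 and not clamped


class TestAr1LogDensity:
    def test_length_one_is_marginal_normal(self):
        assert mdl.ar1_log_density([0.3], 0.9, 0.2) == pytest.approx(
            stats.norm.logpdf(0.3, 0, 0.2), abs=1e-12)

    def test_rho_zero_is_independent_normals(self):
        x = np.array([0.1, -0.4, 0.2])
        assert mdl.ar1_log_density(x, 0.0, 0.3) == pytest.approx(
            stats.norm.logpdf(x, 0, 0.3).sum(), abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 12])
    def test_matches_dense_covariance_oracle(self, n, rng):
        """Stationary AR(1) joint density == MVN with cov sigma^2 rho^|i-j|."""
        for _ in range(20):
            rho = rng.uniform(-0.95, 0.95)
            sigma = rng.uniform(0.05, 2.0)
            x = rng.normal(0, sigma, n)
            i = np.arange(n)
            cov = sigma**2 * rho ** np.abs(i[:, None] - i[None, :])
            oracle = stats.multivariate_normal.logpdf(x, mean=np.zeros(n), cov=cov)
            assert mdl.ar1_log_density(x, rho, sigma) == pytest.approx(oracle, abs=1e-8)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            mdl.ar1_log_density([0.1], 1.0, 0.2)
        with pytest.raises(ValueError):
            mdl.ar1_log_density([0.1], 0.5, 0.0)


class TestLatentTrajectories:
    GRID = np.arange(1990, 2015)

    def test_zero_distortion_reduces_to_logistic(self):
        p = _params(self.GRID)
        traj = mdl.latent_trajectories(p, self.GRID, beta=1.0)
        lhs = logit(traj.P / p.Ptilde)
        rhs = p.pace_P * (self.GRID - p.Omega_P)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_hand_evaluated_point(self):
        # frozen from closed-form evaluation of the stated formulas at t=2010
        p = _params(self.GRID, alpha=-1.0)
        traj = mdl.latent_trajectories(p, self.GRID, beta=0.0)
        i = 2010 - 1990
        assert traj.P[i] == pytest.approx(0.5848468629040039, abs=1e-12)
        assert traj.R[i] == pytest.approx(0.9 * expit(1.2), abs=1e-12)
        assert traj.M[i] == pytest.approx(0.5848468629040039 * 0.9 * expit(1.2), abs=1e-12)

    def test_identities_over_random_parameter_draws(self, rng):
        """M+T=P exactly, M+T+Z<1, and all bounds, over 10^4 draws."""
        grid = np.arange(2000, 2006)
        n = grid.size
        for _ in range(10_000):
            p = PopulationParameters(
                Ptilde=rng.uniform(0.01, 0.99), Omega_P=rng.uniform(1950, 2050),
                pace_P=rng.uniform(0.01, 1.0), Rtilde=rng.uniform(0.01, 0.99),
                Omega_R=rng.uniform(1950, 2050), pace_R=rng.uniform(0.01, 1.0),
                alpha=rng.normal(0, 2), eps_P=rng.normal(0, 1, n),
                eps_R=rng.normal(0, 1, n), eps_Z=rng.normal(0, 1, n),
            )
            tr = mdl.latent_trajectories(p, grid, beta=rng.normal(0, 2))
            assert np.all((tr.P > 0) & (tr.P < 1))
            assert np.all((tr.R > 0) & (tr.R < 1))
            assert np.all((tr.Z > 0) & (tr.Z < 1 - tr.P))
            # T is defined as P - M, so M + T reproduces P to one ulp
            np.testing.assert_allclose(tr.M + tr.T, tr.P, rtol=1e-14, atol=0)
            assert np.all(tr.M + tr.T + tr.Z < 1)

    def test_year_index_ties_round_down(self):
        traj = Trajectories(grid=np.arange(1990, 2000), P=None, R=None, Z=None, M=None, T=None)
        assert traj.year_index(1994.5) == 4      # tie -> 1994
        assert traj.year_index(1994.51) == 5
        assert traj.year_index(1994.0) == 4
        with pytest.raises(ValueError):
            traj.year_index(2005.0)


def _obs(y_m=None, y_t=None, y_u=None, se=0.02, source="DHS", t=2002.0, mismatch=False):
    return SurveyObservation(
        division_code=4, start_date=t, end_date=t, is_in_union="Y",
        source_type=source, sample_mismatch=mismatch,
        prop_modern=y_m, prop_traditional=y_t, prop_unmet=y_u,
        se_modern=se, se_traditional=se, se_unmet=se,
    )


class TestObservationLogLikelihood:
    GRID = np.arange(1990, 2015)

    def _traj(self, gp, **kw):
        return mdl.latent_trajectories(_params(self.GRID, **kw), self.GRID, gp.beta)

    def test_all_components_missing_contributes_zero(self):
        gp = _flat_gp()
        ob = _obs()
        ob.prop_modern = None  # all three missing; bypass reader validation
        assert mdl.observation_log_likelihood(ob, self._traj(gp), gp) == 0.0

    def test_mode_value_of_centered_normal(self):
        gp = _flat_gp(tau=0.0)
        traj = self._traj(gp)
        y = float(traj.M[2002 - 1990])
        ob = _obs(y_m=y, se=0.02)
        se_logit = 0.02 / (y * (1 - y))
        expected = -0.5 * np.log(2 * np.pi * se_logit**2)
        assert mdl.observation_log_likelihood(ob, traj, gp) == pytest.approx(expected, abs=1e-10)

    def test_matches_direct_normal_density_oracle(self):
        """DHS modern obs vs scipy normal logpdf with the stated moments."""
        gp = _flat_gp(tau=0.1)
        traj = self._traj(gp)
        latent_m = float(traj.M[2002 - 1990])
        ob = _obs(y_m=0.30, se=0.02)
        var = (0.02 / (0.3 * 0.7)) ** 2 + 0.1**2
        oracle = stats.norm.logpdf(logit(0.30), loc=logit(latent_m), scale=np.sqrt(var))
        assert mdl.observation_log_likelihood(ob, traj, gp) == pytest.approx(oracle, abs=1e-10)

    def test_bias_and_mismatch_enter_the_moments(self):
        gp = _flat_gp(tau=0.05, bias=0.2, tau_mismatch=0.1)
        traj = self._traj(gp)
        latent_u = float(traj.Z[2002 - 1990])
        ob = _obs(y_u=0.25, source="MICS", mismatch=True)
        var = (0.02 / (0.25 * 0.75)) ** 2 + 0.05**2 + 0.1**2
        oracle = stats.norm.logpdf(logit(0.25), loc=logit(latent_u) + 0.2, scale=np.sqrt(var))
        assert mdl.observation_log_likelihood(ob, traj, gp) == pytest.approx(oracle, abs=1e-10)

    def test_further_from_prediction_is_less_likely(self):
        """Monotone decay of the likelihood in logit distance from the mean."""
        gp = _flat_gp(tau=0.05)
        traj = self._traj(gp)
        y = 0.3
        ob = _obs(y_m=y)
        m0 = logit(float(traj.M[2002 - 1990]))
        vals = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            shifted = self._traj(gp, eps=0.0)
            shifted.M = expit(np.full_like(traj.M, logit(y) + abs(logit(y) - m0) + shift))
            vals.append(mdl.observation_log_likelihood(ob, shifted, gp))
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestLogPosterior:
    GRID = np.arange(1995, 2010)

    def test_no_data_at_prior_modes_equals_hand_sum(self):
        """Term-by-term oracle: seven prior densities at their modes plus
        three AR(1) densities at zero vectors."""
        gp = _flat_gp()
        pr = gp.prior(34)
        p = _params(self.GRID, eps=0.0,
                    Ptilde=float(expit(pr.mu_logit_Ptilde)), pace_P=float(np.exp(pr.mu_log_pace_P)),
                    Omega_P=pr.mu_Omega_P, Rtilde=float(expit(pr.mu_logit_Rtilde)),
                    pace_R=float(np.exp(pr.mu_log_pace_R)), Omega_R=pr.mu_Omega_R,
                    alpha=pr.mu_alpha)
        oracle = sum(stats.norm.logpdf(0.0, 0.0, sd) for sd in pr.sds())
        oracle += 3 * mdl.ar1_log_density(np.zeros(self.GRID.size), gp.rho_P, gp.sigma_P)
        assert mdl.log_posterior(p, [], gp, 34, self.GRID) == pytest.approx(oracle, abs=1e-10)

    def test_additivity_of_the_three_parts(self):
        gp = _flat_gp(tau=0.05)
        p = _params(self.GRID, eps=0.05)
        obs = [_obs(y_m=0.3, t=2002.0), _obs(y_u=0.2, t=2005.0, source="MICS")]
        traj = mdl.latent_trajectories(p, self.GRID, gp.beta)
        lik = sum(mdl.observation_log_likelihood(ob, traj, gp) for ob in obs)
        assert mdl.log_posterior(p, obs, gp, 34, self.GRID) == pytest.approx(
            mdl.log_posterior(p, [], gp, 34, self.GRID) + lik, abs=1e-10)

    def test_duplicating_an_observation_adds_its_term(self):
        gp = _flat_gp(tau=0.05)
        p = _params(self.GRID, eps=0.02)
        ob = _obs(y_m=0.3, t=2002.0)
        traj = mdl.latent_trajectories(p, self.GRID, gp.beta)
        term = mdl.observation_log_likelihood(ob, traj, gp)
        assert mdl.log_posterior(p, [ob, ob], gp, 34, self.GRID) - mdl.log_posterior(
            p, [ob], gp, 34, self.GRID) == pytest.approx(term, abs=1e-10)

    def test_unknown_level_key(self):
        gp = _flat_gp()
        with pytest.raises(KeyError):
            mdl.log_posterior(_params(self.GRID), [], gp, 99, self.GRID)

    def test_finite_for_random_valid_inputs(self, rng):
        gp = _flat_gp(tau=0.05)
        obs = [_obs(y_m=0.3, y_t=0.05, y_u=0.2, t=2002.0)]
        for _ in range(50):
            p = _params(self.GRID, eps=float(rng.normal(0, 0.3)),
                        Ptilde=float(rng.uniform(0.05, 0.95)),
                        alpha=float(rng.normal(-1, 1)))
            assert np.isfinite(mdl.log_posterior(p, obs, gp, 34, self.GRID))


class TestFlattenedPosterior:
    """The sampler backend agrees with the reference density and its
    gradient agrees with central finite differences."""

    def _ctx_theta(self, rng):
        gp = _flat_gp(tau=0.05, bias=0.1)
        grid = np.arange(1995, 2010)
        obs = [_obs(y_m=0.3, y_t=0.08, y_u=0.2, t=2002.0),
               _obs(y_m=0.4, t=2007.0, source="MICS", mismatch=True)]
        ctx = mdl.build_context(obs, gp, 34, grid)
        theta = ctx.pack(_params(grid)) + 0.1 * rng.standard_normal(ctx.dim)
        return gp, grid, obs, ctx, theta

    def test_matches_reference_log_posterior(self, rng):
        gp, grid, obs, ctx, theta = self._ctx_theta(rng)
        lp, _ = mdl.log_posterior_and_grad(theta, ctx)
        assert lp == pytest.approx(
            mdl.log_posterior(ctx.unpack(theta), obs, gp, 34, grid), abs=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        _, _, _, ctx, theta = self._ctx_theta(rng)
        _, g = mdl.log_posterior_and_grad(theta, ctx)
        h = 1e-6
        for i in range(0, ctx.dim, 3):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (mdl.log_posterior_and_grad(tp, ctx)[0]
                  - mdl.log_posterior_and_grad(tm, ctx)[0]) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_make_grid_extends_to_cover_observations():
    obs = [_obs(t=1987.4), _obs(t=2003.0)]
    grid = mdl.make_grid(1990, 2000, obs)
    assert grid[0] == 1987 and grid[-1] == 2003
    assert np.array_equal(np.diff(grid), np.ones(grid.size - 1))
    grid0 = mdl.make_grid(1990, 2000, [])
    assert grid0[0] == 1990 and grid0[-1] == 2000
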