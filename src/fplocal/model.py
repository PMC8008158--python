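"""Single-population probability model and its exact log-posterior.

Model
-----
On an annual grid t the three latent components are

    P_t = Ptilde * inv_logit(pace_P * (t - Omega_P) + eps_P,t)   total use
    R_t = Rtilde * inv_logit(pace_R * (t - Omega_R) + eps_R,t)   modern share
    Z_t = (1 - P_t) * inv_logit(alpha + beta * P_t + eps_Z,t)    unmet need

with modern use M = P*R and traditional use T = P*(1-R).  Systematic
change follows logistic growth curves; year-to-year departures from
them are zero-mean stationary AR(1) series.  The seven population-level
parameters carry Normal priors (on the logit / log scale for bounded
quantities) whose moments, together with the AR(1) parameters, the
fixed slope ``beta``, and the observation-error structure, come from a
:class:`~fplocal.datatypes.GlobalParameters` fixture.

A survey observation of component k from source s contributes

    logit(y_k) ~ Normal( logit(latent_k(t_i)) + bias[s, k],
                         se_logit^2 + tau[s, k]^2 + 1{mismatch} * tau_mismatch^2 )

where ``se_logit = se / (y (1 - y))`` is the delta-method transfer of
the proportion-scale sampling error to the logit scale.  Missing
components contribute nothing; cross-component errors are independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .datatypes import (
    COMPONENTS,
    GlobalParameters,
    PopulationParameters,
    SurveyObservation,
    TOP_LEVEL_NAMES,
    Trajectories,
)

#: Observed proportions are clamped into this closed interval before the
#: logit transform; clamping is recorded per observation component.
CLAMP_LO = 0.001
CLAMP_HI = 0.999

_LOG_2PI = float(np.log(2.0 * np.pi))

_COMP_INDEX = {"modern": 0, "traditional": 1, "unmet": 2}


def logit_transform(p):
    """log(p / (1-p)) for p strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def inv_logit(x):
    return expit(x)


def clamp_proportion(p: float) -> tuple[float, bool]:
    """Clamp a proportion into [CLAMP_LO, CLAMP_HI]; flags if clamped."""
    if p < CLAMP_LO:
        return CLAMP_LO, True
    if p > CLAMP_HI:
        return CLAMP_HI, True
    return p, False


def systematic_curve(t, asymptote: float, timing: float, pace: float):
    """Logistic growth curve: asymptote / (1 + exp(-pace * (t - timing))).

    Strictly increasing in t, tending to 0 in the distant past and to
    ``asymptote`` in the distant future; equals asymptote/2 at
    ``t == timing``.
    """
    if not 0 < asymptote < 1:
        raise ValueError(f"asymptote must lie in (0, 1), got {asymptote}")
    if not pace > 0:
        raise ValueError(f"pace must be positive, got {pace}")
    return asymptote * expit(pace * (np.asarray(t, dtype=float) - timing))


def ar1_log_density(series, rho: float, sigma: float) -> float:
    """Joint log-density of a zero-mean stationary AR(1) series.

    The first element is Normal(0, sigma^2); each subsequent element is
    Normal(rho * previous, sigma^2 * (1 - rho^2)), so the marginal
    variance is sigma^2 at every lag.
    """
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a nonempty 1-D vector")
    v_marg = sigma**2
    lp = -0.5 * (_LOG_2PI + np.log(v_marg)) - 0.5 * x[0] ** 2 / v_marg
    if x.size > 1:
        v_inno = v_marg * (1.0 - rho**2)
        resid = x[1:] - rho * x[:-1]
        lp += -0.5 * (x.size - 1) * (_LOG_2PI + np.log(v_inno))
        lp += -0.5 * np.sum(resid**2) / v_inno
    return float(lp)


def make_grid(first_year: int, last_year: int,
              obs: list[SurveyObservation] | None = None) -> np.ndarray:
    """Consecutive integer estimation grid.

    Spans the requested years, extended to cover every observation's
    reference time — the model is fit to all data, including dates
    outside the reporting window.
    """
    lo, hi = int(first_year), int(last_year)
    if obs:
        times = [ob.reference_time for ob in obs]
        lo = min(lo, int(np.floor(min(times))))
        hi = max(hi, int(np.ceil(max(times))))
    return np.arange(lo, hi + 1)


def latent_trajectories(params: PopulationParameters, grid,
                        beta: float) -> Trajectories:
    """Evaluate the latent indicator trajectories on the grid."""
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("empty grid")
    params.validate(grid_length=grid.size)
    P = params.Ptilde * expit(params.pace_P * (grid - params.Omega_P) + params.eps_P)
    R = params.Rtilde * expit(params.pace_R * (grid - params.Omega_R) + params.eps_R)
    Z = (1.0 - P) * expit(params.alpha + beta * P + params.eps_Z)
    M = P * R
    T = P - M
    return Trajectories(grid=grid, P=P, R=R, Z=Z, M=M, T=T)


def _se_logit(se: float, y: float) -> float:
    return se / (y * (1.0 - y))


def observation_terms(ob: SurveyObservation, gp: GlobalParameters):
    """Per-component likelihood ingredients for one SE-complete observation.

    Yields ``(component, clamped_y, logit_y, bias, variance, clamped)``
    for each non-missing component.
    """
    for comp in COMPONENTS:
        y = ob.proportion(comp)
        if y is None:
            continue
        se = ob.standard_error(comp)
        if se is None:
            raise ValueError(
                f"observation has missing se for component {comp!r}; "
                "run impute_sampling_errors first"
            )
        y_c, clamped = clamp_proportion(y)
        var = _se_logit(se, y_c) ** 2 + gp.tau[ob.source_type][comp] ** 2
        if ob.sample_mismatch:
            var += gp.tau_mismatch**2
        yield comp, y_c, float(logit_transform(y_c)), gp.bias[ob.source_type][comp], var, clamped


def observation_log_likelihood(ob: SurveyObservation, traj: Trajectories,
                               gp: GlobalParameters) -> float:
    """Log-likelihood contribution of one survey observation.

    Sums independent Normal log-densities on the logit scale over the
    observation's non-missing components; an observation with all
    components missing contributes exactly 0.
    """
    idx = traj.year_index(ob.reference_time)
    latent = {"modern": traj.M[idx], "traditional": traj.T[idx], "unmet": traj.Z[idx]}
    lp = 0.0
    for comp, _y, logit_y, bias, var, _cl in observation_terms(ob, gp):
        mean = float(logit_transform(latent[comp])) + bias
        lp += -0.5 * (_LOG_2PI + np.log(var)) - 0.5 * (logit_y - mean) ** 2 / var
    return float(lp)


def log_posterior(params: PopulationParameters, obs: list[SurveyObservation],
                  gp: GlobalParameters, level_key: int, grid) -> float:
    """Exact log-posterior density (up to the normalizing constant).

    Sum of (a) the seven Normal priors at the fixture's moments for
    ``level_key``, (b) stationary AR(1) log-densities of the three
    distortion series, and (c) the observation log-likelihood.
    """
    grid = np.asarray(grid)
    lp_prior = gp.prior(level_key)
    theta = np.array([
        float(logit_transform(params.Ptilde)), np.log(params.pace_P), params.Omega_P,
        float(logit_transform(params.Rtilde)), np.log(params.pace_R), params.Omega_R,
        params.alpha,
    ])
    mu, sd = lp_prior.means(), lp_prior.sds()
    lp = float(np.sum(-0.5 * (_LOG_2PI + np.log(sd**2)) - 0.5 * ((theta - mu) / sd) ** 2))
    lp += ar1_log_density(params.eps_P, gp.rho_P, gp.sigma_P)
    lp += ar1_log_density(params.eps_R, gp.rho_R, gp.sigma_R)
    lp += ar1_log_density(params.eps_Z, gp.rho_Z, gp.sigma_Z)
    traj = latent_trajectories(params, grid, gp.beta)
    for ob in obs:
        lp += observation_log_likelihood(ob, traj, gp)
    return lp


# ----------------------------------------------------------------------
# Fast flattened log-posterior with analytic gradient (sampler backend)
# ----------------------------------------------------------------------

@dataclass
class ModelContext:
    """Precomputed arrays binding data + fixture to a flat parameter vector.

    The unconstrained vector is
    ``[logit_Ptilde, log_pace_P, Omega_P, logit_Rtilde, log_pace_R,
    Omega_R, alpha, eps_P (n), eps_R (n), eps_Z (n)]`` of length
    ``7 + 3 n`` where n is the grid length.
    """

    grid: np.ndarray
    mu: np.ndarray            # (7,) prior means
    sd: np.ndarray            # (7,) prior SDs
    beta: float
    rho: np.ndarray           # (3,) for eps_P, eps_R, eps_Z
    sigma: np.ndarray         # (3,)
    obs_idx: np.ndarray       # (m,) grid index of each likelihood term
    obs_comp: np.ndarray      # (m,) 0=modern, 1=traditional, 2=unmet
    obs_z: np.ndarray         # (m,) logit(y) - bias
    obs_var: np.ndarray       # (m,) total logit-scale variance

    @property
    def n_years(self) -> int:
        return self.grid.size

    @property
    def dim(self) -> int:
        return 7 + 3 * self.n_years

    def pack(self, params: PopulationParameters) -> np.ndarray:
        head = np.array([
            float(logit_transform(params.Ptilde)), np.log(params.pace_P), params.Omega_P,
            float(logit_transform(params.Rtilde)), np.log(params.pace_R), params.Omega_R,
            params.alpha,
        ])
        return np.concatenate([head, params.eps_P, params.eps_R, params.eps_Z])

    def unpack(self, theta: np.ndarray) -> PopulationParameters:
        n = self.n_years
        return PopulationParameters(
            Ptilde=float(expit(theta[0])), pace_P=float(np.exp(theta[1])), Omega_P=float(theta[2]),
            Rtilde=float(expit(theta[3])), pace_R=float(np.exp(theta[4])), Omega_R=float(theta[5]),
            alpha=float(theta[6]),
            eps_P=theta[7:7 + n].copy(),
            eps_R=theta[7 + n:7 + 2 * n].copy(),
            eps_Z=theta[7 + 2 * n:].copy(),
        )

    def trajectories(self, theta: np.ndarray) -> Trajectories:
        return latent_trajectories(self.unpack(theta), self.grid, self.beta)


def build_context(obs: list[SurveyObservation], gp: GlobalParameters,
                  level_key: int, grid) -> ModelContext:
    grid = np.asarray(grid)
    prior = gp.prior(level_key)
    idx, comp, z, var = [], [], [], []
    base = int(grid[0])
    for ob in obs:
        year = int(np.ceil(ob.reference_time - 0.5))
        i = year - base
        if not 0 <= i < grid.size:
            raise ValueError(f"observation at {ob.reference_time} falls outside the grid")
        for c, _y, logit_y, bias, v, _cl in observation_terms(ob, gp):
            idx.append(i)
            comp.append(_COMP_INDEX[c])
            z.append(logit_y - bias)
            var.append(v)
    return ModelContext(
        grid=grid,
        mu=prior.means(), sd=prior.sds(),
        beta=gp.beta,
        rho=np.array([gp.rho_P, gp.rho_R, gp.rho_Z]),
        sigma=np.array([gp.sigma_P, gp.sigma_R, gp.sigma_Z]),
        obs_idx=np.asarray(idx, dtype=np.intp),
        obs_comp=np.asarray(comp, dtype=np.intp),
        obs_z=np.asarray(z, dtype=float),
        obs_var=np.asarray(var, dtype=float),
    )


def _ar1_logp_grad(x: np.ndarray, rho: float, sigma: float):
    v1 = sigma**2
    n = x.size
    lp = -0.5 * (_LOG_2PI + np.log(v1)) - 0.5 * x[0] ** 2 / v1
    g = np.empty_like(x)
    if n == 1:
        g[0] = -x[0] / v1
        return lp, g
    vi = v1 * (1.0 - rho**2)
    e = x[1:] - rho * x[:-1]
    lp += -0.5 * (n - 1) * (_LOG_2PI + np.log(vi)) - 0.5 * np.dot(e, e) / vi
    g[0] = -x[0] / v1 + rho * e[0] / vi
    g[1:] = -e / vi
    g[1:-1] += rho * e[1:] / vi
    return lp, g


def log_posterior_and_grad(theta: np.ndarray, ctx: ModelContext):
    """Log-posterior and its gradient w.r.t. the unconstrained vector.

    Matches :func:`log_posterior` exactly (including normalizing
    constants of every Normal factor); the gradient is analytic.
    Numerically degenerate points (overflowing pace, latent proportions
    at the boundary) return -inf so samplers reject them.
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _logp_grad_impl(theta, ctx)


def _logp_grad_impl(theta: np.ndarray, ctx: ModelContext):
    n = ctx.n_years
    g = np.zeros_like(theta)

    d = (theta[:7] - ctx.mu) / ctx.sd
    lp = float(np.sum(-0.5 * (_LOG_2PI + np.log(ctx.sd**2)) - 0.5 * d * d))
    g[:7] = -d / ctx.sd

    eps = [theta[7:7 + n], theta[7 + n:7 + 2 * n], theta[7 + 2 * n:]]
    for k in range(3):
        lpk, gk = _ar1_logp_grad(eps[k], float(ctx.rho[k]), float(ctx.sigma[k]))
        lp += lpk
        g[7 + k * n:7 + (k + 1) * n] += gk

    if ctx.obs_idx.size == 0:
        return lp, g

    Pt = expit(theta[0])
    paceP = np.exp(theta[1])
    OmP = theta[2]
    Rt = expit(theta[3])
    paceR = np.exp(theta[4])
    OmR = theta[5]
    alpha = theta[6]

    tP = ctx.grid - OmP
    tR = ctx.grid - OmR
    sP = expit(paceP * tP + eps[0])
    sR = expit(paceR * tR + eps[1])
    P = Pt * sP
    R = Rt * sR
    sZ = expit(alpha + ctx.beta * P + eps[2])
    Z = (1.0 - P) * sZ
    M = P * R
    T = P - M

    lat = np.choose(ctx.obs_comp, [M[ctx.obs_idx], T[ctx.obs_idx], Z[ctx.obs_idx]])
    if not np.all((lat > 0.0) & (lat < 1.0)):
        # latent underflowed to the boundary (or overflowed): reject
        return -np.inf, g
    r = ctx.obs_z - (np.log(lat) - np.log1p(-lat))
    lp += float(np.sum(-0.5 * (_LOG_2PI + np.log(ctx.obs_var)) - 0.5 * r * r / ctx.obs_var))

    # chain rule back through the trajectories
    dl_dL = (r / ctx.obs_var) / (lat * (1.0 - lat))
    gM = np.zeros(n)
    gT = np.zeros(n)
    gZ = np.zeros(n)
    for comp_idx, acc in ((0, gM), (1, gT), (2, gZ)):
        sel = ctx.obs_comp == comp_idx
        np.add.at(acc, ctx.obs_idx[sel], dl_dL[sel])

    sZp = sZ * (1.0 - sZ)
    dZdP = -sZ + (1.0 - P) * sZp * ctx.beta
    gP = gM * R + gT * (1.0 - R) + gZ * dZdP
    gR = (gM - gT) * P
    dPdeta = Pt * sP * (1.0 - sP)
    dRdeta = Rt * sR * (1.0 - sR)
    gZ_eta = gZ * (1.0 - P) * sZp

    g[7:7 + n] += gP * dPdeta
    g[7 + n:7 + 2 * n] += gR * dRdeta
    g[7 + 2 * n:] += gZ_eta
    g[0] += np.sum(gP * sP) * Pt * (1.0 - Pt)
    g[1] += np.sum(gP * dPdeta * tP) * paceP
    g[2] += -paceP * np.sum(gP * dPdeta)
    g[3] += np.sum(gR * sR) * Rt * (1.0 - Rt)
    g[4] += np.sum(gR * dRdeta * tR) * paceR
    g[5] += -paceR * np.sum(gR * dRdeta)
    g[6] += np.sum(gZ_eta)
    return lp, g


__all__ = [
    "CLAMP_LO", "CLAMP_HI", "TOP_LEVEL_NAMES",
    "logit_transform", "inv_logit", "clamp_proportion",
    "systematic_curve", "ar1_log_density", "make_grid",
    "latent_trajectories", "observation_log_likelihood", "log_posterior",
    "ModelContext", "build_context", "log_posterior_and_grad",
    "observation_terms",
]
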