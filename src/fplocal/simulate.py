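"""Synthetic fixtures: global-parameter files and whole populations.

The generator emulates the statistical world the model assumes: it
draws population parameters from the fixture priors, builds latent
trajectories through the model's own equations, and observes them
through the exact survey error model (source-type bias plus sampling
and non-sampling noise on the logit scale).  Because simulation and
likelihood share one set of equations, simulated data are exactly
on-model — which is what makes prior/parameter-recovery and
calibration checks meaningful.

Fixture default values are documented package constants standing in
for point estimates a real deployment would take from a prior
multi-country model run; they are chosen to be demographically
plausible (total-use asymptotes centred near 62%, uptake paces of a
few percent per year, inflection times in the late 20th century,
strongly autocorrelated distortions), not to reproduce any published
run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import (
    COMPONENTS,
    Division,
    GlobalParameters,
    LevelPriors,
    PopulationCount,
    PopulationParameters,
    SOURCE_TYPES,
    SurveyObservation,
    Trajectories,
)
from . import data_io
from .model import latent_trajectories, logit_transform, inv_logit

#: Documented default prior moments (shared by every generated level
#: key up to seeded jitter on the means).
DEFAULT_PRIOR = dict(
    mu_logit_Ptilde=0.5, sd_logit_Ptilde=1.0,      # asymptote of total use ~62%
    mu_log_pace_P=np.log(0.08), sd_log_pace_P=0.4,  # uptake pace ~8%/year
    mu_Omega_P=2000.0, sd_Omega_P=8.0,              # inflection year
    mu_logit_Rtilde=1.0, sd_logit_Rtilde=1.0,       # modern-share asymptote ~73%
    mu_log_pace_R=np.log(0.06), sd_log_pace_R=0.4,
    mu_Omega_R=1995.0, sd_Omega_R=8.0,
    mu_alpha=-1.0, sd_alpha=0.5,                    # unmet-need level (logit)
)


def generate_global_parameters(seed: int, level_keys=(34,)) -> GlobalParameters:
    """A valid, deterministic global-parameter fixture.

    Prior means get a small seeded jitter per level key; AR(1)
    autocorrelations are drawn in [0.8, 0.95] (strong year-to-year
    persistence) with stationary SDs in [0.05, 0.15]; DHS biases are
    exactly zero (reference source type) and other source-type biases
    and non-sampling SDs are drawn small.
    """
    rng = np.random.default_rng(seed)
    levels = {}
    for key in level_keys:
        jitter = dict(DEFAULT_PRIOR)
        for name in ("mu_logit_Ptilde", "mu_logit_Rtilde", "mu_alpha"):
            jitter[name] = jitter[name] + 0.1 * rng.standard_normal()
        levels[int(key)] = LevelPriors(**{k: float(v) for k, v in jitter.items()})
    bias = {}
    tau = {}
    for s in SOURCE_TYPES:
        bias[s] = {}
        tau[s] = {}
        for c in COMPONENTS:
            bias[s][c] = 0.0 if s == "DHS" else float(rng.normal(0.0, 0.05))
            tau[s][c] = float(rng.uniform(0.02, 0.10))
    gp = GlobalParameters(
        levels=levels,
        beta=1.0,
        rho_P=float(rng.uniform(0.80, 0.95)), sigma_P=float(rng.uniform(0.05, 0.15)),
        rho_R=float(rng.uniform(0.80, 0.95)), sigma_R=float(rng.uniform(0.05, 0.15)),
        rho_Z=float(rng.uniform(0.80, 0.95)), sigma_Z=float(rng.uniform(0.05, 0.15)),
        bias=bias,
        tau=tau,
        tau_mismatch=0.10,
    )
    gp.validate()
    return gp


def simulate_ar1(rng, n: int, rho: float, sigma: float, size: int | None = None) -> np.ndarray:
    """Stationary zero-mean AR(1) draws; shape (size, n) or (n,)."""
    shape = (n,) if size is None else (size, n)
    x = np.empty(shape)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    z = rng.standard_normal(shape)
    x[..., 0] = sigma * z[..., 0]
    for t in range(1, n):
        x[..., t] = rho * x[..., t - 1] + innov_sd * z[..., t]
    return x


@dataclass
class SimulationConfig:
    """Settings of one synthetic population.

    Defaults: a 25-year annual grid, 5 surveys spread over it with
    mixed source types and proportion-scale sampling errors of 0.02 —
    the data sparsity typical of a single-country fit.
    """

    first_year: int = 1990
    last_year: int = 2014
    survey_years: tuple[int, ...] = (1992, 1997, 2002, 2007, 2012)
    source_types: tuple[str, ...] = ("DHS", "MICS", "NATIONAL", "OTHER", "DHS")
    se_modern: float = 0.02
    se_traditional: float = 0.02
    se_unmet: float = 0.02
    division_code: int = 4
    is_in_union: str = "Y"
    level_key: int = 34
    region_code: int = 903
    n_women_start: float = 5.0e6
    n_women_growth: float = 0.01       # exponential growth per year
    sample_mismatch: bool = False
    seed: int = 0


@dataclass
class SimulatedPopulation:
    """Ground truth plus the observable datasets of one synthetic population."""

    truth: PopulationParameters
    trajectories: Trajectories
    observations: list[SurveyObservation]
    counts: list[PopulationCount]
    divisions: list[Division]
    config: SimulationConfig

    def write(self, directory: str | Path, gp: GlobalParameters | None = None) -> dict:
        """Write survey/population/divisions CSVs (+ fixture, truth, manifest)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        data_io.write_survey_data(self.observations, d / "survey.csv")
        data_io.write_population_counts(self.counts, d / "population.csv")
        data_io.write_divisions(self.divisions, d / "divisions.csv")
        if gp is not None:
            gp.to_json(d / "global_parameters.json")
        truth = {
            "parameters": {
                "Ptilde": self.truth.Ptilde, "Omega_P": self.truth.Omega_P,
                "pace_P": self.truth.pace_P, "Rtilde": self.truth.Rtilde,
                "Omega_R": self.truth.Omega_R, "pace_R": self.truth.pace_R,
                "alpha": self.truth.alpha,
                "eps_P": self.truth.eps_P.tolist(),
                "eps_R": self.truth.eps_R.tolist(),
                "eps_Z": self.truth.eps_Z.tolist(),
            },
            "grid": self.trajectories.grid.tolist(),
            "M": self.trajectories.M.tolist(),
            "T": self.trajectories.T.tolist(),
            "Z": self.trajectories.Z.tolist(),
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest = {
            "seed": self.config.seed,
            "truth": "truth.json",
            "survey": "survey.csv",
            "population": "population.csv",
            "divisions": "divisions.csv",
            "division_numeric_code": self.config.division_code,
            "is_in_union": self.config.is_in_union,
            "level_key": self.config.level_key,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest


def _sample_observed_logit(rng, m: float, se: float, tau2: float) -> float:
    """Draw logit(y) from the normalized observation density.

    The survey likelihood evaluates the delta-method sampling SD at the
    *observed* proportion, ``se / (y (1 - y))``, so the observation
    density in u = logit(y) is

        p(u) ∝ v(u)^{-1/2} exp( -(u - m)^2 / (2 v(u)) ),
        v(u) = (se / (y(u) (1 - y(u))))^2 + tau2,

    with m the biased latent logit.  Sampling this density by numerical
    inverse CDF (rather than a plain Normal with variance fixed at the
    latent value) keeps the generator and the likelihood exactly
    consistent, which self-simulation calibration checks rely on.
    Degenerate noise (se = tau = 0) returns m itself.
    """
    if se == 0.0 and tau2 == 0.0:
        return m
    ulo, uhi = float(logit_transform(1e-5)), float(logit_transform(1.0 - 1e-5))
    y0 = float(inv_logit(m))
    s0 = np.sqrt((se / (y0 * (1.0 - y0))) ** 2 + tau2)
    fine = m + s0 * np.linspace(-10.0, 10.0, 801)
    coarse = np.linspace(ulo, uhi, 801)
    u = np.unique(np.clip(np.concatenate([fine, coarse]), ulo, uhi))
    y = inv_logit(u)
    v = (se / (y * (1.0 - y))) ** 2 + tau2
    logp = -0.5 * np.log(v) - 0.5 * (u - m) ** 2 / v
    p = np.exp(logp - logp.max())
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(u))])
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, u))


def draw_population_parameters(gp: GlobalParameters, level_key: int, n_years: int,
                               rng) -> PopulationParameters:
    """Draw the population-specific unknowns from the fixture priors."""
    pr = gp.prior(level_key)
    head = pr.means() + pr.sds() * rng.standard_normal(7)
    return PopulationParameters(
        Ptilde=float(inv_logit(head[0])), pace_P=float(np.exp(head[1])), Omega_P=float(head[2]),
        Rtilde=float(inv_logit(head[3])), pace_R=float(np.exp(head[4])), Omega_R=float(head[5]),
        alpha=float(head[6]),
        eps_P=simulate_ar1(rng, n_years, gp.rho_P, gp.sigma_P),
        eps_R=simulate_ar1(rng, n_years, gp.rho_R, gp.sigma_R),
        eps_Z=simulate_ar1(rng, n_years, gp.rho_Z, gp.sigma_Z),
    )


def simulate_population(gp: GlobalParameters, config: SimulationConfig) -> SimulatedPopulation:
    """One synthetic population: truth drawn from the priors, surveys
    observed through the exact observation model.

    Each survey's reference period is the single survey year, so its
    reference time hits the grid exactly.  Observed logits are drawn
    from the normalized observation density around the biased latent
    logit (see :func:`_sample_observed_logit`): delta-method sampling
    variance at the observed proportion plus the source type's
    non-sampling variance, exactly as the likelihood evaluates them.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = np.arange(cfg.first_year, cfg.last_year + 1)
    truth = draw_population_parameters(gp, cfg.level_key, grid.size, rng)
    traj = latent_trajectories(truth, grid, gp.beta)

    ses = {"modern": cfg.se_modern, "traditional": cfg.se_traditional, "unmet": cfg.se_unmet}
    observations = []
    for year, source in zip(cfg.survey_years, cfg.source_types):
        idx = int(year) - cfg.first_year
        latent = {"modern": traj.M[idx], "traditional": traj.T[idx], "unmet": traj.Z[idx]}
        # joint redraw until the observed triplet satisfies the survey-data
        # invariants (component sums below 1); the heavy upper tail of the
        # observation density makes occasional violations possible
        for _attempt in range(10_000):
            props = {}
            for comp in COMPONENTS:
                L = float(latent[comp])
                tau2 = gp.tau[source][comp] ** 2
                if cfg.sample_mismatch:
                    tau2 += gp.tau_mismatch**2
                mean = float(logit_transform(L)) + gp.bias[source][comp]
                u = _sample_observed_logit(rng, mean, ses[comp], tau2)
                props[comp] = float(inv_logit(u))
            if (props["modern"] + props["traditional"] <= 1.0
                    and props["modern"] + props["traditional"] + props["unmet"] <= 1.0):
                break
        else:  # pragma: no cover - astronomically unlikely for valid fixtures
            raise RuntimeError("could not draw a valid observation triplet")
        observations.append(SurveyObservation(
            division_code=cfg.division_code,
            start_date=float(year), end_date=float(year),
            is_in_union=cfg.is_in_union,
            source_type=source,
            sample_mismatch=cfg.sample_mismatch,
            prop_modern=props["modern"],
            prop_traditional=props["traditional"],
            prop_unmet=props["unmet"],
            se_modern=ses["modern"],
            se_traditional=ses["traditional"],
            se_unmet=ses["unmet"],
        ))

    counts = []
    for union in ("Y", "N"):
        scale = 1.0 if union == "Y" else 0.6
        for j, year in enumerate(grid):
            counts.append(PopulationCount(
                division_code=cfg.division_code,
                year=int(year),
                is_in_union=union,
                n_women=scale * cfg.n_women_start * np.exp(cfg.n_women_growth * j),
            ))
    divisions = [Division(
        division_code=cfg.division_code,
        name=f"synthetic-{cfg.division_code}",
        subregion_code=cfg.level_key,
        region_code=cfg.region_code,
    )]
    return SimulatedPopulation(
        truth=truth, trajectories=traj, observations=observations,
        counts=counts, divisions=divisions, config=cfg,
    )
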