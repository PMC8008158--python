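"""Self-simulation checks of posterior calibration.

If the sampler targets the model's exact posterior, then over datasets
drawn from the model's own prior and observation model the true modern
prevalence at any year is a draw from its posterior: the central 95%
credible band should cover it ~95% of the time, the 80% band ~80%, and
its rank among the posterior draws should be uniform.  This module runs
that experiment end to end (simulate -> fit -> summarize) so both the
test suite and the acceptance script exercise one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import DEFAULT_QUANTILE_PROBS, FitConfig
from .inference import fit_model
from .simulate import SimulationConfig, generate_global_parameters, simulate_population


@dataclass
class CoverageResult:
    """Outcome of one coverage experiment at a held-out year."""

    held_out_year: int
    n_replicates: int
    outer_coverage_pct: float      # nominal 95 under default quantiles
    inner_coverage_pct: float      # nominal 80
    ranks: np.ndarray              # rank of truth among posterior draws, per replicate
    n_posterior_draws: int


def run_coverage_experiment(
    seed: int,
    n_replicates: int = 100,
    held_out_year: int = 2010,
    sim_config: SimulationConfig | None = None,
    chains: int = 2,
    warmup_iterations: int = 500,
    kept_iterations: int = 500,
    probs=DEFAULT_QUANTILE_PROBS,
) -> CoverageResult:
    """Fit ``n_replicates`` self-simulated populations and measure
    credible-band coverage of true modern prevalence at a held-out year.

    Every replicate draws fresh truth from the fixture priors (fixture
    generated from ``seed``), simulates 5 surveys on a 25-year grid,
    and fits with short chains.  The held-out year defaults to a grid
    year with no survey.  Returns empirical coverage (in percent) of
    the bands between the outer and inner pairs of ``probs``, plus the
    rank of the truth among the posterior draws of modern prevalence
    for rank-uniformity checks.
    """
    base = sim_config or SimulationConfig()
    if held_out_year in base.survey_years:
        raise ValueError("held-out year must not carry a survey")
    gp = generate_global_parameters(seed)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)

    outer_lo, inner_lo, _, inner_hi, outer_hi = probs
    outer_hits = 0
    inner_hits = 0
    ranks = np.empty(n_replicates, dtype=int)
    n_draws = chains * kept_iterations
    for r in range(n_replicates):
        rep_seed = int(children[r].generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        sim = simulate_population(gp, replace(base, seed=rep_seed))
        idx = held_out_year - base.first_year
        truth_m = float(sim.trajectories.M[idx])
        config = FitConfig(
            first_year=base.first_year, last_year=base.last_year,
            chains=chains, warmup_iterations=warmup_iterations,
            kept_iterations=kept_iterations, seed=rep_seed,
        )
        fit = fit_model(sim.observations, gp, base.level_key, config)
        m_draws = fit.trajectories["M"][..., idx].reshape(-1)
        qs = np.quantile(m_draws, [outer_lo, inner_lo, inner_hi, outer_hi])
        outer_hits += int(qs[0] <= truth_m <= qs[3])
        inner_hits += int(qs[1] <= truth_m <= qs[2])
        ranks[r] = int(np.sum(m_draws < truth_m))
    return CoverageResult(
        held_out_year=held_out_year,
        n_replicates=n_replicates,
        outer_coverage_pct=100.0 * outer_hits / n_replicates,
        inner_coverage_pct=100.0 * inner_hits / n_replicates,
        ranks=ranks,
        n_posterior_draws=n_draws,
    )


def rank_uniformity_pvalue(ranks: np.ndarray, n_posterior_draws: int,
                           n_bins: int = 10) -> float:
    """Chi-square goodness-of-fit p-value for uniformity of SBC ranks."""
    from scipy import stats

    edges = np.linspace(0, n_posterior_draws + 1, n_bins + 1)
    counts, _ = np.histogram(ranks, bins=edges)
    expected = len(ranks) / n_bins
    stat = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(stat, df=n_bins - 1))
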