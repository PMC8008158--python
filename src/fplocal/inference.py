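"""Posterior sampling, fit packaging, and convergence diagnostics.

The sampler is Hamiltonian Monte Carlo on the unconstrained parameter
vector (asymptotes on the logit scale, paces on the log scale, AR(1)
distortions as-is), with dual-averaging step-size adaptation and a
diagonal mass matrix estimated during warmup.  Gradients are analytic
(:func:`fplocal.model.log_posterior_and_grad`).  Chains run
sequentially; each draws its RNG stream from the fit seed, so identical
inputs and seed reproduce draws bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as _model
from .datatypes import (
    FitConfig,
    GlobalParameters,
    SurveyObservation,
    TrajectoryDraws,
)
from .model import ModelContext, build_context, inv_logit

_TRAJ_NAMES = ("P", "R", "Z", "M", "T")


@dataclass
class FitResult:
    """Posterior draws plus the core data of one model fit.

    ``draws`` maps each top-level parameter name to a (chains, kept)
    array on its natural scale (Ptilde, pace_P, ... rather than their
    transforms); ``eps`` maps each distortion series to a
    (chains, kept, n_years) array.  ``trajectories`` holds the derived
    latent indicators P, R, Z, M, T with the same leading shape.
    """

    draws: dict[str, np.ndarray]
    eps: dict[str, np.ndarray]
    trajectories: dict[str, np.ndarray]
    grid: np.ndarray
    config: FitConfig
    level_key: int
    processed_observations: pd.DataFrame
    bias_adjusted_observations: pd.DataFrame
    division_code: int | None = None
    is_in_union: str | None = None
    accept_rate: float | None = None

    @property
    def n_draws(self) -> int:
        return self.config.chains * self.config.kept_iterations

    def trajectory_draws(self) -> TrajectoryDraws:
        """Flatten (chain, iteration) into a single draw axis."""
        n = self.grid.size

        def flat(a):
            return a.reshape(-1, n)

        return TrajectoryDraws(
            grid=self.grid,
            M=flat(self.trajectories["M"]),
            T=flat(self.trajectories["T"]),
            Z=flat(self.trajectories["Z"]),
            division=self.division_code,
            is_in_union=self.is_in_union,
        )

    # ---- serialization ------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write the fit to a directory: columnar CSVs plus a manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        chains, kept = self.config.chains, self.config.kept_iterations
        ch, it = np.meshgrid(np.arange(chains), np.arange(kept), indexing="ij")
        params = pd.DataFrame({"chain": ch.ravel(), "iteration": it.ravel()})
        for name in TOP_LEVEL_NAMES_NATURAL:
            params[name] = self.draws[name].ravel()
        params.to_csv(d / "parameters.csv", index=False)

        n = self.grid.size
        rows = {
            "chain": np.repeat(ch.ravel(), n),
            "iteration": np.repeat(it.ravel(), n),
            "year": np.tile(self.grid, chains * kept),
        }
        for name in _TRAJ_NAMES:
            rows[name] = self.trajectories[name].reshape(-1)
        pd.DataFrame(rows).to_csv(d / "trajectories.csv", index=False)

        self.processed_observations.to_csv(d / "processed_observations.csv", index=False)
        self.bias_adjusted_observations.to_csv(d / "bias_adjusted_observations.csv", index=False)
        manifest = {
            "config": asdict(self.config),
            "level_key": int(self.level_key),
            "grid": [int(y) for y in self.grid],
            "division_code": self.division_code,
            "is_in_union": self.is_in_union,
            "accept_rate": self.accept_rate,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "FitResult":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        cfg_dict = manifest["config"]
        cfg_dict["quantile_probs"] = tuple(cfg_dict["quantile_probs"])
        config = FitConfig(**cfg_dict)
        grid = np.asarray(manifest["grid"])
        chains, kept = config.chains, config.kept_iterations
        params = pd.read_csv(d / "parameters.csv")
        draws = {
            name: params[name].to_numpy().reshape(chains, kept)
            for name in TOP_LEVEL_NAMES_NATURAL
        }
        traj_df = pd.read_csv(d / "trajectories.csv")
        n = grid.size
        trajectories = {
            name: traj_df[name].to_numpy().reshape(chains, kept, n)
            for name in _TRAJ_NAMES
        }
        return cls(
            draws=draws,
            eps={},
            trajectories=trajectories,
            grid=grid,
            config=config,
            level_key=manifest["level_key"],
            processed_observations=pd.read_csv(d / "processed_observations.csv"),
            bias_adjusted_observations=pd.read_csv(d / "bias_adjusted_observations.csv"),
            division_code=manifest.get("division_code"),
            is_in_union=manifest.get("is_in_union"),
            accept_rate=manifest.get("accept_rate"),
        )


#: Natural-scale names under which top-level draws are stored.
TOP_LEVEL_NAMES_NATURAL = (
    "Ptilde", "pace_P", "Omega_P", "Rtilde", "pace_R", "Omega_R", "alpha",
)


def _to_natural(theta_head: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "Ptilde": inv_logit(theta_head[..., 0]),
        "pace_P": np.exp(theta_head[..., 1]),
        "Omega_P": theta_head[..., 2],
        "Rtilde": inv_logit(theta_head[..., 3]),
        "pace_R": np.exp(theta_head[..., 4]),
        "Omega_R": theta_head[..., 5],
        "alpha": theta_head[..., 6],
    }


# ----------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ----------------------------------------------------------------------

def _leapfrog(theta, p, grad, step, n_steps, inv_mass, logp_grad):
    p = p + 0.5 * step * grad
    for i in range(n_steps):
        theta = theta + step * inv_mass * p
        lp, grad = logp_grad(theta)
        if not np.isfinite(lp):
            return theta, p, lp, grad
        p = p + (step if i < n_steps - 1 else 0.5 * step) * grad
    return theta, p, lp, grad


def _hmc_chain(logp_grad, theta0, n_warmup, n_kept, rng, *,
               n_leapfrog=12, target_accept=0.85, inv_mass0=None):
    """One HMC chain; returns (kept draws, mean acceptance prob)."""
    dim = theta0.size
    theta = theta0.copy()
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log-posterior at the initial point")

    inv_mass = np.ones(dim) if inv_mass0 is None else inv_mass0.copy()
    step = 0.1
    # dual averaging (Hoffman & Gelman constants)
    mu_da = np.log(10.0 * step)
    log_step_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    win_lo, win_hi = int(0.25 * n_warmup), int(0.75 * n_warmup)
    window: list[np.ndarray] = []
    draws = np.empty((n_kept, dim))
    accept_sum = 0.0

    total = n_warmup + n_kept
    for i in range(total):
        warming = i < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        n_steps = int(rng.integers(max(1, n_leapfrog - 3), n_leapfrog + 4))
        h0 = lp - 0.5 * np.dot(p0 * p0, inv_mass)
        theta_new, p_new, lp_new, grad_new = _leapfrog(
            theta, p0, grad, step, n_steps, inv_mass, logp_grad)
        if np.isfinite(lp_new):
            h1 = lp_new - 0.5 * np.dot(p_new * p_new, inv_mass)
            alpha = min(1.0, np.exp(min(0.0, h1 - h0)))
        else:
            alpha = 0.0
        if rng.random() < alpha:
            theta, lp, grad = theta_new, lp_new, grad_new

        if warming:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - alpha)
            log_step = mu_da - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_step_bar = eta * log_step + (1.0 - eta) * log_step_bar
            step = float(np.exp(log_step))
            if win_lo <= i < win_hi:
                window.append(theta.copy())
            if i == win_hi - 1 and len(window) >= 10:
                w = np.asarray(window)
                var = w.var(axis=0, ddof=1)
                k = w.shape[0]
                # Stan-style shrinkage of the diagonal metric
                inv_mass = (k / (k + 5.0)) * var + 1e-3 * (5.0 / (k + 5.0))
                # restart step-size adaptation around the current value
                mu_da = np.log(10.0 * step)
                h_bar = 0.0
                log_step_bar = np.log(step)
                adapt_count = 0
            if i == n_warmup - 1:
                step = float(np.exp(log_step_bar))
        else:
            accept_sum += alpha
            draws[i - n_warmup] = theta
    return draws, accept_sum / max(n_kept, 1)


def _prior_scale_metric(ctx: ModelContext) -> np.ndarray:
    """Diagonal inverse metric seeded at the prior marginal variances.

    Parameters live on very different scales (timing parameters are
    calendar years with SD ~8; distortions have SD ~0.1), so starting
    the mass matrix from the prior variances lets warmup adaptation
    begin in roughly the right geometry instead of discovering four
    orders of magnitude from scratch.
    """
    inv_mass = np.empty(ctx.dim)
    inv_mass[:7] = ctx.sd**2
    n = ctx.n_years
    for k in range(3):
        inv_mass[7 + k * n:7 + (k + 1) * n] = ctx.sigma[k] ** 2
    return inv_mass


def _initial_point(ctx: ModelContext, rng) -> np.ndarray:
    theta = np.empty(ctx.dim)
    theta[:7] = ctx.mu + 0.1 * ctx.sd * rng.standard_normal(7)
    n = ctx.n_years
    for k in range(3):
        theta[7 + k * n:7 + (k + 1) * n] = (
            0.1 * ctx.sigma[k] * rng.standard_normal(n)
        )
    return theta


def fit_model(obs: list[SurveyObservation], gp: GlobalParameters,
              level_key: int, config: FitConfig) -> FitResult:
    """Sample the single-population posterior by MCMC.

    ``obs`` must already be filtered to one population and be
    SE-complete (see :func:`fplocal.data_io.impute_sampling_errors`).
    Zero observations is legal: the fit then samples the prior.
    Identical inputs and seed give identical draws.
    """
    config.validate()
    grid = _model.make_grid(config.first_year, config.last_year, obs)
    ctx = build_context(obs, gp, level_key, grid)

    def logp_grad(theta):
        return _model.log_posterior_and_grad(theta, ctx)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.chains + 1)
    init_rng = np.random.default_rng(chain_seeds[-1])

    chains_out = []
    accept = []
    for c in range(config.chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta0 = None
        for _attempt in range(10):
            cand = _initial_point(ctx, init_rng)
            if np.isfinite(logp_grad(cand)[0]):
                theta0 = cand
                break
        if theta0 is None:
            raise FloatingPointError(
                "could not find a finite log-posterior initial point after 10 jitters"
            )
        draws, acc = _hmc_chain(
            logp_grad, theta0, config.warmup_iterations, config.kept_iterations, rng,
            inv_mass0=_prior_scale_metric(ctx))
        chains_out.append(draws)
        accept.append(acc)

    theta_draws = np.stack(chains_out)             # (chains, kept, dim)
    n = ctx.n_years
    draws = {k: np.ascontiguousarray(v) for k, v in _to_natural(theta_draws[..., :7]).items()}
    eps = {
        "eps_P": theta_draws[..., 7:7 + n],
        "eps_R": theta_draws[..., 7 + n:7 + 2 * n],
        "eps_Z": theta_draws[..., 7 + 2 * n:],
    }
    trajectories = _derive_trajectories(theta_draws, ctx)
    processed, adjusted = _core_data_tables(obs, gp)
    division = obs[0].division_code if obs else None
    union = obs[0].is_in_union if obs else None
    return FitResult(
        draws=draws, eps=eps, trajectories=trajectories, grid=grid,
        config=config, level_key=int(level_key),
        processed_observations=processed, bias_adjusted_observations=adjusted,
        division_code=division, is_in_union=union,
        accept_rate=float(np.mean(accept)),
    )


def _derive_trajectories(theta_draws: np.ndarray, ctx: ModelContext) -> dict[str, np.ndarray]:
    from scipy.special import expit

    n = ctx.n_years
    Pt = expit(theta_draws[..., 0:1])
    paceP = np.exp(theta_draws[..., 1:2])
    OmP = theta_draws[..., 2:3]
    Rt = expit(theta_draws[..., 3:4])
    paceR = np.exp(theta_draws[..., 4:5])
    OmR = theta_draws[..., 5:6]
    alpha = theta_draws[..., 6:7]
    epsP = theta_draws[..., 7:7 + n]
    epsR = theta_draws[..., 7 + n:7 + 2 * n]
    epsZ = theta_draws[..., 7 + 2 * n:]
    grid = ctx.grid
    P = Pt * expit(paceP * (grid - OmP) + epsP)
    R = Rt * expit(paceR * (grid - OmR) + epsR)
    Z = (1.0 - P) * expit(alpha + ctx.beta * P + epsZ)
    M = P * R
    return {"P": P, "R": R, "Z": Z, "M": M, "T": P - M}


def _core_data_tables(obs: list[SurveyObservation], gp: GlobalParameters):
    """Processed and bias-adjusted observation tables (core data)."""
    processed_rows, adjusted_rows = [], []
    for i, ob in enumerate(obs):
        base = {
            "obs_id": i,
            "division_numeric_code": ob.division_code,
            "is_in_union": ob.is_in_union,
            "data_series_type": ob.source_type,
            "reference_time": ob.reference_time,
            "sample_mismatch": ob.sample_mismatch,
        }
        prow = dict(base)
        arow = dict(base)
        for comp, y_c, logit_y, bias, var, clamped in _model.observation_terms(ob, gp):
            prow[f"prop_{comp}"] = y_c
            prow[f"se_{comp}"] = ob.standard_error(comp)
            prow[f"logit_variance_{comp}"] = var
            prow[f"clamped_{comp}"] = clamped
            arow[f"prop_{comp}_adjusted"] = float(inv_logit(logit_y - bias))
        processed_rows.append(prow)
        adjusted_rows.append(arow)
    base_cols = ["obs_id", "division_numeric_code", "is_in_union",
                 "data_series_type", "reference_time", "sample_mismatch"]
    processed = pd.DataFrame(processed_rows, columns=base_cols if not processed_rows else None)
    adjusted = pd.DataFrame(adjusted_rows, columns=base_cols if not adjusted_rows else None)
    return processed, adjusted


# ----------------------------------------------------------------------
# Convergence diagnostics
# ----------------------------------------------------------------------

@dataclass
class Diagnostics:
    """Split-chain R-hat and effective sample size per scalar parameter."""

    table: pd.DataFrame       # columns: parameter, rhat, ess
    converged: bool

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        status = "converged" if self.converged else "NOT converged"
        return f"<Diagnostics: {len(self.table)} parameters, {status}>"


RHAT_THRESHOLD = 1.1


def convergence_diagnostics(fit: FitResult) -> Diagnostics:
    """Split-chain potential scale reduction and ESS for the top-level
    parameters; the overall flag is true iff every finite R-hat < 1.1.

    Degenerate (constant) chains yield NaN R-hat/ESS rather than an
    error; NaNs are excluded from the convergence flag.
    """
    import arviz as az

    if fit.config.chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    rows = []
    for name in TOP_LEVEL_NAMES_NATURAL:
        arr = fit.draws[name]
        with np.errstate(all="ignore"):
            if np.allclose(arr, arr.flat[0]):
                rhat, ess = float("nan"), float("nan")
            else:
                data = az.convert_to_dataset(arr[:, :, None].transpose(0, 1, 2)[:, :, 0])
                rhat = float(az.rhat(data)["x"].values)
                ess = float(az.ess(data)["x"].values)
        rows.append({"parameter": name, "rhat": rhat, "ess": ess})
    table = pd.DataFrame(rows)
    finite = table["rhat"].dropna()
    converged = bool((finite < RHAT_THRESHOLD).all()) and len(finite) > 0
    return Diagnostics(table=table, converged=converged)


def trace_plots(fit: FitResult, directory: str | Path) -> list[Path]:
    """Write one trace-plot image per top-level parameter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in TOP_LEVEL_NAMES_NATURAL:
        fig, ax = plt.subplots(figsize=(7, 3))
        for c in range(fit.config.chains):
            ax.plot(fit.draws[name][c], lw=0.6, alpha=0.8, label=f"chain {c}")
        ax.set_title(name)
        ax.set_xlabel("kept iteration")
        ax.legend(fontsize=7)
        out = d / f"trace_{name}.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        paths.append(out)
    return paths
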