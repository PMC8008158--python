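"""Core domain types shared across the package.

The model tracks three latent components for one population of women
(a division crossed with a union status): total contraceptive use P,
the modern share of use R, and unmet need Z.  Everything that is *not*
specific to the population being fitted — prior means and spreads,
AR(1) smoothing parameters, source-type biases and non-sampling error
SDs — is fixed in a :class:`GlobalParameters` fixture obtained from a
previous multi-country model run (or generated synthetically).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

SOURCE_TYPES = ("DHS", "MICS", "NATIONAL", "OTHER")
COMPONENTS = ("modern", "traditional", "unmet")
UNION_STATUSES = ("Y", "N")

#: Default quantile probabilities: median plus the 80% and 95% bands.
DEFAULT_QUANTILE_PROBS = (0.025, 0.10, 0.50, 0.90, 0.975)


@dataclass
class SurveyObservation:
    """One survey-based estimate of family-planning proportions.

    Proportions and standard errors are on the proportion scale; a
    value of ``None`` means missing.  ``sample_mismatch`` flags surveys
    whose sample population differs from the target group (women aged
    15-49 of the given union status); such observations receive extra
    non-sampling variance in the likelihood.
    """

    division_code: int
    start_date: float
    end_date: float
    is_in_union: str
    source_type: str
    prop_modern: float | None = None
    prop_traditional: float | None = None
    prop_unmet: float | None = None
    se_modern: float | None = None
    se_traditional: float | None = None
    se_unmet: float | None = None
    age_range: str = "15-49"
    sample_mismatch: bool = False

    @property
    def reference_time(self) -> float:
        """Survey reference time: midpoint of the fieldwork period."""
        return 0.5 * (self.start_date + self.end_date)

    def proportion(self, component: str) -> float | None:
        return getattr(self, f"prop_{_short(component)}")

    def standard_error(self, component: str) -> float | None:
        return getattr(self, f"se_{_short(component)}")

    def validate(self) -> None:
        if self.is_in_union not in UNION_STATUSES:
            raise ValueError(f"is_in_union must be one of {UNION_STATUSES}, got {self.is_in_union!r}")
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source_type {self.source_type!r}")
        if self.start_date > self.end_date:
            raise ValueError(f"start_date {self.start_date} exceeds end_date {self.end_date}")
        props = [self.prop_modern, self.prop_traditional, self.prop_unmet]
        for name, p in zip(COMPONENTS, props):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"proportion {name}={p} outside [0, 1]")
        if all(p is None for p in props):
            raise ValueError("all three proportions missing")
        if self.prop_modern is not None and self.prop_traditional is not None:
            if self.prop_modern + self.prop_traditional > 1.0 + 1e-9:
                raise ValueError("modern + traditional use exceeds 1")
            if self.prop_unmet is not None and (
                self.prop_modern + self.prop_traditional + self.prop_unmet > 1.0 + 1e-9
            ):
                raise ValueError("modern + traditional + unmet exceeds 1")
        for name in COMPONENTS:
            se = self.standard_error(name)
            if se is not None and se < 0:
                raise ValueError(f"se_{_short(name)}={se} is negative")


def _short(component: str) -> str:
    return {"modern": "modern", "traditional": "traditional", "unmet": "unmet"}[component]


@dataclass(frozen=True)
class PopulationCount:
    """Number of women in one (division, year, union status) cell."""

    division_code: int
    year: int
    is_in_union: str
    n_women: float

    def validate(self) -> None:
        if self.n_women < 0:
            raise ValueError(f"n_women={self.n_women} is negative")
        if self.is_in_union not in UNION_STATUSES:
            raise ValueError(f"is_in_union must be one of {UNION_STATUSES}")


@dataclass(frozen=True)
class Division:
    """A population's geographic unit, nested in subregion and region.

    In a subnational table each subnation is listed as a division whose
    subregion code is the code of its parent nation.
    """

    division_code: int
    name: str
    subregion_code: int
    region_code: int


@dataclass(frozen=True)
class LevelPriors:
    """Normal prior moments for the seven population-level parameters.

    Scales: ``logit_Ptilde``/``logit_Rtilde`` are logit-transformed
    asymptotes, ``log_pace_*`` are log rates (per year), ``Omega_*``
    are calendar years (inflection timing), ``alpha`` is the unmet-need
    level on the logit scale.
    """

    mu_logit_Ptilde: float
    sd_logit_Ptilde: float
    mu_log_pace_P: float
    sd_log_pace_P: float
    mu_Omega_P: float
    sd_Omega_P: float
    mu_logit_Rtilde: float
    sd_logit_Rtilde: float
    mu_log_pace_R: float
    sd_log_pace_R: float
    mu_Omega_R: float
    sd_Omega_R: float
    mu_alpha: float
    sd_alpha: float

    def means(self) -> np.ndarray:
        return np.array([
            self.mu_logit_Ptilde, self.mu_log_pace_P, self.mu_Omega_P,
            self.mu_logit_Rtilde, self.mu_log_pace_R, self.mu_Omega_R,
            self.mu_alpha,
        ])

    def sds(self) -> np.ndarray:
        return np.array([
            self.sd_logit_Ptilde, self.sd_log_pace_P, self.sd_Omega_P,
            self.sd_logit_Rtilde, self.sd_log_pace_R, self.sd_Omega_R,
            self.sd_alpha,
        ])


#: Order of the seven top-level parameters in flattened vectors.
TOP_LEVEL_NAMES = (
    "logit_Ptilde", "log_pace_P", "Omega_P",
    "logit_Rtilde", "log_pace_R", "Omega_R",
    "alpha",
)


@dataclass
class GlobalParameters:
    """All fixed non-population-specific parameters.

    ``levels`` maps a prior-level key (a subregion code, or a country
    code in subnational mode) to the Normal prior moments of the seven
    population-level parameters.  ``bias`` and ``tau`` map
    (source type, component) to an additive logit-scale bias and a
    logit-scale non-sampling SD; DHS is the reference source type with
    zero bias.  ``beta`` is the fixed slope of unmet need on total use.
    """

    levels: dict[int, LevelPriors]
    beta: float
    rho_P: float
    sigma_P: float
    rho_R: float
    sigma_R: float
    rho_Z: float
    sigma_Z: float
    bias: dict[str, dict[str, float]]
    tau: dict[str, dict[str, float]]
    tau_mismatch: float

    def validate(self) -> None:
        if not self.levels:
            raise ValueError("fixture defines no prior levels")
        for key, lp in self.levels.items():
            for sd in lp.sds():
                if not sd > 0:
                    raise ValueError(f"non-positive prior SD at level {key}")
        for rho in (self.rho_P, self.rho_R, self.rho_Z):
            if not abs(rho) < 1:
                raise ValueError(f"|rho| must be < 1, got {rho}")
        for sigma in (self.sigma_P, self.sigma_R, self.sigma_Z):
            if not sigma > 0:
                raise ValueError(f"sigma must be > 0, got {sigma}")
        for s in SOURCE_TYPES:
            for c in COMPONENTS:
                if self.tau[s][c] < 0:
                    raise ValueError(f"tau[{s},{c}] negative")
        for c in COMPONENTS:
            if self.bias["DHS"][c] != 0.0:
                raise ValueError("DHS is the reference source type; its bias must be 0")
        if self.tau_mismatch < 0:
            raise ValueError("tau_mismatch negative")

    def prior(self, level_key: int) -> LevelPriors:
        try:
            return self.levels[int(level_key)]
        except KeyError:
            raise KeyError(
                f"prior level {level_key} not in fixture (available: {sorted(self.levels)})"
            ) from None

    # -- fixture (de)serialization: hierarchical JSON ------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "levels": {str(k): asdict(v) for k, v in sorted(self.levels.items())},
            "shared": {
                "beta": self.beta,
                "rho_P": self.rho_P, "sigma_P": self.sigma_P,
                "rho_R": self.rho_R, "sigma_R": self.sigma_R,
                "rho_Z": self.rho_Z, "sigma_Z": self.sigma_Z,
                "bias": self.bias,
                "tau": self.tau,
                "tau_mismatch": self.tau_mismatch,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GlobalParameters":
        payload = json.loads(Path(path).read_text())
        shared = payload["shared"]
        gp = cls(
            levels={int(k): LevelPriors(**v) for k, v in payload["levels"].items()},
            beta=shared["beta"],
            rho_P=shared["rho_P"], sigma_P=shared["sigma_P"],
            rho_R=shared["rho_R"], sigma_R=shared["sigma_R"],
            rho_Z=shared["rho_Z"], sigma_Z=shared["sigma_Z"],
            bias={s: dict(v) for s, v in shared["bias"].items()},
            tau={s: dict(v) for s, v in shared["tau"].items()},
            tau_mismatch=shared["tau_mismatch"],
        )
        gp.validate()
        return gp


@dataclass
class FitConfig:
    """Settings of one model fit."""

    first_year: int = 1970
    last_year: int = 2030
    chains: int = 4
    warmup_iterations: int = 1000
    kept_iterations: int = 1000
    seed: int = 0
    subnational: bool = False
    quantile_probs: tuple[float, ...] = DEFAULT_QUANTILE_PROBS

    def validate(self) -> None:
        if self.first_year > self.last_year:
            raise ValueError("first_year exceeds last_year")
        if self.chains < 1 or self.warmup_iterations < 1 or self.kept_iterations < 1:
            raise ValueError("chains and iteration counts must be positive")
        probs = self.quantile_probs
        if not all(0 < p < 1 for p in probs) or any(
            b <= a for a, b in zip(probs, probs[1:])
        ):
            raise ValueError("quantile_probs must be strictly increasing in (0, 1)")


@dataclass
class PopulationParameters:
    """The population-specific unknowns of one fit.

    Asymptotes live in (0, 1), paces are rates per year (> 0), Omegas
    are calendar years.  ``eps_*`` hold one AR(1) distortion per grid
    year for total use, modern share and unmet need respectively.
    """

    Ptilde: float
    Omega_P: float
    pace_P: float
    Rtilde: float
    Omega_R: float
    pace_R: float
    alpha: float
    eps_P: np.ndarray
    eps_R: np.ndarray
    eps_Z: np.ndarray

    def validate(self, grid_length: int | None = None) -> None:
        if not (0 < self.Ptilde < 1 and 0 < self.Rtilde < 1):
            raise ValueError("asymptotes must lie strictly in (0, 1)")
        if not (self.pace_P > 0 and self.pace_R > 0):
            raise ValueError("pace parameters must be positive")
        n = len(self.eps_P)
        if not (len(self.eps_R) == n and len(self.eps_Z) == n):
            raise ValueError("distortion series lengths differ")
        if grid_length is not None and n != grid_length:
            raise ValueError("distortion series length does not match the grid")


@dataclass
class Trajectories:
    """Latent indicator trajectories on an annual grid (all proportions)."""

    grid: np.ndarray          # consecutive integer years
    P: np.ndarray             # total contraceptive use
    R: np.ndarray             # modern share of use
    Z: np.ndarray             # unmet need
    M: np.ndarray             # modern use = P * R
    T: np.ndarray             # traditional use = P * (1 - R)

    def year_index(self, t: float) -> int:
        """Map a decimal year to its nearest grid index (ties round down)."""
        year = math.ceil(t - 0.5)
        idx = year - int(self.grid[0])
        if not (0 <= idx < len(self.grid)):
            raise ValueError(f"time {t} falls outside the estimation grid")
        return idx


@dataclass
class TrajectoryDraws:
    """Posterior draws of the base proportions, one row per draw.

    The common currency of the post-processing modules: indicator
    calculation, union-status combination and multi-population
    aggregation all consume and produce this shape.  ``n_women`` is the
    per-year population size used to scale proportions to user counts
    (``None`` when counts were not supplied).
    """

    grid: np.ndarray
    M: np.ndarray             # (n_draws, n_years)
    T: np.ndarray
    Z: np.ndarray
    n_women: np.ndarray | None = None
    division: str | int | None = None
    is_in_union: str | None = None

    @property
    def n_draws(self) -> int:
        return self.M.shape[0]
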