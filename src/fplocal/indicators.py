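"""Derived family-planning indicators and their credible intervals.

All derived quantities — including ratio indicators such as demand
satisfied — are computed per posterior draw and only then summarized
into quantiles, so posterior uncertainty propagates correctly (the
quantile of a ratio is not the ratio of quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import DEFAULT_QUANTILE_PROBS, PopulationCount, TrajectoryDraws

#: Indicators measured as proportions of women.
PROPORTION_INDICATORS = (
    "modern", "traditional", "total_use", "unmet_need", "non_use",
    "total_demand", "demand_satisfied", "demand_satisfied_modern",
    "unmet_need_modern", "no_need",
)
#: Indicators measured as counts of women (require population counts).
COUNT_INDICATORS = (
    "users_modern", "users_traditional", "users_total", "women_with_unmet_need",
)
ALL_INDICATORS = PROPORTION_INDICATORS + COUNT_INDICATORS


def population_series(counts: Sequence[PopulationCount], division_code, is_in_union: str,
                      years) -> np.ndarray:
    """Number of women per requested year for one population.

    Counts are taken for the exact calendar year — no interpolation; a
    missing year is an error.
    """
    table = {
        pc.year: pc.n_women
        for pc in counts
        if pc.division_code == division_code and pc.is_in_union == is_in_union
    }
    out = np.empty(len(years), dtype=float)
    for j, y in enumerate(years):
        if int(y) not in table:
            raise KeyError(
                f"no population count for division {division_code}, "
                f"union {is_in_union!r}, year {int(y)}"
            )
        out[j] = table[int(y)]
    return out


def indicator_draws(draws: TrajectoryDraws) -> dict[str, np.ndarray]:
    """Per-draw, per-year values of every derivable indicator.

    Count indicators are included only when ``draws.n_women`` is set.
    ``unmet_need_modern`` is the unmet need for *modern* methods
    (women with unmet need plus traditional users); ``no_need`` is
    non-use minus unmet need.
    """
    M, T, Z = draws.M, draws.T, draws.Z
    total_use = M + T
    total_demand = total_use + Z
    out = {
        "modern": M,
        "traditional": T,
        "total_use": total_use,
        "unmet_need": Z,
        "non_use": 1.0 - total_use,
        "total_demand": total_demand,
        "demand_satisfied": np.divide(
            total_use, total_demand,
            out=np.zeros_like(total_use), where=total_demand > 0),
        "demand_satisfied_modern": np.divide(
            M, total_demand, out=np.zeros_like(M), where=total_demand > 0),
        "unmet_need_modern": Z + T,
        "no_need": 1.0 - total_use - Z,
    }
    if draws.n_women is not None:
        w = np.asarray(draws.n_women, dtype=float)
        out["users_modern"] = M * w
        out["users_traditional"] = T * w
        out["users_total"] = total_use * w
        out["women_with_unmet_need"] = Z * w
    return out


@dataclass
class IndicatorEstimates:
    """Per-year quantiles of each indicator, in long format.

    ``table`` has columns (indicator, year, percentile, value) where
    ``percentile`` is the quantile probability.  Proportion indicators
    are dimensionless; ``users_*`` and ``women_with_unmet_need`` are
    counts of women.
    """

    table: pd.DataFrame
    division: str | int | None = None
    is_in_union: str | None = None

    def values(self, indicator: str, percentile: float) -> pd.Series:
        sub = self.table[
            (self.table["indicator"] == indicator)
            & (np.isclose(self.table["percentile"], percentile))
        ]
        return sub.set_index("year")["value"]

    @property
    def indicators(self) -> list[str]:
        return list(dict.fromkeys(self.table["indicator"]))

    @property
    def percentiles(self) -> list[float]:
        return sorted(self.table["percentile"].unique())

    def write_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "is_in_union", self.is_in_union)
        out.insert(0, "division_numeric_code", self.division)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "IndicatorEstimates":
        df = pd.read_csv(path)
        division = df["division_numeric_code"].iloc[0] if len(df) else None
        union = df["is_in_union"].iloc[0] if len(df) else None
        table = df.drop(columns=["division_numeric_code", "is_in_union"])
        return cls(table=table, division=division, is_in_union=union)


def summarize_quantiles(draw_values: dict[str, np.ndarray], years,
                        probs: Sequence[float] = DEFAULT_QUANTILE_PROBS,
                        division=None, is_in_union=None) -> IndicatorEstimates:
    """Empirical quantiles of per-draw indicator values.

    Uses linear interpolation between closest order statistics (the
    type-7 convention, numpy's default).  The default probabilities
    give the median and the bounds of the 80% and 95% credible bands.
    """
    probs = list(probs)
    years = np.asarray(years)
    frames = []
    for name, vals in draw_values.items():
        if vals.shape[0] == 0:
            raise ValueError("no posterior draws to summarize")
        q = np.quantile(vals, probs, axis=0)           # (n_probs, n_years)
        frames.append(pd.DataFrame({
            "indicator": name,
            "year": np.tile(years, len(probs)),
            "percentile": np.repeat(probs, years.size),
            "value": q.ravel(),
        }))
    table = pd.concat(frames, ignore_index=True)
    return IndicatorEstimates(table=table, division=division, is_in_union=is_in_union)


def calculate_indicators(fit, counts: Sequence[PopulationCount] | None = None,
                         years=None, probs=None) -> IndicatorEstimates:
    """Full post-processing of one fit: draws -> indicators -> quantiles.

    ``years`` defaults to the fit's reporting window (first to last
    configured year).  Count indicators are produced when ``counts`` is
    given and must then cover every requested year.
    """
    draws = fit.trajectory_draws()
    if years is None:
        years = np.arange(fit.config.first_year, fit.config.last_year + 1)
    years = np.asarray(years)
    sel = np.searchsorted(draws.grid, years)
    if np.any(sel >= draws.grid.size) or np.any(draws.grid[sel] != years):
        raise ValueError("requested years outside the fitted grid")
    sub = TrajectoryDraws(
        grid=years, M=draws.M[:, sel], T=draws.T[:, sel], Z=draws.Z[:, sel],
        division=draws.division, is_in_union=draws.is_in_union,
    )
    if counts is not None:
        sub.n_women = population_series(counts, fit.division_code, fit.is_in_union, years)
    values = indicator_draws(sub)
    return summarize_quantiles(
        values, years, probs or fit.config.quantile_probs,
        division=fit.division_code, is_in_union=fit.is_in_union,
    )
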