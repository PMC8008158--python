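"""Combining fits across union statuses and across populations.

Aggregate proportions are population-weighted means of the component
proportions, with weights equal to the number of women in each
component population for the relevant year and union status; user
counts simply add.  Ratio indicators (demand satisfied and friends)
are always recomputed from the aggregated base proportions — never
averaged themselves.  Draws are paired by (chain, iteration) index
across fits; fits with different grids or draw counts are rejected.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datatypes import PopulationCount, TrajectoryDraws
from .indicators import population_series


def _check_compatible(draw_sets: Sequence[TrajectoryDraws]) -> None:
    ref = draw_sets[0]
    for ds in draw_sets[1:]:
        if ds.grid.size != ref.grid.size or np.any(ds.grid != ref.grid):
            raise ValueError("fits have mismatched estimation grids")
        if ds.n_draws != ref.n_draws:
            raise ValueError("fits have mismatched numbers of posterior draws")


def _weighted(draw_sets: Sequence[TrajectoryDraws], weights: list[np.ndarray],
              division, is_in_union) -> TrajectoryDraws:
    _check_compatible(draw_sets)
    w = np.asarray(weights, dtype=float)            # (k, n_years)
    total = w.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("total population weight is zero for some year")
    M = sum(wi * ds.M for wi, ds in zip(w, draw_sets)) / total
    T = sum(wi * ds.T for wi, ds in zip(w, draw_sets)) / total
    Z = sum(wi * ds.Z for wi, ds in zip(w, draw_sets)) / total
    return TrajectoryDraws(
        grid=draw_sets[0].grid.copy(), M=M, T=T, Z=Z, n_women=total,
        division=division, is_in_union=is_in_union,
    )


def combine_union_fits(fit_in, fit_not,
                       counts: Sequence[PopulationCount],
                       years=None) -> TrajectoryDraws:
    """All-women draws from paired in-union and not-in-union fits.

    Per draw d and year t each base proportion is
    ``(W_in * p_in + W_not * p_not) / (W_in + W_not)`` with W the
    number of women of each union status; user counts sum.  The result
    feeds :func:`fplocal.indicators.indicator_draws`, which recomputes
    ratio indicators from the aggregated bases.
    """
    if {fit_in.is_in_union, fit_not.is_in_union} != {"Y", "N"}:
        raise ValueError("expected one in-union ('Y') and one not-in-union ('N') fit")
    if fit_in.is_in_union == "N":
        fit_in, fit_not = fit_not, fit_in
    ds_in = _restrict(fit_in.trajectory_draws(), years)
    ds_not = _restrict(fit_not.trajectory_draws(), years)
    if fit_in.division_code != fit_not.division_code:
        raise ValueError("union-status fits refer to different divisions")
    yrs = ds_in.grid
    w_in = population_series(counts, fit_in.division_code, "Y", yrs)
    w_not = population_series(counts, fit_not.division_code, "N", yrs)
    return _weighted([ds_in, ds_not], [w_in, w_not],
                     division=fit_in.division_code, is_in_union="ALL")


def aggregate_populations(fits: Sequence,
                          counts: Sequence[PopulationCount] | None = None,
                          years=None, label="aggregate") -> TrajectoryDraws:
    """Aggregate several population fits into one set of draws.

    All fits must share the union status, grid and draw count, and
    refer to distinct divisions.  Base proportions are count-weighted
    means across populations (weights: women of the shared union status
    in each population); user counts sum.  A single fit aggregates to
    itself.

    Inputs may be fit results or already-aggregated
    :class:`~fplocal.datatypes.TrajectoryDraws` (which carry their own
    summed weights), so aggregation composes: combine union statuses
    per population first, then aggregate divisions, or aggregate in
    stages.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    unions = {_union_of(f) for f in fits}
    if len(unions) != 1:
        raise ValueError("fits mix union statuses; combine unions per population first")
    divisions = [_division_of(f) for f in fits]
    if len(set(divisions)) != len(divisions):
        raise ValueError(f"duplicate divisions among fits: {sorted(map(str, divisions))}")
    union = unions.pop()
    draw_sets = [_restrict(_as_draws(f), years) for f in fits]
    yrs = draw_sets[0].grid
    weights = []
    for f, ds in zip(fits, draw_sets):
        if ds.n_women is not None:
            weights.append(np.asarray(ds.n_women, dtype=float))
        elif counts is not None:
            weights.append(population_series(counts, _division_of(f), union, yrs))
        else:
            raise ValueError(
                f"population counts required for fit of division {_division_of(f)}"
            )
    return _weighted(draw_sets, weights, division=label, is_in_union=union)


def _as_draws(obj) -> TrajectoryDraws:
    return obj if isinstance(obj, TrajectoryDraws) else obj.trajectory_draws()


def _union_of(obj) -> str:
    return obj.is_in_union


def _division_of(obj):
    return obj.division if isinstance(obj, TrajectoryDraws) else obj.division_code


def _restrict(ds: TrajectoryDraws, years) -> TrajectoryDraws:
    if years is None:
        return ds
    years = np.asarray(years)
    sel = np.searchsorted(ds.grid, years)
    if np.any(sel >= ds.grid.size) or np.any(ds.grid[sel] != years):
        raise ValueError("requested years outside the fitted grid")
    return TrajectoryDraws(
        grid=years, M=ds.M[:, sel], T=ds.T[:, sel], Z=ds.Z[:, sel],
        n_women=None if ds.n_women is None else np.asarray(ds.n_women)[sel],
        division=ds.division, is_in_union=ds.is_in_union,
    )
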