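"""Plots of indicator estimates over the survey data they were fit to."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .datatypes import SurveyObservation
from .indicators import IndicatorEstimates, PROPORTION_INDICATORS

#: Which observed quantity backs each plottable indicator.
_OBS_COMPONENT = {
    "modern": "modern",
    "traditional": "traditional",
    "unmet_need": "unmet",
}

_BAND_DARK = "#54278f"    # 80% band
_BAND_LIGHT = "#cbc9e2"   # 95% band


def plot_estimates(
    estimates: IndicatorEstimates,
    obs: Sequence[SurveyObservation] = (),
    indicators: Sequence[str] = ("modern",),
    directory: str | Path = ".",
) -> list[Path]:
    """One image per indicator: median line, dark 80% and light 95%
    credible bands, survey observations with ±2 SE bars.

    Proportions are drawn on a [0, 1] axis.  Raises if an indicator is
    not present in the estimates.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    available = estimates.indicators
    probs = estimates.percentiles
    if len(probs) < 5:
        raise ValueError("estimates need the default five quantiles for band plots")
    outer_lo, inner_lo, mid, inner_hi, outer_hi = probs[0], probs[1], probs[len(probs) // 2], probs[-2], probs[-1]
    paths = []
    for name in indicators:
        if name not in available:
            raise KeyError(f"indicator {name!r} not in estimates; available: {available}")
        years = estimates.values(name, mid).index.to_numpy()
        fig, ax = plt.subplots(figsize=(7, 4.5))
        ax.fill_between(years, estimates.values(name, outer_lo), estimates.values(name, outer_hi),
                        color=_BAND_LIGHT, label="95% credible band")
        ax.fill_between(years, estimates.values(name, inner_lo), estimates.values(name, inner_hi),
                        color=_BAND_DARK, alpha=0.55, label="80% credible band")
        ax.plot(years, estimates.values(name, mid), color=_BAND_DARK, lw=1.5, label="median")
        comp = _OBS_COMPONENT.get(name)
        if comp is not None:
            for ob in obs:
                y = ob.proportion(comp)
                if y is None:
                    continue
                se = ob.standard_error(comp) or 0.0
                ax.errorbar(ob.reference_time, y, yerr=2 * se, fmt="o", ms=4,
                            color="black", capsize=2, lw=1)
        if name in PROPORTION_INDICATORS:
            ax.set_ylim(0, 1)
        ax.set_xlim(years.min(), years.max())
        ax.set_xlabel("year")
        ax.set_ylabel(name.replace("_", " "))
        ax.legend(fontsize=8, loc="upper left")
        out = d / f"{name}.png"
        fig.savefig(out, dpi=110, bbox_inches="tight")
        plt.close(fig)
        paths.append(out)
    return paths
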