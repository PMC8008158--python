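"""Reading, validating, filtering and completing the input datasets.

Three CSV inputs drive a fit: survey observations, population counts
and the division hierarchy.  All files are comma-separated UTF-8 with a
header row; an empty cell means missing.  Errors carry the 1-based data
row number (excluding the header) so a user can find the offending line.
"""

from __future__ import annotations

import math
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datatypes import (
    Division,
    PopulationCount,
    SOURCE_TYPES,
    SurveyObservation,
)

SURVEY_COLUMNS = [
    "division_numeric_code", "start_date", "end_date", "is_in_union",
    "age_range", "data_series_type", "sample_mismatch",
    "contraceptive_use_modern", "contraceptive_use_traditional",
    "unmet_need_any", "se_modern", "se_traditional", "se_unmet_need",
]
POPULATION_COLUMNS = ["division_numeric_code", "mid_year", "is_in_union", "population_count"]
DIVISION_COLUMNS = [
    "division_numeric_code", "name_country",
    "division_numeric_code_sub_region", "division_numeric_code_region",
]

#: Fallback SE used when a component has no observed SE at all.
DEFAULT_SE = 0.025
#: All sampling errors are floored here after imputation.
SE_FLOOR = 0.005

_TRUTHY = {"true", "t", "y", "yes", "1", "1.0"}
_FALSY = {"false", "f", "n", "no", "0", "0.0", ""}


def _opt_float(value, row: int, field: str, lo=None, hi=None) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: field {field!r} is not numeric: {value!r}") from None
    if lo is not None and x < lo or hi is not None and x > hi:
        raise ValueError(f"row {row}: field {field!r} value {x} outside allowed range")
    return x


def _parse_bool(value, row: int, field: str) -> bool:
    s = str(value).strip().lower()
    if isinstance(value, float) and math.isnan(value):
        return False
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"row {row}: field {field!r} is not a boolean: {value!r}")


def read_survey_data(path: str | Path) -> list[SurveyObservation]:
    """Read a survey-data CSV into a list of observations (file order).

    Rejects malformed rows loudly: proportions outside [0, 1], reversed
    date ranges, unknown source-type labels and rows with all three
    proportions missing each raise :class:`ValueError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey data file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey data missing columns: {missing}")
    out: list[SurveyObservation] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        source = str(rec["data_series_type"]).strip()
        if source not in SOURCE_TYPES:
            raise ValueError(f"row {i}: unknown source_type label {source!r}")
        ob = SurveyObservation(
            division_code=int(rec["division_numeric_code"]),
            start_date=float(rec["start_date"]),
            end_date=float(rec["end_date"]),
            is_in_union=str(rec["is_in_union"]).strip(),
            age_range=str(rec["age_range"]),
            source_type=source,
            sample_mismatch=_parse_bool(rec["sample_mismatch"], i, "sample_mismatch"),
            prop_modern=_opt_float(rec["contraceptive_use_modern"], i, "contraceptive_use_modern", 0, 1),
            prop_traditional=_opt_float(rec["contraceptive_use_traditional"], i, "contraceptive_use_traditional", 0, 1),
            prop_unmet=_opt_float(rec["unmet_need_any"], i, "unmet_need_any", 0, 1),
            se_modern=_opt_float(rec["se_modern"], i, "se_modern", 0),
            se_traditional=_opt_float(rec["se_traditional"], i, "se_traditional", 0),
            se_unmet=_opt_float(rec["se_unmet_need"], i, "se_unmet_need", 0),
        )
        try:
            ob.validate()
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
        out.append(ob)
    return out


def write_survey_data(obs: Iterable[SurveyObservation], path: str | Path) -> None:
    rows = []
    for ob in obs:
        rows.append({
            "division_numeric_code": ob.division_code,
            "start_date": ob.start_date,
            "end_date": ob.end_date,
            "is_in_union": ob.is_in_union,
            "age_range": ob.age_range,
            "data_series_type": ob.source_type,
            "sample_mismatch": ob.sample_mismatch,
            "contraceptive_use_modern": ob.prop_modern,
            "contraceptive_use_traditional": ob.prop_traditional,
            "unmet_need_any": ob.prop_unmet,
            "se_modern": ob.se_modern,
            "se_traditional": ob.se_traditional,
            "se_unmet_need": ob.se_unmet,
        })
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False)


def filter_observations(
    obs: Sequence[SurveyObservation], division_code: int, is_in_union: str
) -> list[SurveyObservation]:
    """Observations of one population, original order preserved."""
    return [
        ob for ob in obs
        if ob.division_code == division_code and ob.is_in_union == is_in_union
    ]


def impute_sampling_errors(
    obs: Sequence[SurveyObservation], default_se: float = DEFAULT_SE
) -> list[SurveyObservation]:
    """Complete missing sampling errors within one population's data.

    A missing SE for a component becomes the maximum *observed* SE for
    that component across ``obs`` (a conservative choice pooled over
    source types), or ``default_se`` if none is observed.  All SEs are
    then floored at ``SE_FLOOR`` so no observation claims implausible
    precision.  Observed SEs above the floor are left untouched, which
    makes the operation idempotent.
    """
    fills = {}
    for comp, attr in (("modern", "se_modern"), ("traditional", "se_traditional"), ("unmet", "se_unmet")):
        observed = [getattr(ob, attr) for ob in obs if getattr(ob, attr) is not None]
        fills[attr] = max(observed) if observed else default_se
    out = []
    for ob in obs:
        updates = {}
        for attr, fill in fills.items():
            se = getattr(ob, attr)
            se = fill if se is None else se
            updates[attr] = max(se, SE_FLOOR)
        out.append(replace(ob, **updates))
    return out


def read_population_counts(path: str | Path) -> list[PopulationCount]:
    """Read the population-count CSV; duplicates and negatives are errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"population data file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"population data missing columns: {missing}")
    out: list[PopulationCount] = []
    seen: set[tuple] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        pc = PopulationCount(
            division_code=int(rec["division_numeric_code"]),
            year=int(rec["mid_year"]),
            is_in_union=str(rec["is_in_union"]).strip(),
            n_women=float(rec["population_count"]),
        )
        try:
            pc.validate()
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
        key = (pc.division_code, pc.year, pc.is_in_union)
        if key in seen:
            raise ValueError(f"row {i}: duplicate population count for {key}")
        seen.add(key)
        out.append(pc)
    return out


def write_population_counts(counts: Iterable[PopulationCount], path: str | Path) -> None:
    rows = [{
        "division_numeric_code": pc.division_code,
        "mid_year": pc.year,
        "is_in_union": pc.is_in_union,
        "population_count": pc.n_women,
    } for pc in counts]
    pd.DataFrame(rows, columns=POPULATION_COLUMNS).to_csv(path, index=False)


def read_divisions(path: str | Path) -> list[Division]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"divisions file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in DIVISION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"divisions data missing columns: {missing}")
    out = []
    seen = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        code = int(rec["division_numeric_code"])
        if code in seen:
            raise ValueError(f"row {i}: duplicate division code {code}")
        seen.add(code)
        out.append(Division(
            division_code=code,
            name=str(rec["name_country"]),
            subregion_code=int(rec["division_numeric_code_sub_region"]),
            region_code=int(rec["division_numeric_code_region"]),
        ))
    return out


def write_divisions(divisions: Iterable[Division], path: str | Path) -> None:
    rows = [{
        "division_numeric_code": d.division_code,
        "name_country": d.name,
        "division_numeric_code_sub_region": d.subregion_code,
        "division_numeric_code_region": d.region_code,
    } for d in divisions]
    pd.DataFrame(rows, columns=DIVISION_COLUMNS).to_csv(path, index=False)


def resolve_prior_level(
    divisions: Sequence[Division], division_code: int, subnational: bool = False
) -> int:
    """Key under which the fixture stores this population's priors.

    In national mode this is the division's subregion code.  In
    subnational mode the divisions table lists each subnation as a
    "country" whose subregion column holds its parent nation, so the
    same lookup returns the parent country's code — the fixture for a
    subnational run is keyed by country rather than by subregion.
    """
    for d in divisions:
        if d.division_code == division_code:
            return d.subregion_code
    mode = "subnational" if subnational else "national"
    raise KeyError(f"unknown division code {division_code} ({mode} mode)")
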