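"""Survey/population/divisions readers, SE imputation, prior-level lookup."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

from fplocal import data_io
from fplocal.datatypes import Division, PopulationCount, SurveyObservation

SURVEY_HEADER = ",".join(data_io.SURVEY_COLUMNS)


def _survey_row(division=4, start=1999.0, end=2000.0, union="Y", age="15-49",
                source="DHS", mismatch="FALSE", pm="0.3", pt="0.1", pu="0.2",
                sm="0.01", st_="0.01", su="0.02"):
    return f"{division},{start},{end},{union},{age},{source},{mismatch},{pm},{pt},{pu},{sm},{st_},{su}"


def _write_survey(tmp_path, rows):
    p = tmp_path / "survey.csv"
    p.write_text(SURVEY_HEADER + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadSurveyData:
    def test_well_formed_rows_read_in_order(self, tmp_path):
        rows = [_survey_row(start=1990.0, end=1991.0),
                _survey_row(start=1995.5, end=1996.5, source="MICS"),
                _survey_row(start=2005.0, end=2005.0, union="N")]
        obs = data_io.read_survey_data(_write_survey(tmp_path, rows))
        assert len(obs) == 3
        assert [ob.start_date for ob in obs] == [1990.0, 1995.5, 2005.0]
        assert obs[1].source_type == "MICS"
        assert obs[0].reference_time == pytest.approx(1990.5)

    def test_proportion_out_of_range_names_row_and_field(self, tmp_path):
        path = _write_survey(tmp_path, [_survey_row(), _survey_row(pm="1.2")])
        with pytest.raises(ValueError, match="row 2.*contraceptive_use_modern"):
            data_io.read_survey_data(path)

    def test_empty_se_cell_reads_as_missing_not_zero(self, tmp_path):
        obs = data_io.read_survey_data(_write_survey(tmp_path, [_survey_row(sm="")]))
        assert obs[0].se_modern is None
        assert obs[0].se_traditional == 0.01

    def test_unknown_source_type_rejected(self, tmp_path):
        path = _write_survey(tmp_path, [_survey_row(source="CENSUS")])
        with pytest.raises(ValueError, match="row 1.*CENSUS"):
            data_io.read_survey_data(path)

    def test_reversed_dates_rejected(self, tmp_path):
        path = _write_survey(tmp_path, [_survey_row(start=2001.0, end=2000.0)])
        with pytest.raises(ValueError, match="row 1"):
            data_io.read_survey_data(path)

    def test_all_proportions_missing_rejected(self, tmp_path):
        path = _write_survey(tmp_path, [_survey_row(pm="", pt="", pu="")])
        with pytest.raises(ValueError, match="row 1"):
            data_io.read_survey_data(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            data_io.read_survey_data(tmp_path / "absent.csv")


def test_survey_round_trip(tmp_path, sim):
    """Writing observations to CSV and re-reading reproduces every field."""
    path = tmp_path / "rt.csv"
    data_io.write_survey_data(sim.observations, path)
    back = data_io.read_survey_data(path)
    assert len(back) == len(sim.observations)
    for a, b in zip(sim.observations, back):
        for f in dataclasses.fields(SurveyObservation):
            va, vb = getattr(a, f.name), getattr(b, f.name)
            if isinstance(va, float):
                assert vb == pytest.approx(va, rel=1e-12)
            else:
                assert va == vb


@given(
    divisions=st.lists(st.sampled_from([1, 4, 8]), min_size=0, max_size=12),
    unions=st.lists(st.sampled_from(["Y", "N"]), min_size=0, max_size=12),
)
def test_filter_is_subset_and_idempotent(divisions, unions):
    obs = [
        SurveyObservation(division_code=d, start_date=2000, end_date=2001,
                          is_in_union=u, source_type="DHS", prop_modern=0.2)
        for d, u in zip(divisions, unions)
    ]
    kept = data_io.filter_observations(obs, 4, "Y")
    assert all(ob.division_code == 4 and ob.is_in_union == "Y" for ob in kept)
    assert [id(o) for o in kept] == [id(o) for o in obs if o.division_code == 4 and o.is_in_union == "Y"]
    assert data_io.filter_observations(kept, 4, "Y") == kept


class TestImputeSamplingErrors:
    def _obs(self, **kw):
        base = dict(division_code=4, start_date=2000, end_date=2001, is_in_union="Y",
                    source_type="DHS", prop_modern=0.3, prop_traditional=0.1, prop_unmet=0.2)
        base.update(kw)
        return SurveyObservation(**base)

    def test_missing_becomes_max_observed(self):
        obs = [self._obs(se_modern=0.01), self._obs(se_modern=0.02), self._obs(se_modern=None)]
        out = data_io.impute_sampling_errors(obs)
        assert out[2].se_modern == pytest.approx(0.02)
        assert out[0].se_modern == pytest.approx(0.01)

    def test_default_when_none_observed(self):
        obs = [self._obs(), self._obs()]
        out = data_io.impute_sampling_errors(obs, default_se=0.025)
        assert all(ob.se_unmet == pytest.approx(0.025) for ob in out)

    def test_floor_applied_to_observed_values(self):
        out = data_io.impute_sampling_errors([self._obs(se_traditional=0.002)])
        assert out[0].se_traditional == pytest.approx(0.005)

    def test_idempotent_and_floored(self):
        obs = [self._obs(se_modern=0.001), self._obs(se_modern=None, se_unmet=0.04)]
        once = data_io.impute_sampling_errors(obs)
        twice = data_io.impute_sampling_errors(once)
        assert once == twice
        for ob in once:
            for comp in ("modern", "traditional", "unmet"):
                assert ob.standard_error(comp) >= data_io.SE_FLOOR


class TestPopulationCounts:
    def _write(self, tmp_path, rows):
        p = tmp_path / "pop.csv"
        p.write_text(",".join(data_io.POPULATION_COLUMNS) + "\n" + "\n".join(rows) + "\n")
        return p

    def test_reads_valid_rows(self, tmp_path):
        path = self._write(tmp_path, ["4,2015,Y,5e6", "4,2015,N,2e6"])
        counts = data_io.read_population_counts(path)
        assert counts == [
            PopulationCount(4, 2015, "Y", 5e6),
            PopulationCount(4, 2015, "N", 2e6),
        ]

    def test_duplicate_key_rejected(self, tmp_path):
        path = self._write(tmp_path, ["4,2015,Y,5e6", "4,2015,Y,6e6"])
        with pytest.raises(ValueError, match="row 2.*duplicate"):
            data_io.read_population_counts(path)

    def test_negative_count_rejected(self, tmp_path):
        path = self._write(tmp_path, ["4,2015,Y,-1"])
        with pytest.raises(ValueError, match="row 1"):
            data_io.read_population_counts(path)


class TestResolvePriorLevel:
    DIVS = [Division(4, "A", 34, 903), Division(356, "B", 921, 935),
            Division(9001, "A-state", 356, 935)]

    def test_national_mode_returns_subregion(self):
        assert data_io.resolve_prior_level(self.DIVS, 4, subnational=False) == 34

    def test_subnational_mode_returns_parent_country(self):
        # a subnation is listed as a "country" whose subregion is its nation
        assert data_io.resolve_prior_level(self.DIVS, 9001, subnational=True) == 356

    def test_unknown_code_errors(self):
        with pytest.raises(KeyError):
            data_io.resolve_prior_level(self.DIVS, 999, subnational=False)


def test_divisions_round_trip(tmp_path):
    divs = TestResolvePriorLevel.DIVS
    path = tmp_path / "div.csv"
    data_io.write_divisions(divs, path)
    assert data_io.read_divisions(path) == divs
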