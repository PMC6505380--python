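"""Profile/assay data model and CSV round-trip behaviour."""

import numpy as np
import pytest

from ddipk.errors import FormatError, ValidationError
from ddipk.profiles import (
    AssayTable,
    ConcentrationTimeProfile,
    read_assay_table,
    read_profiles,
    write_assay_table,
    write_profiles,
)
from conftest import make_profile


def _write_csv(path, rows, header="subject_id,analyte,group,dose_mg_per_kg,route,time_h,conc,conc_unit,blq"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path


class TestReadProfiles:
    def test_unit_scaling_ug_to_ng(self, tmp_path):
        p = _write_csv(
            tmp_path / "a.csv",
            [f"S1,mdz,vehicle,10,oral,{t},{c},ug/ml,0" for t, c in [(0.5, 1.2), (1, 2.4), (2, 1.0), (4, 0.3)]],
        )
        (prof,) = read_profiles(p, unit_policy="ng/ml")
        np.testing.assert_allclose(prof.concentrations, [1200.0, 2400.0, 1000.0, 300.0])
        assert prof.conc_unit == "ng/ml"

    def test_rows_sorted_by_time_and_length(self, tmp_path):
        times = [0.25, 0.5, 1, 2, 4, 8]
        rows = [f"S1,mdz,vehicle,10,oral,{t},{10 * t},ng/ml,0" for t in reversed(times)]
        (prof,) = read_profiles(_write_csv(tmp_path / "a.csv", rows))
        assert len(prof.times) == 6
        assert np.all(np.diff(prof.times) > 0)

    def test_blq_token_sets_flag_without_value(self, tmp_path):
        rows = [
            "S1,mdz,vehicle,10,oral,0.5,100,ng/ml,0",
            "S1,mdz,vehicle,10,oral,1,80,ng/ml,0",
            "S1,mdz,vehicle,10,oral,2,BLQ,ng/ml,0",
        ]
        (prof,) = read_profiles(_write_csv(tmp_path / "a.csv", rows))
        assert prof.blq_flags.tolist() == [False, False, True]
        assert np.isnan(prof.concentrations[2])

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject_id,analyte,group,dose_mg_per_kg,route,time_h,conc,conc_unit\nS1,m,v,1,oral,1,5,ng/ml\n")
        with pytest.raises(FormatError, match="blq"):
            read_profiles(p)

    @pytest.mark.parametrize(
        "bad_row, match",
        [
            ("S1,mdz,vehicle,10,oral,-1,5,ng/ml,0", "row 3.*time"),
            ("S1,mdz,vehicle,10,oral,3,-5,ng/ml,0", "row 3.*concentration"),
        ],
    )
    def test_negative_values_report_row_number(self, tmp_path, bad_row, match):
        rows = ["S1,mdz,vehicle,10,oral,1,5,ng/ml,0", bad_row]
        with pytest.raises(ValidationError, match=match):
            read_profiles(_write_csv(tmp_path / "a.csv", rows))

    def test_duplicate_sample_rejected(self, tmp_path):
        rows = [
            "S1,mdz,vehicle,10,oral,1,5,ng/ml,0",
            "S1,mdz,vehicle,10,oral,1,6,ng/ml,0",
        ]
        with pytest.raises(ValidationError, match="duplicate"):
            read_profiles(_write_csv(tmp_path / "a.csv", rows))

    def test_cassette_dosing_one_profile_per_subject_analyte(self, tmp_path):
        rows = [
            f"S1,{a},vehicle,10,oral,{t},{c},ng/ml,0"
            for a in ("midazolam", "caffeine")
            for t, c in [(0.5, 10), (1, 20), (2, 5)]
        ]
        profs = read_profiles(_write_csv(tmp_path / "a.csv", rows))
        assert {(p.subject_id, p.analyte) for p in profs} == {("S1", "midazolam"), ("S1", "caffeine")}


class TestWriteProfiles:
    def test_empty_collection_header_only(self, tmp_path):
        out = tmp_path / "out.csv"
        write_profiles([], out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("subject_id,")

    def test_two_point_profile_two_rows(self, tmp_path):
        out = tmp_path / "out.csv"
        write_profiles([make_profile([0.5, 1.0], [3.0, 1.5])], out)
        assert len(out.read_text().strip().splitlines()) == 3

    def test_round_trip_identity(self, tmp_path):
        profs = [
            make_profile([0.25, 0.5, 1, 2], [5.0, 11.0, 7.0, np.nan], blq=[0, 0, 0, 1]),
            make_profile([1, 2, 4], [0.9, 0.5, 0.1], subject_id="S2", conc_unit="ug/ml").to_unit("ng/ml"),
            make_profile([0.5, 8], [2.0, 0.03], subject_id="S3", analyte="caffeine", group="RIF"),
        ]
        out = tmp_path / "rt.csv"
        write_profiles(profs, out)
        back = read_profiles(out, unit_policy="ng/ml")
        assert sorted(back, key=lambda p: (p.subject_id, p.analyte)) == sorted(
            profs, key=lambda p: (p.subject_id, p.analyte)
        )

    def test_blq_token_survives_round_trip(self, tmp_path):
        out = tmp_path / "rt.csv"
        write_profiles([make_profile([1, 2], [5.0, np.nan], blq=[0, 1])], out)
        assert "BLQ" in out.read_text()
        (back,) = read_profiles(out)
        assert back.blq_flags.tolist() == [False, True]


class TestProfileInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(times=[1.0], concs=[5.0]),  # too short
            dict(times=[2.0, 1.0], concs=[1.0, 2.0]),  # not increasing
            dict(times=[-1.0, 1.0], concs=[1.0, 2.0]),  # negative time
            dict(times=[1.0, 2.0], concs=[1.0, -2.0]),  # negative conc
            dict(times=[1.0, 2.0], concs=[1.0, 2.0], dose=0.0),  # zero dose
            dict(times=[1.0, 2.0], concs=[1.0, 2.0], route="iv"),  # unknown route
        ],
    )
    def test_invalid_profiles_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_profile(kwargs.pop("times"), kwargs.pop("concs"), **kwargs)

    def test_unit_conversion_exact(self):
        p = make_profile([1, 2], [1.5, 0.25], conc_unit="ug/ml")
        q = p.to_unit("ng/ml")
        assert q.concentrations.tolist() == [1500.0, 250.0]
        assert q.to_unit("ug/ml") == p


class TestAssayTable:
    def test_round_trip(self, tmp_path):
        t = AssayTable(np.array([0.1, 0.5, 1.0, 5.0]), np.array([1.0, 3.0, 4.0, 4.8]))
        out = tmp_path / "assay.csv"
        write_assay_table(t, out)
        assert read_assay_table(out) == t

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            AssayTable(np.array([0.1, -0.5]), np.array([1.0, 2.0]))
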