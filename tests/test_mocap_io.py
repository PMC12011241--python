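"""Marker file and parameter-table IO."""

import numpy as np
import pandas as pd
import pytest

import gaitlat as gl
from gaitlat.errors import MocapFormatError, ValidationError
from gaitlat.mocap_io import MarkerCsvSchema


def tiny_mts(n=2, names=("head",)):
    rng = np.random.default_rng(5)
    markers = {m: rng.normal(0, 100, (n, 3)) for m in names}
    return gl.MarkerTrajectorySet(sampling_rate=120.0, markers=markers)


class TestTrc:
    def test_round_trip_identity(self, tmp_path):
        mts = tiny_mts()
        path = tmp_path / "t.trc"
        gl.write_trc(mts, path)
        back = gl.read_trc(path)
        assert back.sampling_rate == 120.0
        np.testing.assert_array_equal(back.markers["head"], mts.markers["head"])

    def test_metre_units_converted_once(self, tmp_path):
        path = tmp_path / "m.trc"
        lines = ["PathFileType\t4\t(X/Y/Z)\tm.trc",
                 "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
                 "120\t120\t1\t1\tm\t120\t1\t1",
                 "Frame#\tTime\thead\t\t",
                 "\t\tX1\tY1\tZ1", "",
                 "1\t0.0\t1.5\t0.0\t2.0"]
        path.write_text("\n".join(lines) + "\n")
        mts = gl.read_trc(path)
        assert mts.markers["head"][0, 0] == 1500.0
        assert mts.markers["head"][0, 2] == 2000.0

    def test_bad_column_count_is_format_error(self, tmp_path):
        path = tmp_path / "bad.trc"
        lines = ["PathFileType\t4\t(X/Y/Z)\tbad.trc",
                 "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
                 "120\t120\t1\t1\tmm\t120\t1\t1",
                 "Frame#\tTime\thead\t\t",
                 "\t\tX1\tY1\tZ1", "",
                 "1\t0.0\t1.0\t2.0\t3.0\t4.0"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(MocapFormatError, match="column count"):
            gl.read_trc(path)

    def test_missing_units_requires_override(self, tmp_path):
        path = tmp_path / "nounits.trc"
        lines = ["PathFileType\t4\t(X/Y/Z)\tnounits.trc",
                 "DataRate\tCameraRate\tNumFrames\tNumMarkers\tOrigDataRate",
                 "120\t120\t1\t1\t120",
                 "Frame#\tTime\thead\t\t",
                 "\t\tX1\tY1\tZ1", "",
                 "1\t0.0\t1.0\t2.0\t3.0"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(MocapFormatError, match="Units"):
            gl.read_trc(path)
        mts = gl.read_trc(path, units_override="mm")
        assert mts.markers["head"][0, 0] == 1.0

    def test_missing_samples_flagged_invalid(self, tmp_path):
        mts = tiny_mts(n=3)
        mts.valid["head"][1] = False
        path = tmp_path / "gap.trc"
        gl.write_trc(mts, path)
        back = gl.read_trc(path)
        assert not back.valid["head"][1]
        assert np.isnan(back.markers["head"][1]).all()
        assert back.valid["head"][[0, 2]].all()


class TestMarkerCsv:
    def test_generator_round_trip(self, tmp_path, fast_config):
        mts, _ = gl.generate_trial(fast_config, 0, "NB", "Normal", seed=1)
        path = tmp_path / "trial.csv"
        gl.write_marker_csv(mts, path)
        back = gl.read_marker_csv(path, MarkerCsvSchema(sampling_rate=120.0))
        back.require_markers()
        for m in gl.mocap_io.REQUIRED_MARKERS:
            np.testing.assert_allclose(back.markers[m], mts.markers[m])

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(MocapFormatError):
            gl.read_marker_csv(path, MarkerCsvSchema(sampling_rate=120.0))

    def test_missing_sampling_rate_is_error(self, tmp_path):
        path = tmp_path / "t.csv"
        gl.write_marker_csv(tiny_mts(names=gl.mocap_io.REQUIRED_MARKERS), path)
        with pytest.raises(MocapFormatError, match="sampling_rate"):
            gl.read_marker_csv(path, MarkerCsvSchema())

    def test_missing_column_lists_names(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame({"head_x": [1.0], "head_y": [2.0]}).to_csv(path, index=False)
        with pytest.raises(MocapFormatError, match="head_z"):
            gl.read_marker_csv(path, MarkerCsvSchema(sampling_rate=120.0,
                                                     markers=("head",)))


class TestParameterTable:
    @staticmethod
    def full_table(n=17, parameter="stride_time"):
        rows = [{"participant": f"P{p}", "sw": sw, "sp": sp, "segment": "-",
                 "parameter": parameter, "value": 1.0 + 0.01 * p}
                for p in range(n) for sw in ("NB", "WB")
                for sp in ("Normal", "Slow")]
        return pd.DataFrame(rows)

    def test_17_participants_4_conditions_gives_68_rows(self, tmp_path):
        path = tmp_path / "t.csv"
        self.full_table().to_csv(path, index=False)
        table = gl.read_parameter_table(path)
        assert len(table) == 68
        gl.check_complete_design(table)

    def test_duplicate_key_rejected(self, tmp_path):
        df = self.full_table(n=2)
        df = pd.concat([df, df.iloc[[0]]])
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="duplicate"):
            gl.read_parameter_table(path)

    def test_missing_cell_names_participant_and_condition(self, tmp_path):
        df = self.full_table(n=3)
        df = df[~((df.participant == "P1") & (df.sw == "WB") & (df.sp == "Slow"))]
        path = tmp_path / "inc.csv"
        df.to_csv(path, index=False)
        table = gl.read_parameter_table(path)
        with pytest.raises(ValidationError, match="P1.*WB.*Slow"):
            gl.check_complete_design(table)

    def test_level_synonyms_normalised(self, tmp_path):
        df = self.full_table(n=1)
        df["sw"] = ["narrow", "narrow", "wide", "wide"]
        df["sp"] = ["4.5", "2.2", "4.5", "2.2"]
        path = tmp_path / "syn.csv"
        df.to_csv(path, index=False)
        table = gl.read_parameter_table(path)
        assert set(table.sw) == {"NB", "WB"}
        assert set(table.sp) == {"Normal", "Slow"}

    def test_synthetic_summary_round_trip(self, tmp_path, fast_config):
        cohort = gl.generate_cohort(fast_config)
        path = tmp_path / "truth.csv"
        cohort.truth_table.to_csv(path, index=False)
        back = gl.read_parameter_table(path)
        merged = cohort.truth_table.merge(
            back, on=["participant", "sw", "sp", "segment", "parameter"])
        np.testing.assert_allclose(merged.value_x, merged.value_y)

    def test_xlsx_ingestion(self, tmp_path):
        path = tmp_path / "s1_style.xlsx"
        self.full_table(n=2).to_excel(path, index=False)
        table = gl.read_parameter_table(path)
        assert len(table) == 8


class TestWriteReports:
    def test_file_set_and_empty_pairwise_header(self, tmp_path):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, (5, 2, 2, 3))
        wa = gl.WithinAnova(y, {"sw": ("NB", "WB"), "sp": ("Normal", "Slow"),
                                "segment": ("head", "T4", "pelvis")})
        report = gl.decompose_interactions(wa)
        files = gl.write_reports(report, tmp_path)
        names = {f.name for f in files}
        assert {"anova.csv", "simple_interactions.csv", "simple_simple.csv",
                "pairwise.csv", "summary.json"} <= names
        pairwise = (tmp_path / "pairwise.csv").read_text().strip().splitlines()
        assert len(pairwise) >= 1  # header survives even with no rows
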