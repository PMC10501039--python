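"""Peak-table data model, I/O, quantifier selection, retention indices
and group summaries."""

import numpy as np
import pandas as pd
import pytest

from vocscreen.exceptions import (
    DuplicateRecordError,
    EmptyTableError,
    NoSignalError,
    PeakTableFormatError,
    RetentionRangeError,
)
from vocscreen.peak_model import (
    PeakTable,
    VOCSpecies,
    compute_retention_index,
    group_summary,
    read_peak_table,
    select_quantifier_ion,
    write_peak_table,
)

LONG_HEADER = "subject_id\tgroup\tvoc_id\tname\tcas\tretention_time_min\tmz\tfragment_area\ttic_area\n"


def _tiny_long(tmp_path, rows, name="tiny.tsv"):
    path = tmp_path / name
    path.write_text(LONG_HEADER + "".join(rows))
    return path


class TestVOCSpecies:
    def test_fragment_mz_must_lie_in_scan_range(self):
        with pytest.raises(ValueError, match="scan range"):
            VOCSpecies("x", "x", 10.0, (34,))
        with pytest.raises(ValueError, match="scan range"):
            VOCSpecies("x", "x", 10.0, (301,))

    def test_quantifier_must_be_a_fragment(self):
        with pytest.raises(ValueError, match="not a fragment"):
            VOCSpecies("x", "x", 10.0, (43, 57), quantifier_mz=99)

    def test_retention_time_positive(self):
        with pytest.raises(ValueError, match="retention time"):
            VOCSpecies("x", "x", 0.0, (43,))


class TestReadPeakTable:
    def test_hand_written_long_file_zero_fills_missing_cells(self, tmp_path):
        # 2 subjects x 2 VOCs, one (subject, voc) cell absent from the file
        rows = [
            "s1\tpositive\tv1\tVOC one\t\t10.0\t43\t100.0\t900.0\n",
            "s1\tpositive\tv2\tVOC two\t\t12.0\t57\t50.0\t400.0\n",
            "s2\tcontrol\tv1\tVOC one\t\t10.0\t43\t80.0\t700.0\n",
        ]
        table = read_peak_table(_tiny_long(tmp_path, rows))
        assert table.subject_ids == ["s1", "s2"]
        assert len(table.species) == 2
        # dense grid: 2 subjects x 2 single-fragment VOCs
        assert len(table.measurements) == 4
        assert table.fragment_areas("v2", 57).loc["s2"] == 0.0
        assert table.tic_areas("v2").loc["s2"] == 0.0
        assert not table.detected("v2").loc["s2"]

    def test_missing_column_is_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("subject_id\tgroup\tvoc_id\n")
        with pytest.raises(PeakTableFormatError, match="tic_area"):
            read_peak_table(path)

    def test_empty_data_section_raises(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(LONG_HEADER)
        with pytest.raises(EmptyTableError):
            read_peak_table(path)

    def test_duplicate_cell_raises(self, tmp_path):
        rows = [
            "s1\tpositive\tv1\tVOC one\t\t10.0\t43\t100.0\t900.0\n",
            "s1\tpositive\tv1\tVOC one\t\t10.0\t43\t101.0\t900.0\n",
            "s2\tcontrol\tv1\tVOC one\t\t10.0\t43\t80.0\t700.0\n",
        ]
        with pytest.raises(DuplicateRecordError):
            read_peak_table(_tiny_long(tmp_path, rows))

    def test_detection_floor_zeroes_small_areas(self, tmp_path):
        rows = [
            "s1\tpositive\tv1\tVOC one\t\t10.0\t43\t5.0\t900.0\n",
            "s2\tcontrol\tv1\tVOC one\t\t10.0\t43\t80.0\t700.0\n",
        ]
        table = read_peak_table(_tiny_long(tmp_path, rows), detection_floor=10.0)
        assert table.fragment_areas("v1", 43).loc["s1"] == 0.0


class TestRoundTrip:
    def test_long_roundtrip_is_identity_on_the_grid(self, tmp_path, fixture_table):
        path = tmp_path / "rt.tsv"
        write_peak_table(fixture_table, path)
        back = read_peak_table(path)
        key = ["subject_id", "voc_id", "mz"]
        a = fixture_table.measurements.sort_values(key).reset_index(drop=True)
        b = back.measurements.sort_values(key).reset_index(drop=True)
        assert (a["fragment_area"].to_numpy() == b["fragment_area"].to_numpy()).all()
        assert (a["tic_area"].to_numpy() == b["tic_area"].to_numpy()).all()
        assert back.subject_ids == fixture_table.subject_ids

    def test_fixture_dimensions_match_study_design(self, fixture_table):
        assert len(fixture_table.subject_ids) == 18
        assert len(fixture_table.species) == 157

    def test_wide_view_roundtrip(self, tmp_path, fixture_table):
        path = tmp_path / "wide.tsv"
        write_peak_table(fixture_table, path, format="wide")
        back = read_peak_table(path, format="wide")
        v = fixture_table.quantifier_areas("texanol")
        w = back.quantifier_areas("texanol")
        assert np.allclose(v.to_numpy(), w.to_numpy())


class TestQuantifierSelection:
    @staticmethod
    def _table(areas_by_mz):
        species = [VOCSpecies("v", "v", 10.0, tuple(areas_by_mz))]
        rows = []
        for mz, areas in areas_by_mz.items():
            for i, a in enumerate(areas):
                rows.append((f"s{i}", "v", mz, a, 1.0))
        subjects = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(next(iter(areas_by_mz.values()))))],
                "group": ["positive", "control"],
            }
        )
        meas = pd.DataFrame(
            rows, columns=["subject_id", "voc_id", "mz", "fragment_area", "tic_area"]
        )
        return species[0], PeakTable(species=species, subjects=subjects, measurements=meas)

    def test_largest_total_area_wins(self):
        sp, table = self._table({79: [300.0, 200.0], 94: [100.0, 200.0]})
        assert select_quantifier_ion(sp, table) == 79
        assert sp.quantifier_mz == 79

    def test_single_fragment_is_its_own_quantifier(self):
        sp, table = self._table({60: [1.0, 2.0]})
        assert select_quantifier_ion(sp, table) == 60

    def test_tie_breaks_toward_smaller_mz(self):
        sp, table = self._table({70: [50.0, 50.0], 55: [60.0, 40.0]})
        assert select_quantifier_ion(sp, table) == 55

    def test_all_zero_signal_raises(self):
        sp, table = self._table({60: [0.0, 0.0], 73: [0.0, 0.0]})
        with pytest.raises(NoSignalError):
            select_quantifier_ion(sp, table)

    def test_permutation_invariance_in_subject_order(self, fixture_table):
        sp = fixture_table.species_by_id["dimethyl_sulfone"]
        first = select_quantifier_ion(sp, fixture_table)
        shuffled = PeakTable(
            species=fixture_table.species,
            subjects=fixture_table.subjects.iloc[::-1],
            measurements=fixture_table.measurements,
        )
        assert select_quantifier_ion(sp, shuffled) == first == 79


class TestRetentionIndex:
    ALKANES = {10: 12.0, 11: 16.0, 12: 21.0}

    def test_anchor_points_are_exact(self):
        for c, t in self.ALKANES.items():
            assert compute_retention_index(t, self.ALKANES) == 100 * c

    def test_midpoint_and_quarter_interpolation(self):
        assert compute_retention_index(14.0, self.ALKANES) == pytest.approx(1050.0)
        assert compute_retention_index(13.0, self.ALKANES) == pytest.approx(1025.0)

    def test_monotone_in_rt(self):
        rts = np.linspace(12.0, 21.0, 40)
        ris = [compute_retention_index(t, self.ALKANES) for t in rts]
        assert all(b > a for a, b in zip(ris, ris[1:]))

    def test_out_of_range_raises(self):
        with pytest.raises(RetentionRangeError):
            compute_retention_index(11.0, self.ALKANES)
        with pytest.raises(RetentionRangeError):
            compute_retention_index(22.0, self.ALKANES)

    def test_non_increasing_alkanes_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            compute_retention_index(13.0, {10: 12.0, 11: 11.0})


class TestGroupSummary:
    @pytest.mark.parametrize(
        "ctrl_mean, pos_mean, fold_2dp",
        [
            # published cohort summaries recomputed from the printed means
            (3.667, 7.222, 1.97),  # frailty checklist
            (0.667, 3.556, 5.33),  # depression subdomain, self-report
            (1.000, 2.667, 2.67),  # depression subdomain, by others
        ],
    )
    def test_fold_matches_published_two_decimal_values(self, ctrl_mean, pos_mean, fold_2dp):
        # constant-shift samples engineered to hit the printed group means
        ctrl = np.full(9, ctrl_mean)
        pos = np.full(9, pos_mean)
        ctrl[0] += 1e-9  # avoid fully degenerate pooled sample
        summ = group_summary({"control": ctrl, "positive": pos}, "var")
        assert round(summ.fold, 2) == fold_2dp

    def test_identical_groups_give_fold_one(self):
        vals = np.array([1.0, 2.0, 3.0])
        s = group_summary({"control": vals, "positive": vals}, "v")
        assert s.fold == pytest.approx(1.0)

    def test_sem_uses_sample_sd(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        s = group_summary({"control": vals, "positive": vals + 1}, "v")
        assert s.sem_control == pytest.approx(vals.std(ddof=1) / 2.0)

    def test_zero_control_mean_flags_fold_undefined(self):
        s = group_summary(
            {"control": np.zeros(3), "positive": np.ones(3)}, "v"
        )
        assert not s.fold_defined
        assert np.isnan(s.fold)

    def test_fold_scale_invariance(self):
        rng = np.random.default_rng(1)
        ctrl, pos = rng.lognormal(size=8), rng.lognormal(0.5, size=8)
        f1 = group_summary({"control": ctrl, "positive": pos}, "v").fold
        f2 = group_summary({"control": 37.0 * ctrl, "positive": 37.0 * pos}, "v").fold
        assert f1 == pytest.approx(f2, rel=1e-12)
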