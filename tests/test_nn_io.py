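import numpy as np
import pandas as pd
import pytest

from fractalhrv import NNSeries, filter_normal_beats, label_sleep_wake, read_rr, write_rr
from fractalhrv.nn_io import (
    ParseError,
    UnanalyzableRecordError,
    ValidationError,
    read_diary,
    write_results,
)

from conftest import make_series


class TestReadWrite:
    def test_one_column_accumulates_beat_times(self, tmp_path):
        p = tmp_path / "r.rr"
        p.write_text("1000\n1000\n1000\n")
        s = read_rr(p, dialect="nn")
        assert s.n_beats == 3
        np.testing.assert_allclose(s.beat_times, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(s.nn_ms, 1000.0)

    def test_two_column_with_header(self, tmp_path):
        p = tmp_path / "r.rr"
        p.write_text("beat_time_s,nn_ms\n0.8,800\n1.6,800\n")
        s = read_rr(p)
        assert s.n_beats == 2
        assert s.beat_times[-1] == pytest.approx(1.6)

    def test_round_trip_preserves_series_exactly(self, tmp_path, rng):
        nn = np.round(rng.normal(1000, 60, size=1000) / 8) * 8
        s = make_series(nn)
        s.beat_labels[17] = "ectopic"
        write_rr(s, tmp_path / "w.rr", dialect="t_nn")
        back = read_rr(tmp_path / "w.rr", subject_id="T01")
        np.testing.assert_array_equal(back.nn_ms, s.nn_ms)
        np.testing.assert_array_equal(back.beat_times, s.beat_times)
        assert list(back.beat_labels) == list(s.beat_labels)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.rr"
        p.write_text("1000\nabc\n900\n")
        with pytest.raises(ParseError, match="line 2"):
            read_rr(p, dialect="nn")

    def test_non_positive_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.rr"
        p.write_text("1000\n-5\n")
        with pytest.raises(ValidationError):
            read_rr(p, dialect="nn")


class TestFilterNormalBeats:
    def test_all_normal_unchanged(self):
        s = make_series([1000.0] * 50)
        out, rep = filter_normal_beats(s)
        assert rep.n_excluded == 0
        assert out.n_beats == 50

    def test_relative_change_rule(self):
        s = make_series([1000, 1000, 400, 1000])
        out, rep = filter_normal_beats(s, max_rel_change=0.2, force=True)
        assert out.n_beats == 3
        assert rep.n_rel_change == 1
        assert 400 not in out.nn_ms

    def test_bounds_rule_overrides(self):
        # a 2500-ms beat is excluded by bounds regardless of relative change
        s = make_series([1900.0] * 10 + [2500.0] + [1900.0] * 10)
        out, rep = filter_normal_beats(s, max_rel_change=1.0, force=True)
        assert rep.n_out_of_bounds == 1
        assert out.nn_ms.max() <= 2000

    def test_idempotent(self, rng):
        nn = rng.normal(900, 200, size=400).clip(150, 2600)
        s = make_series(nn)
        once, _ = filter_normal_beats(s, force=True)
        twice, rep2 = filter_normal_beats(once, force=True)
        assert rep2.n_excluded == 0
        np.testing.assert_array_equal(once.nn_ms, twice.nn_ms)
        np.testing.assert_array_equal(once.beat_times, twice.beat_times)

    def test_excess_exclusion_raises_unless_forced(self):
        s = make_series([1000, 100] * 50)
        with pytest.raises(UnanalyzableRecordError):
            filter_normal_beats(s)
        out, rep = filter_normal_beats(s, force=True)
        assert rep.fraction_excluded > 0.2


class TestSleepWake:
    def _day_series(self):
        return make_series([1000.0] * 86400)  # 24 h of 1-s beats

    def test_partition_is_exhaustive_and_exclusive(self):
        s = self._day_series()
        spans = label_sleep_wake(s, [(23.5, 5.667)])  # clock hours
        labels = spans.label_times(s.beat_times)
        n_asleep = int(np.sum(labels == "asleep"))
        n_awake = int(np.sum(labels == "awake"))
        assert n_asleep + n_awake == s.n_beats

    def test_sleep_duration_matches_diary(self):
        # 23:30-05:40 is 6.17 h of sleep
        s = self._day_series()
        spans = label_sleep_wake(s, [(23.5, 5.0 + 40.0 / 60.0)])
        assert spans.total_sleep_h == pytest.approx(6.1667, abs=1e-3)
        labels = spans.label_times(s.beat_times)
        assert np.sum(labels == "asleep") == pytest.approx(6.1667 * 3600, abs=5)
        # wake reference = arising = end of main sleep span (23:30 is 16.5 h
        # after the 07:00 record start, plus the 6.17-h sleep)
        assert spans.wake_reference_s == pytest.approx((16.5 + 6.1667) * 3600, abs=5)

    def test_diary_covering_whole_record(self):
        s = make_series([1000.0] * 3600)
        spans = label_sleep_wake(s, [(0.0, s.beat_times[-1] + 1)], diary_in_clock_hours=False)
        labels = spans.label_times(s.beat_times)
        assert np.all(labels == "asleep")

    def test_empty_diary_raises(self):
        with pytest.raises(ValidationError):
            label_sleep_wake(self._day_series(), [])

    def test_auto_detect_moves_boundary_to_step(self):
        # NN lengthens abruptly at 23:00 (16 h into a record starting 07:00);
        # the diary says 23:15 -> auto-detect should move onset to ~23:00
        nn = np.concatenate([np.full(72000, 800.0), np.full(26000, 1100.0)])
        s = make_series(nn)
        onset_true_s = np.cumsum(nn)[71999] / 1000.0  # 16 h
        spans = label_sleep_wake(s, [(23.25, 5.5)], auto_detect=True)
        assert abs(spans.sleep_intervals_s[0][0] - onset_true_s) < 600


class TestWriteResults:
    def test_empty_table_writes_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["subject_id", "beta"])
        paths = write_results({"t": df}, tmp_path)
        csv = (tmp_path / "t.csv").read_text().strip()
        assert csv == "subject_id,beta"

    def test_csv_and_json_encode_identical_numbers(self, tmp_path, rng):
        df = pd.DataFrame({"a": rng.normal(size=5), "b": rng.integers(0, 9, 5)})
        write_results({"x": df}, tmp_path)
        import json

        back_csv = pd.read_csv(tmp_path / "x.csv", float_precision="round_trip")
        back_json = pd.DataFrame(json.loads((tmp_path / "x.json").read_text()))
        np.testing.assert_array_equal(back_csv["a"].to_numpy(), back_json["a"].to_numpy())
        np.testing.assert_array_equal(back_csv["b"].to_numpy(), back_json["b"].to_numpy())


def test_read_diary_parses_clock_times(tmp_path):
    p = tmp_path / "diary.csv"
    p.write_text("subject_id,session_id,sleep_onset,sleep_offset\nS01,Pre,23:30,05:40\n")
    d = read_diary(p)
    assert d.loc[0, "sleep_onset_h"] == pytest.approx(23.5)
    assert d.loc[0, "sleep_offset_h"] == pytest.approx(5.0 + 40 / 60)
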