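import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reefrange as rr


def det_frame(rows):
    """rows: (iso_time, receiver, transmitter)."""
    return pd.DataFrame({
        "timestamp": pd.to_datetime([r[0] for r in rows], utc=True),
        "receiver_id": [r[1] for r in rows],
        "transmitter_id": [r[2] for r in rows],
    })


class TestReadDetections:
    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("timestamp,receiver_id,transmitter_id\n")
        out = rr.read_detections(p)
        assert len(out) == 0

    def test_missing_column_is_hard_error(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("timestamp,receiver_id\n2020-01-01T00:00:00Z,R1\n")
        with pytest.raises(ValueError, match="transmitter_id"):
            rr.read_detections(p)

    def test_malformed_rows_dropped_and_counted(self, tmp_path):
        lines = ["timestamp,receiver_id,transmitter_id"]
        for i in range(9):
            lines.append(f"2020-01-01T00:0{i}:00Z,R1,T1")
        lines.append("not-a-time,R1,T1")
        p = tmp_path / "d.csv"
        p.write_text("\n".join(lines) + "\n")
        out = rr.read_detections(p)
        assert len(out) == 9
        assert out.attrs["n_malformed"] == 1

    def test_unsorted_input_sorted_ascending(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("timestamp,receiver_id,transmitter_id\n"
                     "2020-01-02T00:00:00Z,R1,T1\n"
                     "2020-01-01T00:00:00Z,R2,T1\n")
        out = rr.read_detections(p)
        assert out["timestamp"].is_monotonic_increasing
        assert list(out["receiver_id"]) == ["R2", "R1"]


class TestFalseDetectionFilter:
    def test_mutually_supporting_pings_kept(self):
        det = det_frame([("2020-01-01T00:00:00Z", "R1", "T1"),
                         ("2020-01-01T00:01:00Z", "R1", "T1")])
        out, removed = rr.filter_false_detections(det)
        assert len(out) == 2 and removed == 0

    def test_isolated_ping_removed(self):
        det = det_frame([("2020-01-01T00:00:00Z", "R1", "T1"),
                         ("2020-01-01T02:00:00Z", "R1", "T1"),  # 7200 s gap
                         ("2020-01-01T02:01:00Z", "R1", "T1")])
        out, removed = rr.filter_false_detections(det, window_s=3600)
        assert removed == 1
        assert out["timestamp"].min() == pd.Timestamp("2020-01-01T02:00:00Z")

    def test_same_tag_other_receiver_does_not_support(self):
        det = det_frame([("2020-01-01T00:00:00Z", "R1", "T1"),
                         ("2020-01-01T00:01:00Z", "R2", "T1")])
        out, removed = rr.filter_false_detections(det)
        assert removed == 2 and len(out) == 0

    def test_empty_input(self):
        det = det_frame([])
        out, removed = rr.filter_false_detections(det)
        assert len(out) == 0 and removed == 0

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            rr.filter_false_detections(det_frame([]), window_s=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50000), st.sampled_from(["R1", "R2"]),
                              st.sampled_from(["T1", "T2"])), max_size=40))
    def test_filter_idempotent_and_pure(self, rows):
        det = det_frame([(pd.Timestamp("2020-01-01", tz="UTC") + pd.Timedelta(seconds=s),
                          r, t) for s, r, t in rows])
        before = det.copy()
        once, n1 = rr.filter_false_detections(det)
        twice, n2 = rr.filter_false_detections(once)
        pd.testing.assert_frame_equal(once, twice)
        assert n2 == 0
        pd.testing.assert_frame_equal(det, before)  # input not mutated


class TestPostCaptureWindow:
    @pytest.fixture()
    def tagging(self):
        return pd.DataFrame({
            "transmitter_id": ["T1"], "sex": ["male"], "maturity": ["adult"],
            "length_cm": [150.0], "tag_date": [pd.Timestamp("2020-01-01")],
            "tag_receiver_id": ["R1"]})

    def test_window_boundary(self, tagging):
        # local midnight 2020-01-01 is 2019-12-31T13:00Z at UTC+11
        det = det_frame([("2020-01-14T00:00:00Z", "R1", "T1"),   # day 13: inside
                         ("2020-01-16T00:00:00Z", "R1", "T1")])  # day 15: outside
        out = rr.apply_post_capture_window(det, tagging, days=14)
        assert len(out) == 1
        assert out["timestamp"].iloc[0] == pd.Timestamp("2020-01-16T00:00:00Z")

    def test_cutoff_is_closed_open(self, tagging):
        cutoff = pd.Timestamp("2020-01-14T13:00:00Z")  # local midnight + 14 d
        det = det_frame([(cutoff - pd.Timedelta(seconds=1), "R1", "T1"),
                         (cutoff, "R1", "T1")])
        out = rr.apply_post_capture_window(det, tagging, days=14)
        assert list(out["timestamp"]) == [cutoff]

    def test_zero_days_is_identity_after_tagging(self, tagging):
        det = det_frame([("2020-01-02T00:00:00Z", "R1", "T1"),
                         ("2020-03-01T00:00:00Z", "R1", "T1")])
        out = rr.apply_post_capture_window(det, tagging, days=0)
        pd.testing.assert_frame_equal(out, det)

    def test_unknown_transmitter_errors(self, tagging):
        det = det_frame([("2020-01-20T00:00:00Z", "R1", "T9")])
        with pytest.raises(KeyError, match="T9"):
            rr.apply_post_capture_window(det, tagging)


class TestCohort:
    @staticmethod
    def make_tables(n, lost_rx_for, detected_ids):
        tagging = pd.DataFrame({
            "transmitter_id": [f"T{i}" for i in range(n)],
            "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
            "maturity": ["adult"] * n,
            "length_cm": [150.0] * n,
            "tag_date": [pd.Timestamp("2020-01-01")] * n,
            "tag_receiver_id": [f"R{i % 3}" for i in range(n)]})
        receivers = pd.DataFrame({
            "receiver_id": ["R0", "R1", "R2"], "reef_id": ["reef_1"] * 3,
            "position_km": [0.0, 1.0, 2.0], "lat": [0.0] * 3, "lon": [0.0] * 3,
            "status": ["lost" if f"R{i}" in lost_rx_for else "active" for i in range(3)]})
        det = det_frame([("2020-02-01T00:00:00Z", "R0", t) for t in detected_ids])
        return det, tagging, receivers

    def test_no_exclusions(self):
        det, tagging, receivers = self.make_tables(6, set(), [f"T{i}" for i in range(6)])
        rep = rr.build_cohort(det, tagging, receivers)
        assert rep.n_retained == rep.n_tagged == 6
        assert rep.group_counts == {"adult_female": 3, "adult_male": 3}

    def test_silent_and_lost_shark_counted_once_under_lost(self):
        # T0 tagged at R0 (lost) and also silent: must appear only in the lost bucket
        det, tagging, receivers = self.make_tables(3, {"R0"}, ["T1", "T2"])
        rep = rr.build_cohort(det, tagging, receivers)
        assert rep.excluded_lost_ids == ["T0"]
        assert rep.n_excluded_silent == 0
        assert rep.n_retained == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.sets(st.integers(0, 2)), st.sets(st.integers(0, 29)))
    def test_arithmetic_identity(self, n, lost, detected):
        det, tagging, receivers = self.make_tables(
            n, {f"R{i}" for i in lost}, [f"T{i}" for i in detected if i < n])
        rep = rr.build_cohort(det, tagging, receivers)
        assert rep.n_retained == rep.n_tagged - rep.n_excluded_silent \
            - rep.n_excluded_lost_receiver
        assert not (set(rep.excluded_silent_ids) & set(rep.excluded_lost_ids))
        assert sum(rep.group_counts.values()) == rep.n_retained
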