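import numpy as np
import pandas as pd
import pytest

import reefrange as rr
from reefrange.home_range import _interval_difference


def det_frame(rows):
    return pd.DataFrame({
        "timestamp": pd.to_datetime([r[0] for r in rows], utc=True),
        "receiver_id": [r[1] for r in rows],
        "transmitter_id": [r[2] for r in rows],
    })


class TestDailyOccurrences:
    def test_many_pings_collapse_to_one_occurrence(self):
        rows = [(pd.Timestamp("2020-01-01T01:00:00Z") + pd.Timedelta(seconds=60 * i),
                 "R1", "T1") for i in range(100)]
        m = rr.daily_occurrences(det_frame(rows))
        assert len(m.table) == 1

    def test_local_midnight_splits_days(self):
        # 23:59 and 00:01 local (UTC+11) = 12:59Z and 13:01Z
        det = det_frame([("2020-01-01T12:59:00Z", "R1", "T1"),
                         ("2020-01-01T13:01:00Z", "R1", "T1")])
        m = rr.daily_occurrences(det, tz_offset_hours=11)
        assert len(m.table) == 2
        assert sorted(m.table["day"].dt.day) == [1, 2]

    def test_two_receivers_same_day_both_count(self):
        det = det_frame([("2020-01-01T01:00:00Z", "R1", "T1"),
                         ("2020-01-01T02:00:00Z", "R2", "T1")])
        m = rr.daily_occurrences(det)
        assert len(m.table) == 2
        assert set(m.table["receiver_id"]) == {"R1", "R2"}

    def test_cohort_restriction(self):
        det = det_frame([("2020-01-01T01:00:00Z", "R1", "T1"),
                         ("2020-01-01T01:00:00Z", "R1", "T2")])
        m = rr.daily_occurrences(det, cohort_ids=["T1"])
        assert m.sharks() == ["T1"]


class TestCoreReceivers:
    def test_prefix_at_95(self):
        assert rr.select_core_receivers({"R1": 50, "R2": 45, "R3": 5}) == ["R1", "R2"]

    def test_single_receiver(self):
        assert rr.select_core_receivers({"R1": 10}) == ["R1"]

    def test_two_equal_receivers_both_needed(self):
        assert rr.select_core_receivers({"R1": 1, "R2": 1}) == ["R1", "R2"]

    def test_ties_broken_by_receiver_id(self):
        assert rr.select_core_receivers({"R2": 5, "R1": 5}, threshold=0.5) == ["R1"]

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            rr.select_core_receivers({})

    def test_threshold_one_returns_all(self):
        counts = {"R1": 7, "R2": 2, "R3": 1}
        assert set(rr.select_core_receivers(counts, threshold=1.0)) == set(counts)


class TestHullArea:
    def test_linear_area_function(self, toy_receivers, linear_reef):
        assert rr.hull_area(["R1", "R2"], toy_receivers, linear_reef) == pytest.approx(6.0)

    def test_single_receiver_zero_area(self, toy_receivers, linear_reef):
        assert rr.hull_area(["R2"], toy_receivers, linear_reef) == 0.0

    def test_two_reefs_sum_without_inter_reef_water(self):
        receivers = pd.DataFrame({
            "receiver_id": ["A1", "A2", "B1", "B2"],
            "reef_id": ["ra", "ra", "rb", "rb"],
            "position_km": [1.0, 4.0, 0.0, 2.0],
            "lat": [0.0] * 4, "lon": [0.0] * 4, "status": ["active"] * 4})
        reefs = {"ra": rr.ReefGeometry.from_density("ra", 10.0, 2.0),
                 "rb": rr.ReefGeometry.from_density("rb", 5.0, 1.0)}
        assert rr.hull_area(["A1", "A2", "B1", "B2"], receivers, reefs) \
            == pytest.approx(6.0 + 2.0)

    def test_unknown_receiver_errors(self, toy_receivers, linear_reef):
        with pytest.raises(KeyError, match="R9"):
            rr.hull_area(["R9"], toy_receivers, linear_reef)


def occurrences_from_counts(counts, month=3):
    """Build an occurrence matrix with given per-receiver daily counts."""
    rows = []
    day = pd.Timestamp(f"2020-{month:02d}-01")
    for rx, n in counts.items():
        for i in range(n):
            rows.append({"transmitter_id": "T1", "day": day + pd.Timedelta(days=i),
                         "month": month, "receiver_id": rx})
    return rr.DailyOccurrenceMatrix(pd.DataFrame(rows))


class TestComputeUD:
    def test_worked_example(self, toy_receivers, linear_reef):
        m = occurrences_from_counts({"R1": 50, "R2": 45, "R3": 5})
        ud = rr.compute_ud("T1", m, toy_receivers, linear_reef)
        assert ud.ud95_km2 == pytest.approx(6.0)    # hull R1..R2 through A(s)=2s
        assert ud.ud100_km2 == pytest.approx(12.0)  # hull R1..R3
        assert set(ud.core_receivers) == {"R1", "R2"}

    def test_single_receiver_shark_null_ud(self, toy_receivers, linear_reef):
        m = occurrences_from_counts({"R2": 30})
        ud = rr.compute_ud("T1", m, toy_receivers, linear_reef)
        assert ud.ud95_km2 == ud.ud100_km2 == 0.0
        assert ud.n_receivers == 1

    def test_absent_in_season_is_none_not_zero(self, toy_receivers, linear_reef):
        m = occurrences_from_counts({"R1": 5}, month=3)  # non-mating only
        assert rr.compute_ud("T1", m, toy_receivers, linear_reef, "mating") is None
        assert rr.compute_ud("T1", m, toy_receivers, linear_reef, "non_mating") is not None

    def test_threshold_one_makes_ud95_equal_ud100(self, toy_receivers, linear_reef):
        m = occurrences_from_counts({"R1": 97, "R2": 2, "R3": 1})
        ud = rr.compute_ud("T1", m, toy_receivers, linear_reef, threshold=1.0)
        assert ud.ud95_km2 == ud.ud100_km2

    def test_ud95_below_ud100_and_bounded(self, toy_receivers, linear_reef):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = {rx: int(n) for rx, n in
                      zip(["R1", "R2", "R3"], rng.integers(0, 40, 3)) if n > 0}
            if not counts:
                continue
            ud = rr.compute_ud("T1", occurrences_from_counts(counts),
                               toy_receivers, linear_reef)
            assert 0 <= ud.ud95_km2 <= ud.ud100_km2 <= linear_reef["reef_1"].total_area_km2

    def test_adding_detections_never_shrinks_ud100(self, toy_receivers, linear_reef):
        m1 = occurrences_from_counts({"R1": 5, "R2": 5})
        m2 = occurrences_from_counts({"R1": 5, "R2": 5, "R3": 1})
        ud1 = rr.compute_ud("T1", m1, toy_receivers, linear_reef)
        ud2 = rr.compute_ud("T1", m2, toy_receivers, linear_reef)
        assert ud2.ud100_km2 >= ud1.ud100_km2


class TestSeasonalUse:
    @staticmethod
    def matrix_with_hulls(non_mating_span, mating_span):
        """Occurrences putting receivers at 1-km marks over the given spans."""
        rows = []
        for s in range(non_mating_span[0], non_mating_span[1] + 1):
            rows.append({"transmitter_id": "T1", "day": pd.Timestamp("2020-03-01"),
                         "month": 3, "receiver_id": f"S{s:02d}"})
        for s in range(mating_span[0], mating_span[1] + 1):
            rows.append({"transmitter_id": "T1", "day": pd.Timestamp("2020-08-01"),
                         "month": 8, "receiver_id": f"S{s:02d}"})
        return rr.DailyOccurrenceMatrix(pd.DataFrame(rows))

    @pytest.fixture()
    def dense_receivers(self):
        return pd.DataFrame({
            "receiver_id": [f"S{s:02d}" for s in range(11)],
            "reef_id": ["reef_1"] * 11,
            "position_km": [float(s) for s in range(11)],
            "lat": [0.0] * 11, "lon": [0.0] * 11, "status": ["active"] * 11})

    def test_exclusive_mating_fraction_worked_example(self, dense_receivers, linear_reef):
        # non-mating hull [1,5], mating hull [1,7], A(s)=2s:
        # exclusive area A(7)-A(5)=4, UD100 = A(7)-A(1)=12, fraction 1/3
        m = self.matrix_with_hulls((1, 5), (1, 7))
        su = rr.seasonal_use("T1", m, dense_receivers, linear_reef)
        assert su.fraction_exclusive_mating == pytest.approx(1.0 / 3.0)

    def test_no_mating_detections_gives_zero(self, dense_receivers, linear_reef):
        rows = [{"transmitter_id": "T1", "day": pd.Timestamp("2020-03-01"),
                 "month": 3, "receiver_id": "S01"},
                {"transmitter_id": "T1", "day": pd.Timestamp("2020-04-01"),
                 "month": 4, "receiver_id": "S05"}]
        su = rr.seasonal_use("T1", rr.DailyOccurrenceMatrix(pd.DataFrame(rows)),
                             dense_receivers, linear_reef)
        assert su.fraction_exclusive_mating == 0.0

    def test_identical_seasonal_hulls_give_zero(self, dense_receivers, linear_reef):
        m = self.matrix_with_hulls((2, 6), (2, 6))
        su = rr.seasonal_use("T1", m, dense_receivers, linear_reef)
        assert su.fraction_exclusive_mating == 0.0

    def test_interval_difference_pieces(self):
        assert _interval_difference((1, 7), (1, 5)) == [(5, 7)]
        assert _interval_difference((0, 10), (3, 6)) == [(0, 3), (6, 10)]
        assert _interval_difference((2, 6), (0, 10)) == []
        assert _interval_difference((2, 6), None) == [(2, 6)]


class TestInterReefDistance:
    def test_same_reef_zero(self):
        reef = rr.ReefGeometry.from_density("x", 5.0, 1.0, anchors=((0.0, 0.0),))
        assert rr.inter_reef_distance(reef, reef) == 0.0

    def test_one_degree_on_equator(self):
        a = rr.ReefGeometry.from_density("a", 5.0, 1.0, anchors=((0.0, 0.0),))
        b = rr.ReefGeometry.from_density("b", 5.0, 1.0, anchors=((0.0, 1.0),))
        assert rr.inter_reef_distance(a, b) == pytest.approx(111.2, abs=0.3)

    def test_symmetric_and_uses_nearest_anchor_pair(self):
        a = rr.ReefGeometry.from_density("a", 5.0, 1.0,
                                         anchors=((0.0, 0.0), (0.0, 0.5)))
        b = rr.ReefGeometry.from_density("b", 5.0, 1.0,
                                         anchors=((0.0, 1.0), (0.0, 2.0)))
        d_ab = rr.inter_reef_distance(a, b)
        assert d_ab == rr.inter_reef_distance(b, a)
        # half a degree of great circle: 0.5 * 2*pi*R/360
        assert d_ab == pytest.approx(0.5 * 111.195, rel=1e-3)
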