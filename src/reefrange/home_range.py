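"""One-dimensional utilization distributions on linear reef habitat.

Receiver arrays moored along the outer slope of barrier reefs form an
essentially linear monitoring system: each receiver sits at a curvilinear
position ``s`` (km) along its reef axis.  Kernel home-range estimators are
not applicable at the spatial resolution of such arrays, so the home range
of a tracked animal is summarised by one-dimensional convex hulls — the
stretch of reef between the outermost receivers it visited — mapped into
km² of reef-slope habitat through a cumulative area function ``A(s)``.

Two metrics are produced per animal:

* ``UD100`` — slope area delimited by *all* receivers visited;
* ``UD95``  — slope area delimited by the smallest subset of receivers
  that together account for at least 95 % of daily occurrences.

An animal seen on a single receiver has no hull extent and is assigned
``UD95 = UD100 = 0``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MATING_MONTHS = frozenset({7, 8, 9})  # July–September, austral winter

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius, used for great-circle distance


# ---------------------------------------------------------------------------
# Reef geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReefGeometry:
    """Curvilinear axis of one reef with its cumulative slope-area function.

    ``A(s)`` gives the km² of outer reef slope between the reef origin and
    curvilinear position ``s`` (km).  It is piecewise linear, ``A(0) = 0``
    and non-decreasing, so any interval ``[s0, s1]`` of reef maps to
    ``A(s1) - A(s0)`` km² of habitat.

    Parameters
    ----------
    reef_id : str
        Identifier of the reef.
    length_km : float
        Extent of the reef axis.
    s_knots, area_knots : arrays
        Knots of the piecewise-linear cumulative area function.
    anchors : sequence of (lat, lon)
        Reference coordinates (typically the reef endpoints) used for
        shortest straight-line distances between separate reefs.
    """

    reef_id: str
    length_km: float
    s_knots: np.ndarray
    area_knots: np.ndarray
    anchors: tuple = ()

    def __post_init__(self):
        s = np.asarray(self.s_knots, dtype=float)
        a = np.asarray(self.area_knots, dtype=float)
        if s.shape != a.shape or s.ndim != 1 or len(s) < 2:
            raise ValueError("s_knots and area_knots must be 1-d arrays of equal length >= 2")
        if s[0] != 0.0 or a[0] != 0.0:
            raise ValueError("cumulative area must start at A(0) = 0")
        if np.any(np.diff(s) <= 0):
            raise ValueError("s_knots must be strictly increasing")
        if np.any(np.diff(a) < 0):
            raise ValueError("cumulative area must be non-decreasing")
        if not math.isclose(s[-1], self.length_km, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("last s knot must equal reef length")
        object.__setattr__(self, "s_knots", s)
        object.__setattr__(self, "area_knots", a)

    @classmethod
    def from_density(cls, reef_id: str, length_km: float, density_km2_per_km: float | Sequence[float],
                     anchors: tuple = ()) -> "ReefGeometry":
        """Build a geometry with (piecewise-)constant slope-area density.

        A scalar density gives ``A(s) = density * s``; a sequence gives one
        constant density per equal-length segment.
        """
        if np.isscalar(density_km2_per_km):
            dens = np.array([float(density_km2_per_km)])
        else:
            dens = np.asarray(density_km2_per_km, dtype=float)
        if np.any(dens < 0):
            raise ValueError("area density must be non-negative")
        edges = np.linspace(0.0, length_km, len(dens) + 1)
        areas = np.concatenate([[0.0], np.cumsum(dens * np.diff(edges))])
        return cls(reef_id, length_km, edges, areas, anchors=anchors)

    def cumulative_area(self, s) -> np.ndarray | float:
        """Evaluate ``A(s)`` (clamped to the reef extent)."""
        s_arr = np.clip(np.asarray(s, dtype=float), 0.0, self.length_km)
        out = np.interp(s_arr, self.s_knots, self.area_knots)
        return float(out) if np.isscalar(s) or out.ndim == 0 else out

    @property
    def total_area_km2(self) -> float:
        return float(self.area_knots[-1])

    def interval_area(self, s0: float, s1: float) -> float:
        """Slope area of the reef portion between two curvilinear positions."""
        if s1 < s0:
            s0, s1 = s1, s0
        return self.cumulative_area(s1) - self.cumulative_area(s0)


def inter_reef_distance(reef_a: ReefGeometry, reef_b: ReefGeometry) -> float:
    """Shortest straight-line (great-circle) distance between two reefs, km.

    Animals moving between separate reefs are conservatively assumed to
    travel this distance; inter-reef water never contributes habitat area.
    Returns 0 for a reef paired with itself.
    """
    if reef_a.reef_id == reef_b.reef_id:
        return 0.0
    if not reef_a.anchors or not reef_b.anchors:
        raise ValueError("both reefs need anchor coordinates")
    best = math.inf
    for lat1, lon1 in reef_a.anchors:
        for lat2, lon2 in reef_b.anchors:
            best = min(best, _haversine_km(lat1, lon1, lat2, lon2))
    return best


def _haversine_km(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


# ---------------------------------------------------------------------------
# Daily occurrence binning
# ---------------------------------------------------------------------------

@dataclass
class DailyOccurrenceMatrix:
    """Daily presence of each animal at each receiver.

    ``table`` has one row per (transmitter, local calendar day, receiver)
    with at least one detection that day; a day may contribute to several
    receivers if the animal was heard at more than one.
    """

    table: pd.DataFrame  # columns: transmitter_id, day, month, receiver_id
    tz_offset_hours: float = 11.0

    def sharks(self) -> list:
        return sorted(self.table["transmitter_id"].unique())

    def counts_for(self, transmitter_id: str, months: Iterable[int] | None = None) -> pd.Series:
        """Per-receiver daily-occurrence counts for one animal.

        ``months`` restricts occurrences to local calendar months (e.g. the
        mating season); ``None`` keeps the whole monitoring period.
        """
        sub = self.table[self.table["transmitter_id"] == transmitter_id]
        if months is not None:
            sub = sub[sub["month"].isin(set(months))]
        return sub.groupby("receiver_id").size().sort_index()


def daily_occurrences(detections: pd.DataFrame, cohort_ids: Iterable[str] | None = None,
                      tz_offset_hours: float = 11.0) -> DailyOccurrenceMatrix:
    """Split the monitoring period into daily bins in study-local time.

    Detections carry UTC timestamps; calendar days are taken in the study
    timezone (default UTC+11, New Caledonia).  Multiple detections of the
    same animal at the same receiver within one local day collapse to a
    single occurrence.
    """
    det = detections
    if cohort_ids is not None:
        det = det[det["transmitter_id"].isin(set(cohort_ids))]
    if len(det) == 0:
        empty = pd.DataFrame(columns=["transmitter_id", "day", "month", "receiver_id"])
        return DailyOccurrenceMatrix(empty, tz_offset_hours)
    local = pd.to_datetime(det["timestamp"], utc=True) + pd.Timedelta(hours=tz_offset_hours)
    table = pd.DataFrame({
        "transmitter_id": det["transmitter_id"].to_numpy(),
        "day": local.dt.floor("D").dt.tz_localize(None).to_numpy(),
        "receiver_id": det["receiver_id"].to_numpy(),
    })
    table = table.drop_duplicates().reset_index(drop=True)
    table["month"] = pd.DatetimeIndex(table["day"]).month
    table = table[["transmitter_id", "day", "month", "receiver_id"]]
    table = table.sort_values(["transmitter_id", "day", "receiver_id"]).reset_index(drop=True)
    return DailyOccurrenceMatrix(table, tz_offset_hours)


# ---------------------------------------------------------------------------
# Core-receiver selection and hulls
# ---------------------------------------------------------------------------

def select_core_receivers(per_receiver_daily_counts: Mapping[str, int] | pd.Series,
                          threshold: float = 0.95) -> list:
    """Receivers accounting for ``threshold`` of daily occurrences.

    Receivers are ranked by descending daily-occurrence count (ties broken
    by ascending receiver id) and the shortest prefix whose cumulative count
    reaches ``threshold`` of the total is returned.
    """
    counts = pd.Series(dict(per_receiver_daily_counts), dtype=float)
    if counts.empty:
        raise ValueError("empty occurrence counts")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    counts = counts.sort_index().sort_values(ascending=False, kind="stable")
    total = counts.sum()
    cum = counts.cumsum()
    # first position where the cumulative share reaches the threshold
    k = int(np.argmax(cum.to_numpy() >= threshold * total - 1e-12)) + 1
    return list(counts.index[:k])


def hull_intervals(receiver_ids: Iterable[str], receivers: pd.DataFrame) -> dict:
    """Per-reef 1-d convex hull ``[s_min, s_max]`` of a receiver subset."""
    ids = list(receiver_ids)
    rec = receivers.set_index("receiver_id")
    unknown = [r for r in ids if r not in rec.index]
    if unknown:
        raise KeyError(f"unknown receivers: {unknown}")
    sub = rec.loc[ids]
    out = {}
    for reef_id, grp in sub.groupby("reef_id"):
        out[str(reef_id)] = (float(grp["position_km"].min()), float(grp["position_km"].max()))
    return out


def hull_area(receiver_ids: Iterable[str], receivers: pd.DataFrame,
              reefs: Mapping[str, ReefGeometry]) -> float:
    """Slope area (km²) of the per-reef hulls spanned by a receiver subset.

    The hull on each reef is the interval between the outermost receivers of
    the subset on that reef; areas are summed over reefs and open water
    between reefs contributes nothing.  A subset confined to one receiver
    has zero extent and zero area.
    """
    total = 0.0
    for reef_id, (s0, s1) in hull_intervals(receiver_ids, receivers).items():
        if reef_id not in reefs:
            raise KeyError(f"no geometry for reef {reef_id!r}")
        total += reefs[reef_id].interval_area(s0, s1)
    return total


# ---------------------------------------------------------------------------
# Utilization distributions
# ---------------------------------------------------------------------------

SEASONS = ("all", "mating", "non_mating")


@dataclass
class UtilizationDistribution:
    shark_id: str
    season: str
    core_receivers: list
    all_receivers: list
    hulls95: dict = field(default_factory=dict)  # reef_id -> (s_min, s_max)
    hulls100: dict = field(default_factory=dict)
    ud95_km2: float = 0.0
    ud100_km2: float = 0.0

    @property
    def n_receivers(self) -> int:
        return len(self.all_receivers)


def _season_months(season: str, mating_months: frozenset = MATING_MONTHS):
    if season == "all":
        return None
    if season == "mating":
        return mating_months
    if season == "non_mating":
        return frozenset(range(1, 13)) - mating_months
    raise ValueError(f"unknown season {season!r}")


def compute_ud(shark_id: str, matrix: DailyOccurrenceMatrix, receivers: pd.DataFrame,
               reefs: Mapping[str, ReefGeometry], season: str = "all",
               threshold: float = 0.95,
               mating_months: frozenset = MATING_MONTHS) -> UtilizationDistribution | None:
    """UD95/UD100 of one animal for one season.

    Returns ``None`` when the animal has no occurrence in the season — an
    absent result, deliberately distinct from a present animal whose hull
    has zero extent (``UD = 0``).
    """
    counts = matrix.counts_for(shark_id, months=_season_months(season, mating_months))
    if counts.empty:
        return None
    all_rx = sorted(counts.index)
    core_rx = select_core_receivers(counts, threshold=threshold)
    h100 = hull_intervals(all_rx, receivers)
    h95 = hull_intervals(core_rx, receivers)
    ud100 = sum(reefs[r].interval_area(*iv) for r, iv in h100.items())
    ud95 = sum(reefs[r].interval_area(*iv) for r, iv in h95.items())
    return UtilizationDistribution(shark_id, season, core_rx, all_rx, h95, h100,
                                   float(ud95), float(ud100))


@dataclass
class SeasonalUse:
    shark_id: str
    fraction_exclusive_mating: float
    ud_mating: UtilizationDistribution | None
    ud_non_mating: UtilizationDistribution | None
    ud_all: UtilizationDistribution | None


def _interval_difference(a: tuple, b: tuple | None) -> list:
    """Parts of closed interval ``a`` not covered by ``b`` (0, 1 or 2 pieces)."""
    if b is None:
        return [a]
    a0, a1 = a
    b0, b1 = b
    pieces = []
    if b0 > a0:
        pieces.append((a0, min(a1, b0)))
    if b1 < a1:
        pieces.append((max(a0, b1), a1))
    return [(x0, x1) for x0, x1 in pieces if x1 > x0]


def seasonal_use(shark_id: str, matrix: DailyOccurrenceMatrix, receivers: pd.DataFrame,
                 reefs: Mapping[str, ReefGeometry], threshold: float = 0.95,
                 mating_months: frozenset = MATING_MONTHS) -> SeasonalUse:
    """Share of the year-long UD100 used only during the mating season.

    The mating-season hull on each reef is differenced against the
    non-mating hull; the remaining reef portions are mapped through the
    cumulative area function and divided by the year-long UD100.  Animals
    with no mating-season detections, or with a year-long UD100 of zero,
    get a fraction of 0.
    """
    ud_all = compute_ud(shark_id, matrix, receivers, reefs, "all", threshold, mating_months)
    ud_mat = compute_ud(shark_id, matrix, receivers, reefs, "mating", threshold, mating_months)
    ud_non = compute_ud(shark_id, matrix, receivers, reefs, "non_mating", threshold, mating_months)
    if ud_mat is None or ud_all is None or ud_all.ud100_km2 <= 0:
        return SeasonalUse(shark_id, 0.0, ud_mat, ud_non, ud_all)
    exclusive = 0.0
    non_hulls = ud_non.hulls100 if ud_non is not None else {}
    for reef_id, m_iv in ud_mat.hulls100.items():
        for s0, s1 in _interval_difference(m_iv, non_hulls.get(reef_id)):
            exclusive += reefs[reef_id].interval_area(s0, s1)
    frac = exclusive / ud_all.ud100_km2
    return SeasonalUse(shark_id, float(min(max(frac, 0.0), 1.0)), ud_mat, ud_non, ud_all)


# ---------------------------------------------------------------------------
# Cohort-level table
# ---------------------------------------------------------------------------

def ud_table(matrix: DailyOccurrenceMatrix, tagging: pd.DataFrame, receivers: pd.DataFrame,
             reefs: Mapping[str, ReefGeometry], seasons: Sequence[str] = SEASONS,
             threshold: float = 0.95,
             mating_months: frozenset = MATING_MONTHS) -> pd.DataFrame:
    """Long-format UD table for every animal and season.

    One row per (animal, season) in which the animal was present; columns
    include sex, maturity, UD areas, receiver count and the exclusive
    mating-season fraction (repeated on each season row of the animal).
    """
    tag = tagging.set_index("transmitter_id")
    rows = []
    for shark in matrix.sharks():
        su = seasonal_use(shark, matrix, receivers, reefs, threshold, mating_months)
        by_season = {"all": su.ud_all, "mating": su.ud_mating, "non_mating": su.ud_non_mating}
        for season in seasons:
            ud = by_season[season]
            if ud is None:
                continue
            rows.append({
                "transmitter_id": shark,
                "sex": tag.loc[shark, "sex"] if shark in tag.index else "",
                "maturity": tag.loc[shark, "maturity"] if shark in tag.index else "",
                "season": season,
                "ud95_km2": ud.ud95_km2,
                "ud100_km2": ud.ud100_km2,
                "n_receivers": ud.n_receivers,
                "fraction_exclusive_mating": su.fraction_exclusive_mating,
            })
    return pd.DataFrame(rows, columns=["transmitter_id", "sex", "maturity", "season",
                                       "ud95_km2", "ud100_km2", "n_receivers",
                                       "fraction_exclusive_mating"])
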