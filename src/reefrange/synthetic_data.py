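"""Seeded synthetic telemetry systems with known ground truth.

No raw telemetry is publicly deposited for the study system this package
models, so analyses are exercised on synthetic data whose statistical
structure matches the field situation: a handful of barrier-reef sections
treated as linear habitat, receivers moored at regular spacing along the
outer slope, and a cohort of tagged sharks in four sex × maturity groups
with group-specific range sizes (adult males largest by far, then juvenile
males, adult females, juvenile females).  Adult males expand their range
during the July–September mating season.  Each shark-day draws an
independent position uniformly over the animal's (seasonal) true range —
days are exchangeable, which is exactly the assumption the daily-bin UD
estimator relies on; within-day movement is not modelled.

The generator also reproduces the observational artefacts the cleaning
steps exist for: a two-week post-capture window, animals that fall silent
after it, receivers lost at sea, and isolated spurious decodes at
receivers far from an animal's true range.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .home_range import MATING_MONTHS, ReefGeometry

GROUPS = ("adult_male", "adult_female", "juvenile_male", "juvenile_female")

#: degrees of longitude per km at the equator
_KM_PER_DEG = 111.32


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic reef / receiver / shark system.

    Defaults describe the emulated study conditions: ~70 receivers over 4
    reef regions, 147 sharks, a 0.5 km²-per-km outer-slope strip, 30–90 s
    transmission delays, group range spans ordered adult male ≫ juvenile
    male > adult female > juvenile female, and an adult-male mating-season
    expansion sized so roughly half the male range is used exclusively in
    July–September.
    """

    seed: int = 0
    n_reefs: int = 4
    reef_lengths: tuple = (100.0, 72.0, 52.0, 44.0)          # km per reef
    area_density: tuple = (0.5, 0.5, 0.5, 0.5)               # km² slope per km
    receiver_spacing: float = 4.0                            # km
    group_sizes: dict = field(default_factory=lambda: {
        "adult_male": 66, "adult_female": 24, "juvenile_male": 24, "juvenile_female": 33})
    group_range_spans: dict = field(default_factory=lambda: {
        "adult_male": 20.0, "juvenile_male": 12.0, "adult_female": 9.0, "juvenile_female": 5.0})
    male_mating_expansion: float = 22.0                      # km added Jul–Sep
    detection_radius: float = 2.0                            # km
    daily_pings_mean: float = 12.0                           # detections logged per day
    p_silent: float = 29.0 / 147.0
    n_lost_receivers: int = 3
    n_false_detections: int = 30
    study_start: dt.date = dt.date(2015, 7, 15)
    study_end: dt.date = dt.date(2016, 12, 31)
    tag_window_days: int = 30                                # tag dates spread over this
    tz_offset_hours: float = 11.0

    def __post_init__(self):
        if len(self.reef_lengths) != self.n_reefs or len(self.area_density) != self.n_reefs:
            raise ValueError("reef_lengths and area_density must have n_reefs entries")
        if any(l <= 0 for l in self.reef_lengths):
            raise ValueError("reef lengths must be positive")
        if self.receiver_spacing <= 0 or self.detection_radius < 0:
            raise ValueError("spacing must be positive, detection radius non-negative")
        if any(s < 0 for s in self.group_range_spans.values()) or self.male_mating_expansion < 0:
            raise ValueError("range spans must be non-negative")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if not 0 <= self.p_silent <= 1:
            raise ValueError("p_silent must be a probability")
        if (self.study_end - self.study_start).days <= 14:
            raise ValueError("study must last more than 14 days")

    @property
    def n_sharks(self) -> int:
        return sum(self.group_sizes.get(g, 0) for g in GROUPS)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated system, for parameter-recovery tests.

    ``table`` has one row per shark: group, home reef, seasonal true range
    intervals ``[a, b]`` in curvilinear km, tagging receiver, silent flag
    and tag date.  The mating interval contains the non-mating interval for
    adult males and equals it for the other groups.
    """

    table: pd.DataFrame
    lost_receivers: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# System generation
# ---------------------------------------------------------------------------

_REEF_LATS = (-19.7, -20.9, -21.8, -22.6, -18.9, -23.4)
_REEF_LON0 = 163.0
_REEF_LON_GAP_DEG = 1.6


def _build_reefs(config: SimulationConfig) -> dict:
    reefs = {}
    for i in range(config.n_reefs):
        length = float(config.reef_lengths[i])
        lat = _REEF_LATS[i % len(_REEF_LATS)]
        lon0 = _REEF_LON0 + i * (_REEF_LON_GAP_DEG + max(config.reef_lengths) / _KM_PER_DEG)
        lon1 = lon0 + length / (_KM_PER_DEG * math.cos(math.radians(lat)))
        reef_id = f"reef_{i + 1}"
        reefs[reef_id] = ReefGeometry.from_density(
            reef_id, length, config.area_density[i],
            anchors=((lat, lon0), (lat, lon1)))
    return reefs


def _receiver_latlon(reef: ReefGeometry, s: float) -> tuple:
    (lat, lon0), _ = reef.anchors
    return lat, lon0 + s / (_KM_PER_DEG * math.cos(math.radians(lat)))


def _place_receivers(reefs: dict, config: SimulationConfig) -> pd.DataFrame:
    rows = []
    k = 0
    for reef_id in sorted(reefs):
        reef = reefs[reef_id]
        if config.receiver_spacing > reef.length_km:
            raise ValueError(f"no receiver fits on {reef_id}: "
                             f"spacing {config.receiver_spacing} km > length {reef.length_km} km")
        positions = np.arange(0.0, reef.length_km + 1e-9, config.receiver_spacing)
        for s in positions:
            k += 1
            lat, lon = _receiver_latlon(reef, float(s))
            rows.append({"receiver_id": f"R{k:03d}", "reef_id": reef_id,
                         "position_km": float(s), "lat": lat, "lon": lon,
                         "status": "active",
                         "deploy_start": config.study_start.isoformat(),
                         "deploy_end": config.study_end.isoformat()})
    return pd.DataFrame(rows)


def generate_system(config: SimulationConfig):
    """Generate reefs, receiver array, tagged cohort and ground truth.

    Returns ``(reefs, receivers, tagging, truth)``.  Deterministic for a
    fixed seed.  Each shark's tagging receiver lies inside its true range;
    ``n_lost_receivers`` receivers are flagged ``lost``; a fixed number of
    sharks (``round(p_silent * n)``) is designated silent after the
    post-capture window.
    """
    rng = np.random.default_rng(config.seed)
    reefs = _build_reefs(config)
    receivers = _place_receivers(reefs, config)

    reef_ids = sorted(reefs)
    lengths = np.array([reefs[r].length_km for r in reef_ids])
    reef_weights = lengths / lengths.sum()

    rows = []
    tid = 0
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        span = float(config.group_range_spans.get(group, 0.0))
        maturity, sex = group.split("_")
        for _ in range(n):
            tid += 1
            reef_id = reef_ids[rng.choice(len(reef_ids), p=reef_weights)]
            length = reefs[reef_id].length_km
            span_eff = min(span, length)
            if group == "adult_male":
                span_year = min(span_eff + config.male_mating_expansion, length)
            else:
                span_year = span_eff
            a_year = rng.uniform(0.0, length - span_year) if length > span_year else 0.0
            b_year = a_year + span_year
            # non-mating range sits at one (random) end of the full-year range
            if rng.random() < 0.5:
                a_nm, b_nm = a_year, a_year + span_eff
            else:
                a_nm, b_nm = b_year - span_eff, b_year
            length_cm = {"adult_male": 165.0, "adult_female": 170.0,
                         "juvenile_male": 110.0, "juvenile_female": 105.0}[group] \
                + rng.normal(0.0, 8.0)
            tag_offset = int(rng.integers(0, config.tag_window_days + 1))
            rows.append({"transmitter_id": f"T{tid:03d}", "group": group,
                         "sex": sex, "maturity": maturity, "reef_id": reef_id,
                         "a_nonmating": a_nm, "b_nonmating": b_nm,
                         "a_mating": a_year, "b_mating": b_year,
                         "length_cm": round(float(length_cm), 1),
                         "tag_date": config.study_start + dt.timedelta(days=tag_offset)})
    truth_tbl = pd.DataFrame(rows, columns=[
        "transmitter_id", "group", "sex", "maturity", "reef_id",
        "a_nonmating", "b_nonmating", "a_mating", "b_mating", "length_cm", "tag_date"])

    # tagging receiver: drawn among receivers inside the non-mating range
    tag_rx = []
    for row in truth_tbl.itertuples(index=False):
        on_reef = receivers[receivers["reef_id"] == row.reef_id]
        inside = on_reef[(on_reef["position_km"] >= row.a_nonmating)
                         & (on_reef["position_km"] <= row.b_nonmating)]
        if len(inside) == 0:  # narrow range between two receivers: take nearest
            centre = 0.5 * (row.a_nonmating + row.b_nonmating)
            inside = on_reef.iloc[[int((on_reef["position_km"] - centre).abs().argmin())]]
        tag_rx.append(inside["receiver_id"].iloc[int(rng.integers(0, len(inside)))])
    truth_tbl["tag_receiver_id"] = tag_rx

    n_silent = int(round(config.p_silent * len(truth_tbl)))
    silent_idx = rng.choice(len(truth_tbl), size=n_silent, replace=False) if n_silent else []
    truth_tbl["silent"] = False
    truth_tbl.loc[list(silent_idx), "silent"] = True

    lost = []
    if config.n_lost_receivers > 0:
        lost_idx = rng.choice(len(receivers), size=config.n_lost_receivers, replace=False)
        lost = sorted(receivers["receiver_id"].iloc[lost_idx])
        receivers.loc[receivers["receiver_id"].isin(lost), "status"] = "lost"

    truth = SyntheticTruth(table=truth_tbl.reset_index(drop=True), lost_receivers=list(lost))
    return reefs, receivers, tagging_table(truth), truth


def tagging_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Tagging metadata table (what a field data sheet would contain)."""
    t = truth.table
    return pd.DataFrame({
        "transmitter_id": t["transmitter_id"],
        "sex": t["sex"],
        "maturity": t["maturity"],
        "length_cm": t["length_cm"],
        "tag_date": pd.to_datetime(t["tag_date"]),
        "tag_receiver_id": t["tag_receiver_id"],
    })


# ---------------------------------------------------------------------------
# Detection simulation
# ---------------------------------------------------------------------------

def simulate_detections(truth: SyntheticTruth, receivers: pd.DataFrame,
                        config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate the detection log of a generated system.

    Per shark-day, a position is drawn uniformly over the seasonal true
    range; every *active* receiver within ``detection_radius`` (curvilinear
    km, same reef) logs that day's ping train.  Ping counts per day are
    Poisson(``daily_pings_mean``); successive inter-ping delays are uniform
    on 30–90 s, emulating the tags' randomised duty cycle.  Silent sharks
    transmit only during the first 14 days after tagging.  Isolated false
    decodes (``n_false_detections`` in total) are injected at receivers on
    reefs other than the animal's home reef.  Output is sorted by time.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    active = receivers[receivers["status"] == "active"]
    rx_by_reef = {reef: grp[["receiver_id", "position_km"]].reset_index(drop=True)
                  for reef, grp in active.groupby("reef_id")}

    start = config.study_start
    n_days_total = (config.study_end - start).days + 1
    all_days = pd.date_range(start, config.study_end, freq="D")
    months = all_days.month.to_numpy()
    mating = np.isin(months, list(MATING_MONTHS))

    ts_chunks, rx_chunks, tx_chunks = [], [], []
    for row in truth.table.itertuples(index=False):
        day0 = (row.tag_date - start).days
        if row.silent:
            day1 = min(day0 + 14, n_days_total)
        else:
            day1 = n_days_total
        if day1 <= day0:
            continue
        idx = np.arange(day0, day1)
        lo = np.where(mating[idx], row.a_mating, row.a_nonmating)
        hi = np.where(mating[idx], row.b_mating, row.b_nonmating)
        pos = rng.uniform(lo, hi)
        n_pings = rng.poisson(config.daily_pings_mean, size=len(idx))
        rx = rx_by_reef.get(row.reef_id)
        if rx is None:
            continue
        rx_pos = rx["position_km"].to_numpy()
        rx_ids = rx["receiver_id"].to_numpy()
        day_ns = all_days.values[idx].astype("datetime64[ns]").astype("int64")
        for d in range(len(idx)):
            n = n_pings[d]
            if n == 0:
                continue
            hear = np.abs(rx_pos - pos[d]) <= config.detection_radius
            if not hear.any():
                continue
            delays = rng.uniform(30.0, 90.0, size=n)
            t0 = rng.uniform(0.0, max(1.0, 86400.0 - delays.sum()))
            tsec = t0 + np.cumsum(delays)
            heard = rx_ids[hear]
            t_ns = day_ns[d] + (tsec * 1e9).astype("int64")
            ts_chunks.append(np.repeat(t_ns, len(heard)))
            rx_chunks.append(np.tile(heard, n))
            tx_chunks.append(np.full(n * len(heard), row.transmitter_id, dtype=object))

    # injected false decodes: isolated single pings away from the true range
    n_false = config.n_false_detections
    if n_false > 0 and len(truth.table) > 0 and len(active) > 0:
        t = truth.table
        for _ in range(n_false):
            s = t.iloc[int(rng.integers(0, len(t)))]
            other = active[active["reef_id"] != s["reef_id"]]
            if len(other) == 0:
                far = active[(active["reef_id"] == s["reef_id"])
                             & ((active["position_km"] < s["a_mating"] - 3 * config.detection_radius)
                                | (active["position_km"] > s["b_mating"] + 3 * config.detection_radius))]
                if len(far) == 0:
                    continue
                other = far
            rx_id = other["receiver_id"].iloc[int(rng.integers(0, len(other)))]
            day = int(rng.integers((s["tag_date"] - start).days, n_days_total))
            sec = float(rng.uniform(0, 86400.0))
            t_ns = int(all_days.values[day].astype("datetime64[ns]").astype("int64") + sec * 1e9)
            ts_chunks.append(np.array([t_ns], dtype="int64"))
            rx_chunks.append(np.array([rx_id], dtype=object))
            tx_chunks.append(np.array([s["transmitter_id"]], dtype=object))

    if not ts_chunks:
        return pd.DataFrame({"timestamp": pd.DatetimeIndex([], tz="UTC"),
                             "receiver_id": pd.Series([], dtype=object),
                             "transmitter_id": pd.Series([], dtype=object)})
    # times above are in local clock; store UTC
    local_ns = np.concatenate(ts_chunks)
    ts = pd.to_datetime(local_ns, utc=True) - pd.Timedelta(hours=config.tz_offset_hours)
    out = pd.DataFrame({"timestamp": ts,
                        "receiver_id": np.concatenate(rx_chunks),
                        "transmitter_id": np.concatenate(tx_chunks)})
    out["timestamp"] = out["timestamp"].dt.floor("s")
    out = out.sort_values(["timestamp", "receiver_id", "transmitter_id"],
                          kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# The frozen study-scale cohort fixture
# ---------------------------------------------------------------------------

PAPER_COHORT_SEED = 20150715
PAPER_COHORT_CONFIG = SimulationConfig(seed=PAPER_COHORT_SEED, n_lost_receivers=0)


def paper_cohort():
    """Deterministic study-scale fixture: 147 sharks, 29 silent, 3 of them
    tagged at receivers that were subsequently lost.

    The three lost-receiver animals are engineered to be a subset of the 29
    silent ones and sole users of their tagging receivers, so the cohort
    rules (lost-receiver exclusions first, then silence) retain exactly 118
    animals without excluding bystanders.  Returns
    ``(config, reefs, receivers, tagging, truth)``.
    """
    config = PAPER_COHORT_CONFIG
    reefs, receivers, _, truth = generate_system(config)
    t = truth.table
    silent_ids = list(t.loc[t["silent"], "transmitter_id"])
    assert len(silent_ids) == 29, "fixture invariant: 29 silent sharks"

    rx_usage = t.groupby("tag_receiver_id")["transmitter_id"].apply(list)
    lost = []
    lost_sharks = []
    for tid in silent_ids:
        rx = t.loc[t["transmitter_id"] == tid, "tag_receiver_id"].iloc[0]
        if rx_usage.get(rx) == [tid]:
            lost.append(rx)
            lost_sharks.append(tid)
        if len(lost) == 3:
            break
    if len(lost) < 3:  # move a silent shark to an unused receiver in its range
        used = set(t["tag_receiver_id"])
        for tid in silent_ids:
            if tid in lost_sharks:
                continue
            row = t[t["transmitter_id"] == tid].iloc[0]
            on_reef = receivers[receivers["reef_id"] == row["reef_id"]]
            free = on_reef[(~on_reef["receiver_id"].isin(used))
                           & (on_reef["position_km"] >= row["a_nonmating"])
                           & (on_reef["position_km"] <= row["b_nonmating"])]
            if len(free) == 0:
                continue
            rx = free["receiver_id"].iloc[0]
            t.loc[t["transmitter_id"] == tid, "tag_receiver_id"] = rx
            used.add(rx)
            lost.append(rx)
            lost_sharks.append(tid)
            if len(lost) == 3:
                break
    assert len(lost) == 3, "fixture invariant: 3 lost tagging receivers"
    receivers = receivers.copy()
    receivers.loc[receivers["receiver_id"].isin(lost), "status"] = "lost"
    truth = SyntheticTruth(table=t, lost_receivers=sorted(lost))
    return config, reefs, receivers, tagging_table(truth), truth


# ---------------------------------------------------------------------------
# GeoJSON / CSV writers
# ---------------------------------------------------------------------------

def write_system(outdir, reefs: dict, receivers: pd.DataFrame, tagging: pd.DataFrame,
                 detections: pd.DataFrame, truth: SyntheticTruth | None = None) -> dict:
    """Write the system as the plain-text files downstream stages read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    det = detections.copy()
    det["timestamp"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    paths["detections"] = outdir / "detections.csv"
    det.to_csv(paths["detections"], index=False)

    paths["receivers"] = outdir / "receivers.csv"
    receivers.to_csv(paths["receivers"], index=False)

    tg = tagging.copy()
    tg["tag_date"] = pd.to_datetime(tg["tag_date"]).dt.strftime("%Y-%m-%d")
    paths["tagging"] = outdir / "tagging.csv"
    tg.to_csv(paths["tagging"], index=False)

    feats = []
    area_rows = []
    for reef_id in sorted(reefs):
        reef = reefs[reef_id]
        coords = [[lon, lat] for lat, lon in reef.anchors]
        feats.append({"type": "Feature",
                      "properties": {"reef_id": reef_id, "length_km": reef.length_km},
                      "geometry": {"type": "LineString", "coordinates": coords}})
        for s, a in zip(reef.s_knots, reef.area_knots):
            area_rows.append({"reef_id": reef_id, "s_km": float(s), "cum_area_km2": float(a)})
    paths["reefs"] = outdir / "reefs.geojson"
    paths["reefs"].write_text(json.dumps({"type": "FeatureCollection", "features": feats},
                                         sort_keys=True))
    paths["reef_areas"] = outdir / "reef_areas.csv"
    pd.DataFrame(area_rows).to_csv(paths["reef_areas"], index=False)

    if truth is not None:
        tt = truth.table.copy()
        tt["tag_date"] = pd.to_datetime(tt["tag_date"]).dt.strftime("%Y-%m-%d")
        paths["truth"] = outdir / "truth.csv"
        tt.to_csv(paths["truth"], index=False)
    return paths


def read_reef_geometries(reefs_geojson, reef_areas_csv) -> dict:
    """Rebuild :class:`ReefGeometry` objects from the files written above."""
    fc = json.loads(Path(reefs_geojson).read_text())
    areas = pd.read_csv(reef_areas_csv)
    reefs = {}
    for feat in fc["features"]:
        reef_id = feat["properties"]["reef_id"]
        length = float(feat["properties"]["length_km"])
        anchors = tuple((lat, lon) for lon, lat in feat["geometry"]["coordinates"])
        sub = areas[areas["reef_id"] == reef_id].sort_values("s_km")
        reefs[reef_id] = ReefGeometry(reef_id, length, sub["s_km"].to_numpy(),
                                      sub["cum_area_km2"].to_numpy(), anchors=anchors)
    return reefs


# ---------------------------------------------------------------------------
# MPA / reef-polygon fixtures for the screening stage
# ---------------------------------------------------------------------------

def _box_coords(lon0, lat0, lon1, lat1):
    return [[[lon0, lat0], [lon1, lat0], [lon1, lat1], [lon0, lat1], [lon0, lat0]]]


def build_mpa_fixture_collections() -> tuple[dict, dict]:
    """Engineered WDPA-style MPA polygons and reef polygons (GeoJSON dicts).

    Covers every screening branch: IUCN categories in and outside {I, Ia,
    Ib, II}, a missing designation year, centroids outside the latitude and
    longitude box, a polygon straddling the antimeridian, a polygon with no
    reef overlap, a self-intersecting (bowtie) polygon needing repair, a
    missing IUCN attribute, and reef squares of analytically known geodesic
    area.  Retained after screening: M01, M05, M06, M09; above the 95 km²
    reef-area threshold: M01, M05, M09.
    """
    reefs = {"type": "FeatureCollection", "features": [
        {"type": "Feature",  # 0.1° x 0.1° square at the equator, ~123.6 km²
         "properties": {"reef_id": "reef_eq"},
         "geometry": {"type": "Polygon",
                      "coordinates": _box_coords(160.0, -0.05, 160.1, 0.05)}},
        {"type": "Feature",  # square on the antimeridian side, at 10°S
         "properties": {"reef_id": "reef_am"},
         "geometry": {"type": "Polygon",
                      "coordinates": _box_coords(-170.05, -10.05, -169.95, -9.95)}},
        {"type": "Feature",  # 1° x 1° reef bank, ~12,300 km²
         "properties": {"reef_id": "reef_large"},
         "geometry": {"type": "Polygon",
                      "coordinates": _box_coords(160.5, -5.5, 161.5, -4.5)}},
    ]}

    def mpa(mid, name, cat, year, coords, geom_type="Polygon"):
        props = {"WDPAID": mid, "NAME": name}
        if cat is not None:
            props["IUCN_CAT"] = cat
        props["STATUS_YR"] = year if year is not None else 0
        return {"type": "Feature", "properties": props,
                "geometry": {"type": geom_type, "coordinates": coords}}

    mpas = {"type": "FeatureCollection", "features": [
        mpa("M01", "Equator Reserve", "II", 2008, _box_coords(159.9, -0.2, 160.2, 0.2)),
        mpa("M02", "Multi-Use Park", "VI", 2000, _box_coords(159.9, -0.2, 160.2, 0.2)),
        mpa("M03", "Undated Sanctuary", "Ia", None, _box_coords(159.9, -0.2, 160.2, 0.2)),
        mpa("M04", "Atlantic Outpost", "II", 2012, _box_coords(19.8, -5.2, 20.2, -4.8)),
        # centroid at 170°W: inside the study box once longitude is normalized
        mpa("M05", "Dateline Atoll", "II", 2015,
            _box_coords(-170.2, -10.2, -169.8, -9.8)),
        mpa("M06", "Reef Sliver Reserve", "I", 1995, _box_coords(160.0, -0.05, 160.02, 0.05)),
        # straddles the antimeridian (179.8°E to 179.8°W); no reef beneath it
        mpa("M07", "Dateline Sands", "II", 2005, _box_coords(179.8, -15.2, -179.8, -14.8)),
        mpa("M08", "Northern Park", "II", 2018, _box_coords(160.0, 29.8, 160.3, 30.2)),
        # bowtie: self-intersecting ring over the large reef bank, repairable
        mpa("M09", "Bowtie Bank", "II", 2010,
            [[[160.5, -5.5], [161.5, -4.5], [160.5, -4.5], [161.5, -5.5], [160.5, -5.5]]]),
        mpa("M10", "Unclassified Area", None, 2001, _box_coords(160.0, -0.2, 160.3, 0.2)),
    ]}
    return mpas, reefs


def generate_mpa_fixtures(mpa_path, reef_path) -> tuple[Path, Path]:
    """Write the engineered MPA and reef-polygon fixtures as GeoJSON."""
    mpas, reefs = build_mpa_fixture_collections()
    mpa_path, reef_path = Path(mpa_path), Path(reef_path)
    mpa_path.parent.mkdir(parents=True, exist_ok=True)
    reef_path.parent.mkdir(parents=True, exist_ok=True)
    mpa_path.write_text(json.dumps(mpas, sort_keys=True))
    reef_path.write_text(json.dumps(reefs, sort_keys=True))
    return mpa_path, reef_path
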