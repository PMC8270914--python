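"""Screening of WDPA-style protected-area polygons against reef habitat.

Candidate MPAs for covering reef-shark home ranges are screened on four
criteria: a strict management category (IUCN I — including Ia/Ib — or II,
i.e. no extractive activities), a known designation year, a centroid inside
the species' Indo-Pacific range box (26°S–26°N, 25°E westwards to 150°W —
a box that spans the antimeridian), and a non-empty intersection with reef
habitat.  The reef area protected by each MPA is the geodesic area of the
intersection between the MPA polygon and the reef polygons, and MPAs are
classified against a threshold reef area (95 km² by default).

Areas are computed on the WGS84 ellipsoid via the authalic-latitude
cylindrical equal-area mapping: a ring's vertices ``(λ, φ)`` map to
``(R_a·λ, R_a·sin β(φ))`` where ``β`` is the authalic latitude and ``R_a``
the authalic radius, and the planar shoelace area of the mapped ring is the
ellipsoidal area (exact for constant-latitude edges, and accurate far
beyond the needs of reef-scale polygons otherwise).  Longitudes are
unwrapped per ring, so antimeridian-straddling geometries are handled
without cutting.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape
from shapely.ops import transform as shp_transform

logger = logging.getLogger("reefrange")

STRICT_IUCN = frozenset({"I", "IA", "IB", "II"})
RANGE_BOX = (-26.0, 26.0, 25.0, -150.0)  # lat_min, lat_max, lon_east_start, lon_west_end
REEF_AREA_THRESHOLD_KM2 = 95.0

# WGS84
_A_KM = 6378.137
_F = 1.0 / 298.257223563
_E2 = _F * (2 - _F)
_E = math.sqrt(_E2)


def _authalic_q(phi: np.ndarray) -> np.ndarray:
    s = np.sin(phi)
    return (1 - _E2) * (s / (1 - _E2 * s * s)
                        - (1 / (2 * _E)) * np.log((1 - _E * s) / (1 + _E * s)))


_QP = float(_authalic_q(np.array([math.pi / 2]))[0])
_RA2 = _A_KM * _A_KM * _QP / 2.0  # squared authalic radius


def _ring_area_km2(coords) -> float:
    arr = np.asarray(coords, dtype=float)
    lam = np.unwrap(np.radians(arr[:, 0]))
    y = _authalic_q(np.radians(arr[:, 1])) / _QP  # sin of authalic latitude
    x = lam
    return _RA2 * 0.5 * abs(float(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1])))


def geodesic_area_km2(geom) -> float:
    """Ellipsoidal (WGS84) area of a polygonal geometry, in km²."""
    if geom.is_empty:
        return 0.0
    if geom.geom_type == "Polygon":
        area = _ring_area_km2(geom.exterior.coords)
        for hole in geom.interiors:
            area -= _ring_area_km2(hole.coords)
        return max(area, 0.0)
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        return sum(geodesic_area_km2(g) for g in geom.geoms
                   if g.geom_type in ("Polygon", "MultiPolygon"))
    return 0.0


def normalize_lon(lon):
    """Map longitudes to [0°, 360°), the frame in which the range box is convex."""
    return np.mod(lon, 360.0)


def _to_lon360(geom):
    """Shift a geometry into the [0, 360) longitude frame.

    Rings are unwrapped first so antimeridian-straddling polygons stay in
    one piece instead of wrapping around the globe.
    """
    def _fix(x, y):
        x = np.asarray(x, dtype=float)
        x = np.degrees(np.unwrap(np.radians(x)))
        shift = np.floor(x.mean() / 360.0) * 360.0
        x = x - shift
        if x.mean() < 0:
            x = x + 360.0
        return x, y

    return shp_transform(_fix, geom)


def _repair(geom):
    if geom.is_valid:
        return geom
    fixed = shapely.make_valid(geom)
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        fixed = shapely.unary_union(polys) if polys else fixed
    return fixed


_ID_KEYS = ("WDPAID", "wdpaid", "wdpa_id", "mpa_id", "id")
_NAME_KEYS = ("NAME", "name", "ORIG_NAME")
_IUCN_KEYS = ("IUCN_CAT", "iucn_cat", "iucn_category")
_YEAR_KEYS = ("STATUS_YR", "status_yr", "status_year", "year")


def _first(props: dict, keys, default=None):
    for k in keys:
        if k in props and props[k] not in (None, ""):
            return props[k]
    return default


def read_mpa_polygons(path) -> pd.DataFrame:
    """Read WDPA-style MPA polygons from GeoJSON.

    Attribute names are normalised (WDPAID/NAME/IUCN_CAT/STATUS_YR and
    common lowercase variants); a missing IUCN category becomes
    ``"not reported"`` and a missing or zero status year becomes NA.
    Invalid geometries are repaired; features without geometry are dropped
    with a warning.
    """
    fc = json.loads(Path(path).read_text())
    feats = fc.get("features", [])
    rows = []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if not feat.get("geometry"):
            logger.warning("read_mpa_polygons: feature %s has no geometry, dropped",
                           _first(props, _ID_KEYS, default=k))
            continue
        geom = _repair(shape(feat["geometry"]))
        year = _first(props, _YEAR_KEYS)
        try:
            year = int(year) if year is not None else None
        except (TypeError, ValueError):
            year = None
        if year is not None and year <= 0:  # WDPA encodes unknown years as 0
            year = None
        geom360 = _to_lon360(geom)
        centroid = geom360.centroid
        rows.append({
            "mpa_id": str(_first(props, _ID_KEYS, default=f"feature_{k}")),
            "name": str(_first(props, _NAME_KEYS, default="")),
            "iucn_category": str(_first(props, _IUCN_KEYS, default="not reported")),
            "status_year": year,
            "geometry": geom,
            "geometry_lon360": geom360,
            "centroid_lat": float(centroid.y),
            "centroid_lon360": float(normalize_lon(centroid.x)),
        })
    df = pd.DataFrame(rows, columns=["mpa_id", "name", "iucn_category", "status_year",
                                     "geometry", "geometry_lon360",
                                     "centroid_lat", "centroid_lon360"])
    df["status_year"] = df["status_year"].astype("Int64")
    return df


def read_reef_polygons(path) -> list:
    """Reef-habitat polygons from GeoJSON, repaired and in the lon-360 frame."""
    fc = json.loads(Path(path).read_text())
    return [_to_lon360(_repair(shape(f["geometry"])))
            for f in fc.get("features", []) if f.get("geometry")]


def filter_mpas(records: pd.DataFrame, reef_polygons: list,
                box: tuple = RANGE_BOX) -> pd.DataFrame:
    """Keep strict, dated MPAs inside the range box that touch reef habitat.

    ``box`` is ``(lat_min, lat_max, lon_east_start, lon_west_end)``; the
    longitude test is performed in the [0°, 360°) frame so a box such as
    25°E → 150°W (i.e. 25°–210°) spans the antimeridian naturally.
    Order-independent and idempotent (row-wise predicate).
    """
    lat_min, lat_max, lon0, lon1 = box
    lon0n, lon1n = normalize_lon(lon0), normalize_lon(lon1)
    reef_union = shapely.unary_union(reef_polygons) if reef_polygons else None

    def keep(row) -> bool:
        cat = str(row.iucn_category).strip().upper()
        if cat not in STRICT_IUCN:
            return False
        if pd.isna(row.status_year):
            return False
        if not (lat_min <= row.centroid_lat <= lat_max):
            return False
        lon = row.centroid_lon360
        inside = (lon0n <= lon <= lon1n) if lon0n <= lon1n \
            else (lon >= lon0n or lon <= lon1n)
        if not inside:
            return False
        if reef_union is None or not row.geometry_lon360.intersects(reef_union):
            return False
        return True

    mask = [keep(row) for row in records.itertuples(index=False)]
    return records[mask].reset_index(drop=True)


def reef_area_covered(geometry_lon360, reef_polygons: list) -> float:
    """Geodesic area (km²) of the intersection of an MPA with reef habitat."""
    if not reef_polygons:
        return 0.0
    geom = _repair(geometry_lon360)
    if not geom.is_valid:
        raise ValueError("geometry invalid after repair")
    inter = geom.intersection(shapely.unary_union(reef_polygons))
    return geodesic_area_km2(inter)


def add_reef_areas(records: pd.DataFrame, reef_polygons: list) -> pd.DataFrame:
    out = records.copy()
    out["reef_area_km2"] = [reef_area_covered(g, reef_polygons)
                            for g in out["geometry_lon360"]]
    return out


def classify_by_reef_area(records: pd.DataFrame,
                          threshold_km2: float = REEF_AREA_THRESHOLD_KM2,
                          year_bin: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition MPAs at a strict reef-area threshold; summarise by year bin.

    Returns ``(above, summary)`` where ``above`` holds the records with
    ``reef_area_km2 > threshold`` and ``summary`` counts records (and how
    many are above threshold) per designation-year bin.
    """
    if "reef_area_km2" not in records.columns:
        raise ValueError("records need a reef_area_km2 column (see add_reef_areas)")
    above = records[records["reef_area_km2"] > threshold_km2].reset_index(drop=True)
    with_year = records[records["status_year"].notna()].copy()
    if len(with_year):
        bins = (with_year["status_year"].astype(int) // year_bin) * year_bin
        summary = (with_year.assign(year_bin=bins)
                   .groupby("year_bin")
                   .agg(n_mpas=("mpa_id", "size"),
                        n_above=("reef_area_km2", lambda a: int((a > threshold_km2).sum())))
                   .reset_index())
    else:
        summary = pd.DataFrame(columns=["year_bin", "n_mpas", "n_above"])
    return above, summary
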