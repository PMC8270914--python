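"""End-to-end pipeline: simulate → clean → home range → stats → coverage → MPAs.

Stages are pure functions of their inputs and a master seed; the master
seed is fanned out to per-stage seeds with ``numpy.random.SeedSequence``
(spawn keys in a fixed order), so each stage is reproducible in isolation
and two runs with the same seed produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import home_range, mpa_coverage, mpa_screening, population_stats, synthetic_data
from . import telemetry_io

logger = logging.getLogger("reefrange")

SCHEMA_VERSION = "reefrange-schema 1"

# fixed spawn order for per-stage seed derivation
_STAGE_NAMES = ("simulate", "stats", "curves", "coverage")


@dataclass
class PipelineConfig:
    """All knobs of a full pipeline run.

    Thresholds and resampling counts default to the study constants: 0.95
    core-receiver share, 10 km² reporting threshold, 95 km² MPA reef-area
    threshold, 0.8 coverage target, 5000 / 999 / 200 permutation and
    bootstrap counts, UTC+11 study timezone and a July–September mating
    season.
    """

    out_dir: str = "reefrange_out"
    seed: int = 0
    simulate: bool = True                      # generate inputs before running
    detections: str | None = None              # used when simulate is False
    receivers: str | None = None
    tagging: str | None = None
    reefs_geojson: str | None = None
    reef_areas: str | None = None
    mpas_geojson: str | None = None
    reef_polygons_geojson: str | None = None
    tz_offset_hours: float = 11.0
    mating_months: tuple = (7, 8, 9)
    core_threshold: float = 0.95
    report_threshold_km2: float = 10.0
    mpa_threshold_km2: float = 95.0
    coverage_target: float = 0.8
    false_window_s: float = 3600.0
    post_capture_days: int = 14
    permanova_iter: int = 5000
    pairwise_perm: int = 999
    bootstrap_runs: int = 200
    coverage_grid_max: float = 200.0
    named_mpa_sizes: dict = field(default_factory=lambda: {
        "abore_10km2": 10.0, "entrecasteaux_80km2": 80.0, "chesterfield_1130km2": 1130.0})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mating_months" in data:
            data["mating_months"] = tuple(data["mating_months"])
        return cls(**data)


def stage_seeds(master_seed: int) -> dict:
    """Derive one independent 31-bit seed per stage from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_STAGE_NAMES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_STAGE_NAMES, children)}


def _write_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the summary report (also written as ``report.json``).  Any
    stage failure is re-raised annotated with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    mating_months = frozenset(config.mating_months)
    report: dict = {"seed": config.seed, "stages": {}}

    stage = "inputs"
    try:
        if config.simulate:
            cfg, reefs, receivers, tagging, truth = synthetic_data.paper_cohort()
            detections = synthetic_data.simulate_detections(
                truth, receivers, cfg, seed=seeds["simulate"])
            paths = synthetic_data.write_system(out / "inputs", reefs, receivers,
                                                tagging, detections, truth)
            mpa_path, reef_poly_path = synthetic_data.generate_mpa_fixtures(
                out / "inputs" / "mpas.geojson", out / "inputs" / "reef_polygons.geojson")
        else:
            for name in ("detections", "receivers", "tagging", "reefs_geojson",
                         "reef_areas", "mpas_geojson", "reef_polygons_geojson"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input {name!r} missing: {p}")
            paths = {"detections": config.detections, "receivers": config.receivers,
                     "tagging": config.tagging, "reefs": config.reefs_geojson,
                     "reef_areas": config.reef_areas}
            mpa_path, reef_poly_path = config.mpas_geojson, config.reef_polygons_geojson
            detections = telemetry_io.read_detections(paths["detections"])
            receivers = telemetry_io.read_receivers(paths["receivers"])
            tagging = telemetry_io.read_tagging(paths["tagging"])
            reefs = synthetic_data.read_reef_geometries(paths["reefs"], paths["reef_areas"])
        if config.simulate:
            detections = telemetry_io.read_detections(paths["detections"])
            receivers = telemetry_io.read_receivers(paths["receivers"])
            tagging = telemetry_io.read_tagging(paths["tagging"])
            reefs = synthetic_data.read_reef_geometries(paths["reefs"], paths["reef_areas"])
        report["stages"]["inputs"] = {"n_detections_raw": int(len(detections)),
                                      "n_receivers": int(len(receivers)),
                                      "n_tagged": int(len(tagging))}

        stage = "filter"
        filtered, n_removed = telemetry_io.filter_false_detections(
            detections, window_s=config.false_window_s)
        windowed = telemetry_io.apply_post_capture_window(
            filtered, tagging, days=config.post_capture_days,
            tz_offset_hours=config.tz_offset_hours)
        cohort = telemetry_io.build_cohort(windowed, tagging, receivers)
        report["stages"]["filter"] = {
            "n_false_removed": int(n_removed),
            "n_after_window": int(len(windowed)),
            "n_tagged": cohort.n_tagged,
            "n_excluded_silent": cohort.n_excluded_silent,
            "n_excluded_lost_receiver": cohort.n_excluded_lost_receiver,
            "n_retained": cohort.n_retained,
            "group_counts": cohort.group_counts,
        }

        stage = "homerange"
        matrix = home_range.daily_occurrences(windowed, cohort.retained_ids,
                                              tz_offset_hours=config.tz_offset_hours)
        ud = home_range.ud_table(matrix, tagging, receivers, reefs,
                                 threshold=config.core_threshold,
                                 mating_months=mating_months)
        _write_table(ud, out / "ud.csv")
        ud_all = ud[ud["season"] == "all"].reset_index(drop=True)
        report["stages"]["homerange"] = {
            "n_sharks_with_ud": int(len(ud_all)),
            "mean_ud95_km2": float(ud_all["ud95_km2"].mean()),
            "mean_ud100_km2": float(ud_all["ud100_km2"].mean()),
            "n_single_receiver": int((ud_all["n_receivers"] == 1).sum()),
        }

        stage = "stats"
        stats_out: dict = {}
        rng_seed = seeds["stats"]
        for metric in ("ud95_km2", "ud100_km2"):
            per_metric: dict = {}
            for season in home_range.SEASONS:
                sub = ud[ud["season"] == season]
                if len(sub) < 4 or sub["sex"].nunique() < 2 or sub["maturity"].nunique() < 2:
                    continue
                y = population_stats.transform_ud(sub[metric].to_numpy())
                res = population_stats.permanova_two_way(
                    y, sub["sex"].to_numpy(), sub["maturity"].to_numpy(),
                    max_iter=config.permanova_iter, seed=rng_seed)
                per_metric[season] = [dataclasses.asdict(r) for r in res]
                rng_seed += 1
            stats_out[metric] = per_metric
        groups = ud_all["maturity"].str.cat(ud_all["sex"], sep="_")
        pair_p = population_stats.pairwise_permutation_t(
            population_stats.transform_ud(ud_all["ud100_km2"].to_numpy()),
            groups.to_numpy(), n_perm=config.pairwise_perm, seed=seeds["stats"] + 100)
        stats_out["pairwise_ud100_p"] = {c: {r: (None if pd.isna(pair_p.loc[r, c])
                                                 else float(pair_p.loc[r, c]))
                                             for r in pair_p.index}
                                         for c in pair_p.columns}
        summaries = {}
        prop = {}
        for metric in ("ud95_km2", "ud100_km2"):
            gs = population_stats.group_summary(ud_all, metric,
                                                n_boot=config.bootstrap_runs,
                                                seed=seeds["curves"])
            summaries[metric] = gs.to_dict(orient="records")
            mean, lo, hi = population_stats.bootstrap_mean_ci(
                ud_all[metric].to_numpy(), n_boot=config.bootstrap_runs,
                seed=seeds["curves"] + 1)
            frac, flo, fhi = population_stats.proportion_below(
                ud_all[metric].to_numpy(), config.report_threshold_km2,
                n_boot=config.bootstrap_runs, seed=seeds["curves"] + 2)
            prop[metric] = {"overall_mean_km2": mean, "ci": [lo, hi],
                            "prop_below_threshold": frac, "prop_ci": [flo, fhi],
                            "threshold_km2": config.report_threshold_km2}
        stats_out["group_means"] = summaries
        stats_out["overall"] = prop
        (out / "stats.json").write_text(json.dumps(stats_out, indent=1, sort_keys=True))
        report["stages"]["stats"] = {"written": "stats.json"}

        stage = "coverage"
        adult_males = ud_all[(ud_all["sex"] == "male") & (ud_all["maturity"] == "adult")]
        grid = np.arange(1.0, config.coverage_grid_max + 0.5, 1.0)
        curve_rows = []
        cov_summary: dict = {"at_named_sizes": {}, "min_size_for_target": {}}
        for subgroup, sub in (("all", ud_all), ("adult_male", adult_males)):
            for metric in ("ud95_km2", "ud100_km2"):
                vals = sub[metric].to_numpy()
                if len(vals) == 0:
                    continue
                curve = mpa_coverage.coverage_curve(vals, grid, subgroup=subgroup,
                                                    metric=metric)
                for s, pi in zip(curve.S_grid, curve.Pi):
                    curve_rows.append({"subgroup": subgroup, "metric": metric,
                                       "S_km2": float(s), "Pi": float(pi)})
                key = f"{subgroup}.{metric}"
                cov_summary["at_named_sizes"][key] = {
                    name: float(mpa_coverage.coverage_probability(vals, s).Pi_overall)
                    for name, s in config.named_mpa_sizes.items()}
                cov_summary["min_size_for_target"][key] = float(
                    mpa_coverage.min_size_for_target(vals, config.coverage_target))
        _write_table(pd.DataFrame(curve_rows), out / "coverage.csv")
        report["stages"]["coverage"] = cov_summary

        stage = "screen-mpas"
        mpas = mpa_screening.read_mpa_polygons(mpa_path)
        reef_polys = mpa_screening.read_reef_polygons(reef_poly_path)
        kept = mpa_screening.filter_mpas(mpas, reef_polys)
        kept = mpa_screening.add_reef_areas(kept, reef_polys)
        above, by_year = mpa_screening.classify_by_reef_area(
            kept, threshold_km2=config.mpa_threshold_km2)
        screened = kept.drop(columns=["geometry", "geometry_lon360"])
        _write_table(screened, out / "screened_mpas.csv")
        feats = []
        for row in kept.itertuples(index=False):
            feats.append({"type": "Feature",
                          "properties": {"mpa_id": row.mpa_id, "name": row.name,
                                         "iucn_category": row.iucn_category,
                                         "status_year": int(row.status_year),
                                         "reef_area_km2": row.reef_area_km2},
                          "geometry": json.loads(shapely_to_geojson(row.geometry))})
        (out / "screened_mpas.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": feats}, sort_keys=True))
        report["stages"]["screen_mpas"] = {
            "n_input": int(len(mpas)),
            "n_retained": int(len(kept)),
            "n_above_threshold": int(len(above)),
            "threshold_km2": config.mpa_threshold_km2,
            "above_ids": sorted(above["mpa_id"].tolist()),
            "by_year_bin": by_year.to_dict(orient="records"),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", out / "report.json")
    return report


def shapely_to_geojson(geom) -> str:
    return shapely.to_geojson(geom)
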