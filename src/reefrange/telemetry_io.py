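"""Reading and cleaning passive acoustic telemetry tables.

Detection logs exported from receiver downloads are cleaned in three
steps before home-range estimation:

1. *false-detection filtering* — coded transmitters occasionally produce
   spurious decodes; a detection with no corroborating detection of the
   same transmitter at the same receiver within a configurable time window
   is treated as false and removed;
2. *post-capture window* — behaviour in the first two weeks after capture
   and surgery is not considered representative, so those detections are
   discarded;
3. *cohort exclusion* — animals tagged at a receiver that was subsequently
   lost cannot have their range estimated reliably and are excluded, as are
   animals with no detection at all after the post-capture window.

All operations are pure: inputs are never mutated in place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("reefrange")

DETECTION_COLUMNS = ("timestamp", "receiver_id", "transmitter_id")
RECEIVER_COLUMNS = ("receiver_id", "reef_id", "position_km", "lat", "lon", "status")
TAGGING_COLUMNS = ("transmitter_id", "sex", "maturity", "length_cm", "tag_date", "tag_receiver_id")

POST_CAPTURE_DAYS = 14
FALSE_DETECTION_WINDOW_S = 3600.0


def _read_csv(path, required) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    return df


def read_detections(path) -> pd.DataFrame:
    """Read a detection CSV (timestamp, receiver_id, transmitter_id).

    Timestamps are parsed as UTC; rows whose timestamp cannot be parsed or
    whose ids are empty are dropped and counted in a log warning.  The
    returned table is sorted by time.
    """
    df = _read_csv(path, DETECTION_COLUMNS)
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    ok = ts.notna() & df["receiver_id"].fillna("").ne("") & df["transmitter_id"].fillna("").ne("")
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("read_detections: dropped %d malformed row(s) from %s", n_bad, path)
    out = pd.DataFrame({
        "timestamp": ts[ok],
        "receiver_id": df.loc[ok, "receiver_id"],
        "transmitter_id": df.loc[ok, "transmitter_id"],
    })
    out = out.sort_values(["timestamp", "receiver_id", "transmitter_id"],
                          kind="stable").reset_index(drop=True)
    out.attrs["n_malformed"] = n_bad
    return out


def read_receivers(path) -> pd.DataFrame:
    df = _read_csv(path, RECEIVER_COLUMNS)
    out = df.copy()
    out["position_km"] = out["position_km"].astype(float)
    out["lat"] = out["lat"].astype(float)
    out["lon"] = out["lon"].astype(float)
    if out["receiver_id"].duplicated().any():
        raise ValueError("duplicate receiver_id in receiver table")
    return out.reset_index(drop=True)


def read_tagging(path) -> pd.DataFrame:
    df = _read_csv(path, TAGGING_COLUMNS)
    out = df.copy()
    out["length_cm"] = out["length_cm"].astype(float)
    out["tag_date"] = pd.to_datetime(out["tag_date"]).dt.normalize()
    bad_sex = set(out["sex"]) - {"male", "female"}
    bad_mat = set(out["maturity"]) - {"adult", "juvenile"}
    if bad_sex or bad_mat:
        raise ValueError(f"invalid sex/maturity values: {bad_sex | bad_mat}")
    return out.reset_index(drop=True)


def filter_false_detections(detections: pd.DataFrame,
                            window_s: float = FALSE_DETECTION_WINDOW_S
                            ) -> tuple[pd.DataFrame, int]:
    """Drop detections with no same-tag same-receiver neighbour within ±window.

    A genuine tag transmits every 30–90 s, so a real visit to a receiver
    leaves clusters of detections; an isolated single decode with its
    nearest neighbour (same transmitter, same receiver) more than
    ``window_s`` away is removed as a likely false decode.  Idempotent:
    surviving detections keep the neighbours that supported them.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if len(detections) == 0:
        return detections.copy(), 0
    df = detections.sort_values(["transmitter_id", "receiver_id", "timestamp"],
                                kind="stable")
    t = df["timestamp"].astype("int64").to_numpy() / 1e9
    same = (df["transmitter_id"].to_numpy()[1:] == df["transmitter_id"].to_numpy()[:-1]) & \
           (df["receiver_id"].to_numpy()[1:] == df["receiver_id"].to_numpy()[:-1])
    gap = np.diff(t)
    prev_ok = np.concatenate([[False], same & (gap <= window_s)])
    next_ok = np.concatenate([same & (gap <= window_s), [False]])
    keep = prev_ok | next_ok
    out = df[keep].sort_values(["timestamp", "receiver_id", "transmitter_id"],
                               kind="stable").reset_index(drop=True)
    return out, int((~keep).sum())


def apply_post_capture_window(detections: pd.DataFrame, tagging: pd.DataFrame,
                              days: int = POST_CAPTURE_DAYS,
                              tz_offset_hours: float = 11.0) -> pd.DataFrame:
    """Drop each animal's detections within ``days`` of its tagging date.

    The window is closed-open: ``[tag instant, tag instant + days*86400 s)``
    where the tag instant is local midnight of the tagging date.  Every
    transmitter in the detections must appear in the tagging table.
    """
    if len(detections) == 0:
        return detections.copy()
    tag_dates = tagging.set_index("transmitter_id")["tag_date"]
    unknown = sorted(set(detections["transmitter_id"]) - set(tag_dates.index))
    if unknown:
        raise KeyError(f"transmitters missing from tagging table: {unknown}")
    tag_local_midnight = pd.to_datetime(detections["transmitter_id"].map(tag_dates))
    cutoff_utc = (tag_local_midnight - pd.Timedelta(hours=tz_offset_hours)
                  + pd.Timedelta(days=days)).dt.tz_localize("UTC")
    keep = detections["timestamp"] >= cutoff_utc
    return detections[keep].reset_index(drop=True)


@dataclass
class CohortReport:
    """Outcome of the cohort exclusion rules.

    ``n_retained = n_tagged - n_excluded_silent - n_excluded_lost_receiver``
    always holds; an animal both silent and tagged at a lost receiver is
    counted once, under the lost-receiver rule (applied first).
    """

    n_tagged: int
    n_excluded_silent: int
    n_excluded_lost_receiver: int
    n_retained: int
    retained_ids: list = field(default_factory=list)
    excluded_silent_ids: list = field(default_factory=list)
    excluded_lost_ids: list = field(default_factory=list)
    group_counts: dict = field(default_factory=dict)


def group_label(sex: str, maturity: str) -> str:
    return f"{maturity}_{sex}"


def build_cohort(detections_after_window: pd.DataFrame, tagging: pd.DataFrame,
                 receivers: pd.DataFrame) -> CohortReport:
    """Apply the exclusion rules and report retained animals per group.

    Exclusions, in order of precedence:

    1. animals whose tagging receiver has status ``lost``;
    2. remaining animals with zero detections after the post-capture window.
    """
    lost_rx = set(receivers.loc[receivers["status"] == "lost", "receiver_id"])
    detected = set(detections_after_window["transmitter_id"].unique())
    excluded_lost, excluded_silent, retained = [], [], []
    for row in tagging.itertuples(index=False):
        if row.tag_receiver_id in lost_rx:
            excluded_lost.append(row.transmitter_id)
        elif row.transmitter_id not in detected:
            excluded_silent.append(row.transmitter_id)
        else:
            retained.append(row.transmitter_id)
    grp = tagging.set_index("transmitter_id")
    counts: dict = {}
    for tid in retained:
        label = group_label(grp.loc[tid, "sex"], grp.loc[tid, "maturity"])
        counts[label] = counts.get(label, 0) + 1
    report = CohortReport(
        n_tagged=len(tagging),
        n_excluded_silent=len(excluded_silent),
        n_excluded_lost_receiver=len(excluded_lost),
        n_retained=len(retained),
        retained_ids=sorted(retained),
        excluded_silent_ids=sorted(excluded_silent),
        excluded_lost_ids=sorted(excluded_lost),
        group_counts=dict(sorted(counts.items())),
    )
    logger.info("cohort: %d tagged, %d lost-receiver, %d silent, %d retained",
                report.n_tagged, report.n_excluded_lost_receiver,
                report.n_excluded_silent, report.n_retained)
    return report
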