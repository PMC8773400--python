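"""Raw RSSI readings -> day-level directed dyad records.

Mirrors the proximity card's storage chain and the cohort filters applied
before any network analysis:

1. 15-s RSSI readings are classified into proximity classes from their
   maximum over 2-minute windows (class 0: [-20, -50] dBm, <= 1 m;
   class 1: (-50, -56], 1-2 m; class 2: (-56, -62], 2-4 m; below -62 dBm
   nothing is stored).
2. A 2-minute window survives only if every one of its eight 15-s slots
   holds a reading at or above the -62 dBm floor (the continuity rule).
3. Windows aggregate to 2-hour blocks (counts per class), blocks to daily
   per-dyad minutes per class.
4. Cards that only ever observe, or are only ever observed, are dropped
   (symmetric-role filter); then the anomalous first and last trial days
   are trimmed.

Alignment conventions (the firmware's grids are not documented): 2-minute
windows tile from the top of the hour, 2-hour blocks start at even local
hours, days split at local midnight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Storage floor: readings strictly below this are never stored.
RSSI_FLOOR_DBM = -62
#: Hardware ceiling: stronger readings clamp into class 0.
RSSI_CEILING_DBM = -20
#: Closed right endpoints of the class bands, strongest first.
CLASS_LOWER_BOUNDS = (-50, -56, -62)  # class 0, 1, 2

WINDOW = pd.Timedelta(minutes=2)
SLOT = pd.Timedelta(seconds=15)
SLOTS_PER_WINDOW = 8
BLOCK = pd.Timedelta(hours=2)

CLASS_COUNT_COLS = ["n_class0", "n_class1", "n_class2"]
CLASS_MIN_COLS = ["min_class0", "min_class1", "min_class2"]


class PipelineError(ValueError):
    pass


def classify_proximity(rssi: int) -> int | None:
    """Map an integer RSSI (dBm) to proximity class 0/1/2, or None.

    Values above the -20 dBm hardware ceiling clamp into class 0; values
    below the -62 dBm floor are unstorable and return None.  Total on all
    integers, monotone: a stronger signal never maps to a farther class.
    """
    if rssi < RSSI_FLOOR_DBM:
        return None
    for cls, lower in enumerate(CLASS_LOWER_BOUNDS):
        if rssi >= lower:  # right endpoints are closed: -50 -> 0, -56 -> 1
            return cls
    return 2  # unreachable: rssi >= -62 == CLASS_LOWER_BOUNDS[2]


def classify_proximity_array(rssi: np.ndarray) -> np.ndarray:
    """Vectorised classify_proximity; unstorable readings map to -1."""
    rssi = np.asarray(rssi)
    out = np.full(rssi.shape, -1, dtype=int)
    out[rssi >= RSSI_FLOOR_DBM] = 2
    out[rssi >= CLASS_LOWER_BOUNDS[1]] = 1
    out[rssi >= CLASS_LOWER_BOUNDS[0]] = 0
    return out


def build_two_minute_records(readings: pd.DataFrame) -> pd.DataFrame:
    """Collapse 15-s readings into stored 2-minute proximity records.

    A (observer, observed, window) is stored iff all eight 15-s slots of
    the window contain a reading at or above -62 dBm; its class comes from
    the window's maximum RSSI.  Duplicate readings within one 15-s slot
    keep the maximum (with a warning), matching a scan that reports the
    strongest packet.

    Returns columns ``observer_id, observed_id, window_start,
    proximity_class``.
    """
    cols = ["observer_id", "observed_id", "window_start", "proximity_class"]
    if readings.empty:
        return pd.DataFrame(columns=cols)
    df = readings.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["slot"] = df["timestamp"].dt.floor(SLOT)

    keys = ["observer_id", "observed_id", "slot"]
    if df.duplicated(keys).any():
        n_dup = int(df.duplicated(keys).sum())
        logger.warning("%d duplicate readings within 15-s slots; keeping maxima", n_dup)
    slots = df.groupby(keys, as_index=False)["rssi_dbm"].max()

    slots = slots[slots["rssi_dbm"] >= RSSI_FLOOR_DBM]
    if slots.empty:
        return pd.DataFrame(columns=cols)
    slots["window_start"] = slots["slot"].dt.floor(WINDOW)
    grp = slots.groupby(["observer_id", "observed_id", "window_start"])["rssi_dbm"]
    agg = grp.agg(n_slots="size", max_rssi="max").reset_index()
    stored = agg[agg["n_slots"] == SLOTS_PER_WINDOW].copy()
    stored["proximity_class"] = classify_proximity_array(stored["max_rssi"].to_numpy())
    return stored[cols].reset_index(drop=True)


def aggregate_two_hour(records: pd.DataFrame) -> pd.DataFrame:
    """Count 2-minute records per class within even-hour 2-h blocks.

    Returns columns ``observer_id, observed_id, block_start, n_class0,
    n_class1, n_class2``.
    """
    cols = ["observer_id", "observed_id", "block_start", *CLASS_COUNT_COLS]
    if records.empty:
        return pd.DataFrame(columns=cols)
    df = records.copy()
    df["block_start"] = pd.to_datetime(df["window_start"]).dt.floor(BLOCK)
    counts = (
        df.groupby(["observer_id", "observed_id", "block_start", "proximity_class"])
        .size()
        .unstack("proximity_class", fill_value=0)
        .reindex(columns=[0, 1, 2], fill_value=0)
    )
    counts.columns = CLASS_COUNT_COLS
    return counts.reset_index()[cols]


def aggregate_daily(blocks: pd.DataFrame) -> pd.DataFrame:
    """Sum 2-h block counts to per-dyad daily minutes per class.

    Minutes are (count of 2-minute records) * 2, so they are even and total
    at most 1440 per dyad-day.  Returns columns ``observer_id, observed_id,
    date, min_class0, min_class1, min_class2``.
    """
    cols = ["observer_id", "observed_id", "date", *CLASS_MIN_COLS]
    if blocks.empty:
        return pd.DataFrame(columns=cols)
    df = blocks.copy()
    df["date"] = pd.to_datetime(df["block_start"]).dt.normalize()
    daily = (
        df.groupby(["observer_id", "observed_id", "date"], as_index=False)[
            CLASS_COUNT_COLS
        ].sum()
    )
    for cnt, minutes in zip(CLASS_COUNT_COLS, CLASS_MIN_COLS):
        daily[minutes] = daily[cnt] * 2
    return daily[cols]


@dataclass
class FilterReport:
    """Machine-readable account of cohort filtering."""

    role_filter_removed: list[str] = field(default_factory=list)
    day_trim_removed: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "role_filter_removed": sorted(self.role_filter_removed),
            "n_role_filter_removed": len(self.role_filter_removed),
            "day_trim_removed": sorted(self.day_trim_removed),
            "n_day_trim_removed": len(self.day_trim_removed),
        }


def filter_reciprocal_roles(daily: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop cards that never appear in both observing and observed roles.

    A card that only ever observes (or is only ever observed) cannot have
    both sides of any interaction assessed, so it and all its records are
    removed.  Applied in a single pass — cards whose partners are removed
    are not re-examined.

    Returns (filtered daily records, sorted removed card IDs).
    """
    if daily.empty:
        return daily.copy(), []
    observers = set(daily["observer_id"])
    observed = set(daily["observed_id"])
    keep = observers & observed
    removed = sorted((observers | observed) - keep)
    out = daily[
        daily["observer_id"].isin(keep) & daily["observed_id"].isin(keep)
    ].reset_index(drop=True)
    return out, removed


def trim_trial_days(
    daily: pd.DataFrame, first_day, last_day
) -> tuple[pd.DataFrame, list[str]]:
    """Drop the anomalous first and last trial days.

    Roll-out and collection make the boundary days unrepresentative of
    participant behaviour.  Cards left with no records are reported as
    removed.  Raises if the trim would empty the dataset.

    Returns (trimmed daily records, sorted removed card IDs).
    """
    if daily.empty:
        return daily.copy(), []
    dates = pd.to_datetime(daily["date"])
    drop = dates.isin([pd.Timestamp(first_day), pd.Timestamp(last_day)])
    out = daily[~drop].reset_index(drop=True)
    if out.empty:
        raise PipelineError("trimming first/last day removed every record")
    before = set(daily["observer_id"]) | set(daily["observed_id"])
    after = set(out["observer_id"]) | set(out["observed_id"])
    return out, sorted(before - after)


def run_pipeline(
    readings: pd.DataFrame,
    first_day=None,
    last_day=None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full chain: readings -> daily dyads -> role filter -> day trim.

    ``first_day``/``last_day`` default to the earliest and latest dates in
    the data; pass None for both *and* ``trim=False`` semantics by calling
    the stage functions directly instead.
    """
    daily = aggregate_daily(aggregate_two_hour(build_two_minute_records(readings)))
    daily, role_removed = filter_reciprocal_roles(daily)
    report = FilterReport(role_filter_removed=role_removed)
    if daily.empty:
        return daily, report
    if first_day is None:
        first_day = pd.to_datetime(daily["date"]).min()
    if last_day is None:
        last_day = pd.to_datetime(daily["date"]).max()
    daily, trim_removed = trim_trial_days(daily, first_day, last_day)
    report.day_trim_removed = trim_removed
    return daily, report


# ---------------------------------------------------------------------------
# CSV interfaces

def read_readings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={"timestamp_iso8601": "timestamp"})
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df[["observer_id", "observed_id", "timestamp", "rssi_dbm"]]


def write_daily_csv(daily: pd.DataFrame, path) -> None:
    out = daily.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_daily_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df
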