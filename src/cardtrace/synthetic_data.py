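"""Synthetic cohort, contact, RSSI-stream and interview generators.

The trial this package analyses produced three kinds of raw data, none of
them public: Bluetooth-card scan logs, case-investigation interview reports,
and (unobserved) true contact events.  This module generates all three with
the statistical structure the analysis assumes, so the full pipeline is
testable end to end:

* a cohort partitioned into households;
* dyadic true contact events with distances (<= 4 m) and durations (>= 2 min);
* directed RSSI reading streams following a log-distance path-loss model,
  RSSI(d) = RSSI(1 m) - 20 log10(d) + noise, sampled every 15 s while both
  cards are worn;
* wear compliance that can decay over the trial, plus the household
  "cards left at home" artifact (co-located cards logging each other at
  close range all day);
* an interview process with per-event recall probability and occasional
  +/- 1 day date misreporting, with same-day repeat contacts collapsed.

All randomness flows from ``GeneratorConfig.seed`` through per-stage child
streams, so each generator is reproducible independently of call order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Scan cadence of the card firmware.
READING_INTERVAL_S = 15
#: Assumed separation (m) of co-located cards left at home together.
HOUSEHOLD_COLOCATION_DISTANCE_M = 0.5

# Child-stream tags so each generator stage has its own reproducible RNG.
_STREAM_POPULATION = 1
_STREAM_CONTACTS = 2
_STREAM_WEAR = 3
_STREAM_RSSI = 4
_STREAM_REPORTS = 5


def _rng(config: "GeneratorConfig", stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


class DataError(ValueError):
    """Raised when input tables reference unknown participants or days."""


def _check_distribution(name: str, dist: dict) -> None:
    if not dist:
        raise ConfigurationError(f"{name} is empty")
    weights = np.array(list(dist.values()), dtype=float)
    if (weights < 0).any():
        raise ConfigurationError(f"{name} has negative weights")
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ConfigurationError(f"{name} weights sum to {weights.sum():.6f}, not 1")


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic trial.

    Defaults emulate a ~700-participant, 7-day community pilot: most contact
    events are short and close, card wearing decays over the week, a small
    fraction of multi-person households leave their cards co-located at home,
    and interviewees recall most but not all of their contacts.
    """

    n_participants: int = 700
    n_days: int = 7
    n_interviewed: int = 65
    #: Probability a household has size 1..6.
    household_size_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.30, 3: 0.18, 4: 0.15, 5: 0.08, 6: 0.04}
    )
    #: Expected non-household true contact events per participant per day.
    contact_rate: float = 2.0
    #: Daily probability of a contact event for each cohabiting pair.
    household_contact_prob: float = 0.5
    #: Mixture over true interaction distances in metres; support (0, 4].
    distance_distribution: dict[float, float] = field(
        default_factory=lambda: {0.5: 0.40, 1.5: 0.35, 3.0: 0.25}
    )
    #: Mixture over true durations in minutes; support >= 2.
    duration_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.25, 6: 0.25, 14: 0.20, 30: 0.15, 60: 0.10, 120: 0.05}
    )
    #: Per-day probability a participant wears their card (length n_days).
    wear_prob_by_day: list[float] = field(
        default_factory=lambda: [0.90, 0.85, 0.80, 0.70, 0.65, 0.60, 0.55]
    )
    #: Per day, probability a multi-person household leaves >= 2 cards
    #: co-located at home all day (the >= 22 h class-0 signature).
    p_household_card_left_home: float = 0.05
    #: Path-loss calibration: RSSI at 1 m, dBm.
    rssi_at_1m: float = -50.0
    rssi_noise_sd: float = 2.0
    #: Per-event per-participant interview recall probability.
    p_report: float = 0.7
    #: Probability a recalled event is reported one day early/late.
    p_date_shift: float = 0.05
    seed: int = 0
    base_date: str = "2020-11-09"

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        _check_distribution("household_size_distribution", self.household_size_distribution)
        _check_distribution("distance_distribution", self.distance_distribution)
        _check_distribution("duration_distribution", self.duration_distribution)
        if any(d <= 0 or d > 4 for d in self.distance_distribution):
            raise ConfigurationError("distances must lie in (0, 4] m")
        if any(m < 2 for m in self.duration_distribution):
            raise ConfigurationError("durations must be >= 2 min")
        if len(self.wear_prob_by_day) != self.n_days:
            raise ConfigurationError(
                f"wear_prob_by_day has length {len(self.wear_prob_by_day)}, "
                f"expected n_days={self.n_days}"
            )
        for name, p in [
            ("contact_rate", self.contact_rate),
            ("household_contact_prob", self.household_contact_prob),
            ("p_household_card_left_home", self.p_household_card_left_home),
            ("p_report", self.p_report),
            ("p_date_shift", self.p_date_shift),
            *[(f"wear_prob_by_day[{i}]", p) for i, p in enumerate(self.wear_prob_by_day)],
        ]:
            if name == "contact_rate":
                if p < 0:
                    raise ConfigurationError("contact_rate must be >= 0")
            elif not 0 <= p <= 1:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")

    @property
    def base_timestamp(self) -> pd.Timestamp:
        return pd.Timestamp(self.base_date)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("household_size_distribution", "duration_distribution"):
            if key in raw:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        if "distance_distribution" in raw:
            raw["distance_distribution"] = {
                float(k): float(v) for k, v in raw["distance_distribution"].items()
            }
        return cls(**raw)


@dataclass(frozen=True)
class WearSchedule:
    """Per-day card-wearing and household co-location indicators.

    ``wear`` is indexed by participant_id with one boolean column per trial
    day (1-based).  ``household_colocated`` is indexed by household_id the
    same way; a True entry means that household's cards were left together
    at home all day, so its members are treated as not wearing.
    """

    wear: pd.DataFrame
    household_colocated: pd.DataFrame


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Partition ``n_participants`` into households.

    Household sizes are drawn i.i.d. from ``household_size_distribution``;
    the final household is truncated so the cohort size is exact.

    Returns a DataFrame with columns ``participant_id, household_id``.
    """
    rng = _rng(config, _STREAM_POPULATION)
    sizes_support = np.array(sorted(config.household_size_distribution))
    weights = np.array(
        [config.household_size_distribution[s] for s in sizes_support], dtype=float
    )
    weights = weights / weights.sum()

    sizes: list[int] = []
    total = 0
    while total < config.n_participants:
        size = int(rng.choice(sizes_support, p=weights))
        size = min(size, config.n_participants - total)
        sizes.append(size)
        total += size

    width = len(str(config.n_participants))
    pids = [f"P{i:0{width}d}" for i in range(1, config.n_participants + 1)]
    hids = np.repeat(
        [f"H{h:0{width}d}" for h in range(1, len(sizes) + 1)], sizes
    )
    return pd.DataFrame({"participant_id": pids, "household_id": hids})


def _sample_mixture(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    support = np.array(sorted(dist), dtype=float)
    w = np.array([dist[k] for k in sorted(dist)], dtype=float)
    return rng.choice(support, size=n, p=w / w.sum())


def generate_true_contacts(
    population: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Draw ground-truth dyadic contact events for the whole trial.

    Two processes run per day: a population-level random-mixing process with
    ``Poisson(n_participants * contact_rate / 2)`` events between uniformly
    chosen distinct pairs (so each participant expects ``contact_rate``
    events/day), and a household process giving each cohabiting pair an
    event with probability ``household_contact_prob``.  Events start on the
    card's 2-minute recording grid and fit within their day.

    Returns a DataFrame with columns ``person_a, person_b, day, start_time,
    duration_min, distance_m``, pairs in canonical order (a < b).
    """
    if population.empty:
        raise DataError("population is empty")
    rng = _rng(config, _STREAM_CONTACTS)
    pids = population["participant_id"].to_numpy()
    n = len(pids)

    rows_a, rows_b, rows_day = [], [], []
    for day in range(1, config.n_days + 1):
        n_events = rng.poisson(n * config.contact_rate / 2.0)
        if n_events and n >= 2:
            i = rng.integers(0, n, size=n_events)
            # uniform distinct partner via shifted draw
            j = (i + rng.integers(1, n, size=n_events)) % n
            a, b = np.minimum(i, j), np.maximum(i, j)
            rows_a.append(pids[a])
            rows_b.append(pids[b])
            rows_day.append(np.full(n_events, day))
        # household process
        for _, members in population.groupby("household_id")["participant_id"]:
            m = members.to_numpy()
            if len(m) < 2:
                continue
            ai, bi = np.triu_indices(len(m), k=1)
            hit = rng.random(len(ai)) < config.household_contact_prob
            if hit.any():
                rows_a.append(m[ai[hit]])
                rows_b.append(m[bi[hit]])
                rows_day.append(np.full(int(hit.sum()), day))

    if not rows_a:
        return pd.DataFrame(
            columns=["person_a", "person_b", "day", "start_time", "duration_min", "distance_m"]
        )
    a = np.concatenate(rows_a)
    b = np.concatenate(rows_b)
    day = np.concatenate(rows_day)
    n_ev = len(a)
    duration = _sample_mixture(rng, config.duration_distribution, n_ev).astype(int)
    distance = _sample_mixture(rng, config.distance_distribution, n_ev)
    # start slot on the 2-min grid, leaving room for the event within the day
    max_slot = (1440 - duration) // 2
    slot = (rng.random(n_ev) * (max_slot + 1)).astype(int)
    start = (
        config.base_timestamp
        + pd.to_timedelta(day - 1, unit="D")
        + pd.to_timedelta(slot * 2, unit="min")
    )
    out = pd.DataFrame(
        {
            "person_a": a,
            "person_b": b,
            "day": day,
            "start_time": start,
            "duration_min": duration,
            "distance_m": distance,
        }
    ).sort_values(["day", "start_time", "person_a", "person_b"], kind="stable")
    return out.reset_index(drop=True)


def generate_wear_schedule(
    population: pd.DataFrame, config: GeneratorConfig
) -> WearSchedule:
    """Draw per-participant-day wear indicators and household co-location.

    A participant wears their card on day ``d`` with probability
    ``wear_prob_by_day[d-1]``.  Independently, each household with >= 2
    members is flagged "cards left at home" on each day with probability
    ``p_household_card_left_home``; members of a flagged household-day are
    forced to wear=False (their cards sit at home logging each other).
    """
    rng = _rng(config, _STREAM_WEAR)
    days = list(range(1, config.n_days + 1))
    probs = np.asarray(config.wear_prob_by_day)
    wear = pd.DataFrame(
        rng.random((len(population), config.n_days)) < probs[None, :],
        index=pd.Index(population["participant_id"], name="participant_id"),
        columns=days,
    )
    hh_sizes = population.groupby("household_id").size()
    hh_ids = hh_sizes.index
    coloc = pd.DataFrame(
        (rng.random((len(hh_ids), config.n_days)) < config.p_household_card_left_home)
        & (hh_sizes.to_numpy()[:, None] >= 2),
        index=pd.Index(hh_ids, name="household_id"),
        columns=days,
    )
    member_hh = population.set_index("participant_id")["household_id"]
    flagged = coloc.loc[member_hh.to_numpy()].to_numpy()
    wear.iloc[:, :] = wear.to_numpy() & ~flagged
    return WearSchedule(wear=wear, household_colocated=coloc)


def _path_loss_rssi(
    rng: np.random.Generator, distance: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    mu = config.rssi_at_1m - 20.0 * np.log10(distance)
    noise = rng.normal(0.0, config.rssi_noise_sd, size=distance.shape) if config.rssi_noise_sd > 0 else 0.0
    return np.rint(mu + noise).astype(int)


def simulate_rssi_stream(
    events: pd.DataFrame,
    wear_schedule: WearSchedule,
    config: GeneratorConfig,
    population: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Emit directed 15-s RSSI readings for worn-card encounters.

    For every true contact event whose two participants both wear their
    cards that day, two directed reading streams (one per card) cover the
    event at 15-s cadence; each reading is ``rssi_at_1m - 20 log10(d)``
    plus Gaussian noise, rounded to integer dBm.  Readings below the -62 dBm
    storage floor are still emitted — discarding them is the card firmware's
    job, modelled downstream.  Households flagged as having left their cards
    together emit continuous close-range readings between every card pair in
    the household for the whole day (``population`` must then be supplied to
    resolve household membership).

    Returns a DataFrame ``observer_id, observed_id, timestamp, rssi_dbm``.
    """
    known = set(wear_schedule.wear.index)
    cols = ["observer_id", "observed_id", "timestamp", "rssi_dbm"]
    obs_frames: list[pd.DataFrame] = []

    if not events.empty:
        bad = (set(events["person_a"]) | set(events["person_b"])) - known
        if bad:
            raise DataError(f"events reference unknown participants: {sorted(bad)[:5]}")
        wear = wear_schedule.wear
        a_worn = wear.to_numpy()[
            wear.index.get_indexer(events["person_a"]), events["day"].to_numpy() - 1
        ]
        b_worn = wear.to_numpy()[
            wear.index.get_indexer(events["person_b"]), events["day"].to_numpy() - 1
        ]
        live = events.loc[a_worn & b_worn]
        if not live.empty:
            per_event = (live["duration_min"].to_numpy() * 60) // READING_INTERVAL_S
            idx = np.repeat(np.arange(len(live)), per_event)
            offsets = np.concatenate([np.arange(k) for k in per_event])
            t = live["start_time"].to_numpy()[idx] + offsets * np.timedelta64(
                READING_INTERVAL_S, "s"
            )
            dist = live["distance_m"].to_numpy()[idx]
            a = live["person_a"].to_numpy()[idx]
            b = live["person_b"].to_numpy()[idx]
            rng = _rng(config, _STREAM_RSSI)
            for obs, seen in ((a, b), (b, a)):
                obs_frames.append(
                    pd.DataFrame(
                        {
                            "observer_id": obs,
                            "observed_id": seen,
                            "timestamp": t,
                            "rssi_dbm": _path_loss_rssi(rng, dist, config),
                        }
                    )
                )

    # Household cards-left-at-home artifact: full-day mutual close-range logs.
    coloc = wear_schedule.household_colocated
    if coloc.to_numpy().any():
        if population is None:
            raise DataError(
                "population required to expand household co-location readings"
            )
        rng_hh = _rng(config, _STREAM_RSSI + 100)
        n_per_day = (24 * 3600) // READING_INTERVAL_S
        members_by_hh = population.groupby("household_id")["participant_id"].agg(list)
        for hh, day_flags in coloc.iterrows():
            members = members_by_hh.get(hh, [])
            if len(members) < 2:
                continue
            for day, flagged in day_flags.items():
                if not flagged:
                    continue
                day_start = config.base_timestamp + pd.Timedelta(days=day - 1)
                t = day_start + pd.to_timedelta(
                    np.arange(n_per_day) * READING_INTERVAL_S, unit="s"
                )
                dist = np.full(n_per_day, HOUSEHOLD_COLOCATION_DISTANCE_M)
                for i, pi in enumerate(members):
                    for pj in members[i + 1 :]:
                        for obs, seen in ((pi, pj), (pj, pi)):
                            obs_frames.append(
                                pd.DataFrame(
                                    {
                                        "observer_id": obs,
                                        "observed_id": seen,
                                        "timestamp": t,
                                        "rssi_dbm": _path_loss_rssi(rng_hh, dist, config),
                                    }
                                )
                            )

    if not obs_frames:
        return pd.DataFrame(columns=cols)
    out = pd.concat(obs_frames, ignore_index=True)
    return out.sort_values(
        ["observer_id", "observed_id", "timestamp"], kind="stable"
    ).reset_index(drop=True)


def simulate_case_reports(
    events: pd.DataFrame,
    interviewed_ids,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Sample interview reports from true contact events.

    Each interviewed participant recalls each of their events independently
    with probability ``p_report``; a recalled event's date shifts one day
    earlier or later (uniformly) with probability ``p_date_shift``, clamped
    to the trial window.  Interviewees do not report repeated same-day
    contacts with one person, so duplicate (reporter, contact, day) rows
    collapse to a single report carrying the longest duration.

    Returns a DataFrame ``reporter_id, contact_id, day, duration_min``.
    """
    interviewed = set(interviewed_ids)
    cols = ["reporter_id", "contact_id", "day", "duration_min"]
    if events.empty or not interviewed or config.p_report == 0:
        return pd.DataFrame(columns=cols)
    rng = _rng(config, _STREAM_REPORTS)

    frames = []
    for reporter_col, contact_col in (("person_a", "person_b"), ("person_b", "person_a")):
        sub = events[events[reporter_col].isin(interviewed)]
        if sub.empty:
            continue
        recalled = sub.loc[rng.random(len(sub)) < config.p_report]
        if recalled.empty:
            continue
        day = recalled["day"].to_numpy().copy()
        shift_mask = rng.random(len(recalled)) < config.p_date_shift
        signs = rng.choice([-1, 1], size=len(recalled))
        day[shift_mask] = np.clip(day[shift_mask] + signs[shift_mask], 1, config.n_days)
        frames.append(
            pd.DataFrame(
                {
                    "reporter_id": recalled[reporter_col].to_numpy(),
                    "contact_id": recalled[contact_col].to_numpy(),
                    "day": day,
                    "duration_min": recalled["duration_min"].to_numpy(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    out = (
        out.groupby(["reporter_id", "contact_id", "day"], as_index=False)["duration_min"]
        .max()
        .sort_values(["day", "reporter_id", "contact_id"], kind="stable")
        .reset_index(drop=True)
    )
    return out[cols]


# ---------------------------------------------------------------------------
# CSV interfaces

def write_readings_csv(readings: pd.DataFrame, path) -> None:
    out = readings.rename(columns={"timestamp": "timestamp_iso8601"}).copy()
    out["timestamp_iso8601"] = pd.to_datetime(out["timestamp_iso8601"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


def write_reports_csv(reports: pd.DataFrame, config: GeneratorConfig, path) -> None:
    out = reports.copy()
    out["date_iso8601"] = (
        config.base_timestamp + pd.to_timedelta(out["day"] - 1, unit="D")
    ).dt.strftime("%Y-%m-%d")
    out[["reporter_id", "contact_id", "date_iso8601", "duration_min"]].to_csv(
        path, index=False
    )


def write_truth_csv(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["start_time"] = pd.to_datetime(out["start_time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
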