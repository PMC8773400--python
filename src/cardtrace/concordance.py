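"""Card-vs-interview concordance: confusion matrices, rates, compliance flags.

The two instruments are cross-tabulated over an explicit dyad-day universe:
every ordered (reporter, other) pair, for every reporter in the interviewed
cohort, every other in the card-network roster, and every analysis day
(self-pairs included — they can only ever be true negatives, but the
published panel totals include them).  A pair-day is card-positive when the
two cards logged any minutes at an included proximity class in either
direction, and report-positive when the reporter named that contact for
that day.  Treating reports as truth gives a true-positive rate (reported
events the cards caught) and false-positive rate (card detections never
reported); widening the class set can only grow both, tracing a partial
ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .card_pipeline import CLASS_MIN_COLS

#: Class-0 duration (minutes) above which an unreported dyad-day is treated
#: as a cards-left-at-home signature.
DEFAULT_LONG_DURATION_MIN = 22 * 60

VALID_CLASS_SETS = (frozenset({0}), frozenset({0, 1}), frozenset({0, 1, 2}))


class UniverseError(ValueError):
    pass


@dataclass(frozen=True)
class DyadDayUniverse:
    """Ordered (reporter, other, day) triples the confusion matrix covers."""

    reporters: frozenset
    others: frozenset
    days: tuple

    @property
    def size(self) -> int:
        return len(self.reporters) * len(self.others) * len(self.days)


@dataclass(frozen=True)
class ConfusionMatrix:
    tn: int
    fn: int
    fp: int
    tp: int
    class_set: frozenset

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.fp + self.tp

    @property
    def report_margin(self) -> int:
        return self.tp + self.fn


def _check_class_set(class_set) -> frozenset:
    cs = frozenset(class_set)
    if cs not in VALID_CLASS_SETS:
        raise UniverseError(f"class_set must be one of {{0}}, {{0,1}}, {{0,1,2}}; got {set(cs)}")
    return cs


def _card_positive_triples(
    card_daily: pd.DataFrame, universe: DyadDayUniverse, class_set: frozenset
) -> set:
    mins = [CLASS_MIN_COLS[c] for c in sorted(class_set)]
    sub = card_daily[
        card_daily["day"].isin(universe.days) & (card_daily[mins].sum(axis=1) > 0)
    ]
    out = set()
    for obs, obsd, day in zip(sub["observer_id"], sub["observed_id"], sub["day"]):
        if obs in universe.reporters and obsd in universe.others:
            out.add((obs, obsd, day))
        if obsd in universe.reporters and obs in universe.others:
            out.add((obsd, obs, day))
    return out


def _report_positive_triples(
    reports: pd.DataFrame, universe: DyadDayUniverse
) -> set:
    sub = reports[reports["day"].isin(universe.days)]
    bad = set(sub["reporter_id"]) - universe.reporters
    bad |= set(sub["contact_id"]) - universe.others
    if bad:
        raise UniverseError(f"report IDs outside the universe: {sorted(map(str, bad))[:5]}")
    return set(zip(sub["reporter_id"], sub["contact_id"], sub["day"]))


def build_confusion_matrix(
    card_daily: pd.DataFrame,
    reports: pd.DataFrame,
    universe: DyadDayUniverse,
    class_set=(0, 1, 2),
) -> ConfusionMatrix:
    """Cross-tabulate card detection vs interview report over the universe.

    ``card_daily`` needs a ``day`` column on the same labels as
    ``universe.days`` and ``reports['day']``.  Card IDs outside the universe
    are ignored (the card network is larger than any one analysis slice);
    report IDs outside it raise.
    """
    cs = _check_class_set(class_set)
    card_pos = _card_positive_triples(card_daily, universe, cs)
    rep_pos = _report_positive_triples(reports, universe)
    tp = len(card_pos & rep_pos)
    fp = len(card_pos - rep_pos)
    fn = len(rep_pos - card_pos)
    tn = universe.size - tp - fp - fn
    return ConfusionMatrix(tn=tn, fn=fn, fp=fp, tp=tp, class_set=cs)


def detection_rates(cm: ConfusionMatrix) -> dict:
    """Headline rates from a confusion matrix.

    ``reported_detected_pct``: % of reported events the cards detected
    (the true-positive rate, in percent); ``detected_unreported_pct``: % of
    card detections that went unreported; ``tpr``/``fpr`` as proportions.
    """
    if cm.tp + cm.fn == 0:
        raise UniverseError("no reported events: detection rate undefined")
    if cm.tn + cm.fp == 0:
        raise UniverseError("empty negative margin: fpr undefined")
    tpr = cm.tp / (cm.tp + cm.fn)
    return {
        "reported_detected_pct": 100.0 * tpr,
        "detected_unreported_pct": (
            100.0 * cm.fp / (cm.fp + cm.tp) if (cm.fp + cm.tp) else 0.0
        ),
        "tpr": tpr,
        "fpr": cm.fp / (cm.fp + cm.tn),
    }


def daily_tpr_fpr(
    card_daily: pd.DataFrame,
    reports: pd.DataFrame,
    universe: DyadDayUniverse,
    class_sets=VALID_CLASS_SETS,
) -> pd.DataFrame:
    """Per-day, per-class-set detection rates (partial-ROC coordinates).

    Days with no reported events get ``tpr`` = NaN and are flagged in the
    ``tpr_defined`` column rather than raising, so a full trial table can
    still be produced.
    """
    rows = []
    for day in universe.days:
        day_universe = DyadDayUniverse(universe.reporters, universe.others, (day,))
        for cs in class_sets:
            cm = build_confusion_matrix(card_daily, reports, day_universe, cs)
            defined = cm.tp + cm.fn > 0
            rows.append(
                {
                    "day": day,
                    "class_set": "+".join(str(c) for c in sorted(cs)),
                    "tpr": cm.tp / (cm.tp + cm.fn) if defined else float("nan"),
                    "fpr": cm.fp / (cm.fp + cm.tn),
                    "n_reported": cm.tp + cm.fn,
                    "tpr_defined": defined,
                }
            )
    return pd.DataFrame(rows)


def noncompliance_summary(
    card_daily: pd.DataFrame,
    reports: pd.DataFrame,
    interviewed=None,
    long_duration_min: int = DEFAULT_LONG_DURATION_MIN,
    days=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-day non-compliance signatures.

    Returns ``(zero_interaction, long_flags)``:

    * ``zero_interaction`` — per day, the fraction of reporters (people who
      reported >= 1 event anywhere in the trial) whose cards logged no
      record in either role that day: the "card not worn" signature;
    * ``long_flags`` — ordered (reporter, other, day) card contacts whose
      class-0 minutes exceed ``long_duration_min`` with no matching report:
      the "cards left at home together" signature.  With the threshold at 0
      this enumerates every unreported class-0 card contact, i.e. the
      class-0 false positives.
    """
    reporters = set(reports["reporter_id"]) if interviewed is None else set(interviewed)
    if days is None:
        days = sorted(set(card_daily["day"]) | set(reports["day"]))

    active_by_day = {
        day: set(sub["observer_id"]) | set(sub["observed_id"])
        for day, sub in card_daily.groupby("day")
    }
    zero_rows = [
        {
            "day": day,
            "n_reporters": len(reporters),
            "n_zero_interaction": sum(
                1 for r in reporters if r not in active_by_day.get(day, set())
            ),
        }
        for day in days
    ]
    zero = pd.DataFrame(zero_rows)
    zero["pct_zero_interaction"] = 100.0 * zero["n_zero_interaction"] / zero["n_reporters"]

    reported = set(zip(reports["reporter_id"], reports["contact_id"], reports["day"]))
    # class-0 minutes per unordered pair per day, max over directions
    best: dict[tuple, float] = {}
    for obs, obsd, day, m0 in zip(
        card_daily["observer_id"],
        card_daily["observed_id"],
        card_daily["day"],
        card_daily["min_class0"],
    ):
        if day not in days:
            continue
        key = (obs, obsd, day) if str(obs) <= str(obsd) else (obsd, obs, day)
        best[key] = max(best.get(key, 0), m0)
    flag_rows = []
    for (a, b, day), m0 in sorted(best.items(), key=lambda kv: str(kv[0])):
        if m0 <= long_duration_min:
            continue
        for reporter, other in ((a, b), (b, a)):
            if reporter in reporters and (reporter, other, day) not in reported:
                flag_rows.append(
                    {
                        "reporter_id": reporter,
                        "other_id": other,
                        "day": day,
                        "min_class0": m0,
                    }
                )
    long_flags = pd.DataFrame(
        flag_rows, columns=["reporter_id", "other_id", "day", "min_class0"]
    )
    return zero, long_flags
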