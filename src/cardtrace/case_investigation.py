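"""Interview-report normalisation and the date-reassignment sensitivity step.

Case investigators elicit, for each contact event, the contact's identity,
the date, and the duration (>= 2 min); same-day repeats with one person are
recorded once.  This module turns such reports into day-level directed
networks, restricts reporters to the card cohort so sensor and self-report
data cover the same people, and implements the sensitivity analysis that
moves unreciprocated reports one day earlier/later when doing so pairs them
with the alter's report (date-recall error correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .reciprocity import DailyDirectedNetwork

logger = logging.getLogger(__name__)


class ReportDataError(ValueError):
    pass


def dedupe_reports(reports: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (reporter, contact, day) rows, keeping max duration."""
    keys = ["reporter_id", "contact_id", "day"]
    if reports.duplicated(keys).any():
        n = int(reports.duplicated(keys).sum())
        logger.warning("%d duplicate same-day reports collapsed", n)
        reports = reports.groupby(keys, as_index=False)["duration_min"].max()
    return reports


def build_reported_dyads(
    reports: pd.DataFrame, nodes, days=None
) -> dict[object, DailyDirectedNetwork]:
    """Day-indexed directed networks (reporter -> contact) from reports.

    ``nodes`` is the explicit roster used for density downstream.  ``days``
    defaults to the days present in the reports; pass the full trial range
    to include report-free days as empty networks.
    """
    if (reports["reporter_id"] == reports["contact_id"]).any():
        raise ReportDataError("self-reported contact present")
    reports = dedupe_reports(reports)
    nodes = frozenset(nodes)
    if days is None:
        days = sorted(reports["day"].unique())
    by_day = dict(iter(reports.groupby("day")))
    out = {}
    for day in days:
        sub = by_day.get(day)
        edges = (
            frozenset(zip(sub["reporter_id"], sub["contact_id"]))
            if sub is not None
            else frozenset()
        )
        out[day] = DailyDirectedNetwork(day, nodes, edges)
    return out


@dataclass
class CohortExclusionReport:
    """Reporter exclusions by category, mirroring the nesting restriction."""

    no_cohort_contacts: list = field(default_factory=list)
    reporter_not_in_card_network: list = field(default_factory=list)
    n_noncohort_contact_rows: int = 0

    def to_dict(self) -> dict:
        return {
            "no_cohort_contacts": sorted(self.no_cohort_contacts),
            "n_no_cohort_contacts": len(self.no_cohort_contacts),
            "reporter_not_in_card_network": sorted(self.reporter_not_in_card_network),
            "n_reporter_not_in_card_network": len(self.reporter_not_in_card_network),
            "n_noncohort_contact_rows": self.n_noncohort_contact_rows,
        }


def restrict_to_card_cohort(
    reports: pd.DataFrame, card_node_ids
) -> tuple[pd.DataFrame, CohortExclusionReport]:
    """Nest the interviewed subpopulation within the card cohort.

    Drops (a) reporters none of whose named contacts belong to the card
    cohort — their reports cannot be checked against anything — and then
    (b) reporters who themselves lack a card with both observing and
    observed activity (``card_node_ids`` is the role-filtered card roster).
    Contacts outside the cohort are removed from the surviving reporters'
    rows.
    """
    cohort = set(card_node_ids)
    excl = CohortExclusionReport()
    keep_rows = []
    for reporter, sub in reports.groupby("reporter_id"):
        in_cohort = sub["contact_id"].isin(cohort)
        if not in_cohort.any():
            excl.no_cohort_contacts.append(reporter)
            continue
        if reporter not in cohort:
            excl.reporter_not_in_card_network.append(reporter)
            continue
        excl.n_noncohort_contact_rows += int((~in_cohort).sum())
        keep_rows.append(sub[in_cohort])
    if keep_rows:
        out = pd.concat(keep_rows, ignore_index=True)
    else:
        out = reports.iloc[0:0].copy()
    return out, excl


@dataclass(frozen=True)
class DateMove:
    reporter: object
    contact: object
    from_day: object
    to_day: object


def reassign_unreciprocated_dates(
    networks: dict[object, DailyDirectedNetwork],
    prefer: str = "earlier",
) -> tuple[dict[object, DailyDirectedNetwork], list[DateMove]]:
    """One-shot date-recall correction for unreciprocated reports.

    An unreciprocated edge i -> j on day d moves to an adjacent day d' in
    {d-1, d+1} iff, in the ORIGINAL data, (a) i has no edge to j on d' and
    (b) j -> i exists on d' (so the move creates a mutual dyad there).  If
    both neighbours qualify the ``prefer`` day wins ("earlier" by default).

    Moves are computed from the original networks in one shot — a moved
    edge never enables a further move.  Because the reverse edge a mover
    pairs with may itself qualify to move, proposals are resolved
    deterministically (in destination-day order): accepting a move pins its
    partner edge in place, and a proposal whose edge is pinned, whose
    partner has already moved away, or whose destination slot is taken is
    cancelled.  Every accepted move therefore creates a mutual dyad, the
    total edge count is conserved, and the mutual-dyad count never
    decreases.

    Returns (adjusted networks, list of applied moves).
    """
    if prefer not in ("earlier", "later"):
        raise ValueError("prefer must be 'earlier' or 'later'")
    days = sorted(networks)
    proposals: list[DateMove] = []
    for d in days:
        net = networks[d]
        for i, j in sorted(net.edges):
            if (j, i) in net.edges:
                continue  # already mutual
            neighbours = [d - 1, d + 1] if prefer == "earlier" else [d + 1, d - 1]
            for d2 in neighbours:
                if d2 not in networks:
                    continue
                adj = networks[d2].edges
                if (i, j) not in adj and (j, i) in adj:
                    proposals.append(DateMove(i, j, d, d2))
                    break

    applied: list[DateMove] = []
    pinned: set[tuple] = set()  # edges used as a partner; must stay put
    moved: set[tuple] = set()  # edges accepted as movers (at original slot)
    claimed: set[tuple] = set()  # destination slots taken
    # resolution sweeps destinations in the preferred direction
    ordered = sorted(
        proposals,
        key=lambda m: (m.to_day, m.from_day, str(m.reporter), str(m.contact)),
        reverse=prefer == "later",
    )
    for mv in ordered:
        edge = (mv.reporter, mv.contact, mv.from_day)
        partner = (mv.contact, mv.reporter, mv.to_day)
        slot = (mv.reporter, mv.contact, mv.to_day)
        if edge in pinned or partner in moved or slot in claimed:
            logger.warning("cancelled conflicting date move %s", mv)
            continue
        pinned.add(partner)
        moved.add(edge)
        claimed.add(slot)
        applied.append(mv)

    new_edges = {d: set(networks[d].edges) for d in days}
    for mv in applied:
        new_edges[mv.from_day].discard((mv.reporter, mv.contact))
        new_edges[mv.to_day].add((mv.reporter, mv.contact))
    adjusted = {d: networks[d].replace_edges(new_edges[d]) for d in days}
    return adjusted, applied


# ---------------------------------------------------------------------------
# CSV interfaces

def read_reports_csv(path, base_date=None) -> pd.DataFrame:
    """Read a reports CSV (reporter_id, contact_id, date_iso8601, duration_min).

    With ``base_date`` given, dates convert to 1-based trial day indices in
    a ``day`` column; otherwise ``day`` holds the parsed dates.
    """
    df = pd.read_csv(path)
    dates = pd.to_datetime(df["date_iso8601"])
    if base_date is not None:
        df["day"] = (dates - pd.Timestamp(base_date)).dt.days + 1
    else:
        df["day"] = dates
    return df[["reporter_id", "contact_id", "day", "duration_min"]]
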