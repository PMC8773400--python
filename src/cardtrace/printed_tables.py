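"""In-trial summary tables from the 2020 Rotorua Bluetooth-card pilot.

The raw Ministry of Health card and case-investigation data are not public;
what survives are the published daily summaries. This module ships those
summaries as typed constants together with the arithmetic needed to recover
the integer edge counts behind them, so every downstream statistic (pooled
reciprocity, the grouped-binomial trend models, the confusion-matrix rates)
can be recomputed from first principles.

Conventions
-----------
* Trial days are indexed 1..7 and correspond to 2020-11-09 .. 2020-11-15.
* The card network's node set is the 736 cards that passed the
  symmetric-role filter (before the first/last-day trim); the
  case-investigation node set is the 65 retained interviewees.  These are
  the node counts under which the published densities and rho-hat values
  reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: RSSI (dBm) class boundaries: class 0 = [-20, -50] (<= 1 m),
#: class 1 = (-50, -56] (1-2 m), class 2 = (-56, -62] (2-4 m).
RSSI_CLASS_EDGES: tuple[int, int, int, int] = (-20, -50, -56, -62)

#: Node-set sizes under which the published densities reproduce.
CARD_N_NODES = 736
REPORT_N_NODES = 65

#: Trial calendar: day index -> date.
TRIAL_START = pd.Timestamp("2020-11-09")
N_TRIAL_DAYS = 7
#: Days analysed for the card network (first/last day trimmed).
CARD_ANALYSIS_DAYS = (2, 3, 4, 5, 6)
REPORT_ANALYSIS_DAYS = (1, 2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class DailyReciprocityRow:
    """One row of the published per-day reciprocity table."""

    dataset: str  # "card" or "case_investigation"
    day: int  # trial day index, 1-based
    r: float  # printed reciprocity (4 dp)
    sigma_r: float  # printed binomial SE (4 dp)
    rho_hat: float  # printed Garlaschelli-Loffredo estimate (4 dp)
    sigma_rho: float  # printed jackknife SE (4 dp); see note below
    n_edges: int  # directed day-level contact events


#: Published per-day reciprocity summaries.  The printed sigma_rho column is
#: retained verbatim for reference but is not reproduced by the stated
#: leave-one-dyad-out jackknife on these counts; see docs/methods.md.
DAILY_RECIPROCITY: tuple[DailyReciprocityRow, ...] = (
    DailyReciprocityRow("card", 2, 0.8771, 0.0070, 0.8766, 0.0149, 2214),
    DailyReciprocityRow("card", 3, 0.8616, 0.0092, 0.8613, 0.0188, 1395),
    DailyReciprocityRow("card", 4, 0.8527, 0.0115, 0.8524, 0.0227, 957),
    DailyReciprocityRow("card", 5, 0.8960, 0.0099, 0.8958, 0.0227, 942),
    DailyReciprocityRow("card", 6, 0.9160, 0.0104, 0.9159, 0.0260, 714),
    DailyReciprocityRow("case_investigation", 1, 0.7500, 0.1083, 0.7490, 0.2014, 16),
    DailyReciprocityRow("case_investigation", 2, 0.4615, 0.1383, 0.4599, 0.2692, 13),
    DailyReciprocityRow("case_investigation", 3, 0.6667, 0.1361, 0.6657, 0.2553, 12),
    DailyReciprocityRow("case_investigation", 4, 0.6154, 0.1349, 0.6142, 0.2510, 13),
    DailyReciprocityRow("case_investigation", 5, 0.7692, 0.1169, 0.7685, 0.2252, 13),
    DailyReciprocityRow("case_investigation", 6, 0.5455, 0.1501, 0.5442, 0.2919, 11),
    DailyReciprocityRow("case_investigation", 7, 0.6667, 0.1361, 0.6657, 0.2553, 12),
)

#: Published 2x2 contact cross-tabulations (card detection vs interview
#: report) over trial days 2-6, one panel per proximity-class threshold.
#: Keys are the included class sets; cells are (tn, fn, fp, tp) where the
#: "positive" condition of the first letter is the card and of the truth is
#: the interview report.
CONFUSION_PANELS: dict[frozenset[int], dict[str, int]] = {
    frozenset({0}): {"tn": 238_818, "fn": 173, "fp": 131, "tp": 78},
    frozenset({0, 1}): {"tn": 238_727, "fn": 123, "fp": 222, "tp": 128},
    frozenset({0, 1, 2}): {"tn": 238_632, "fn": 89, "fp": 317, "tp": 162},
}


def reconstruct_daily_counts() -> pd.DataFrame:
    """Recover integer reciprocated/total edge counts from the printed table.

    For each day the number of reciprocated directed edges is ``round(r * n)``
    (``r`` printed to 4 decimals, ``n`` the printed edge count).  The
    reconstruction is validated by rounding each recovered proportion back to
    4 decimals and comparing with the printed ``r``; a mismatch raises.

    Returns
    -------
    DataFrame with columns ``dataset, day, reciprocated, total`` — the
    grouped-binomial observations used by the trend models.
    """
    rows = []
    for row in DAILY_RECIPROCITY:
        succ = round(row.r * row.n_edges)
        if round(succ / row.n_edges, 4) != row.r:
            raise ValueError(
                f"reconstructed count {succ}/{row.n_edges} does not round back "
                f"to printed r={row.r} ({row.dataset}, day {row.day})"
            )
        rows.append((row.dataset, row.day, succ, row.n_edges))
    return pd.DataFrame(rows, columns=["dataset", "day", "reciprocated", "total"])
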