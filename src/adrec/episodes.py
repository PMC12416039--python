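"""Treatment-episode construction from antidepressant dispensing records.

An episode is one treatment attempt: it starts at a dispensing of an index
antidepressant and is classified within a fixed disposition window into one of
four dispositions — *continued*, *switched*, *discontinued*, or *augmented* —
based on gap-tolerant coverage of the index drug and the appearance of other
antidepressants.  The binary surrogate response outcome (standing in for
remission, which claims data lack) is persistence: a patient responds when
they stay on the index drug through the response window (10 weeks by
default).  Premature abandonment, switching, or augmentation all mark the
initial choice as incorrect.
"""

from __future__ import annotations

import decimal
import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DISPOSITIONS = ("continued", "switched", "discontinued", "augmented")

Disposition = Literal["continued", "switched", "discontinued", "augmented"]

#: Columns expected in a dispensing-record table.
DISPENSING_COLUMNS = ("patient_id", "drug", "fill_date", "days_supply")


@dataclass(frozen=True)
class EpisodeWindows:
    """Day-count windows governing episode classification.

    Parameters
    ----------
    response_window_days:
        Coverage span required for a positive response; 70 days = 10 weeks.
    disposition_window_days:
        Horizon within which the four-way disposition is decided; fills at or
        beyond ``start + disposition_window_days`` open a new episode.
    gap_tolerance_days:
        Largest lapse between consecutive index-drug fills that still counts
        as continuous coverage.
    """

    response_window_days: int = 70
    disposition_window_days: int = 100
    gap_tolerance_days: int = 15

    def __post_init__(self) -> None:
        if min(self.response_window_days, self.disposition_window_days,
               self.gap_tolerance_days) <= 0:
            raise ValueError("all window parameters must be positive")
        if self.response_window_days > self.disposition_window_days:
            raise ValueError(
                "response_window_days must not exceed disposition_window_days"
            )


@dataclass(frozen=True)
class Episode:
    """One antidepressant treatment attempt with its outcome labels."""

    patient_id: str
    index_drug: str
    start_day: int
    disposition: Disposition
    response: int
    covered_days: int


def _merged_coverage_end(intervals: list[tuple[int, int]], gap: int) -> int:
    """End of the gap-bridged coverage chain anchored at the first interval.

    Intervals are half-open ``[start, end)`` and must be sorted by start.
    A following interval extends the chain when it begins within ``gap``
    days of the current chain end.
    """
    end = intervals[0][1]
    for b, e in intervals[1:]:
        if b <= end + gap:
            end = max(end, e)
        else:
            break
    return end


def build_episodes(
    dispensings: pd.DataFrame,
    windows: EpisodeWindows | None = None,
    *,
    response_mode: Literal["strict", "coverage"] = "strict",
) -> list[Episode]:
    """Segment dispensing records into labeled treatment episodes.

    Each patient's fills are scanned in date order.  A fill opens an episode
    whose index drug is that fill's drug; every fill before
    ``start + disposition_window_days`` belongs to the episode, and the next
    fill at or past that horizon opens a new one.  Disposition rules, applied
    to gap-tolerant index coverage within the window:

    * another antidepressant starts while index coverage is alive → *augmented*
    * another antidepressant starts after index coverage lapsed → *switched*
    * no other drug and coverage has not lapsed beyond tolerance by the end
      of the disposition window → *continued*
    * coverage lapses and nothing else starts → *discontinued*

    ``response_mode`` controls the surrogate outcome.  Under ``"strict"``
    (default) response is 1 only for continued episodes whose coverage spans
    the response window; under ``"coverage"`` any episode whose index coverage
    reaches the response window responds, even if it lapses or changes later
    in the (longer) disposition window.

    Records with non-positive ``days_supply`` or negative ``fill_date`` are
    rejected with a logged warning.  Empty input yields an empty list.
    """
    windows = windows or EpisodeWindows()
    if dispensings.empty:
        return []
    missing = set(DISPENSING_COLUMNS) - set(dispensings.columns)
    if missing:
        raise ValueError(f"dispensing table lacks columns: {sorted(missing)}")

    bad = (dispensings["days_supply"] < 1) | (dispensings["fill_date"] < 0)
    if bad.any():
        logger.warning("rejecting %d invalid dispensing records", int(bad.sum()))
        dispensings = dispensings[~bad]

    out: list[Episode] = []
    ordered = dispensings.sort_values(["patient_id", "fill_date", "drug"])
    for pid, group in ordered.groupby("patient_id", sort=True):
        fills = list(
            group[["drug", "fill_date", "days_supply"]].itertuples(index=False)
        )
        i = 0
        while i < len(fills):
            start = int(fills[i].fill_date)
            index_drug = fills[i].drug
            horizon = start + windows.disposition_window_days
            j = i
            while j < len(fills) and fills[j].fill_date < horizon:
                j += 1
            chunk = fills[i:j]
            out.append(
                _classify(str(pid), index_drug, start, chunk, windows,
                          response_mode)
            )
            i = j
    return out


def _classify(
    pid: str,
    index_drug: str,
    start: int,
    fills: list,
    w: EpisodeWindows,
    response_mode: str,
) -> Episode:
    index_iv = sorted(
        (int(f.fill_date), int(f.fill_date) + int(f.days_supply))
        for f in fills
        if f.drug == index_drug
    )
    cov_end = _merged_coverage_end(index_iv, w.gap_tolerance_days)
    other = [int(f.fill_date) for f in fills if f.drug != index_drug]

    horizon = start + w.disposition_window_days
    if other:
        first_other = min(other)
        disposition = "augmented" if first_other < cov_end else "switched"
    elif cov_end + w.gap_tolerance_days >= horizon:
        # Not lapsed beyond tolerance by window end counts as continued.
        disposition = "continued"
    else:
        disposition = "discontinued"

    covered = min(cov_end, horizon) - start
    if response_mode == "strict":
        response = int(
            disposition == "continued"
            and covered >= w.response_window_days
        )
    elif response_mode == "coverage":
        response = int(covered >= w.response_window_days)
    else:
        raise ValueError(f"unknown response_mode: {response_mode!r}")
    return Episode(pid, index_drug, start, disposition, response, covered)


def episodes_frame(episodes: Iterable[Episode]) -> pd.DataFrame:
    """Episode list as a tidy table (one row per episode)."""
    return pd.DataFrame([e.__dict__ for e in episodes])


def _round_half_up(x: float, places: int) -> float:
    q = decimal.Decimal(10) ** -places
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def disposition_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percent share per disposition, half-up rounded to one decimal."""
    unknown = set(counts) - set(DISPOSITIONS)
    if unknown:
        raise ValueError(f"unknown dispositions: {sorted(unknown)}")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no episodes to summarize")
    return {
        d: _round_half_up(100.0 * counts.get(d, 0) / total, 1)
        for d in DISPOSITIONS
    }


def summarize_dispositions(episodes: Iterable[Episode]) -> pd.DataFrame:
    """Four-way disposition summary with counts and percentages.

    Percentages are count/total x 100, half-up rounded to one decimal, so the
    table reproduces printed cohort summaries exactly.
    """
    episodes = list(episodes)
    if not episodes:
        raise ValueError("cannot summarize an empty episode list")
    counts = {d: 0 for d in DISPOSITIONS}
    for e in episodes:
        counts[e.disposition] += 1
    pct = disposition_percentages(counts)
    return pd.DataFrame(
        {"disposition": DISPOSITIONS,
         "count": [counts[d] for d in DISPOSITIONS],
         "percent": [pct[d] for d in DISPOSITIONS]}
    )


def treatment_frequency_from_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Per-treatment frequency table from raw counts.

    Rows sorted by count descending (ties by name); percent half-up rounded
    to two decimals.
    """
    if not counts:
        raise ValueError("no treatments to tabulate")
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {"treatment": [k for k, _ in rows],
         "count": [v for _, v in rows],
         "percent": [_round_half_up(100.0 * v / total, 2) for _, v in rows]}
    )


def treatment_frequency_table(episodes: Iterable[Episode]) -> pd.DataFrame:
    """Frequency of index treatments among episodes."""
    episodes = list(episodes)
    if not episodes:
        raise ValueError("cannot tabulate an empty episode list")
    counts: dict[str, int] = {}
    for e in episodes:
        counts[e.index_drug] = counts.get(e.index_drug, 0) + 1
    return treatment_frequency_from_counts(counts)
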