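"""Blastocyst culture scoring: the six-level ladder and outcome tables.

Embryos cultured from E3.5 are scored daily on an ordinal ladder —
compacted morula < blastocyst < expanded blastocyst < hatched <
ICM/trophectoderm outgrowth — with ``dead`` as an absorbing terminal
state.  A live embryo's status never regresses.  Summaries report, per
day, the number of embryos at each (highest) status, that day's new
deaths and the cumulative dead percentage of the cohort.

A pre-ladder status ``pre_morula`` (an embryo that never compacted) is
accepted as a terminal dead-precursor for rare anomalous records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import CULTURE_STATUSES, PRE_LADDER_STATUS

__all__ = [
    "LADDER",
    "DEAD",
    "CultureRecord",
    "CultureSummary",
    "validate_trajectories",
    "summarize_culture",
    "outcome_rates",
]

DEAD = "dead"
#: Ordinal ladder from least to most advanced (pre_morula is pre-ladder).
LADDER = (
    PRE_LADDER_STATUS,
    "compacted_morula",
    "blastocyst",
    "expanded_blastocyst",
    "hatched",
    "outgrowth",
)
_RANK = {status: i for i, status in enumerate(LADDER)}


@dataclass(frozen=True)
class CultureRecord:
    """One embryo on one culture day."""

    embryo_id: str
    day: int
    status: str
    genotype: str | None = None
    litter: str | None = None

    def __post_init__(self) -> None:
        if self.status not in _RANK and self.status != DEAD:
            raise ValueError(
                f"unknown culture status {self.status!r}; the six legal statuses "
                f"are {', '.join(CULTURE_STATUSES)}"
            )
        if self.day < 1:
            raise ValueError("days are numbered from 1")


@dataclass
class CultureSummary:
    """Per-day outcome table for one cultured cohort."""

    n: int
    litters: int | None
    status_counts: pd.DataFrame  # index day; columns ladder statuses (live embryos)
    new_deaths: pd.Series  # index day
    cumulative_dead: pd.Series
    cumulative_dead_pct: pd.Series  # one-decimal percentages of n
    healthy: pd.Series
    healthy_pct: pd.Series


def _by_embryo(records: Iterable[CultureRecord]) -> dict[str, dict[int, CultureRecord]]:
    out: dict[str, dict[int, CultureRecord]] = {}
    for rec in records:
        days = out.setdefault(rec.embryo_id, {})
        if rec.day in days:
            raise ValueError(f"duplicate record for embryo {rec.embryo_id} day {rec.day}")
        days[rec.day] = rec
    return out


def validate_trajectories(records: Iterable[CultureRecord]) -> list[str]:
    """Check every embryo's trajectory; returns violation messages.

    Violations: a live status lower on the ladder than a previous day's
    (regression), or any non-dead status after death (death is absorbing).
    Duplicate (embryo, day) records raise.
    """
    violations: list[str] = []
    for embryo_id, days in _by_embryo(records).items():
        dead = False
        last_rank = -1
        for day in sorted(days):
            status = days[day].status
            if dead and status != DEAD:
                violations.append(
                    f"embryo {embryo_id}: status {status!r} on day {day} after death"
                )
                continue
            if status == DEAD:
                dead = True
                continue
            rank = _RANK[status]
            if rank < last_rank:
                violations.append(
                    f"embryo {embryo_id}: regression to {status!r} on day {day}"
                )
            last_rank = max(last_rank, rank)
    return violations


def summarize_culture(
    records: Iterable[CultureRecord], n_days: int | None = None
) -> CultureSummary:
    """Build the per-day outcome table of a cultured cohort.

    Every live embryo must have a record for every day up to ``n_days``
    (default: the last day observed anywhere); after death, records are
    optional and death is carried forward.  Percentages are reported to one
    decimal place of the cohort size N.
    """
    records = list(records)
    violations = validate_trajectories(records)
    if violations:
        raise ValueError("invalid trajectories: " + "; ".join(violations))
    by_embryo = _by_embryo(records)
    if not by_embryo:
        raise ValueError("no culture records")
    if n_days is None:
        n_days = max(max(days) for days in by_embryo.values())
    n = len(by_embryo)
    litter_ids = {r.litter for r in records if r.litter is not None}
    days = range(1, n_days + 1)
    counts = pd.DataFrame(0, index=list(days), columns=list(LADDER))
    counts.index.name = "day"
    death_day: dict[str, int] = {}
    for embryo_id, embryo_days in by_embryo.items():
        for day in days:
            if embryo_id in death_day:
                break
            rec = embryo_days.get(day)
            if rec is None:
                raise ValueError(
                    f"embryo {embryo_id}: missing record for day {day} while alive"
                )
            if rec.status == DEAD:
                death_day[embryo_id] = day
            else:
                counts.loc[day, rec.status] += 1
    new_deaths = pd.Series(0, index=list(days))
    for day in death_day.values():
        new_deaths.loc[day] += 1
    cumulative = new_deaths.cumsum()
    healthy = n - cumulative
    return CultureSummary(
        n=n,
        litters=len(litter_ids) or None,
        status_counts=counts.drop(
            columns=[c for c in (PRE_LADDER_STATUS,) if counts[c].eq(0).all()]
        ),
        new_deaths=new_deaths,
        cumulative_dead=cumulative,
        cumulative_dead_pct=(100.0 * cumulative / n).round(1),
        healthy=healthy,
        healthy_pct=(100.0 * healthy / n).round(1),
    )


def outcome_rates(
    records: Iterable[CultureRecord],
    denominator: str = "all",
    thresholds: Sequence[str] = ("hatched", "outgrowth"),
) -> dict[str, int]:
    """Whole-percent rates of embryos at or beyond ladder thresholds.

    Uses final-day statuses.  ``denominator`` is "all" (the whole cohort)
    or "survivors" (embryos alive on the final day).  Rates are rounded to
    the nearest integer percent, the convention used in prose reporting
    (e.g. 22 of 25 hatched-or-beyond → 88%).
    """
    if denominator not in ("all", "survivors"):
        raise ValueError("denominator must be 'all' or 'survivors'")
    by_embryo = _by_embryo(records)
    finals: dict[str, str] = {}
    for embryo_id, days in by_embryo.items():
        statuses = [days[d].status for d in sorted(days)]
        finals[embryo_id] = DEAD if DEAD in statuses else statuses[-1]
    pool = (
        list(finals)
        if denominator == "all"
        else [e for e, s in finals.items() if s != DEAD]
    )
    if not pool:
        raise ValueError("empty denominator")
    rates: dict[str, int] = {}
    for threshold in thresholds:
        if threshold not in _RANK:
            raise ValueError(f"unknown ladder status {threshold!r}")
        num = sum(
            1
            for e in pool
            if finals[e] != DEAD and _RANK[finals[e]] >= _RANK[threshold]
        )
        rates[threshold] = round(100.0 * num / len(pool))
    return rates
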