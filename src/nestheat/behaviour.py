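"""Incubation attendance metrics from bout/recess logs and focal observations.

A nest-day observation runs from dawn (when the first bird relieves the
overnight incubator) to early evening. The log is a sequence of intervals,
each either an incubation bout (clutch attended) or a recess (unattended).
Attendance is the summed bout time over the observation window; the recess
count and an any-recess indicator feed the temperature analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import InvalidInputError, OverlapError

#: intervals shorter than this (seconds) are treated as rounding slack when
#: checking contiguity, not as real gaps
GAP_SLACK_S = 1.0


@dataclass(frozen=True)
class BoutRecord:
    """One attended (incubation) or unattended (recess) interval."""

    nest_id: str
    date: object
    start: object  # datetime-like; anything subtractable to a timedelta
    end: object
    kind: str  # "incubation" | "recess"
    incubator_id: str | None = None

    def __post_init__(self):
        if self.kind not in ("incubation", "recess"):
            raise InvalidInputError(f"unknown interval kind {self.kind!r}")
        if not self.start < self.end:
            raise InvalidInputError("interval start must precede end")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass(frozen=True)
class AttendanceSummary:
    """Per nest-day attendance metrics."""

    nest_id: str
    date: object
    obs_start: object
    obs_end: object
    prop_incubated: float
    n_recesses: int
    prop_unattended: float
    any_recess: bool


def validate_bout_series(
    bouts: Sequence[BoutRecord],
    obs_window: tuple,
    coerce_gaps: bool = False,
) -> tuple[list[BoutRecord], dict]:
    """Sort, overlap-check and (optionally) gap-fill one nest-day's intervals.

    Returns the sorted series and a report dict with any gaps found
    (uncovered sub-intervals of ``obs_window``). With ``coerce_gaps`` the
    gaps are converted into synthetic recess records. Overlapping intervals
    raise :class:`OverlapError` with the offending pair attached.
    """
    obs_start, obs_end = obs_window
    if not obs_start < obs_end:
        raise InvalidInputError("observation window is empty")
    series = sorted(bouts, key=lambda b: (b.start, b.end))
    for a, b in zip(series, series[1:]):
        if (a.end - b.start).total_seconds() > GAP_SLACK_S:
            raise OverlapError(
                f"intervals overlap at {b.start}", pair=(a, b)
            )
    gaps = []
    cursor = obs_start
    for b in series:
        if (b.start - cursor).total_seconds() > GAP_SLACK_S:
            gaps.append((cursor, b.start))
        cursor = max(cursor, b.end)
    if (obs_end - cursor).total_seconds() > GAP_SLACK_S:
        gaps.append((cursor, obs_end))
    report = {"n_gaps": len(gaps), "gaps": gaps, "coerced": coerce_gaps and bool(gaps)}
    if coerce_gaps and gaps:
        nest = series[0].nest_id if series else "unknown"
        date = series[0].date if series else None
        for g0, g1 in gaps:
            series.append(
                BoutRecord(nest_id=nest, date=date, start=g0, end=g1, kind="recess")
            )
        series.sort(key=lambda b: (b.start, b.end))
        report["gaps"] = []
    return series, report


def attendance_summary(
    bouts: Sequence[BoutRecord], obs_window: tuple
) -> AttendanceSummary:
    """Attendance metrics for one validated nest-day series.

    prop_incubated = summed incubation-bout seconds over the window length;
    prop_unattended is its exact complement (recess + uncovered time).
    """
    obs_start, obs_end = obs_window
    total = (obs_end - obs_start).total_seconds()
    if total <= 0:
        raise InvalidInputError("zero-length observation window")
    inc = sum(b.duration_s for b in bouts if b.kind == "incubation")
    n_rec = sum(1 for b in bouts if b.kind == "recess")
    prop = inc / total
    first = bouts[0] if bouts else None
    return AttendanceSummary(
        nest_id=first.nest_id if first else "unknown",
        date=first.date if first else None,
        obs_start=obs_start,
        obs_end=obs_end,
        prop_incubated=prop,
        n_recesses=n_rec,
        prop_unattended=1.0 - prop,
        any_recess=n_rec > 0,
    )


def attendance_table(bouts_df: pd.DataFrame, coerce_gaps: bool = True) -> pd.DataFrame:
    """Per nest-day attendance from a bouts table.

    Expects columns nest_id, date, start, end, kind (ISO datetimes). The
    observation window is taken as [min(start), max(end)] per nest-day.
    """
    df = bouts_df.copy()
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    rows = []
    for (nest, day), grp in df.groupby(["nest_id", "date"], sort=True):
        records = [
            BoutRecord(
                nest_id=nest,
                date=day,
                start=r.start,
                end=r.end,
                kind=r.kind,
                incubator_id=getattr(r, "incubator_id", None),
            )
            for r in grp.itertuples()
        ]
        window = (min(r.start for r in records), max(r.end for r in records))
        series, _ = validate_bout_series(records, window, coerce_gaps=coerce_gaps)
        s = attendance_summary(series, window)
        rows.append(
            {
                "nest_id": s.nest_id,
                "date": s.date,
                "obs_start": s.obs_start,
                "obs_end": s.obs_end,
                "prop_incubated": s.prop_incubated,
                "n_recesses": s.n_recesses,
                "prop_unattended": s.prop_unattended,
                "any_recess": s.any_recess,
            }
        )
    return pd.DataFrame(rows)


def focal_time_budget(
    focals: pd.DataFrame, target_label: str = "incubating"
) -> pd.DataFrame:
    """Proportion of observed time in a target behaviour per bird-day.

    ``focals`` has columns bird_id, date, behaviour_label, duration
    (seconds, > 0). Returns bird_id, date, total_s, target_s, proportion.
    """
    if focals.empty:
        raise InvalidInputError("no focal records")
    if (focals["duration"] <= 0).any():
        raise InvalidInputError("focal durations must be positive")
    rows = []
    for (bird, day), grp in focals.groupby(["bird_id", "date"], sort=True):
        total = float(grp["duration"].sum())
        target = float(grp.loc[grp["behaviour_label"] == target_label, "duration"].sum())
        rows.append(
            {
                "bird_id": bird,
                "date": day,
                "total_s": total,
                "target_s": target,
                "proportion": target / total,
            }
        )
    return pd.DataFrame(rows)
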