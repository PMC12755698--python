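"""Case-crossover structure: first warm-season cases and time-stratified referents.

Each person contributes a single case day (the admission date of their first
hospitalization over the study period, kept only when it falls in the
June–September warm season) and up to four bidirectional referent days: every
other day of the same calendar month and year that shares the case day's day
of week. Because a weekday occurs four or five times in a month, every case
has exactly three or four referents. Exposures — not survival or enrollment —
define referent validity in this time-stratified design, so referent days are
never excluded on person-level grounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .windows import WindowSpec, windowed_exposures

__all__ = [
    "WARM_SEASON_MONTHS",
    "DropLog",
    "select_cases",
    "referent_days",
    "build_matched_sets",
]

logger = logging.getLogger(__name__)

WARM_SEASON_MONTHS = (6, 7, 8, 9)


@dataclass
class DropLog:
    """Accounting of person-days lost while building matched sets."""

    candidate_rows: int = 0
    dropped_missing_coverage: int = 0
    dropped_empty_stratum: int = 0
    retained_rows: int = 0
    dropped_sets: list[str] = field(default_factory=list)


def select_cases(events: pd.DataFrame) -> pd.DataFrame:
    """Reduce an event table to one warm-season case day per person.

    The first event (earliest ``admission_date``) of each person is taken;
    it becomes a case only if its month is June–September. A person whose
    first event falls outside the warm season is excluded — later events are
    never promoted, mirroring the first-hospitalization rule.
    """
    if events.empty:
        return pd.DataFrame(columns=["person_id", "area_id", "case_date", "primary_dx"])
    events = events.sort_values(["admission_date", "person_id"], kind="stable")
    first = events.groupby("person_id", sort=True, as_index=False).first()
    month = pd.to_datetime(first["admission_date"]).dt.month
    cases = first[month.isin(WARM_SEASON_MONTHS)].copy()
    cases = cases.rename(columns={"admission_date": "case_date"})
    cols = ["person_id", "area_id", "case_date"]
    if "primary_dx" in cases.columns:
        cols.append("primary_dx")
    return cases[cols].sort_values("person_id", ignore_index=True)


def referent_days(case_date) -> list[pd.Timestamp]:
    """All other same-weekday days in the case day's calendar month.

    Bidirectional time-stratified referent selection: the returned days may
    precede or follow the case day, are in ascending order, and number three
    or four depending on how many times the weekday occurs in the month.
    """
    case = pd.Timestamp(case_date)
    month_start = case.replace(day=1)
    month_end = case + pd.offsets.MonthEnd(0)
    # first same-weekday day of the month, then step by 7 days
    first_match = month_start + pd.Timedelta(days=(case.dayofweek - month_start.dayofweek) % 7)
    days = pd.date_range(first_match, month_end, freq="7D")
    return [d for d in days if d != case]


def build_matched_sets(
    cases: pd.DataFrame,
    exposures: pd.DataFrame,
    window: WindowSpec | None = None,
) -> tuple[pd.DataFrame, DropLog]:
    """Expand cases into long-format matched sets with windowed exposures.

    Output columns: ``set_id, person_id, area_id, date, is_case, tmax_w,
    pm25_w``; one row per person-day, grouped by set. Person-days whose
    exposure window is not fully covered in the person's area are dropped; a
    set is dropped (and logged) when its case day lacks coverage or no
    referent survives.
    """
    window = window or WindowSpec()
    log = DropLog()
    if cases.empty:
        empty = pd.DataFrame(
            columns=["set_id", "person_id", "area_id", "date", "is_case", "tmax_w", "pm25_w"]
        )
        return empty, log

    rows = []
    for person_id, area_id, case_date in zip(
        cases["person_id"], cases["area_id"], pd.to_datetime(cases["case_date"])
    ):
        rows.append((person_id, person_id, area_id, case_date, 1))
        for ref in referent_days(case_date):
            rows.append((person_id, person_id, area_id, ref, 0))
    long = pd.DataFrame(rows, columns=["set_id", "person_id", "area_id", "date", "is_case"])
    log.candidate_rows = len(long)

    win = windowed_exposures(exposures, window)
    merged = long.merge(win, on=["area_id", "date"], how="left", validate="many_to_one")
    covered = merged.dropna(subset=["tmax_w", "pm25_w"])
    log.dropped_missing_coverage = len(merged) - len(covered)

    case_ok = covered.groupby("set_id")["is_case"].sum()
    ref_ok = covered.groupby("set_id")["is_case"].apply(lambda c: (1 - c).sum())
    good = case_ok.index[(case_ok == 1) & (ref_ok >= 1)]
    out = covered[covered["set_id"].isin(good)].reset_index(drop=True)
    log.dropped_empty_stratum = len(covered) - len(out)
    log.retained_rows = len(out)

    dropped = sorted(set(covered["set_id"]) - set(good)) + sorted(
        set(long["set_id"]) - set(covered["set_id"])
    )
    log.dropped_sets = list(dropped)
    for sid in dropped:
        logger.info("matched set %s dropped (missing coverage or empty stratum)", sid)
    return out, log
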