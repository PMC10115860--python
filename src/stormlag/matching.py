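"""Matched exposed/unexposed-day design and the long model table.

Each storm's closest-approach day in a ZCTA (the "exposed day") is matched
to up to 10 control index days drawn from *different years*, within a
seven-day window of the exposed day's day-of-year (to preserve season), and
not within 3 days of any other storm in the same ZCTA.  Around every index
day — exposed or control — a 10-day window spanning lags -2..+7 supplies
the observation days, so a fully matched storm-ZCTA contributes
(1 + 10) x 10 = 110 day-rows to the model table.

Day-of-year arithmetic uses a 365-day calendar with Feb 29 mapped onto
Feb 28, so the seven-day seasonal window does not drift across leap years.
Distances to other storms, by contrast, are true calendar-day differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Lag offsets (days relative to the index day) in model-table order.
LAGS = tuple(range(-2, 8))

#: Model-table column name for each lag indicator ("m" marks negative lags).
LAG_COLUMNS = tuple(f"lag_{l}" if l >= 0 else f"lag_m{-l}" for l in LAGS)

#: Default number of control index days per exposed day.
N_CONTROLS = 10

#: Seasonal matching half-width in (365-calendar) days of the year.
DOY_WINDOW = 7

#: Control candidates within this many calendar days of another storm are excluded.
STORM_EXCLUSION_DAYS = 3


def doy365(d: date) -> int:
    """Day of year on a fixed 365-day calendar; Feb 29 counts as Feb 28 (59)."""
    if d.month == 2 and d.day == 29:
        return 59
    doy = d.timetuple().tm_yday
    if d.year % 4 == 0 and (d.year % 100 != 0 or d.year % 400 == 0) and doy > 60:
        return doy - 1
    return doy


def doy_distance(a: date, b: date) -> int:
    """Circular distance between two dates' 365-calendar days of year."""
    diff = abs(doy365(a) - doy365(b))
    return min(diff, 365 - diff)


def _dates_for_doy(doy: int, year: int) -> list[date]:
    """Calendar dates in ``year`` whose 365-calendar day-of-year equals ``doy``."""
    leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
    if not leap:
        return [date(year, 1, 1) + timedelta(days=doy - 1)]
    if doy < 59:
        return [date(year, 1, 1) + timedelta(days=doy - 1)]
    if doy == 59:  # Feb 28 and Feb 29 share slot 59
        return [date(year, 2, 28), date(year, 2, 29)]
    return [date(year, 1, 1) + timedelta(days=doy)]


def window_dates(index_day: date) -> list[date]:
    """The ordered 10 observation days at lags -2..+7 around an index day."""
    return [index_day + timedelta(days=l) for l in LAGS]


def find_control_candidates(
    exposed_day: date,
    zcta_storm_days: set[date],
    study_years: range,
) -> set[date]:
    """All calendar days eligible to serve as control index days.

    A candidate day ``d`` must satisfy four predicates:

    1. its year lies in ``study_years`` but differs from the exposed day's;
    2. its day-of-year is within :data:`DOY_WINDOW` of the exposed day's
       (365-calendar, circular);
    3. it is more than :data:`STORM_EXCLUSION_DAYS` calendar days from every
       storm day in the same ZCTA;
    4. its full lag window (-2..+7) lies inside the study period.

    Returns the (possibly empty) candidate set.
    """
    years = list(study_years)
    if not years:
        raise ValueError("study_years is empty")
    period_start = date(years[0], 1, 1)
    period_end = date(years[-1], 12, 31)
    target = doy365(exposed_day)
    doys = [(target - 1 + off) % 365 + 1 for off in range(-DOY_WINDOW, DOY_WINDOW + 1)]

    out: set[date] = set()
    for year in years:
        if year == exposed_day.year:
            continue
        for doy in doys:
            for d in _dates_for_doy(doy, year):
                if d + timedelta(days=LAGS[0]) < period_start:
                    continue
                if d + timedelta(days=LAGS[-1]) > period_end:
                    continue
                near_storm = any(
                    abs((d - s).days) <= STORM_EXCLUSION_DAYS for s in zcta_storm_days
                )
                if not near_storm:
                    out.add(d)
    return out


def sample_controls(
    candidates: set[date],
    k: int = N_CONTROLS,
    rng: np.random.Generator | None = None,
) -> list[date]:
    """Sample ``k`` control index days uniformly without replacement.

    If fewer than ``k`` candidates exist, all of them are returned and the
    deficit is logged; the caller decides whether a short set is acceptable.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    ordered = sorted(candidates)
    if len(ordered) <= k:
        if len(ordered) < k:
            logger.warning(
                "only %d control candidates available (requested %d)",
                len(ordered),
                k,
            )
        return ordered
    idx = rng.choice(len(ordered), size=k, replace=False)
    return sorted(ordered[i] for i in idx)


@dataclass(frozen=True)
class MatchedSet:
    """One exposed index day with its sampled control index days."""

    zcta_id: str
    storm_id: str
    exposed_day: date
    control_days: tuple[date, ...]

    @property
    def set_id(self) -> str:
        return f"{self.zcta_id}:{self.storm_id}"

    @property
    def deficit(self) -> int:
        return max(0, N_CONTROLS - len(self.control_days))

    def windows(self) -> dict[date, list[date]]:
        """Lag windows keyed by index day (exposed first)."""
        days = [self.exposed_day, *self.control_days]
        return {d: window_dates(d) for d in days}


@dataclass
class MatchingReport:
    """Bookkeeping from matched-set construction, for the run manifest."""

    n_sets: int = 0
    n_dropped_no_candidates: int = 0
    n_dropped_window: int = 0
    n_deficit_sets: int = 0
    dropped: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_sets": self.n_sets,
            "n_dropped_no_candidates": self.n_dropped_no_candidates,
            "n_dropped_window_truncated": self.n_dropped_window,
            "n_deficit_sets": self.n_deficit_sets,
            "dropped": self.dropped,
        }


def build_matched_sets(
    events: pd.DataFrame,
    study_years: range,
    k: int = N_CONTROLS,
    rng: np.random.Generator | None = None,
    require_full: bool = False,
) -> tuple[list[MatchedSet], MatchingReport]:
    """Form matched sets for every qualifying storm-ZCTA exposure.

    ``events`` carries one row per (storm, ZCTA) with ``storm_id``,
    ``zcta_id`` and ``closest_date``.  Exposed days whose lag window leaves
    the study period are ineligible and dropped (logged).  With
    ``require_full=True``, sets with fewer than ``k`` candidates are dropped
    instead of kept short.  Control days are sampled independently per
    storm, so the same day may serve several storms in a multi-storm ZCTA.
    """
    rng = rng if rng is not None else np.random.default_rng()
    years = list(study_years)
    period_start = date(years[0], 1, 1)
    period_end = date(years[-1], 12, 31)

    sets: list[MatchedSet] = []
    report = MatchingReport()
    events = events.sort_values(["zcta_id", "closest_date", "storm_id"], kind="mergesort")
    for zcta_id, group in events.groupby("zcta_id", sort=True):
        storm_days = {pd.Timestamp(d).date() for d in group["closest_date"]}
        for row in group.itertuples(index=False):
            exposed_day = pd.Timestamp(row.closest_date).date()
            set_label = f"{zcta_id}:{row.storm_id}"
            if (
                exposed_day + timedelta(days=LAGS[0]) < period_start
                or exposed_day + timedelta(days=LAGS[-1]) > period_end
            ):
                report.n_dropped_window += 1
                report.dropped.append(set_label)
                logger.warning(
                    "exposed day %s for %s truncated by the study period; set dropped",
                    exposed_day,
                    set_label,
                )
                continue
            candidates = find_control_candidates(exposed_day, storm_days, study_years)
            if not candidates or (require_full and len(candidates) < k):
                report.n_dropped_no_candidates += 1
                report.dropped.append(set_label)
                logger.warning("no eligible controls for %s; set dropped", set_label)
                continue
            controls = sample_controls(candidates, k=k, rng=rng)
            if len(controls) < k:
                report.n_deficit_sets += 1
            sets.append(
                MatchedSet(
                    zcta_id=str(zcta_id),
                    storm_id=str(row.storm_id),
                    exposed_day=exposed_day,
                    control_days=tuple(controls),
                )
            )
    report.n_sets = len(sets)
    return sets, report


class MissingCountError(KeyError):
    """A window day has no count (or denominator) row to join."""

    def __init__(self, missing: list[tuple]):
        self.missing = missing
        shown = ", ".join(f"({z}, {d})" for z, d in missing[:10])
        more = "" if len(missing) <= 10 else f" ... (+{len(missing) - 10} more)"
        super().__init__(f"missing counts/denominators for: {shown}{more}")


def build_model_table(
    matched_sets: list[MatchedSet],
    counts: pd.DataFrame,
    denominators: pd.DataFrame,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Assemble the long day-level table the distributed-lag model is fit to.

    One row per (matched set, index day, lag position).  Exposed-window rows
    carry a 1 in the indicator column for their own lag; control-window rows
    are all-zero (they are the unexposed comparison days).  Counts are
    joined on (zcta, date); the offset is the log beneficiary denominator
    for the row's (zcta, year).

    Parameters
    ----------
    counts : DataFrame with columns ``zcta_id``, ``date``, ``count``.
    denominators : DataFrame with columns ``zcta_id``, ``year``, ``denominator``.
    on_missing : "error" raises :class:`MissingCountError` listing the
        offending (zcta, date) pairs; "drop" silently drops every set that
        touches a missing day.

    Returns
    -------
    DataFrame with columns ``set_id``, ``zcta_id``, ``storm_id``, ``date``,
    ``role`` (exposed|control), ``lag`` (position, -2..7), the 10 indicator
    columns of :data:`LAG_COLUMNS`, ``count``, ``log_denom``, ``dow``
    (0=Monday), ``year``, ``exposed_flag``.
    """
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    if not matched_sets:
        return _empty_model_table()

    recs = []
    for ms in matched_sets:
        for role, index_day in (("exposed", ms.exposed_day), *((("control", c)) for c in ms.control_days)):
            for lag, d in zip(LAGS, window_dates(index_day)):
                recs.append((ms.set_id, ms.zcta_id, ms.storm_id, d, role, lag))
    table = pd.DataFrame(
        recs, columns=["set_id", "zcta_id", "storm_id", "date", "role", "lag"]
    )
    table["date"] = pd.to_datetime(table["date"])

    for lag, col in zip(LAGS, LAG_COLUMNS):
        table[col] = ((table["role"] == "exposed") & (table["lag"] == lag)).astype(np.int8)

    counts = counts.copy()
    counts["date"] = pd.to_datetime(counts["date"])
    table = table.merge(counts[["zcta_id", "date", "count"]], on=["zcta_id", "date"], how="left")
    table["year"] = table["date"].dt.year
    table = table.merge(
        denominators[["zcta_id", "year", "denominator"]], on=["zcta_id", "year"], how="left"
    )

    missing_mask = table["count"].isna() | table["denominator"].isna()
    if missing_mask.any():
        rows = table.loc[missing_mask, ["zcta_id", "date"]]
        missing = [(z, d.date()) for z, d in rows.itertuples(index=False)]
        if on_missing == "error":
            raise MissingCountError(missing)
        bad_sets = set(table.loc[missing_mask, "set_id"])
        logger.warning(
            "dropping %d matched sets with missing counts/denominators", len(bad_sets)
        )
        table = table.loc[~table["set_id"].isin(bad_sets)]

    table["count"] = table["count"].astype(np.int64)
    table["log_denom"] = np.log(table["denominator"].to_numpy(dtype=float))
    table["dow"] = table["date"].dt.dayofweek.astype(np.int8)
    table["exposed_flag"] = (table["role"] == "exposed").astype(np.int8)
    return table.drop(columns=["denominator"]).reset_index(drop=True)


def _empty_model_table() -> pd.DataFrame:
    cols = ["set_id", "zcta_id", "storm_id", "date", "role", "lag", *LAG_COLUMNS,
            "count", "year", "log_denom", "dow", "exposed_flag"]
    return pd.DataFrame(columns=cols)
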