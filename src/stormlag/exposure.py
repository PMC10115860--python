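"""ZCTA-level tropical-cyclone exposure from storm windspeed records.

A spatial unit (county or ZCTA) counts as exposed to a storm when the
modeled peak sustained windspeed at the unit reaches 21 m/s — strong
gale-force winds, roughly the tropical-storm threshold.  Exposures modeled
at the county level are downscaled to ZCTAs by assigning each ZCTA the
full event list of the county containing the largest share of its land
area.  Windspeeds are in m/s throughout; unit conversion belongs at the
I/O boundary, not inside the pipeline.

Storm-event tables are plain :class:`pandas.DataFrame` objects with columns
``storm_id``, ``unit_id`` (or ``zcta_id`` / ``county_id``), ``closest_date``
(ISO-8601 / datetime64) and ``windspeed``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Qualifying sustained windspeed in m/s (closed lower bound).
EXPOSURE_THRESHOLD_MS = 21.0

EVENT_COLUMNS = ["storm_id", "zcta_id", "closest_date", "windspeed"]


class MissingAssignmentError(KeyError):
    """Raised when a ZCTA has no county overlap row to inherit exposure from."""

    def __init__(self, zctas):
        self.zctas = sorted(str(z) for z in zctas)
        super().__init__(
            "no county overlap available for ZCTA(s): " + ", ".join(self.zctas)
        )


def classify_exposed(windspeed) -> bool | np.ndarray:
    """Return True where ``windspeed`` (m/s) meets the 21 m/s threshold.

    Accepts a scalar or array.  Negative or non-finite values are rejected:
    a modeled windspeed is a physical quantity and silence here would let
    unit errors (knots, mph) slip through as unexposed days.
    """
    arr = np.asarray(windspeed, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("windspeed must be finite")
    if np.any(arr < 0):
        raise ValueError("windspeed must be nonnegative (m/s)")
    out = arr >= EXPOSURE_THRESHOLD_MS
    if np.isscalar(windspeed) or arr.ndim == 0:
        return bool(out)
    return out


def filter_exposed(events: pd.DataFrame) -> pd.DataFrame:
    """Keep only events with qualifying (>=21 m/s) windspeed.

    Idempotent: filtering an already-filtered table is a no-op.
    """
    keep = classify_exposed(events["windspeed"].to_numpy())
    return events.loc[keep].reset_index(drop=True)


def assign_zcta_exposure(
    county_events: pd.DataFrame,
    overlaps: pd.DataFrame,
    zctas=None,
) -> pd.DataFrame:
    """Downscale county-level storm events to ZCTAs by largest land-area overlap.

    Each ZCTA inherits the complete event list of the single county with
    the largest ``land_area_fraction``; windspeed and date are copied
    unchanged.  Equal fractions are broken deterministically toward the
    lexicographically smallest ``county_id`` (logged as a warning).

    Parameters
    ----------
    county_events : DataFrame
        Columns ``storm_id``, ``county_id``, ``closest_date``, ``windspeed``.
    overlaps : DataFrame
        Columns ``zcta_id``, ``county_id``, ``land_area_fraction`` in [0, 1].
        Fractions for one ZCTA may sum to less than 1 (water/unassigned).
    zctas : iterable, optional
        If given, every listed ZCTA must appear in ``overlaps``; otherwise
        :class:`MissingAssignmentError` is raised naming the offenders.

    Returns
    -------
    DataFrame with columns ``storm_id``, ``zcta_id``, ``closest_date``,
    ``windspeed``; one row per (storm, ZCTA).
    """
    frac = overlaps["land_area_fraction"].to_numpy(dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("land_area_fraction must lie in [0, 1]")

    if zctas is not None:
        missing = set(zctas) - set(overlaps["zcta_id"])
        if missing:
            raise MissingAssignmentError(missing)

    # Sort so the largest fraction wins; ties resolve to smallest county_id.
    ranked = overlaps.sort_values(
        ["zcta_id", "land_area_fraction", "county_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("zcta_id", keep="first")

    ties = (
        overlaps.merge(
            best[["zcta_id", "land_area_fraction"]], on="zcta_id", suffixes=("", "_best")
        )
        .query("land_area_fraction == land_area_fraction_best")
        .groupby("zcta_id")
        .size()
    )
    for zcta in ties[ties > 1].index:
        chosen = best.loc[best["zcta_id"] == zcta, "county_id"].iloc[0]
        logger.warning(
            "ZCTA %s has tied land-area fractions; assigned to county %s "
            "(smallest identifier)",
            zcta,
            chosen,
        )

    assigned = best[["zcta_id", "county_id"]].merge(county_events, on="county_id")
    return (
        assigned[["storm_id", "zcta_id", "closest_date", "windspeed"]]
        .sort_values(["zcta_id", "closest_date", "storm_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def summarize_exposure(events: pd.DataFrame, zctas=None) -> pd.DataFrame:
    """Per-ZCTA storm burden: count, mean intensity, most-extreme intensity.

    ``events`` must already be restricted to qualifying storms (>=21 m/s);
    use :func:`filter_exposed` first.  ZCTAs listed in ``zctas`` but absent
    from ``events`` get ``n_storms = 0`` with NaN intensity fields.

    Duplicate (storm_id, zcta_id) pairs are rejected — one closest-approach
    record per storm and unit is the atom of exposure.
    """
    if events.duplicated(["storm_id", "zcta_id"]).any():
        dups = events.loc[
            events.duplicated(["storm_id", "zcta_id"]), ["storm_id", "zcta_id"]
        ]
        raise ValueError(
            f"duplicate (storm_id, zcta_id) rows: {dups.to_records(index=False)[:5]}"
        )

    grouped = events.groupby("zcta_id")["windspeed"]
    summary = pd.DataFrame(
        {
            "n_storms": grouped.size(),
            "mean_windspeed": grouped.mean(),
            "max_windspeed": grouped.max(),
        }
    )
    if zctas is not None:
        summary = summary.reindex(list(zctas))
        summary["n_storms"] = summary["n_storms"].fillna(0).astype(int)
    return summary.rename_axis("zcta_id").reset_index()
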