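"""Community (census) covariates: fixed per-ZCTA profiles and median splits.

Ten ZCTA-level covariates describe the communities in which beneficiaries
live: education (% with a bachelor's degree), poverty (%), income,
percent non-English speakers, household density, median housing value,
population density, percent urban, percent Black residents, and percent
owner-occupied housing.  The pipeline collapses each covariate to a single
fixed value per ZCTA over the whole study period (areal interpolation
across boundary vintages, then time-weighted averaging), classifies ZCTAs
above/below the state-wide median, and checks that the binary labels are
stable over time before they are used as effect-modification strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical covariate order used in profiles and the correlation matrix.
COVARIATES = [
    "education",
    "poverty",
    "income",
    "pct_non_english",
    "household_density",
    "housing_value",
    "population_density",
    "pct_urban",
    "pct_black",
    "pct_owner_occupied",
]

ABOVE = "above"
BELOW = "below"


@dataclass(frozen=True)
class StrataComparison:
    """Two-sample comparison of a storm metric across a binary ZCTA split."""

    covariate: str
    metric: str
    mean_above: float
    sd_above: float
    n_above: int
    mean_below: float
    sd_below: float
    n_below: int
    t_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class StabilityResult:
    """Agreement of a covariate between the start and end of the period."""

    pearson_r: float
    fraction_crossing_median: float
    r_threshold: float
    consistency_threshold: float

    @property
    def passes(self) -> bool:
        if np.isnan(self.pearson_r):
            return False
        return (
            self.pearson_r >= self.r_threshold
            and 1.0 - self.fraction_crossing_median >= self.consistency_threshold
        )


def interpolate_boundaries(
    values_on_old_units: pd.Series, overlap: pd.DataFrame
) -> pd.Series:
    """Area-weighted interpolation of a covariate onto a new set of units.

    ``overlap`` has columns ``old_id``, ``new_id``, ``weight`` (nonnegative
    areas or area fractions).  Each new unit's value is the weight-normalized
    mean of the old-unit values it intersects.  New units whose total weight
    is zero (or that only intersect old units with missing values) come back
    as NaN rather than raising: downstream restriction to complete ZCTAs is
    the place to drop them.
    """
    w = overlap["weight"].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("overlap weights must be nonnegative")
    merged = overlap.merge(
        values_on_old_units.rename("value"), left_on="old_id", right_index=True, how="left"
    )
    ok = merged["value"].notna() & (merged["weight"] > 0)
    merged = merged.loc[ok]
    num = (merged["value"] * merged["weight"]).groupby(merged["new_id"]).sum()
    den = merged.groupby("new_id")["weight"].sum()
    out = (num / den).reindex(overlap["new_id"].unique())
    out.index.name = "new_id"
    return out


def time_weighted_average(observations: pd.DataFrame) -> pd.Series:
    """Collapse repeated census observations to one fixed value per ZCTA.

    ``observations`` has columns ``zcta_id``, ``value``, ``weight`` where the
    weight is the number of study years each observation represents (e.g. a
    decennial value covering 2000-2009 gets weight 10).  ZCTAs with no
    non-missing observation are absent from the result.
    """
    w = observations["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("observation weights must be positive")
    obs = observations.loc[observations["value"].notna()]
    num = (obs["value"] * obs["weight"]).groupby(obs["zcta_id"]).sum()
    den = obs.groupby("zcta_id")["weight"].sum()
    out = num / den
    out.index.name = "zcta_id"
    return out.rename("value")


def median_split(values: pd.Series) -> tuple[pd.Series, float]:
    """Label each unit above/below the median of ``values``.

    A unit is ``"above"`` iff its value strictly exceeds the median; ties at
    the median are labeled ``"below"`` — an arbitrary but deterministic rule,
    applied uniformly.  Missing values get missing labels.  Requires at
    least two non-missing values.
    """
    clean = values.dropna()
    if len(clean) < 2:
        raise ValueError("median_split requires >=2 non-missing values")
    med = float(clean.median())
    labels = pd.Series(
        np.where(values > med, ABOVE, BELOW), index=values.index, dtype=object
    )
    labels[values.isna()] = np.nan
    return labels, med


def stability_check(
    begin_values: pd.Series,
    end_values: pd.Series,
    r_threshold: float = 0.85,
    consistency_threshold: float = 0.92,
) -> StabilityResult:
    """Is a covariate's above/below-median classification stable over time?

    Computes Pearson's r between begin- and end-of-period values, and the
    fraction of ZCTAs whose side of the period median differs between the
    two time points.  The period median is taken over the per-ZCTA mean of
    begin and end (the best available stand-in for the period-average value
    the split is actually based on).  Thresholds default to the levels at
    which a split is considered trustworthy: r >= 0.85 and >= 92% of ZCTAs
    staying on one side.

    Zero variance in either vector leaves ``pearson_r`` NaN (flagged
    undefined) rather than raising.
    """
    paired = pd.DataFrame({"begin": begin_values, "end": end_values}).dropna()
    if len(paired) < 3:
        raise ValueError("stability_check requires >=3 paired non-missing values")
    b = paired["begin"].to_numpy(dtype=float)
    e = paired["end"].to_numpy(dtype=float)
    if np.std(b) == 0 or np.std(e) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(b, e)[0, 1])
    period_median = float(np.median((b + e) / 2.0))
    crossing = float(np.mean((b > period_median) != (e > period_median)))
    return StabilityResult(r, crossing, r_threshold, consistency_threshold)


def compare_strata(
    metric_values: pd.Series,
    labels: pd.Series,
    covariate: str = "",
    metric: str = "",
    welch: bool = True,
) -> StrataComparison:
    """Two-sided t test of a storm metric between above- and below-median ZCTAs.

    Welch's unequal-variance form by default; ``welch=False`` gives the
    pooled-variance test.  Each stratum needs at least two values.
    """
    df = pd.DataFrame({"value": metric_values, "label": labels}).dropna()
    above = df.loc[df["label"] == ABOVE, "value"].to_numpy(dtype=float)
    below = df.loc[df["label"] == BELOW, "value"].to_numpy(dtype=float)
    if len(above) < 2 or len(below) < 2:
        raise ValueError("each stratum needs >=2 values for a t test")
    t, p = stats.ttest_ind(above, below, equal_var=not welch)
    return StrataComparison(
        covariate=covariate,
        metric=metric,
        mean_above=float(above.mean()),
        sd_above=float(above.std(ddof=1)),
        n_above=len(above),
        mean_below=float(below.mean()),
        sd_below=float(below.std(ddof=1)),
        n_below=len(below),
        t_statistic=float(t),
        p_value=float(p),
    )


def correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the ten community covariates.

    ``profiles`` holds one row per ZCTA with the :data:`COVARIATES` columns.
    A constant covariate yields NaN in its row/column (undefined, flagged);
    the remaining entries are unaffected.
    """
    cols = [c for c in COVARIATES if c in profiles.columns]
    if len(profiles.dropna(subset=cols)) < 3:
        raise ValueError("correlation_matrix requires >=3 complete profiles")
    return profiles[cols].corr(method="pearson", min_periods=3)


def build_profiles(covariates: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Attach above/below-median labels for every covariate.

    Returns a copy of ``covariates`` (indexed by ``zcta_id``) with one
    ``label_<covariate>`` column per covariate, plus the medians used.
    """
    out = covariates.copy()
    medians: dict[str, float] = {}
    for cov in COVARIATES:
        if cov not in out.columns:
            continue
        labels, med = median_split(out[cov])
        out[f"label_{cov}"] = labels
        medians[cov] = med
    return out, medians
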