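"""Synthetic storm calendars, covariates, denominators and daily counts.

The generator is the forward model of the distributed-lag regression the
package fits: for each ZCTA-day the event rate is

    rate = exp(alpha + alpha_z + sum_l beta_l x_{t+l} + dow + year) * n

with ``alpha_z ~ N(0, sigma^2)`` drawn once per ZCTA, ``x`` the lag
indicators around simulated storm days, and ``n`` the beneficiary
denominator.  Counts are Poisson.  Because every parameter is known,
downstream matching and model fitting can be tested for exact recovery.

Defaults are calibrated to an 18-year coastal-state Medicare setting:
about 0.23 qualifying storms per ZCTA-year (≈4 storms over 18 years),
sustained windspeeds from a normal truncated at the 21 m/s exposure
threshold (mean ≈ 27.6 m/s), a few thousand beneficiaries per ZCTA, and a
baseline around half a hospitalization per ZCTA-day.

Counts are generated at the resolution of 12 individual-level subgroups
(age x sex x dual-Medicaid eligibility) by multinomial thinning of the
ZCTA-day total, so subgroup counts always sum exactly to the totals used
in overall analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

from stormlag.community import COVARIATES, build_profiles
from stormlag.matching import LAGS

AGE_GROUPS = ("65-74", "75-84", "85+")
SEX_GROUPS = ("male", "female")
DUAL_GROUPS = ("yes", "no")

#: Marginal enrollment shares used for subgroup denominators.
AGE_SHARES = (0.50, 0.33, 0.17)
SEX_SHARES = (0.45, 0.55)
DUAL_SHARES = (0.20, 0.80)

#: The 12 joint subgroups (age, sex, dual) in fixed order.
SUBGROUPS = tuple(
    (a, s, d) for a in AGE_GROUPS for s in SEX_GROUPS for d in DUAL_GROUPS
)
SUBGROUP_SHARES = np.array(
    [
        AGE_SHARES[AGE_GROUPS.index(a)]
        * SEX_SHARES[SEX_GROUPS.index(s)]
        * DUAL_SHARES[DUAL_GROUPS.index(d)]
        for a, s, d in SUBGROUPS
    ]
)

_STRATIFIER_AXES = {"age": 0, "sex": 1, "dual": 2}
_STRATIFIER_LEVELS = {"age": AGE_GROUPS, "sex": SEX_GROUPS, "dual": DUAL_GROUPS}
_MARGINAL_SHARES = {"age": AGE_SHARES, "sex": SEX_SHARES, "dual": DUAL_SHARES}


def default_community_correlation() -> np.ndarray:
    """A realistic positive-definite correlation among the ten covariates.

    Income correlates positively with education and housing value and
    negatively with poverty; the two density measures and percent urban
    form a cluster; owner occupancy runs against poverty.
    """
    R = np.eye(len(COVARIATES))
    pairs = {
        ("income", "housing_value"): 0.7,
        ("income", "education"): 0.5,
        ("income", "poverty"): -0.55,
        ("education", "poverty"): -0.35,
        ("education", "housing_value"): 0.4,
        ("poverty", "housing_value"): -0.35,
        ("poverty", "pct_owner_occupied"): -0.4,
        ("population_density", "household_density"): 0.75,
        ("population_density", "pct_urban"): 0.6,
        ("household_density", "pct_urban"): 0.5,
        ("poverty", "pct_non_english"): 0.3,
    }
    idx = {c: i for i, c in enumerate(COVARIATES)}
    for (a, b), r in pairs.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


@dataclass
class ScenarioConfig:
    """All knobs of the data-generating process (the simulation "truth").

    Parameters
    ----------
    n_zctas : number of spatial units.
    year_start, year_end : inclusive study years.
    storms_per_year : expected qualifying storms per ZCTA-year.
    windspeed_loc, windspeed_scale : location/scale (m/s) of the sustained
        windspeed distribution, truncated below at 21 m/s so every emitted
        storm qualifies as an exposure.
    true_lag_betas : 10 log-RRs, one per lag -2..7.
    baseline_log_rate : log events per beneficiary-day (alpha).
    dow_effects : 7 log-rate shifts, Monday first and fixed at 0.
    year_effects : one log-rate shift per study year, first fixed at 0;
        ``None`` means all zero.
    random_intercept_sd : SD of the ZCTA random intercept (alpha_z).
    denominator_range : inclusive bounds for beneficiaries per ZCTA-year.
    annual_denominators : redraw the denominator every year (True) or keep
        one per ZCTA for the whole period (False).
    modifier_effect : optional additive log-RR applied, in ZCTAs above the
        median of ``modifier_covariate``, to the lags in ``modifier_lags``
        (ln 2 doubles the lag-0 risk there, the canonical
        effect-modification scenario).
    season : (first, last) storm month, inclusive.
    subgroup_resolution : also generate the 12-cell subgroup counts.
    rate_ceiling : guard against runaway rates (expected counts per
        ZCTA-day above this raise).
    seed : base seed for all randomness.
    """

    n_zctas: int = 100
    year_start: int = 1999
    year_end: int = 2016
    storms_per_year: float = 0.226
    windspeed_loc: float = 27.0
    windspeed_scale: float = 4.2
    true_lag_betas: tuple[float, ...] = tuple(0.0 for _ in LAGS)
    baseline_log_rate: float = -9.4
    dow_effects: tuple[float, ...] = (0.0, 0.01, 0.01, 0.0, -0.01, -0.06, -0.08)
    year_effects: tuple[float, ...] | None = None
    random_intercept_sd: float = 0.15
    denominator_range: tuple[int, int] = (2000, 10000)
    annual_denominators: bool = True
    modifier_effect: float | None = None
    modifier_lags: tuple[int, ...] = (0,)
    modifier_covariate: str = "poverty"
    season: tuple[int, int] = (6, 11)
    subgroup_resolution: bool = True
    community_correlation: np.ndarray | None = None
    rate_ceiling: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_zctas < 1:
            raise ValueError("n_zctas must be positive")
        if self.year_end < self.year_start:
            raise ValueError("year range must be nondecreasing")
        if self.storms_per_year < 0:
            raise ValueError("storms_per_year must be nonnegative")
        if len(self.true_lag_betas) != len(LAGS):
            raise ValueError(f"true_lag_betas needs {len(LAGS)} entries (lags -2..7)")
        if len(self.dow_effects) != 7 or self.dow_effects[0] != 0.0:
            raise ValueError("dow_effects needs 7 entries with the first "
                             "(Monday, the reference) equal to 0")
        if self.year_effects is not None:
            if len(self.year_effects) != self.n_years:
                raise ValueError("year_effects needs one entry per study year")
            if self.year_effects[0] != 0.0:
                raise ValueError("the first year is the reference: effect must be 0")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be nonnegative")
        lo, hi = self.denominator_range
        if lo < 1 or hi < lo:
            raise ValueError("denominator_range must be positive and ordered")
        if not 1 <= self.season[0] <= self.season[1] <= 12:
            raise ValueError("season months must be ordered within 1..12")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    def resolved_year_effects(self) -> np.ndarray:
        if self.year_effects is None:
            return np.zeros(self.n_years)
        return np.asarray(self.year_effects, dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.community_correlation is not None:
            d["community_correlation"] = np.asarray(
                self.community_correlation
            ).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("true_lag_betas", "dow_effects", "year_effects",
                    "denominator_range", "modifier_lags", "season"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("community_correlation") is not None:
            d["community_correlation"] = np.asarray(d["community_correlation"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Everything a pipeline run needs, plus the generating truth."""

    storm_events: pd.DataFrame
    counts: pd.DataFrame
    denominators: pd.DataFrame
    community: pd.DataFrame
    medians: dict[str, float]
    truth: ScenarioConfig
    subgroup_counts: np.ndarray | None = None

    def counts_by(self, stratifier: str) -> dict[str, pd.DataFrame]:
        """Daily counts per level of ``stratifier`` (age | sex | dual)."""
        if self.subgroup_counts is None:
            raise ValueError("dataset was generated without subgroup resolution")
        axis = _STRATIFIER_AXES[stratifier]
        out = {}
        for level in _STRATIFIER_LEVELS[stratifier]:
            cols = [i for i, g in enumerate(SUBGROUPS) if g[axis] == level]
            df = self.counts[["zcta_id", "date"]].copy()
            df["count"] = self.subgroup_counts[:, cols].sum(axis=1)
            out[level] = df
        return out

    def denominators_by(self, stratifier: str) -> dict[str, pd.DataFrame]:
        """Beneficiary denominators per level (fixed enrollment shares)."""
        shares = _MARGINAL_SHARES[stratifier]
        out = {}
        for level, share in zip(_STRATIFIER_LEVELS[stratifier], shares):
            df = self.denominators.copy()
            df["denominator"] = df["denominator"] * share
            out[level] = df
        return out

    def write(self, outdir) -> None:
        """Write the dataset as delimited text plus the scenario config."""
        import pathlib

        import yaml

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.storm_events.to_csv(outdir / "storm_events.csv", index=False)
        self.counts.to_csv(outdir / "counts.csv", index=False)
        self.denominators.to_csv(outdir / "denominators.csv", index=False)
        self.community.to_csv(outdir / "community.csv")
        with open(outdir / "scenario.yaml", "w") as fh:
            yaml.safe_dump(self.truth.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# generators

def _zcta_ids(n: int) -> list[str]:
    return [f"Z{i:04d}" for i in range(n)]


def generate_storm_calendar(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate qualifying storm events (closest-approach day + windspeed).

    Each ZCTA draws a Poisson(storms_per_year x n_years) number of storms
    with dates uniform over the configured season (June-November by
    default), independently across ZCTAs.  Two storms in one ZCTA can fall
    arbitrarily close together, which is exactly what exercises the 3-day
    control exclusion downstream.  Windspeeds come from a normal truncated
    below at 21 m/s, so every emitted event qualifies as an exposure.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    season_days = pd.DatetimeIndex(
        [
            d
            for year in config.years
            for d in pd.date_range(
                date(year, config.season[0], 1),
                pd.Timestamp(date(year, config.season[1], 1))
                + pd.offsets.MonthEnd(0),
            )
        ]
    )
    a = (21.0 - config.windspeed_loc) / config.windspeed_scale
    rows = []
    for zcta in _zcta_ids(config.n_zctas):
        n_storms = rng.poisson(config.storms_per_year * config.n_years)
        if n_storms == 0:
            continue
        picks = rng.choice(len(season_days), size=n_storms, replace=False)
        winds = stats.truncnorm.rvs(
            a, np.inf, loc=config.windspeed_loc, scale=config.windspeed_scale,
            size=n_storms, random_state=rng,
        )
        for i, (p, w) in enumerate(zip(sorted(picks), winds)):
            rows.append((f"{zcta}-S{i}", zcta, season_days[p], float(w)))
    return pd.DataFrame(
        rows, columns=["storm_id", "zcta_id", "closest_date", "windspeed"]
    )


def generate_community(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the ten community covariates from a correlated Gaussian copula.

    Latent values are multivariate normal with the configured correlation
    (default :func:`default_community_correlation`); marginals are mapped
    to plausible scales — percentages through the normal CDF, incomes,
    housing values and densities through lognormal transforms.
    """
    if config.n_zctas < 2:
        raise ValueError("community generation needs n_zctas >= 2")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    R = (
        np.asarray(config.community_correlation, dtype=float)
        if config.community_correlation is not None
        else default_community_correlation()
    )
    if R.shape != (len(COVARIATES), len(COVARIATES)):
        raise ValueError("community correlation must be 10x10")
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("community correlation matrix is not positive "
                         "definite") from exc
    z = rng.standard_normal((config.n_zctas, len(COVARIATES))) @ L.T
    u = stats.norm.cdf(z)

    df = pd.DataFrame(index=pd.Index(_zcta_ids(config.n_zctas), name="zcta_id"))
    col = {c: i for i, c in enumerate(COVARIATES)}
    df["education"] = 100 * u[:, col["education"]] * 0.6  # % bachelor's, 0-60
    df["poverty"] = 100 * u[:, col["poverty"]] * 0.4  # % in poverty, 0-40
    df["income"] = 30000 * np.exp(0.4 * z[:, col["income"]])
    df["pct_non_english"] = 100 * u[:, col["pct_non_english"]] * 0.3
    df["household_density"] = 400 * np.exp(0.9 * z[:, col["household_density"]])
    df["housing_value"] = 150000 * np.exp(0.5 * z[:, col["housing_value"]])
    df["population_density"] = 1000 * np.exp(1.1 * z[:, col["population_density"]])
    df["pct_urban"] = 100 * u[:, col["pct_urban"]]
    df["pct_black"] = 100 * u[:, col["pct_black"]] * 0.5
    df["pct_owner_occupied"] = 100 * (0.2 + 0.75 * u[:, col["pct_owner_occupied"]])
    return df[COVARIATES]


def generate_denominators(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Beneficiary counts per ZCTA-year (annual redraw or constant)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.denominator_range
    zctas = _zcta_ids(config.n_zctas)
    years = list(config.years)
    if config.annual_denominators:
        denom = rng.integers(lo, hi + 1, size=(len(zctas), len(years)))
    else:
        denom = np.repeat(
            rng.integers(lo, hi + 1, size=(len(zctas), 1)), len(years), axis=1
        )
    return pd.DataFrame(
        {
            "zcta_id": np.repeat(zctas, len(years)),
            "year": np.tile(years, len(zctas)),
            "denominator": denom.ravel(),
        }
    )


def generate_counts(
    config: ScenarioConfig,
    events: pd.DataFrame,
    denominators: pd.DataFrame,
    above_modifier: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray | None, pd.Series]:
    """Draw Poisson counts for every ZCTA-day from the forward model.

    Returns ``(counts, subgroup_counts, random_intercepts)``; the subgroup
    array (rows aligned with ``counts``) is ``None`` when
    ``config.subgroup_resolution`` is off.  ``above_modifier`` marks the
    ZCTAs whose lag effects receive ``modifier_effect``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    zctas = _zcta_ids(config.n_zctas)
    zcta_index = {z: i for i, z in enumerate(zctas)}
    dates = pd.date_range(
        date(config.year_start, 1, 1), date(config.year_end, 12, 31)
    )
    n_days = len(dates)

    alpha_z = rng.normal(0.0, config.random_intercept_sd, size=len(zctas))

    eta_lag = np.zeros((len(zctas), n_days))
    betas = np.asarray(config.true_lag_betas, dtype=float)
    mod = np.zeros_like(betas)
    if config.modifier_effect is not None:
        for l in config.modifier_lags:
            mod[LAGS.index(l)] = config.modifier_effect
    start_ts = dates[0]
    for row in events.itertuples(index=False):
        zi = zcta_index[row.zcta_id]
        d0 = (pd.Timestamp(row.closest_date) - start_ts).days
        if not 0 <= d0 < n_days:
            raise ValueError(f"storm date {row.closest_date} outside the year range")
        extra = mod if (
            above_modifier is not None and bool(above_modifier.get(row.zcta_id, False))
        ) else 0.0
        b = betas + extra
        for k, l in enumerate(LAGS):
            idx = d0 + l
            if 0 <= idx < n_days:
                eta_lag[zi, idx] += b[k]

    dow = dates.dayofweek.to_numpy()
    dow_eff = np.asarray(config.dow_effects, dtype=float)[dow]
    year_idx = dates.year.to_numpy() - config.year_start
    year_eff = config.resolved_year_effects()[year_idx]

    denom_wide = (
        denominators.pivot(index="zcta_id", columns="year", values="denominator")
        .reindex(zctas)
        .to_numpy(dtype=float)
    )
    denom_day = denom_wide[:, year_idx]

    log_rate = (
        config.baseline_log_rate
        + alpha_z[:, None]
        + eta_lag
        + dow_eff[None, :]
        + year_eff[None, :]
    )
    mean = np.exp(log_rate) * denom_day
    if mean.max() > config.rate_ceiling:
        raise ValueError(
            f"expected count {mean.max():.3g} exceeds the rate ceiling "
            f"{config.rate_ceiling:.3g}; check baseline_log_rate/betas"
        )

    total = rng.poisson(mean).astype(np.int64)
    counts = pd.DataFrame(
        {
            "zcta_id": np.repeat(zctas, n_days),
            "date": np.tile(dates, len(zctas)),
            "count": total.ravel(),
        }
    )
    sub = None
    if config.subgroup_resolution:
        sub = rng.multinomial(total.ravel(), SUBGROUP_SHARES)
    intercepts = pd.Series(alpha_z, index=pd.Index(zctas, name="zcta_id"))
    return counts, sub, intercepts


def simulate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Generate a complete synthetic study from one seeded configuration.

    A single generator seeded with ``config.seed`` drives community
    covariates, the storm calendar, denominators and counts in a fixed
    order, so identical configs give byte-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    covariates = generate_community(config, rng)
    profiles, medians = build_profiles(covariates)
    events = generate_storm_calendar(config, rng)
    denominators = generate_denominators(config, rng)
    above = None
    if config.modifier_effect is not None:
        above = profiles[f"label_{config.modifier_covariate}"] == "above"
    counts, sub, _ = generate_counts(config, events, denominators, above, rng)
    return SyntheticDataset(
        storm_events=events,
        counts=counts,
        denominators=denominators,
        community=profiles,
        medians=medians,
        truth=config,
        subgroup_counts=sub,
    )
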