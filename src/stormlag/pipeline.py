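"""End-to-end runs and stratified effect-modification analyses.

Stratified analyses come in two flavors.  *Community* stratification
partitions the matched sets by a ZCTA-level above/below-median label and
fits the distributed-lag model independently in each stratum.  *Individual*
stratification keeps the same matched windows but swaps in subgroup-specific
counts and offsets (age group, sex, dual-Medicaid eligibility).  Strata are
compared with a two-sample z test on log-RRs from the independently fitted
strata — the standard construction when only stratum-specific estimates and
their standard errors are available.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from stormlag.community import COVARIATES, compare_strata
from stormlag.dlm import DlmFit, cumulative_rr, fit_dlm, lag_rr, rr_table
from stormlag.exposure import filter_exposed, summarize_exposure
from stormlag.matching import LAGS, build_matched_sets, build_model_table
from stormlag.synthetic import ScenarioConfig, SyntheticDataset, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class StratumFit:
    """One stratum's fit and bookkeeping (fit is None for empty strata)."""

    label: str
    fit: DlmFit | None
    n_sets: int
    n_rows: int

    @property
    def empty(self) -> bool:
        return self.fit is None


@dataclass
class StratifiedResult:
    """Fits for every stratum of one stratifier, plus comparisons."""

    stratifier: str
    outcome: str
    strata: dict[str, StratumFit]

    def rr_tables(self, alpha_level: float = 0.05) -> pd.DataFrame:
        frames = []
        for label, sf in self.strata.items():
            if sf.empty:
                continue
            t = rr_table(sf.fit, alpha_level)
            t.insert(0, "stratum", label)
            t.insert(0, "stratifier", self.stratifier)
            t.insert(0, "outcome", self.outcome)
            frames.append(t)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample z test of a log-RR between independently fitted strata."""

    target: str
    diff_log_rr: float
    se: float
    z: float
    p_value: float
    flagged: bool = False

    @property
    def significant(self) -> bool:
        return (not self.flagged) and self.p_value < 0.05


def compare_strata_rr(
    fit_a: DlmFit, fit_b: DlmFit, target: int | str = "cumulative"
) -> ComparisonResult:
    """Test whether a lag (or cumulative) log-RR differs between two strata.

    ``z = (logRR_a - logRR_b) / sqrt(se_a^2 + se_b^2)`` with a two-sided
    normal p-value; valid because the strata are fit on disjoint data.
    ``target`` is a lag in -2..7 or ``"cumulative"``.  Flagged (separated /
    unavailable) estimates propagate to a flagged comparison.
    """
    if target == "cumulative":
        ea, eb = cumulative_rr(fit_a), cumulative_rr(fit_b)
        name = "cumulative"
    else:
        idx = LAGS.index(int(target))
        ea, eb = lag_rr(fit_a)[idx], lag_rr(fit_b)[idx]
        name = f"lag {target}"
    if ea.flagged or eb.flagged:
        return ComparisonResult(name, float("nan"), float("nan"),
                                float("nan"), float("nan"), flagged=True)
    diff = ea.log_rr - eb.log_rr
    se = float(np.sqrt(ea.se_log_rr**2 + eb.se_log_rr**2))
    z = diff / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(name, float(diff), se, float(z), p)


def stratify_community(
    table: pd.DataFrame,
    labels: pd.Series,
    stratifier: str = "",
    outcome: str = "synthetic",
    **fit_kwargs,
) -> StratifiedResult:
    """Partition the model table by a ZCTA label and fit each stratum.

    ``labels`` maps zcta_id -> "above"/"below".  Every ZCTA present in the
    table must carry a label.  A stratum that ends up with no matched sets
    is reported as empty rather than raising.
    """
    zctas = pd.Index(table["zcta_id"].unique())
    missing = zctas.difference(labels.dropna().index)
    if len(missing):
        raise KeyError(f"ZCTAs without a {stratifier!r} label: {list(missing)[:5]}")
    strata: dict[str, StratumFit] = {}
    for label in ("above", "below"):
        in_stratum = labels.index[labels == label]
        part = table.loc[table["zcta_id"].isin(in_stratum)]
        n_sets = part["set_id"].nunique()
        if n_sets == 0:
            strata[label] = StratumFit(label, None, 0, 0)
            continue
        fit = fit_dlm(part, **fit_kwargs)
        strata[label] = StratumFit(label, fit, n_sets, len(part))
    return StratifiedResult(stratifier, outcome, strata)


def stratify_individual(
    matched_sets,
    counts_by: dict[str, pd.DataFrame],
    denominators_by: dict[str, pd.DataFrame],
    outcome: str = "synthetic",
    stratifier: str = "",
    **fit_kwargs,
) -> StratifiedResult:
    """Fit the model per subgroup with subgroup-specific counts and offsets.

    The matched windows are shared across subgroups; only the outcome
    counts and the beneficiary offsets change.  Missing denominators for a
    subgroup raise, naming the subgroup.
    """
    strata: dict[str, StratumFit] = {}
    for level, counts in counts_by.items():
        if level not in denominators_by:
            raise KeyError(f"no denominators for subgroup {level!r}")
        table = build_model_table(matched_sets, counts, denominators_by[level])
        n_sets = table["set_id"].nunique() if len(table) else 0
        if n_sets == 0:
            strata[level] = StratumFit(level, None, 0, 0)
            continue
        fit = fit_dlm(table, **fit_kwargs)
        strata[level] = StratumFit(level, fit, n_sets, len(table))
    return StratifiedResult(stratifier, outcome, strata)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    config_hash: str
    seed: int
    matching_seed: int
    package_version: str
    n_zctas_included: int
    n_zctas_excluded: int
    excluded_zctas: list[str]
    matching_report: dict
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _package_version() -> str:
    import stormlag

    return stormlag.__version__


def _config_hash(config: ScenarioConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(
    config: ScenarioConfig | str | pathlib.Path,
    outdir: str | pathlib.Path | None = None,
    community_stratifiers: tuple[str, ...] = tuple(COVARIATES),
    individual_stratifiers: tuple[str, ...] = ("age", "sex", "dual"),
    n_controls: int = 10,
    **fit_kwargs,
) -> dict:
    """Simulate (or load) a scenario and run the full analysis.

    Steps: generate the synthetic study, restrict to ZCTAs with at least
    one qualifying storm and complete community data, form matched sets,
    build the model table, fit the overall distributed-lag model, then run
    community and individual stratifications with between-stratum
    comparisons of the cumulative RR.  Outputs (tidy CSVs + JSON manifest)
    land in ``outdir`` when given.

    Returns a dict with the dataset, fits, stratified results, comparison
    table and manifest.
    """
    if not isinstance(config, ScenarioConfig):
        with open(config) as fh:
            config = ScenarioConfig.from_dict(yaml.safe_load(fh))

    ds = simulate_dataset(config)
    events = filter_exposed(ds.storm_events)

    # Restriction: complete community data and >=1 qualifying storm.
    complete = ds.community[COVARIATES].notna().all(axis=1)
    with_storm = ds.community.index.isin(events["zcta_id"])
    included = ds.community.index[complete & with_storm]
    excluded = ds.community.index.difference(included)
    if len(excluded):
        logger.info("excluding %d ZCTAs (no storm or incomplete data)", len(excluded))
    events = events[events["zcta_id"].isin(included)]

    exposure_summary = summarize_exposure(events, zctas=list(included))

    matching_seed = config.seed + 1_000_003
    rng = np.random.default_rng(matching_seed)
    sets, match_report = build_matched_sets(
        events, config.years, k=n_controls, rng=rng
    )

    table = build_model_table(sets, ds.counts, ds.denominators)
    overall_fit = fit_dlm(table, **fit_kwargs) if len(table) else None

    community_results: list[StratifiedResult] = []
    comparisons: list[dict] = []
    if overall_fit is not None:
        for cov in community_stratifiers:
            labels = ds.community[f"label_{cov}"]
            res = stratify_community(
                table, labels, stratifier=cov, **fit_kwargs
            )
            community_results.append(res)
            above, below = res.strata["above"], res.strata["below"]
            if not (above.empty or below.empty):
                cmp = compare_strata_rr(above.fit, below.fit, "cumulative")
                comparisons.append(
                    {"stratifier": cov, **dataclasses.asdict(cmp)}
                )

    individual_results: list[StratifiedResult] = []
    if overall_fit is not None and ds.subgroup_counts is not None:
        for strat in individual_stratifiers:
            individual_results.append(
                stratify_individual(
                    sets,
                    ds.counts_by(strat),
                    ds.denominators_by(strat),
                    stratifier=strat,
                    **fit_kwargs,
                )
            )

    comparisons_df = pd.DataFrame(comparisons)
    if len(comparisons_df):
        # Bonferroni column alongside unadjusted p-values, for transparency.
        m = len(comparisons_df)
        comparisons_df["p_bonferroni"] = np.minimum(
            comparisons_df["p_value"] * m, 1.0
        )

    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=_config_hash(config),
        seed=config.seed,
        matching_seed=matching_seed,
        package_version=_package_version(),
        n_zctas_included=len(included),
        n_zctas_excluded=len(excluded),
        excluded_zctas=[str(z) for z in excluded],
        matching_report=match_report.as_dict(),
    )

    results = {
        "dataset": ds,
        "exposure_summary": exposure_summary,
        "matched_sets": sets,
        "model_table": table,
        "overall_fit": overall_fit,
        "community_results": community_results,
        "individual_results": individual_results,
        "comparisons": comparisons_df,
        "manifest": manifest,
    }

    if outdir is not None:
        _write_outputs(results, pathlib.Path(outdir))
    return results


def _write_outputs(results: dict, outdir: pathlib.Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results["exposure_summary"].to_csv(outdir / "exposure_summary.csv", index=False)
    fit = results["overall_fit"]
    if fit is not None:
        rr_table(fit).to_csv(outdir / "rr_overall.csv", index=False)
        with open(outdir / "fit_overall.json", "w") as fh:
            json.dump(
                {
                    "beta": fit.beta.tolist(),
                    "se": fit.se.tolist(),
                    "vcov": fit.vcov.tolist(),
                    "nuisance": fit.nuisance,
                    "random_intercept_var": fit.random_intercept_var,
                    "method": fit.method,
                    "converged": fit.converged,
                    "loglik": fit.loglik,
                },
                fh,
                indent=2,
            )
    strat_frames = [
        r.rr_tables() for r in results["community_results"] + results["individual_results"]
    ]
    strat_frames = [f for f in strat_frames if len(f)]
    if strat_frames:
        pd.concat(strat_frames, ignore_index=True).to_csv(
            outdir / "rr_stratified.csv", index=False
        )
    if len(results["comparisons"]):
        results["comparisons"].to_csv(outdir / "comparisons.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        fh.write(results["manifest"].to_json())
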