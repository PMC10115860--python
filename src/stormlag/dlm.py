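"""Distributed-lag mixed Poisson regression and relative-risk summaries.

The model for the daily count :math:`Y_t^z` of events in ZCTA *z*:

.. math::

    \\log E[Y_t^z] = \\alpha + \\alpha^z + \\sum_{l=-2}^{7} \\beta_l x_{t+l}^z
        + \\log n^z_{T} + \\delta' \\mathrm{DOW}_t + \\gamma' \\mathrm{Year}_t

where :math:`x^z_{t+l}` indicates that day *t* sits at lag *l* of a
storm-exposed day, :math:`\\alpha^z \\sim N(0, \\sigma^2)` is a ZCTA random
intercept, and the offset :math:`\\log n^z_T` turns the mean into a rate per
beneficiary.  ``exp(beta_l)`` is the lag-*l* relative risk; the cumulative
relative risk over the 10-day storm period is ``exp(sum_l beta_l)``.

Fitting is by maximum (Laplace-approximated marginal) likelihood.  Random
intercepts are independent across ZCTAs, so the marginal likelihood factors
by cluster; for a fixed variance the fixed effects and cluster modes are
found by penalized iteratively reweighted least squares (IRLS) with step
halving, and the variance is profiled on an outer one-dimensional search.
With the variance at zero the model collapses to a plain Poisson GLM and
the same IRLS code path applies without the penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from stormlag.matching import LAGS, LAG_COLUMNS

logger = logging.getLogger(__name__)


class NotConvergedError(RuntimeError):
    """The likelihood optimizer did not reach the convergence tolerance."""


@dataclass
class DlmFit:
    """A fitted distributed-lag Poisson model.

    ``beta``/``se``/``vcov`` are indexed by lag position (-2..7, the order
    of :data:`stormlag.matching.LAGS`).  Lags exhibiting separation (all
    observed counts zero where the indicator is 1) are fit without their
    column; their ``beta`` is ``-inf`` with infinite SE and they are marked
    in ``separated``.
    """

    beta: np.ndarray
    vcov: np.ndarray
    se: np.ndarray
    nuisance: dict[str, float]
    random_intercept_var: float
    converged: bool
    n_iter: int
    loglik: float
    loglik_path: list[float]
    method: str
    n_rows: int
    n_zctas: int
    separated: np.ndarray = field(default_factory=lambda: np.zeros(len(LAGS), bool))

    @property
    def lags(self) -> tuple[int, ...]:
        return LAGS

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": LAGS, "beta": self.beta, "se": self.se,
                             "separated": self.separated})


@dataclass(frozen=True)
class RrEstimate:
    """A relative risk with its Wald confidence interval on the log scale."""

    label: str
    rr: float
    ci_low: float
    ci_high: float
    log_rr: float
    se_log_rr: float
    flagged: bool = False


# ---------------------------------------------------------------------------
# design matrix

def _design_matrix(
    table: pd.DataFrame,
    include_dow: bool = True,
    include_year: bool = True,
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray, np.ndarray, int]:
    """Build (X, names, y, offset, zcta_codes, n_zctas) from a model table.

    Day-of-week enters as categorical with Monday (0) as reference; year as
    categorical with the earliest year as reference.  Dummy columns for
    levels absent from the table are dropped.
    """
    y = table["count"].to_numpy(dtype=float)
    offset = table["log_denom"].to_numpy(dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("log-denominator offsets must be finite")

    cols = [np.ones(len(table))]
    names = ["intercept"]
    for c in LAG_COLUMNS:
        cols.append(table[c].to_numpy(dtype=float))
        names.append(c)
    if include_dow:
        dow = table["dow"].to_numpy()
        for d in range(1, 7):  # Monday = reference
            v = (dow == d).astype(float)
            if v.any():
                cols.append(v)
                names.append(f"dow_{d}")
    if include_year:
        years = np.sort(table["year"].unique())
        for yv in years[1:]:  # first year = reference
            v = (table["year"].to_numpy() == yv).astype(float)
            cols.append(v)
            names.append(f"year_{yv}")
    X = np.column_stack(cols)
    zcta, codes = np.unique(table["zcta_id"].to_numpy(), return_inverse=True)
    return X, names, y, offset, codes, len(zcta)


def _detect_separation(table: pd.DataFrame) -> np.ndarray:
    """Lags that cannot be estimated from this table.

    Either the indicator never takes the value 1 (the lag is absent, so its
    coefficient is unidentifiable) or it is present but every accompanying
    count is zero (separation: the MLE diverges to -inf).
    """
    sep = np.zeros(len(LAGS), dtype=bool)
    for i, c in enumerate(LAG_COLUMNS):
        ind = table[c].to_numpy() == 1
        if not ind.any() or table.loc[ind, "count"].sum() == 0:
            sep[i] = True
    return sep


# ---------------------------------------------------------------------------
# inner optimizers

def _poisson_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # log y! omitted: constant in the parameters.
    return float(y @ eta - np.exp(eta).sum())


def _irls_glm(X, y, offset, tol, max_iter):
    """Plain Poisson IRLS (Newton with step halving; monotone in loglik)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.sum(), 0.5)) - np.log(np.exp(offset).sum())
    eta = X @ beta + offset
    ll = _poisson_ll(y, eta)
    path = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        mu = np.exp(eta)
        XW = X * mu[:, None]
        H = X.T @ XW
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise NotConvergedError(f"singular information matrix: {exc}") from exc
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand + offset
            ll_c = _poisson_ll(y, eta_c)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        beta, eta = cand, eta_c
        path.append(ll_c)
        if abs(ll_c - ll) <= tol * (abs(ll) + 1.0):
            ll = ll_c
            converged = True
            break
        ll = ll_c
    mu = np.exp(eta)
    cov = np.linalg.inv(X.T @ (X * mu[:, None]))
    return beta, cov, ll, path, converged, it


def _penalized_irls(X, y, offset, codes, q, sigma2, tol, max_iter,
                    beta0=None, b0=None):
    """Joint penalized Newton over fixed effects and ZCTA intercepts.

    Maximizes sum of Poisson loglik minus b'b / (2 sigma2).  Returns the
    mode, the penalized loglik there, and the fitted means (for the
    Laplace determinant term and the covariance extraction).
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if beta0 is None:
        beta[0] = np.log(max(y.sum(), 0.5)) - np.log(np.exp(offset).sum())
    b = np.zeros(q) if b0 is None else b0.copy()

    def pen_ll(beta_, b_):
        eta_ = X @ beta_ + offset + b_[codes]
        return _poisson_ll(y, eta_) - float(b_ @ b_) / (2.0 * sigma2), eta_

    ll, eta = pen_ll(beta, b)
    converged = False
    for it in range(1, max_iter + 1):
        mu = np.exp(eta)
        resid = y - mu
        XW = X * mu[:, None]
        H_bb_diag = np.bincount(codes, weights=mu, minlength=q) + 1.0 / sigma2
        H_xb = np.zeros((p, q))
        for j in range(p):
            H_xb[j] = np.bincount(codes, weights=XW[:, j], minlength=q)
        H = np.zeros((p + q, p + q))
        H[:p, :p] = X.T @ XW
        H[:p, p:] = H_xb
        H[p:, :p] = H_xb.T
        H[p:, p:] = np.diag(H_bb_diag)
        g = np.concatenate([
            X.T @ resid,
            np.bincount(codes, weights=resid, minlength=q) - b / sigma2,
        ])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise NotConvergedError(f"singular penalized information: {exc}") from exc
        scale = 1.0
        for _ in range(30):
            beta_c = beta + scale * step[:p]
            b_c = b + scale * step[p:]
            ll_c, eta_c = pen_ll(beta_c, b_c)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        beta, b, eta = beta_c, b_c, eta_c
        if abs(ll_c - ll) <= tol * (abs(ll) + 1.0):
            ll = ll_c
            converged = True
            break
        ll = ll_c
    mu = np.exp(eta)
    return beta, b, ll, mu, H, converged, it


def _laplace_marginal_ll(pen_ll, mu, codes, q, sigma2):
    """Laplace-approximate marginal loglik given the penalized mode."""
    w_z = np.bincount(codes, weights=mu, minlength=q)
    return pen_ll - 0.5 * float(np.log1p(sigma2 * w_z).sum())


# ---------------------------------------------------------------------------
# public fitting API

def fit_dlm(
    table: pd.DataFrame,
    random_intercept: bool = True,
    include_dow: bool = True,
    include_year: bool = True,
    tol: float = 1e-8,
    max_iter: int = 200,
    sigma_bounds: tuple[float, float] = (1e-3, 3.0),
    quasipoisson: bool = False,
) -> DlmFit:
    """Fit the distributed-lag Poisson model to a long model table.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`stormlag.matching.build_model_table`.
    random_intercept : bool
        Estimate a ZCTA random intercept by Laplace-approximated marginal
        likelihood.  Automatically disabled (with a log message) when the
        table contains fewer than two ZCTAs.  If the variance profile is
        maximized at (effectively) zero the fit reduces to the plain GLM.
    include_dow, include_year : bool
        Day-of-week / year categorical controls (references: Monday, first
        year present).
    tol : float
        Relative log-likelihood change declaring convergence.
    max_iter : int
        Cap on IRLS iterations (inner loop).
    sigma_bounds : (float, float)
        Search interval for the random-intercept SD.
    quasipoisson : bool
        Inflate the coefficient covariance by the Pearson chi-square scale
        (dispersion) estimate.  Off by default: the model is Poisson.

    Returns
    -------
    DlmFit — with ``converged=False`` and diagnostics rather than an
    exception when the optimizer stalls; downstream RR extraction refuses
    unconverged fits.
    """
    if len(table) == 0:
        raise ValueError("model table is empty")
    separated = _detect_separation(table)
    work = table
    active = [c for c, s in zip(LAG_COLUMNS, separated) if not s]
    if separated.any():
        logger.warning(
            "inestimable lag(s) %s: indicator absent or all counts zero",
            [l for l, s in zip(LAGS, separated) if s],
        )
        work = table.copy()
        for c, s in zip(LAG_COLUMNS, separated):
            if s:
                work[c] = 0  # column dropped from the design below

    X, names, y, offset, codes, q = _design_matrix(work, include_dow, include_year)
    keep = [i for i, nm in enumerate(names)
            if nm not in LAG_COLUMNS or nm in active]
    X = X[:, keep]
    names = [names[i] for i in keep]

    if random_intercept and q < 2:
        logger.warning("fewer than 2 ZCTAs; random intercept disabled")
        random_intercept = False

    if not random_intercept:
        beta_hat, cov, ll, path, conv, n_iter = _irls_glm(X, y, offset, tol, max_iter)
        if quasipoisson:
            cov = cov * _pearson_scale(y, np.exp(X @ beta_hat + offset), X.shape[1])
        return _assemble_fit(beta_hat, cov, names, separated, 0.0, conv, n_iter,
                             ll, path, "glm", len(table), q)

    # Plain GLM as the sigma -> 0 limit and warm start.
    beta_glm, cov_glm, ll_glm, path_glm, conv_glm, it_glm = _irls_glm(
        X, y, offset, tol, max_iter
    )

    cache: dict[float, tuple] = {}

    def neg_marginal(log_sigma: float) -> float:
        sigma2 = float(np.exp(2.0 * log_sigma))
        beta_, b_, pll, mu, H, conv_, _ = _penalized_irls(
            X, y, offset, codes, q, sigma2, tol, max_iter, beta0=beta_glm
        )
        mll = _laplace_marginal_ll(pll, mu, codes, q, sigma2)
        cache[log_sigma] = (sigma2, beta_, b_, mu, H, mll, conv_)
        return -mll

    lo, hi = np.log(sigma_bounds[0]), np.log(sigma_bounds[1])
    try:
        res = optimize.minimize_scalar(
            neg_marginal, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-4},
        )
        if float(res.x) not in cache:
            neg_marginal(float(res.x))
        sigma2, beta_hat, b_hat, mu, H, mll, conv = cache[float(res.x)]
    except NotConvergedError as exc:
        logger.warning("GLMM optimizer failed (%s); falling back to fixed "
                       "ZCTA intercepts", exc)
        return _fit_fixed_zcta_fallback(work, active, separated, include_dow,
                                        include_year, tol, max_iter, q)

    if mll <= ll_glm + 1e-8 or np.isclose(np.exp(res.x), sigma_bounds[0], rtol=1e-2):
        # Variance profile maximized at (effectively) zero: plain GLM.
        if quasipoisson:
            cov_glm = cov_glm * _pearson_scale(
                y, np.exp(X @ beta_glm + offset), X.shape[1]
            )
        return _assemble_fit(beta_glm, cov_glm, names, separated, 0.0, conv_glm,
                             it_glm, ll_glm, path_glm, "glm", len(table), q)

    p = X.shape[1]
    Hinv = np.linalg.inv(H)
    cov = Hinv[:p, :p]
    if quasipoisson:
        cov = cov * _pearson_scale(y, mu, p + q)
    return _assemble_fit(beta_hat, cov, names, separated, sigma2, conv,
                         int(res.nfev), mll, [mll], "glmm_laplace",
                         len(table), q)


def _pearson_scale(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Quasi-Poisson dispersion: Pearson chi-square over residual df."""
    return float(((y - mu) ** 2 / mu).sum() / max(len(y) - n_params, 1))


def _fit_fixed_zcta_fallback(table, active, separated, include_dow,
                             include_year, tol, max_iter, q):
    """Conditional-style escape hatch: ZCTA enters as fixed indicators."""
    X, names, y, offset, codes, _ = _design_matrix(table, include_dow, include_year)
    keep = [i for i, nm in enumerate(names) if nm not in LAG_COLUMNS or nm in active]
    X = X[:, keep]
    names = [names[i] for i in keep]
    dummies = np.zeros((len(table), q - 1))
    for z in range(1, q):
        dummies[:, z - 1] = (codes == z).astype(float)
    X = np.hstack([X, dummies])
    names = names + [f"zcta_{z}" for z in range(1, q)]
    beta_hat, cov, ll, path, conv, n_iter = _irls_glm(X, y, offset, tol, max_iter)
    return _assemble_fit(beta_hat, cov, names, separated, float("nan"), conv,
                         n_iter, ll, path, "glm_fixed_zcta", len(table), q)


def _assemble_fit(coef, cov, names, separated, sigma2, converged, n_iter,
                  ll, path, method, n_rows, n_zctas) -> DlmFit:
    beta = np.full(len(LAGS), -np.inf)
    se = np.full(len(LAGS), np.inf)
    vcov = np.full((len(LAGS), len(LAGS)), np.nan)
    idx = {nm: i for i, nm in enumerate(names)}
    present = [i for i, c in enumerate(LAG_COLUMNS) if c in idx]
    cols = [idx[LAG_COLUMNS[i]] for i in present]
    beta[present] = coef[cols]
    sub = cov[np.ix_(cols, cols)]
    vcov[np.ix_(present, present)] = sub
    se[present] = np.sqrt(np.diag(sub))
    nuisance = {nm: float(coef[i]) for nm, i in idx.items()
                if nm not in LAG_COLUMNS}
    return DlmFit(
        beta=beta, vcov=vcov, se=se, nuisance=nuisance,
        random_intercept_var=float(sigma2), converged=bool(converged),
        n_iter=int(n_iter), loglik=float(ll), loglik_path=list(path),
        method=method, n_rows=int(n_rows), n_zctas=int(n_zctas),
        separated=separated.copy(),
    )


# ---------------------------------------------------------------------------
# relative risks

def _wald(label: str, log_rr: float, se: float, alpha_level: float,
          flagged: bool = False) -> RrEstimate:
    if flagged or not np.isfinite(log_rr) or not np.isfinite(se):
        return RrEstimate(label, float("nan"), float("nan"), float("nan"),
                          log_rr, se, flagged=True)
    z = stats.norm.ppf(1.0 - alpha_level / 2.0)
    return RrEstimate(
        label=label,
        rr=float(np.exp(log_rr)),
        ci_low=float(np.exp(log_rr - z * se)),
        ci_high=float(np.exp(log_rr + z * se)),
        log_rr=float(log_rr),
        se_log_rr=float(se),
    )


def lag_rr(fit: DlmFit, alpha_level: float = 0.05) -> list[RrEstimate]:
    """Per-lag relative risks exp(beta_l) with Wald 100(1-alpha)% intervals."""
    if not fit.converged:
        raise NotConvergedError("refusing to summarize an unconverged fit")
    return [
        _wald(f"lag {l}", fit.beta[i], fit.se[i], alpha_level,
              flagged=bool(fit.separated[i]))
        for i, l in enumerate(LAGS)
    ]


def cumulative_rr(fit: DlmFit, alpha_level: float = 0.05) -> RrEstimate:
    """Storm-period cumulative relative risk exp(sum_l beta_l).

    The standard error is the delta-method form sqrt(1' V 1) over the lag
    block of the covariance.  Any separated lag leaves the cumulative
    estimate flagged unavailable: a -inf coefficient makes the sum
    meaningless.
    """
    if not fit.converged:
        raise NotConvergedError("refusing to summarize an unconverged fit")
    if fit.separated.any():
        return RrEstimate("cumulative", float("nan"), float("nan"),
                          float("nan"), float("-inf"), float("inf"),
                          flagged=True)
    log_rr = float(fit.beta.sum())
    se = float(np.sqrt(np.ones(len(LAGS)) @ fit.vcov @ np.ones(len(LAGS))))
    return _wald("cumulative", log_rr, se, alpha_level)


def rr_table(fit: DlmFit, alpha_level: float = 0.05) -> pd.DataFrame:
    """Tidy per-lag + cumulative RR table (one row per estimate)."""
    ests = lag_rr(fit, alpha_level) + [cumulative_rr(fit, alpha_level)]
    return pd.DataFrame(
        {
            "label": [e.label for e in ests],
            "rr": [e.rr for e in ests],
            "ci_low": [e.ci_low for e in ests],
            "ci_high": [e.ci_high for e in ests],
            "log_rr": [e.log_rr for e in ests],
            "se_log_rr": [e.se_log_rr for e in ests],
            "flagged": [e.flagged for e in ests],
        }
    )
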