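"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive — day-by-day calendar scans and
textbook formulas — and shares no code with the implementation paths it
verifies.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np


def brute_force_candidates(
    exposed_day: date,
    zcta_storm_days: set[date],
    study_years: range,
    doy_window: int = 7,
    exclusion_days: int = 3,
) -> set[date]:
    """Scan every calendar day of the study period; apply the four predicates.

    Day-of-year uses the same leap convention as the implementation is
    documented to use (Feb 29 counts as Feb 28) but computes it from
    scratch per day.
    """

    def doy(d: date) -> int:
        # position of the (month, day) slot in a non-leap year
        ref_year = 2001
        day = min(d.day, 28) if (d.month == 2 and d.day == 29) else d.day
        return (date(ref_year, d.month, day) - date(ref_year, 1, 1)).days + 1

    years = list(study_years)
    start, end = date(years[0], 1, 1), date(years[-1], 12, 31)
    target = doy(exposed_day)
    out = set()
    d = start
    while d <= end:
        ok = d.year != exposed_day.year
        diff = abs(doy(d) - target)
        ok = ok and min(diff, 365 - diff) <= doy_window
        ok = ok and all(
            abs((d - s).days) > exclusion_days for s in zcta_storm_days
        )
        ok = ok and (d - timedelta(days=2) >= start) and (d + timedelta(days=7) <= end)
        if ok:
            out.add(d)
        d += timedelta(days=1)
    return out


def irls_poisson(X: np.ndarray, y: np.ndarray, offset: np.ndarray,
                 tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Textbook iteratively reweighted least squares for a Poisson GLM.

    Working response z = eta + (y - mu)/mu, weights w = mu, repeated
    weighted least squares until the coefficients stop moving.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / mu
        W = mu
        WX = X * W[:, None]
        new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's two-sample t statistic and two-sided p from first principles."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return float(t), float(p)


def pearson_matrix(values: np.ndarray) -> np.ndarray:
    """Pearson correlations column-by-column from the covariance definition."""
    n, p = values.shape
    centered = values - values.mean(axis=0)
    out = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            denom = np.sqrt((centered[:, i] ** 2).sum() * (centered[:, j] ** 2).sum())
            out[i, j] = (centered[:, i] * centered[:, j]).sum() / denom
    return out
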