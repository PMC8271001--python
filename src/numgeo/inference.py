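"""Correlational inference and a priori power analysis.

Zero-order and partial Pearson correlations with pairwise deletion, the
paired t-test, the full study-style correlation grid, and required sample
size for detecting a correlation.

Three power methods are provided for ``required_n_correlation``:

* ``"normal-approx"`` (default) — the classic closed-form approximation
  with noncentrality r*sqrt(n)/sqrt(1-r^2) against normal critical values,
  i.e. n = ((z_{1-alpha} + z_{power}) * sqrt(1-r^2)/r)^2.  This is the
  formula that reproduces the study-planning convention this package
  models (it returns 42 for r=0.34, power 0.75, one-tailed alpha 0.05).
* ``"nct"`` — power of the correlation t-test from the noncentral-t
  distribution of r*sqrt(n-2)/sqrt(1-r^2) (returns 45 for that query).
* ``"exact-r"`` — fully exact power by integrating Hotelling's density of
  the sample correlation under bivariate normality (also 45).

The gap between the approximate and exact answers for small effects is a
known property of the approximation and is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .errors import (
    ConfigurationError,
    DegenerateTestError,
    InsufficientDataError,
    PowerUnreachableError,
)


@dataclass
class CorrelationResult:
    x: str
    y: str
    r: float
    p: float
    n: int
    df: int
    covariates: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PowerQuery:
    """Specification of an a priori correlation power analysis."""

    effect_size_r: float
    power: float
    alpha: float = 0.05
    tails: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.effect_size_r < 1):
            raise ConfigurationError("effect_size_r must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not (self.alpha < self.power < 1):
            raise ConfigurationError("power must lie in (alpha, 1)")
        if self.tails not in (1, 2):
            raise ConfigurationError("tails must be 1 or 2")


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _complete(*series) -> list[np.ndarray]:
    arrays = [np.asarray(pd.Series(s), dtype=float) for s in series]
    lengths = {a.size for a in arrays}
    if len(lengths) != 1:
        raise ConfigurationError(f"series lengths differ: {sorted(lengths)}")
    mask = ~np.any([np.isnan(a) for a in arrays], axis=0)
    return [a[mask] for a in arrays]


def pearson(x, y, *, names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Zero-order Pearson correlation on pairwise-complete cases.

    p two-tailed from t = r*sqrt(n-2)/sqrt(1-r^2).
    """
    xa, ya = _complete(x, y)
    n = xa.size
    if n < 3:
        raise InsufficientDataError(f"only {n} complete pairs; need >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise DegenerateTestError("zero variance in one of the series")
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(
        x=names[0], y=names[1], r=float(r), p=float(p), n=n, df=n - 2
    )


def partial_correlation(
    x,
    y,
    covariates,
    *,
    names: tuple[str, str] = ("x", "y"),
    covariate_names: Sequence[str] = (),
) -> CorrelationResult:
    """Partial Pearson correlation controlling for one or more covariates.

    Defined (and computed) as the correlation of the OLS residuals of x
    and y after regression on the covariates plus intercept, on cases
    complete for x, y and every covariate; p from t with df = n - 2 - k.
    """
    cov_list = covariates if isinstance(covariates, (list, tuple)) else [covariates]
    if not cov_list:
        raise ConfigurationError("need at least one covariate (else use pearson)")
    arrays = _complete(x, y, *cov_list)
    xa, ya, covs = arrays[0], arrays[1], arrays[2:]
    k = len(covs)
    n = xa.size
    if n < k + 4:
        raise InsufficientDataError(f"only {n} complete cases for {k} covariate(s)")
    design = np.column_stack([np.ones(n)] + [c for c in covs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ConfigurationError("covariates are collinear (rank-deficient design)")
    beta_x, *_ = np.linalg.lstsq(design, xa, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ya, rcond=None)
    rx = xa - design @ beta_x
    ry = ya - design @ beta_y
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise DegenerateTestError("a series is fully explained by the covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if df < 1:
        raise InsufficientDataError("non-positive degrees of freedom")
    t = r * np.sqrt(df) / np.sqrt(max(1.0 - r * r, 1e-300))
    p = float(2 * stats.t.sf(abs(t), df))
    cn = tuple(covariate_names) if covariate_names else tuple(
        f"z{i + 1}" for i in range(k)
    )
    return CorrelationResult(
        x=names[0], y=names[1], r=r, p=p, n=n, df=df, covariates=cn
    )


def partial_correlation_recursive(rxy: float, rxz: float, ryz: float) -> float:
    """First-order recursion formula for a single covariate (oracle route)."""
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise DegenerateTestError("degenerate marginal correlations")
    return float((rxy - rxz * ryz) / denom)


def paired_t(x, y) -> tuple[float, int, float]:
    """Classical paired t-test on complete pairs; returns (t, df, p)."""
    xa, ya = _complete(x, y)
    n = xa.size
    if n < 2:
        raise InsufficientDataError(f"only {n} complete pairs; need >= 2")
    d = xa - ya
    if np.std(d) == 0:
        raise DegenerateTestError("zero variance of paired differences")
    t, p = stats.ttest_rel(xa, ya)
    return float(t), n - 1, float(p)


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------

def _r_density(r, rho, n):
    """Hotelling's exact density of the sample correlation coefficient."""
    lg = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2 * np.log1p(-(rho**2))
        + (n - 4) / 2 * np.log1p(-(r**2))
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return np.exp(lg) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)


def power_correlation(
    n: int, r: float, alpha: float = 0.05, tails: int = 1, method: str = "normal-approx"
) -> float:
    """Power of the level-alpha test of rho = 0 against rho = r at size n."""
    if n < 4:
        return 0.0
    if method == "normal-approx":
        delta = r * np.sqrt(n) / np.sqrt(1 - r * r)
        zcrit = stats.norm.ppf(1 - alpha / tails)
        power = stats.norm.sf(zcrit - delta)
        if tails == 2:
            power += stats.norm.cdf(-zcrit - delta)
        return float(power)
    df = n - 2
    tcrit = stats.t.ppf(1 - alpha / tails, df)
    if method == "nct":
        delta = r * np.sqrt(df) / np.sqrt(1 - r * r)
        power = stats.nct.sf(tcrit, df, delta)
        if tails == 2:
            power += stats.nct.cdf(-tcrit, df, delta)
        return float(power)
    if method == "exact-r":
        rcrit = tcrit / np.sqrt(df + tcrit**2)
        hi, _ = integrate.quad(_r_density, rcrit, 1, args=(r, n))
        power = hi
        if tails == 2:
            lo, _ = integrate.quad(_r_density, -1, -rcrit, args=(r, n))
            power += lo
        return float(power)
    raise ConfigurationError(f"unknown power method {method!r}")


def required_n_correlation(
    query: PowerQuery,
    method: str = "normal-approx",
    n_ceiling: int = 1_000_000,
) -> int:
    """Smallest n whose power reaches the target (monotone search, floor 4)."""
    lo, hi = 4, 4
    if power_correlation(lo, query.effect_size_r, query.alpha, query.tails, method) >= query.power:
        return lo
    while power_correlation(hi, query.effect_size_r, query.alpha, query.tails, method) < query.power:
        lo = hi
        hi *= 2
        if hi > n_ceiling:
            raise PowerUnreachableError(
                f"power {query.power} unreachable below n = {n_ceiling}"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_correlation(mid, query.effect_size_r, query.alpha, query.tails, method) >= query.power:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# Correlation report grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationRequest:
    x: str
    y: str
    covariates: tuple[str, ...] = ()


def default_report_grid() -> list[CorrelationRequest]:
    """The study-style analysis grid: each measure against the formal
    geometry index, zero-order and under the standard covariate sets."""
    grid: list[CorrelationRequest] = []
    measures = ("acc_overall", "acc_run1", "acc_run2", "sensitivity")
    for m in measures:
        grid.append(CorrelationRequest(m, "combined_index"))
        grid.append(CorrelationRequest(m, "combined_index", ("age",)))
    grid.append(CorrelationRequest("sensitivity", "combined_index", ("age", "acc_overall")))
    grid.append(CorrelationRequest("acc_overall", "combined_index", ("age", "sensitivity")))
    grid.append(CorrelationRequest("acc_run2", "combined_index", ("age", "sensitivity")))
    grid.append(CorrelationRequest("sensitivity", "combined_index", ("age", "acc_run2")))
    grid.append(CorrelationRequest("sensitivity", "acc_overall", ("age",)))
    grid.append(CorrelationRequest("acc_overall", "combined_index", ("verbal_score",)))
    grid.append(CorrelationRequest("sensitivity", "combined_index", ("verbal_score",)))
    grid.append(CorrelationRequest("acc_overall", "verbal_score"))
    grid.append(CorrelationRequest("sensitivity", "verbal_score"))
    return grid


def correlation_report(
    scores: pd.DataFrame,
    requests: Sequence[CorrelationRequest] | None = None,
) -> pd.DataFrame:
    """Evaluate every requested zero-order/partial correlation on a
    child-scores table (pairwise deletion per request)."""
    reqs = list(requests) if requests is not None else default_report_grid()
    rows = []
    for req in reqs:
        for name in (req.x, req.y, *req.covariates):
            if name not in scores.columns:
                raise ConfigurationError(f"unknown variable {name!r} in report request")
        flags = []
        if req.x == req.y:
            xa = scores[req.x].dropna()
            res = CorrelationResult(
                x=req.x, y=req.y, r=1.0, p=0.0, n=len(xa), df=len(xa) - 2,
                covariates=req.covariates,
            )
            flags.append("self_correlation")
        elif req.covariates:
            res = partial_correlation(
                scores[req.x],
                scores[req.y],
                [scores[c] for c in req.covariates],
                names=(req.x, req.y),
                covariate_names=req.covariates,
            )
        else:
            res = pearson(scores[req.x], scores[req.y], names=(req.x, req.y))
        rows.append(
            {
                "x": res.x,
                "y": res.y,
                "covariates": "+".join(req.covariates),
                "r": res.r,
                "p": res.p,
                "n": res.n,
                "df": res.df,
                "flags": ";".join(flags),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(out)  # for user-side multiplicity corrections
    return out
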