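"""Psychometric estimation of numerosity discrimination thresholds.

Each child judges which of two dot patches is more numerous (2AFC): a test
patch of fixed numerosity (9) against a probe varying from 3 to 16 by the
method of constant stimuli.  The probability of reporting the probe as more
numerous rises with probe numerosity and, per Weber's law for numerosity,
is modelled as a cumulative Gaussian on a *log* numerosity axis:

    P(report probe greater | probe x) = Phi((ln x - mu) / sigma)

The fit is by trial-level Bernoulli maximum likelihood over (mu, sigma).
Derived quantities:

* PSE = e^mu, the point of subjective equality (50% point);
* JND = x_75 - x_50 = e^mu (e^{z75 sigma} - 1), with z75 = Phi^{-1}(0.75),
  the numerosity difference between the 50% and 75% points;
* Weber fraction WF = JND / test numerosity;
* normalized sensitivity = 1 / WF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .errors import (
    ConfigurationError,
    DegenerateFitError,
    EmptyDataError,
    InsufficientDataError,
)

Z75 = float(stats.norm.ppf(0.75))  # ~0.6744898

_PCLIP = 1e-9


@dataclass(frozen=True)
class TrialRecord2AFC:
    """One numerosity discrimination trial."""

    child_id: str
    session: int
    probe: int
    test: int
    response_probe_greater: bool

    def __post_init__(self) -> None:
        if not (3 <= self.probe <= 16):
            raise ConfigurationError(
                f"probe numerosity {self.probe} outside the protocol range [3, 16]"
            )


@dataclass
class PsychometricFit:
    """Cumulative-Gaussian fit on the log-numerosity axis plus thresholds."""

    mu: float
    sigma: float
    n_trials: int
    loglik: float
    pse: float
    jnd: float | None = None
    wf: float | None = None
    sensitivity: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer and model settings for :func:`fit_psychometric`.

    sigma is clamped to [sigma_floor, sigma_ceiling]; hitting either bound
    is flagged rather than silently returned.  ``method="mle"`` is the
    default trial-level Bernoulli likelihood; ``method="lsq"`` fits the
    aggregated proportions by least squares (sensitivity-analysis mode).
    ``lapse`` mixes in a stimulus-independent guessing rate symmetrically:
    p -> lapse/2 + (1 - lapse) p.
    """

    sigma_floor: float = 0.01
    sigma_ceiling: float = 5.0
    min_trials: int = 10
    method: str = "mle"
    lapse: float = 0.0
    sensitivity_cap: float = 1e4

    def __post_init__(self) -> None:
        if not (0 < self.sigma_floor < self.sigma_ceiling):
            raise ConfigurationError("need 0 < sigma_floor < sigma_ceiling")
        if not (0 <= self.lapse < 1):
            raise ConfigurationError("lapse must lie in [0, 1)")
        if self.method not in ("mle", "lsq"):
            raise ConfigurationError(f"unknown fit method {self.method!r}")


def _as_arrays(trials: Iterable) -> tuple[np.ndarray, np.ndarray, str]:
    """Extract (probes, responses, child_id) from records, a DataFrame, or
    a (probes, responses) array pair."""
    if isinstance(trials, pd.DataFrame):
        if trials.empty:
            raise EmptyDataError("no trials supplied")
        if "n_probe_greater" in trials.columns:
            raise ConfigurationError(
                "aggregated count tables are accepted by fit_psychometric, "
                "not by trial-level helpers"
            )
        probes = trials["probe"].to_numpy(dtype=float)
        resp = trials["response_probe_greater"].to_numpy(dtype=bool)
        cid = str(trials["child_id"].iloc[0]) if "child_id" in trials else "?"
        return probes, resp, cid
    if isinstance(trials, tuple) and len(trials) == 2:
        probes = np.asarray(trials[0], dtype=float)
        resp = np.asarray(trials[1], dtype=bool)
        if probes.size == 0:
            raise EmptyDataError("no trials supplied")
        return probes, resp, "?"
    recs = list(trials)
    if not recs:
        raise EmptyDataError("no trials supplied")
    probes = np.array([t.probe for t in recs], dtype=float)
    resp = np.array([t.response_probe_greater for t in recs], dtype=bool)
    return probes, resp, str(recs[0].child_id)


def _extract_counts(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    """(unique probes, successes, totals, child_id) from trial-level input
    or an already-aggregated (probe, n_trials, n_probe_greater) table."""
    if isinstance(trials, pd.DataFrame) and "n_probe_greater" in trials.columns:
        if trials.empty:
            raise EmptyDataError("no trials supplied")
        probes = trials["probe"].to_numpy(dtype=float)
        k = trials["n_probe_greater"].to_numpy(dtype=float)
        n = trials["n_trials"].to_numpy(dtype=float)
        cid = str(trials["child_id"].iloc[0]) if "child_id" in trials else "?"
        if np.any(k > n) or np.any(n <= 0):
            raise ConfigurationError("invalid aggregated counts (need 0 <= k <= n)")
        return probes, k, n, cid
    probes, resp, cid = _as_arrays(trials)
    agg = aggregate_proportions((probes, resp))
    return (
        agg["probe"].to_numpy(dtype=float),
        agg["n_probe_greater"].to_numpy(dtype=float),
        agg["n_trials"].to_numpy(dtype=float),
        cid,
    )


def aggregate_proportions(trials) -> pd.DataFrame:
    """Collapse trials of one child into (probe, n_trials, n_probe_greater).

    Counts conserve the input: the n_trials column sums to the number of
    trials supplied.
    """
    probes, resp, _ = _as_arrays(trials)
    values, inverse = np.unique(probes, return_inverse=True)
    n = np.bincount(inverse, minlength=values.size)
    k = np.bincount(inverse, weights=resp.astype(float), minlength=values.size)
    return pd.DataFrame(
        {"probe": values, "n_trials": n.astype(int), "n_probe_greater": k.astype(int)}
    )


_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _predicted_p(lnx: np.ndarray, mu: float, sigma: float, lapse: float) -> np.ndarray:
    p = ndtr((lnx - mu) / sigma)
    if lapse:
        p = lapse / 2 + (1 - lapse) * p
    return np.clip(p, _PCLIP, 1 - _PCLIP)


def neg_loglik(
    params: Sequence[float],
    lnx: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    lapse: float = 0.0,
) -> float:
    """Negative binomial log-likelihood of the cumulative-Gaussian model."""
    mu, sigma = params
    p = _predicted_p(lnx, mu, float(sigma), lapse)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def _neg_loglik_grad(params, lnx, k, n, lapse=0.0):
    mu, sigma = params
    z = (lnx - mu) / sigma
    base = ndtr(z)
    p = lapse / 2 + (1 - lapse) * base if lapse else base
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    phi = _INV_SQRT_2PI * np.exp(-0.5 * z * z) * (1 - lapse)
    w = k / p - (n - k) / (1 - p)
    dmu = -(w * phi * (-1.0 / sigma)).sum()
    dsig = -(w * phi * (-z / sigma)).sum()
    return np.array([dmu, dsig])


def fit_psychometric(trials, options: FitOptions | None = None) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit for one child's trials.

    Raises :class:`DegenerateFitError` when every response is identical
    (the location parameter is then unidentified) and
    :class:`InsufficientDataError` below ``options.min_trials`` trials or
    with fewer than two distinct probe values.
    """
    opts = options or FitOptions()
    probes_u, k, n, child = _extract_counts(trials)
    if n.sum() < opts.min_trials:
        raise InsufficientDataError(
            f"child {child!r}: {int(n.sum())} trials < minimum {opts.min_trials}"
        )
    if probes_u.size < 2:
        raise InsufficientDataError(
            f"child {child!r}: trials span only {probes_u.size} distinct probe value(s)"
        )
    if k.sum() == 0 or k.sum() == n.sum():
        raise DegenerateFitError(
            f"child {child!r}: all {int(n.sum())} responses identical; "
            "psychometric location is unidentified"
        )
    lnx = np.log(probes_u)

    mu0 = _initial_mu(lnx, k / n)
    flags: list[str] = []
    if opts.method == "lsq":
        mu, sigma, obj = _fit_lsq(lnx, k, n, mu0, opts)
        loglik = -neg_loglik((mu, sigma), lnx, k, n, opts.lapse)
    else:
        mu, sigma, obj = _fit_mle(lnx, k, n, mu0, opts)
        loglik = -obj
    if sigma <= opts.sigma_floor * (1 + 1e-9):
        sigma = opts.sigma_floor
        flags.append("sigma_at_floor")
    if sigma >= opts.sigma_ceiling * (1 - 1e-9):
        sigma = opts.sigma_ceiling
        flags.append("sigma_at_ceiling")
    return PsychometricFit(
        mu=float(mu),
        sigma=float(sigma),
        n_trials=int(n.sum()),
        loglik=float(loglik),
        pse=float(np.exp(mu)),
        flags=flags,
    )


def _initial_mu(lnx: np.ndarray, p: np.ndarray) -> float:
    # first crossing of 0.5, interpolated; fallback to the probe-range centre
    above = np.nonzero(p >= 0.5)[0]
    below = np.nonzero(p < 0.5)[0]
    if above.size and below.size and below[0] < above[-1]:
        i = above[above > below[0]]
        if i.size:
            j = i[0]
            x0, x1 = lnx[j - 1], lnx[j]
            p0, p1 = p[j - 1], p[j]
            if p1 > p0:
                return float(x0 + (0.5 - p0) / (p1 - p0) * (x1 - x0))
    return float(lnx.mean())


def _mu_bounds(lnx: np.ndarray) -> tuple[float, float]:
    return float(lnx.min() - 2.0), float(lnx.max() + 2.0)


def _nll_and_grad(params, lnx, k, n, lapse=0.0):
    mu, sigma = params
    z = (lnx - mu) / sigma
    base = ndtr(z)
    p = lapse / 2 + (1 - lapse) * base if lapse else base
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    nll = -(k * np.log(p) + (n - k) * np.log1p(-p)).sum()
    phi = _INV_SQRT_2PI * np.exp(-0.5 * z * z) * (1 - lapse)
    w = k / p - (n - k) / (1 - p)
    dmu = (w * phi).sum() / sigma
    dsig = (w * phi * z).sum() / sigma
    return float(nll), np.array([dmu, dsig])


def _fit_mle(lnx, k, n, mu0, opts):
    bounds = [_mu_bounds(lnx), (opts.sigma_floor, opts.sigma_ceiling)]
    best = None
    for sigma0 in (0.3, 0.1, 0.8):
        res = optimize.minimize(
            _nll_and_grad,
            x0=np.array([mu0, sigma0]),
            jac=True,
            args=(lnx, k, n, opts.lapse),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1]), float(best.fun)


def _fit_lsq(lnx, k, n, mu0, opts):
    p_obs = k / n

    def sse(params):
        return float(((_predicted_p(lnx, params[0], params[1], opts.lapse) - p_obs) ** 2 * n).sum())

    bounds = [_mu_bounds(lnx), (opts.sigma_floor, opts.sigma_ceiling)]
    best = None
    for sigma0 in (0.1, 0.3, 0.8):
        res = optimize.minimize(sse, x0=np.array([mu0, sigma0]), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1]), float(best.fun)


def grid_search_fit(
    trials,
    options: FitOptions | None = None,
    *,
    n_mu: int = 400,
    n_sigma: int = 400,
) -> PsychometricFit:
    """Exhaustive likelihood evaluation on an (mu, sigma) lattice.

    Brute-force companion to :func:`fit_psychometric`, used to validate the
    optimizer: the MLE must land within one lattice step of the grid
    optimum.  sigma is scanned logarithmically between floor and ceiling.
    """
    opts = options or FitOptions()
    probes_u, k, n, _ = _extract_counts(trials)
    lnx = np.log(probes_u)
    lo, hi = _mu_bounds(lnx)
    mus = np.linspace(lo, hi, n_mu)
    sigmas = np.geomspace(opts.sigma_floor, opts.sigma_ceiling, n_sigma)
    z = (lnx[None, None, :] - mus[None, :, None]) / sigmas[:, None, None]
    p = np.clip(stats.norm.cdf(z), _PCLIP, 1 - _PCLIP)
    if opts.lapse:
        p = np.clip(opts.lapse / 2 + (1 - opts.lapse) * p, _PCLIP, 1 - _PCLIP)
    ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=2)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return PsychometricFit(
        mu=float(mus[j]),
        sigma=float(sigmas[i]),
        n_trials=int(n.sum()),
        loglik=float(ll[i, j]),
        pse=float(np.exp(mus[j])),
    )


def derive_thresholds(
    fit: PsychometricFit,
    test_numerosity: int = 9,
    options: FitOptions | None = None,
) -> PsychometricFit:
    """Populate JND, Weber fraction and normalized sensitivity on a fit.

    JND is the (upward) numerosity difference between the 75% and 50%
    points of the fitted curve: e^mu (e^{z75 sigma} - 1).  A sigma pinned
    at the ceiling is flagged ``unreliable_threshold``; a diverging
    sensitivity is capped (flag ``sensitivity_capped``).
    """
    opts = options or FitOptions()
    jnd = float(np.exp(fit.mu) * np.expm1(Z75 * fit.sigma))
    wf = jnd / test_numerosity
    flags = list(fit.flags)
    if "sigma_at_ceiling" in flags and "unreliable_threshold" not in flags:
        flags.append("unreliable_threshold")
    if wf > 0 and 1.0 / wf <= opts.sensitivity_cap:
        sensitivity = 1.0 / wf
    else:
        sensitivity = opts.sensitivity_cap
        flags.append("sensitivity_capped")
    return replace(fit, jnd=jnd, wf=wf, sensitivity=sensitivity, flags=flags)


def estimate_sensitivity(trials, options: FitOptions | None = None, test_numerosity: int = 9) -> float:
    """Fit one child's trials and return normalized sensitivity (1/WF)."""
    fit = fit_psychometric(trials, options)
    return float(derive_thresholds(fit, test_numerosity, options).sensitivity)


def fit_all(
    trials: pd.DataFrame,
    options: FitOptions | None = None,
    test_numerosity: int = 9,
) -> pd.DataFrame:
    """Fit every child in a numerosity_trials table; returns the fits table."""
    rows = []
    for cid, grp in trials.groupby("child_id", sort=True):
        fit = derive_thresholds(
            fit_psychometric(grp, options), test_numerosity, options
        )
        rows.append(
            {
                "child_id": str(cid),
                "mu": fit.mu,
                "sigma": fit.sigma,
                "pse": fit.pse,
                "jnd": fit.jnd,
                "wf": fit.wf,
                "sensitivity": fit.sensitivity,
                "n_trials": fit.n_trials,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(rows)
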