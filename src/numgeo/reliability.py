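"""Measurement reliability: split-half bootstrap and Cronbach's alpha.

The split-half "sample-with-replacement" bootstrap quantifies the
reliability of quantities extracted from psychometric functions: per
iteration, each participant's trials are resampled twice (independently,
with replacement, each resample as large as the participant's data set),
the estimator is applied to both resamples, and the two resulting
estimates are correlated across participants.  The mean and standard
deviation of the correlation over iterations give the reliability and its
standard error.

Cronbach's alpha measures the internal consistency of item-level scores;
its 95% confidence interval uses the Feldt F-distribution argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateTestError,
    InsufficientDataError,
    NumgeoError,
)

logger = logging.getLogger(__name__)


@dataclass
class ReliabilityResult:
    mean_r: float
    se_r: float
    n_iterations: int
    seed: int
    n_children: int
    n_estimator_failures: int = 0


@dataclass
class AlphaResult:
    alpha: float
    ci_low: float
    ci_high: float
    n_items: int
    n_subjects: int
    confidence: float = 0.95


def _take(data, idx: np.ndarray):
    """Positional resampling for DataFrames, arrays, array tuples or lists."""
    if isinstance(data, pd.DataFrame):
        return data.iloc[idx]
    if isinstance(data, tuple):
        return tuple(np.asarray(a)[idx] for a in data)
    if isinstance(data, np.ndarray):
        return data[idx]
    return [data[i] for i in idx]


def _size(data) -> int:
    if isinstance(data, tuple):
        return len(data[0])
    return len(data)


def bootstrap_split_half(
    trials_by_child: Mapping,
    estimator: Callable,
    n_iter: int = 10_000,
    seed: int = 0,
    *,
    mode: str = "full",
    method: str = "pearson",
    on_error: str = "skip",
) -> ReliabilityResult:
    """Split-half sample-with-replacement bootstrap reliability.

    ``mode="full"`` (default): two independent with-replacement resamples,
    each as large as the child's full data set.  ``mode="half"``: the
    trials are randomly split into disjoint halves, each half resampled
    with replacement to its own size.  ``method`` selects Pearson (default)
    or Spearman correlation across children.  Estimator failures on a
    resample drop that child for that iteration (``on_error="skip"``, with
    a logged count) or abort (``on_error="abort"``).

    Child order never matters: children are processed in sorted-id order.
    """
    if mode not in ("full", "half"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown method {method!r}")
    if on_error not in ("skip", "abort"):
        raise ConfigurationError(f"unknown on_error policy {on_error!r}")
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    ids = sorted(trials_by_child, key=str)
    if len(ids) < 3:
        raise InsufficientDataError("need at least 3 children for reliability")
    data = {cid: trials_by_child[cid] for cid in ids}
    sizes = {cid: _size(data[cid]) for cid in ids}
    for cid, n in sizes.items():
        if n < 2:
            raise InsufficientDataError(f"child {cid!r} has fewer than 2 trials")

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def corr(a, b) -> float:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if np.array_equal(a, b):
            # identical estimate vectors correlate exactly (noiseless estimator)
            return 1.0
        if method == "pearson":
            return float(stats.pearsonr(a, b)[0])
        return float(stats.spearmanr(a, b)[0])

    rs = np.empty(n_iter)
    n_failures = 0
    for it in range(n_iter):
        est1, est2 = [], []
        for cid in ids:
            n = sizes[cid]
            if mode == "full":
                idx1 = rng.integers(0, n, n)
                idx2 = rng.integers(0, n, n)
            else:
                perm = rng.permutation(n)
                h1, h2 = perm[: n // 2], perm[n // 2:]
                idx1 = h1[rng.integers(0, h1.size, h1.size)]
                idx2 = h2[rng.integers(0, h2.size, h2.size)]
            try:
                v1 = float(estimator(_take(data[cid], idx1)))
                v2 = float(estimator(_take(data[cid], idx2)))
            except NumgeoError as exc:
                if on_error == "abort":
                    raise
                n_failures += 1
                logger.debug("iteration %d: child %r skipped (%s)", it, cid, exc)
                continue
            est1.append(v1)
            est2.append(v2)
        if len(est1) < 3:
            raise InsufficientDataError(
                f"iteration {it}: fewer than 3 children with valid estimates"
            )
        rs[it] = corr(est1, est2)
    return ReliabilityResult(
        mean_r=float(np.mean(rs)),
        se_r=float(np.std(rs, ddof=1)) if n_iter > 1 else 0.0,
        n_iterations=n_iter,
        seed=seed,
        n_children=len(ids),
        n_estimator_failures=n_failures,
    )


def cronbach_alpha(
    items,
    confidence: float = 0.95,
) -> AlphaResult:
    """Cronbach's alpha with a Feldt confidence interval.

    ``items`` is a subjects x items matrix (DataFrame or array) of binary
    or graded scores; rows with missing cells are removed listwise with a
    logged count.  alpha = k/(k-1) * (1 - sum of item variances / variance
    of row totals), with unbiased (ddof=1) variances.
    """
    x = items.to_numpy(dtype=float) if isinstance(items, pd.DataFrame) else np.asarray(items, dtype=float)
    if x.ndim != 2:
        raise ConfigurationError("items must be a 2-D subjects x items matrix")
    complete = ~np.isnan(x).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("cronbach_alpha: %d subject(s) removed listwise", n_dropped)
    x = x[complete]
    n, k = x.shape
    if k < 2:
        raise InsufficientDataError("need at least 2 items")
    if n < 3:
        raise InsufficientDataError("need at least 3 complete subjects")
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise DegenerateTestError("zero variance of total scores; alpha undefined")
    item_var = np.var(x, axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    # Feldt interval: (1 - alpha_hat)/(1 - alpha) ~ F(n-1, (n-1)(k-1))
    gamma = 1.0 - confidence
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_hi = stats.f.ppf(1 - gamma / 2, df1, df2)
    f_lo = stats.f.ppf(gamma / 2, df1, df2)
    ci_low = 1.0 - (1.0 - alpha) * f_hi
    ci_high = 1.0 - (1.0 - alpha) * f_lo
    return AlphaResult(
        alpha=float(alpha),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_items=int(k),
        n_subjects=int(n),
        confidence=confidence,
    )


def battery_item_matrix(battery: pd.DataFrame, factor: str | None = None) -> pd.DataFrame:
    """Pivot a battery_items table into a subjects x items 0/1 matrix."""
    frame = battery if factor is None else battery[battery["factor"] == factor]
    return (
        frame.pivot_table(
            index="child_id", columns="item_id", values="correct", aggfunc="first"
        ).astype(float)
    )
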