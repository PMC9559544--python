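"""Power machinery for the one-sided binomial design and small inferential
utilities.

The study design tests whether a classifier's accuracy over ``n``
participants beats chance ``p0`` with an exact one-sided binomial test.
Power for that test is computed exactly from the binomial tail — the
smallest significant success count ``k*`` satisfies
``P(X >= k* | n, p0) <= alpha`` — or by Monte-Carlo simulation of success
counts at the true accuracy; the two agree within simulation error.

Also here: Welch's two-sample t-test, the Pearson correlation with its
Fisher-transform confidence interval, and the Fisher z comparison of two
independent correlations,
``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError


@dataclass(frozen=True)
class CriticalCount:
    """Smallest success count significant under the one-sided binomial test;
    ``attainable`` is False when no k <= n reaches significance."""

    n: int
    alpha: float
    p0: float
    k: int | None
    attainable: bool

    @property
    def accuracy_percent(self) -> float:
        return float("nan") if self.k is None else 100.0 * self.k / self.n


@dataclass
class PowerGrid:
    n_values: list[int]
    accuracy_values: list[float]
    alpha: float
    p0: float
    method: str
    reps: int | None
    seed: int | None
    table: pd.DataFrame  # columns: n, true_accuracy, power


@dataclass(frozen=True)
class CorrComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    z_stat: float
    p: float


# ---------------------------------------------------------------------------
# binomial design
# ---------------------------------------------------------------------------

def min_significant_count(n: int, alpha: float = 0.05, p0: float = 0.5,
                          ) -> CriticalCount:
    """Smallest k with exact upper-tail P(X >= k | n, p0) <= alpha."""
    if n < 1:
        raise ConfigError("n must be at least 1")
    if not 0.0 < p0 < 1.0:
        raise ConfigError("p0 must lie strictly inside (0, 1)")
    k_grid = np.arange(n + 2)
    tail = stats.binom.sf(k_grid - 1, n, p0)  # P(X >= k)
    hits = np.nonzero(tail[: n + 1] <= alpha)[0]
    if hits.size == 0:
        return CriticalCount(n, alpha, p0, None, False)
    return CriticalCount(n, alpha, p0, int(hits[0]), True)


def binomial_power(n: int, true_accuracy: float, alpha: float = 0.05,
                   p0: float = 0.5, method: str = "exact",
                   reps: int = 10_000,
                   seed: int | None = None) -> float:
    """Power of the one-sided exact binomial test.

    ``exact``: P(X >= k* | n, true_accuracy) with k* the smallest
    significant count.  ``simulation``: fraction of ``reps`` simulated
    Binomial(n, true_accuracy) draws reaching k*.
    """
    if not 0.0 <= true_accuracy <= 1.0:
        raise ConfigError("true_accuracy must lie in [0, 1]")
    crit = min_significant_count(n, alpha, p0)
    if not crit.attainable:
        return 0.0
    if method == "exact":
        return float(stats.binom.sf(crit.k - 1, n, true_accuracy))
    if method == "simulation":
        if reps < 100:
            warnings.warn("fewer than 100 simulation replicates; the power "
                          "estimate will be noisy")
        rng = np.random.default_rng(seed)
        draws = rng.binomial(n, true_accuracy, size=reps)
        return float(np.mean(draws >= crit.k))
    raise ConfigError(f"unknown method {method!r}; use 'exact' or "
                      "'simulation'")


def power_curve(n_values, accuracy_values, alpha: float = 0.05,
                p0: float = 0.5, method: str = "exact", reps: int = 10_000,
                seed: int | None = None) -> PowerGrid:
    """Power per (sample size, true accuracy) grid cell."""
    n_values = [int(v) for v in n_values]
    accuracy_values = [float(v) for v in accuracy_values]
    if not n_values or not accuracy_values:
        raise ConfigError("power_curve grids must be non-empty")
    rows = []
    for n in n_values:
        for acc in accuracy_values:
            rows.append((n, acc, binomial_power(n, acc, alpha, p0, method,
                                                reps, seed)))
    table = pd.DataFrame(rows, columns=["n", "true_accuracy", "power"])
    return PowerGrid(n_values, accuracy_values, alpha, p0, method,
                     reps if method == "simulation" else None, seed, table)


# ---------------------------------------------------------------------------
# inferential utilities
# ---------------------------------------------------------------------------

def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test (two-tailed): returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("each sample needs at least two values")
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        raise DegenerateDataError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_r_ci(x, y, level: float = 0.95,
                 ) -> tuple[float, tuple[float, float], float, float]:
    """Pearson r with its Fisher-transform CI: returns (r, (lo, hi), t, p).

    The CI uses the variance-stabilising atanh transform with standard
    error 1/sqrt(n-3); t = r sqrt(n-2) / sqrt(1-r^2) with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise DegenerateDataError("correlation CI needs n >= 4")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DegenerateDataError("zero-variance input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(np.arctanh(r) + np.array([-zcrit, zcrit]) * se)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r ** 2, 1e-300))
    return r, (float(lo), float(hi)), float(t), float(res.pvalue)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int,
                     ) -> CorrComparison:
    """Two-sided comparison of two independent correlations via Fisher's z."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise DegenerateDataError("|r| must be < 1 for the Fisher "
                                      "transform")
        if n < 4:
            raise DegenerateDataError("each correlation needs n >= 4")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrComparison(r1, r2, n1, n2, float(z), float(p))
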