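"""Cluster-based permutation tests on binned time series.

Controls the family-wise error of pointwise tests over an autocorrelated
time series (here 25-ms pupil bins) by (1) computing a pointwise t statistic
per bin — Welch's two-sample t for a group contrast, or a one-sample t
against zero — (2) grouping consecutive suprathreshold bins of equal sign
into clusters scored by their mass (sum of t values), and (3) comparing each
observed mass with the permutation distribution of the maximal absolute
cluster mass under random group relabeling (two-sample) or per-participant
sign flips (one-sample).

The cluster-forming threshold defaults to the two-sided pointwise
``alpha=0.05`` critical t at each bin's degrees of freedom, recomputed for
every permutation (Welch df depends on the relabeling).  Monte-Carlo
p-values use the ``(b + 1) / (B + 1)`` estimator; when the full relabeling
space is no larger than ``n_perm`` it is enumerated exhaustively and the
p-value is the exact proportion (the identity relabeling included).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateDataError

POINTWISE_ALPHA = 0.05
BIN_MS = 25


@dataclass(frozen=True)
class Cluster:
    start_bin: int          # half-open [start_bin, end_bin)
    end_bin: int
    start_ms: float
    end_ms: float
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    exhaustive: bool
    pointwise_alpha: float
    seed: int | None
    null_max_mass: np.ndarray = field(repr=False, default=None)

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "exhaustive": self.exhaustive,
            "pointwise_alpha": self.pointwise_alpha,
            "seed": self.seed,
            "clusters": [vars(c) for c in self.clusters],
        }


# ---------------------------------------------------------------------------
# pointwise statistics
# ---------------------------------------------------------------------------

def welch_t_series(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Per-bin Welch t and Welch–Satterthwaite df for two participant
    matrices of shape (n_subjects, n_bins).

    A bin where every participant of both groups holds the same constant
    (as bin 0 of realigned pupil traces, pinned at 0 by the first-sample
    subtraction) carries no group information and gets t = 0; a bin with
    zero variance in both groups but different means is genuinely undefined
    and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise DegenerateDataError("need at least two participants per group")
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    denom = va + vb
    delta = a.mean(axis=0) - b.mean(axis=0)
    bad = (denom == 0.0) & (delta != 0.0)
    if bad.any():
        raise DegenerateDataError(
            f"zero variance in bin(s) {np.nonzero(bad)[0].tolist()}: "
            "pointwise statistic undefined")
    const = denom == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(const, 0.0, delta / np.sqrt(denom))
        df = np.where(const, float(na + nb - 2),
                      denom ** 2 / (va ** 2 / max(na - 1, 1)
                                    + vb ** 2 / max(nb - 1, 1)))
    return t, df


def onesample_t_series(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin one-sample t against zero; df = n - 1.

    Bins identically zero across participants (the realignment anchor) get
    t = 0; zero-variance bins at a nonzero constant raise.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if n < 2:
        raise DegenerateDataError("need at least two participants")
    sd = a.std(axis=0, ddof=1)
    mean = a.mean(axis=0)
    bad = (sd == 0.0) & (mean != 0.0)
    if bad.any():
        raise DegenerateDataError(
            f"zero variance in bin(s) {np.nonzero(bad)[0].tolist()}: "
            "pointwise statistic undefined")
    const = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(const, 0.0, mean / (sd / np.sqrt(n)))
    df = np.full(a.shape[1], float(n - 1))
    return t, df


def pointwise_stat(curves_a: np.ndarray, curves_b: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t (B given) or one-sample t vs 0 (B omitted)."""
    if curves_b is None:
        return onesample_t_series(curves_a)
    return welch_t_series(curves_a, curves_b)


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def form_clusters(stat: np.ndarray, threshold: np.ndarray | float,
                  ) -> list[tuple[int, int, float]]:
    """Maximal same-sign runs with |t| > threshold; returns
    (start, end, mass) with half-open bin indices."""
    stat = np.asarray(stat, dtype=float)
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), stat.shape)
    above = np.abs(stat) > thr
    sign = np.sign(stat)
    out = []
    i, n = 0, stat.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            out.append((i, j + 1, float(stat[i:j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def _critical_t(df: np.ndarray, alpha: float) -> np.ndarray:
    return stats.t.ppf(1.0 - alpha / 2.0, df)


def _max_abs_mass(stat: np.ndarray, threshold: np.ndarray | float) -> float:
    return max((abs(m) for (_, _, m) in form_clusters(stat, threshold)),
               default=0.0)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(curves_a: np.ndarray,
                     curves_b: np.ndarray | None = None,
                     n_perm: int = 5000,
                     seed: int | None = None,
                     pointwise_alpha: float = POINTWISE_ALPHA,
                     bin_ms: float = BIN_MS,
                     onset_ms: float = 0.0) -> ClusterResult:
    """Cluster-based permutation test; see the module docstring.

    ``curves_a``/``curves_b`` are (participants x bins) matrices; omit
    ``curves_b`` for the one-sample (sign-flip) design.  ``onset_ms`` maps
    bin 0 to epoch time for the reported cluster bounds.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be at least 1")
    a = np.asarray(curves_a, dtype=float)
    b = None if curves_b is None else np.asarray(curves_b, dtype=float)
    t_obs, df_obs = pointwise_stat(a, b)
    thr_obs = _critical_t(df_obs, pointwise_alpha)
    observed = form_clusters(t_obs, thr_obs)

    if b is None:
        null, exhaustive = _null_one_sample(a, n_perm, seed, pointwise_alpha)
    else:
        null, exhaustive = _null_two_sample(a, b, n_perm, seed,
                                            pointwise_alpha)

    clusters = []
    for (s, e, mass) in observed:
        count = int(np.sum(null >= abs(mass) - 1e-12))
        if exhaustive:
            p = count / null.size
        else:
            p = (count + 1) / (null.size + 1)
        clusters.append(Cluster(s, e, onset_ms + s * bin_ms,
                                onset_ms + e * bin_ms, mass, p))
    return ClusterResult(clusters, int(null.size), exhaustive,
                         pointwise_alpha, seed, null_max_mass=null)


def _null_two_sample(a: np.ndarray, b: np.ndarray, n_perm: int,
                     seed: int | None, alpha: float,
                     ) -> tuple[np.ndarray, bool]:
    na, nb = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    n = na + nb
    total = math.comb(n, na)
    if total <= n_perm:
        masses = np.empty(total)
        for k, combo in enumerate(itertools.combinations(range(n), na)):
            idx_a = np.array(combo)
            mask = np.zeros(n, dtype=bool)
            mask[idx_a] = True
            t, df = welch_t_series(pooled[mask], pooled[~mask])
            masses[k] = _max_abs_mass(t, _critical_t(df, alpha))
        return masses, True
    rng = np.random.default_rng(seed)
    masses = np.empty(n_perm)
    order = np.arange(n)
    for k in range(n_perm):
        rng.shuffle(order)
        t, df = welch_t_series(pooled[order[:na]], pooled[order[na:]])
        masses[k] = _max_abs_mass(t, _critical_t(df, alpha))
    return masses, False


def _null_one_sample(a: np.ndarray, n_perm: int, seed: int | None,
                     alpha: float) -> tuple[np.ndarray, bool]:
    n = a.shape[0]
    thr = _critical_t(np.full(a.shape[1], float(n - 1)), alpha)
    if 2 ** n <= n_perm:
        masses = np.empty(2 ** n)
        for k in range(2 ** n):
            signs = np.array([1.0 if (k >> i) & 1 else -1.0
                              for i in range(n)])
            t, _ = onesample_t_series(a * signs[:, None])
            masses[k] = _max_abs_mass(t, thr)
        return masses, True
    rng = np.random.default_rng(seed)
    masses = np.empty(n_perm)
    for k in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t, _ = onesample_t_series(a * signs[:, None])
        masses[k] = _max_abs_mass(t, thr)
    return masses, False
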