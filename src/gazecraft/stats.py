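"""Group-level inference for paired time courses and scalar contrasts.

Implements the three statistical tools the analysis rests on:

* classical paired t-tests with Cohen's d = |t|/sqrt(n) and a 95% CI on
  the mean difference;
* cluster-based sign-flip permutation tests on paired time courses
  (sample-level two-sided thresholding, maximum cluster-mass null per
  sign, 0.025 alpha per side);
* JZS Bayes factors for the one-sample t-test — a Cauchy(0, r) prior on
  the standardized effect size under the alternative — evaluated by
  numerical integration, with a prior-scale sensitivity sweep, plus the
  noncentral-t power solver used for sensitivity analyses.

Throughout, ``bf01`` is the evidence for the null over the alternative
(bf01 > 1 favours the null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import integrate, optimize
from scipy import stats as sps

__all__ = [
    "StatResult",
    "BayesFactorResult",
    "Cluster",
    "ClusterTestConfig",
    "ClusterTestResult",
    "paired_stats",
    "one_sample_stats",
    "cohen_d_from_t",
    "jzs_bf01",
    "bf_sensitivity",
    "cluster_permutation_test",
    "sensitivity_power_d",
    "power_one_sample_t",
    "DEFAULT_BF_SCALES",
]

DEFAULT_BF_SCALES = (0.5, 0.707, 1.0, 2.0)


@dataclass
class StatResult:
    t: float
    df: int
    p: float
    d: float
    mean_diff: float
    ci_low: float
    ci_high: float


@dataclass
class BayesFactorResult:
    t: float
    n: int
    prior_scale: float
    bf01: float

    @property
    def df(self) -> int:
        return self.n - 1

    @property
    def bf10(self) -> float:
        return 1.0 / self.bf01


def cohen_d_from_t(t: float, n: int) -> float:
    """Effect size for a one-sample/paired t: d = |t| / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return abs(t) / np.sqrt(n)


def one_sample_stats(diff: np.ndarray, alpha: float = 0.05) -> StatResult:
    """One-sample t-test against zero on a vector of differences."""
    diff = np.asarray(diff, dtype=float)
    n = diff.size
    if n < 2:
        raise ValueError("need n >= 2")
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences")
    mean = diff.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    return StatResult(
        t=float(t),
        df=df,
        p=float(p),
        d=cohen_d_from_t(t, n),
        mean_diff=float(mean),
        ci_low=float(mean - tc * se),
        ci_high=float(mean + tc * se),
    )


def paired_stats(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> StatResult:
    """Two-sided paired t-test on x − y with Cohen's d and 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_stats(x - y, alpha=alpha)


class IntegrationError(RuntimeError):
    """The Bayes-factor quadrature did not reach the requested accuracy."""


def jzs_bf01(t: float, n: int, r: float = 0.707) -> BayesFactorResult:
    """JZS one-sample Bayes factor: evidence for the null over a Cauchy(0, r) alternative.

    The marginal likelihood under the alternative integrates the
    noncentral-t density of the observed t over the Cauchy prior on the
    standardized effect size delta (noncentrality delta·sqrt(n)); the null
    likelihood is the central-t density.  Quadrature tolerance is 1e-10 so
    values printed at two decimals are stable.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if r <= 0:
        raise ValueError("prior scale must be positive")
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, df, delta * sqrt_n) * sps.cauchy.pdf(delta, scale=r)

    alt, abserr = integrate.quad(
        integrand, -np.inf, np.inf, epsabs=1e-12, epsrel=1e-10, limit=400
    )
    if not np.isfinite(alt) or alt <= 0 or abserr > 1e-6 * alt:
        raise IntegrationError(
            f"marginal likelihood quadrature unreliable (value={alt}, abserr={abserr})"
        )
    null = sps.t.pdf(t, df)
    return BayesFactorResult(t=float(t), n=int(n), prior_scale=float(r), bf01=float(null / alt))


def bf_sensitivity(
    t: float, n: int, scales: tuple[float, ...] = DEFAULT_BF_SCALES
) -> list[BayesFactorResult]:
    """Recompute the Bayes factor across Cauchy prior scales."""
    return [jzs_bf01(t, n, r) for r in scales]


# --------------------------------------------------------------------------
# cluster-based sign-flip permutation test


@dataclass
class ClusterTestConfig:
    n_permutations: int = 10000
    cluster_alpha: float = 0.05   # two-sided sample-level cluster-forming alpha
    side_alpha: float = 0.025     # per-side cluster significance level
    seed: int | None = None

    def validate(self) -> None:
        if not (0 < self.cluster_alpha < 1 and 0 < self.side_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    sign: int
    mass: float
    p: float

    @property
    def significant(self) -> bool:
        return self._sig

    _sig: bool = field(default=False, repr=False)


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    threshold: float
    n_permutations: int
    side_alpha: float
    exact: bool = False

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= self.side_alpha]


def _clusters_1d(tvals: np.ndarray, thresh: float):
    """Maximal contiguous supra-threshold runs of one sign: (start, stop, sign, mass)."""
    out = []
    for sign in (1, -1):
        mask = tvals * sign > thresh
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append((int(s), int(e), sign, float(tvals[s:e].sum())))
    return sorted(out)


def _max_masses(tmat: np.ndarray, thresh: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-row maximum positive and maximum |negative| cluster mass."""
    n_rows = tmat.shape[0]
    pos = np.zeros(n_rows)
    neg = np.zeros(n_rows)
    for i in range(n_rows):
        for _, _, sign, mass in _clusters_1d(tmat[i], thresh):
            if sign > 0:
                pos[i] = max(pos[i], mass)
            else:
                neg[i] = max(neg[i], -mass)
    return pos, neg


def _t_matrix(signs: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """Sample-level t values for each sign-flip pattern (rows of ``signs``)."""
    n = diffs.shape[0]
    ssq = (diffs**2).sum(axis=0)            # invariant under sign flips
    m = signs @ diffs / n
    var = (ssq - n * m**2) / (n - 1)
    return m / np.sqrt(np.maximum(var, 1e-300) / n)


def cluster_permutation_test(
    diffs: np.ndarray,
    config: ClusterTestConfig | None = None,
    times: np.ndarray | None = None,
    exact: bool = False,
) -> ClusterTestResult:
    """Cluster-based permutation test of paired difference time courses vs zero.

    ``diffs`` is (n_participants, n_time).  Sample-level paired t values
    beyond the two-sided cluster-forming threshold define clusters whose
    mass (summed t) is compared against a max-mass null built by randomly
    sign-flipping whole participant curves; positive and negative clusters
    are tested separately at ``side_alpha`` each.  Monte-Carlo p-values use
    the (b + 1)/(m + 1) convention; ``exact=True`` enumerates all 2^n sign
    patterns instead (p = proportion of patterns reaching the observed
    mass, the identity included).
    """
    config = config or ClusterTestConfig()
    config.validate()
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2 or diffs.shape[0] < 2:
        raise ValueError("diffs must be (n_participants >= 2, n_time)")
    n, n_time = diffs.shape
    if times is None:
        times = np.arange(n_time)
    elif len(times) != n_time:
        raise ValueError("time axis does not match the difference curves")
    df = n - 1
    thresh = float(sps.t.ppf(1.0 - config.cluster_alpha / 2.0, df))

    tvals = _t_matrix(np.ones((1, n)), diffs)[0]
    observed = _clusters_1d(tvals, thresh)

    if exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20 participants")
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        null_pos, null_neg = _max_masses(_t_matrix(signs, diffs), thresh)
        m = signs.shape[0]

        def pval(sign: int, mass: float) -> float:
            null = null_pos if sign > 0 else null_neg
            return float(np.mean(null >= abs(mass)))

    else:
        rng = np.random.default_rng(config.seed)
        m = config.n_permutations
        null_pos = np.empty(m)
        null_neg = np.empty(m)
        chunk = max(1, min(m, 20_000_000 // max(1, n * n_time)))
        done = 0
        while done < m:
            k = min(chunk, m - done)
            signs = rng.choice((1.0, -1.0), size=(k, n))
            p_, n_ = _max_masses(_t_matrix(signs, diffs), thresh)
            null_pos[done : done + k] = p_
            null_neg[done : done + k] = n_
            done += k

        def pval(sign: int, mass: float) -> float:
            null = null_pos if sign > 0 else null_neg
            return float((np.sum(null >= abs(mass)) + 1.0) / (m + 1.0))

    clusters = []
    for s, e, sign, mass in observed:
        p = pval(sign, mass)
        c = Cluster(
            start_ms=float(times[s]),
            end_ms=float(times[e - 1] + (times[1] - times[0] if n_time > 1 else 1)),
            sign=sign,
            mass=mass,
            p=p,
        )
        c._sig = p <= config.side_alpha
        clusters.append(c)
    return ClusterTestResult(
        clusters=clusters,
        threshold=thresh,
        n_permutations=m,
        side_alpha=config.side_alpha,
        exact=exact,
    )


# --------------------------------------------------------------------------
# power sensitivity


def power_one_sample_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power of a one-sample/paired t-test at effect size d."""
    df = n - 1
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * np.sqrt(n)
    upper = sps.nct.sf(tc, df, nc)
    lower = sps.nct.cdf(-tc, df, nc)
    if np.isnan(lower):  # negligible opposite-tail mass underflows for large nc
        lower = 0.0
    return float(upper + lower)


def sensitivity_power_d(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest effect size d reaching the target power (noncentral-t root solve)."""
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2")
    f = lambda d: power_one_sample_t(d, n, alpha) - power
    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 100:
            raise ValueError("requested power unreachable at this sample size")
    return float(optimize.brentq(f, 1e-9, hi, xtol=1e-10))
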