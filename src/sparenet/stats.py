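"""Statistical toolkit for group comparisons of abnormality measures.

Implements the tests used throughout the analysis from first principles
so their behavior is oracle-verifiable: an exact (enumerative) one-tailed
Wilcoxon rank-sum, Cohen's d, BCa bootstrap confidence intervals,
Benjamini-Hochberg FDR, Spearman rank correlation, a robust-regression
slope permutation test, and a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata


@dataclass
class StatResult:
    """A test statistic with its p-value and optional effect size / CI."""

    statistic: float
    pvalue: float
    effect_size: float | None = None
    ci: tuple[float, float] | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("CI lower bound exceeds upper bound")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum, exact by enumeration


def _exact_ranksum_tail(ranks2: np.ndarray, n1: int, w2: int, upper: bool) -> float:
    """P(rank-sum of a random size-n1 subset >= or <= w2), ties mid-ranked.

    ``ranks2`` are the combined mid-ranks doubled so they are integers;
    ``w2`` is the observed doubled rank-sum of sample 1. Counting is done
    by dynamic programming over the subset-sum distribution, which
    enumerates all C(N, n1) equally likely rank assignments exactly.
    """
    total = int(ranks2.sum())
    # counts[k][s] = number of size-k subsets with doubled rank-sum s
    counts = np.zeros((n1 + 1, total + 1), dtype=object)
    counts[0, 0] = 1
    for r in ranks2:
        r = int(r)
        kmax = n1
        for k in range(kmax, 0, -1):
            counts[k, r:] = counts[k, r:] + counts[k - 1, : total + 1 - r]
    dist = counts[n1]
    n_total = dist.sum()
    if upper:
        favourable = dist[w2:].sum()
    else:
        favourable = dist[: w2 + 1].sum()
    return float(favourable / n_total)


def ranksum_exact(
    x, y, alternative: str = "greater", exact_cap: int = 25
) -> StatResult:
    """One-tailed Wilcoxon rank-sum test with exact enumeration p-values.

    Parameters
    ----------
    x, y : array-like
        The two samples; the statistic is the rank-sum of ``x`` within the
        pooled sample (mid-ranks for ties).
    alternative : {"greater", "less"}
        "greater" tests whether ``x`` tends to exceed ``y``.
    exact_cap : int
        Combined sample size up to which the exact null distribution is
        enumerated; beyond it a tie-corrected normal approximation with
        continuity correction is used (flagged in ``method``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    n1, n = x.size, combined.size
    w = float(ranks[:n1].sum())

    if n <= exact_cap:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w))
        p = _exact_ranksum_tail(ranks2, n1, w2, upper=(alternative == "greater"))
        method = "ranksum-exact"
    else:
        n2 = y.size
        mu = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        elif alternative == "greater":
            p = float(sps.norm.sf((w - mu - 0.5) / np.sqrt(var)))
        else:
            p = float(sps.norm.cdf((w - mu + 0.5) / np.sqrt(var)))
        method = "ranksum-normal-approx"
    return StatResult(statistic=w, pvalue=min(p, 1.0), method=method)


# ---------------------------------------------------------------------------
# Effect size


def cohen_d(x, y) -> float:
    """Cohen's d with the pooled (n1 + n2 - 2) SD denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    n1, n2 = x.size, y.size
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD; Cohen's d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# BCa bootstrap


def bootstrap_ci_bca(
    sample,
    statistic,
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI of a statistic.

    The bias correction z0 comes from the fraction of resample statistics
    below the observed value; the acceleration comes from the jackknife
    skewness of the statistic over leave-one-out samples. Fully seeded.

    ``statistic`` may accept an ``axis`` keyword (like ``np.median``), in
    which case the resample statistics are computed in one vectorized
    call.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("sample must contain at least 2 observations")
    rng = np.random.default_rng(seed)
    obs = float(statistic(sample))

    idx = rng.integers(0, sample.size, size=(n_resamples, sample.size))
    resamples = sample[idx]
    try:
        boot = np.asarray(statistic(resamples, axis=1), dtype=float)
    except TypeError:
        boot = np.array([statistic(row) for row in resamples], dtype=float)

    if np.allclose(boot, boot[0]):
        import warnings

        warnings.warn("degenerate bootstrap distribution; returning point interval")
        return obs, obs

    p0 = (np.sum(boot < obs) + 0.5 * np.sum(boot == obs)) / n_resamples
    p0 = min(max(p0, 1.0 / (2 * n_resamples)), 1 - 1.0 / (2 * n_resamples))
    z0 = sps.norm.ppf(p0)

    # jackknife acceleration
    n = sample.size
    mask = ~np.eye(n, dtype=bool)
    jack_samples = np.broadcast_to(sample, (n, n))[mask].reshape(n, n - 1)
    try:
        jack = np.asarray(statistic(jack_samples, axis=1), dtype=float)
    except TypeError:
        jack = np.array([statistic(row) for row in jack_samples], dtype=float)
    diffs = jack.mean() - jack
    denom = (diffs**2).sum() ** 1.5
    a = (diffs**3).sum() / (6 * denom) if denom > 0 else 0.0

    alpha = (1 - level) / 2
    lo_hi = []
    for z_alpha in (sps.norm.ppf(alpha), sps.norm.ppf(1 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha))
        lo_hi.append(float(np.quantile(boot, sps.norm.cdf(adj))))
    return min(lo_hi), max(lo_hi)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns
    -------
    reject : boolean array
        True for the k smallest p-values where k = max{i : p(i) <= q*i/m}.
    adjusted : array
        BH-adjusted p-values (monotone cumulative minimum from the top).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)

    below = p[order] <= q * np.arange(1, m + 1) / m
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        reject[order[: k + 1]] = True
    return reject, adjusted


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman_rho(x, y) -> StatResult:
    """Spearman rank correlation with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return StatResult(statistic=rho, pvalue=p, method="spearman-t-approx")


# ---------------------------------------------------------------------------
# Robust regression slope + permutation test


def robust_slope(x, y, max_iter: int = 50, tol: float = 1e-8) -> float:
    """Slope of a bisquare (Tukey biweight) IRLS straight-line fit.

    Starts from OLS, reweights residuals with the biweight function at
    the conventional tuning constant c = 4.685 * MAD-scale, and iterates
    to convergence. Falls back to OLS when the residual scale collapses
    (perfect fit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def wls(w):
        # closed-form weighted straight-line fit (2x2 normal equations)
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0:
            return np.array([ym, 0.0])
        slope = (w * (x - xm) * (y - ym)).sum() / sxx
        return np.array([ym - slope * xm, slope])

    beta = wls(np.ones_like(x))
    c = 4.685
    for _ in range(max_iter):
        resid = y - beta[0] - beta[1] * x
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= tol * max(1.0, float(np.abs(y).max())):
            break
        u = resid / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0 or (w > 0).sum() < 2:
            break
        beta_new = wls(w)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return float(beta[1])


def permutation_slope_test(
    x, y, n_perm: int = 1000, seed: int | np.random.Generator = 0
) -> StatResult:
    """Permutation test of the robust-regression slope.

    The response is permuted ``n_perm`` times and the two-sided p-value
    uses the add-one convention:
    p = (1 + #{|slope_perm| >= |slope_obs|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    rng = np.random.default_rng(seed)
    obs = robust_slope(x, y)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if abs(robust_slope(x, perm)) >= abs(obs):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return StatResult(statistic=obs, pvalue=p, method="robust-slope-permutation")


# ---------------------------------------------------------------------------
# Paired t-test


def paired_t(pre, post, level: float = 0.95) -> StatResult:
    """Two-sided paired t-test on pre-minus-post differences.

    Returns the t statistic, two-sided p, the mean difference as the
    effect estimate, and its t-based confidence interval.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    n = diff.size
    se = sd / np.sqrt(n)
    t = float(diff.mean() / se)
    p = float(2 * sps.t.sf(abs(t), df=n - 1))
    half = sps.t.ppf(0.5 + level / 2, df=n - 1) * se
    return StatResult(
        statistic=t,
        pvalue=p,
        effect_size=float(diff.mean()),
        ci=(float(diff.mean() - half), float(diff.mean() + half)),
        method="paired-t",
    )
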