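"""Statistical tests shared across the pipeline.

Thin, explicitly-specified wrappers around scipy/statsmodels primitives:
Mood's median test with a stated tie policy, Welch's t, exact two-sided
binomial, hypergeometric enrichment, Benjamini-Hochberg FDR, and the
between-replicate empirical tail p-value used for ΔTU / ΔΨ significance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    effect: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.p_value <= 1 or np.isnan(self.p_value)):
            # clamp numerically-zero p to the smallest positive float so the
            # documented invariant p in (0, 1] holds
            self.p_value = max(self.p_value, np.finfo(float).tiny)


def moods_median_test(x, y) -> TestResult:
    """Mood's median test on two samples.

    Counts above / at-or-below the grand median (ties assigned to the
    "<= median" row), then a chi-square test with continuity correction when
    all expected counts are >= 5, otherwise Fisher's exact test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size + y.size < 4:
        raise ValueError("Mood's median test needs a combined n >= 4")
    pooled = np.concatenate([x, y])
    gm = np.median(pooled)
    above = np.array([(x > gm).sum(), (y > gm).sum()])
    at_or_below = np.array([x.size, y.size]) - above
    table = np.array([above, at_or_below])
    if above.sum() == 0 or at_or_below.sum() == 0:
        warnings.warn("all values fall on one side of the grand median; p = 1")
        return TestResult("moods_median", 0.0, 1.0, (x.size, y.size),
                          {"median_x": float(np.median(x)),
                           "median_y": float(np.median(y)),
                           "grand_median": float(gm)})
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected >= 5).all():
        stat, p, _, _ = sps.chi2_contingency(table, correction=True)
    else:
        stat, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult("moods_median", float(stat), float(p), (x.size, y.size),
                      {"median_x": float(np.median(x)),
                       "median_y": float(np.median(y)),
                       "grand_median": float(gm),
                       "direction": "x>y" if np.median(x) > np.median(y)
                       else ("x<y" if np.median(x) < np.median(y) else "x=y")})


def welch_t_test(x, y, two_tailed: bool = True) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t-test needs n >= 2 in each group")
    alt = "two-sided" if two_tailed else "greater"
    res = sps.ttest_ind(x, y, equal_var=False, alternative=alt)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                      (x.size, y.size),
                      {"mean_x": float(x.mean()), "mean_y": float(y.mean()),
                       "mean_diff": float(x.mean() - y.mean())})


def binomial_test(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test (sum of point probabilities <= P(k))."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    res = sps.binomtest(k, n, p0, alternative="two-sided")
    return TestResult("binomial", float(k), float(res.pvalue), (n,),
                      {"proportion": k / n, "p0": p0})


def hypergeom_enrichment(hits: int, draw_size: int, category_size: int,
                         universe_size: int) -> TestResult:
    """Upper-tail hypergeometric enrichment P(X >= hits)."""
    if not (0 <= hits <= draw_size <= universe_size) or category_size > universe_size:
        raise ValueError("inconsistent hypergeometric counts")
    p = float(sps.hypergeom.sf(hits - 1, universe_size, category_size, draw_size))
    expected = draw_size * category_size / universe_size
    return TestResult("hypergeom", float(hits), p, (draw_size,),
                      {"expected": expected,
                       "fold": hits / expected if expected > 0 else np.nan})


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def empirical_tail_p(observed: np.ndarray, observed_bins: np.ndarray,
                     null_values: np.ndarray, null_bins: np.ndarray,
                     n_bins: int = 5, max_null_per_bin: int = 100_000,
                     seed: int = 0) -> np.ndarray:
    """Two-sided empirical p-values against a pooled null, binned by a
    covariate (here: log10 expression).

    Bin edges are covariate quantiles computed on the null covariates; each
    observation is compared with the |null| values of its bin:
    p = (1 + #{|null| >= |obs|}) / (1 + N_bin). Deterministic given seed
    (the seed only matters when a bin's null pool is subsampled).
    """
    observed = np.asarray(observed, dtype=float)
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null pool")
    n_bins = max(1, min(n_bins, max(1, null_values.size // 20)))
    edges = np.quantile(null_bins, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 2:
        edges = np.array([-np.inf, np.inf])
    obs_bin = np.clip(np.searchsorted(edges[1:-1], observed_bins, side="right"),
                      0, edges.size - 2)
    null_bin = np.clip(np.searchsorted(edges[1:-1], null_bins, side="right"),
                       0, edges.size - 2)
    rng = np.random.default_rng(seed)
    p = np.empty(observed.size, dtype=float)
    for b in range(edges.size - 1):
        pool = np.abs(null_values[null_bin == b])
        if pool.size == 0:
            pool = np.abs(null_values)
        if pool.size > max_null_per_bin:
            pool = rng.choice(pool, size=max_null_per_bin, replace=False)
        pool.sort()
        mask = obs_bin == b
        if not mask.any():
            continue
        # #{|null| >= |obs|} via sorted pool
        ge = pool.size - np.searchsorted(pool, np.abs(observed[mask]), side="left")
        p[mask] = (1.0 + ge) / (1.0 + pool.size)
    return p
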