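"""Group-comparison machinery: assumption checks, omnibus tests, post hoc.

Dispatch mirrors common practice in comparative morphometrics: check
normality (Anderson-Darling and Shapiro-Wilk, both must pass in every group)
and variance homogeneity (variance-ratio F); two groups get an unpaired t
(pooled when variances are homogeneous, Welch otherwise); three or more get
one-way ANOVA when assumptions hold, Kruskal-Wallis otherwise.  Post hoc:
Bonferroni-adjusted pairwise t with the pooled ANOVA error term (the default),
Tukey HSD on request, or Dunn's rank test after Kruskal-Wallis.
"""
from __future__ import annotations

from itertools import combinations
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

from .types import DegenerateInputError, GroupComparison, PosthocResult

ALPHA_DEFAULT = 0.05


def _clean_samples(samples: Dict[str, Sequence[float]]) -> Dict[str, np.ndarray]:
    out = {}
    for name, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        out[name] = arr
    return out


def anderson_darling_pass(x: np.ndarray, alpha: float = ALPHA_DEFAULT) -> bool:
    """Anderson-Darling normality check at the given level.

    scipy reports critical values at fixed levels rather than a p-value; the
    statistic is compared against the critical value at ``alpha``.
    """
    import warnings

    with warnings.catch_warnings():
        # scipy >= 1.17 announces an API change for `anderson`; the
        # critical-value interface used here still behaves as documented.
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float) / 100.0
    idx = int(np.argmin(np.abs(levels - alpha)))
    return bool(res.statistic < res.critical_values[idx])


def variance_ratio_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided variance-ratio F-test (larger variance on top)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va >= vb:
        F, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        F, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = 2.0 * stats.f.sf(F, dfn, dfd)
    return float(F), float(min(p, 1.0))


def check_assumptions(
    samples: Dict[str, Sequence[float]], alpha: float = ALPHA_DEFAULT
) -> tuple[Dict[str, bool], bool]:
    """Normality per group (both tests must pass) and variance homogeneity.

    Normality requires p >= alpha on Shapiro-Wilk *and* a sub-critical
    Anderson-Darling statistic.  Variance homogeneity is the variance-ratio
    F-test, taken over all pairs for > 2 groups (fails if any pair fails).
    Constant samples are degenerate: normality is undefined.
    """
    clean = _clean_samples(samples)
    normal = {}
    for name, x in clean.items():
        if len(x) < 3:
            raise DegenerateInputError(f"group {name!r} has n < 3; cannot test normality")
        if np.ptp(x) == 0:
            raise DegenerateInputError(f"group {name!r} is constant; normality undefined")
        sw_p = stats.shapiro(x).pvalue
        normal[name] = bool(sw_p >= alpha) and anderson_darling_pass(x, alpha)
    equal_var = True
    for a, b in combinations(clean.values(), 2):
        _, p = variance_ratio_test(a, b)
        if p < alpha:
            equal_var = False
            break
    return normal, equal_var


def _bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def _pairwise_t_pooled_mse(clean: Dict[str, np.ndarray]) -> list[PosthocResult]:
    """Pairwise t with the pooled ANOVA mean-square error, Bonferroni-adjusted."""
    names = list(clean)
    N = sum(len(v) for v in clean.values())
    k = len(names)
    df_err = N - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in clean.values())
    mse = sse / df_err
    pairs = list(combinations(names, 2))
    out = []
    for a, b in pairs:
        xa, xb = clean[a], clean[b]
        se = np.sqrt(mse * (1 / len(xa) + 1 / len(xb)))
        t = (xa.mean() - xb.mean()) / se
        p = 2.0 * stats.t.sf(abs(t), df_err)
        out.append(PosthocResult((a, b), float(t), _bonferroni(p, len(pairs)), "bonferroni"))
    return out


def _tukey(clean: Dict[str, np.ndarray]) -> list[PosthocResult]:
    names = list(clean)
    res = stats.tukey_hsd(*clean.values())
    out = []
    for i, j in combinations(range(len(names)), 2):
        out.append(
            PosthocResult(
                (names[i], names[j]),
                float(res.statistic[i, j]),
                float(res.pvalue[i, j]),
                "tukey",
            )
        )
    return out


def dunn_test(clean: Dict[str, np.ndarray]) -> list[PosthocResult]:
    """Dunn's post-hoc rank test with tie correction, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T] (1/n_i + 1/n_j)), where
    Rbar are mean ranks over the pooled sample (average ranks for ties) and
    T = sum(t^3 - t)/(12 (N - 1)) corrects for tied values.
    """
    names = list(clean)
    pooled = np.concatenate([clean[n] for n in names])
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    idx = 0
    mean_ranks = {}
    for n in names:
        m = len(clean[n])
        mean_ranks[n] = ranks[idx : idx + m].mean()
        idx += m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    pairs = list(combinations(names, 2))
    out = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1 / len(clean[a]) + 1 / len(clean[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out.append(PosthocResult((a, b), float(z), _bonferroni(p, len(pairs)), "dunn"))
    return out


def compare_groups(
    samples: Dict[str, Sequence[float]],
    variable: str = "",
    force_method: Optional[str] = None,
    posthoc: Optional[str] = None,
    alpha: float = ALPHA_DEFAULT,
) -> GroupComparison:
    """Omnibus comparison across labeled samples, with post hoc for >= 3 groups.

    ``force_method`` in {"t_test", "welch_t_test", "anova", "kruskal_wallis"}
    overrides dispatch; ``posthoc`` in {"bonferroni", "tukey", "dunn"}
    overrides the default pairing (bonferroni after ANOVA, dunn after
    Kruskal-Wallis).
    """
    clean = _clean_samples(samples)
    names = list(clean)
    for name, x in clean.items():
        if len(x) < 2:
            raise DegenerateInputError(f"group {name!r} has n < 2")
    k = len(names)
    if k < 2:
        raise DegenerateInputError("need at least two groups")

    degenerate = any(np.ptp(x) == 0 for x in clean.values())
    if force_method is None:
        if degenerate:
            # constant group: normality is undefined, use the parametric test
            # directly (identical data resolve to the trivial no-difference answer)
            method = "t_test" if k == 2 else "anova"
        else:
            normal, equal_var = check_assumptions(clean, alpha)
            if k == 2:
                method = "t_test" if equal_var else "welch_t_test"
            else:
                method = "anova" if (all(normal.values()) and equal_var) else "kruskal_wallis"
    else:
        method = force_method

    vals = list(clean.values())
    if method == "t_test":
        res = stats.ttest_ind(vals[0], vals[1], equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        df = len(vals[0]) + len(vals[1]) - 2
    elif method == "welch_t_test":
        res = stats.ttest_ind(vals[0], vals[1], equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    elif method == "anova":
        res = stats.f_oneway(*vals)
        stat, p = float(res.statistic), float(res.pvalue)
        df = sum(len(v) for v in vals) - k
        if np.isnan(stat) and all(np.array_equal(vals[0], v) for v in vals):
            stat, p = 0.0, 1.0
    elif method == "kruskal_wallis":
        res = stats.kruskal(*vals)
        stat, p = float(res.statistic), float(res.pvalue)
        df = k - 1
    else:
        raise ValueError(f"unknown method {force_method!r}")

    if np.isnan(stat) and k == 2 and np.array_equal(vals[0], vals[1]):
        stat, p = 0.0, 1.0  # identical samples: no difference by definition

    comp = GroupComparison(
        variable=variable,
        omnibus=method,
        statistic=stat,
        df=df,
        p=p,
        group_names=names,
        group_n=[len(v) for v in vals],
    )
    want_posthoc = posthoc is not None or k >= 3
    if want_posthoc and k >= 2:
        choice = posthoc or ("dunn" if method == "kruskal_wallis" else "bonferroni")
        if choice == "bonferroni":
            comp.posthoc = _pairwise_t_pooled_mse(clean)
        elif choice == "tukey":
            comp.posthoc = _tukey(clean)
        elif choice == "dunn":
            comp.posthoc = dunn_test(clean)
        else:
            raise ValueError(f"unknown posthoc {posthoc!r}")
    return comp
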