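"""Statistical-test selection glue.

Group comparisons follow the screen-then-test convention: samples are
checked for normality (Shapiro-Wilk) and compared with a parametric test
when the screen passes in every group (Welch t-test for two groups,
one-way ANOVA otherwise) or a rank test when it fails (Mann-Whitney /
Kruskal-Wallis).  The choice is recorded in the returned record so every
reported p value names its test and sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class TestRecord:
    test_name: str
    statistic: float
    p: float
    n_per_group: tuple
    normality_ps: tuple
    normal: bool

    def to_row(self) -> dict:
        return dict(test=self.test_name, statistic=self.statistic, p=self.p,
                    n=",".join(str(n) for n in self.n_per_group))


def _all_identical(groups):
    flat = np.concatenate(groups)
    return np.allclose(flat, flat[0])


def choose_test(groups: list, alpha_normal: float = 0.01) -> TestRecord:
    """Normality-screened two-or-more-sample comparison.

    The screen alpha defaults to 0.01: a screen is meant to catch clear
    departures from normality, and a laxer cut-off would abandon the
    parametric branch for ~10% of genuinely Gaussian two-group data.
    Groups with fewer than 3 observations cannot be screened and default
    to the rank test.  Identical samples short-circuit to p = 1 (no
    evidence of difference under either branch).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = tuple(len(g) for g in groups)
    if _all_identical(groups):
        return TestRecord("identical", 0.0, 1.0, ns, (), True)
    norm_ps = []
    screenable = all(len(g) >= 3 for g in groups)
    if screenable:
        for g in groups:
            if np.allclose(g, g[0]):
                norm_ps.append(0.0)  # degenerate: treat as non-normal
            else:
                norm_ps.append(float(stats.shapiro(g).pvalue))
    normal = screenable and all(p > alpha_normal for p in norm_ps)
    if normal:
        if len(groups) == 2:
            t, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
            return TestRecord("welch_t", float(t), float(p), ns, tuple(norm_ps), True)
        f, p = stats.f_oneway(*groups)
        return TestRecord("anova", float(f), float(p), ns, tuple(norm_ps), True)
    if len(groups) == 2:
        u, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return TestRecord("mannwhitney", float(u), float(p), ns, tuple(norm_ps), False)
    h, p = stats.kruskal(*groups)
    return TestRecord("kruskal", float(h), float(p), ns, tuple(norm_ps), False)


def holm_correction(pvals) -> np.ndarray:
    """Holm step-down adjusted p values (optional multiple-comparison flag)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
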