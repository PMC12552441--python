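"""Rank-based test battery with Benjamini–Hochberg adjustment.

Thin, uniform wrappers over scipy/statsmodels so every analysis stage emits
the same :class:`TestResult` record and adjusts p-values within a declared
family at FDR < 0.05.  The common-language effect size CLES = U/(n1*n2) is
attached to Mann–Whitney results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic_name: str           # "U", "T", "H", "KS_D", "hypergeom"
    statistic_value: float
    p_value: float
    tails: str = "two"            # "one" | "two"
    effect_size: Optional[float] = None  # CLES for MWU
    n_per_group: Optional[tuple] = None
    p_adjusted: Optional[float] = None
    label: Optional[str] = None


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U with CLES = U/(n1*n2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    res = stats.mannwhitneyu(x, y, alternative=alternative)
    cles = res.statistic / (len(x) * len(y))
    return TestResult("U", float(res.statistic), float(res.pvalue),
                      "two" if alternative == "two-sided" else "one",
                      effect_size=float(cles), n_per_group=(len(x), len(y)))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Wilcoxon signed-rank on paired samples.

    All-tied differences carry no information; flagged with p = NaN.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    d = x - y
    if np.all(d == 0):
        return TestResult("T", float("nan"), float("nan"), "two",
                          n_per_group=(len(x), len(y)))
    res = stats.wilcoxon(x, y)
    return TestResult("T", float(res.statistic), float(res.pvalue), "two",
                      n_per_group=(len(x), len(y)))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    res = stats.ks_2samp(x, y)
    return TestResult("KS_D", float(res.statistic), float(res.pvalue), "two",
                      n_per_group=(len(x), len(y)))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    res = stats.kruskal(*groups)
    return TestResult("H", float(res.statistic), float(res.pvalue), "two",
                      n_per_group=tuple(len(g) for g in groups))


def dunn_posthoc(groups: Dict[str, Sequence[float]]) -> List[TestResult]:
    """Dunn's test for all group pairs after Kruskal–Wallis.

    Z statistics from pooled midranks with tie correction; two-sided p.
    """
    names = list(groups)
    data = [np.asarray(groups[k], float) for k in names]
    pooled = np.concatenate(data)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes = [], []
    start = 0
    for d in data:
        mean_ranks.append(ranks[start:start + len(d)].mean())
        sizes.append(len(d))
        start += len(d)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            out.append(TestResult("Z", float(z), float(p), "two",
                                  n_per_group=(sizes[i], sizes[j]),
                                  label=f"{names[i]}-{names[j]}"))
    return out


def hypergeom_enrichment(k: int, n_draws: int, K: int, N: int) -> TestResult:
    """P(X >= k) for k successes in n draws from N with K marked."""
    p = float(stats.hypergeom.sf(k - 1, N, K, n_draws))
    return TestResult("hypergeom", float(k), p, "one",
                      n_per_group=(n_draws, N))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p_values, float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def adjust_family(results: Sequence[TestResult]) -> List[TestResult]:
    """BH-adjust a family of TestResults in place and return it."""
    adj = bh_adjust([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return list(results)
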