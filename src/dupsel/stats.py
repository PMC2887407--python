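"""Hypothesis tests: likelihood-ratio tests, Tajima's relative rate test,
and two-group comparisons of per-sequence statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "LRTResult",
    "RRTResult",
    "lrt",
    "chi2_pvalue",
    "tajima_rrt",
    "compare_groups",
    "significance_stars",
]


def chi2_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability of ``stat`` with ``df`` degrees."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if stat < 0:
        raise ValueError("statistic must be nonnegative")
    return float(sps.chi2.sf(stat, df))


def significance_stars(p: float) -> str:
    """Conventional star rendering: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class LRTResult:
    """2ΔL = 2(lnL_alt - lnL_null) against chi-square with df = Δparams.

    A negative statistic (possible when the models are not truly nested or
    differently dimensioned) is reported as-is with ``negative=True`` and
    p = 1, never silently truncated.
    """

    lnL_null: float
    lnL_alt: float
    df: int
    stat: float
    p_value: float
    negative: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def lrt(lnL_null: float, lnL_alt: float, df_null: int, df_alt: int) -> LRTResult:
    """Likelihood-ratio test between two nested fits.

    Parameters are the two maximized log-likelihoods and the two free
    parameter counts; the alternative must have strictly more parameters.
    """
    if df_alt <= df_null:
        raise ValueError("alternative model must have more free parameters")
    stat = 2.0 * (lnL_alt - lnL_null)
    df = df_alt - df_null
    if stat < 0:
        return LRTResult(lnL_null, lnL_alt, df, stat, 1.0, negative=True)
    return LRTResult(lnL_null, lnL_alt, df, stat, chi2_pvalue(stat, df))


def lrt_from_fits(fit_null, fit_alt) -> LRTResult:
    """LRT taking two CodonModelResults (or anything with lnL / n_params)."""
    return lrt(fit_null.lnL, fit_alt.lnL, fit_null.n_params, fit_alt.n_params)


@dataclass
class RRTResult:
    """Tajima's one-degree-of-freedom relative rate test.

    m1 counts sites where only lineage A differs (A != B and B == outgroup),
    m2 the mirror image; under equal rates m1 and m2 are exchangeable and
    (m1-m2)^2/(m1+m2) is asymptotically chi-square with 1 df.
    """

    m1: int
    m2: int
    n_sites: int
    ratio: float | None
    chi2: float | None
    p_value: float | None
    defined: bool = True

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value) if self.defined else ""


def tajima_rrt(seq_a: str, seq_b: str, outgroup: str) -> RRTResult:
    """Tajima's relative rate test on three aligned nucleotide sequences.

    Sites with a gap or N in any of the three sequences are dropped.  When
    no lineage-unique differences exist the test is undefined and flagged.
    The rate ratio m1/m2 is reported as None when m2 = 0.
    """
    if not (len(seq_a) == len(seq_b) == len(outgroup)):
        raise ValueError("sequences differ in length")
    m1 = m2 = n = 0
    for x, y, o in zip(seq_a, seq_b, outgroup):
        if x not in "ACGT" or y not in "ACGT" or o not in "ACGT":
            continue
        n += 1
        if x != y:
            if y == o:
                m1 += 1
            elif x == o:
                m2 += 1
    if m1 + m2 == 0:
        return RRTResult(m1, m2, n, None, None, None, defined=False)
    chi2 = (m1 - m2) ** 2 / (m1 + m2)
    ratio = m1 / m2 if m2 > 0 else None
    return RRTResult(m1, m2, n, ratio, chi2, chi2_pvalue(chi2, 1))


def compare_groups(values_a, values_b) -> tuple[float, float, float, float]:
    """Welch two-sample t-test on per-sequence statistics.

    Returns (mean_a, mean_b, t, p).  Degenerate input with zero variance in
    both groups and equal means gives t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return float(a.mean()), float(b.mean()), 0.0, 1.0
        return float(a.mean()), float(b.mean()), math.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(a.mean()), float(b.mean()), float(t), float(p)
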