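"""Two-cohort mutation-frequency comparison.

Per gene, a 2x2 table (mutated / unmutated in each cohort) is tested with
Fisher's exact test (probability-mass two-sided rule), and the effect is
summarized by the conditional maximum-likelihood odds ratio of the Fisher
noncentral hypergeometric model with an exact (tail-inversion) confidence
interval — the reporting convention of exact-test software such as R's
``fisher.test`` and maftools' ``mafCompare``.  P-values are adjusted with
Benjamini-Hochberg.

Per-gene denominators may differ (a gene unsequenced in one source cohort
simply has a smaller cohort size for that gene).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneCounts",
    "ComparisonResult",
    "exact_test",
    "conditional_mle_or",
    "exact_ci",
    "compare_cohorts",
]


@dataclass(frozen=True)
class GeneCounts:
    """2x2 table for one gene: cohort 1 (a mutated, b not), cohort 2 (c, d)."""

    gene: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("zero-size cohort")


@dataclass(frozen=True)
class ComparisonResult:
    gene: str
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    adjusted_p: float = float("nan")


def _support(a: int, b: int, c: int, d: int) -> tuple[int, int, int, int, int]:
    r1, r2 = a + b, c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return r1, r2, c1, lo, hi


def exact_test(counts: GeneCounts) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.

    Computed with exact integer arithmetic (binomial-coefficient numerators
    over a common denominator), so ties are resolved exactly rather than to
    floating-point tolerance.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    r1, r2, c1, lo, hi = _support(a, b, c, d)
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(lo, hi + 1):
        num = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num <= num_obs:
            total += num
    denom = math.comb(r1 + r2, c1)
    return total / denom


def _log_weights(r1: int, r2: int, c1: int, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    k = np.arange(lo, hi + 1)
    lw = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
    )
    return k, lw


def _cond_dist(k: np.ndarray, lw: np.ndarray, log_psi: float) -> np.ndarray:
    lp = lw + k * log_psi
    return np.exp(lp - logsumexp(lp))


def _solve_monotone(f, lo: float = -40.0, hi: float = 40.0) -> float:
    """Root of an increasing function of log-psi, expanding the bracket as
    needed."""
    flo, fhi = f(lo), f(hi)
    while flo > 0 and lo > -400:
        lo *= 2
        flo = f(lo)
    while fhi < 0 and hi < 400:
        hi *= 2
        fhi = f(hi)
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)


def conditional_mle_or(counts: GeneCounts) -> float:
    """Odds ratio maximizing the Fisher noncentral hypergeometric likelihood
    conditional on the table margins.

    The conditional score equation is E_psi[A] = a; the expectation is
    strictly increasing in psi, so the MLE is found by root bracketing.
    Tables at the edge of the support give 0 (a at minimum) or inf (a at
    maximum).
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    r1, r2, c1, lo, hi = _support(a, b, c, d)
    if lo == hi:
        return float("nan")  # margins admit a single table: not estimable
    if a == lo:
        return 0.0
    if a == hi:
        return float("inf")
    k, lw = _log_weights(r1, r2, c1, lo, hi)

    def score(log_psi: float) -> float:
        w = _cond_dist(k, lw, log_psi)
        return float(w @ k) - a

    return math.exp(_solve_monotone(score))


def exact_ci(counts: GeneCounts, level: float = 0.95) -> tuple[float, float]:
    """Exact confidence interval for the conditional odds ratio.

    Each endpoint inverts a one-sided noncentral hypergeometric tail test at
    (1 - level)/2: the lower endpoint is the psi at which P(A >= a) equals
    the half-level, the upper where P(A <= a) does.  Zero cells give 0 or
    inf endpoints.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    alpha2 = (1.0 - level) / 2.0
    r1, r2, c1, lo, hi = _support(a, b, c, d)
    if lo == hi:
        return (float("nan"), float("nan"))
    k, lw = _log_weights(r1, r2, c1, lo, hi)

    if a == lo:
        ci_low = 0.0
    else:
        def f_low(log_psi):
            w = _cond_dist(k, lw, log_psi)
            return float(w[k >= a].sum()) - alpha2  # increasing in psi

        ci_low = math.exp(_solve_monotone(f_low))
    if a == hi:
        ci_high = float("inf")
    else:
        def f_high(log_psi):
            w = _cond_dist(k, lw, log_psi)
            return alpha2 - float(w[k <= a].sum())  # increasing in psi

        ci_high = math.exp(_solve_monotone(f_high))
    return ci_low, ci_high


def compare_cohorts(
    counts: list[GeneCounts] | None = None,
    *,
    mutated_1: dict[str, int] | None = None,
    sizes_1: dict[str, int] | None = None,
    mutated_2: dict[str, int] | None = None,
    sizes_2: dict[str, int] | None = None,
    genes: list[str] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Run the per-gene comparison and return a table sorted by p-value.

    Either pass prebuilt ``counts``, or per-gene mutated counts and cohort
    sizes for the two cohorts (per-gene sizes allow genes unsequenced in a
    source cohort to use the reduced denominator).  Genes absent from either
    cohort are dropped with a warning.
    """
    if counts is None:
        if None in (mutated_1, sizes_1, mutated_2, sizes_2):
            raise ValueError("pass counts or all per-cohort dictionaries")
        gene_list = genes or sorted(set(sizes_1) & set(sizes_2))
        counts = []
        for g in gene_list:
            if g not in sizes_1 or g not in sizes_2:
                warnings.warn(f"gene {g} absent from one cohort; dropped", stacklevel=2)
                continue
            a = int(mutated_1.get(g, 0))
            c = int(mutated_2.get(g, 0))
            counts.append(GeneCounts(g, a, sizes_1[g] - a, c, sizes_2[g] - c))
    if not counts:
        raise ValueError("no genes shared between cohorts")
    rows = []
    for gc in counts:
        p = exact_test(gc)
        orr = conditional_mle_or(gc)
        ci_lo, ci_hi = exact_ci(gc, level=level)
        rows.append((gc.gene, gc.a, gc.a + gc.b, gc.c, gc.c + gc.d, p, orr, ci_lo, ci_hi))
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "mutated_1", "n_1", "mutated_2", "n_2",
            "p_value", "odds_ratio", "ci_low", "ci_high",
        ],
    )
    df["adjusted_p"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values("p_value", kind="mergesort", ignore_index=True)
    return df
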