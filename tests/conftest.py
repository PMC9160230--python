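"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately brute-force (exhaustive least-squares
changepoint search, exact-fraction hypergeometric enumeration, grid
search / bisection for the noncentral hypergeometric) and independent of
the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from oncopanel.filtering import VariantRecord
from oncopanel.simulate import SimConfig, generate_cohort


def ls_changepoint_oracle(x, max_changes: int = 2, min_len: int = 8) -> list[int]:
    """Exhaustive least-squares changepoint search: smallest number of
    changes (0..max_changes) achieving minimal SSE, segments >= min_len."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    S = np.r_[0, np.cumsum(x)]
    S2 = np.r_[0, np.cumsum(x**2)]

    def sse(lo, hi):
        s = S[hi] - S[lo]
        return S2[hi] - S2[lo] - s * s / (hi - lo)

    best = (np.inf, [])
    for k in range(max_changes + 1):
        for bps in itertools.combinations(range(1, n), k):
            prev, tot, ok = 0, 0.0, True
            for b in (*bps, n):
                if b - prev < min_len:
                    ok = False
                    break
                tot += sse(prev, b)
                prev = b
            if ok and tot < best[0] - 1e-9:
                best = (tot, list(bps))
    return best[1]


def random_step_series(
    rng: np.random.Generator,
    n_range=(25, 51),
    max_changes: int = 2,
    min_len: int = 8,
    min_gap: float = 0.5,
) -> np.ndarray:
    """Noise-free piecewise-constant series whose segments are long enough
    for a permutation test at alpha=0.01 to resolve."""
    n = int(rng.integers(*n_range))
    k = int(rng.integers(0, max_changes + 1))
    while True:
        if k:
            bps = sorted(rng.choice(np.arange(min_len, n - min_len + 1), size=k,
                                    replace=False))
        else:
            bps = []
        lens = np.diff([0, *bps, n])
        if (lens >= min_len).all():
            break
    levels = [0.0]
    for _ in range(k):
        step = rng.uniform(min_gap, 2.0) * (1 if rng.random() < 0.5 else -1)
        levels.append(levels[-1] + step)
    return np.concatenate([np.full(l, lv) for l, lv in zip(lens, levels)])


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Probability-mass two-sided Fisher p via exact-fraction recurrence."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {lo: Fraction(math.comb(r1, lo) * math.comb(r2, c1 - lo),
                          math.comb(r1 + r2, c1))}
    for k in range(lo, hi):
        probs[k + 1] = probs[k] * Fraction((r1 - k) * (c1 - k),
                                           (k + 1) * (r2 - c1 + k + 1))
    pa = probs[a]
    return float(sum(v for v in probs.values() if v <= pa))


def _nchg_logpmf(k, r1, r2, c1, log_psi):
    lw = np.array([
        math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
        + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1)
        + x * log_psi
        for x in k
    ])
    m = lw.max()
    w = np.exp(lw - m)
    return w / w.sum()


def cmle_grid_oracle(a, b, c, d, tol=1e-8) -> float:
    """Golden-section maximization of the conditional likelihood in
    log-odds space."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    k = np.arange(lo, hi + 1)
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf

    def loglik(t):
        w = _nchg_logpmf(k, r1, r2, c1, t)
        return math.log(w[a - lo])

    g = (math.sqrt(5) - 1) / 2
    x1, x2 = -40.0, 40.0
    m1 = x2 - g * (x2 - x1)
    m2 = x1 + g * (x2 - x1)
    f1, f2 = loglik(m1), loglik(m2)
    while x2 - x1 > tol:
        if f1 < f2:
            x1, m1, f1 = m1, m2, f2
            m2 = x1 + g * (x2 - x1)
            f2 = loglik(m2)
        else:
            x2, m2, f2 = m2, m1, f1
            m1 = x2 - g * (x2 - x1)
            f1 = loglik(m1)
    return math.exp((x1 + x2) / 2)


def ci_bisect_oracle(a, b, c, d, level=0.95) -> tuple[float, float]:
    """Bisection inversion of the one-sided noncentral tail tests."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    k = np.arange(lo, hi + 1)
    alpha2 = (1 - level) / 2

    def tail_ge(t):  # P(A >= a), increasing in t
        return _nchg_logpmf(k, r1, r2, c1, t)[k >= a].sum()

    def tail_le(t):  # P(A <= a), decreasing in t
        return _nchg_logpmf(k, r1, r2, c1, t)[k <= a].sum()

    def bisect(f, target, increasing):
        x1, x2 = -50.0, 50.0
        for _ in range(200):
            mid = (x1 + x2) / 2
            if (f(mid) < target) == increasing:
                x1 = mid
            else:
                x2 = mid
        return math.exp((x1 + x2) / 2)

    ci_lo = 0.0 if a == lo else bisect(tail_ge, alpha2, True)
    ci_hi = math.inf if a == hi else bisect(tail_le, alpha2, False)
    return ci_lo, ci_hi


def make_variant(
    pos=100, vaf=0.5, depth=100, population_af=0.2, chrom="chr1", gene="G",
    consequence="other", predicted=None, hotspot=False, mnp=None, sample="s1",
) -> VariantRecord:
    return VariantRecord(
        sample_id=sample, chromosome=chrom, pos=pos, ref="C", alt="T",
        gene=gene, depth=depth, alt_count=int(round(vaf * depth)),
        population_af=population_af, consequence=consequence,
        predicted_class=predicted, hotspot=hotspot, matched_normal_present=mnp,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured noisy cohort (session-cached)."""
    cfg = SimConfig(n_samples=8, n_paired=3, seed=42)
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = SimConfig(n_samples=6, n_paired=2, seed=7).noise_free()
    return cfg, *generate_cohort(cfg)
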