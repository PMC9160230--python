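"""Circular binary segmentation (CBS).

Recursive changepoint detection on an ordered numeric series.  Each
(sub)series is treated as circular: every arc is compared against its
complement with a two-sample t statistic, the maximal arc is located, and
the split is accepted when a permutation test deems it significant.  The
procedure then recurses into the resulting pieces.

Determinism: the permutation stream is driven by a caller-supplied seed or
Generator; identical inputs and seed give identical breakpoints.  Ties in
the arc statistic are broken toward the leftmost (lexicographically first)
arc.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

__all__ = ["cbs_segment", "segment_means"]

_REL_EPS = 1e-12


def _arc_index_arrays(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All circular arcs (i, j), 0 <= i < j <= n, with both the arc and its
    complement at least ``min_width`` long.  Lexicographic order (leftmost
    tie-breaking relies on it)."""
    ii, jj = [], []
    for i in range(0, n):
        lo = i + min_width
        hi = min(n, i + n - min_width)
        for j in range(lo, hi + 1):
            if i == 0 and j == n:
                continue
            ii.append(i)
            jj.append(j)
    return np.asarray(ii, dtype=np.intp), np.asarray(jj, dtype=np.intp)


def _arc_stats(X: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Squared two-sample t statistic for every arc, rows of ``X`` batched.

    Returns shape (B, n_arcs).  Zero-variance degeneracies: equal means give
    0; distinct means with zero within-group variance give +inf.
    """
    X = np.atleast_2d(X)
    B, n = X.shape
    S = np.zeros((B, n + 1))
    np.cumsum(X, axis=1, out=S[:, 1:])
    tot = S[:, -1:]
    m = (jj - ii).astype(float)
    sa = S[:, jj] - S[:, ii]
    between = sa**2 / m + (tot - sa) ** 2 / (n - m) - tot**2 / n
    sst = np.einsum("ij,ij->i", X, X)[:, None] - tot**2 / n
    ssw = sst - between
    scale = np.maximum(sst, 1.0) * _REL_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = between * (n - 2) / ssw
    t2 = np.where(between <= scale, 0.0, t2)
    t2 = np.where((ssw <= scale) & (between > scale), np.inf, t2)
    return t2


def _permutation_p(
    x: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    observed: float,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value for the maximal arc statistic, with early stop
    once significance at ``alpha`` is no longer attainable."""
    # p = (1 + exceed) / (1 + n_perm); split impossible once exceed >= cap
    cap = math.ceil(alpha * (n_perm + 1)) - 1
    exceed = 0
    done = 0
    batch = 250
    thresh = observed * (1.0 - 1e-9) if np.isfinite(observed) else np.inf
    while done < n_perm:
        b = min(batch, n_perm - done)
        P = rng.permuted(np.tile(x, (b, 1)), axis=1)
        stats = _arc_stats(P, ii, jj).max(axis=1)
        if np.isfinite(observed):
            exceed += int(np.count_nonzero(stats >= thresh))
        else:
            exceed += int(np.count_nonzero(np.isinf(stats)))
        done += b
        if exceed > cap:
            break
    return (1 + exceed) / (1 + done)


def _segment_recursive(
    x: np.ndarray,
    offset: int,
    alpha: float,
    n_perm: int,
    min_bins: int,
    rng: np.random.Generator,
    out: list[int],
) -> None:
    n = len(x)
    if n < 2 * max(min_bins, 1):
        return
    ii, jj = _arc_index_arrays(n, max(min_bins, 1))
    if len(ii) == 0:
        return
    stats = _arc_stats(x, ii, jj)[0]
    k = int(np.argmax(stats))
    obs = stats[k]
    if obs <= 0.0:
        return
    p = _permutation_p(x, ii, jj, obs, n_perm, alpha, rng)
    if p >= alpha:
        return
    i, j = int(ii[k]), int(jj[k])
    if i > 0:
        out.append(offset + i)
    if j < n:
        out.append(offset + j)
    for lo, hi in ((0, i), (i, j), (j, n)):
        if hi - lo > 0:
            _segment_recursive(x[lo:hi], offset + lo, alpha, n_perm, min_bins, rng, out)


def cbs_segment(
    values,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_bins: int = 3,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Segment an ordered series; return sorted interior breakpoints.

    A breakpoint ``k`` means the series splits between indices ``k-1`` and
    ``k``.  Series shorter than ``min_bins`` yield no breakpoints (with a
    warning); a constant series yields none.

    Parameters
    ----------
    values : 1-D array-like of float
    alpha : permutation significance level for accepting a split.
    n_perm : number of permutations per split decision.
    min_bins : minimal segment width considered.
    seed, rng : permutation stream; pass ``rng`` to share a stream across
        calls, else ``seed`` creates a fresh one.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < max(min_bins, 2):
        warnings.warn(
            f"series of length {x.size} shorter than min_bins={min_bins}; "
            "no segmentation attempted",
            stacklevel=2,
        )
        return []
    if rng is None:
        rng = np.random.default_rng(seed)
    out: list[int] = []
    _segment_recursive(x, 0, alpha, n_perm, min_bins, rng, out)
    return sorted(out)


def segment_means(values, breakpoints: list[int]) -> list[tuple[int, int, float]]:
    """(start, end, mean) per segment implied by ``breakpoints``."""
    x = np.asarray(values, dtype=float).ravel()
    bounds = [0, *breakpoints, len(x)]
    return [
        (lo, hi, float(x[lo:hi].mean()))
        for lo, hi in zip(bounds[:-1], bounds[1:])
        if hi > lo
    ]
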