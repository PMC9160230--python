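"""Copy-number calling from targeted-panel coverage.

A pooled-normal reference model (per-bin median of total-depth-normalized
coverage) turns per-bin tumor depths into log2 ratios; per-chromosome
circular binary segmentation yields segments, whose means are optionally
recentered and converted to integer copy numbers, with or without a known
tumor purity, and classified into copy states.

Coverage tables are pandas DataFrames with columns
``chromosome, start, end, gene`` plus either ``depth`` or ``log2_ratio``;
bins sorted by (chromosome, start); coordinates 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .segmentation import cbs_segment

__all__ = [
    "ReferenceModel",
    "CnSegment",
    "CopyStateThresholds",
    "build_reference",
    "log2_ratios",
    "segment_coverage",
    "recenter",
    "estimate_copies",
    "classify_copy_state",
    "call_copy_number",
]

BIN_COLUMNS = ["chromosome", "start", "end", "gene"]

#: copy-state vocabulary, ordered from lowest to highest copy number
STATES = ["deep_deletion", "shallow_deletion", "neutral", "gain", "amplification"]


@dataclass(frozen=True)
class CopyStateThresholds:
    """Copy-number class boundaries.

    Defaults follow the usual tumor-panel convention: 0 copies is a deep
    (homozygous) deletion, 1 a shallow deletion, 2 neutral, 3-4 a copy
    gain, and 5 or more an amplification.
    """

    deep_max: int = 0
    shallow_max: int = 1
    neutral_max: int = 2
    gain_max: int = 4


@dataclass
class ReferenceModel:
    """Pooled-normal coverage baseline: per-bin location (median of
    total-depth-normalized coverage), spread, and a reliability flag."""

    bins: pd.DataFrame  # BIN_COLUMNS + location, spread, reliable
    min_median_depth: float = 10.0


@dataclass
class CnSegment:
    chromosome: str
    start: int
    end: int
    n_bins: int
    mean_log2: float
    copy_number: int | None = None
    state: str | None = None


def _check_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    ka = a[BIN_COLUMNS[:3]].reset_index(drop=True)
    kb = b[BIN_COLUMNS[:3]].reset_index(drop=True)
    if len(ka) != len(kb) or not ka.equals(kb):
        raise ValueError("coverage tables are on different bin grids")


def build_reference(
    normals: list[pd.DataFrame], min_median_depth: float = 10.0
) -> ReferenceModel:
    """Build the pooled-normal reference from raw-depth coverage tables.

    Each sample is normalized by its mean bin depth before taking the
    per-bin median (location) and standard deviation (spread) across
    samples.  Bins whose median *raw* depth falls below
    ``min_median_depth`` are flagged unreliable and excluded from ratio
    computation downstream.
    """
    if not normals:
        raise ValueError("at least one normal sample required")
    first = normals[0]
    mat = np.empty((len(normals), len(first)))
    raw = np.empty_like(mat)
    for s, df in enumerate(normals):
        _check_grid(first, df)
        depth = df["depth"].to_numpy(dtype=float)
        total = depth.mean()
        if total <= 0:
            raise ValueError(f"normal sample {s} has zero total depth")
        raw[s] = depth
        mat[s] = depth / total
    bins = first[BIN_COLUMNS].copy().reset_index(drop=True)
    bins["location"] = np.median(mat, axis=0)
    bins["spread"] = mat.std(axis=0, ddof=0)
    bins["reliable"] = np.median(raw, axis=0) >= min_median_depth
    return ReferenceModel(bins=bins, min_median_depth=min_median_depth)


def log2_ratios(sample: pd.DataFrame, ref: ReferenceModel) -> pd.DataFrame:
    """Per-bin log2(sample/reference) on reliable bins, median-centered.

    The sample is total-depth normalized like the reference, so the ratios
    are invariant to global sequencing yield; zero-depth bins are floored
    at half a read to keep the ratio finite.
    """
    _check_grid(sample, ref.bins)
    keep = ref.bins["reliable"].to_numpy()
    loc = ref.bins["location"].to_numpy(dtype=float)
    if np.any(keep & (loc <= 0)):
        raise ValueError("zero reference location on a reliable bin")
    depth = sample["depth"].to_numpy(dtype=float)
    total = depth.mean()
    if total <= 0:
        raise ValueError("sample has zero total depth")
    norm = np.maximum(depth, 0.5) / total
    out = sample[BIN_COLUMNS].copy().reset_index(drop=True)
    out = out.loc[keep].reset_index(drop=True)
    ratio = np.log2(norm[keep] / loc[keep])
    ratio -= np.median(ratio)
    out["log2_ratio"] = ratio
    return out


def segment_coverage(
    coverage: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_bins: int = 3,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[CnSegment]:
    """Segment per-bin log2 ratios chromosome by chromosome."""
    if rng is None:
        rng = np.random.default_rng(seed)
    segments: list[CnSegment] = []
    for chrom, sub in coverage.groupby("chromosome", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        vals = sub["log2_ratio"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bps = cbs_segment(vals, alpha=alpha, n_perm=n_perm, min_bins=min_bins, rng=rng)
        bounds = [0, *bps, len(vals)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            segments.append(
                CnSegment(
                    chromosome=str(chrom),
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    n_bins=hi - lo,
                    mean_log2=float(vals[lo:hi].mean()),
                )
            )
    return segments


def _auto_shift(segments: list[CnSegment], cluster_gap: float = 0.2) -> float:
    """Bin-weighted modal segment mean: cluster segment means (split at gaps
    larger than ``cluster_gap``), take the cluster with the largest total
    bin weight, and return its bin-weighted mean.  Shift-invariant, hence
    recentering with it is idempotent."""
    means = np.array([s.mean_log2 for s in segments])
    weights = np.array([s.n_bins for s in segments], dtype=float)
    order = np.argsort(means, kind="mergesort")
    means, weights = means[order], weights[order]
    cluster_ids = np.concatenate([[0], np.cumsum(np.diff(means) > cluster_gap)])
    best, best_w = 0.0, -1.0
    for cid in np.unique(cluster_ids):
        m = cluster_ids == cid
        w = weights[m].sum()
        if w > best_w:
            best_w = w
            best = float(np.average(means[m], weights=weights[m]))
    return best


def recenter(
    segments: list[CnSegment],
    shift: float | str = "auto",
    purity: float | None = None,
    thresholds: CopyStateThresholds | None = None,
) -> list[CnSegment]:
    """Subtract a basal-ploidy shift from all segment means and recompute
    copy numbers/states.  ``shift="auto"`` uses the bin-weighted modal
    segment mean, restoring the modal copy class to log2 0."""
    if not segments:
        raise ValueError("no segments to recenter")
    if shift == "auto":
        shift = _auto_shift(segments)
    out = []
    for s in segments:
        s2 = replace(s, mean_log2=s.mean_log2 - float(shift))
        s2.copy_number = estimate_copies(s2.mean_log2, purity)
        s2.state = classify_copy_state(s2.copy_number, thresholds)
        out.append(s2)
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def estimate_copies(mean_log2: float, purity: float | None = None) -> int:
    """Integer copy number from a segment's mean log2 ratio.

    Without purity this is round(2 * 2**mean_log2).  With tumor purity p the
    admixture with diploid normal cells is inverted first:
    CN = (2 * 2**mean_log2 - 2(1-p)) / p, clipped at 0.  Halves round away
    from zero.
    """
    if not math.isfinite(mean_log2):
        raise ValueError("non-finite segment mean")
    absolute = 2.0 * 2.0**mean_log2
    if purity is None:
        return max(0, _round_half_away(absolute))
    if purity <= 0 or purity > 1:
        raise ValueError("purity must be in (0, 1]")
    cn = (absolute - 2.0 * (1.0 - purity)) / purity
    return max(0, _round_half_away(cn))


def classify_copy_state(
    copy_number: int, thresholds: CopyStateThresholds | None = None
) -> str:
    """Map an integer copy number to its copy-state class."""
    t = thresholds or CopyStateThresholds()
    if copy_number < 0:
        raise ValueError("copy number must be non-negative")
    if copy_number <= t.deep_max:
        return "deep_deletion"
    if copy_number <= t.shallow_max:
        return "shallow_deletion"
    if copy_number <= t.neutral_max:
        return "neutral"
    if copy_number <= t.gain_max:
        return "gain"
    return "amplification"


def call_copy_number(
    coverage: pd.DataFrame,
    purity: float | None = None,
    recenter_mode: float | str | None = None,
    thresholds: CopyStateThresholds | None = None,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_bins: int = 3,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[CnSegment]:
    """Coverage log2 ratios -> segmented, integer copy-number calls."""
    segments = segment_coverage(
        coverage, alpha=alpha, n_perm=n_perm, min_bins=min_bins, seed=seed, rng=rng
    )
    if recenter_mode is not None:
        return recenter(segments, recenter_mode, purity=purity, thresholds=thresholds)
    for s in segments:
        s.copy_number = estimate_copies(s.mean_log2, purity)
        s.state = classify_copy_state(s.copy_number, thresholds)
    return segments
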