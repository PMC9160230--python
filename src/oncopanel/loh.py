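"""Allelic-imbalance and LOH detection from heterozygous-SNP VAF deviations.

Informative SNPs are germline heterozygotes: population allele frequency
strictly inside a configured interval (default (0.0001, 0.95)), depth
strictly above a floor (default 30x), and observed VAF strictly inside
homozygote-exclusion cutoffs.  Their absolute deviations |VAF - 0.5| are
segmented per chromosome (on variant index, so panel gaps do not dominate
the arc statistics); a segment whose mean deviation reaches the threshold
(default 0.15) is called imbalanced.  With a matched normal, per-variant
VAF shifts |tumor - normal| add a paired-support flag.  Combining an
imbalanced segment with its copy-number state yields the LOH mechanism:
copy-neutral LOH at 2 copies, deletion-LOH at <=1, imbalanced gain at >=3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnv import CnSegment
from .filtering import VariantRecord
from .segmentation import cbs_segment

__all__ = [
    "HetVariant",
    "DevSegment",
    "LohCall",
    "select_informative",
    "deviation_series",
    "call_imbalance",
    "paired_shift",
    "classify_loh",
]

DEFAULT_AF_RANGE = (0.0001, 0.95)
DEFAULT_MIN_DEPTH = 30
DEFAULT_HOM_CUTOFFS = (0.05, 0.95)
DEFAULT_DEV_THRESHOLD = 0.15


@dataclass
class HetVariant:
    chromosome: str
    pos: int
    vaf: float
    depth: int
    population_af: float

    @property
    def deviation(self) -> float:
        return abs(self.vaf - 0.5)


@dataclass
class DevSegment:
    chromosome: str
    start: int
    end: int
    n_variants: int
    mean_deviation: float
    imbalance: bool
    low_confidence: bool = False
    paired_support: bool | None = None
    mean_shift: float | None = None
    variant_index: tuple[int, int] = (0, 0)  # per-chromosome index range


@dataclass
class LohCall:
    chromosome: str
    start: int
    end: int
    mechanism: str  # cnloh | deletion_loh | imbalanced_gain | unknown_copy_state | none
    copy_number: int | None = None
    paired_support: bool | None = None
    mean_deviation: float = 0.0


def select_informative(
    variants: list[VariantRecord],
    af_range: tuple[float, float] = DEFAULT_AF_RANGE,
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_cutoffs: tuple[float, float] | None = DEFAULT_HOM_CUTOFFS,
) -> list[HetVariant]:
    """Informative heterozygous SNPs, sorted by position.

    All bounds are strict: population AF strictly inside ``af_range``,
    depth strictly greater than ``min_depth``, VAF strictly inside
    ``hom_cutoffs`` (pass ``None`` to disable homozygote exclusion).
    """
    out = []
    for v in variants:
        if not (af_range[0] < v.population_af < af_range[1]):
            continue
        if v.depth <= min_depth:
            continue
        vaf = v.vaf
        if hom_cutoffs is not None and not (hom_cutoffs[0] < vaf < hom_cutoffs[1]):
            continue
        out.append(HetVariant(v.chromosome, v.pos, vaf, v.depth, v.population_af))
    out.sort(key=lambda h: (h.chromosome, h.pos))
    return out


def deviation_series(hets: list[HetVariant]) -> np.ndarray:
    """|VAF - 0.5| per variant, in input order."""
    return np.array([h.deviation for h in hets], dtype=float)


def call_imbalance(
    hets: list[HetVariant],
    threshold: float = DEFAULT_DEV_THRESHOLD,
    statistic: str = "mean",
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_bins: int = 3,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[DevSegment]:
    """Segment the deviation series per chromosome and flag imbalance.

    A segment is imbalanced when its mean (or median, per ``statistic``)
    deviation is at least ``threshold``.  Chromosomes with fewer than
    ``min_bins`` informative variants yield a single low-confidence
    segment.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    agg = np.median if statistic == "median" else np.mean
    segments: list[DevSegment] = []
    by_chrom: dict[str, list[HetVariant]] = {}
    for h in hets:
        by_chrom.setdefault(h.chromosome, []).append(h)
    for chrom, hs in by_chrom.items():
        hs.sort(key=lambda h: h.pos)
        devs = deviation_series(hs)
        if len(hs) < min_bins:
            val = float(agg(devs))
            segments.append(
                DevSegment(
                    chromosome=chrom,
                    start=hs[0].pos,
                    end=hs[-1].pos + 1,
                    n_variants=len(hs),
                    mean_deviation=val,
                    imbalance=val >= threshold,
                    low_confidence=True,
                    variant_index=(0, len(hs)),
                )
            )
            continue
        bps = cbs_segment(devs, alpha=alpha, n_perm=n_perm, min_bins=min_bins, rng=rng)
        bounds = [0, *bps, len(hs)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            val = float(agg(devs[lo:hi]))
            segments.append(
                DevSegment(
                    chromosome=chrom,
                    start=hs[lo].pos,
                    end=hs[hi - 1].pos + 1,
                    n_variants=hi - lo,
                    mean_deviation=val,
                    imbalance=val >= threshold,
                    variant_index=(lo, hi),
                )
            )
    segments.sort(key=lambda s: (s.chromosome, s.start))
    return segments


def paired_shift(
    normal_variants: list[VariantRecord],
    tumor_variants: list[VariantRecord],
    segments: list[DevSegment],
    shift_threshold: float = DEFAULT_DEV_THRESHOLD,
    hom_cutoffs: tuple[float, float] | None = DEFAULT_HOM_CUTOFFS,
) -> tuple[dict[tuple, float], list[DevSegment]]:
    """Per-variant |tumor VAF - normal VAF| at shared loci heterozygous in
    the normal, plus per-segment paired-support flags.

    A segment gains ``paired_support`` when the mean shift of its loci
    reaches ``shift_threshold``; segments with no shared het loci keep
    ``paired_support = None`` (absent).  With no shared loci at all the
    segments are returned unchanged.
    """
    cuts = hom_cutoffs or (0.0, 1.0)
    normal_by_key = {
        v.key: v for v in normal_variants if cuts[0] < v.vaf < cuts[1]
    }
    shifts: dict[tuple, float] = {}
    positions: dict[str, list[tuple[int, float]]] = {}
    for t in tumor_variants:
        n = normal_by_key.get(t.key)
        if n is None:
            continue
        s = abs(t.vaf - n.vaf)
        shifts[t.key] = s
        positions.setdefault(t.chromosome, []).append((t.pos, s))
    for seg in segments:
        in_seg = [
            s
            for pos, s in positions.get(seg.chromosome, [])
            if seg.start <= pos < seg.end
        ]
        if not in_seg:
            continue
        seg.mean_shift = float(np.mean(in_seg))
        seg.paired_support = seg.mean_shift >= shift_threshold
    return shifts, segments


def _majority_copy_number(
    chrom: str, start: int, end: int, cn_segments: list[CnSegment]
) -> int | None:
    """Copy number of the overlap-weighted majority state, weighting each
    overlapping CN segment by overlapped length times its bin density."""
    weights: dict[int, float] = {}
    for s in cn_segments:
        if s.chromosome != chrom or s.copy_number is None:
            continue
        ov = min(end, s.end) - max(start, s.start)
        if ov <= 0:
            continue
        density = s.n_bins / max(s.end - s.start, 1)
        weights[s.copy_number] = weights.get(s.copy_number, 0.0) + ov * density
    if not weights:
        return None
    return max(sorted(weights), key=lambda k: weights[k])


def classify_loh(
    dev_segments: list[DevSegment], cn_segments: list[CnSegment]
) -> list[LohCall]:
    """Combine imbalance flags with copy number into LOH mechanism calls.

    Imbalanced at 2 copies -> cnloh; at <=1 -> deletion_loh; at >=3 ->
    imbalanced_gain.  Balanced segments get mechanism "none"; imbalanced
    segments without copy-number information are reported with
    "unknown_copy_state".
    """
    calls = []
    for seg in dev_segments:
        cn = _majority_copy_number(seg.chromosome, seg.start, seg.end, cn_segments)
        if not seg.imbalance:
            mech = "none"
        elif cn is None:
            mech = "unknown_copy_state"
        elif cn <= 1:
            mech = "deletion_loh"
        elif cn == 2:
            mech = "cnloh"
        else:
            mech = "imbalanced_gain"
        calls.append(
            LohCall(
                chromosome=seg.chromosome,
                start=seg.start,
                end=seg.end,
                mechanism=mech,
                copy_number=cn,
                paired_support=seg.paired_support,
                mean_deviation=seg.mean_deviation,
            )
        )
    return calls
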