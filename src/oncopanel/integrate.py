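"""Gene-level integration of mutations, copy states and LOH calls.

Each (gene, sample) pair gets one alteration record with a mechanism label
drawn from a fixed priority table, a biallelic-inactivation flag, and — when
a mutation coexists with extra copies — a mutant-allele multiplicity
estimate m = VAF * (p*CN + 2(1-p)) / p that detects amplification of the
mutated allele.  Records across a cohort assemble into a genes x samples
matrix with per-gene alteration frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import CnSegment, CopyStateThresholds, classify_copy_state
from .filtering import GeneMutationSummary
from .loh import LohCall
from .simulate import TruthSample, expected_vaf

__all__ = [
    "GeneAlteration",
    "CohortMatrix",
    "MECHANISMS",
    "BIALLELIC_MECHANISMS",
    "multiplicity_estimate",
    "mechanism_label",
    "gene_copy_state",
    "gene_loh_mechanism",
    "integrate_gene_sample",
    "build_matrix",
    "truth_alterations",
]

MECHANISMS = [
    "multiple_mutations",
    "mutation_plus_deletion",
    "mutation_plus_cnloh",
    "mutant_allele_amplified",
    "deep_deletion",
    "amplification",
    "single_hit",
    "none",
]
BIALLELIC_MECHANISMS = {
    "multiple_mutations",
    "mutation_plus_deletion",
    "mutation_plus_cnloh",
    "mutant_allele_amplified",
    "deep_deletion",
}

MULTIPLICITY_AMP_THRESHOLD = 1.5
MULTIPLICITY_MIN_CN = 3


@dataclass(frozen=True)
class TruthMutationEvidence:
    """Minimal mutation evidence attached to truth-derived records (the
    planted driver mutations are pathogenic by construction)."""

    pathogenicity: str
    hotspot: bool = False


@dataclass
class GeneAlteration:
    gene: str
    sample_id: str
    mechanism_label: str
    biallelic: bool
    n_mutations: int = 0
    copy_number: int | None = None
    copy_state: str | None = None
    loh_mechanism: str | None = None
    multiplicity: float | None = None
    putative: bool = False  # multiplicity computed without a known purity
    inconsistent: bool = False
    mutations: list = field(default_factory=list)

    @property
    def altered(self) -> bool:
        return self.mechanism_label != "none"


@dataclass
class CohortMatrix:
    """Genes x samples mechanism-label grid with per-gene frequencies."""

    labels: pd.DataFrame  # index genes, columns samples
    mutated: pd.DataFrame  # boolean: >=1 non-benign small-scale mutation
    alterations: dict  # (gene, sample_id) -> GeneAlteration

    @property
    def frequencies(self) -> pd.Series:
        freq = (self.labels != "none").mean(axis=1)
        return freq.sort_values(ascending=False, kind="mergesort")

    @property
    def samples(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.labels.index)


def multiplicity_estimate(vaf: float, copy_number: int, purity: float) -> float:
    """Mutant-allele multiplicity: copies per tumor cell carrying the
    mutation, from its VAF under the admixture model."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    return vaf * (purity * copy_number + 2.0 * (1.0 - purity)) / purity


def mechanism_label(
    n_mutations: int,
    copy_state: str | None,
    loh_mechanism: str | None,
    multiplicity: float | None,
    copy_number: int | None,
) -> tuple[str, bool]:
    """Priority rule table mapping merged evidence to (label, biallelic)."""
    if copy_state == "deep_deletion":
        return "deep_deletion", True
    if n_mutations >= 2:
        return "multiple_mutations", True
    if n_mutations == 1:
        if copy_state == "shallow_deletion" or loh_mechanism == "deletion_loh":
            return "mutation_plus_deletion", True
        if loh_mechanism == "cnloh":
            return "mutation_plus_cnloh", True
        if (
            multiplicity is not None
            and copy_number is not None
            and multiplicity >= MULTIPLICITY_AMP_THRESHOLD
            and copy_number >= MULTIPLICITY_MIN_CN
        ):
            return "mutant_allele_amplified", True
        return "single_hit", False
    if copy_state == "amplification":
        return "amplification", False
    return "none", False


def gene_copy_state(
    chrom: str, start: int, end: int, cn_segments: list[CnSegment]
) -> tuple[int | None, str | None]:
    """Bin-weighted majority copy number/state over a gene's extent."""
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
        return None, None
    cn = max(sorted(weights), key=lambda k: weights[k])
    return cn, classify_copy_state(cn)


def gene_loh_mechanism(
    chrom: str,
    start: int,
    end: int,
    loh_calls: list[LohCall],
    copy_number: int | None = None,
) -> str | None:
    """Gene-level LOH mechanism: overlap-weighted majority imbalance vote
    over the gene's extent, combined with the gene's own copy number.

    A deviation segment can span adjacent genes in different copy states
    (their deviations may coincide), so the mechanism is re-derived from
    this gene's copy number rather than inherited from the segment."""
    w_imb = w_bal = 0.0
    for call in loh_calls:
        if call.chromosome != chrom:
            continue
        ov = min(end, call.end) - max(start, call.start)
        if ov <= 0:
            continue
        if call.mechanism == "none":
            w_bal += ov
        else:
            w_imb += ov
    if w_imb + w_bal == 0:
        return None
    if w_imb <= w_bal:
        return "none"
    if copy_number is None:
        return "unknown_copy_state"
    if copy_number <= 1:
        return "deletion_loh"
    if copy_number == 2:
        return "cnloh"
    return "imbalanced_gain"


def integrate_gene_sample(
    gene: str,
    sample_id: str,
    summary: GeneMutationSummary | None,
    copy_number: int | None,
    copy_state: str | None,
    loh_mechanism: str | None,
    purity: float | None = None,
) -> GeneAlteration:
    """Merge one gene/sample's evidence into an alteration record.

    With an unknown purity the multiplicity uses purity 1 and the record is
    marked putative.  A mutation observed at good VAF inside a called deep
    deletion is flagged inconsistent (but still integrated).
    """
    n_mut = summary.n_mutations if summary else 0
    mult = None
    putative = False
    if summary and n_mut >= 1 and copy_number is not None:
        p = purity if purity is not None else 1.0
        putative = purity is None
        mult = multiplicity_estimate(summary.max_vaf, copy_number, p)
    label, biallelic = mechanism_label(n_mut, copy_state, loh_mechanism, mult, copy_number)
    inconsistent = bool(
        copy_state == "deep_deletion" and summary and summary.max_vaf > 0.1
    )
    return GeneAlteration(
        gene=gene,
        sample_id=sample_id,
        mechanism_label=label,
        biallelic=biallelic,
        n_mutations=n_mut,
        copy_number=copy_number,
        copy_state=copy_state,
        loh_mechanism=loh_mechanism,
        multiplicity=mult,
        putative=putative,
        inconsistent=inconsistent,
        mutations=list(summary.mutations) if summary else [],
    )


def build_matrix(alterations: list[GeneAlteration]) -> CohortMatrix:
    """Assemble per-(gene, sample) records into the cohort matrix."""
    if not alterations:
        raise ValueError("empty cohort")
    seen = set()
    for a in alterations:
        key = (a.gene, a.sample_id)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
    genes = list(dict.fromkeys(a.gene for a in alterations))
    samples = list(dict.fromkeys(a.sample_id for a in alterations))
    labels = pd.DataFrame("none", index=genes, columns=samples, dtype=object)
    mutated = pd.DataFrame(False, index=genes, columns=samples)
    store = {}
    for a in alterations:
        labels.loc[a.gene, a.sample_id] = a.mechanism_label
        mutated.loc[a.gene, a.sample_id] = a.n_mutations >= 1
        store[(a.gene, a.sample_id)] = a
    return CohortMatrix(labels=labels, mutated=mutated, alterations=store)


def truth_alterations(
    truths: list[TruthSample],
    dev_threshold: float = 0.15,
    thresholds: CopyStateThresholds | None = None,
) -> list[GeneAlteration]:
    """Truth-derived alteration records, applying the same rule table to the
    simulator's ground truth (true copy numbers, expected VAF deviations,
    true multiplicities) — the oracle an end-to-end run is scored against."""
    out = []
    for t in truths:
        for seg in t.segments:
            state = classify_copy_state(seg.total_copies, thresholds)
            # expected |VAF - 0.5| of an observable germline het in this segment
            if seg.total_copies > 0 and (t.purity < 1 or seg.total_copies > 0):
                try:
                    dev = abs(
                        expected_vaf(t.purity, seg.total_copies, seg.minor_copies, 1)
                        - 0.5
                    )
                except ValueError:
                    dev = 0.0
            else:
                dev = 0.0
            imbalanced = dev >= dev_threshold
            if not imbalanced:
                loh = "none"
            elif seg.total_copies <= 1:
                loh = "deletion_loh"
            elif seg.total_copies == 2:
                loh = "cnloh"
            else:
                loh = "imbalanced_gain"
            muts = [
                v
                for v in t.variants
                if v.gene == seg.gene
                and v.origin == "somatic"
                and v.annotation in ("truncating", "missense_pathogenic")
            ]
            mult = float(max((v.multiplicity for v in muts), default=0)) if muts else None
            label, biallelic = mechanism_label(
                len(muts), state, loh, mult, seg.total_copies
            )
            evidence = [
                TruthMutationEvidence(pathogenicity="pathogenic", hotspot=v.hotspot)
                for v in muts
            ]
            out.append(
                GeneAlteration(
                    gene=seg.gene,
                    sample_id=t.sample_id,
                    mechanism_label=label,
                    biallelic=biallelic,
                    n_mutations=len(muts),
                    copy_number=seg.total_copies,
                    copy_state=state,
                    loh_mechanism=loh,
                    multiplicity=mult,
                    mutations=evidence,
                )
            )
    return out
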