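"""Somatic variant filtering and pathogenicity classification.

Raw per-sample variant tables are reduced to candidate somatic, non-benign
mutations by population-frequency, depth, panel-of-normals and (when a
matched normal exists) germline-subtraction rules, then classified by an
explicit precedence rule standing in for manual curation: an upstream
predictor verdict wins when present; otherwise truncating variants in tumor
suppressors and hotspot variants are pathogenic, silent variants benign,
everything else a VUS.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "GeneMutationSummary",
    "TRUNCATING",
    "CONSEQUENCES",
    "build_pon",
    "filter_common",
    "classify_pathogenicity",
    "collapse_to_gene",
]

CONSEQUENCES = {"nonsense", "frameshift", "splice_site", "missense", "silent", "other"}
TRUNCATING = {"nonsense", "frameshift", "splice_site"}


@dataclass
class VariantRecord:
    """One observed variant in one sample (0-based position)."""

    sample_id: str
    chromosome: str
    pos: int
    ref: str
    alt: str
    gene: str
    depth: int
    alt_count: int
    population_af: float = 0.0
    consequence: str = "other"
    predicted_class: str | None = None  # pathogenic | benign | vus
    hotspot: bool = False
    matched_normal_present: bool | None = None
    pathogenicity: str | None = None  # filled by classify_pathogenicity

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the common-variation / quality filter."""

    max_population_af: float = 0.001
    min_depth: int = 20
    min_alt_reads: int = 4
    pon_max_occurrence: int = 1
    treat_truncating_as_pathogenic: bool = True


@dataclass
class GeneMutationSummary:
    """Non-benign mutations of one gene in one sample."""

    gene: str
    sample_id: str
    mutations: list[VariantRecord] = field(default_factory=list)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def multi_mutation(self) -> bool:
        return len(self.mutations) >= 2

    @property
    def has_truncating(self) -> bool:
        return any(m.consequence in TRUNCATING for m in self.mutations)

    @property
    def has_pathogenic(self) -> bool:
        return any(m.pathogenicity == "pathogenic" for m in self.mutations)

    @property
    def max_vaf(self) -> float:
        return max((m.vaf for m in self.mutations), default=0.0)


def build_pon(normal_variant_tables: list[list[VariantRecord]]) -> Counter:
    """Panel-of-normals occurrence counts: how many normal samples carry
    each (chromosome, pos, ref, alt)."""
    pon: Counter = Counter()
    for table in normal_variant_tables:
        for key in {v.key for v in table}:
            pon[key] += 1
    return pon


def filter_common(
    variants: list[VariantRecord],
    config: FilterConfig | None = None,
    pon: Counter | dict | None = None,
) -> list[VariantRecord]:
    """Remove common genetic variation and low-quality calls.

    Keeps variants with population AF at most ``max_population_af``, depth
    and alt-read support above the floors, and panel-of-normals occurrence
    at most ``pon_max_occurrence``.  Variants seen in the sample's matched
    normal are dropped (somatic definition); records without matched-normal
    information pass that check vacuously (tumor-only mode).
    """
    cfg = config or FilterConfig()
    pon = pon or {}
    kept = []
    for v in variants:
        if v.population_af > cfg.max_population_af:
            continue
        if v.depth < cfg.min_depth or v.alt_count < cfg.min_alt_reads:
            continue
        if pon.get(v.key, 0) > cfg.pon_max_occurrence:
            continue
        if v.matched_normal_present:
            continue
        kept.append(v)
    return kept


def classify_pathogenicity(
    variant: VariantRecord,
    gene_role: str = "other",
    config: FilterConfig | None = None,
) -> str:
    """Rule-based pathogenicity: predictor verdict, then truncating-in-TSG
    and hotspot rules, then silent -> benign, default VUS."""
    cfg = config or FilterConfig()
    if variant.predicted_class in {"pathogenic", "benign", "vus"}:
        return variant.predicted_class
    if variant.consequence not in CONSEQUENCES:
        warnings.warn(
            f"unknown consequence {variant.consequence!r}; classified as vus",
            stacklevel=2,
        )
        return "vus"
    if (
        cfg.treat_truncating_as_pathogenic
        and variant.consequence in TRUNCATING
        and gene_role == "tumor_suppressor"
    ):
        return "pathogenic"
    if variant.hotspot:
        return "pathogenic"
    if variant.consequence == "silent":
        return "benign"
    return "vus"


def collapse_to_gene(
    variants: list[VariantRecord],
    gene_roles: dict[str, str] | None = None,
    config: FilterConfig | None = None,
) -> dict[str, GeneMutationSummary]:
    """Per-gene summaries of one sample's non-benign mutations.

    Classifies each variant (filling ``pathogenicity``), drops benign ones,
    and groups the rest by gene; genes with only benign variants are absent
    from the result.
    """
    roles = gene_roles or {}
    out: dict[str, GeneMutationSummary] = {}
    for v in variants:
        v.pathogenicity = classify_pathogenicity(v, roles.get(v.gene, "other"), config)
        if v.pathogenicity == "benign":
            continue
        summary = out.setdefault(v.gene, GeneMutationSummary(v.gene, v.sample_id))
        summary.mutations.append(v)
    return out
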