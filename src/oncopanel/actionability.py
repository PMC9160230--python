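"""Actionability / prognostic-marker rules over gene alteration records.

The strict rule set keeps pathogenic or hotspot mutations, deep deletions,
and amplifications reaching a copy floor (default 5 total copies), while
eliminating shallow deletions without a second hit, low-level gains and
VUS-only genes.  Each qualifying gene maps to a pathway group, and a cohort
summary reports the fraction of samples carrying at least one qualifying
alteration, overall and per pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .integrate import CohortMatrix, GeneAlteration
from .simulate import GENE_PATHWAYS

__all__ = [
    "ActionabilityRules",
    "Verdict",
    "PATHWAYS",
    "classify_actionable",
    "assign_pathway",
    "cohort_actionable_fraction",
]

PATHWAYS = ["RTK_RAS_PI3K", "cell_cycle", "DNA_repair", "Notch_WNT", "chromatin", "other"]


@dataclass(frozen=True)
class ActionabilityRules:
    min_amplification_copies: int = 5
    allow_deep_deletion: bool = True
    exclude_shallow_without_second_hit: bool = True
    pathway_map: dict = field(default_factory=lambda: dict(GENE_PATHWAYS))

    def __post_init__(self):
        if self.min_amplification_copies < 3:
            raise ValueError("min_amplification_copies must be at least 3")


@dataclass(frozen=True)
class Verdict:
    gene: str
    sample_id: str
    actionable: bool
    reason: str
    pathway: str


def assign_pathway(gene: str, pathway_map: dict | None = None) -> str:
    m = pathway_map if pathway_map is not None else GENE_PATHWAYS
    return m.get(gene, "other")


def _has_qualifying_mutation(alt: GeneAlteration) -> bool:
    return any(
        m.pathogenicity == "pathogenic" or m.hotspot for m in alt.mutations
    )


def classify_actionable(
    alt: GeneAlteration, rules: ActionabilityRules | None = None
) -> Verdict:
    """Apply the rule set to one alteration record.

    Pure function of (record, rules): pathogenic/hotspot mutations, deep
    deletions and sufficiently high amplifications are actionable; shallow
    deletions without a second hit and VUS-only genes are excluded.
    """
    rules = rules or ActionabilityRules()
    pathway = assign_pathway(alt.gene, rules.pathway_map)
    if _has_qualifying_mutation(alt):
        return Verdict(alt.gene, alt.sample_id, True, "pathogenic_mutation", pathway)
    if alt.copy_number is not None and alt.copy_number >= rules.min_amplification_copies:
        return Verdict(alt.gene, alt.sample_id, True, "amplification", pathway)
    if alt.copy_state == "deep_deletion" and rules.allow_deep_deletion:
        return Verdict(alt.gene, alt.sample_id, True, "deep_deletion", pathway)
    if (
        alt.copy_state == "shallow_deletion"
        and rules.exclude_shallow_without_second_hit
        and alt.n_mutations == 0
        and alt.loh_mechanism in (None, "none")
    ):
        return Verdict(alt.gene, alt.sample_id, False, "shallow_no_second_hit", pathway)
    if alt.n_mutations >= 1:
        return Verdict(alt.gene, alt.sample_id, False, "vus_only", pathway)
    return Verdict(alt.gene, alt.sample_id, False, "no_qualifying_event", pathway)


def cohort_actionable_fraction(
    matrix: CohortMatrix, rules: ActionabilityRules | None = None
) -> tuple[float, dict[str, float], list[Verdict]]:
    """Fraction of samples with >=1 actionable alteration, per-pathway
    breakdown, and all per-(gene, sample) verdicts."""
    rules = rules or ActionabilityRules()
    samples = matrix.samples
    if not samples:
        raise ValueError("empty cohort")
    verdicts = [classify_actionable(a, rules) for a in matrix.alterations.values()]
    hit: set[str] = set()
    per_pathway: dict[str, set[str]] = {}
    for v in verdicts:
        if v.actionable:
            hit.add(v.sample_id)
            per_pathway.setdefault(v.pathway, set()).add(v.sample_id)
    fraction = len(hit) / len(samples)
    breakdown = {pw: len(s) / len(samples) for pw, s in sorted(per_pathway.items())}
    return fraction, breakdown, verdicts
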