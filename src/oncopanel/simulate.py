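"""Synthetic tumor-cohort simulator with known ground truth.

Emulates the observed data a tumor-only targeted-panel pipeline consumes:
per-bin coverage log2 ratios, per-sample variant tables (germline SNPs with
population allele frequencies, somatic driver mutations, technical
artifacts), and matched-normal tables for a subset of samples — all driven
by a per-sample truth profile (purity, per-gene total/minor copy numbers,
variant multiplicities).

The observation model is the standard admixture model: a locus with total
tumor copies T, mutant multiplicity m, tumor purity p and g germline copies
in the contaminating normal has expected VAF

    (p*m + (1-p)*g) / (p*T + (1-p)*2),

and a segment's expected coverage log2 ratio is log2((p*T + (1-p)*2)/2).
Read depths are negative-binomial (capture data is overdispersed) and alt
counts binomial at the expected VAF.  Identical seeds give identical
cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .filtering import VariantRecord

__all__ = [
    "PanelDesign",
    "TruthSegment",
    "TruthVariant",
    "TruthSample",
    "SimConfig",
    "GeneEvents",
    "ObservedSample",
    "CohortBundle",
    "default_panel",
    "DEFAULT_GENE_INFO",
    "DEFAULT_EVENT_TABLE",
    "GENE_ROLES",
    "expected_vaf",
    "generate_cohort",
    "simulate_normal_coverage",
    "write_truth",
    "read_truth",
]

BIN_SIZE = 400
BINS_PER_GENE = 24
RATIO_FLOOR = 1.0 / 64.0  # coverage ratio floor keeping log2 finite at CN 0

#: gene, chromosome, panel start, role, pathway — the recurrently altered
#: head-and-neck genes the default panel targets (autosomes only)
DEFAULT_GENE_INFO = [
    ("ARID1A", "chr1", 27_000_000, "tumor_suppressor", "chromatin"),
    ("CASP8", "chr2", 202_100_000, "tumor_suppressor", "other"),
    ("PIK3CA", "chr3", 178_900_000, "oncogene", "RTK_RAS_PI3K"),
    ("FAT1", "chr4", 187_500_000, "tumor_suppressor", "Notch_WNT"),
    ("EGFR", "chr7", 55_000_000, "oncogene", "RTK_RAS_PI3K"),
    ("KMT2C", "chr7", 151_800_000, "tumor_suppressor", "chromatin"),
    ("CDKN2A", "chr9", 21_900_000, "tumor_suppressor", "cell_cycle"),
    ("NOTCH1", "chr9", 139_300_000, "tumor_suppressor", "Notch_WNT"),
    ("PTEN", "chr10", 89_600_000, "tumor_suppressor", "RTK_RAS_PI3K"),
    ("HRAS", "chr11", 530_000, "oncogene", "RTK_RAS_PI3K"),
    ("CCND1", "chr11", 69_400_000, "oncogene", "cell_cycle"),
    ("ATM", "chr11", 108_000_000, "tumor_suppressor", "DNA_repair"),
    ("KMT2D", "chr12", 49_400_000, "tumor_suppressor", "chromatin"),
    ("BRCA2", "chr13", 32_800_000, "tumor_suppressor", "DNA_repair"),
    ("TP53", "chr17", 7_500_000, "tumor_suppressor", "cell_cycle"),
    ("NF1", "chr17", 29_400_000, "tumor_suppressor", "RTK_RAS_PI3K"),
]

GENE_ROLES = {g: role for g, _, _, role, _ in DEFAULT_GENE_INFO}
GENE_PATHWAYS = {g: pw for g, _, _, _, pw in DEFAULT_GENE_INFO}

#: copy-event name -> (total copies, minor copies)
COPY_EVENTS = {
    "neutral": (2, 1),
    "shallow_deletion": (1, 0),
    "cnloh": (2, 0),
    "deep_deletion": (0, 0),
    "gain": (3, 1),
    "amplification": (6, 1),
}


@dataclass(frozen=True)
class GeneEvents:
    """Per-gene event probabilities: a categorical copy event (remainder is
    copy-neutral) and an independent mutation channel."""

    p_mutation: float = 0.0
    p_second_mutation: float = 0.2  # conditional on a first mutation
    copy_probs: dict = field(default_factory=dict)  # event -> probability

    def __post_init__(self):
        probs = list(self.copy_probs.values()) + [self.p_mutation, self.p_second_mutation]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("event probabilities must lie in [0, 1]")
        if sum(self.copy_probs.values()) > 1 + 1e-9:
            raise ValueError("copy-event probabilities sum to more than 1")
        if set(self.copy_probs) - (set(COPY_EVENTS) - {"neutral"}):
            raise ValueError(f"unknown copy event in {set(self.copy_probs)}")


#: default driver-event probabilities for the panel genes
DEFAULT_EVENT_TABLE = {
    "TP53": GeneEvents(0.75, 0.2, {"shallow_deletion": 0.25, "cnloh": 0.25,
                                   "gain": 0.05, "amplification": 0.05}),
    "FAT1": GeneEvents(0.50, 0.15, {"shallow_deletion": 0.30}),
    "NOTCH1": GeneEvents(0.40, 0.1, {"shallow_deletion": 0.15, "cnloh": 0.10}),
    "KMT2C": GeneEvents(0.35, 0.1, {"shallow_deletion": 0.25, "cnloh": 0.10}),
    "CDKN2A": GeneEvents(0.30, 0.1, {"deep_deletion": 0.20, "shallow_deletion": 0.20,
                                     "cnloh": 0.10}),
    "KMT2D": GeneEvents(0.30, 0.1, {"shallow_deletion": 0.15}),
    "CCND1": GeneEvents(0.05, 0.1, {"amplification": 0.20, "gain": 0.15}),
    "PIK3CA": GeneEvents(0.20, 0.1, {"gain": 0.10, "amplification": 0.05}),
    "EGFR": GeneEvents(0.10, 0.1, {"amplification": 0.15, "gain": 0.10}),
    "PTEN": GeneEvents(0.10, 0.1, {"deep_deletion": 0.05, "shallow_deletion": 0.10}),
    "HRAS": GeneEvents(0.05, 0.0, {}),
    "CASP8": GeneEvents(0.10, 0.1, {}),
    "ATM": GeneEvents(0.05, 0.1, {"shallow_deletion": 0.30}),
    "BRCA2": GeneEvents(0.10, 0.1, {"shallow_deletion": 0.10, "cnloh": 0.05}),
    "ARID1A": GeneEvents(0.15, 0.1, {}),
    "NF1": GeneEvents(0.10, 0.1, {"deep_deletion": 0.03, "shallow_deletion": 0.10}),
}


@dataclass
class PanelDesign:
    """Targeted capture design: per-bin intervals, each assigned one gene."""

    intervals: pd.DataFrame  # chromosome, start, end, gene (0-based half-open)

    def __post_init__(self):
        df = self.intervals
        if len(df) == 0:
            raise ValueError("empty panel")
        if (df["start"] >= df["end"]).any():
            raise ValueError("panel intervals must satisfy start < end")
        for _, sub in df.groupby("chromosome"):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError("panel intervals overlap within a chromosome")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.intervals["gene"]))

    def gene_interval(self, gene: str) -> tuple[str, int, int]:
        sub = self.intervals[self.intervals["gene"] == gene]
        if len(sub) == 0:
            raise KeyError(gene)
        return str(sub["chromosome"].iloc[0]), int(sub["start"].min()), int(sub["end"].max())


def default_panel(
    bins_per_gene: int = BINS_PER_GENE, bin_size: int = BIN_SIZE
) -> PanelDesign:
    """Contiguously tiled bins over each default gene locus."""
    rows = []
    for gene, chrom, start, _, _ in DEFAULT_GENE_INFO:
        for b in range(bins_per_gene):
            rows.append((chrom, start + b * bin_size, start + (b + 1) * bin_size, gene))
    return PanelDesign(pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene"]))


@dataclass
class TruthSegment:
    chromosome: str
    start: int
    end: int
    gene: str
    total_copies: int
    minor_copies: int

    def __post_init__(self):
        if not 0 <= self.total_copies <= 60:
            raise ValueError("total copies out of range")
        if self.minor_copies > self.total_copies - self.minor_copies:
            raise ValueError("minor copies exceed the major allele count")


@dataclass
class TruthVariant:
    chromosome: str
    pos: int
    gene: str
    origin: str  # germline | somatic
    multiplicity: int
    population_af: float
    annotation: str  # truncating | missense_pathogenic | missense_benign | silent
    hotspot: bool = False
    germline_copies: int = 0  # copies in the contaminating normal (0, 1, 2)
    ref: str = "C"
    alt: str = "T"

    def __post_init__(self):
        if self.origin == "germline" and self.population_af <= 0:
            raise ValueError("germline variants need population_af > 0")
        if self.origin == "somatic" and self.population_af != 0:
            raise ValueError("somatic variants have population_af = 0")


@dataclass
class TruthSample:
    sample_id: str
    purity: float
    segments: list[TruthSegment]
    variants: list[TruthVariant]
    has_matched_normal: bool = False

    def __post_init__(self):
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")

    def segment_for(self, gene: str) -> TruthSegment:
        for s in self.segments:
            if s.gene == gene:
                return s
        raise KeyError(gene)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation controls.

    Defaults mirror the study conditions the pipeline is meant for: 48
    tumor samples of which 13 have matched normals, ~150x mean tumor depth
    (overdispersed), log2 coverage noise 0.15, purity 0.6-0.9, and a
    common-SNP backbone dense enough that every gene segment carries
    >=20 informative heterozygotes.
    """

    n_samples: int = 48
    n_paired: int = 13
    mean_depth: float = 150.0
    normal_mean_depth: float = 100.0
    depth_dispersion: float | None = 10.0  # NB shape k; None -> deterministic
    log2_noise_sd: float = 0.15
    binomial_sampling: bool = True
    het_snp_density: float = 2.5  # germline SNPs per kb of panel
    hom_snp_fraction: float = 0.25
    purity_range: tuple[float, float] = (0.6, 0.9)
    n_artifact_loci: int = 5
    artifact_prob: float = 0.8
    passenger_silent_rate: float = 1.0  # mean silent somatic passengers / sample
    passenger_benign_rate: float = 1.0
    driver_event_table: dict = field(
        default_factory=lambda: dict(DEFAULT_EVENT_TABLE)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_paired > self.n_samples:
            raise ValueError("n_paired exceeds n_samples")
        for name in (
            "mean_depth", "normal_mean_depth", "log2_noise_sd",
            "het_snp_density", "hom_snp_fraction", "passenger_silent_rate",
            "passenger_benign_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("purity_range must be ordered within [0, 1]")

    def noise_free(self) -> "SimConfig":
        """Deterministic-observation variant of this configuration: exact
        depths and VAFs, no coverage noise, purity 1, no homozygous SNPs
        (at purity 1 they are indistinguishable from LOH heterozygotes)."""
        return replace(
            self,
            depth_dispersion=None,
            log2_noise_sd=0.0,
            binomial_sampling=False,
            purity_range=(1.0, 1.0),
            hom_snp_fraction=0.0,
        )


@dataclass
class ObservedSample:
    sample_id: str
    purity: float
    coverage: pd.DataFrame  # chromosome, start, end, gene, log2_ratio
    variants: list[VariantRecord]
    normal_variants: list[VariantRecord] | None = None


@dataclass
class CohortBundle:
    panel: PanelDesign
    samples: list[ObservedSample]


class DegenerateLocusError(ValueError):
    """Raised when a locus has no DNA at all (purity 1 and zero copies)."""


def expected_vaf(
    purity: float,
    total_copies: int,
    multiplicity: int,
    germline_copies_in_normal: int,
) -> float:
    """Expected variant allele fraction under the admixture model."""
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    if multiplicity > total_copies:
        raise ValueError("multiplicity cannot exceed total copies")
    denom = purity * total_copies + (1.0 - purity) * 2.0
    if denom <= 0:
        raise DegenerateLocusError("no DNA at locus (purity 1, zero copies)")
    vaf = (purity * multiplicity + (1.0 - purity) * germline_copies_in_normal) / denom
    return min(1.0, max(0.0, vaf))


_BASES = np.array(list("ACGT"))


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = rng.integers(0, 4)
    j = (i + 1 + rng.integers(0, 3)) % 4
    return str(_BASES[i]), str(_BASES[j])


def _draw_depth(
    mean: float, dispersion: float | None, rng: np.random.Generator
) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(round(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _draw_alt(depth: int, evaf: float, binomial: bool, rng: np.random.Generator) -> int:
    if depth <= 0:
        return 0
    if binomial:
        return int(rng.binomial(depth, evaf))
    return int(round(depth * evaf))


def _population_af(rng: np.random.Generator) -> float:
    """Mixture favoring common variants, with tails on both sides of the
    informativeness window (0.0001, 0.95) so the filter has work to do."""
    u = rng.random()
    if u < 0.80:
        return float(rng.uniform(0.05, 0.50))
    if u < 0.90:
        return float(10.0 ** rng.uniform(-6.0, -4.5))
    return float(rng.uniform(0.96, 0.995))


def _sample_truth(
    sample_id: str,
    paired: bool,
    config: SimConfig,
    panel: PanelDesign,
    rng: np.random.Generator,
) -> TruthSample:
    lo, hi = config.purity_range
    purity = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    segments: list[TruthSegment] = []
    variants: list[TruthVariant] = []
    for gene in panel.genes:
        chrom, gstart, gend = panel.gene_interval(gene)
        events = config.driver_event_table.get(gene, GeneEvents())
        names = list(events.copy_probs)
        probs = [events.copy_probs[n] for n in names]
        names.append("neutral")
        probs.append(1.0 - sum(probs))
        event = names[rng.choice(len(names), p=np.asarray(probs) / sum(probs))]
        total, minor = COPY_EVENTS[event]
        segments.append(TruthSegment(chrom, gstart, gend, gene, total, minor))
        major = total - minor

        # somatic driver mutations (none on fully deleted loci)
        n_mut = 0
        if total > 0 and rng.random() < events.p_mutation:
            n_mut = 1 + int(rng.random() < events.p_second_mutation)
        positions = set()
        role = GENE_ROLES.get(gene, "tumor_suppressor")
        for _ in range(n_mut):
            pos = int(rng.integers(gstart, gend))
            while pos in positions:
                pos = int(rng.integers(gstart, gend))
            positions.add(pos)
            mult = major if (minor == 0 or rng.random() < 0.8) else minor
            mult = max(1, mult)
            if role == "oncogene":
                ann, hot = "missense_pathogenic", True
            else:
                ann = "truncating" if rng.random() < 0.8 else "missense_pathogenic"
                hot = False
            ref, alt = _draw_alleles(rng)
            variants.append(
                TruthVariant(chrom, pos, gene, "somatic", mult, 0.0, ann,
                             hotspot=hot, germline_copies=0, ref=ref, alt=alt)
            )

        # germline SNP backbone
        length_kb = (gend - gstart) / 1000.0
        n_snp = int(rng.poisson(config.het_snp_density * length_kb))
        snp_pos = sorted(
            set(int(p) for p in rng.integers(gstart, gend, size=n_snp)) - positions
        )
        # Heterozygous SNPs alternate between the two parental haplotypes
        # (random starting side).  The deviation statistic is symmetric in
        # the carrier haplotype, so alternation is statistically inert
        # downstream while keeping both haplotypes represented even in
        # segments with few SNPs.
        on_minor = rng.random() < 0.5
        for pos in snp_pos:
            af = _population_af(rng)
            ref, alt = _draw_alleles(rng)
            if rng.random() < config.hom_snp_fraction:
                variants.append(
                    TruthVariant(chrom, pos, gene, "germline", total, af,
                                 "silent" if rng.random() < 0.5 else "missense_benign",
                                 germline_copies=2, ref=ref, alt=alt)
                )
            else:
                mult = minor if on_minor else major
                on_minor = not on_minor
                variants.append(
                    TruthVariant(chrom, pos, gene, "germline", mult, af,
                                 "silent" if rng.random() < 0.5 else "missense_benign",
                                 germline_copies=1, ref=ref, alt=alt)
                )

    # silent / predicted-benign somatic passengers
    for rate, ann in (
        (config.passenger_silent_rate, "silent"),
        (config.passenger_benign_rate, "missense_benign"),
    ):
        for _ in range(int(rng.poisson(rate))):
            row = panel.intervals.iloc[int(rng.integers(0, len(panel.intervals)))]
            seg = next(s for s in segments if s.gene == row["gene"])
            if seg.total_copies == 0:
                continue
            pos = int(rng.integers(row["start"], row["end"]))
            ref, alt = _draw_alleles(rng)
            variants.append(
                TruthVariant(str(row["chromosome"]), pos, str(row["gene"]), "somatic",
                             1, 0.0, ann, germline_copies=0, ref=ref, alt=alt)
            )
    variants.sort(key=lambda v: (v.chromosome, v.pos))
    return TruthSample(sample_id, purity, segments, variants, has_matched_normal=paired)


def _consequence_of(annotation: str, rng: np.random.Generator) -> tuple[str, str | None]:
    """Map a truth annotation to an observed consequence + predictor label."""
    if annotation == "truncating":
        return str(rng.choice(["nonsense", "frameshift", "splice_site"])), None
    if annotation == "missense_pathogenic":
        return "missense", "pathogenic"
    if annotation == "missense_benign":
        return "missense", "benign"
    return "silent", None


def _observe_sample(
    truth: TruthSample,
    config: SimConfig,
    panel: PanelDesign,
    artifacts: list[tuple[str, int, str, str, str]],
    rng: np.random.Generator,
) -> ObservedSample:
    p = truth.purity
    seg_by_gene = {s.gene: s for s in truth.segments}

    # coverage log2 ratios
    cov = panel.intervals.copy().reset_index(drop=True)
    ratios = np.array(
        [
            max(
                (p * seg_by_gene[g].total_copies + (1 - p) * 2.0) / 2.0,
                RATIO_FLOOR,
            )
            for g in cov["gene"]
        ]
    )
    noise = (
        rng.normal(0.0, config.log2_noise_sd, size=len(cov))
        if config.log2_noise_sd > 0
        else 0.0
    )
    cov["log2_ratio"] = np.log2(ratios) + noise

    # tumor variant table
    tumor: list[VariantRecord] = []
    normal: list[VariantRecord] | None = [] if truth.has_matched_normal else None
    for v in truth.variants:
        seg = seg_by_gene[v.gene]
        ratio = (p * seg.total_copies + (1 - p) * 2.0) / 2.0
        mu = config.mean_depth * ratio
        depth = _draw_depth(mu, config.depth_dispersion, rng)
        if depth <= 0:
            alt_count = 0
        else:
            evaf = expected_vaf(p, seg.total_copies, v.multiplicity, v.germline_copies)
            alt_count = _draw_alt(depth, evaf, config.binomial_sampling, rng)
        consequence, predicted = _consequence_of(v.annotation, rng)
        if alt_count > 0:
            tumor.append(
                VariantRecord(
                    sample_id=truth.sample_id,
                    chromosome=v.chromosome, pos=v.pos, ref=v.ref, alt=v.alt,
                    gene=v.gene, depth=depth, alt_count=alt_count,
                    population_af=v.population_af, consequence=consequence,
                    predicted_class=predicted, hotspot=v.hotspot,
                    matched_normal_present=(
                        (v.origin == "germline") if truth.has_matched_normal else None
                    ),
                )
            )
        if normal is not None and v.origin == "germline":
            ndepth = _draw_depth(config.normal_mean_depth, config.depth_dispersion, rng)
            nvaf = 1.0 if v.germline_copies == 2 else 0.5
            nalt = _draw_alt(ndepth, nvaf, config.binomial_sampling, rng)
            if nalt > 0:
                normal.append(
                    VariantRecord(
                        sample_id=truth.sample_id + "_N",
                        chromosome=v.chromosome, pos=v.pos, ref=v.ref, alt=v.alt,
                        gene=v.gene, depth=ndepth, alt_count=nalt,
                        population_af=v.population_af, consequence=consequence,
                        predicted_class=predicted,
                    )
                )

    # recurrent technical artifacts (shared loci across samples)
    for chrom, pos, ref, alt, gene in artifacts:
        for table, mean in ((tumor, config.mean_depth), (normal, config.normal_mean_depth)):
            if table is None:
                continue
            if rng.random() >= config.artifact_prob:
                continue
            depth = _draw_depth(mean, config.depth_dispersion, rng)
            alt_count = _draw_alt(
                depth, float(rng.uniform(0.05, 0.15)), config.binomial_sampling, rng
            )
            if depth > 0 and alt_count > 0:
                table.append(
                    VariantRecord(
                        sample_id=truth.sample_id if table is tumor else truth.sample_id + "_N",
                        chromosome=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                        depth=depth, alt_count=max(alt_count, 1),
                        population_af=0.0, consequence="missense",
                    )
                )
    tumor.sort(key=lambda v: (v.chromosome, v.pos))
    if normal is not None:
        normal.sort(key=lambda v: (v.chromosome, v.pos))
        normal_keys = {v.key for v in normal}
        for v in tumor:
            v.matched_normal_present = v.key in normal_keys
    return ObservedSample(truth.sample_id, p, cov, tumor, normal)


def generate_cohort(
    config: SimConfig | None = None, panel: PanelDesign | None = None
) -> tuple[list[TruthSample], CohortBundle]:
    """Simulate a cohort: truth profiles plus the observed data bundle."""
    config = config or SimConfig()
    panel = panel or default_panel()
    root = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    artifacts = []
    for _ in range(config.n_artifact_loci):
        row = panel.intervals.iloc[int(cohort_rng.integers(0, len(panel.intervals)))]
        pos = int(cohort_rng.integers(row["start"], row["end"]))
        ref, alt = _draw_alleles(cohort_rng)
        artifacts.append((str(row["chromosome"]), pos, ref, alt, str(row["gene"])))

    truths: list[TruthSample] = []
    observed: list[ObservedSample] = []
    child_seeds = root.spawn(config.n_samples + 1)[1:]
    for idx in range(config.n_samples):
        rng = np.random.default_rng(child_seeds[idx])
        sample_id = f"S{idx + 1:02d}"
        truth = _sample_truth(sample_id, idx < config.n_paired, config, panel, rng)
        truths.append(truth)
        observed.append(_observe_sample(truth, config, panel, artifacts, rng))
    return truths, CohortBundle(panel=panel, samples=observed)


def simulate_normal_coverage(
    panel: PanelDesign,
    n_samples: int,
    mean_depth: float = 100.0,
    dispersion: float | None = 20.0,
    bias_sd: float = 0.3,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Raw-depth coverage tables for a pool of diploid normals, sharing a
    per-bin capture-efficiency bias (lognormal)."""
    rng = np.random.default_rng(seed)
    bias = np.exp(rng.normal(0.0, bias_sd, size=len(panel.intervals)))
    out = []
    for s in range(n_samples):
        df = panel.intervals.copy().reset_index(drop=True)
        mu = mean_depth * bias
        if dispersion is None:
            depth = np.round(mu)
        else:
            pr = dispersion / (dispersion + mu)
            depth = rng.negative_binomial(dispersion, pr)
        df["depth"] = depth.astype(int)
        out.append(df)
    return out


def _variant_to_dict(v: TruthVariant) -> dict:
    return dataclasses.asdict(v)


def write_truth(truths: list[TruthSample], path: str | Path) -> None:
    """Round-trippable JSON serialization of the cohort ground truth."""
    if not truths:
        raise ValueError("no truth records to write")
    payload = [
        {
            "sample_id": t.sample_id,
            "purity": t.purity,
            "has_matched_normal": t.has_matched_normal,
            "segments": [dataclasses.asdict(s) for s in t.segments],
            "variants": [_variant_to_dict(v) for v in t.variants],
        }
        for t in truths
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> list[TruthSample]:
    payload = json.loads(Path(path).read_text())
    out = []
    for rec in payload:
        out.append(
            TruthSample(
                sample_id=rec["sample_id"],
                purity=rec["purity"],
                segments=[TruthSegment(**s) for s in rec["segments"]],
                variants=[TruthVariant(**v) for v in rec["variants"]],
                has_matched_normal=rec["has_matched_normal"],
            )
        )
    return out
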