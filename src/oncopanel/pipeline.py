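"""End-to-end pipeline: simulate (or load) -> copy number -> allelic
imbalance -> variant filtering -> gene integration -> actionability
[-> cohort comparison], with a summary JSON recording parameters and
per-stage counts.  A single seed is fanned out into independent per-stage
substreams, so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .actionability import ActionabilityRules, cohort_actionable_fraction
from .cnv import CopyStateThresholds, call_copy_number
from .compare import compare_cohorts
from .filtering import FilterConfig, build_pon, collapse_to_gene, filter_common
from .integrate import (
    build_matrix,
    gene_copy_state,
    gene_loh_mechanism,
    integrate_gene_sample,
)
from .loh import (
    DEFAULT_AF_RANGE,
    DEFAULT_DEV_THRESHOLD,
    DEFAULT_HOM_CUTOFFS,
    DEFAULT_MIN_DEPTH,
    call_imbalance,
    classify_loh,
    paired_shift,
    select_informative,
)
from .simulate import GENE_ROLES, SimConfig, generate_cohort, write_truth

log = logging.getLogger("oncopanel")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline configuration; unknown keys in a config file are rejected."""

    out_dir: str = "oncopanel_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    noise_free: bool = False
    use_true_purity: bool = True
    cnv: dict = field(default_factory=dict)  # alpha, n_perm, min_bins, recenter
    loh: dict = field(default_factory=dict)  # threshold, hom_cutoffs, ...
    filter: dict = field(default_factory=dict)  # FilterConfig overrides
    actionability: dict = field(default_factory=dict)  # ActionabilityRules overrides
    compare: dict = field(default_factory=dict)  # group_1 / group_2 sample lists

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    sim = SimConfig(seed=cfg.seed, **cfg.simulate)
    return sim.noise_free() if cfg.noise_free else sim


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages on a simulated cohort; write outputs under
    ``cfg.out_dir`` and return the summary dictionary."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}

    sim = _sim_config(cfg)
    truths, bundle = generate_cohort(sim)
    write_truth(truths, out / "truth.json")
    io.write_panel_bed(bundle.panel, out / "panel.bed")
    summary["parameters"] = {
        "simulate": {
            k: v for k, v in dataclasses.asdict(sim).items()
            if k != "driver_event_table"
        },
        "cnv": cfg.cnv,
        "loh": cfg.loh,
        "filter": cfg.filter,
        "noise_free": cfg.noise_free,
    }
    summary["stages"]["simulate"] = {
        "n_samples": len(bundle.samples),
        "n_paired": sum(s.normal_variants is not None for s in bundle.samples),
        "n_variants": sum(len(s.variants) for s in bundle.samples),
    }
    results = analyze_cohort(bundle, truths, cfg, out, summary)
    io.write_json(summary, out / "summary.json")
    return results


def analyze_cohort(bundle, truths, cfg: PipelineConfig, out: Path | None, summary: dict) -> dict:
    """Shared analysis core (also used without file output by tests and the
    acceptance script)."""
    panel = bundle.panel
    truth_by_id = {t.sample_id: t for t in truths} if truths else {}

    cnv_kwargs = dict(
        alpha=cfg.cnv.get("alpha", 0.01),
        n_perm=cfg.cnv.get("n_perm", 1000),
        min_bins=cfg.cnv.get("min_bins", 3),
    )
    recenter_mode = cfg.cnv.get("recenter", "auto")
    thresholds = CopyStateThresholds()
    loh_threshold = cfg.loh.get("threshold", DEFAULT_DEV_THRESHOLD)
    hom_cutoffs = cfg.loh.get("hom_cutoffs", list(DEFAULT_HOM_CUTOFFS))
    hom_cutoffs = tuple(hom_cutoffs) if hom_cutoffs else None
    af_range = tuple(cfg.loh.get("af_range", DEFAULT_AF_RANGE))
    loh_min_depth = cfg.loh.get("min_depth", DEFAULT_MIN_DEPTH)
    fcfg = FilterConfig(**cfg.filter)
    rules = ActionabilityRules(**cfg.actionability)

    ss = np.random.SeedSequence(cfg.seed)
    cnv_rng, loh_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    pon = build_pon(
        [s.normal_variants for s in bundle.samples if s.normal_variants is not None]
    )

    all_segments = {}
    all_loh = {}
    alterations = []
    n_kept = 0
    for sample in bundle.samples:
        purity = None
        if cfg.use_true_purity and sample.sample_id in truth_by_id:
            purity = truth_by_id[sample.sample_id].purity
        segments = call_copy_number(
            sample.coverage, purity=purity, recenter_mode=recenter_mode,
            thresholds=thresholds, rng=cnv_rng, **cnv_kwargs,
        )
        all_segments[sample.sample_id] = segments

        hets = select_informative(
            sample.variants, af_range=af_range, min_depth=loh_min_depth,
            hom_cutoffs=hom_cutoffs,
        )
        dev_segments = call_imbalance(
            hets, threshold=loh_threshold, rng=loh_rng,
            alpha=cnv_kwargs["alpha"], n_perm=cnv_kwargs["n_perm"],
            min_bins=cnv_kwargs["min_bins"],
        )
        if sample.normal_variants is not None:
            paired_shift(sample.normal_variants, sample.variants, dev_segments,
                         shift_threshold=cfg.loh.get("shift_threshold", loh_threshold),
                         hom_cutoffs=hom_cutoffs)
        loh_calls = classify_loh(dev_segments, segments)
        all_loh[sample.sample_id] = loh_calls

        kept = filter_common(sample.variants, fcfg, pon)
        n_kept += len(kept)
        summaries = collapse_to_gene(kept, GENE_ROLES, fcfg)
        for gene in panel.genes:
            chrom, gstart, gend = panel.gene_interval(gene)
            cn, state = gene_copy_state(chrom, gstart, gend, segments)
            loh_mech = gene_loh_mechanism(chrom, gstart, gend, loh_calls, cn)
            alterations.append(
                integrate_gene_sample(
                    gene, sample.sample_id, summaries.get(gene),
                    cn, state, loh_mech, purity,
                )
            )

    matrix = build_matrix(alterations)
    fraction, breakdown, verdicts = cohort_actionable_fraction(matrix, rules)

    summary["stages"]["cnv"] = {
        "n_segments": sum(len(s) for s in all_segments.values())
    }
    summary["stages"]["loh"] = {
        "n_calls": sum(len(c) for c in all_loh.values()),
        "n_imbalanced": sum(
            sum(c.mechanism != "none" for c in calls) for calls in all_loh.values()
        ),
    }
    summary["stages"]["filter"] = {
        "n_input": sum(len(s.variants) for s in bundle.samples),
        "n_kept": n_kept,
    }
    summary["stages"]["integrate"] = {
        "n_records": len(alterations),
        "n_biallelic": sum(a.biallelic for a in alterations),
    }
    summary["stages"]["actionability"] = {
        "fraction": fraction,
        "per_pathway": breakdown,
    }

    comparison = None
    if cfg.compare.get("group_1") and cfg.compare.get("group_2"):
        g1, g2 = cfg.compare["group_1"], cfg.compare["group_2"]
        sizes1 = {g: len(g1) for g in matrix.genes}
        sizes2 = {g: len(g2) for g in matrix.genes}
        mut1 = {g: int(matrix.mutated.loc[g, g1].sum()) for g in matrix.genes}
        mut2 = {g: int(matrix.mutated.loc[g, g2].sum()) for g in matrix.genes}
        comparison = compare_cohorts(
            mutated_1=mut1, sizes_1=sizes1, mutated_2=mut2, sizes_2=sizes2
        )
        summary["stages"]["compare"] = {"n_genes": len(comparison)}

    if out is not None:
        io.write_segments(all_segments, out / "segments.seg")
        _write_loh(all_loh, out / "loh.tsv")
        matrix.labels.to_csv(out / "matrix.tsv", sep="\t")
        matrix.mutated.astype(int).to_csv(out / "mutated.tsv", sep="\t")
        _write_verdicts(verdicts, out / "actionability.tsv")
        if comparison is not None:
            comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)

    return {
        "matrix": matrix,
        "segments": all_segments,
        "loh": all_loh,
        "actionable_fraction": fraction,
        "per_pathway": breakdown,
        "verdicts": verdicts,
        "comparison": comparison,
        "summary": summary,
    }


def _write_loh(all_loh: dict, path: Path) -> None:
    import pandas as pd

    rows = []
    for sid, calls in all_loh.items():
        for c in calls:
            rows.append(
                {
                    "sample": sid, "chromosome": c.chromosome, "start": c.start,
                    "end": c.end, "mechanism": c.mechanism,
                    "copy_number": "." if c.copy_number is None else c.copy_number,
                    "mean_deviation": repr(c.mean_deviation),
                    "paired_support": (
                        "." if c.paired_support is None else int(c.paired_support)
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_verdicts(verdicts, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "gene": v.gene, "sample": v.sample_id,
                "actionable": int(v.actionable), "reason": v.reason,
                "pathway": v.pathway,
            }
            for v in verdicts
        ]
    ).to_csv(path, sep="\t", index=False)
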