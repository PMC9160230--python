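"""Readers and writers for the pipeline's text formats.

Internal coordinates are 0-based half-open everywhere; conversions happen
only at the I/O boundary (VCF positions are 1-based on disk, BED and the
TSV dialects stay 0-based).  Floats are serialized with ``repr`` so round
trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cnv import CnSegment
from .filtering import VariantRecord
from .simulate import PanelDesign

__all__ = [
    "read_panel_bed",
    "write_panel_bed",
    "read_coverage",
    "write_coverage",
    "read_variants",
    "write_variants",
    "read_segments",
    "write_segments",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=PRED,Number=1,Type=String,Description="Predicted class">
##INFO=<ID=HOT,Number=0,Type=Flag,Description="Hotspot">
##INFO=<ID=MNP,Number=1,Type=Integer,Description="Present in matched normal (1/0)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_TSV_COLUMNS = [
    "sample_id", "chromosome", "pos", "ref", "alt", "gene", "depth",
    "alt_count", "population_af", "consequence", "predicted_class",
    "hotspot", "matched_normal_present",
]


def read_panel_bed(path: str | Path) -> PanelDesign:
    """BED4: chromosome, start, end, gene name."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected 4 BED columns")
        rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return PanelDesign(pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene"]))


def write_panel_bed(panel: PanelDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in panel.intervals.itertuples(index=False):
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.gene}\n")


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Coverage TSV with ``depth`` or ``log2_ratio`` value column."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    needed = {"chromosome", "start", "end", "gene"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: missing columns {needed - set(df.columns)}")
    if not ({"depth", "log2_ratio"} & set(df.columns)):
        raise ValueError(f"{path}: needs a depth or log2_ratio column")
    return df


def write_coverage(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "log2_ratio" in out.columns:
        out["log2_ratio"] = out["log2_ratio"].map(repr)
    out.to_csv(path, sep="\t", index=False)


def _variant_line(v: VariantRecord) -> str:
    info = [f"GENE={v.gene}", f"POPAF={v.population_af!r}", f"CSQ={v.consequence}"]
    if v.predicted_class:
        info.append(f"PRED={v.predicted_class}")
    if v.hotspot:
        info.append("HOT")
    if v.matched_normal_present is not None:
        info.append(f"MNP={int(v.matched_normal_present)}")
    ref_count = v.depth - v.alt_count
    return (
        f"{v.chromosome}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
        f"{';'.join(info)}\tDP:AD\t{v.depth}:{ref_count},{v.alt_count}\n"
    )


def write_variants(
    variants: list[VariantRecord], path: str | Path, dialect: str = "vcf"
) -> None:
    path = Path(path)
    if dialect == "vcf":
        sample = variants[0].sample_id if variants else "SAMPLE"
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER.format(sample=sample))
            for v in variants:
                fh.write(_variant_line(v))
    elif dialect == "maf_tsv":
        rows = [
            {
                "sample_id": v.sample_id, "chromosome": v.chromosome, "pos": v.pos,
                "ref": v.ref, "alt": v.alt, "gene": v.gene, "depth": v.depth,
                "alt_count": v.alt_count, "population_af": repr(v.population_af),
                "consequence": v.consequence,
                "predicted_class": v.predicted_class or ".",
                "hotspot": int(v.hotspot),
                "matched_normal_present": (
                    "." if v.matched_normal_present is None
                    else int(v.matched_normal_present)
                ),
            }
            for v in variants
        ]
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _parse_info(info: str) -> dict:
    out = {}
    for item in info.split(";"):
        if not item or item == ".":
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = True
    return out


def read_variants(path: str | Path, dialect: str | None = None) -> list[VariantRecord]:
    """Read a VCF or MAF-like TSV into variant records (0-based internal)."""
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "maf_tsv"
    if dialect == "vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"predicted_class": str},
                     float_precision="round_trip")
    out = []
    for r in df.itertuples(index=False):
        mnp = r.matched_normal_present
        out.append(
            VariantRecord(
                sample_id=str(r.sample_id), chromosome=str(r.chromosome),
                pos=int(r.pos), ref=str(r.ref), alt=str(r.alt), gene=str(r.gene),
                depth=int(r.depth), alt_count=int(r.alt_count),
                population_af=float(r.population_af), consequence=str(r.consequence),
                predicted_class=None if str(r.predicted_class) == "." else str(r.predicted_class),
                hotspot=bool(int(r.hotspot)),
                matched_normal_present=None if str(mnp) == "." else bool(int(mnp)),
            )
        )
    return out


def _read_vcf(path: Path) -> list[VariantRecord]:
    sample_id = "SAMPLE"
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            if len(cols) >= 10:
                sample_id = cols[9]
            continue
        parts = line.split("\t")
        if len(parts) < 10:
            raise ValueError(f"{path}:{ln}: truncated VCF record")
        try:
            info = _parse_info(parts[7])
            fmt = dict(zip(parts[8].split(":"), parts[9].split(":")))
            depth = int(fmt["DP"])
            alt_count = int(fmt["AD"].split(",")[1])
            mnp = info.get("MNP")
            out.append(
                VariantRecord(
                    sample_id=sample_id, chromosome=parts[0], pos=int(parts[1]) - 1,
                    ref=parts[3], alt=parts[4], gene=info.get("GENE", "."),
                    depth=depth, alt_count=alt_count,
                    population_af=float(info.get("POPAF", 0.0)),
                    consequence=info.get("CSQ", "other"),
                    predicted_class=info.get("PRED"),
                    hotspot=bool(info.get("HOT", False)),
                    matched_normal_present=None if mnp is None else bool(int(mnp)),
                )
            )
        except (KeyError, ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln}: malformed VCF record ({exc})") from exc
    return out


SEG_COLUMNS = ["sample", "chromosome", "start", "end", "n_bins", "mean_log2"]


def write_segments(
    segments: dict[str, list[CnSegment]] | list[CnSegment],
    path: str | Path,
    sample: str = "SAMPLE",
) -> None:
    """SEG-style TSV; pass a dict keyed by sample for multi-sample files.
    copy_number/state columns are written when present."""
    if isinstance(segments, list):
        segments = {sample: segments}
    rows = []
    for sid, segs in segments.items():
        for s in segs:
            rows.append(
                {
                    "sample": sid, "chromosome": s.chromosome, "start": s.start,
                    "end": s.end, "n_bins": s.n_bins, "mean_log2": repr(s.mean_log2),
                    "copy_number": "." if s.copy_number is None else s.copy_number,
                    "state": s.state or ".",
                }
            )
    pd.DataFrame(rows, columns=SEG_COLUMNS + ["copy_number", "state"]).to_csv(
        path, sep="\t", index=False
    )


def read_segments(path: str | Path) -> dict[str, list[CnSegment]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SEG columns {missing}")
    out: dict[str, list[CnSegment]] = {}
    for r in df.itertuples(index=False):
        seg = CnSegment(
            chromosome=str(r.chromosome), start=int(r.start), end=int(r.end),
            n_bins=int(r.n_bins), mean_log2=float(r.mean_log2),
        )
        if hasattr(r, "copy_number") and str(r.copy_number) != ".":
            seg.copy_number = int(r.copy_number)
        if hasattr(r, "state") and str(r.state) != ".":
            seg.state = str(r.state)
        out.setdefault(str(r.sample), []).append(seg)
    for sid, segs in out.items():
        ordered = sorted(segs, key=lambda s: (s.chromosome, s.start))
        for a, b in zip(ordered, ordered[1:]):
            if a.chromosome == b.chromosome and b.start < a.end:
                raise ValueError(f"{path}: overlapping segments for sample {sid}")
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
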