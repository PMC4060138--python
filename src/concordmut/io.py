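"""Readers and writers for the pipeline's external formats.

Tab-separated text is the canonical intermediate (the analysis is
count-level, not read-level); VCF 4.2 with paired NORMAL/TUMOR samples and
AD/DP FORMAT fields is supported at the boundary.  All genomic coordinates
are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .pathways import PathwayDefinition

SITE_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt",
    "normal_ref", "normal_alt", "tumor_ref", "tumor_alt",
    "gene", "func_class",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=concordmut
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Cohort sample id">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=FC,Number=1,Type=String,Description="Functional class">
##INFO=<ID=SS,Number=1,Type=String,Description="Somatic status">
##INFO=<ID=SPV,Number=1,Type=Float,Description="Somatic p-value">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref and alt read depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
"""


def write_site_table(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a site table as canonical TSV (1-based inclusive coordinates)."""
    cols = [c for c in SITE_COLUMNS if c in sites.columns]
    sites[cols].to_csv(path, sep="\t", index=False)


def read_site_table(path: str | os.PathLike, dialect: str = "tsv") -> pd.DataFrame:
    """Read site observations from ``tsv`` or ``vcf`` input.

    TSV: the canonical columns written by :func:`write_site_table`.
    VCF: paired-sample records with AD FORMAT fields for NORMAL and TUMOR;
    multi-allelic rows are split into one observation per alternate allele.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = [c for c in SITE_COLUMNS[1:-2] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: site table lacks columns {missing}")
        return df
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def _read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise ValueError(f"{path}: expected 2 samples (NORMAL, TUMOR), got {vcf.samples}")
    rows = []
    for i, v in enumerate(vcf, start=1):
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(f"{path}: record {i} ({v.CHROM}:{v.POS}) lacks the AD FORMAT field")
        for alt_i, alt in enumerate(v.ALT, start=1):
            rows.append(
                {
                    "sample": v.INFO.get("SAMPLE", ""),
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": alt,
                    "normal_ref": int(ad[0][0]),
                    "normal_alt": int(ad[0][alt_i]),
                    "tumor_ref": int(ad[1][0]),
                    "tumor_alt": int(ad[1][alt_i]),
                    "gene": v.INFO.get("GENE", ""),
                    "func_class": v.INFO.get("FC", ""),
                }
            )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_vcf(sites: pd.DataFrame, path: str | os.PathLike, sample: str = "") -> None:
    """Write one sample's site table as a two-sample (NORMAL, TUMOR) VCF 4.2."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for r in sites.itertuples(index=False):
            info = []
            if sample or getattr(r, "sample", ""):
                info.append(f"SAMPLE={sample or r.sample}")
            if getattr(r, "gene", ""):
                info.append(f"GENE={r.gene}")
            if getattr(r, "func_class", ""):
                info.append(f"FC={r.func_class}")
            if hasattr(r, "status"):
                info.append(f"SS={r.status}")
            if hasattr(r, "somatic_p") and pd.notna(r.somatic_p):
                info.append(f"SPV={r.somatic_p:.6g}")
            nd = int(r.normal_ref) + int(r.normal_alt)
            td = int(r.tumor_ref) + int(r.tumor_alt)
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\tGT:AD:DP\t"
                f"./.:{int(r.normal_ref)},{int(r.normal_alt)}:{nd}\t"
                f"./.:{int(r.tumor_ref)},{int(r.tumor_alt)}:{td}\n"
            )


def read_gmt(path: str | os.PathLike) -> list[PathwayDefinition]:
    """Read GMT pathway definitions (name <tab> description <tab> genes...).

    Duplicate genes within a set are collapsed; lines with fewer than three
    fields are rejected with their line number.
    """
    pathways = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has {len(parts)} fields (< 3)")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{ln}: GMT set {name!r} has no genes")
            pathways.append(PathwayDefinition(name, desc, genes))
    return pathways


def write_gmt(pathways: list[PathwayDefinition], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *pw.genes]) + "\n")


def write_expression(counts: pd.DataFrame, lengths: pd.Series, prefix: str | os.PathLike) -> None:
    """Write a genes x samples count matrix and its gene-length column file."""
    prefix = Path(prefix)
    counts.rename_axis("gene").to_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
    lengths.rename("length").rename_axis("gene").to_csv(prefix.with_suffix(".lengths.tsv"), sep="\t")


def read_expression(prefix: str | os.PathLike) -> tuple[pd.DataFrame, pd.Series]:
    prefix = Path(prefix)
    counts = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col="gene")
    lengths = pd.read_csv(prefix.with_suffix(".lengths.tsv"), sep="\t", index_col="gene")["length"]
    return counts, lengths


def write_clinical(clinical: pd.DataFrame, path: str | os.PathLike) -> None:
    clinical.rename_axis("sample").to_csv(path)


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample")
    for col in ("status", "ttlf"):
        if col not in df.columns:
            raise ValueError(f"{path}: clinical table lacks the {col!r} column")
    return df
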