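"""Readers and writers for the pipeline's file dialects.

Supported formats: per-sample signal files (TSV of marker_id/LRR/BAF),
PennCNV ``.rawcnv`` call lines, PLINK ``.cnv`` tables, PED pedigrees,
BED / BED+ interval files and VCF (read through cyvcf2, written as text).
All genomic coordinates are 1-based inclusive except BED input, which is
converted from its half-open 0-based convention on read and back on write.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import CnvCall, MarkerMap, Pedigree, TruthCnv

__all__ = [
    "read_marker_map",
    "write_marker_map",
    "read_signal_file",
    "write_signal_file",
    "read_rawcnv",
    "write_rawcnv",
    "read_plink_cnv",
    "write_plink_cnv",
    "read_ped",
    "write_ped",
    "read_bed",
    "write_bed",
    "read_truth_bed",
    "write_truth_bed",
    "read_vcf_variants",
    "write_vcf_variants",
]


# ---------------------------------------------------------------------------
# marker map / signal files


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.df.to_csv(path, sep="\t", index=False)


def read_signal_file(path) -> pd.DataFrame:
    """One sample's signal file: columns marker_id, lrr, baf."""
    return pd.read_csv(path, sep="\t", dtype={"marker_id": str})


def write_signal_file(marker_ids: Sequence[str], lrr, baf, path) -> None:
    pd.DataFrame({"marker_id": marker_ids, "lrr": lrr, "baf": baf}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


# ---------------------------------------------------------------------------
# PennCNV rawcnv dialect

_RAWCNV_RE = re.compile(
    r"chr(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state\d+,cn=(?P<cn>\d+)\s+(?P<sample>\S+)\s+"
    r"startsnp=(?P<startsnp>\S+)\s+endsnp=(?P<endsnp>\S+)"
)

_STATE_BY_CN = {0: 1, 1: 2, 2: 3, 3: 5, 4: 6}  # PennCNV state numbering


def write_rawcnv(calls: Iterable[CnvCall], path, marker_map: MarkerMap | None = None) -> None:
    """Write calls as PennCNV rawcnv lines.

    startsnp/endsnp are looked up from the map when given, else written
    as the call's bp bounds.
    """
    lines = []
    for c in calls:
        if marker_map is not None:
            idx = marker_map.markers_in(c.chrom, c.start, c.end)
            if len(idx):
                startsnp = marker_map.df["marker_id"].iloc[idx[0]]
                endsnp = marker_map.df["marker_id"].iloc[idx[-1]]
            else:
                startsnp = endsnp = "NA"
        else:
            startsnp, endsnp = str(c.start), str(c.end)
        state = _STATE_BY_CN[c.copy_number]
        lines.append(
            f"chr{c.chrom}:{c.start}-{c.end}\tnumsnp={c.n_snps}\t"
            f"length={c.length:,}\tstate{state},cn={c.copy_number}\t"
            f"{c.sample_id}\tstartsnp={startsnp}\tendsnp={endsnp}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_rawcnv(path, source: str = "array") -> list[CnvCall]:
    calls = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        m = _RAWCNV_RE.match(line)
        if m is None:
            raise ValueError(f"unparseable rawcnv line: {line!r}")
        cn = int(m["cn"])
        calls.append(
            CnvCall(
                sample_id=m["sample"],
                chrom=m["chrom"],
                start=int(m["start"]),
                end=int(m["end"]),
                type="del" if cn < 2 else "dup",
                copy_number=cn,
                n_snps=int(m["numsnp"]),
                source=source,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# PLINK .cnv dialect (FID IID CHR BP1 BP2 TYPE SCORE SITES; TYPE = copy number)


def write_plink_cnv(calls: Iterable[CnvCall], path) -> None:
    rows = [
        {
            "FID": c.sample_id,
            "IID": c.sample_id,
            "CHR": c.chrom,
            "BP1": c.start,
            "BP2": c.end,
            "TYPE": c.copy_number,
            "SCORE": 0,
            "SITES": c.n_snps,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["FID", "IID", "CHR", "BP1", "BP2", "TYPE", "SCORE", "SITES"]).to_csv(
        path, sep="\t", index=False
    )


def read_plink_cnv(path, source: str = "array") -> list[CnvCall]:
    df = pd.read_csv(path, sep=r"\s+", dtype={"IID": str, "CHR": str})
    calls = []
    for row in df.itertuples(index=False):
        cn = int(row.TYPE)
        calls.append(
            CnvCall(
                sample_id=str(row.IID),
                chrom=str(row.CHR),
                start=int(row.BP1),
                end=int(row.BP2),
                type="del" if cn < 2 else "dup",
                copy_number=cn,
                n_snps=int(row.SITES),
                source=source,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# PED


def read_ped(path) -> Pedigree:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    return Pedigree(df)


def write_ped(pedigree: Pedigree, path) -> None:
    pedigree.df[["fid", "iid", "father", "mother", "sex", "phenotype"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# BED (+ optional extra columns)


def read_bed(path) -> list[tuple]:
    """Plain BED intervals as (chrom, start, end) with 1-based inclusive coords."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom = parts[0].removeprefix("chr")
        start0, end0 = int(parts[1]), int(parts[2])
        out.append((chrom, start0 + 1, end0, *parts[3:]))
    return out


def write_bed(intervals: Iterable[tuple], path) -> None:
    """(chrom, start, end, *extra) with 1-based inclusive coords -> BED lines."""
    lines = []
    for chrom, start, end, *extra in intervals:
        cols = [str(chrom), str(start - 1), str(end)] + [str(x) for x in extra]
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_truth_bed(truth: Iterable[TruthCnv], path) -> None:
    """Truth CNVs as BED+ with extra columns cn and sample_id."""
    write_bed(
        ((t.chrom, t.start, t.end, t.copy_number, t.sample_id, t.inherited_from) for t in truth),
        path,
    )


def read_truth_bed(path) -> list[TruthCnv]:
    out = []
    for chrom, start, end, cn, sample_id, *rest in read_bed(path):
        out.append(
            TruthCnv(
                sample_id=sample_id,
                chrom=chrom,
                start=start,
                end=end,
                copy_number=int(cn),
                inherited_from=rest[0] if rest else "founder",
            )
        )
    return out


# ---------------------------------------------------------------------------
# VCF with ANN-style per-transcript annotations

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele|Effect|Transcript'">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf_variants(records: Iterable[dict], path) -> None:
    """Write simple single-sample-per-record variants grouped into one VCF.

    Each record is a dict with keys ``chrom, pos, ref, alt, sample_id,
    genotype`` ('hom_alt'/'het'/'hom_ref') and ``transcript_effects`` (list of
    (transcript_id, effect) pairs). All samples present in the records become
    VCF sample columns; absent genotypes are emitted as ./. .
    """
    records = list(records)
    samples = sorted({r["sample_id"] for r in records})
    gt_code = {"hom_alt": "1/1", "het": "0/1", "hom_ref": "0/0"}
    by_site: dict[tuple, dict] = {}
    for r in records:
        key = (r["chrom"], r["pos"], r["ref"], r["alt"])
        site = by_site.setdefault(key, {"ann": r["transcript_effects"], "gts": {}})
        site["gts"][r["sample_id"]] = gt_code[r["genotype"]]
    lines = [_VCF_HEADER.rstrip()]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for (chrom, pos, ref, alt), site in sorted(by_site.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        ann = ",".join(f"{alt}|{eff}|{tx}" for tx, eff in site["ann"])
        gts = "\t".join(site["gts"].get(s, "./.") for s in samples)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tANN={ann}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_variants(path) -> list[dict]:
    """Read a VCF back into per-sample variant records (see write_vcf_variants)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    out = []
    for v in vcf:
        ann = v.INFO.get("ANN", "")
        effects = []
        for entry in ann.split(","):
            if not entry:
                continue
            _, eff, tx = entry.split("|")
            effects.append((tx, eff))
        for i, s in enumerate(samples):
            a, b = v.genotypes[i][0], v.genotypes[i][1]
            if a < 0 or b < 0:
                continue
            genotype = {0: "hom_ref", 1: "het", 2: "hom_alt"}[int(a > 0) + int(b > 0)]
            out.append(
                {
                    "sample_id": s,
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": v.ALT[0],
                    "genotype": genotype,
                    "transcript_effects": effects,
                }
            )
    return out
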