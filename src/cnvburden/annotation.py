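"""Annotation of CNV calls against genes, curated gene sets, hotspots and
size classes.

A call covers a gene when at least 80% of the gene's length lies inside the
call; it hits a recurrent hotspot when it covers at least 50% of the
hotspot's length. Both bounds inclusive. Size classes split at 1 Mb with a
strict inequality: a call is "large" only above 1,000,000 bp. Strand is
ignored (CNVs are unstranded). The curated lists (epilepsy-associated
genes, loss-of-function-intolerant genes with pLI > 0.99) are user-supplied
symbol sets; small editable example fixtures ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .types import CnvCall, intersection_length

__all__ = [
    "GeneSet",
    "Hotspot",
    "AnnotatedCall",
    "annotate_genes",
    "annotate_hotspots",
    "classify_size",
    "annotate_call",
    "annotate_cohort",
]


class GeneSet:
    """Named gene intervals, optionally restricted to a symbol subset.

    ``genes`` is a DataFrame with columns symbol/chrom/start/end (strand
    optional and unused for overlap arithmetic).
    """

    def __init__(self, name: str, genes: pd.DataFrame):
        required = {"symbol", "chrom", "start", "end"}
        if required - set(genes.columns):
            raise ValueError(f"gene table needs columns {sorted(required)}")
        if genes["symbol"].duplicated().any():
            raise ValueError("duplicate gene symbols")
        if (genes["start"] > genes["end"]).any():
            raise ValueError("invalid gene interval")
        self.name = name
        self.genes = genes.reset_index(drop=True)
        self._trees: dict = {}
        for i, row in self.genes.iterrows():
            self._trees.setdefault(str(row["chrom"]), IntervalTree()).addi(
                int(row["start"]), int(row["end"]) + 1, i
            )

    @classmethod
    def from_tsv(cls, name: str, path) -> "GeneSet":
        return cls(name, pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def overlapping(self, chrom: str, start: int, end: int):
        tree = self._trees.get(str(chrom))
        if tree is None:
            return []
        return [self.genes.iloc[iv.data] for iv in sorted(tree.overlap(start, end + 1))]


@dataclass(frozen=True)
class Hotspot:
    """One recurrent rearrangement locus (e.g. 15q13.3, 22q11.2)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"invalid hotspot interval {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnnotatedCall:
    call: CnvCall
    genes_covered: tuple = ()
    hotspots_hit: tuple = ()
    in_epilepsy_gene: bool = False
    in_pli_gene: bool = False
    in_hotspot: bool = False
    size_class: str = "small"

    @property
    def coding(self) -> bool:
        return len(self.genes_covered) > 0


def annotate_genes(
    call: CnvCall,
    genes: GeneSet,
    min_gene_fraction: float = 0.8,
) -> tuple:
    """Symbols of genes with >= min_gene_fraction of their length in the call."""
    covered = []
    for gene in genes.overlapping(call.chrom, call.start, call.end):
        glen = int(gene["end"]) - int(gene["start"]) + 1
        inter = intersection_length(call.start, call.end, int(gene["start"]), int(gene["end"]))
        if inter / glen >= min_gene_fraction:
            covered.append(gene["symbol"])
    return tuple(covered)


def annotate_hotspots(
    call: CnvCall,
    hotspots,
    min_hotspot_fraction: float = 0.5,
) -> tuple:
    """Names of hotspots with >= min_hotspot_fraction of their length in the call."""
    hit = []
    for hs in hotspots:
        if hs.chrom != call.chrom:
            continue
        inter = intersection_length(call.start, call.end, hs.start, hs.end)
        if inter / hs.length >= min_hotspot_fraction:
            hit.append(hs.name)
    return tuple(hit)


def classify_size(call: CnvCall, threshold: int = 1_000_000) -> str:
    """"large" strictly above the threshold (default >1 Mb), else "small"."""
    return "large" if call.length > threshold else "small"


def annotate_call(
    call: CnvCall,
    genes: GeneSet,
    hotspots=(),
    epilepsy_genes: set | None = None,
    pli_genes: set | None = None,
    min_gene_fraction: float = 0.8,
    min_hotspot_fraction: float = 0.5,
    size_threshold: int = 1_000_000,
) -> AnnotatedCall:
    covered = annotate_genes(call, genes, min_gene_fraction)
    hit = annotate_hotspots(call, hotspots, min_hotspot_fraction)
    return AnnotatedCall(
        call=call,
        genes_covered=covered,
        hotspots_hit=hit,
        in_epilepsy_gene=bool(epilepsy_genes and set(covered) & epilepsy_genes),
        in_pli_gene=bool(pli_genes and set(covered) & pli_genes),
        in_hotspot=len(hit) > 0,
        size_class=classify_size(call, size_threshold),
    )


def annotate_cohort(calls, genes: GeneSet, hotspots=(), epilepsy_genes=None, pli_genes=None, **kw):
    """Annotate a list of calls; pure and order-independent."""
    return [
        annotate_call(c, genes, hotspots, epilepsy_genes, pli_genes, **kw) for c in calls
    ]
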