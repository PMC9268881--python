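"""Screen validated deletions for unmasked recessive variants.

A heterozygous deletion leaves a single homologous chromosome, so any
variant inside the deleted interval should be called homozygous
(hemizygous in reality). The screen keeps homozygous variants located
inside a validated deletion as candidates; heterozygous calls in the same
interval are retained separately as QC flags (likely genotyping
artifacts), never as candidates.

Effect classification over per-transcript annotations: a variant is
loss-of-function (lof) or nonsense-mediated-decay (nmd) when that effect
appears in strictly more than 90% of its transcripts; any missense
annotation makes it a missense candidate regardless of fraction; otherwise
it is non-coding (all annotations non-coding) or other.

Non-coding candidates are scored per brain tissue (amygdala, cortex,
hippocampus) with a constraint-violation score: the product of the gene's
variation-potential directionality score and the variant's predicted
expression change in that tissue. Higher means more deleterious; all
scores non-positive means not likely deleterious; no score at all means no
predicted functional effect. The expression model itself is pluggable (a
lookup table or any callable); only the scoring arithmetic lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import pandas as pd

from .types import CnvCall

__all__ = [
    "VariantCandidate",
    "ConstraintScore",
    "TableExpressionProvider",
    "screen_deletion",
    "classify_effect",
    "constraint_violation",
    "label_uneecon",
]

log = logging.getLogger(__name__)

TISSUES = ("amygdala", "cortex", "hippocampus")

LOF_EFFECTS = {
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
    "stop_lost",
    "transcript_ablation",
    "lof",
}
NMD_EFFECTS = {"NMD_transcript_variant", "nmd"}
MISSENSE_EFFECTS = {"missense_variant", "missense"}
NONCODING_EFFECTS = {
    "intron_variant",
    "intergenic_variant",
    "intergenic_region",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "regulatory_region_variant",
    "non_coding_transcript_variant",
    "noncoding",
}


@dataclass
class VariantCandidate:
    """A homozygous variant inside a validated deletion."""

    sample_id: str
    deletion: CnvCall
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    transcript_effects: tuple = ()
    effect_class: str = "other"
    transcript_effect_fraction: float = 0.0
    external_af: Optional[float] = None
    uneecon_score: Optional[float] = None
    uneecon_label: Optional[str] = None
    clinvar_status: Optional[str] = None
    constraint_scores: dict = field(default_factory=dict)
    constraint_label: Optional[str] = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ConstraintScore:
    gene: str
    tissue: str
    directionality: float
    expression_change: float

    @property
    def score(self) -> float:
        return self.directionality * self.expression_change


class TableExpressionProvider:
    """Predicted expression changes looked up from a table.

    A stand-in provider for tests and toy analyses: maps
    ((chrom, pos, ref, alt), tissue) -> fold-change effect. Any callable
    with the same signature can replace it.
    """

    def __init__(self, table: dict):
        self.table = dict(table)

    def __call__(self, variant_key: tuple, tissue: str) -> Optional[float]:
        return self.table.get((variant_key, tissue))


def screen_deletion(
    deletion: CnvCall,
    variants,
    validated: bool = True,
) -> tuple[list[VariantCandidate], list[dict]]:
    """Candidates (homozygous, inside the deletion) and het QC flags.

    ``variants`` are record dicts with keys sample_id, chrom, pos, ref,
    alt, genotype ('hom_alt'/'het'/'hom_ref') and transcript_effects.
    Refuses unvalidated deletions: the screen is only meaningful on events
    confirmed by sequencing or segregation.
    """
    if not validated:
        raise ValueError(
            f"deletion {deletion.chrom}:{deletion.start}-{deletion.end} is not "
            "validated; screen only validated deletions"
        )
    if deletion.type != "del":
        raise ValueError("can only screen deletions for unmasked variants")
    candidates, qc_flags = [], []
    for v in variants:
        if v["sample_id"] != deletion.sample_id or v["chrom"] != deletion.chrom:
            continue
        if not (deletion.start <= v["pos"] <= deletion.end):
            continue
        if v["genotype"] == "het":
            qc_flags.append({**v, "flag": "heterozygous_in_hemizygous_region"})
            continue
        if v["genotype"] != "hom_alt":
            continue
        candidates.append(
            VariantCandidate(
                sample_id=v["sample_id"],
                deletion=deletion,
                chrom=v["chrom"],
                pos=v["pos"],
                ref=v["ref"],
                alt=v["alt"],
                genotype=v["genotype"],
                transcript_effects=tuple(v.get("transcript_effects", ())),
            )
        )
    return candidates, qc_flags


def classify_effect(candidate: VariantCandidate) -> VariantCandidate:
    """Assign the effect class from per-transcript annotations (in place).

    lof/nmd requires the effect in strictly more than 90% of transcripts;
    a single missense transcript suffices for the missense class.
    """
    effects = [eff for _, eff in candidate.transcript_effects]
    if not effects:
        raise ValueError("candidate has no transcript annotations")
    n = len(effects)
    lof_frac = sum(e in LOF_EFFECTS for e in effects) / n
    nmd_frac = sum(e in NMD_EFFECTS for e in effects) / n
    if lof_frac > 0.9:
        candidate.effect_class = "lof"
        candidate.transcript_effect_fraction = lof_frac
    elif nmd_frac > 0.9:
        candidate.effect_class = "nmd"
        candidate.transcript_effect_fraction = nmd_frac
    elif any(e in MISSENSE_EFFECTS for e in effects):
        frac = sum(e in MISSENSE_EFFECTS for e in effects) / n
        candidate.effect_class = "missense"
        candidate.transcript_effect_fraction = frac
    elif all(e in NONCODING_EFFECTS for e in effects):
        candidate.effect_class = "noncoding"
        candidate.transcript_effect_fraction = 1.0
    else:
        candidate.effect_class = "other"
        candidate.transcript_effect_fraction = 0.0
    return candidate


def constraint_violation(
    candidate: VariantCandidate,
    directionality: pd.DataFrame,
    expression_change: Callable,
    gene: str,
    tissues=TISSUES,
) -> VariantCandidate:
    """Per-tissue constraint-violation scores for one candidate (in place).

    ``directionality`` is a gene x tissue table; ``expression_change`` a
    provider callable. A missing gene or tissue leaves that score absent
    (logged); a candidate with no scores at all is labelled as having no
    predicted functional effect, one whose scores are all non-positive as
    not likely deleterious, otherwise possibly deleterious.
    """
    scores = {}
    for tissue in tissues:
        if gene not in directionality.index or tissue not in directionality.columns:
            log.info("no directionality for %s/%s: no constraint score", gene, tissue)
            continue
        change = expression_change(candidate.key, tissue)
        if change is None:
            log.info("no expression change for %s/%s", candidate.key, tissue)
            continue
        cs = ConstraintScore(
            gene=gene,
            tissue=tissue,
            directionality=float(directionality.loc[gene, tissue]),
            expression_change=float(change),
        )
        scores[tissue] = cs
    candidate.constraint_scores = scores
    if not scores:
        candidate.constraint_label = "no_predicted_functional_effect"
    elif all(cs.score <= 0 for cs in scores.values()):
        candidate.constraint_label = "not_likely_deleterious"
    else:
        candidate.constraint_label = "possibly_deleterious"
    return candidate


def label_uneecon(
    candidate: VariantCandidate,
    uneecon_scores: dict,
    threshold: float = 0.15,
) -> VariantCandidate:
    """Join a missense deleteriousness score; below threshold = not deleterious."""
    score = uneecon_scores.get(candidate.key)
    candidate.uneecon_score = score
    if score is not None:
        candidate.uneecon_label = (
            "not_deleterious" if score < threshold else "possibly_deleterious"
        )
    return candidate
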