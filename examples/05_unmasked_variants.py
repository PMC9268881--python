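"""Screen validated deletions for unmasked recessive variants.

A heterozygous deletion makes the surviving homologue effectively
hemizygous, so variants inside it are called homozygous. The screen keeps
homozygous variants in the deleted interval, classifies their effect over
transcripts, joins deleteriousness scores and computes per-tissue
constraint-violation scores for non-coding candidates.
"""

from cnvburden import (
    CohortConfig,
    TableExpressionProvider,
    classify_effect,
    constraint_violation,
    label_uneecon,
    screen_deletion,
    simulate_cohort,
)
from cnvburden.annotation import GeneSet
from cnvburden.types import CnvCall

cfg = CohortConfig(n_families=20, n_population_controls=30, seq_fraction=1.0, seed=11)
bundle = simulate_cohort(cfg)
provider = TableExpressionProvider(bundle.expression_change)
genes = GeneSet("genes", bundle.genes)

n_cand = n_flag = 0
for t in bundle.truth_cnvs:
    if t.type != "del" or not bundle.variants:
        continue
    deletion = CnvCall(t.sample_id, t.chrom, t.start, t.end, "del", t.copy_number, 10)
    cands, flags = screen_deletion(deletion, bundle.variants, validated=True)
    n_flag += len(flags)
    for cand in cands:
        classify_effect(cand)
        label_uneecon(cand, bundle.uneecon_scores)
        line = (f"{cand.sample_id} {cand.chrom}:{cand.pos}{cand.ref}>{cand.alt} "
                f"{cand.effect_class}")
        if cand.uneecon_label:
            line += f" (UNEECON {cand.uneecon_score}: {cand.uneecon_label})"
        if cand.effect_class == "noncoding":
            near = genes.overlapping(cand.chrom, cand.pos, cand.pos)
            gene = near[0]["symbol"] if near else bundle.directionality.index[0]
            constraint_violation(cand, bundle.directionality, provider, gene)
            scores = {t_: round(s.score, 3) for t_, s in cand.constraint_scores.items()}
            line += f" constraint={scores} -> {cand.constraint_label}"
        print(line)
        n_cand += 1
print(f"\n{n_cand} homozygous candidates; {n_flag} heterozygous QC flags "
      "(possible genotyping artifacts inside hemizygous regions)")
# lof/nmd requires the effect in >90% of transcripts; any missense counts;
# a candidate whose constraint scores are all <=0 is not likely deleterious.
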