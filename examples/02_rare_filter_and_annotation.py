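"""Cohort frequency estimation, rarity filtering and gene/hotspot annotation.

Takes the simulated truth calls of a cohort, estimates each call's carrier
frequency (reciprocal-overlap matching), keeps the rare (<=1%) subset and
annotates it against the bundle's synthetic gene models and hotspots.
"""

from cnvburden import (
    CohortConfig,
    GeneSet,
    Hotspot,
    annotate_cohort,
    cnv_frequency,
    filter_rare,
    simulate_cohort,
)
from cnvburden.types import CnvCall

cfg = CohortConfig(n_families=20, n_population_controls=150, seed=7)
bundle = simulate_cohort(cfg)
calls = [
    CnvCall(t.sample_id, t.chrom, t.start, t.end, t.type, t.copy_number, 10)
    for t in bundle.truth_cnvs
]
n = len(bundle.samples)
records = cnv_frequency(calls, n_samples=n, overlap_threshold=0.5)
rare = filter_rare(records, max_freq=0.01)
print(f"{len(calls)} calls; {len(rare)} rare at <=1% of {n} samples")
print("dropped common-locus carriers:", len(calls) - len(rare))

genes = GeneSet("genes", bundle.genes)
hotspots = [Hotspot(*h) for h in bundle.hotspots]
annotated = annotate_cohort(
    rare, genes, hotspots,
    epilepsy_genes=bundle.gene_sets["epilepsy"], pli_genes=bundle.gene_sets["pli"],
)
large = [a for a in annotated if a.size_class == "large"]
print(f"large (>1 Mb) rare calls: {len(large)}")
print(f"  coding: {sum(a.coding for a in large)}")
print(f"  in epilepsy genes: {sum(a.in_epilepsy_gene for a in large)}")
print(f"  in pLI>0.99 genes: {sum(a.in_pli_gene for a in large)}")
print(f"  in hotspots: {sum(a.in_hotspot for a in large)}")
# Coding means >=80% of some gene lies inside the call; hotspot means the
# call covers >=50% of a recurrent locus.
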