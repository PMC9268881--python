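"""Cross-platform validation, pedigree segregation and double-hit screening.

Validates simulated array calls against the bundle's sequencing call sets,
classifies transmission within trios (including de novo events) and scans
for samples carrying two large rare CNVs.
"""

from collections import Counter

from cnvburden import (
    CohortConfig,
    classify_segregation,
    detect_double_hits,
    simulate_cohort,
    validate_call,
)
from cnvburden.types import CnvCall

cfg = CohortConfig(n_families=25, n_population_controls=40, seq_fraction=0.8,
                   de_novo_rate=0.2, p_family_cnv=0.9, seed=2)
bundle = simulate_cohort(cfg)
calls_by_sample = {iid: [] for iid in bundle.samples["sample_id"]}
for t in bundle.truth_cnvs:
    calls_by_sample[t.sample_id].append(
        CnvCall(t.sample_id, t.chrom, t.start, t.end, t.type, t.copy_number, 10)
    )

statuses = Counter()
for calls in calls_by_sample.values():
    for c in calls:
        v = validate_call(c, bundle.seq_calls, bundle.pedigree, calls_by_sample)
        statuses[v.status] += 1
print("validation:", dict(statuses))

classes = Counter()
for calls in calls_by_sample.values():
    for c in calls:
        fa, mo = bundle.pedigree.parents_of(c.sample_id)
        if fa is None and mo is None:
            continue
        classes[classify_segregation(c, bundle.pedigree, calls_by_sample).classification] += 1
print("segregation:", dict(classes))

hits = detect_double_hits({s: c for s, c in calls_by_sample.items() if c})
for h in hits:
    print(f"double hit in {h.sample_id}: "
          f"{h.call_a.chrom}:{h.call_a.start}-{h.call_a.end}{h.call_a.type} + "
          f"{h.call_b.chrom}:{h.call_b.start}-{h.call_b.end}{h.call_b.type} "
          f"(same chromosome: {h.same_chromosome})")
# A call is validated when a same-type WGS/WES call covers >=50% of it and is
# at most twice its length, or when a parent carries a matching call; de novo
# requires both parents genotyped and neither matching.
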