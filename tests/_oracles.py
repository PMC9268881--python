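"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the library paths they verify:
exhaustive path enumeration for the HMM decoder, all-pairs interval
arithmetic for frequency/overlap engines, and direct set filters for the
variant screen.
"""

import numpy as np

from cnvburden.types import intersection_length, union_length


def brute_force_viterbi(lrr, baf, pos, params):
    """Best state path by scoring every one of the 5**n paths.

    Scores are accumulated in a dense array indexed by the base-5 encoding
    of the path (most significant digit = first marker), so the winner is a
    full enumeration, not dynamic programming.
    """
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    n = len(lrr)
    emis = params.log_emission(lrr, baf)
    scores = params.log_prior() + emis[0]
    for t in range(1, n):
        trans = params.log_transition(pos[t] - pos[t - 1])
        # scores laid out with the current state as the last base-5 digit
        scores = (
            scores.reshape(-1, 5)[:, :, None] + trans[None, :, :] + emis[t][None, None, :]
        ).ravel()
    best = int(np.argmax(scores))
    path = []
    for _ in range(n):
        path.append(best % 5)
        best //= 5
    return np.array(path[::-1], dtype=int)


def brute_force_frequency(calls, n_samples, threshold=0.5):
    """All-pairs carrier counts: intersection/union >= threshold, same type."""
    records = []
    for a in calls:
        carriers = {a.sample_id}
        for b in calls:
            if a.type != b.type or a.chrom != b.chrom:
                continue
            inter = intersection_length(a.start, a.end, b.start, b.end)
            if inter == 0:
                continue
            if inter / union_length(a.start, a.end, b.start, b.end) >= threshold:
                carriers.add(b.sample_id)
        records.append((a, len(carriers), len(carriers) / n_samples))
    return records


def brute_force_gene_coverage(call, genes, min_fraction=0.8):
    """Symbols with >= min_fraction of the gene inside the call (all-pairs)."""
    out = []
    for row in genes.itertuples(index=False):
        if str(row.chrom) != call.chrom:
            continue
        glen = row.end - row.start + 1
        inter = intersection_length(call.start, call.end, row.start, row.end)
        if inter / glen >= min_fraction:
            out.append(row.symbol)
    return out


def brute_force_screen(deletion, variants):
    """{inside interval} & {homozygous-alt} as plain set filters."""
    return [
        v
        for v in variants
        if v["sample_id"] == deletion.sample_id
        and v["chrom"] == deletion.chrom
        and deletion.start <= v["pos"] <= deletion.end
        and v["genotype"] == "hom_alt"
    ]
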