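"""Cohort-level CNV frequency estimation and rare-CNV filtering.

Two calls of the same type (deletions and duplications counted separately)
"match" when their intersection length divided by their union length is at
least the overlap threshold (default 0.5) — the documented behaviour of
PLINK's second frequency method. A call's count is the number of distinct
cohort samples carrying at least one matching call, the carrier itself
included, and its frequency is count / n_samples. Rare means frequency at
most 1% (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .types import CnvCall, intersection_length, union_length

__all__ = ["FrequencyRecord", "cnv_frequency", "filter_rare", "calls_match"]


@dataclass(frozen=True)
class FrequencyRecord:
    call: CnvCall
    count: int  # distinct carrier samples, including self
    frequency: float

    def __post_init__(self):
        if not (1 <= self.count):
            raise ValueError("count must be >= 1 (self always matches)")
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError("frequency must lie in (0, 1]")


def calls_match(a: CnvCall, b: CnvCall, overlap_threshold: float = 0.5) -> bool:
    """True when two same-type calls overlap reciprocally (intersection/union)."""
    if a.type != b.type or a.chrom != b.chrom:
        return False
    inter = intersection_length(a.start, a.end, b.start, b.end)
    if inter == 0:
        return False
    return inter / union_length(a.start, a.end, b.start, b.end) >= overlap_threshold


def cnv_frequency(
    calls, n_samples: int, overlap_threshold: float = 0.5
) -> list[FrequencyRecord]:
    """Carrier count and frequency for every call in a cohort.

    A sample with several calls matching one query still counts once.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    calls = list(calls)
    trees: dict[tuple, IntervalTree] = {}
    for i, c in enumerate(calls):
        trees.setdefault((c.chrom, c.type), IntervalTree()).addi(c.start, c.end + 1, i)
    records = []
    for c in calls:
        carriers = {c.sample_id}
        for iv in trees[(c.chrom, c.type)].overlap(c.start, c.end + 1):
            other = calls[iv.data]
            if calls_match(c, other, overlap_threshold):
                carriers.add(other.sample_id)
        count = len(carriers)
        records.append(FrequencyRecord(call=c, count=count, frequency=count / n_samples))
    return records


def filter_rare(records, max_freq: float = 0.01) -> list[CnvCall]:
    """Keep calls at or below the rarity cutoff (frequency <= 1% by default)."""
    return [r.call for r in records if r.frequency <= max_freq]
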