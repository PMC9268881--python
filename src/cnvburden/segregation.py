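"""Validation of array calls against sequencing, pedigree segregation,
de novo detection and double-CNV-hit screening.

Validation: an array call is validated when either sequencing call set
(WGS or WES) contains a same-type call covering at least 50% of the array
call's length, provided the sequencing call is no more than twice the array
call's length (guards against spurious giant calls). The 50% overlap is
one-sided, relative to the array call; the 2x length cap supplies the
reciprocal guard. Both bounds are inclusive at exactly 50% and exactly 2x.

Segregation: a child's call is transmitted when a parent carries a
same-type call covering at least 50% of the child call; de novo requires
both parents present *with call data* and neither matching; any parent
without call data makes the classification unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .types import CnvCall, Pedigree, intersection_length

__all__ = [
    "ValidationResult",
    "SegregationCall",
    "DoubleHit",
    "validate_against_sequencing",
    "classify_segregation",
    "validate_call",
    "detect_double_hits",
]


@dataclass(frozen=True)
class ValidationResult:
    call: CnvCall
    status: str  # validated_wgs | validated_wes | validated_segregation | unvalidated
    matched_call: Optional[CnvCall] = None

    def __post_init__(self):
        if self.status.startswith("validated") and self.matched_call is None:
            raise ValueError("validated status requires a matched call")

    @property
    def validated(self) -> bool:
        return self.status.startswith("validated")


@dataclass(frozen=True)
class SegregationCall:
    call: CnvCall
    classification: str  # transmitted_by_affected | transmitted_by_unaffected | de_novo | unknown
    parent_id: Optional[str] = None
    note: str = ""


@dataclass(frozen=True)
class DoubleHit:
    sample_id: str
    call_a: CnvCall
    call_b: CnvCall

    def __post_init__(self):
        if self.call_a == self.call_b:
            raise ValueError("a double hit needs two distinct calls")

    @property
    def same_chromosome(self) -> bool:
        return self.call_a.chrom == self.call_b.chrom


def _covers(query: CnvCall, target: CnvCall, min_fraction: float = 0.5) -> bool:
    """True when ``query`` covers >= min_fraction of ``target``'s length."""
    if query.chrom != target.chrom or query.type != target.type:
        return False
    inter = intersection_length(query.start, query.end, target.start, target.end)
    return inter / target.length >= min_fraction


def validate_against_sequencing(call: CnvCall, seq_calls) -> ValidationResult:
    """Validate one array call against WGS/WES call sets.

    A match from either platform suffices; WGS is reported when both match.
    """
    if call.source != "array":
        raise ValueError("only array calls are validated against sequencing")
    matches = []
    for sc in seq_calls:
        if sc.sample_id != call.sample_id:
            continue
        if not _covers(sc, call, 0.5):
            continue
        if sc.length > 2 * call.length:
            continue
        matches.append(sc)
    if not matches:
        return ValidationResult(call=call, status="unvalidated")
    matches.sort(key=lambda c: (c.source != "wgs", -c.overlap(call)))
    best = matches[0]
    return ValidationResult(call=call, status=f"validated_{best.source}", matched_call=best)


def classify_segregation(
    call: CnvCall, pedigree: Pedigree, cohort_calls: dict
) -> SegregationCall:
    """Classify one child call as transmitted, de novo, or unknown.

    ``cohort_calls`` maps sample id -> list of that sample's calls; a parent
    is "with call data" iff it appears as a key (possibly with an empty
    list). Parents with an unknown phenotype still transmit, but the result
    is reported as unknown with a note (a plausible transmission at most).
    """
    if call.sample_id not in pedigree:
        raise KeyError(f"sample {call.sample_id!r} absent from pedigree")
    father, mother = pedigree.parents_of(call.sample_id)
    parent_match = None
    for parent in (father, mother):
        if parent is None or parent not in cohort_calls:
            continue
        for pc in cohort_calls[parent]:
            if _covers(pc, call, 0.5):
                parent_match = parent
                break
        if parent_match:
            break
    if parent_match is not None:
        aff = pedigree.is_affected(parent_match)
        if aff is None:
            return SegregationCall(
                call=call,
                classification="unknown",
                parent_id=parent_match,
                note="matching parent call but parent phenotype unknown "
                "(plausible transmission)",
            )
        cls = "transmitted_by_affected" if aff else "transmitted_by_unaffected"
        return SegregationCall(call=call, classification=cls, parent_id=parent_match)
    both_present = all(
        p is not None and p in cohort_calls for p in (father, mother)
    )
    if both_present:
        return SegregationCall(call=call, classification="de_novo")
    return SegregationCall(
        call=call, classification="unknown", note="parent without call data"
    )


def validate_call(
    call: CnvCall,
    seq_calls,
    pedigree: Pedigree | None = None,
    cohort_calls: dict | None = None,
) -> ValidationResult:
    """Sequencing validation first, family segregation as fallback."""
    res = validate_against_sequencing(call, seq_calls)
    if res.validated or pedigree is None or cohort_calls is None:
        return res
    if call.sample_id not in pedigree:
        return res
    seg = classify_segregation(call, pedigree, cohort_calls)
    if seg.classification.startswith("transmitted"):
        matched = next(
            pc for pc in cohort_calls[seg.parent_id] if _covers(pc, call, 0.5)
        )
        return ValidationResult(call=call, status="validated_segregation", matched_call=matched)
    return res


def detect_double_hits(
    rare_calls_by_sample: dict, min_length: int = 1_000_000
) -> list[DoubleHit]:
    """All unordered pairs of distinct non-overlapping large rare calls.

    Calls must already be merged; deletion+duplication pairs qualify. The
    size bound is inclusive.
    """
    hits = []
    for sid, calls in sorted(rare_calls_by_sample.items()):
        big = sorted(
            (c for c in calls if c.length >= min_length),
            key=lambda c: (c.chrom, c.start, c.end),
        )
        for i in range(len(big)):
            for j in range(i + 1, len(big)):
                a, b = big[i], big[j]
                if a.overlap(b) > 0:
                    continue
                hits.append(DoubleHit(sample_id=sid, call_a=a, call_b=b))
    return hits
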