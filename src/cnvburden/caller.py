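"""Copy-number segmentation of LRR/BAF vectors and the per-call filters.

The segmentation is a five-state hidden Markov model over integer copy
numbers 0-4 along each chromosome, decoded with the Viterbi algorithm.
Emissions combine a Gaussian LRR term (per-state mean/SD) with a
nearest-cluster Gaussian BAF term (the copy-number state determines which
allelic-ratio bands are possible; the zero-copy state has no allelic signal
and uses a flat BAF term). Transitions out of a state become more likely as
the physical gap to the next marker grows, with an exponential distance
decay, and non-neutral states preferentially return to the copy-neutral
state.

This caller is a deliberately simplified stand-in for full SNP-array HMM
callers: no LOH state, no GC model, no family-joint calling. Its parameters
are all exposed so users can tighten it.

Maximal runs of non-neutral states of one sign become calls; downstream
filters drop calls with fewer than 10 markers or under 20 kb, calls mostly
inside excluded regions, and whole samples with more than 50 calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .qc import ExclusionRegions
from .types import CnvCall, MarkerMap

__all__ = [
    "HmmParams",
    "viterbi",
    "path_loglik",
    "call_sample",
    "filter_calls",
    "drop_noisy_samples",
    "merge_adjacent",
]

log = logging.getLogger(__name__)

STATES = (0, 1, 2, 3, 4)  # copy numbers
_NEUTRAL = 2

_BAF_CLUSTERS = {
    0: None,  # no DNA: BAF is uniform noise
    1: (0.0, 1.0),
    2: (0.0, 0.5, 1.0),
    3: (0.0, 1 / 3, 2 / 3, 1.0),
    4: (0.0, 0.25, 0.75, 1.0),
}


@dataclass
class HmmParams:
    """Emission and transition parameters of the copy-number HMM.

    ``p_leave`` is the asymptotic per-marker probability of leaving the
    current state once markers are far apart; at gap d the switch
    probability is ``p_leave * (1 - exp(-d / distance_decay))``, so densely
    spaced markers rarely switch. ``return_bias`` is the share of switch
    mass sent back to copy-neutral from a CNV state.
    """

    lrr_means: np.ndarray = field(
        default_factory=lambda: np.array([-3.5, -0.66, 0.0, 0.40, 0.68])
    )
    lrr_sds: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.2, 0.2, 0.2, 0.2])
    )
    baf_sd: float = 0.05
    p_leave: float = 1e-4
    distance_decay: float = 100_000.0
    return_bias: float = 0.9
    neutral_prior: float = 0.999

    def __post_init__(self):
        self.lrr_means = np.asarray(self.lrr_means, dtype=float)
        self.lrr_sds = np.asarray(self.lrr_sds, dtype=float)
        if (self.lrr_sds <= 0).any() or self.baf_sd <= 0:
            raise ValueError("emission SDs must be positive")
        if not (0 < self.p_leave < 1 and 0 <= self.return_bias <= 1):
            raise ValueError("invalid transition parameters")

    def log_prior(self) -> np.ndarray:
        eps = (1.0 - self.neutral_prior) / 4.0
        pi = np.full(5, eps)
        pi[_NEUTRAL] = self.neutral_prior
        return np.log(pi)

    def _switch_weights(self) -> np.ndarray:
        """Row-stochastic destination weights given that a switch happens."""
        w = np.zeros((5, 5))
        for i in STATES:
            for j in STATES:
                if j == i:
                    continue
                if i == _NEUTRAL:
                    w[i, j] = 1.0 / 4.0
                else:
                    w[i, j] = (
                        self.return_bias
                        if j == _NEUTRAL
                        else (1.0 - self.return_bias) / 3.0
                    )
        return w

    def log_transition(self, gap_bp: float) -> np.ndarray:
        """5x5 log transition matrix for one inter-marker gap (rows sum to 1)."""
        p_sw = self.p_leave * (1.0 - np.exp(-max(gap_bp, 1.0) / self.distance_decay))
        t = (1.0 - p_sw) * np.eye(5) + p_sw * self._switch_weights()
        return np.log(t)

    def log_emission(self, lrr: np.ndarray, baf: np.ndarray) -> np.ndarray:
        """n_markers x 5 matrix of per-state emission log-likelihoods."""
        lrr = np.asarray(lrr, dtype=float)
        baf = np.asarray(baf, dtype=float)
        out = np.empty((len(lrr), 5))
        for s in STATES:
            mu, sd = self.lrr_means[s], self.lrr_sds[s]
            ll = -0.5 * ((lrr - mu) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))
            clusters = _BAF_CLUSTERS[s]
            if clusters is None:
                bterm = 0.0  # uniform density on [0, 1]
            else:
                d = np.min(
                    np.abs(baf[:, None] - np.array(clusters)[None, :]), axis=1
                )
                bterm = -0.5 * (d / self.baf_sd) ** 2 - np.log(
                    self.baf_sd * np.sqrt(2 * np.pi)
                )
            out[:, s] = ll + bterm
        return out


def viterbi(lrr, baf, pos, params: HmmParams) -> np.ndarray:
    """Most likely copy-number path for one chromosome's marker vectors."""
    lrr = np.asarray(lrr, dtype=float)
    n = len(lrr)
    if not (len(baf) == len(pos) == n):
        raise ValueError("lrr, baf and pos must be aligned")
    emis = params.log_emission(lrr, baf)
    score = params.log_prior() + emis[0]
    back = np.zeros((n, 5), dtype=np.int8)
    pos = np.asarray(pos, dtype=float)
    w = params._switch_weights()
    eye = np.eye(5)
    p_sws = params.p_leave * (
        1.0 - np.exp(-np.maximum(np.diff(pos), 1.0) / params.distance_decay)
    )
    for t in range(1, n):
        trans = np.log((1.0 - p_sws[t - 1]) * eye + p_sws[t - 1] * w)
        cand = score[:, None] + trans  # prev state x next state
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(5)] + emis[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_loglik(states, lrr, baf, pos, params: HmmParams) -> float:
    """Joint log-likelihood of one explicit state path (oracle scoring)."""
    states = np.asarray(states, dtype=int)
    emis = params.log_emission(np.asarray(lrr, float), np.asarray(baf, float))
    total = params.log_prior()[states[0]] + emis[0, states[0]]
    for t in range(1, len(states)):
        trans = params.log_transition(pos[t] - pos[t - 1])
        total += trans[states[t - 1], states[t]] + emis[t, states[t]]
    return float(total)


def _runs(path: np.ndarray):
    """Maximal runs of same-sign non-neutral states: yields (start, stop, sign)."""
    sign = np.where(path < _NEUTRAL, -1, np.where(path > _NEUTRAL, 1, 0))
    i = 0
    n = len(path)
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sign[j + 1] == sign[i]:
            j += 1
        yield i, j, sign[i]
        i = j + 1


def call_sample(
    lrr,
    baf,
    marker_map: MarkerMap,
    params: HmmParams | None = None,
    sample_id: str = "sample",
) -> list[CnvCall]:
    """Segment one sample's genome-wide LRR/BAF vectors into CNV calls."""
    if params is None:
        params = HmmParams()
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    if len(lrr) != len(marker_map) or len(baf) != len(marker_map):
        raise ValueError(
            f"signal length {len(lrr)}/{len(baf)} does not match map ({len(marker_map)})"
        )
    calls = []
    pos_all = marker_map.df["pos"].to_numpy()
    for chrom in marker_map.chroms:
        idx = marker_map.chrom_index(chrom)
        path = viterbi(lrr[idx], baf[idx], pos_all[idx], params)
        for i, j, sign in _runs(path):
            states, counts = np.unique(path[i : j + 1], return_counts=True)
            cn = int(states[np.argmax(counts)])
            calls.append(
                CnvCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(pos_all[idx[i]]),
                    end=int(pos_all[idx[j]]),
                    type="del" if sign < 0 else "dup",
                    copy_number=cn,
                    n_snps=j - i + 1,
                    source="array",
                )
            )
    return calls


def filter_calls(
    calls,
    min_snps: int = 10,
    min_length: int = 20_000,
    regions: ExclusionRegions | None = None,
    exclusion_fraction: float = 0.5,
) -> list[CnvCall]:
    """Per-call filters: marker support, length, and excluded-region overlap.

    Thresholds are inclusive on the keep side (exactly 10 markers or exactly
    20 kb passes); a call is dropped when at least ``exclusion_fraction`` of
    its length lies inside an exclusion region.
    """
    out = []
    for c in calls:
        if c.n_snps < min_snps or c.length < min_length:
            continue
        if regions is not None and len(regions):
            if regions.overlap_length(c.chrom, c.start, c.end) / c.length >= exclusion_fraction:
                continue
        out.append(c)
    return out


def drop_noisy_samples(calls_by_sample: dict, max_cnv: int = 50) -> tuple[dict, list]:
    """Remove samples with more than ``max_cnv`` post-filter calls.

    Returns (retained calls_by_sample, dropped sample ids); exactly
    ``max_cnv`` calls is retained.
    """
    retained, dropped = {}, []
    for sid, calls in calls_by_sample.items():
        if len(calls) > max_cnv:
            dropped.append(sid)
            log.warning("sample %s dropped: %d calls > %d", sid, len(calls), max_cnv)
        else:
            retained[sid] = calls
    return retained, dropped


def merge_adjacent(
    calls,
    fraction: float = 0.2,
    marker_map: MarkerMap | None = None,
) -> list[CnvCall]:
    """Merge nearby same-sample/same-chrom/same-type calls, to a fixpoint.

    Two calls merge when the inter-call gap is at most ``fraction`` of the
    merged span (gap / (total span) <= fraction). A merged call's marker
    count is the members' sum plus, when a map is supplied, the markers in
    the gap; its copy number is taken from the larger member.
    """
    groups: dict[tuple, list] = {}
    passthrough = []
    for c in calls:
        groups.setdefault((c.sample_id, c.chrom, c.type, c.source), []).append(c)
    out = []
    for key, group in groups.items():
        group = sorted(group, key=lambda c: (c.start, c.end))
        changed = True
        while changed:
            changed = False
            merged = [group[0]]
            for c in group[1:]:
                prev = merged[-1]
                gap = max(0, c.start - prev.end - 1)
                span = max(prev.end, c.end) - prev.start + 1
                if gap / span <= fraction:
                    if marker_map is not None:
                        gap_snps = (
                            len(marker_map.markers_in(prev.chrom, prev.end + 1, c.start - 1))
                            if c.start > prev.end + 1
                            else 0
                        )
                    else:
                        gap_snps = 0
                    big = prev if prev.n_snps >= c.n_snps else c
                    merged[-1] = prev.replace(
                        end=max(prev.end, c.end),
                        n_snps=prev.n_snps + c.n_snps + gap_snps,
                        copy_number=big.copy_number,
                    )
                    changed = True
                else:
                    merged.append(c)
            group = merged
        out.extend(group)
    out.extend(passthrough)
    return sorted(out, key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
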