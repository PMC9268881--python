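"""Per-sample intensity QC and principal-component batch correction.

QC metrics mirror the usual SNP-array sample filters: the standard
deviation of autosomal LRR (noisy hybridisations), BAF drift (the fraction
of markers whose BAF falls in the off-cluster bands [0.2, 0.25] or
[0.75, 0.8]) and a waviness factor. Default pass thresholds are
lrr_sd <= 0.3, baf_drift <= 0.01 and waviness <= 0.05.

The waviness factor here is the standard deviation of per-window (1 Mb)
median LRR across autosomes — a documented stand-in for the GC-model
waviness of dedicated callers, capturing long-range intensity waves
rather than marker-to-marker noise.

Batch correction removes the top principal components of the mean-centred
LRR matrix, fit on markers outside telomeric/centromeric/immunoglobulin-like
exclusion regions, from every marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import IntensityPanel, MarkerMap, QcMetrics, intersection_length

__all__ = [
    "ExclusionRegions",
    "compute_qc_metrics",
    "qc_report",
    "PcCorrection",
    "pc_correct",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = {"lrr_sd": 0.3, "baf_drift": 0.01, "waviness": 0.05}

_DRIFT_BANDS = ((0.2, 0.25), (0.75, 0.8))


class ExclusionRegions:
    """Sorted, merged genomic intervals excluded from PC fitting and calls."""

    def __init__(self, intervals):
        cleaned = []
        for chrom, start, end, *_ in intervals:
            if start > end or start < 0:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            cleaned.append((str(chrom), int(start), int(end)))
        cleaned.sort()
        merged: list[list] = []
        for chrom, start, end in cleaned:
            if merged and merged[-1][0] == chrom and start <= merged[-1][2] + 1:
                merged[-1][2] = max(merged[-1][2], end)
            else:
                merged.append([chrom, start, end])
        self.intervals = [tuple(iv) for iv in merged]

    @classmethod
    def from_bed(cls, path) -> "ExclusionRegions":
        from .io import read_bed

        return cls(read_bed(path))

    @classmethod
    def empty(cls) -> "ExclusionRegions":
        return cls([])

    def __len__(self) -> int:
        return len(self.intervals)

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        return sum(
            intersection_length(start, end, s, e)
            for c, s, e in self.intervals
            if c == str(chrom)
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == str(chrom) and s <= pos <= e for c, s, e in self.intervals)

    def marker_mask(self, marker_map: MarkerMap) -> np.ndarray:
        """Boolean mask over the map: True for markers inside a region."""
        mask = np.zeros(len(marker_map), dtype=bool)
        df = marker_map.df
        for chrom, start, end in self.intervals:
            mask |= ((df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)).to_numpy()
        return mask


def _waviness(lrr: np.ndarray, chrom: np.ndarray, pos: np.ndarray, window: int = 1_000_000) -> float:
    medians = []
    for c in pd.unique(chrom):
        sel = chrom == c
        p, x = pos[sel], lrr[sel]
        for w in np.unique(p // window):
            win = x[p // window == w]
            if len(win):
                medians.append(np.median(win))
    if len(medians) < 2:
        return 0.0
    return float(np.std(medians, ddof=0))


def compute_qc_metrics(
    panel: IntensityPanel,
    sample_id: str,
    thresholds: dict | None = None,
) -> QcMetrics:
    """QC metrics for one sample, with pass flags at the default thresholds.

    ``lrr_sd`` is the population standard deviation over autosomal markers
    (all of this package's synthetic chromosomes are autosomes; markers on
    chromosomes named X/Y/MT are excluded).
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    lrr, baf = panel.sample(sample_id)  # raises KeyError if absent
    chrom = panel.map.df["chrom"].to_numpy()
    pos = panel.map.df["pos"].to_numpy()
    autosomal = ~np.isin(chrom, ("X", "Y", "MT", "M", "23", "24", "25"))
    if autosomal.sum() < 2:
        raise ValueError("need at least 2 autosomal markers for QC")
    a_lrr = lrr[autosomal]
    lrr_sd = float(np.std(a_lrr, ddof=0))
    in_band = np.zeros(len(baf), dtype=bool)
    for lo, hi in _DRIFT_BANDS:
        in_band |= (baf >= lo) & (baf <= hi)
    baf_drift = float(np.mean(in_band))
    wf = _waviness(a_lrr, chrom[autosomal], pos[autosomal])
    return QcMetrics(
        sample_id=sample_id,
        lrr_sd=lrr_sd,
        baf_drift=baf_drift,
        waviness=wf,
        pass_lrr_sd=lrr_sd <= th["lrr_sd"],
        pass_baf_drift=baf_drift <= th["baf_drift"],
        pass_waviness=wf <= th["waviness"],
    )


def qc_report(panel: IntensityPanel, thresholds: dict | None = None) -> pd.DataFrame:
    """QC metric table over all samples in a panel."""
    rows = []
    for iid in panel.sample_ids:
        m = compute_qc_metrics(panel, iid, thresholds)
        rows.append(
            {
                "sample_id": m.sample_id,
                "lrr_sd": m.lrr_sd,
                "baf_drift": m.baf_drift,
                "waviness": m.waviness,
                "passed": m.passed,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PcCorrection:
    """Fitted principal components of a sample x marker LRR matrix.

    Components are fit on the mean-centred submatrix of markers outside the
    exclusion regions; applying the correction regresses the retained
    per-sample scores out of every marker column and restores the
    per-marker means. Applying a fitted correction twice is a no-op, and
    per-marker variance can only decrease.
    """

    scores: np.ndarray  # samples x n_pcs, orthonormal columns
    n_pcs: int

    @classmethod
    def fit(
        cls,
        lrr: pd.DataFrame,
        marker_map: MarkerMap,
        regions: ExclusionRegions | None,
        n_pcs: int,
    ) -> "PcCorrection":
        n_samples, n_markers = lrr.shape
        if not (0 <= n_pcs < min(n_samples, n_markers)):
            raise ValueError(
                f"n_pcs must be in [0, {min(n_samples, n_markers)}), got {n_pcs}"
            )
        if n_pcs == 0:
            return cls(scores=np.zeros((n_samples, 0)), n_pcs=0)
        mask = (
            ~regions.marker_mask(marker_map)
            if regions is not None and len(regions)
            else np.ones(n_markers, dtype=bool)
        )
        x = lrr.to_numpy(dtype=float)[:, mask]
        xc = x - x.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        return cls(scores=u[:, :n_pcs], n_pcs=n_pcs)

    def apply(self, lrr: pd.DataFrame) -> pd.DataFrame:
        if self.n_pcs == 0:
            return lrr.copy()
        x = lrr.to_numpy(dtype=float)
        mu = x.mean(axis=0, keepdims=True)
        xc = x - mu
        u = self.scores
        resid = xc - u @ (u.T @ xc)
        return pd.DataFrame(resid + mu, index=lrr.index, columns=lrr.columns)


def pc_correct(
    lrr: pd.DataFrame,
    regions: ExclusionRegions | None,
    marker_map: MarkerMap,
    n_pcs: int = 2,
) -> pd.DataFrame:
    """Fit and apply PC batch correction in one step (n_pcs=0 is identity)."""
    return PcCorrection.fit(lrr, marker_map, regions, n_pcs).apply(lrr)
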