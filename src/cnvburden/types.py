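"""Core domain types shared across the pipeline.

Coordinates are 1-based and inclusive throughout (PennCNV/PLINK convention),
so the length of an interval is ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "CnvCall",
    "TruthCnv",
    "QcMetrics",
    "Pedigree",
    "IntensityPanel",
    "interval_length",
    "intersection_length",
    "union_length",
]


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive interval."""
    return end - start + 1


def intersection_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap (bp) of two 1-based inclusive intervals; 0 if disjoint."""
    lo = max(a_start, b_start)
    hi = min(a_end, b_end)
    return max(0, hi - lo + 1)


def union_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Union length (bp) of two 1-based inclusive intervals on one chromosome."""
    return (
        interval_length(a_start, a_end)
        + interval_length(b_start, b_end)
        - intersection_length(a_start, a_end, b_start, b_end)
    )


class MarkerMap:
    """Ordered SNP marker map with population B-allele frequencies.

    Wraps a DataFrame with columns ``marker_id``, ``chrom``, ``pos`` (1-based
    bp) and ``pfb`` (population frequency of the B allele, the caller's
    allele-frequency prior). Positions must be strictly increasing within
    each chromosome.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"marker_id", "chrom", "pos", "pfb"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("marker map is empty")
        df = df.reset_index(drop=True)
        if df["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        if ((df["pfb"] < 0) | (df["pfb"] > 1)).any():
            raise ValueError("pfb values must lie in [0, 1]")
        for chrom, sub in df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on chrom {chrom}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Positional indices (into the map order) of one chromosome's markers."""
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    def markers_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Positional indices of markers inside [start, end] on ``chrom``."""
        mask = (
            (self.df["chrom"] == chrom)
            & (self.df["pos"] >= start)
            & (self.df["pos"] <= end)
        )
        return np.flatnonzero(mask.to_numpy())


@dataclass(frozen=True)
class CnvCall:
    """One copy-number event in one sample.

    ``type`` is ``del`` (copy number < 2) or ``dup`` (> 2); ``source`` records
    the platform that produced the call (``array``, ``wgs`` or ``wes``).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    type: str
    copy_number: int
    n_snps: int
    source: str = "array"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start > end for call {self}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.type not in ("del", "dup"):
            raise ValueError(f"unknown CNV type {self.type!r}")
        if (self.copy_number < 2) != (self.type == "del"):
            raise ValueError(
                f"type {self.type} inconsistent with copy number {self.copy_number}"
            )

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)

    def overlap(self, other: "CnvCall") -> int:
        if self.chrom != other.chrom:
            return 0
        return intersection_length(self.start, self.end, other.start, other.end)

    def replace(self, **kw) -> "CnvCall":
        return replace(self, **kw)


@dataclass(frozen=True)
class TruthCnv:
    """Ground-truth implanted CNV for synthetic cohorts.

    ``inherited_from`` is a parent sample id, ``de_novo`` or ``founder``.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    inherited_from: str = "founder"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start > end")
        if self.copy_number == 2:
            raise ValueError("a truth CNV cannot be copy-neutral")

    @property
    def type(self) -> str:
        return "del" if self.copy_number < 2 else "dup"

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)


@dataclass(frozen=True)
class QcMetrics:
    """Per-sample intensity QC summary with pass/fail flags."""

    sample_id: str
    lrr_sd: float
    baf_drift: float
    waviness: float
    pass_lrr_sd: bool = field(default=True)
    pass_baf_drift: bool = field(default=True)
    pass_waviness: bool = field(default=True)

    @property
    def passed(self) -> bool:
        return self.pass_lrr_sd and self.pass_baf_drift and self.pass_waviness


class Pedigree:
    """Family graph in PED semantics.

    One row per individual: ``fid, iid, father, mother, sex, phenotype``
    with sex 1=male/2=female/0=unknown and phenotype 1=unaffected,
    2=affected, 0 or -9 = unknown. ``father``/``mother`` of founders is "0".
    """

    def __init__(self, df: pd.DataFrame):
        required = {"fid", "iid", "father", "mother", "sex", "phenotype"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        df = df.reset_index(drop=True)
        if df["iid"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        self.df = df
        self._by_iid = {row.iid: row for row in df.itertuples(index=False)}

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_iid

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list:
        return list(self.df["iid"])

    def family_of(self, iid: str) -> str:
        return self._entry(iid).fid

    def parents_of(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        """(father, mother) ids, None for unknown/founder parents."""
        row = self._entry(iid)
        father = row.father if row.father not in ("0", 0, "") else None
        mother = row.mother if row.mother not in ("0", 0, "") else None
        return father, mother

    def is_affected(self, iid: str) -> Optional[bool]:
        ph = int(self._entry(iid).phenotype)
        if ph == 2:
            return True
        if ph == 1:
            return False
        return None

    def sex_of(self, iid: str) -> int:
        return int(self._entry(iid).sex)

    def children_of(self, iid: str) -> list:
        mask = (self.df["father"] == iid) | (self.df["mother"] == iid)
        return list(self.df.loc[mask, "iid"])

    def _entry(self, iid: str):
        try:
            return self._by_iid[iid]
        except KeyError:
            raise KeyError(f"individual {iid!r} not in pedigree") from None


class IntensityPanel:
    """Per-sample LRR/BAF vectors on a shared marker map.

    ``lrr`` and ``baf`` are DataFrames indexed by sample id with one column
    per marker, column order identical to the map order.
    """

    def __init__(self, marker_map: MarkerMap, lrr: pd.DataFrame, baf: pd.DataFrame):
        if not (list(lrr.columns) == list(baf.columns) == list(marker_map.marker_ids)):
            raise ValueError("LRR/BAF columns must match the marker map order")
        if list(lrr.index) != list(baf.index):
            raise ValueError("LRR and BAF sample indices differ")
        self.map = marker_map
        self.lrr = lrr
        self.baf = baf

    @property
    def sample_ids(self) -> list:
        return list(self.lrr.index)

    def sample(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(lrr, baf) vectors for one sample, in map order."""
        if sample_id not in self.lrr.index:
            raise KeyError(f"sample {sample_id!r} not in panel")
        return (
            self.lrr.loc[sample_id].to_numpy(dtype=float),
            self.baf.loc[sample_id].to_numpy(dtype=float),
        )

    def copy(self) -> "IntensityPanel":
        return IntensityPanel(self.map, self.lrr.copy(), self.baf.copy())
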