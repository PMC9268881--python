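"""Synthetic cohort generator with known ground truth.

Emulates what the pipeline consumes from a real genotyping study: per-sample
LRR/BAF intensity vectors on a shared marker map with implanted deletions and
duplications, trio or extended pedigrees with genotype-dependent incompletely
penetrant phenotypes, sequencing-derived CNV call sets for a subset of
samples, and annotated variant tables for variants located inside deletions.
Every stochastic choice is driven by one seeded generator, so a fixed seed
yields byte-identical bundles.

The generator deliberately omits linkage disequilibrium (genotypes are drawn
independently per marker under Hardy-Weinberg) and GC waves; batch effects
are a rank-one additive LRR offset (per-marker loading times per-batch
score), which a single principal component can remove exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import CnvCall, IntensityPanel, MarkerMap, Pedigree, TruthCnv

__all__ = [
    "SignalModel",
    "CohortConfig",
    "CohortBundle",
    "simulate_cohort",
    "implant_cnv",
    "simulate_burden_table",
    "simulate_caller_benchmark",
    "write_bundle",
]

TISSUES = ("amygdala", "cortex", "hippocampus")


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SignalModel:
    """Intensity signatures of each copy-number state.

    LRR means follow common SNP-array practice: a homozygous deletion wipes
    out the signal (about -3.5), a hemizygous deletion sits near -0.66, and
    single/double duplications near +0.40/+0.68. BAF clusters are the allele
    ratios each state permits; the four-copy state is approximated without
    its 0.5 cluster.
    """

    lrr_means: dict = field(
        default_factory=lambda: {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}
    )

    def baf_clusters(self, copy_number: int) -> Optional[list[float]]:
        """Allowed BAF clusters; None means no signal (cn=0, BAF is noise)."""
        return {
            0: None,
            1: [0.0, 1.0],
            2: [0.0, 0.5, 1.0],
            3: [0.0, 1 / 3, 2 / 3, 1.0],
            4: [0.0, 0.25, 0.75, 1.0],
        }[copy_number]

    def draw_baf(self, copy_number: int, pfb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw noise-free BAF cluster values for markers with prior freq pfb."""
        if copy_number == 0:
            return rng.uniform(0.0, 1.0, size=len(pfb))
        n = copy_number
        k = rng.binomial(n, pfb)
        if copy_number == 4:
            # no distinct 0.5 band: push balanced genotypes to a flanking cluster
            mid = k == 2
            k = np.where(mid, np.where(rng.random(len(pfb)) < 0.5, 1, 3), k)
        return k / n


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    Defaults describe a desk-scale familial epilepsy study: a few dozen
    families (trios or three-generation extended families) plus unrelated
    population controls, genotyped in two batches on a four-chromosome toy
    genome, with one large risk CNV segregating per carrier family under
    incomplete penetrance.
    """

    n_families: int = 30
    family_structure: str = "trio"  # "trio" | "extended"
    n_population_controls: int = 100
    n_chromosomes: int = 4
    n_markers_per_chrom: int = 1500
    marker_spacing: int = 5000  # mean inter-marker distance, bp
    n_batches: int = 2
    batch_offset_sd: float = 0.1  # LRR units
    noise_sd_lrr: float = 0.15
    noise_sd_baf: float = 0.03
    penetrance: float = 0.8
    baseline_risk: float = 0.05
    sex_effect: float = 0.0  # additive log-odds of affection for males
    p_family_cnv: float = 0.6
    family_cnv_large: bool = True
    family_cnv_length: tuple = (1_050_000, 1_500_000)  # bp, when large
    p_cnv_at_hotspot: float = 0.3
    background_cnv_rate: float = 0.3  # Poisson mean per founder/control
    de_novo_rate: float = 0.02
    n_common_loci: int = 2
    common_cnv_freq: float = 0.05
    seq_fraction: float = 0.5
    boundary_jitter: float = 0.05  # seq-call endpoint jitter, fraction of length
    p_lof_variant: float = 0.0  # chance a deletion hides a fully truncating SNV
    group_proportions: dict = field(
        default_factory=lambda: {"GGE": 0.4, "NAFE": 0.3, "mixed": 0.1, "DEE": 0.2}
    )
    force_transmission: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "penetrance",
            "baseline_risk",
            "p_family_cnv",
            "p_cnv_at_hotspot",
            "common_cnv_freq",
            "seq_fraction",
            "boundary_jitter",
            "p_lof_variant",
        ):
            _check_prob(name, getattr(self, name))
        if self.n_markers_per_chrom < 1 or self.n_chromosomes < 1:
            raise ConfigurationError("marker map would be empty")
        if self.family_structure not in ("trio", "extended"):
            raise ConfigurationError(f"unknown family_structure {self.family_structure!r}")
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("group_proportions must sum to 1")


@dataclass
class CohortBundle:
    """Everything simulate_cohort produces, with ground truth attached."""

    config: CohortConfig
    marker_map: MarkerMap
    panel: IntensityPanel
    pedigree: Pedigree
    samples: pd.DataFrame  # sample_id, family, role, group, sex, batch, affected, ...
    truth_cnvs: list
    seq_calls: list
    variants: list
    variant_truth: list
    genes: pd.DataFrame
    gene_sets: dict
    hotspots: list  # (name, chrom, start, end)
    directionality: pd.DataFrame
    expression_change: dict
    uneecon_scores: dict
    external_af: dict

    @property
    def truth_by_sample(self) -> dict:
        out: dict[str, list] = {}
        for t in self.truth_cnvs:
            out.setdefault(t.sample_id, []).append(t)
        return out


# ---------------------------------------------------------------------------
# intensity construction


def implant_cnv(
    panel: IntensityPanel,
    cnv: TruthCnv,
    signal_model: SignalModel | None = None,
    rng: np.random.Generator | None = None,
    noise_sd_lrr: float = 0.0,
    noise_sd_baf: float = 0.0,
) -> IntensityPanel:
    """Return a copy of ``panel`` with ``cnv``'s intensity signature written in.

    Markers inside the event get LRR re-centred on the state mean and BAF
    drawn from the state's allowed cluster set (plus optional noise); markers
    outside are untouched.
    """
    if signal_model is None:
        signal_model = SignalModel()
    if rng is None:
        rng = np.random.default_rng(0)
    idx = panel.map.markers_in(cnv.chrom, cnv.start, cnv.end)
    if len(idx) == 0:
        raise ValueError(
            f"no markers in interval {cnv.chrom}:{cnv.start}-{cnv.end}"
        )
    out = panel.copy()
    lrr = out.lrr.loc[cnv.sample_id].to_numpy(dtype=float)
    baf = out.baf.loc[cnv.sample_id].to_numpy(dtype=float)
    pfb = panel.map.df["pfb"].to_numpy()[idx]
    lrr[idx] = signal_model.lrr_means[cnv.copy_number] + rng.normal(
        0.0, noise_sd_lrr, size=len(idx)
    ) if noise_sd_lrr > 0 else signal_model.lrr_means[cnv.copy_number]
    clusters = signal_model.draw_baf(cnv.copy_number, pfb, rng)
    if noise_sd_baf > 0:
        clusters = np.clip(clusters + rng.normal(0.0, noise_sd_baf, size=len(idx)), 0.0, 1.0)
    baf[idx] = clusters
    out.lrr.loc[cnv.sample_id] = lrr
    out.baf.loc[cnv.sample_id] = baf
    return out


def _make_marker_map(cfg: CohortConfig, rng: np.random.Generator) -> MarkerMap:
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        gaps = rng.integers(
            max(1, cfg.marker_spacing // 2),
            cfg.marker_spacing + cfg.marker_spacing // 2,
            size=cfg.n_markers_per_chrom,
        )
        pos = np.cumsum(gaps) + 1000
        pfb = np.round(rng.uniform(0.05, 0.95, size=cfg.n_markers_per_chrom), 4)
        for i in range(cfg.n_markers_per_chrom):
            rows.append((f"rs{c}_{i + 1}", str(c), int(pos[i]), float(pfb[i])))
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "pfb"]))


def _chrom_span(marker_map: MarkerMap, chrom: str) -> tuple[int, int]:
    sub = marker_map.df[marker_map.df["chrom"] == chrom]["pos"]
    return int(sub.iloc[0]), int(sub.iloc[-1])


def _make_genes_hotspots(cfg: CohortConfig, marker_map: MarkerMap, rng: np.random.Generator):
    """Tile synthetic genes along each chromosome; one hotspot per chromosome."""
    genes = []
    hotspots = []
    for chrom in marker_map.chroms:
        lo, hi = _chrom_span(marker_map, chrom)
        pos = lo + 50_000
        i = 0
        while pos + 80_000 < hi:
            i += 1
            length = int(rng.integers(30_000, 70_000))
            genes.append((f"GENE{chrom}_{i}", chrom, pos, pos + length - 1, "+"))
            pos += length + int(rng.integers(80_000, 160_000))
        mid = (lo + hi) // 2
        hotspots.append((f"hs{chrom}q", chrom, mid - 600_000, mid + 600_000))
    gene_df = pd.DataFrame(genes, columns=["symbol", "chrom", "start", "end", "strand"])
    symbols = gene_df["symbol"].tolist()
    gene_sets = {
        "epilepsy": set(symbols[::10]),
        "pli": set(symbols[3::7]),
    }
    return gene_df, gene_sets, hotspots


# ---------------------------------------------------------------------------
# pedigree construction


def _build_families(cfg: CohortConfig, rng: np.random.Generator):
    """Pedigree rows (phenotype filled later) + per-family group labels."""
    groups = list(cfg.group_proportions)
    probs = np.array([cfg.group_proportions[g] for g in groups])
    ped_rows = []  # fid iid father mother sex
    roles = {}  # iid -> role
    fam_group = {}
    for f in range(1, cfg.n_families + 1):
        fid = f"F{f:04d}"
        group = groups[rng.choice(len(groups), p=probs)]
        fam_group[fid] = group
        structure = "trio" if group == "DEE" else cfg.family_structure
        if structure == "trio":
            fa, mo, ch = f"{fid}_fa", f"{fid}_mo", f"{fid}_ch"
            ped_rows += [
                (fid, fa, "0", "0", 1),
                (fid, mo, "0", "0", 2),
                (fid, ch, fa, mo, int(rng.integers(1, 3))),
            ]
            roles.update({fa: "parent", mo: "parent", ch: "child"})
        else:
            gp1, gp2 = f"{fid}_gp1", f"{fid}_gp2"
            ped_rows += [(fid, gp1, "0", "0", 1), (fid, gp2, "0", "0", 2)]
            roles.update({gp1: "founder", gp2: "founder"})
            for b in (1, 2):
                par = f"{fid}_p{b}"
                sex = 1 if b == 1 else 2
                spouse = f"{fid}_s{b}"
                ped_rows += [
                    (fid, par, gp1, gp2, sex),
                    (fid, spouse, "0", "0", 3 - sex),
                ]
                roles.update({par: "parent", spouse: "spouse"})
                for c in (1, 2):
                    ch = f"{fid}_c{b}{c}"
                    father = par if sex == 1 else spouse
                    mother = spouse if sex == 1 else par
                    ped_rows += [(fid, ch, father, mother, int(rng.integers(1, 3)))]
                    roles[ch] = "child"
    return ped_rows, roles, fam_group


# ---------------------------------------------------------------------------
# CNV placement


def _random_interval(
    marker_map: MarkerMap,
    rng: np.random.Generator,
    length_range: tuple[int, int],
    min_markers: int = 20,
) -> tuple[str, int, int]:
    for _ in range(200):
        chrom = marker_map.chroms[rng.integers(len(marker_map.chroms))]
        lo, hi = _chrom_span(marker_map, chrom)
        length = int(rng.integers(*length_range))
        if hi - lo < length + 2:
            continue
        start = int(rng.integers(lo, hi - length))
        end = start + length - 1
        if len(marker_map.markers_in(chrom, start, end)) >= min_markers:
            return chrom, start, end
    raise ConfigurationError("could not place a CNV with enough marker support")


def _transmit(cnv_region, carriers_out, pedigree_rows, carrier_founders, rng, force):
    """Drop a founder CNV down the pedigree; returns {iid: inherited_from}."""
    status = dict(carrier_founders)  # iid -> label for carriers
    by_child = {r[1]: (r[2], r[3]) for r in pedigree_rows}
    # iterate in pedigree order: parents always precede children in our rows
    for _, iid, father, mother, _sex in pedigree_rows:
        if iid in status:
            continue
        for parent in (father, mother):
            if parent in status:
                p = 1.0 if force else 0.5
                if rng.random() < p:
                    status[iid] = parent
                break
    return status


# ---------------------------------------------------------------------------
# main entry point


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Simulate a complete cohort bundle under ``config``.

    Families carry at most one segregating risk CNV implanted in a founder
    and transmitted Mendelianly (probability 0.5 per meiosis unless
    ``force_transmission``); DEE families instead receive the event de novo
    in the proband. Affection status is drawn per individual: carriers of
    the family risk CNV are affected with probability ``penetrance``,
    everyone else with ``baseline_risk``, optionally shifted on the log-odds
    scale for males. Background and common-locus CNVs are phenotype-neutral.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    marker_map = _make_marker_map(cfg, rng)
    genes, gene_sets, hotspots = _make_genes_hotspots(cfg, marker_map, rng)

    ped_rows, roles, fam_group = _build_families(cfg, rng)
    for i in range(1, cfg.n_population_controls + 1):
        iid = f"CTRL{i:04d}"
        ped_rows.append((iid, iid, "0", "0", int(rng.integers(1, 3))))
        roles[iid] = "population_control"
        fam_group[iid] = "control"

    sample_ids = [r[1] for r in ped_rows]
    founders = [r[1] for r in ped_rows if r[2] == "0" and r[3] == "0"]

    # --- truth CNVs -------------------------------------------------------
    truth: list[TruthCnv] = []
    risk_carrier: dict[str, bool] = {iid: False for iid in sample_ids}

    # common polymorphic loci (phenotype-neutral, frequency > rare cutoff)
    common_loci = []
    for li in range(cfg.n_common_loci):
        chrom, start, end = _random_interval(marker_map, rng, (120_000, 220_000))
        cn = 1 if li % 2 == 0 else 3
        common_loci.append((chrom, start, end, cn))
    for chrom, start, end, cn in common_loci:
        carrier_founders = {
            iid: "founder" for iid in founders if rng.random() < cfg.common_cnv_freq
        }
        status = _transmit(None, None, ped_rows, carrier_founders, rng, False)
        for iid, label in status.items():
            truth.append(TruthCnv(iid, chrom, start, end, cn, label))

    # family risk CNVs
    fids = sorted({r[0] for r in ped_rows if not r[0].startswith("CTRL")})
    for fid in fids:
        if rng.random() >= cfg.p_family_cnv:
            continue
        cn = 1 if rng.random() < 0.7 else 3
        if cfg.family_cnv_large:
            if rng.random() < cfg.p_cnv_at_hotspot:
                name, chrom, hs_start, hs_end = hotspots[rng.integers(len(hotspots))]
                pad = int(rng.integers(20_000, 120_000))
                start, end = hs_start - pad, hs_end + pad
            else:
                chrom, start, end = _random_interval(marker_map, rng, cfg.family_cnv_length)
        else:
            chrom, start, end = _random_interval(marker_map, rng, (150_000, 400_000))
        members = [r for r in ped_rows if r[0] == fid]
        if fam_group[fid] == "DEE":
            # de novo in the proband: parents are non-carriers
            child = [r[1] for r in members if r[2] != "0"][0]
            truth.append(TruthCnv(child, chrom, start, end, cn, "de_novo"))
            risk_carrier[child] = True
            continue
        fam_founders = [r[1] for r in members if r[2] == "0" and r[3] == "0"]
        carrier = fam_founders[rng.integers(len(fam_founders))]
        status = _transmit(None, None, members, {carrier: "founder"}, rng, cfg.force_transmission)
        for iid, label in status.items():
            truth.append(TruthCnv(iid, chrom, start, end, cn, label))
            risk_carrier[iid] = True

    # sporadic de novo CNVs in children (independent of risk-CNV status, so
    # double-hit carriers can arise)
    for fid, iid, father, mother, _sex in ped_rows:
        if father == "0":
            continue
        if rng.random() < cfg.de_novo_rate:
            chrom, start, end = _random_interval(marker_map, rng, (1_000_001, 1_400_000))
            cn = 1 if rng.random() < 0.5 else 3
            truth.append(TruthCnv(iid, chrom, start, end, cn, "de_novo"))

    # background CNVs in founders/controls, transmitted Mendelianly
    for iid in founders:
        for _ in range(rng.poisson(cfg.background_cnv_rate)):
            chrom, start, end = _random_interval(marker_map, rng, (80_000, 350_000))
            cn = 1 if rng.random() < 0.5 else 3
            carrier_founders = {iid: "founder"}
            fid = next(r[0] for r in ped_rows if r[1] == iid)
            members = [r for r in ped_rows if r[0] == fid]
            status = _transmit(None, None, members, carrier_founders, rng, False)
            for carrier, label in status.items():
                truth.append(TruthCnv(carrier, chrom, start, end, cn, label))

    # --- phenotypes -------------------------------------------------------
    sex_by_iid = {r[1]: r[4] for r in ped_rows}
    affected = {}
    for iid in sample_ids:
        p = cfg.penetrance if risk_carrier[iid] else cfg.baseline_risk
        if cfg.sex_effect != 0.0 and 0.0 < p < 1.0:
            logit = math.log(p / (1 - p)) + cfg.sex_effect * (sex_by_iid[iid] == 1)
            p = 1.0 / (1.0 + math.exp(-logit))
        affected[iid] = rng.random() < p

    ped_df = pd.DataFrame(
        [
            (fid, iid, fa, mo, sex, 2 if affected[iid] else 1)
            for fid, iid, fa, mo, sex in ped_rows
        ],
        columns=["fid", "iid", "father", "mother", "sex", "phenotype"],
    )
    pedigree = Pedigree(ped_df)

    # --- sample metadata ---------------------------------------------------
    batches = {iid: f"B{(i % cfg.n_batches) + 1}" for i, iid in enumerate(sample_ids)}
    has_seq = {}
    seq_platform = {}
    for iid in sample_ids:
        in_family = not roles[iid].startswith("population")
        has_seq[iid] = in_family and rng.random() < cfg.seq_fraction
        seq_platform[iid] = ("wgs" if rng.random() < 0.5 else "wes") if has_seq[iid] else None
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "family": [r[0] for r in ped_rows],
            "role": [roles[i] for i in sample_ids],
            "group": [fam_group[r[0]] for r in ped_rows],
            "sex": [sex_by_iid[i] for i in sample_ids],
            "batch": [batches[i] for i in sample_ids],
            "affected": [affected[i] for i in sample_ids],
            "risk_carrier": [risk_carrier[i] for i in sample_ids],
            "platform": [seq_platform[i] for i in sample_ids],
        }
    )
    samples["is_dee_parent"] = (
        (samples["group"] == "DEE") & (samples["role"] == "parent") & (~samples["affected"])
    )

    # --- intensities -------------------------------------------------------
    n, m = len(sample_ids), len(marker_map)
    pfb = marker_map.df["pfb"].to_numpy()
    model = SignalModel()
    # copy-neutral baseline: genotype under HWE, independent markers
    genotype = rng.binomial(2, pfb[None, :].repeat(n, axis=0))
    baf = genotype / 2.0 + rng.normal(0.0, cfg.noise_sd_baf, size=(n, m))
    lrr = rng.normal(0.0, cfg.noise_sd_lrr, size=(n, m))
    # rank-one batch offset
    loading = rng.normal(0.0, 1.0, size=m)
    batch_labels = sorted(set(batches.values()))
    scores = np.linspace(-1.0, 1.0, len(batch_labels)) if len(batch_labels) > 1 else np.array([0.0])
    score_by_batch = dict(zip(batch_labels, scores * cfg.batch_offset_sd))
    sample_score = np.array([score_by_batch[batches[i]] for i in sample_ids])
    lrr += np.outer(sample_score, loading)
    # implant truth CNVs
    row_of = {iid: i for i, iid in enumerate(sample_ids)}
    for t in truth:
        idx = marker_map.markers_in(t.chrom, t.start, t.end)
        if len(idx) == 0:
            raise ConfigurationError(
                f"no markers in simulated interval {t.chrom}:{t.start}-{t.end}"
            )
        r = row_of[t.sample_id]
        lrr[r, idx] = (
            model.lrr_means[t.copy_number]
            + sample_score[r] * loading[idx]
            + rng.normal(0.0, cfg.noise_sd_lrr, size=len(idx))
        )
        clusters = model.draw_baf(t.copy_number, pfb[idx], rng)
        baf[r, idx] = np.clip(
            clusters + rng.normal(0.0, cfg.noise_sd_baf, size=len(idx)), 0.0, 1.0
        )
    baf = np.clip(baf, 0.0, 1.0)
    cols = list(marker_map.marker_ids)
    panel = IntensityPanel(
        marker_map,
        pd.DataFrame(lrr, index=sample_ids, columns=cols),
        pd.DataFrame(baf, index=sample_ids, columns=cols),
    )

    # --- sequencing-derived call sets --------------------------------------
    seq_calls = []
    for t in truth:
        platform = seq_platform.get(t.sample_id)
        if platform is None:
            continue
        j = cfg.boundary_jitter
        ds = int(round(rng.uniform(-j, j) * t.length)) if j > 0 else 0
        de = int(round(rng.uniform(-j, j) * t.length)) if j > 0 else 0
        start = max(1, t.start + ds)
        end = max(start, t.end + de)
        n_snps = max(1, len(marker_map.markers_in(t.chrom, start, end)))
        seq_calls.append(
            CnvCall(
                sample_id=t.sample_id,
                chrom=t.chrom,
                start=start,
                end=end,
                type=t.type,
                copy_number=t.copy_number,
                n_snps=n_snps,
                source=platform,
            )
        )

    # --- variants inside deletions -----------------------------------------
    variants, variant_truth = [], []
    directionality_rows = {}
    expression_change = {}
    uneecon, external_af = {}, {}
    bases = np.array(list("ACGT"))

    def _nearest_gene(chrom, pos):
        sub = genes[genes["chrom"] == chrom]
        d = np.minimum(abs(sub["start"] - pos), abs(sub["end"] - pos))
        inside = (sub["start"] <= pos) & (pos <= sub["end"])
        d = d.where(~inside, 0)
        return sub.loc[d.idxmin(), "symbol"]

    for t in truth:
        if t.type != "del" or seq_platform.get(t.sample_id) is None:
            continue
        span = t.length

        def _new_variant(offset_frac, genotype, effects, role):
            pos = t.start + int(offset_frac * span)
            ref, alt = rng.choice(bases, size=2, replace=False)
            rec = {
                "sample_id": t.sample_id,
                "chrom": t.chrom,
                "pos": pos,
                "ref": str(ref),
                "alt": str(alt),
                "genotype": genotype,
                "transcript_effects": effects,
            }
            variants.append(rec)
            variant_truth.append({**rec, "role": role, "deletion": t})
            return rec

        n_tx = int(rng.integers(4, 9))
        txs = [f"TX{t.chrom}_{t.start}_{k}" for k in range(n_tx)]
        # hom missense candidate (known benign: frequent + low UNEECON)
        n_mis = int(rng.integers(1, n_tx))
        effects = [(tx, "missense_variant") for tx in txs[:n_mis]] + [
            (tx, "synonymous_variant") for tx in txs[n_mis:]
        ]
        rec = _new_variant(0.3, "hom_alt", effects, "candidate_missense")
        key = (rec["chrom"], rec["pos"], rec["ref"], rec["alt"])
        uneecon[key] = float(np.round(rng.uniform(0.01, 0.12), 3))
        external_af[key] = float(np.round(rng.uniform(0.05, 0.4), 3))
        # optional fully penetrant truncating variant
        if rng.random() < cfg.p_lof_variant:
            effects = [(tx, "stop_gained") for tx in txs]
            _new_variant(0.45, "hom_alt", effects, "candidate_lof")
        # hom non-coding candidate with constraint-score tables
        rec = _new_variant(0.6, "hom_alt", [(tx, "intron_variant") for tx in txs], "candidate_noncoding")
        key = (rec["chrom"], rec["pos"], rec["ref"], rec["alt"])
        gene = _nearest_gene(t.chrom, rec["pos"])
        directionality_rows.setdefault(
            gene, {ts: float(np.round(rng.normal(0.0, 0.3), 3)) for ts in TISSUES}
        )
        for ts in TISSUES:
            expression_change[(key, ts)] = float(np.round(rng.normal(0.0, 0.5), 3))
        external_af[key] = float(np.round(rng.uniform(0.1, 0.5), 3))
        # het genotype inside a hemizygous region: genotyping artifact
        _new_variant(0.8, "het", [(txs[0], "missense_variant")], "artifact_het")
        # hom variant just past the deletion boundary: must not be screened
        pos = t.end + 5000
        ref, alt = rng.choice(bases, size=2, replace=False)
        rec = {
            "sample_id": t.sample_id,
            "chrom": t.chrom,
            "pos": pos,
            "ref": str(ref),
            "alt": str(alt),
            "genotype": "hom_alt",
            "transcript_effects": [(txs[0], "missense_variant")],
        }
        variants.append(rec)
        variant_truth.append({**rec, "role": "outside", "deletion": t})

    directionality = pd.DataFrame.from_dict(directionality_rows, orient="index")
    if len(directionality) == 0:
        directionality = pd.DataFrame(columns=list(TISSUES))
    directionality.index.name = "gene"

    return CohortBundle(
        config=cfg,
        marker_map=marker_map,
        panel=panel,
        pedigree=pedigree,
        samples=samples,
        truth_cnvs=truth,
        seq_calls=seq_calls,
        variants=variants,
        variant_truth=variant_truth,
        genes=genes,
        gene_sets=gene_sets,
        hotspots=hotspots,
        directionality=directionality,
        expression_change=expression_change,
        uneecon_scores=uneecon,
        external_af=external_af,
    )


# ---------------------------------------------------------------------------
# caller fidelity benchmark


def simulate_caller_benchmark(
    n_carriers: int = 40,
    n_clean: int = 20,
    min_markers: int = 20,
    noise_sd_lrr: float = 0.15,
    noise_sd_baf: float = 0.03,
    n_chromosomes: int = 2,
    n_markers_per_chrom: int = 1500,
    seed: int = 0,
) -> tuple[IntensityPanel, list[TruthCnv]]:
    """Panel with one hemizygous deletion per carrier sample plus clean samples.

    The standard caller-fidelity benchmark: deletions span at least
    ``min_markers`` markers (lengths drawn between 20 and 120 markers) at
    the stated intensity noise; clean samples carry no CNV at all, so any
    call on them is a false positive.
    """
    cfg = CohortConfig(
        n_chromosomes=n_chromosomes,
        n_markers_per_chrom=n_markers_per_chrom,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    marker_map = _make_marker_map(cfg, rng)
    pfb = marker_map.df["pfb"].to_numpy()
    pos = marker_map.df["pos"].to_numpy()
    chrom_arr = marker_map.df["chrom"].to_numpy()
    model = SignalModel()
    sample_ids = [f"CARRIER{i:03d}" for i in range(n_carriers)] + [
        f"CLEAN{i:03d}" for i in range(n_clean)
    ]
    n, m = len(sample_ids), len(marker_map)
    genotype = rng.binomial(2, pfb[None, :].repeat(n, axis=0))
    baf = np.clip(genotype / 2.0 + rng.normal(0.0, noise_sd_baf, size=(n, m)), 0, 1)
    lrr = rng.normal(0.0, noise_sd_lrr, size=(n, m))
    truths = []
    for i in range(n_carriers):
        n_mark = int(rng.integers(min_markers, 121))
        chrom = str(rng.integers(1, n_chromosomes + 1))
        cidx = np.flatnonzero(chrom_arr == chrom)
        start_k = int(rng.integers(0, len(cidx) - n_mark))
        idx = cidx[start_k : start_k + n_mark]
        t = TruthCnv(
            sample_id=sample_ids[i],
            chrom=chrom,
            start=int(pos[idx[0]]),
            end=int(pos[idx[-1]]),
            copy_number=1,
        )
        truths.append(t)
        lrr[i, idx] = model.lrr_means[1] + rng.normal(0, noise_sd_lrr, size=len(idx))
        clusters = model.draw_baf(1, pfb[idx], rng)
        baf[i, idx] = np.clip(clusters + rng.normal(0, noise_sd_baf, size=len(idx)), 0, 1)
    cols = list(marker_map.marker_ids)
    panel = IntensityPanel(
        marker_map,
        pd.DataFrame(lrr, index=sample_ids, columns=cols),
        pd.DataFrame(baf, index=sample_ids, columns=cols),
    )
    return panel, truths


# ---------------------------------------------------------------------------
# focused case-control generator for burden benchmarking


def simulate_burden_table(
    n_cases: int,
    n_controls: int,
    carrier_rate_cases: float,
    carrier_rate_controls: float,
    family_size: int = 1,
    family_phenotype_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Carrier/phenotype table for burden-model benchmarks.

    Draws carrier status at the given per-group rates; when ``family_size``
    > 1 samples are grouped into families that share a Gaussian random
    effect of SD ``family_phenotype_sd`` on the affection log-odds, creating
    genuine within-family outcome correlation for the GEE to absorb.
    """
    _check_prob("carrier_rate_cases", carrier_rate_cases)
    _check_prob("carrier_rate_controls", carrier_rate_controls)
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    phenotype = np.r_[np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
    rate = np.where(phenotype == 1, carrier_rate_cases, carrier_rate_controls)
    carrier = (rng.random(n) < rate).astype(int)
    sex = rng.integers(0, 2, size=n)
    order = rng.permutation(n)
    family = order // family_size if family_size > 1 else np.arange(n)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "phenotype": phenotype,
            "carrier": carrier,
            "sex": sex,
            "family": [f"FAM{f:05d}" for f in family],
        }
    )
    if family_size > 1 and family_phenotype_sd > 0:
        # re-draw phenotype under a shared family random effect
        base = math.log(0.3 / 0.7)
        eff = {f: rng.normal(0.0, family_phenotype_sd) for f in df["family"].unique()}
        logit = base + np.array([eff[f] for f in df["family"]])
        df["phenotype"] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return df


# ---------------------------------------------------------------------------
# writing a bundle to disk in external formats


def write_bundle(bundle: CohortBundle, outdir) -> dict:
    """Write a bundle in the external file dialects; returns path manifest."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["marker_map"] = outdir / "markers.tsv"
    cio.write_marker_map(bundle.marker_map, paths["marker_map"])
    sigdir = outdir / "signals"
    sigdir.mkdir(exist_ok=True)
    for iid in bundle.panel.sample_ids:
        lrr, baf = bundle.panel.sample(iid)
        cio.write_signal_file(bundle.marker_map.marker_ids, lrr, baf, sigdir / f"{iid}.tsv")
    paths["signals"] = sigdir
    paths["pedigree"] = outdir / "cohort.ped"
    cio.write_ped(bundle.pedigree, paths["pedigree"])
    paths["truth"] = outdir / "truth_cnvs.bed"
    cio.write_truth_bed(bundle.truth_cnvs, paths["truth"])
    paths["seq_calls"] = outdir / "seq_calls.cnv"
    cio.write_plink_cnv(bundle.seq_calls, paths["seq_calls"])
    paths["samples"] = outdir / "samples.tsv"
    bundle.samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["genes"] = outdir / "genes.tsv"
    bundle.genes.to_csv(paths["genes"], sep="\t", index=False)
    paths["hotspots"] = outdir / "hotspots.bed"
    cio.write_bed(
        ((c, s, e, n) for n, c, s, e in bundle.hotspots), paths["hotspots"]
    )
    if bundle.variants:
        paths["variants"] = outdir / "variants.vcf"
        cio.write_vcf_variants(bundle.variants, paths["variants"])
    paths["directionality"] = outdir / "directionality.tsv"
    bundle.directionality.to_csv(paths["directionality"], sep="\t")
    return paths
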