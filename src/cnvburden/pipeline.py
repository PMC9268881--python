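"""End-to-end orchestration: simulate -> qc -> correct -> call -> rare ->
validate -> annotate -> burden -> unmask, under one config and one seed.

Single-process, desk-scale. Every stage writes its outputs under the run
directory and contributes record counts and file checksums to a JSON
manifest that, together with the seed and the echoed parameters, is enough
to reproduce the run byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .annotation import GeneSet, Hotspot, annotate_cohort
from .burden import default_designs, run_burden_suite
from .caller import HmmParams, call_sample, drop_noisy_samples, filter_calls, merge_adjacent
from .catalog import cnv_frequency, filter_rare
from .qc import ExclusionRegions, pc_correct, qc_report
from .segregation import classify_segregation, detect_double_hits, validate_call
from .synthetic import CohortConfig, simulate_cohort, write_bundle
from .unmasked import (
    TableExpressionProvider,
    classify_effect,
    constraint_violation,
    label_uneecon,
    screen_deletion,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "qc",
    "correct",
    "call",
    "rare",
    "validate",
    "annotate",
    "burden",
    "unmask",
)

_DEPENDS = {
    "qc": ("simulate",),
    "correct": ("qc",),
    "call": ("correct",),
    "rare": ("call",),
    "validate": ("rare",),
    "annotate": ("rare",),
    "burden": ("annotate",),
    "unmask": ("validate",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run; defaults are the analysis defaults.

    QC at lrr_sd 0.3 / baf_drift 0.01 / waviness 0.05; calls kept at >= 10
    markers and >= 20 kb, samples dropped above 50 calls, adjacent calls
    merged at gap fraction 0.2; matching/validation overlap 0.5; rarity
    <= 1%; gene coverage 80%; hotspot coverage 50%; large-CNV threshold
    1 Mb; 16 burden tests at alpha 0.05.
    """

    outdir: str = "cnvburden_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc_lrr_sd: float = 0.3
    qc_baf_drift: float = 0.01
    qc_waviness: float = 0.05
    n_pcs: int = 2
    min_snps: int = 10
    min_length: int = 20_000
    max_cnv_per_sample: int = 50
    merge_fraction: float = 0.2
    overlap_threshold: float = 0.5
    max_freq: float = 0.01
    gene_fraction: float = 0.8
    hotspot_fraction: float = 0.5
    large_threshold: int = 1_000_000
    n_tests: int = 16
    alpha: float = 0.05
    uneecon_threshold: float = 0.15
    exclusion_bed: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        stages = {s: True for s in STAGES}
        stages.update(raw.pop("stages", {}))
        cfg = cls(cohort=cohort, stages=stages, **raw)
        cfg.cohort.seed = cfg.seed
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    A disabled stage whose outputs a later enabled stage needs makes that
    later stage refuse with a PipelineError naming both stages.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.cohort.seed = config.seed
    manifest: dict = {"seed": config.seed, "parameters": config.echo(), "stages": {}}
    done: set = set()

    def _record(stage, t0, counts, files=()):
        manifest["stages"][stage] = {
            "records": counts,
            "outputs": {str(p.name): _sha256(p) for p in files},
            "seconds": round(time.perf_counter() - t0, 3),
        }
        done.add(stage)
        log.info("stage %s done in %.2fs: %s", stage, time.perf_counter() - t0, counts)

    def _require(stage):
        for dep in _DEPENDS.get(stage, ()):
            if dep not in done:
                raise PipelineError(
                    f"stage {stage!r} needs outputs of disabled/failed stage {dep!r}"
                )

    def _enabled(stage):
        return config.stages.get(stage, True)

    bundle = None
    try:
        # --- simulate -----------------------------------------------------
        if _enabled("simulate"):
            t0 = time.perf_counter()
            bundle = simulate_cohort(config.cohort)
            paths = write_bundle(bundle, outdir / "cohort")
            _record(
                "simulate",
                t0,
                {
                    "samples": len(bundle.samples),
                    "truth_cnvs": len(bundle.truth_cnvs),
                    "seq_calls": len(bundle.seq_calls),
                    "variants": len(bundle.variants),
                },
                [paths["pedigree"], paths["truth"], paths["seq_calls"]],
            )

        # --- qc -----------------------------------------------------------
        if _enabled("qc"):
            _require("qc")
            t0 = time.perf_counter()
            report = qc_report(
                bundle.panel,
                {
                    "lrr_sd": config.qc_lrr_sd,
                    "baf_drift": config.qc_baf_drift,
                    "waviness": config.qc_waviness,
                },
            )
            qc_path = outdir / "qc_report.tsv"
            report.to_csv(qc_path, sep="\t", index=False)
            keep = set(report.loc[report["passed"], "sample_id"])
            _record(
                "qc", t0, {"samples": len(report), "passed": len(keep)}, [qc_path]
            )
        else:
            keep = set(bundle.panel.sample_ids) if bundle else set()

        # --- correct --------------------------------------------------------
        if _enabled("correct"):
            _require("correct")
            t0 = time.perf_counter()
            regions = (
                ExclusionRegions.from_bed(config.exclusion_bed)
                if config.exclusion_bed
                else ExclusionRegions.empty()
            )
            lrr = bundle.panel.lrr.loc[sorted(keep)]
            corrected = pc_correct(lrr, regions, bundle.marker_map, config.n_pcs)
            _record("correct", t0, {"samples": corrected.shape[0], "n_pcs": config.n_pcs})
        else:
            regions = ExclusionRegions.empty()
            corrected = None

        # --- call -----------------------------------------------------------
        if _enabled("call"):
            _require("call")
            t0 = time.perf_counter()
            params = HmmParams()
            raw_calls = []
            for sid in corrected.index:
                baf = bundle.panel.baf.loc[sid].to_numpy()
                raw_calls.extend(
                    call_sample(
                        corrected.loc[sid].to_numpy(),
                        baf,
                        bundle.marker_map,
                        params,
                        sample_id=sid,
                    )
                )
            filtered = filter_calls(
                raw_calls,
                min_snps=config.min_snps,
                min_length=config.min_length,
                regions=regions,
            )
            by_sample: dict = {sid: [] for sid in corrected.index}
            for c in filtered:
                by_sample[c.sample_id].append(c)
            by_sample, dropped = drop_noisy_samples(by_sample, config.max_cnv_per_sample)
            merged = merge_adjacent(
                [c for cs in by_sample.values() for c in cs],
                fraction=config.merge_fraction,
                marker_map=bundle.marker_map,
            )
            calls_path = outdir / "calls.rawcnv"
            cio.write_rawcnv(merged, calls_path, bundle.marker_map)
            cio.write_plink_cnv(merged, outdir / "calls.cnv")
            _record(
                "call",
                t0,
                {
                    "raw": len(raw_calls),
                    "filtered": len(filtered),
                    "merged": len(merged),
                    "samples_dropped": len(dropped),
                },
                [calls_path],
            )

        # --- rare -----------------------------------------------------------
        if _enabled("rare"):
            _require("rare")
            t0 = time.perf_counter()
            n_samples = len(corrected.index)  # all samples analysed, calls or not
            records = cnv_frequency(merged, n_samples, config.overlap_threshold)
            rare = filter_rare(records, config.max_freq)
            rare_path = outdir / "rare.cnv"
            cio.write_plink_cnv(rare, rare_path)
            _record("rare", t0, {"all": len(merged), "rare": len(rare)}, [rare_path])

        # --- validate / segregate / double hits ------------------------------
        if _enabled("validate"):
            _require("validate")
            t0 = time.perf_counter()
            rare_by_sample: dict = {}
            for c in rare:
                rare_by_sample.setdefault(c.sample_id, [])
                rare_by_sample[c.sample_id].append(c)
            # parents without a genotyping call set are absent from this map
            all_by_sample = {sid: rare_by_sample.get(sid, []) for sid in corrected.index}
            validations, segregations = [], []
            for c in rare:
                v = validate_call(c, bundle.seq_calls, bundle.pedigree, all_by_sample)
                validations.append(v)
                father, mother = bundle.pedigree.parents_of(c.sample_id)
                if father or mother:
                    segregations.append(
                        classify_segregation(c, bundle.pedigree, all_by_sample)
                    )
            hits = detect_double_hits(rare_by_sample, config.large_threshold)
            val_path = outdir / "validation.tsv"
            pd.DataFrame(
                [
                    {
                        "sample_id": v.call.sample_id,
                        "chrom": v.call.chrom,
                        "start": v.call.start,
                        "end": v.call.end,
                        "type": v.call.type,
                        "status": v.status,
                    }
                    for v in validations
                ]
            ).to_csv(val_path, sep="\t", index=False)
            _record(
                "validate",
                t0,
                {
                    "validated": sum(v.validated for v in validations),
                    "unvalidated": sum(not v.validated for v in validations),
                    "de_novo": sum(s.classification == "de_novo" for s in segregations),
                    "double_hits": len(hits),
                },
                [val_path],
            )

        # --- annotate ---------------------------------------------------------
        if _enabled("annotate"):
            _require("annotate")
            t0 = time.perf_counter()
            genes = GeneSet("genes", bundle.genes)
            hotspots = [Hotspot(*h) for h in bundle.hotspots]
            annotated = annotate_cohort(
                rare,
                genes,
                hotspots,
                epilepsy_genes=bundle.gene_sets["epilepsy"],
                pli_genes=bundle.gene_sets["pli"],
                min_gene_fraction=config.gene_fraction,
                min_hotspot_fraction=config.hotspot_fraction,
                size_threshold=config.large_threshold,
            )
            ann_path = outdir / "annotated.tsv"
            pd.DataFrame(
                [
                    {
                        "sample_id": a.call.sample_id,
                        "chrom": a.call.chrom,
                        "start": a.call.start,
                        "end": a.call.end,
                        "type": a.call.type,
                        "size_class": a.size_class,
                        "coding": a.coding,
                        "pli": a.in_pli_gene,
                        "epilepsy_gene": a.in_epilepsy_gene,
                        "hotspot": a.in_hotspot,
                        "genes": ",".join(a.genes_covered),
                    }
                    for a in annotated
                ]
            ).to_csv(ann_path, sep="\t", index=False)
            _record("annotate", t0, {"annotated": len(annotated)}, [ann_path])

        # --- burden -----------------------------------------------------------
        if _enabled("burden"):
            _require("burden")
            t0 = time.perf_counter()
            meta = bundle.samples[bundle.samples["sample_id"].isin(corrected.index)]
            tables = []
            for suite in ("size", "geneset"):
                table, _ = run_burden_suite(
                    meta,
                    annotated,
                    designs=default_designs(suite),
                    alpha=config.alpha,
                )
                table.insert(0, "suite", suite)
                tables.append(table)
            burden_table = pd.concat(tables, ignore_index=True)
            burden_path = outdir / "burden.tsv"
            burden_table.to_csv(burden_path, sep="\t", index=False)
            _record(
                "burden",
                t0,
                {
                    "tests": len(burden_table),
                    "significant": int(burden_table["significant"].sum()),
                },
                [burden_path],
            )

        # --- unmask -----------------------------------------------------------
        if _enabled("unmask"):
            _require("unmask")
            t0 = time.perf_counter()
            provider = TableExpressionProvider(bundle.expression_change)
            genes_set = GeneSet("genes", bundle.genes)
            candidates = []
            for v in validations:
                if not v.validated or v.call.type != "del":
                    continue
                cands, flags = screen_deletion(v.call, bundle.variants, validated=True)
                for cand in cands:
                    classify_effect(cand)
                    label_uneecon(cand, bundle.uneecon_scores, config.uneecon_threshold)
                    if cand.effect_class == "noncoding":
                        near = genes_set.overlapping(cand.chrom, cand.pos, cand.pos)
                        gene = near[0]["symbol"] if near else None
                        if gene is None and len(bundle.directionality):
                            gene = bundle.directionality.index[0]
                        if gene is not None:
                            constraint_violation(
                                cand, bundle.directionality, provider, gene
                            )
                    candidates.append(cand)
            unmask_path = outdir / "unmasked_candidates.tsv"
            pd.DataFrame(
                [
                    {
                        "sample_id": c.sample_id,
                        "chrom": c.chrom,
                        "pos": c.pos,
                        "ref": c.ref,
                        "alt": c.alt,
                        "effect_class": c.effect_class,
                        "uneecon": c.uneecon_score,
                        "uneecon_label": c.uneecon_label,
                        "constraint_label": c.constraint_label,
                    }
                    for c in candidates
                ]
            ).to_csv(unmask_path, sep="\t", index=False)
            _record("unmask", t0, {"candidates": len(candidates)}, [unmask_path])
    except PipelineError:
        raise
    except Exception as exc:  # abort with the stage name
        stage = next((s for s in STAGES if s not in done and _enabled(s)), "?")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
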