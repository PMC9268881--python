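"""Generator contracts: determinism, penetrance model, Mendelian
transmission, implant arithmetic and the sequencing positive control."""

import numpy as np
import pytest
from scipy import stats

from cnvburden.synthetic import (
    CohortConfig,
    ConfigurationError,
    SignalModel,
    implant_cnv,
    simulate_cohort,
)
from cnvburden.types import TruthCnv, intersection_length, union_length

from conftest import SMALL_CONFIG


def test_fixed_seed_gives_byte_identical_bundles():
    cfg = CohortConfig(**SMALL_CONFIG)
    a = simulate_cohort(cfg)
    b = simulate_cohort(CohortConfig(**SMALL_CONFIG))
    assert a.truth_cnvs == b.truth_cnvs
    assert a.panel.lrr.to_numpy().tobytes() == b.panel.lrr.to_numpy().tobytes()
    assert a.panel.baf.to_numpy().tobytes() == b.panel.baf.to_numpy().tobytes()
    assert a.pedigree.df.equals(b.pedigree.df)
    assert a.seq_calls == b.seq_calls


def test_different_seed_changes_intensities():
    a = simulate_cohort(CohortConfig(**SMALL_CONFIG))
    b = simulate_cohort(CohortConfig(**{**SMALL_CONFIG, "seed": 8}))
    assert a.panel.lrr.to_numpy().tobytes() != b.panel.lrr.to_numpy().tobytes()


def test_degenerate_penetrance_split_is_exact():
    """penetrance=1, baseline=0: affection status equals carrier status."""
    cfg = CohortConfig(**{**SMALL_CONFIG, "penetrance": 1.0, "baseline_risk": 0.0})
    bundle = simulate_cohort(cfg)
    assert (bundle.samples["affected"] == bundle.samples["risk_carrier"]).all()


def test_penetrance_half_matches_binomial_bounds():
    """Affected fraction of ~1000 independent carriers stays inside the
    99% binomial band around 0.5."""
    n_aff = 0
    n_car = 0
    for seed in range(18):
        cfg = CohortConfig(
            n_families=50,
            n_population_controls=0,
            n_chromosomes=2,
            n_markers_per_chrom=600,
            penetrance=0.5,
            baseline_risk=0.0,
            p_family_cnv=1.0,
            seed=100 + seed,
        )
        b = simulate_cohort(cfg)
        carriers = b.samples[b.samples["risk_carrier"]]
        n_car += len(carriers)
        n_aff += int(carriers["affected"].sum())
    assert n_car >= 1000
    lo, hi = stats.binom.interval(0.99, n_car, 0.5)
    assert lo <= n_aff <= hi


def test_transmission_rate_is_mendelian():
    """Each parental CNV reaches each offspring at ~0.5 (tracked per event,
    since a parent can carry several independent CNVs)."""
    n_meioses = 0
    n_transmitted = 0
    for seed in range(10):
        cfg = CohortConfig(
            n_families=60,
            n_population_controls=0,
            n_chromosomes=2,
            n_markers_per_chrom=600,
            p_family_cnv=1.0,
            group_proportions={"GGE": 1.0},
            seed=200 + seed,
        )
        b = simulate_cohort(cfg)
        carried = {
            (t.sample_id, t.chrom, t.start, t.end)
            for t in b.truth_cnvs
            if t.inherited_from != "de_novo"
        }
        for t in b.truth_cnvs:
            if t.inherited_from == "de_novo":
                continue
            for child in b.pedigree.children_of(t.sample_id):
                n_meioses += 1
                n_transmitted += (child, t.chrom, t.start, t.end) in carried
    lo, hi = stats.binom.interval(0.999, n_meioses, 0.5)
    assert n_meioses > 500
    assert lo <= n_transmitted <= hi


def test_forced_transmission_reaches_every_descendant():
    cfg = CohortConfig(
        **{**SMALL_CONFIG, "p_family_cnv": 1.0, "force_transmission": True,
           "group_proportions": {"GGE": 1.0}}
    )
    b = simulate_cohort(cfg)
    fam_cnv_samples = {t.sample_id for t in b.truth_cnvs if t.length > 1_000_000}
    for fid, fam in b.samples.groupby("family"):
        if fid.startswith("CTRL"):
            continue
        children = b.pedigree.df[(b.pedigree.df["fid"] == fid) & (b.pedigree.df["father"] != "0")]
        for row in children.itertuples(index=False):
            if row.father in fam_cnv_samples or row.mother in fam_cnv_samples:
                assert row.iid in fam_cnv_samples


def test_seq_calls_cover_every_truth_cnv(small_bundle):
    """Sequenced samples always get a same-type >=50%-overlap call per truth
    CNV: the validation stage's positive control."""
    b = small_bundle
    sequenced = set(b.samples.loc[b.samples["platform"].notna(), "sample_id"])
    seq_by_sample = {}
    for c in b.seq_calls:
        seq_by_sample.setdefault(c.sample_id, []).append(c)
    n_checked = 0
    for t in b.truth_cnvs:
        if t.sample_id not in sequenced:
            continue
        n_checked += 1
        matches = [
            c
            for c in seq_by_sample.get(t.sample_id, [])
            if c.type == t.type
            and c.chrom == t.chrom
            and intersection_length(c.start, c.end, t.start, t.end)
            / union_length(c.start, c.end, t.start, t.end)
            >= 0.5
        ]
        assert matches, f"no sequencing call for truth CNV {t}"
    assert n_checked > 0


@pytest.mark.parametrize(
    "bad", [{"penetrance": 1.2}, {"baseline_risk": -0.1}, {"n_markers_per_chrom": 0}]
)
def test_invalid_config_is_rejected(bad):
    with pytest.raises(ConfigurationError):
        simulate_cohort(CohortConfig(**{**SMALL_CONFIG, **bad}))


class TestImplant:
    def test_noise_free_deletion_signature(self, flat_panel):
        panel = flat_panel(n_markers=200)
        pos = panel.map.df["pos"]
        start, end = int(pos.iloc[50]), int(pos.iloc[99])  # 50 markers
        cnv = TruthCnv("S0", "1", start, end, copy_number=1)
        out = implant_cnv(panel, cnv, SignalModel())
        lrr, baf = out.sample("S0")
        idx = panel.map.markers_in("1", start, end)
        assert len(idx) == 50
        assert np.allclose(lrr[idx], -0.66)
        inside = baf[idx]
        assert not np.any((inside > 0.1) & (inside < 0.9))

    def test_noise_free_duplication_clusters(self, flat_panel):
        panel = flat_panel(n_markers=120)
        pos = panel.map.df["pos"]
        cnv = TruthCnv("S0", "1", int(pos.iloc[10]), int(pos.iloc[80]), copy_number=3)
        out = implant_cnv(panel, cnv, SignalModel())
        _, baf = out.sample("S0")
        idx = panel.map.markers_in("1", cnv.start, cnv.end)
        allowed = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        assert np.all(np.min(np.abs(baf[idx][:, None] - allowed[None, :]), axis=1) < 1e-12)

    def test_implant_changes_only_markers_inside(self, flat_panel):
        panel = flat_panel(n_markers=150)
        pos = panel.map.df["pos"]
        cnv = TruthCnv("S1", "1", int(pos.iloc[40]), int(pos.iloc[70]), copy_number=1)
        out = implant_cnv(panel, cnv, SignalModel())
        idx = set(panel.map.markers_in("1", cnv.start, cnv.end).tolist())
        for sid in panel.sample_ids:
            l0, b0 = panel.sample(sid)
            l1, b1 = out.sample(sid)
            diff = np.flatnonzero((l0 != l1) | (b0 != b1))
            if sid == "S1":
                assert set(diff.tolist()) <= idx
            else:
                assert len(diff) == 0

    def test_no_markers_in_interval_raises_with_coordinates(self, flat_panel):
        panel = flat_panel(n_markers=50)
        last = int(panel.map.df["pos"].iloc[-1])
        cnv = TruthCnv("S0", "1", last + 10_000, last + 20_000, copy_number=1)
        with pytest.raises(ValueError, match=f"{last + 10_000}"):
            implant_cnv(panel, cnv)
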