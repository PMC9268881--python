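"""Homozygote-in-deletion screen, transcript-fraction effect classes and
the constraint-violation product score."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvburden.types import CnvCall
from cnvburden.unmasked import (
    TISSUES,
    TableExpressionProvider,
    VariantCandidate,
    classify_effect,
    constraint_violation,
    label_uneecon,
    screen_deletion,
)

from _oracles import brute_force_screen


DELETION = CnvCall("P1", "15", 31_000_001, 32_000_000, "del", 1, 50)


def _variant(pos, genotype="hom_alt", sample="P1", chrom="15", effects=(("tx1", "missense_variant"),)):
    return {
        "sample_id": sample,
        "chrom": chrom,
        "pos": pos,
        "ref": "C",
        "alt": "T",
        "genotype": genotype,
        "transcript_effects": list(effects),
    }


def _candidate(effects):
    return VariantCandidate(
        sample_id="P1",
        deletion=DELETION,
        chrom="15",
        pos=31_195_835,
        ref="CAG",
        alt="C",
        genotype="hom_alt",
        transcript_effects=tuple(effects),
    )


class TestScreen:
    def test_hom_alt_inside_is_candidate(self):
        cands, flags = screen_deletion(DELETION, [_variant(31_500_000)])
        assert len(cands) == 1 and flags == []

    def test_het_inside_is_qc_flag_not_candidate(self):
        cands, flags = screen_deletion(DELETION, [_variant(31_500_000, "het")])
        assert cands == []
        assert flags[0]["flag"] == "heterozygous_in_hemizygous_region"

    def test_one_bp_past_end_excluded(self):
        cands, _ = screen_deletion(DELETION, [_variant(32_000_001)])
        assert cands == []
        cands, _ = screen_deletion(DELETION, [_variant(32_000_000)])
        assert len(cands) == 1

    def test_unvalidated_deletion_refused(self):
        with pytest.raises(ValueError, match="not.*validated|validated"):
            screen_deletion(DELETION, [], validated=False)

    def test_matches_brute_force_set(self):
        variants = [
            _variant(31_000_001),
            _variant(31_999_999, "het"),
            _variant(30_999_999),
            _variant(31_200_000, sample="OTHER"),
            _variant(31_300_000, chrom="16"),
            _variant(31_400_000, "hom_ref"),
            _variant(31_600_000),
        ]
        cands, _ = screen_deletion(DELETION, variants)
        expected = brute_force_screen(DELETION, variants)
        assert [(c.chrom, c.pos) for c in cands] == [(v["chrom"], v["pos"]) for v in expected]


class TestEffectClass:
    def test_lof_in_all_transcripts(self):
        c = classify_effect(_candidate([(f"t{i}", "stop_gained") for i in range(10)]))
        assert c.effect_class == "lof"
        assert c.transcript_effect_fraction == 1.0

    def test_nine_of_ten_is_not_lof(self):
        effects = [(f"t{i}", "stop_gained") for i in range(9)] + [("t9", "synonymous_variant")]
        c = classify_effect(_candidate(effects))
        assert c.effect_class != "lof"  # 0.9 is not > 0.9

    def test_single_missense_among_eight_counts(self):
        effects = [("t0", "missense_variant")] + [
            (f"t{i}", "synonymous_variant") for i in range(1, 8)
        ]
        c = classify_effect(_candidate(effects))
        assert c.effect_class == "missense"
        assert c.transcript_effect_fraction == pytest.approx(1 / 8)

    def test_all_noncoding(self):
        c = classify_effect(_candidate([("t0", "intron_variant"), ("t1", "intergenic_variant")]))
        assert c.effect_class == "noncoding"

    def test_no_annotations_raises(self):
        with pytest.raises(ValueError):
            classify_effect(_candidate([]))

    @given(st.integers(1, 30), st.integers(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_adding_concordant_transcripts_never_demotes_lof(self, n_lof, n_other):
        effects = [(f"l{i}", "stop_gained") for i in range(n_lof)] + [
            (f"o{i}", "synonymous_variant") for i in range(n_other)
        ]
        before = classify_effect(_candidate(effects)).effect_class
        after = classify_effect(
            _candidate(effects + [("extra", "stop_gained")])
        ).effect_class
        if before == "lof":
            assert after == "lof"


class TestConstraintScore:
    def _tables(self, directionality_values, change):
        directionality = pd.DataFrame(
            {t: [v] for t, v in zip(TISSUES, directionality_values)}, index=["GENE1"]
        )
        provider = TableExpressionProvider(
            {((("15", 31_195_835, "CAG", "C")), t): change for t in TISSUES}
        )
        return directionality, provider

    def _noncoding_candidate(self):
        c = _candidate([("t0", "intron_variant")])
        c.pos, c.ref, c.alt = 31_195_835, "CAG", "C"
        return classify_effect(c)

    def test_product_arithmetic(self):
        directionality, provider = self._tables((1.0, 1.0, 1.0), 0.5)
        c = constraint_violation(self._noncoding_candidate(), directionality, provider, "GENE1")
        assert all(c.constraint_scores[t].score == pytest.approx(0.5) for t in TISSUES)

    def test_zero_expression_change_zero_everywhere(self):
        directionality, provider = self._tables((0.4, -0.2, 1.0), 0.0)
        c = constraint_violation(self._noncoding_candidate(), directionality, provider, "GENE1")
        assert all(c.constraint_scores[t].score == 0.0 for t in TISSUES)
        assert c.constraint_label == "not_likely_deleterious"

    def test_all_negative_scores_not_likely_deleterious(self):
        directionality, provider = self._tables((-0.2, -0.1, -0.3), 1.0)
        c = constraint_violation(self._noncoding_candidate(), directionality, provider, "GENE1")
        assert all(c.constraint_scores[t].score < 0 for t in TISSUES)
        assert c.constraint_label == "not_likely_deleterious"

    def test_missing_gene_means_no_functional_effect(self):
        directionality, provider = self._tables((1.0, 1.0, 1.0), 0.5)
        c = constraint_violation(self._noncoding_candidate(), directionality, provider, "ABSENT")
        assert c.constraint_scores == {}
        assert c.constraint_label == "no_predicted_functional_effect"

    def test_sign_rule(self):
        directionality, provider = self._tables((-0.5, 0.5, -1.0), -2.0)
        c = constraint_violation(self._noncoding_candidate(), directionality, provider, "GENE1")
        signs = [c.constraint_scores[t].score for t in TISSUES]
        assert signs[0] > 0 and signs[1] < 0 and signs[2] > 0
        assert c.constraint_label == "possibly_deleterious"


class TestUneecon:
    def test_below_threshold_not_deleterious(self):
        c = _candidate([("t0", "missense_variant")])
        c.pos = 1000
        label_uneecon(c, {("15", 1000, "CAG", "C"): 0.12})
        assert c.uneecon_label == "not_deleterious"

    def test_at_threshold_possibly_deleterious(self):
        c = _candidate([("t0", "missense_variant")])
        c.pos = 1000
        label_uneecon(c, {("15", 1000, "CAG", "C"): 0.15})
        assert c.uneecon_label == "possibly_deleterious"

    def test_missing_score_leaves_label_unset(self):
        c = _candidate([("t0", "missense_variant")])
        label_uneecon(c, {})
        assert c.uneecon_score is None and c.uneecon_label is None
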