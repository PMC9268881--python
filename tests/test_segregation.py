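"""Sequencing validation rules, pedigree transmission / de novo
classification and double-CNV-hit detection."""

import pandas as pd
import pytest

from cnvburden.caller import merge_adjacent
from cnvburden.segregation import (
    classify_segregation,
    detect_double_hits,
    validate_against_sequencing,
    validate_call,
)
from cnvburden.synthetic import CohortConfig, simulate_cohort
from cnvburden.types import CnvCall, Pedigree

from conftest import SMALL_CONFIG


def _call(sample="CH", chrom="1", start=1_000_001, end=2_000_000, type_="del", src="array"):
    cn = 1 if type_ == "del" else 3
    return CnvCall(sample, chrom, start, end, type_, cn, 50, src)


def _trio_pedigree(father_pheno=2, mother_pheno=1):
    return Pedigree(
        pd.DataFrame(
            {
                "fid": ["F"] * 3,
                "iid": ["FA", "MO", "CH"],
                "father": ["0", "0", "FA"],
                "mother": ["0", "0", "MO"],
                "sex": [1, 2, 1],
                "phenotype": [father_pheno, mother_pheno, 2],
            }
        )
    )


class TestSequencingValidation:
    def test_identical_seq_call_validates(self):
        array = _call()
        seq = _call(src="wgs")
        res = validate_against_sequencing(array, [seq])
        assert res.status == "validated_wgs"
        assert res.matched_call == seq

    def test_seq_call_more_than_twice_length_rejected(self):
        array = _call(start=1_000_001, end=2_000_000)  # 1.0 Mb
        seq = _call(start=500_001, end=3_000_000, src="wgs")  # 2.5 Mb containing it
        assert not validate_against_sequencing(array, [seq]).validated

    def test_exactly_twice_length_accepted(self):
        array = _call(start=1_000_001, end=2_000_000)
        seq = _call(start=1_000_001, end=3_000_000, src="wes")  # exactly 2x
        res = validate_against_sequencing(array, [seq])
        assert res.status == "validated_wes"

    def test_forty_percent_overlap_rejected_fifty_accepted(self):
        array = _call(start=1_000_001, end=2_000_000)
        seq40 = _call(start=1_600_001, end=2_000_000, src="wgs")  # covers 40%
        assert not validate_against_sequencing(array, [seq40]).validated
        seq50 = _call(start=1_500_001, end=2_000_000, src="wgs")  # exactly 50%
        assert validate_against_sequencing(array, [seq50]).validated

    def test_type_mismatch_never_validates(self):
        array = _call(type_="del")
        seq = _call(type_="dup", src="wgs")
        assert not validate_against_sequencing(array, [seq]).validated

    def test_either_platform_suffices_wgs_preferred(self):
        array = _call()
        res = validate_against_sequencing(
            array, [_call(src="wes"), _call(src="wgs")]
        )
        assert res.status == "validated_wgs"

    def test_non_array_call_refused(self):
        with pytest.raises(ValueError):
            validate_against_sequencing(_call(src="wgs"), [])


class TestSegregation:
    def test_affected_father_with_60pct_overlap_transmits(self):
        ped = _trio_pedigree(father_pheno=2)
        child = _call("CH", start=1_000_001, end=2_000_000)
        father = _call("FA", start=1_000_001, end=1_600_000)  # covers 60%
        res = classify_segregation(child, ped, {"FA": [father], "MO": [], "CH": [child]})
        assert res.classification == "transmitted_by_affected"
        assert res.parent_id == "FA"

    def test_unaffected_mother_transmits(self):
        ped = _trio_pedigree()
        child = _call("CH")
        mother = _call("MO")
        res = classify_segregation(child, ped, {"FA": [], "MO": [mother], "CH": [child]})
        assert res.classification == "transmitted_by_unaffected"

    def test_complete_trio_no_parent_match_is_de_novo(self):
        ped = _trio_pedigree()
        child = _call("CH")
        res = classify_segregation(child, ped, {"FA": [], "MO": [], "CH": [child]})
        assert res.classification == "de_novo"

    def test_parent_without_call_data_is_unknown(self):
        ped = _trio_pedigree()
        child = _call("CH")
        res = classify_segregation(child, ped, {"FA": [], "CH": [child]})  # MO unsampled
        assert res.classification == "unknown"

    def test_unknown_parent_phenotype_is_plausible_not_transmitted(self):
        ped = _trio_pedigree(father_pheno=0)
        child = _call("CH")
        res = classify_segregation(child, ped, {"FA": [_call("FA")], "MO": [], "CH": [child]})
        assert res.classification == "unknown"
        assert "plausible" in res.note

    def test_sample_absent_from_pedigree_raises(self):
        with pytest.raises(KeyError):
            classify_segregation(_call("GHOST"), _trio_pedigree(), {})

    def test_segregation_fallback_validates(self):
        ped = _trio_pedigree()
        child = _call("CH")
        res = validate_call(child, [], ped, {"FA": [_call("FA")], "MO": [], "CH": [child]})
        assert res.status == "validated_segregation"


class TestSegregationOnSimulatedTruth:
    def test_noise_free_trios_recover_truth_labels(self):
        """With truth calls as input, classification equals the simulated
        inherited_from label for every child event."""
        cfg = CohortConfig(
            **{**SMALL_CONFIG, "n_families": 25, "de_novo_rate": 0.1, "boundary_jitter": 0.0}
        )
        b = simulate_cohort(cfg)
        calls_by_sample = {
            iid: [] for iid in b.samples["sample_id"]
        }
        for t in b.truth_cnvs:
            calls_by_sample[t.sample_id].append(
                CnvCall(t.sample_id, t.chrom, t.start, t.end, t.type, t.copy_number, 10)
            )
        n_checked = n_denovo = 0
        for t in b.truth_cnvs:
            father, mother = b.pedigree.parents_of(t.sample_id)
            if father is None and mother is None:
                continue
            call = next(
                c
                for c in calls_by_sample[t.sample_id]
                if (c.chrom, c.start, c.end) == (t.chrom, t.start, t.end)
            )
            res = classify_segregation(call, b.pedigree, calls_by_sample)
            n_checked += 1
            if t.inherited_from == "de_novo":
                n_denovo += 1
                assert res.classification == "de_novo"
            else:
                assert res.classification.startswith("transmitted")
                assert res.parent_id == t.inherited_from
        assert n_checked > 10
        assert n_denovo > 0


class TestDoubleHits:
    def test_adjacent_dup_plus_13mb_del_one_hit(self):
        """Mirrors a duplication immediately followed by a 13 Mb deletion on
        one chromosome."""
        dup = _call("P2", chrom="18", start=63_151_948, end=64_412_293, type_="dup")
        dele = _call("P2", chrom="18", start=64_525_217, end=77_553_173, type_="del")
        hits = detect_double_hits({"P2": [dup, dele]})
        assert len(hits) == 1
        assert hits[0].same_chromosome

    def test_single_large_call_no_hit(self):
        assert detect_double_hits({"A": [_call(start=1, end=2_000_000)]}) == []

    def test_small_calls_do_not_qualify(self):
        a = _call("A", start=1, end=999_999)
        b = _call("A", chrom="2", start=1, end=999_998)
        assert detect_double_hits({"A": [a, b]}) == []
        # inclusive at exactly 1 Mb
        c = _call("A", start=1, end=1_000_000)
        d = _call("A", chrom="2", start=1, end=1_000_000)
        assert len(detect_double_hits({"A": [c, d]})) == 1

    def test_cross_chromosome_pairs_count(self):
        a = _call("A", chrom="1", start=1, end=1_500_000)
        b = _call("A", chrom="2", start=1, end=1_500_000, type_="dup")
        hits = detect_double_hits({"A": [a, b]})
        assert len(hits) == 1
        assert not hits[0].same_chromosome

    def test_mergeable_pair_yields_no_hit_after_merging(self):
        """Two same-type calls the 0.2 rule would join must be merged before
        the double-hit screen, leaving a single event."""
        a = _call("A", start=1, end=1_200_000)
        b = _call("A", start=1_300_001, end=2_500_000)  # gap 0.1 Mb / span 2.5 Mb = 0.04
        merged = merge_adjacent([a, b])
        assert len(merged) == 1
        assert detect_double_hits({"A": merged}) == []
        # unmerged they would (incorrectly) look like a double hit
        assert len(detect_double_hits({"A": [a, b]})) == 1
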