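"""GEE logistic burden model: closed-form anchors, agreement with plain
maximum likelihood, CI coverage under family clustering, and the suite
plumbing (designs, exclusions, Bonferroni)."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cnvburden.annotation import AnnotatedCall
from cnvburden.burden import (
    BurdenDesign,
    bonferroni_threshold,
    default_designs,
    fit_burden,
    run_burden_suite,
)
from cnvburden.synthetic import simulate_burden_table
from cnvburden.types import CnvCall


def _toy(carriers_cases, n_cases, carriers_controls, n_controls):
    carrier = np.r_[
        np.ones(carriers_cases),
        np.zeros(n_cases - carriers_cases),
        np.ones(carriers_controls),
        np.zeros(n_controls - carriers_controls),
    ]
    phenotype = np.r_[np.ones(n_cases), np.zeros(n_controls)]
    return carrier, phenotype


class TestFitBurden:
    def test_balanced_carriers_give_or_one(self):
        carrier, phenotype = _toy(10, 100, 10, 100)
        sex = np.tile([0, 1], 100)
        res = fit_burden(carrier, phenotype, sex=sex)
        assert res.or_estimate == pytest.approx(1.0, abs=1e-6)

    def test_two_by_two_matches_cross_product_ratio(self):
        """20/100 vs 10/100 must recover OR (20*90)/(80*10) = 2.25."""
        carrier, phenotype = _toy(20, 100, 10, 100)
        res = fit_burden(carrier, phenotype)
        assert res.or_estimate == pytest.approx(2.25, abs=1e-3)
        assert res.ci95[0] < 2.25 < res.ci95[1]
        assert res.carriers_cases == 20 and res.carriers_controls == 10

    def test_singleton_gee_equals_plain_logit(self):
        df = simulate_burden_table(150, 300, 0.25, 0.10, seed=3)
        res = fit_burden(df["carrier"], df["phenotype"], sex=df["sex"], family=df["family"])
        exog = sm.add_constant(df[["carrier", "sex"]].to_numpy(dtype=float))
        ml = sm.Logit(df["phenotype"].to_numpy(dtype=float), exog).fit(disp=0)
        assert res.coefficient == pytest.approx(ml.params[1], abs=1e-6)

    def test_label_swap_inverts_odds_ratio(self):
        df = simulate_burden_table(120, 240, 0.3, 0.12, seed=5)
        res = fit_burden(df["carrier"], df["phenotype"])
        flipped = fit_burden(df["carrier"], 1 - df["phenotype"])
        assert flipped.or_estimate == pytest.approx(1 / res.or_estimate, rel=1e-6)
        assert flipped.ci95[0] == pytest.approx(1 / res.ci95[1], rel=1e-5)
        assert flipped.ci95[1] == pytest.approx(1 / res.ci95[0], rel=1e-5)

    def test_zero_carriers_everywhere_is_undefined(self):
        carrier, phenotype = _toy(0, 50, 0, 50)
        res = fit_burden(carrier, phenotype)
        assert res.status == "undefined"
        assert np.isnan(res.or_estimate)

    def test_complete_separation_flagged_not_raised(self):
        carrier, phenotype = _toy(30, 50, 0, 50)
        res = fit_burden(carrier, phenotype)
        assert res.status == "separation_warning"

    def test_needs_both_outcomes(self):
        with pytest.raises(ValueError):
            fit_burden([1, 0], [1, 1])

    def test_ci_coverage_with_family_clustering(self):
        """Null OR=1, families of 3 sharing a random effect: the sandwich
        95% CI must cover 1.0 in 93-97% of 500 replicates."""
        covered = 0
        n_reps = 500
        for rep in range(n_reps):
            df = simulate_burden_table(
                300,
                300,
                0.2,
                0.2,
                family_size=3,
                family_phenotype_sd=1.0,
                seed=10_000 + rep,
            )
            res = fit_burden(df["carrier"], df["phenotype"], family=df["family"])
            if res.status != "ok":
                continue
            if res.ci95[0] <= 1.0 <= res.ci95[1]:
                covered += 1
        assert 0.93 <= covered / n_reps <= 0.97

    def test_log_or_recovery_across_effect_sizes(self):
        """True OR in {1, 2, 5} at n=2000 singletons: |log-OR bias| < 0.05."""
        rng = np.random.default_rng(77)
        for true_or in (1.0, 2.0, 5.0):
            coefs = []
            for rep in range(200):
                carrier = (rng.random(2000) < 0.15).astype(float)
                logit = -0.5 + np.log(true_or) * carrier
                phenotype = (rng.random(2000) < 1 / (1 + np.exp(-logit))).astype(float)
                res = fit_burden(carrier, phenotype)
                if res.status == "ok":
                    coefs.append(res.coefficient)
            bias = np.mean(coefs) - np.log(true_or)
            assert abs(bias) < 0.05, f"OR {true_or}: bias {bias}"


class TestBonferroni:
    def test_sixteen_tests_give_0003(self):
        thr = bonferroni_threshold(16, 0.05)
        assert thr == pytest.approx(0.003125)
        assert f"{thr:.3f}" == "0.003"

    @pytest.mark.parametrize("n,expected", [(1, 0.05), (10, 0.005)])
    def test_simple_cases(self, n, expected):
        assert bonferroni_threshold(n) == pytest.approx(expected)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


def _ann(sample, type_="del", length=2_000_000, **flags):
    call = CnvCall(sample, "1", 1, length, type_, 1 if type_ == "del" else 3, 10)
    return AnnotatedCall(
        call=call,
        size_class="large" if length > 1_000_000 else "small",
        genes_covered=flags.get("genes", ()),
        in_epilepsy_gene=flags.get("epilepsy", False),
        in_pli_gene=flags.get("pli", False),
        in_hotspot=flags.get("hotspot", False),
    )


def _samples(n_cases=30, n_controls=60, group="GGE"):
    rows = []
    for i in range(n_cases):
        rows.append((f"CASE{i}", f"FC{i}", group, 1 + i % 2, True, False))
    for i in range(n_controls):
        rows.append((f"CTRL{i}", f"FU{i}", "control", 1 + i % 2, False, False))
    return pd.DataFrame(
        rows, columns=["sample_id", "family", "group", "sex", "affected", "is_dee_parent"]
    )


class TestSuite:
    def test_sixteen_designs_per_suite(self):
        assert len(default_designs("size")) == 16
        assert len(default_designs("geneset")) == 16
        labels = {d.label for d in default_designs("size") + default_designs("geneset")}
        assert len(labels) == 32

    def test_enriched_large_deletions_detected(self):
        samples = _samples(60, 120)
        annotated = [_ann(f"CASE{i}") for i in range(30)] + [
            _ann(f"CTRL{i}") for i in range(6)
        ]
        table, results = run_burden_suite(samples, annotated, default_designs("size"))
        row = table[table["design"] == "GGE:del:large"].iloc[0]
        assert row["carriers_cases"] == 30 and row["carriers_controls"] == 6
        assert row["or"] > 1
        assert row["p_value"] < bonferroni_threshold(16)
        assert bool(row["significant"])

    def test_zero_carrier_category_continues_as_undefined(self):
        samples = _samples()
        annotated = [_ann("CASE0")]  # only one large deletion anywhere
        table, _ = run_burden_suite(samples, annotated, default_designs("size"))
        assert len(table) == 16
        dup_rows = table[table["design"].str.contains("dup")]
        assert (dup_rows["status"] == "undefined").all()

    def test_dee_parents_excluded_from_dee_controls_only(self):
        samples = _samples(20, 40)
        extra = pd.DataFrame(
            [
                (f"DEEP{i}", f"FD{i}", "DEE", 1, False, True)
                for i in range(10)
            ],
            columns=["sample_id", "family", "group", "sex", "affected", "is_dee_parent"],
        )
        samples = pd.concat([samples, extra], ignore_index=True)
        annotated = [_ann("CASE0")]
        designs = [
            BurdenDesign("GGE", "size", "del", size_class="large"),
            BurdenDesign("DEE", "size", "del", size_class="large"),
        ]
        table, _ = run_burden_suite(samples, annotated, designs)
        gge = table.iloc[0]
        dee = table.iloc[1]
        assert gge["n_controls"] == 50  # 40 controls + 10 DEE parents
        assert dee["n_controls"] == 40  # DEE parents removed

    def test_permuted_phenotypes_hold_the_alpha_level(self):
        """Shuffling labels: significant fraction at alpha=0.05 within
        binomial bounds of 0.05."""
        from scipy import stats

        rng = np.random.default_rng(123)
        n_sig = n_tests = 0
        for rep in range(120):
            df = simulate_burden_table(150, 150, 0.2, 0.2, seed=20_000 + rep)
            perm = rng.permutation(df["phenotype"].to_numpy())
            res = fit_burden(df["carrier"], perm)
            if res.status == "ok":
                n_tests += 1
                n_sig += res.p_value < 0.05
        lo, hi = stats.binom.interval(0.999, n_tests, 0.05)
        assert lo <= n_sig <= hi

    def test_power_at_tenfold_case_rate(self):
        """Cases carrying deletions at 10x the control rate, n=350/945:
        significant at the 16-test threshold in >= 80% of seeds."""
        thr = bonferroni_threshold(16)
        wins = 0
        for seed in range(10):
            df = simulate_burden_table(350, 945, 0.10, 0.01, seed=30_000 + seed)
            res = fit_burden(df["carrier"], df["phenotype"], sex=df["sex"])
            wins += res.status == "ok" and res.p_value < thr
        assert wins >= 8

    def test_empty_design_list_gives_empty_table(self):
        table, results = run_burden_suite(_samples(), [], designs=[])
        assert len(table) == 0 and results == []
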