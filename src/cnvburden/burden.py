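"""Case-control CNV burden testing with familial correlation.

The burden model is a logistic regression of affection status on a carrier
indicator (the sample has at least one rare CNV matching the tested
category) with sex as covariate,

    logit P(case) = b0 + b1 * carrier + b2 * sex,

estimated by generalized estimating equations (GEE) with an exchangeable
working correlation within family clusters and cluster-robust (sandwich)
standard errors, so related individuals do not inflate significance.
Unrelated samples are singleton clusters, in which case the GEE reduces to
ordinary maximum-likelihood logistic regression. Odds ratios and Wald 95%
confidence intervals are the exponentials of b1 and b1 +/- 1.96 se.

The full suite enumerates 16 tests per analysis group: four phenotype
groups (GGE, NAFE, mixed, DEE) crossed with either the four
length/type categories ({deletion, duplication} x {small, large}) or the
four deletion gene-set categories (any gene, epilepsy genes, pLI > 0.99
genes, hotspots). Unaffected DEE parents are excluded from the control set
of DEE tests; significance is Bonferroni-controlled over the 16 tests
(alpha 0.05 / 16 = 0.003125, displayed as 0.003).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotation import AnnotatedCall

__all__ = [
    "BurdenDesign",
    "BurdenResult",
    "fit_burden",
    "bonferroni_threshold",
    "default_designs",
    "run_burden_suite",
    "forest_plot",
]

PHENOTYPE_GROUPS = ("GGE", "NAFE", "mixed", "DEE")
SIZE_CATEGORIES = (
    ("del", "small"),
    ("del", "large"),
    ("dup", "small"),
    ("dup", "large"),
)
GENESET_CATEGORIES = ("coding", "epilepsy", "pli", "hotspot")


@dataclass(frozen=True)
class BurdenDesign:
    """One category x phenotype-group contrast.

    ``category`` is either a (cnv_type, size_class) pair for the
    length-based suite or a deletion gene-set label for the gene-set suite.
    """

    group: str
    suite: str  # "size" | "geneset"
    cnv_type: str  # del | dup
    size_class: Optional[str] = None  # small | large | None (any)
    gene_set: Optional[str] = None  # coding | epilepsy | pli | hotspot

    @property
    def label(self) -> str:
        cat = self.size_class if self.suite == "size" else self.gene_set
        return f"{self.group}:{self.cnv_type}:{cat}"

    def matches(self, ann: AnnotatedCall) -> bool:
        if ann.call.type != self.cnv_type:
            return False
        if self.suite == "size":
            return ann.size_class == self.size_class
        return {
            "coding": ann.coding,
            "epilepsy": ann.in_epilepsy_gene,
            "pli": ann.in_pli_gene,
            "hotspot": ann.in_hotspot,
        }[self.gene_set]


@dataclass
class BurdenResult:
    design: Optional[BurdenDesign]
    n_cases: int
    n_controls: int
    carriers_cases: int
    carriers_controls: int
    coefficient: float = np.nan
    se: float = np.nan
    or_estimate: float = np.nan
    ci95: tuple = (np.nan, np.nan)
    p_value: float = np.nan
    significant: bool = False
    status: str = "ok"  # ok | separation_warning | undefined

    def as_row(self) -> dict:
        return {
            "design": self.design.label if self.design else "",
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "carriers_cases": self.carriers_cases,
            "carriers_controls": self.carriers_controls,
            "coefficient": self.coefficient,
            "or": self.or_estimate,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "p_value": self.p_value,
            "significant": self.significant,
            "status": self.status,
        }


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha / n_tests.

    The value is returned at full precision; display rounds to 3 decimals
    (16 tests at alpha 0.05 gives 0.003125, shown as 0.003).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def fit_burden(
    carrier,
    phenotype,
    sex=None,
    family=None,
    design: BurdenDesign | None = None,
) -> BurdenResult:
    """Fit the GEE logistic burden model for one carrier indicator.

    ``carrier`` and ``phenotype`` are 0/1 per sample; ``sex`` an optional
    covariate (any numeric coding); ``family`` cluster labels (samples with
    unique labels are singleton clusters). Complete separation is flagged,
    not raised; a category with zero carriers anywhere is returned as an
    undefined result.
    """
    carrier = np.asarray(carrier, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    n = len(carrier)
    if len(phenotype) != n:
        raise ValueError("carrier and phenotype lengths differ")
    n_cases = int(phenotype.sum())
    n_controls = n - n_cases
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need at least one case and one control")
    cc = int(carrier[phenotype == 1].sum())
    cu = int(carrier[phenotype == 0].sum())
    base = dict(
        design=design,
        n_cases=n_cases,
        n_controls=n_controls,
        carriers_cases=cc,
        carriers_controls=cu,
    )
    if cc == 0 and cu == 0:
        return BurdenResult(**base, status="undefined")
    # any empty cell of the carrier x phenotype 2x2 table => (quasi-)separation
    separated = cc == 0 or cu == 0 or cc == n_cases or cu == n_controls
    cols = {"const": np.ones(n), "carrier": carrier}
    if sex is not None:
        sex = np.asarray(sex, dtype=float)
        if np.ptp(sex) > 0:
            cols["sex"] = sex
    exog = pd.DataFrame(cols)
    groups = (
        np.asarray(family)
        if family is not None
        else np.arange(n)
    )
    _, counts = np.unique(groups, return_counts=True)
    cov_struct = (
        sm.cov_struct.Independence()
        if counts.max() == 1
        else sm.cov_struct.Exchangeable()
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                phenotype,
                exog,
                groups=groups,
                family=sm.families.Binomial(),
                cov_struct=cov_struct,
            )
            res = model.fit(maxiter=200)
        coef = float(res.params["carrier"])
        se = float(res.bse["carrier"])
        pval = float(res.pvalues["carrier"])
    except Exception:
        return BurdenResult(**base, status="separation_warning")
    status = "ok"
    if separated or not np.isfinite(se) or se > 50:
        status = "separation_warning"
    return BurdenResult(
        **base,
        coefficient=coef,
        se=se,
        or_estimate=float(np.exp(coef)),
        ci95=(float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))),
        p_value=pval,
        status=status,
    )


def default_designs(suite: str) -> list[BurdenDesign]:
    """The 16 contrasts of one analysis suite ("size" or "geneset")."""
    designs = []
    for group in PHENOTYPE_GROUPS:
        if suite == "size":
            for cnv_type, size_class in SIZE_CATEGORIES:
                designs.append(
                    BurdenDesign(group=group, suite="size", cnv_type=cnv_type, size_class=size_class)
                )
        elif suite == "geneset":
            for gs in GENESET_CATEGORIES:
                designs.append(
                    BurdenDesign(group=group, suite="geneset", cnv_type="del", gene_set=gs)
                )
        else:
            raise ValueError(f"unknown suite {suite!r}")
    return designs


def run_burden_suite(
    samples: pd.DataFrame,
    annotated_calls,
    designs=None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[BurdenResult]]:
    """Run every design of a burden suite against a cohort.

    ``samples`` needs columns sample_id, group, affected, sex, family and
    is_dee_parent. For each design, cases are the affected members of the
    design's phenotype group; controls are all unaffected samples (familial
    and population controls), minus unaffected DEE parents for DEE designs.
    Significance is evaluated at the Bonferroni threshold for the number of
    designs run.
    """
    if designs is None:
        designs = default_designs("size")
    designs = list(designs)
    if not designs:
        return pd.DataFrame(), []
    threshold = bonferroni_threshold(len(designs), alpha) if designs else alpha
    by_sample: dict[str, list] = {}
    for ann in annotated_calls:
        by_sample.setdefault(ann.call.sample_id, []).append(ann)
    results = []
    for design in designs:
        is_case = (samples["group"] == design.group) & samples["affected"]
        is_control = ~samples["affected"]
        if design.group == "DEE":
            is_control &= ~samples["is_dee_parent"]
        sel = samples[is_case | is_control]
        carrier = np.array(
            [
                any(design.matches(a) for a in by_sample.get(sid, []))
                for sid in sel["sample_id"]
            ],
            dtype=int,
        )
        phenotype = sel["affected"].to_numpy(dtype=int)
        sex = (sel["sex"].to_numpy(dtype=float) == 1).astype(float)
        if phenotype.sum() == 0 or (1 - phenotype).sum() == 0:
            results.append(
                BurdenResult(
                    design=design,
                    n_cases=int(phenotype.sum()),
                    n_controls=int((1 - phenotype).sum()),
                    carriers_cases=int(carrier[phenotype == 1].sum()),
                    carriers_controls=int(carrier[phenotype == 0].sum()),
                    status="undefined",
                )
            )
            continue
        res = fit_burden(carrier, phenotype, sex=sex, family=sel["family"], design=design)
        if res.status == "ok" and np.isfinite(res.p_value):
            res.significant = res.p_value < threshold
        results.append(res)
    table = pd.DataFrame([r.as_row() for r in results])
    return table, results


def forest_plot(table: pd.DataFrame, ax=None):
    """Forest plot of odds ratios with 95% CIs from a burden results table."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(table) + 1))
    ok = table[table["status"] == "ok"].reset_index(drop=True)
    y = np.arange(len(ok))
    ax.errorbar(
        ok["or"],
        y,
        xerr=[ok["or"] - ok["ci_low"], ok["ci_high"] - ok["or"]],
        fmt="o",
        capsize=3,
    )
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(ok["design"])
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (95% CI)")
    return ax
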