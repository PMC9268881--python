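# Methods

## The analysis model

The pipeline treats a genotyping study as a chain of well-defined
decisions, each with an explicit threshold:

**Intensity model.** Each sample contributes two vectors on a shared marker
map: the Log-R ratio (LRR), a normalized total-intensity signal that dips
for deletions and rises for duplications, and the B-allele frequency
(BAF), whose cluster pattern reveals the allelic composition. Copy-number
states imprint characteristic signatures: LRR means of approximately
−3.5 / −0.66 / 0 / +0.40 / +0.68 for copy numbers 0–4, and BAF cluster
sets {uniform}, {0,1}, {0,½,1}, {0,⅓,⅔,1} and {0,¼,¾,1} (the four-copy
state is modelled without a distinct ½ band). These LRR state means are
not uniquely defined by theory; the defaults follow common SNP-array
practice and are overridable in both the generator (`SignalModel`) and the
caller (`HmmParams`).

**Sample QC.** Three per-sample metrics with inclusive pass thresholds:
the population standard deviation of autosomal LRR (≤0.3), BAF drift — the
fraction of markers with BAF in [0.2, 0.25] ∪ [0.75, 0.8] — (≤0.01), and a
waviness factor (≤0.05). The waviness factor is defined here as the
standard deviation of per-1-Mb-window median LRR across autosomes: a
documented stand-in for the GC-model waviness of dedicated callers, chosen
because it captures long-range intensity waves while being insensitive to
marker-level noise (medians) and to isolated CNVs.

**Batch correction.** The top *k* principal components (default *k* = 2;
the appropriate count is data-dependent and left configurable) of the
marker-wise mean-centred LRR matrix are fit on markers outside an
exclusion list (telomeres, centromeres, immunoglobulin loci — regions of
systematic intensity artefact) and regressed out of every marker, after
which marker means are restored. No variance scaling is applied since all
markers share units. The fitted projection is idempotent and can only
reduce per-marker variance; with `n_pcs = 0` it is the identity.

**Caller.** A five-state hidden Markov model over copy numbers 0–4 per
chromosome. Emissions are the sum of a Gaussian LRR log-density (per-state
mean/SD) and a nearest-cluster Gaussian BAF log-density (flat for the
zero-copy state, which has no allelic signal). Transition probability out
of the current state grows with the physical gap d between adjacent
markers as `p_leave · (1 − exp(−d/D))` with decay scale D = 100 kb;
non-neutral states return to copy-neutral with 90% of the switch mass. The
Viterbi path is decoded per chromosome and maximal runs of same-sign
non-neutral states become calls (the run's modal state supplies the copy
number). This is a deliberate simplification of production SNP-array
callers — no loss-of-heterozygosity state, no GC-content model, no
family-joint decoding — and all parameters are exposed so users can
tighten it. Its correctness is anchored two ways: exhaustive enumeration
of all 5ⁿ state paths on instances up to 12 markers must reproduce the
decoded path exactly, and on the standard synthetic benchmark (hemizygous
deletions spanning ≥20 markers at LRR noise SD 0.15) it must recover ≥90%
of implanted events at ≥50% reciprocal overlap with at most one false call
per CNV-free genome.

**Call filters.** Calls need ≥10 supporting markers and ≥20 kb of length
(both inclusive — the bare thresholds are read as "at least"); calls with
≥50% of their length inside an exclusion region are removed; samples with
more than 50 surviving calls are dropped entirely as hybridisation
failures. Adjacent same-sample/same-chromosome/same-type calls merge when
the inter-call gap is at most 20% of the merged span, iterated to a
fixpoint (the operation is idempotent); a merged call's marker count is
the members' sum plus the markers in the gap.

**Frequency and rarity.** Two same-type calls match when intersection
length over union length is ≥0.5 (deletions and duplications always
separate). A call's carrier count is the number of distinct samples with
at least one matching call, the carrier itself included, over the full set
of QC-passing samples; rare means frequency ≤1% (inclusive). Carrier
counting (rather than call counting) was chosen because a sample with two
fragmented calls matching one event is still one carrier.

**Validation and segregation.** An array call is validated when either
sequencing call set (WGS or WES) contains a same-type call covering ≥50%
of the *array* call's length — the overlap is deliberately one-sided,
because sequencing calls have finer breakpoints and a reciprocal rule
would punish the array call's coarse boundaries — provided the sequencing
call is no longer than twice the array call (the guard against spurious
giant calls; both bounds inclusive at exactly 50% and exactly 2×). Calls
without sequencing support fall back to segregation: a parent carrying a
same-type call covering ≥50% of the child call validates it. A child call
is de novo only when both parents are present *with call data* and neither
matches; a missing parent yields "unknown", and a matching parent whose
phenotype is unknown is reported as unknown with a "plausible
transmission" note rather than as a transmission. Double-hit screening
runs after merging and reports every unordered pair of distinct,
non-overlapping rare calls ≥1 Mb (inclusive) in one sample;
deletion + duplication pairs qualify.

**Annotation.** A call covers a gene when ≥80% of the gene's length lies
inside it (the rule is anchored on the gene, not the call, so a large
deletion containing a small gene counts); it hits a hotspot when it covers
≥50% of the hotspot. Strand is ignored — CNVs are unstranded. Size classes
split strictly at 1 Mb: "large" means >1,000,000 bp. The curated lists
(epilepsy-associated genes, pLI > 0.99 loss-of-function-intolerant genes,
recurrent hotspots such as 15q13.3 or 22q11.2) are user-supplied tables;
the repository ships small editable synthetic examples only.

**Burden model.** For each tested category, the carrier indicator (the
sample has ≥1 rare call matching the category — an indicator rather than a
count, matching how carrier tables are reported) enters

    logit P(affected) = β₀ + β₁·carrier + β₂·sex,

estimated by generalized estimating equations with an exchangeable working
correlation within family clusters and cluster-robust sandwich standard
errors. Unrelated samples are singleton clusters, where the GEE reduces
exactly to maximum-likelihood logistic regression (verified to 1e-6).
Odds ratio and CI are `exp(β₁)` and `exp(β₁ ± 1.96·se)` — Wald intervals
with no small-sample correction. A full suite is 16 tests: four phenotype
groups (GGE, NAFE, mixed, DEE) × four categories, either
{deletion, duplication} × {small, large} or deletion × {any gene, epilepsy
gene, pLI, hotspot}; the Bonferroni threshold is 0.05/16 = 0.003125,
displayed as 0.003. Controls for every test are all unaffected samples
(familial plus population controls); unaffected DEE parents are excluded
from the control set of DEE tests only, since they are ascertained through
their affected child. Complete or quasi-complete separation (an empty cell
of the carrier × phenotype table) is flagged as a warning status rather
than raised; a category with no carriers anywhere yields an undefined
result and the suite continues.

The original familial-correlation treatment in this line of work uses a
kinship-matrix GEE; exchangeable within-family clusters are a documented
approximation that is exact for the structures the generator produces
(every pair inside a nuclear or three-generation family is treated as
equally correlated). A kinship matrix thresholded at third degree can be
mapped onto the same cluster interface.

**Unmasked-variant screen.** Only validated deletions are screened — the
point of the screen is that a confirmed hemizygous region should show
homozygous genotype calls. Homozygous-alt variants inside the deletion are
candidates; heterozygous calls there are retained separately as QC flags
(likely genotyping artefacts), never as candidates. Effect classification
over per-transcript annotations: loss-of-function or nonsense-mediated
decay requires the effect in strictly more than 90% of transcripts; any
missense annotation suffices for the missense class; a variant whose
annotations are all non-coding classes is non-coding. Missense candidates
join an external deleteriousness score (UNEECON-style), labelled
not-deleterious below 0.15 (configurable). Non-coding candidates get, per
brain tissue (amygdala, cortex, hippocampus), a constraint-violation score
= gene directionality score × predicted expression change; higher is more
deleterious, all-non-positive means not likely deleterious, and no score
at all means no predicted functional effect. The expression model and the
directionality table are pluggable inputs (a table-backed provider ships
for tests); only the scoring arithmetic is implemented here. Both SNVs and
small indels are accepted.

**Conventions.** Coordinates are 1-based inclusive everywhere
(length = end − start + 1); BED input/output converts from/to its 0-based
half-open convention at the boundary. PED phenotype coding is 1 =
unaffected, 2 = affected, 0/−9 = unknown.

## The synthetic cohort generator

The generator is the package's study-condition definition, not a test
fixture. It emulates:

- a toy genome of 4 chromosomes × 1500 markers at ~5 kb mean spacing
  (≈30 Mb), small enough for desk-scale runs yet large enough that a
  1–1.5 Mb event does not dominate a sample's genome-wide LRR variance;
- trio or three-generation extended families plus unrelated population
  controls; per family, at most one segregating risk CNV implanted in a
  founder and transmitted with probability 0.5 per meiosis (forceable for
  deterministic fixtures). DEE-style families are trios whose event arises
  de novo in the proband, so their parents are unaffected non-carriers —
  mirroring how encephalopathy trios are ascertained;
- incomplete penetrance: carriers of the family risk CNV are affected with
  probability `penetrance` (default 0.8), everyone else with
  `baseline_risk` (default 0.05), optionally shifted on the log-odds scale
  by sex. Background CNVs, common-locus CNVs and sporadic de novo events
  are phenotype-neutral;
- population structure of the call set: phenotype-neutral background CNVs
  (Poisson per founder, transmitted Mendelianly), two common polymorphic
  loci at ~5% founder frequency (so the rarity filter has something to
  remove), and sporadic de novo events in children (so double-hit carriers
  arise);
- intensities: genotypes drawn independently per marker under
  Hardy-Weinberg from the marker's population B-allele frequency; LRR
  noise N(0, 0.15); BAF noise N(0, 0.03) clipped to [0,1]; a rank-one
  batch effect (per-marker loading × per-batch score, default SD 0.1 LRR
  units) constructed to be exactly removable by one principal component so
  the correction stage has a sharp oracle;
- sequencing call sets for a configurable fraction of family samples:
  each truth CNV reproduced with endpoint jitter up to ±5% of its length
  (within the ±10% contract that keeps every truth event validatable);
- in-deletion variant tables for sequenced deletion carriers: a homozygous
  missense candidate (frequent, low deleteriousness score), a homozygous
  non-coding candidate with directionality/expression tables, an optional
  fully truncating variant, a heterozygous artefact inside the deletion
  and a homozygous variant just outside it — the full decision surface of
  the screen.

What it does **not** emulate, and what passing tests therefore cannot
show: linkage disequilibrium and realistic allele-frequency spectra,
GC-content waves, mosaicism, genotyping-error structure beyond Gaussian
noise, breakpoint microhomology, and real gene/hotspot geometry. Results
on real data depend on those; the synthetic benchmarks establish
correctness of the decision rules and estimators, not field performance.

## Numerical choices

- LRR standard deviation uses the population (ddof = 0) estimator.
- PCA is computed by SVD of the centred fitting submatrix; scores are the
  orthonormal left singular vectors, so regression on them is a single
  projection.
- Viterbi runs in log space; ties are broken by `argmax`'s first-index
  rule (ties have measure zero for continuous signals).
- The caller's state priors put 0.999 on copy-neutral.
- Degenerate inputs: an empty cohort for the noisy-sample filter returns
  empty without error; an empty design list yields an empty burden table;
  frequency estimation refuses `n_samples = 0`; intervals with no markers
  are errors that name the interval.
- Separation detection is the exact empty-cell criterion on the 2×2
  carrier × phenotype table, applied before inspecting the fit.
- GEE fitting uses an Independence working structure when every cluster is
  a singleton (identical estimates to Exchangeable, without the undefined
  intra-cluster correlation).

## Problem sizes

The shipped tests and the acceptance script use cohorts of roughly 200–600
samples on 2–3 toy chromosomes, 40 implanted benchmark deletions plus 20
CNV-free genomes for caller fidelity, 500 replicates for null CI coverage,
200 replicates × three effect sizes for log-OR recovery, and exhaustive
path enumeration up to 12 markers (5¹² ≈ 2.4 × 10⁸ paths). These sizes were
chosen so the whole suite completes in minutes on one CPU while keeping
every binomial acceptance band narrow enough to be informative.

## Known limitations

- The caller is a stand-in: real PennCNV-class callers model GC waves,
  use trained state priors and handle chromosome-specific states; absolute
  sensitivity numbers here do not transfer.
- Exchangeable family clusters ignore the kinship gradient inside extended
  families; with strong within-family effect heterogeneity the sandwich SE
  remains valid but efficiency is lost.
- Wald CIs can undercover for very sparse carrier tables near separation;
  such tables are flagged rather than corrected (no Firth-type penalty in
  this version).
- The ≤1% rarity rule needs cohorts of ≥100 samples to be meaningful for
  singleton calls and ≥300 for family-shared events; smaller studies
  should raise `max_freq` deliberately.
- The unmasked-variant screen consumes upstream annotations as given; it
  does not re-validate genotype calls against read evidence.
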