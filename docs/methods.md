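# Methods

## Quantification model

The package analyses threshold-cycle (Ct) data from a paired two-cell-type
qPCR array design: each of n donors contributes one α-cell and one β-cell
sample, each assayed on a panel of several hundred miRNAs plus at least
one endogenous small-RNA control. Lower Ct means higher abundance; one
cycle corresponds to a two-fold difference under the usual assumption of
near-perfect amplification efficiency (no efficiency correction is
applied — see Limitations).

1. **Censoring.** Ct values above the platform detection limit
   (`cutoff_ct`, default 32 cycles) and wells reported as undetected are
   replaced by the limit itself. The pre-censoring detection state
   (Ct strictly below the limit) is kept as a boolean mask. Censoring is
   idempotent and never decreases a Ct.
2. **Detection filter.** A miRNA is retained when it is detected in at
   least `detection_min` (default 4) of the n donors. The population this
   count ranges over is configurable (`detection_scope`): the default
   `either` requires the threshold within the α population *or* within
   the β population, so a miRNA expressed only in one cell type — exactly
   the biologically interesting case — survives; `both` and `pooled` are
   available for sensitivity analyses. Controls never appear in the
   filtered set.
3. **Normalization.** ΔCt = Ct(miRNA) − Ct(control) within each sample.
   The control must be detected in every sample; an undetected control is
   a hard error rather than an imputation, because normalization against
   a censored value is meaningless. All control rows are dropped from the
   normalized matrix. ΔCt is exactly invariant under per-sample additive
   Ct shifts, which is what removes RNA-loading differences and the
   double-sided control drift seen across fixed-tissue preparations.
4. **Pairing.** Technical replicates within (donor, cell type) are
   averaged on the ΔCt scale; each donor must then contribute exactly one
   α and one β profile, and z = ΔCt(α) − ΔCt(β) per donor. Positive z
   means β-enriched.
5. **Fold change.** FC(β vs α) = 2^(mean z) — the relative quantity
   2^−ΔΔCt applied to the donor-averaged ΔΔCt, i.e. a geometric mean of
   per-donor RQs, matching the convention of instrument analysis
   software. An arithmetic mean of per-donor RQs is available
   (`fc_aggregation`), and is systematically larger on skewed rows.
   Fold changes within [2/3, 3/2] (closed band) are categorised as
   `equal`; strictly outside as `beta_enriched` / `alpha_enriched`.
   Reported fold changes are restated in the direction of enrichment.
   For single follow-up assays, RQ = 2^−ΔCt with Ct ≥ 35 cycles reported
   as undetermined rather than quantified.

## One-class SAM

The test statistic per miRNA is d = mean(z) / (se + s₀) with
se = sd/√n (ddof 1). The fudge factor s₀ guards the denominator — Ct
censoring routinely produces zero-variance rows — and is chosen by the
percentile rule: candidate s₀ values are the 0th, 5th, …, 100th
percentiles of the se distribution; for each candidate the features are
split into 20 se-quantile windows and the coefficient of variation of
the within-window median absolute deviations of d is computed; the
candidate minimizing that CV wins (ties to the smallest percentile).
This makes the spread of d approximately independent of se. Fixed and
zero s₀ are available as alternatives.

**Null distribution.** The design is one-class (is the mean of the
paired differences zero?), so the natural permutation null flips the
sign of each donor column independently. When 2^n fits within the
permutation budget (default 1000, so always for n ≤ 9) all sign vectors
are enumerated; the null, and therefore every downstream number, is then
fully deterministic. Sign flips leave each row's sum of squares
unchanged, so all permuted d vectors follow from the flipped means alone
— the full 667 × 64 null costs a single matrix product. Each permuted d
vector is sorted; the expected order statistics d̄ are the rank-wise
means. π₀, the estimated fraction of truly null features, uses the
quartile rule: the count of observed d inside the interquartile range of
the pooled null, divided by half the feature count, capped at 1.

**Calling.** Observed d are sorted (stable, tie-broken by assay ID) and
compared rank-by-rank to d̄. For a threshold Δ, scanning upward from the
first non-negative d, the upper cut is the observed d at the first rank
with d − d̄ ≥ Δ; the lower cut mirrors it downward. Features beyond the
cuts are called; Δ = 0 calls everything by convention.

**FDR estimate.** For the called set, each permutation contributes the
count of its d values beyond the cuts. The estimated FDR is

&nbsp;&nbsp;FDR% = 100 · π₀ · max( median count floored at 1/B ,
mean count over non-self permutations ) / #called.

Two deliberate choices sit in this formula, both forced by the small
exhaustive null (B = 64 for six donors):

* The classic median-count convention alone is badly granular here: the
  median is exactly 0 whenever a handful of coincidentally
  sign-consistent null rows edge past most permutation extremes, which
  happens in a few percent of signal-free datasets and would certify
  them at FDR 0. The floor of 1/B encodes that B permutations cannot
  certify a rate below one event in B — the same reasoning as the
  never-report-zero convention for permutation p-values.
* The mean count is the direct plug-in for the expected number of false
  calls and stays honest exactly where the median collapses to zero; but
  it is inflated by sign-flipped ghosts of genuine signal — above all by
  the global sign mirror of the observed data, which reproduces the
  entire signal on the opposite side of the two-sided cuts. The identity
  permutation and its mirror are therefore excluded from the mean (both
  reproduce the observed configuration; neither is a null draw).

Taking the maximum of the two estimates is conservative and lets each
cover the other's blind spot. On signal-free study-shaped data this
procedure makes no calls in 200 of 200 generator seeds at the 0.5%
target, while recovering 50 planted 2-cycle effects with full
sensitivity — both measured by the acceptance suite, not asserted.

**Δ selection and q-values.** The default Δ grid is 200 points from 0 to
one step beyond the largest |d − d̄|; the final point calls nothing, so
the grid always contains the vacuous empty set and data without
signal select it rather than being forced into a call (a user-supplied
grid that never meets the target returns its largest Δ with a warning).
Selection takes the smallest grid Δ whose FDR estimate (its running
minimum along the grid, which makes the curve non-increasing) meets the
target, 0.5% by default. A feature's q-value is the minimum estimated
FDR over all grid Δ at which it is called; because call sets are nested
in Δ, q-values are monotone in the ranked deviation. Every reported
feature's q-value is at most the achieved FDR of the selected Δ.

## Target intersection

miRNA identifiers from array assay names and from prediction databases
follow different nomenclatures. Both sides are canonicalized (lower-case,
species prefix stripped, `mir`/`let` stem normalized; `*` and `-3p/-5p`
mature-strand suffixes preserved verbatim; unrecognized identifiers pass
through lower-cased with a warning, never silently dropped), then an
optional user-editable alias table is applied. The three database
dialects are fixed column layouts documented in
`targets.read_predictions`; duplicate (miRNA, gene) pairs keep the best
score, malformed lines are logged and skipped, and more than 10%
malformed lines is a hard error. β-enriched miRNAs with fold change
strictly greater than 3 are intersected per database with the five gene
groups; the consensus column counts supporting databases but does not
filter by default (`--min-sources 1`), mirroring a per-algorithm report.
Gene identity is bare-symbol (upper-cased): no ortholog mapping is
attempted between species beyond case normalization.

## Synthetic-data generator

The generator emulates the features of the study design that the
analysis relies on:

* **Baseline** Ct per miRNA ~ Uniform(20, 31) cycles — the working range
  of a preamplified array card, with the upper end deliberately close to
  the 32-cycle limit so censoring actually occurs.
* **Planted effects**: a configurable fraction of miRNAs is β-enriched
  (default 20%, mirroring the dominance of β-cell miRNAs in sorted-islet
  profiles), a small fraction α-enriched (1%) and near-equal (5%,
  |effect| < 0.5 cycles); effect sizes default to Uniform(1, 7) cycles,
  i.e. fold changes 2–128, the span such studies report. The enriched
  cell type's Ct drops by the effect; z therefore equals the effect in
  expectation.
* **Donor noise** (default sd 0.5 cycles) is shared within a donor's
  α/β pair — the preparation-level variability that the paired design
  cancels, and the reason a one-class analysis of paired differences is
  the right test. **Well noise** (sd 0.25 cycles) is independent.
* **Control drift** (sd 1.0 cycle) shifts every assay of a sample,
  including the control, in either direction — so ΔCt removes it
  exactly (verified as an invariance test). The control itself carries
  no independent well noise: control noise would propagate through ΔCt
  into every feature of the sample as a shared shift, correlating the
  whole panel — a different (and analytically hostile) regime from the
  one this generator is meant to emulate.
* **Censoring**: wells whose Ct lands above the limit are emitted as
  undetected, so strongly β-enriched miRNAs near the limit drop out of
  α samples — the regime the detection filter exists for.

The prediction-database generator plants (miRNA, gene, group) triples
for strongly β-enriched miRNAs (effect > 1.6 cycles, i.e. FC > 3) into a
configurable subset of the three databases and adds decoy pairs and
decoy group members; the truth table records everything for round-trip
tests.

What passing the simulation-based tests does **not** show: robustness to
amplification-efficiency differences between assays, preamplification
bias, card-position effects, non-normal or heavy-tailed donor noise,
control instability that is not a pure per-sample shift, or real miRNA
nomenclature messiness. Results on real exports depend on those factors;
the generator's scope is the statistical machinery, not PCR chemistry.

## Problem sizes and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `cutoff_ct` | 32 cycles | array detection limit / censoring point |
| `undetermined_ct` | 35 cycles | single-assay qPCR undetermined threshold |
| `control_assay` | RNU48 | endogenous small-RNA control |
| `detection_min` / scope | 4 / either | donors required for detection |
| `equal_band` | [2/3, 3/2] | fold-change band treated as equal |
| `target_fdr_percent` | 0.5 | SAM target FDR |
| `n_permutations` | 1000 | budget; exhaustive 2^n used when it fits |
| `n_delta` | 200 | Δ grid resolution |
| `min_fc` | 3 (strict) | β-miRNA filter before target intersection |

Simulation-based checks use 667 features × 6 donors (the study shape);
calibration uses 200 generator seeds and recovery 20, sizes at which the
full pipeline runs in well under a minute on one CPU while keeping the
Monte-Carlo error of the reported means small.

## Limitations

* FDR estimates inherit the granularity of the 2^n sign-flip null; with
  very few donors (n ≤ 4) the procedure is intentionally conservative
  and may call nothing at stringent targets.
* No amplification-efficiency correction and no multi-control
  (geometric-mean) normalization; alternative controls are handled by
  re-running with a different `control_assay`.
* Gene-group membership is taken as given input; the package computes
  no enrichment statistics over the intersection report.
* The series-matrix adapter expects sample titles of the form
  "<celltype> <donor>" and is a convenience, not a general GEO client.
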