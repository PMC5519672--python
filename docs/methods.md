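# Methods

## The twin-divergence model

The analysis treats a monozygotic (MZ) twin cohort as a natural experiment
separating genetic from environmental control of expression. For probe *i*
with log2 expression `g_i`, measured in both members (superscripts 1, 2) of
every couple, the divergence score is

    Δ_i = ⟨ |g_i¹ − g_i²| ⟩ / σ_{g_i}

with the numerator the unweighted mean over couples and σ the probe's
sample SD (n−1 denominator) over all 2·n_couples values. Δ is dimensionless
and invariant to affine rescaling of a probe. Probes with zero variance have
no defined score; they are set to NaN and excluded from z-scoring rather
than assigned Δ = 0. Low-Δ probes are concordant within couples relative to
their overall dynamic range — exactly the profile expected of genetically
programmed, age-tracking expression, since an age trend shared by both
twins inflates σ without inflating the within-couple difference.

Scores are z-scored across probes (mean 0, SD 1 over finite entries) and
probes with z ≤ −t are selected. The signature threshold is t = 2.5 SD; the
laxer enrichment threshold is t = 1.5 SD. The selection is the *low* tail:
"at least 2.5 SD below the mean" fixes the sign as z ≤ −2.5.

A whole-array companion: Pearson R between the two members' full profiles,
one value per couple, regressed on couple age by OLS with a classical
t-based 95% CI on the slope (n−2 degrees of freedom). A negative interval
indicates concordance eroding with age.

## Signature extraction

For each of the n_couples leave-one-couple-out folds, Δ and z are
recomputed on the remaining couples and the z ≤ −2.5 set is recorded; the
left-out couple contributes to neither the score nor any model fit in its
fold. One random couple split (exactly one twin per half, uniform,
seed-derived) is drawn per extraction run; each fold fits a ridge model on
the training half restricted to its selection and records the validation-half
R for provenance. The released signature is the intersection of all
per-fold selections minus probes without a gene-symbol annotation, with one
final ridge model fitted on the training half restricted to the signature.
Intersection over folds is the stability filter: a probe whose selection
depends on any single couple is discarded. Because ridge itself performs no
variable selection, "appearing in every fold's model" can only mean
membership in every fold's selected probe set — the implementation adopts
that reading. Selection operates on probes, not symbols; symbol
deduplication happens only at cross-platform transfer.

### Ridge regression

Predictors are centered and scaled to unit sample SD; on that scale the
coefficients solve (Xs′Xs + kI)β = Xs′(y − ȳ) with k = 10⁻⁴ by default
(k = 0 falls back to a minimum-norm least-squares solve). Coefficients are
reported back on the original expression scale with the intercept restored;
both scales are retained in the model object. Columns with zero range are
dropped with a zero coefficient — the range test, not an sd > 0 test,
because float summation can leave a constant column with nonzero computed
SD. With fewer training samples than probes and tiny k the fit approaches
minimum-norm interpolation; that is the intended regime (27 training
samples, tens-to-hundreds of probes) and the couple-split validation half
is what measures real performance.

## Random-signature null

The yardstick for the signature is empirical: draw probe subsets of matched
size uniformly without replacement, evaluate each exactly as the candidate
was evaluated, and rank the candidate by strict inequalities (ties count
neither as outperforming nor as outperformed). Twin-protocol draws reuse the
candidate's couple split and run fit/validate only — the leave-one-out
selection is not re-run per draw, since random signatures have no selection
step to cross-validate. Singleton-protocol draws run one random 10-fold CV
partition each. Null generation is bit-reproducible given the seed.

## Cross-platform transfer

Different platforms share gene symbols, not probes. A signature transfers
as its symbol list: for every symbol present on the target the probe with
the highest average expression is kept (ties broken by probe id, making the
mapping idempotent); absent symbols are dropped and reported. Coefficients
do not transfer — ridge is refitted on the target platform, because probe
affinities and dynamic ranges differ. Evaluation is repeated k-fold CV: per
repeat, a fresh uniform partition into 10 folds, ridge on nine folds,
predictions pooled over held-out folds, one Pearson R per repeat between
pooled predictions and age. Pooling (rather than averaging fold-wise R) is
deliberate: per-fold R on ~3 samples is meaningless. Optional batch labels
enter as 0/1 indicator columns appended to the predictors. The
no-cross-validation resubstitution R is available but labelled optimistic.

Note a statistical subtlety verified during development: under a
permutation null, pooled out-of-fold CV predictions are *negatively*
correlated with the response in expectation (each fold's prediction centers
on a training mean that excludes the held-out samples). The bias shrinks
with sample count and predictor count; the permutation-null tests therefore
draw a fresh permutation per repeat and use a regime (30 samples, 15
probes, 5 folds, measured bias ≈ −0.01) where it is negligible against the
Monte-Carlo tolerance.

## Pathway enrichment

One-sided hypergeometric over-representation (Fisher's exact upper tail):
for a pathway with n_annotated background members of which n_significant
are selected, p = P(X ≥ n_significant) with population = background size
and successes = selected-in-background count. The background is the set of
probes carrying at least one pathway annotation, not the whole array, and
counting is probe-level (a gene with several annotated probes counts per
probe). Raw p is reported alongside a Benjamini–Hochberg q across all
tested pathways. The test choice is the field's standard for
over-representation of an unranked selection; published pathway tables from
other tools may use a different test, so printed p-values are compared only
in their count arithmetic (ratios, selection percentages), never in p.

## Preprocessing

Vendor-processed intensities are log-transformed (base 2, the microarray
convention, exposed as a flag) and quantile-normalized jointly over the
whole supplied matrix, never per batch. The reference distribution is the
across-sample mean of sorted columns; tied values receive the mean of the
reference values at their tied rank positions. Nonpositive values under the
log are a hard error unless the optional +1 offset is engaged (logged
prominently). Quantile normalization is idempotent and preserves
within-sample ranks.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with ground
truth for recovery tests. Values are emitted directly on the post-log
scale. Three probe classes:

* **age_regulated** (5% of probes): baseline + slope·age + couple-shared
  genetic effect + individual noise. Slopes are ±slope_scale·U(0.75, 1.25)
  with random sign.
* **volatile** (15%): as stable, but individual noise SD grows linearly
  with age, 1 + γ·(age − onset); onset defaults to the age minimum, with a
  piecewise onset-age option (default off).
* **stable** (80%): baseline + genetic effect + individual noise.

The couple-shared genetic effect applies to *all* classes. This is a
deliberate modelling choice: genetic control of baseline expression is
genome-wide, and it is what makes the class ordering of mean divergence —
age_regulated < stable ≤ volatile — hold in expectation. Without a shared
component, a pure-noise probe attains the Gaussian maximum of
E|g¹ − g²|/σ (≈ 1.128), and heteroscedastic (volatile) noise can only sit
*below* it by Jensen's inequality; shared variance lowers stable probes
under volatile ones, matching the intended biology (volatile probes are the
environmentally driven ones).

Defaults (units are log2-expression unless noted): 27 couples, 5,000
probes, couple ages uniform on 22–98 years (a fixed-age-list override
exists), baselines U(6, 12), genetic_sd 0.5, individual_sd 0.25,
slope_scale 0.05 per year, divergence growth γ = 0.015 per year, 2% of
probes unannotated. These were chosen once so that the default cohort
reproduces the qualitative regime of a real twin array study — roughly 1%
of probes in the z ≤ −2.5 tail, about half of them surviving the
leave-one-couple-out intersection, and an unambiguously negative
concordance-vs-age slope — and were frozen before the acceptance checks
were finalized. All randomness flows from a single seed through
deterministic named substreams, so every artefact is bit-reproducible.

Singleton validation cohorts reuse per-symbol slopes from the twin truth,
keep a configurable fraction of symbols, may carry several probes per
symbol (differing baselines exercise the highest-average mapping rule), and
apply a platform-wide affine shift. Pathway annotations plant a designated
enriched subset drawing 80% of members from age-regulated probes; the rest
draw uniformly.

### What the generator does not emulate

No raw-intensity, scanner, batch or hybridization physics; no correlated
gene modules (probes are independent given class); noise is Gaussian and
the age trend linear; environmental divergence and transcription noise are
a single term. Consequently, passing recovery tests demonstrates that the
pipeline's statistics behave as designed under their own assumptions — not
that a real cohort of 27 couples would yield a signature of any particular
size or accuracy. Real validation requires real accessions, which this
package deliberately reads only as user-converted TSV.

## Numerical choices and degenerate inputs

* SDs use the n−1 denominator throughout (exposed as `ddof` where relevant).
* Zero-variance probes: NaN divergence, excluded from z-scoring, never
  selected; zero-variance couple profiles are a hard error naming the couple.
* All-equal divergence scores make the z-score undefined: hard error.
* Threshold comparisons are inclusive (z ≤ −t); gene ranking breaks
  coefficient-magnitude ties by probe id; symbol mapping breaks mean ties by
  probe id.
* Empty per-fold intersections raise an error suggesting a laxer threshold
  rather than returning an empty signature.
* Readers reject duplicate identifiers, non-numeric cells (with cell
  coordinates), couples of size ≠ 2 and within-couple age or sex
  discordance; empty GMT pathways load with a warning.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the study-scale design
(27 couples, 5,000 probes) but scale iteration counts to what the checks
need: 1,000 random twin-split signatures (the CLI default remains 100,000),
200–300 CV repeats and null draws (CLI default 10,000), and 20 seeds for
the trend sign check. Iteration counts affect only Monte-Carlo resolution,
not the quantities being estimated; the chosen counts resolve every
comparison the checks make by a wide margin.
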