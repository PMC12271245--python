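# Methods

## The problem

Psychopharmacological treatment of major depression (ICD-10 F3) and
schizophrenia (F2) produces heterogeneous courses: a minority of patients
meet formal response criteria, a large group improves partially and then
gets "stuck", and a substantial group does not improve at all.  `genevec`
implements a multivariate genotype-based approach to predicting this
heterogeneity: instead of testing SNPs one at a time, the genotypes of the
4–8 SNPs within each candidate gene are combined into a single categorical
"gene vector", and the distribution of these multi-SNP genotypic patterns is
(1) used to quantify a cohort's genetic diversity and (2) fed to a
constrained sigmoid neural network that tries to recognize treatment
responders.

Because no patient-level data of this kind are publicly deposited, the
package ships a synthetic-cohort generator that reproduces the *structure*
of such a study, with planted ground truth, so that every stage of the
pipeline can be validated as a parameter-recovery exercise.

## Gene vectors and diversity

A SNP genotype is coded 0/1/2 as the count of the alphabetically later
allele (the analysis is invariant to which allele is counted; the convention
only fixes the numeric code).  For a gene with m member SNPs, ordered by
ascending physical position (digit k = k-th SNP),

    v = sum_k s_k * 3^(k-1),   s_k in {0, 1, 2},

so at most 3^m patterns exist (81 for m=4, 6,561 for m=8).  A vector with
any missing constituent genotype is treated as missing: a base-3 code with
an unknown digit is undefined; no partial patterns are formed.

The *diversity index* d of a gene is the number of distinct patterns
observed in a sample.  Under cross-SNP independence the expected number of
distinct patterns for n subjects is the coupon-collector form
`sum_p [1 - (1 - p)^n]` over all 3^m pattern probabilities (product of
observed per-SNP marginals); with uniform states, n = 4·3^m subjects are
expected to show ~95% of all patterns (98.2% for m=4 exactly).  The
*dependence ratio* — total observed distinct patterns over the total
expected under independence — measures how strongly within-gene LD
suppresses diversity; it is ~1 for independent SNPs and falls well below 1
under dependence.

Between-gene association of pattern categories is summarized by Cramér's V
on the pairwise-complete contingency table, with patterns of fewer than 5
carriers pooled into one rare category per gene and the Bergsma small-sample
bias correction applied by default (`bias_correction=False` gives the
classical V).  This measure is a standard categorical association
coefficient; it is not numerically comparable to correlation measures
defined differently elsewhere.

## Clinical labels

Scores are tracked on HAM-D17 (F3) and PANSS-P (F2), with PANSS-G carrying
F2 baseline severity and inclusion.  Inclusion requires baseline ≥ 15
(HAM-D17) or ≥ 21 (PANSS-G) and at least three assessments in the first two
weeks.  Severity bands: HAM-D17 <20 / 20–24 / >24 and PANSS-G <30 / 30–40 /
>40 (boundaries inclusive into "moderate").  Missing scheduled assessments
are filled by last observation carried forward (no extrapolation before
baseline).

Response is a *sustained* 50% (HAM-D17) or 40% (PANSS-P) reduction of the
baseline score; onset of improvement a sustained 20% reduction; onset within
14 days defines an early improver.  "Sustained" is anchored to the first
qualifying visit: every later visit must retain at least 85% of the
reduction achieved there.  An alternative anchoring to the running-maximum
reduction is available (`anchor="max"`); the first-visit anchor is the
simplest reading of the criterion and is the default.  Because reductions
are fractions of baseline, all labels are invariant under rescaling of the
score scale.  Response and onset labels are only asserted for included
subjects.

## Synthetic cohorts

Defaults reproduce the emulated study conditions: 264 F2 + 638 F3 subjects,
100 genes × 4–8 SNPs (~550 SNPs), responder fractions 29.5%/35.6% and
early-improver fractions 52.3%/57.1% per diagnosis, 2% missing genotypes
with a 14.5% subgroup of high-missingness subjects, 26.1% elevated-IgM
prevalence, and ten embedded response genes (pattern frequency 0.30 in
responders vs 0.05 in non-responders).

* **Genotypes.**  Per-SNP allele frequencies are uniform on (0.1, 0.9);
  genotypes follow Hardy–Weinberg marginally.  Within-gene dependence is a
  Gaussian copula on latent dosages with equicorrelation `within_gene_ld`;
  ld=0 recovers exact independence.  The default ld=0.80 was calibrated
  once so that the study-sized cohort's dependence ratio lands near one
  third, the regime the diversity analysis targets, and then frozen.
  Cross-gene linkage optionally copies one gene's pattern digits into a
  partner gene with a configured probability.
* **Trajectories.**  Each subject is assigned a course class (responder /
  stuck / non-improver) from the configured fractions; "stuck" takes 60% of
  non-responders by default, which places roughly a quarter of subjects in
  the never-improves group.  Baselines come from truncated normals
  calibrated to the severity-band proportions (F3: 24/39/37%; F2: 7/30/63%).
  Improvement is a trigger process: nothing happens until a random trigger
  day, then the score declines linearly to a target level plus i.i.d.
  Gaussian visit noise (sd 1 point).  Responders shed 60–85% of baseline
  over 10–24 days; stuck subjects shed 20–50%, clipped just below the
  diagnosis response threshold (a plateau at or beyond the threshold would
  *be* a response by definition), over 5–12 days; non-improvers stay flat
  (a drift parameter allows worsening).  The visit schedule is days
  {0, 3, 7, 10, 14, 21, 28, 42}.  The early-improver fraction is realized
  by giving that (attenuation-corrected) share of improvers a trigger in
  days 1–6.  Labels are then re-derived by applying the clinical criteria
  to the noisy trajectories, so realized fractions sit within sampling
  noise of the targets rather than being asserted.
* **Planted signal.**  For each configured response gene a random pattern is
  designated and overwritten into responders/non-responders at the
  configured frequencies (independently per gene and subject); the planted
  codes are recorded as ground truth.
* **IgM.**  Elevated-IgM flags hit the configured marginal prevalence, with
  carriers of the modal pattern of designated genes receiving an elevated
  probability scaled by an association-strength parameter (0 = independent).

What the generator does **not** emulate: LD decay along chromosomes,
recombination, ancestry structure, scale-specific item dynamics, dropout,
or any treatment-arm structure.  Passing recovery tests therefore shows the
pipeline is correct and well calibrated on data with the assumed structure
— not that the clinical findings would replicate on real cohorts.

## Response-gene screen

A pattern qualifies when it is rare in one class (frequency < 10%) and
characteristic of the other (frequency ≥ 20% with ≥ 5 carriers), tested in
both directions; genes with any qualifying pattern are "response genes" and
form the classifier pool.  The characteristic-side thresholds are design
choices (the rarity side is the defining rule); both are exposed as
parameters.  No multiple-testing correction is applied; instead the implied
false-positive rate under the null is quantified by a label-permutation /
hypergeometric-split simulation in the test suite.  Screening on the full
labeled sample leaks label information into feature construction for the
subsequent cross-validation; a fold-honest mode (screen on training subjects
only, via the `subjects` argument) is provided.

## Neural-net classifier

Features are per-gene one-hot indicators of the patterns with ≥ 5 carriers
plus an OTHER indicator per gene; a missing gene vector leaves an all-zero
block.  The network is input → one hidden layer → one output, logistic
activations, no bias terms, trained by online per-probe backpropagation of
squared error in shuffled order (one "iteration" = one full epoch).  Weights
are initialized uniformly in ±0.5; the default hidden width is
min(2·n_features, 32).

Numerical choices that matter:

* **Training targets are 0.1/0.9**, not 0/1.  The squared-error update
  carries a factor s(1−s) that vanishes as outputs saturate; with hard 0/1
  targets, constraint-class probes that saturate early become permanently
  unlearnable and the constraint threshold degenerates.  Off-asymptote
  targets keep every probe's gradient alive.  This is the classical remedy
  for sigmoid networks trained on squared error.
* **Threshold policy.**  The decision threshold is the maximum output over
  the constraint class (non-responders, by default) in the *training* data
  plus 1e−9, guaranteeing 100% constraint-class accuracy on the calibration
  set.  In cross-validation the threshold applied to a test fold comes only
  from that fold's training data.
* **Model comparison** is lexicographic: calibration-side constraint
  accuracy (1.0 by construction), then sensitivity, then fewest false
  positives, then a continuous positive-class margin as tie-break.
  Sensitivity must precede the FP count: under the max+δ threshold the
  all-negative classifier attains zero false positives, so an FP-first
  order would always prefer the model that recognizes nobody.
* **Stopping.**  Training stops at the epoch budget (default 2,000; desk
  scale) or when the squared error over the last 8 evaluations oscillates
  within a relative tolerance of 1e−4 without improving.
* **Random-walk restarts** retrain from independent perturbed
  initializations and keep the best pooled-CV key; greedy forward selection
  of classifier genes adds the gene with the best pooled-CV key until no
  gene improves it (capped at 6 genes, matching the small classifier sets
  this design targets) and retains genes selected in ≥ 70% of restarts.
* **Reverse direction.**  Training with responders as the constraint class
  is supported (`constraint_class=1`); on synthetic cohorts it behaves
  poorly (high overlap), which is the expected asymmetry of the design, and
  is reported, not asserted.

## Problem sizes

The recovery suites run at n = 600 subjects with 100 genes (screen,
cross-validated sensitivity) and 15 genes (gene selection), 10–20 seeds per
claim; coverage simulations use 300–500 replicates.  These sizes were chosen
so the full suite completes comfortably on a single CPU while keeping every
statistical bound at least 3 standard errors wide.

## Known limitations

* The between-gene association coefficient is not comparable to
  correlation-based numbers computed under other definitions.
* The constraint-threshold classifier's test-set false-positive rate is
  unconstrained by design; only the calibration set carries the 100%
  guarantee.
* Greedy selection's first step carries no signal when single genes are
  individually non-discriminating (identical single-gene features cannot be
  separated at a zero-FP threshold); recovery relies on later rounds and on
  the stability filter.
* The generator's trajectory model is a stylized trigger process; it is not
  a pharmacological model.
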