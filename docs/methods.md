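# Methods

## Problem and model

`triagekit` evaluates quantitative fluid biomarkers as classifiers of a
binary disease state defined by a reference standard (amyloid PET at
≥ 37 Centiloids, tau PET at SUVR > 1.32, or a binary visual read / clinical
diagnosis). Three estimation layers sit on top of each other:

1. **Ranking accuracy.** The AUC is the Mann–Whitney probability that a
   randomly chosen diseased subject outranks a non-diseased one, ties
   credited ½. Inference uses DeLong's structural-components decomposition:
   per-positive and per-negative placement values whose empirical
   (co)variances give the variance of one AUC and of the difference of two
   AUCs measured on the same subjects. Placements are computed with midranks
   in O(n log n); tests verify exact agreement with an O(n²) pairwise oracle.
   CIs use the normal approximation truncated to [0, 1], not a logit
   transform.

2. **Decision thresholds.** Two constrained rules. Single cutoff: maximise
   sensitivity subject to specificity ≥ 0.90. Two-cutoff triage: the lower
   threshold maximises specificity subject to sensitivity ≥ 0.95; the upper
   maximises sensitivity subject to specificity ≥ 0.95; subjects in between
   are *intermediate* and excluded from accuracy/PPV/NPV, being counted
   instead in the intermediate fraction n_int / (n_classified + n_int).

3. **Uncertainty and comparison.** All metrics are estimated over 1,000
   bootstrap resamples drawn with replacement within each outcome stratum
   (class counts preserved exactly per replicate). The point estimate is the
   bootstrap mean; the observed full-sample statistic is always reported
   beside it; CIs are 2.5/97.5 percentile bounds with the linear-interpolation
   quantile definition. Paired plasma-vs-CSF differences reuse one resample
   index vector per replicate for both markers (the variance-correct pairing),
   computed on the intersection of complete cases for both markers and the
   outcome. The verdict is *equivalent* when the difference CI includes zero
   and *plasma superior* when the CI lies above zero, with the difference
   oriented so that positive favours plasma — including the intermediate
   fraction, where the difference is CSF − plasma and is expressed as a
   fraction of the sample so its maximum is 1.

## Orientation handling

Biomarker direction is declared (`higher_is_positive` for %p-tau217 and CSF
p-tau181/Aβ42, `lower_is_positive` for CSF Aβ42/40) and never inferred from
the data; automatic direction detection can silently flip a weak marker.
Lower-is-positive scores are negated once on entry; all ROC/cutoff machinery
then assumes higher = positive, and thresholds are mapped back to the
measured scale for reporting.

## Numerical and convention choices

* **Candidate thresholds** are midpoints between consecutive distinct
  oriented scores plus ±∞ sentinels. Midpoints make the ≥-boundary
  convention unambiguous and threshold selection invariant under strictly
  increasing transforms; implementations that scan observed values can
  differ by less than one subject's worth of sensitivity/specificity.
* **Boundary conventions**: a score exactly at the single cutoff or the
  upper triage threshold is positive; exactly at the lower threshold is
  intermediate; strictly below the lower threshold is negative.
* **Tie-break** when several thresholds maximise the constrained objective:
  the threshold whose *constrained* metric is smallest is selected, i.e. the
  constraint binds as tightly as possible. This choice is unique (no two
  candidate thresholds share both sensitivity and specificity) and makes
  constraint attainment exact rather than seed-dependent: on tie-free data
  the achieved specificity at the single cutoff is precisely
  ⌈0.9·n_neg⌉/n_neg — exactly 90% whenever 0.9·n_neg is an integer — and
  likewise 95% at the two triage thresholds. The alternative (break ties
  toward the larger constrained metric) overshoots the floor whenever the
  scores adjacent to the binding threshold belong to the constrained class.
  A corollary: on perfectly separable data with a fractional floor the
  selected cutoff sits at the floor inside the negatives rather than in the
  inter-class gap; with a floor of 1.0 (or any floor forcing specificity 1)
  the gap threshold is the unique optimum.
* **Crossed triage thresholds** (lower > upper after orientation) occur when
  the marker is so discriminating that the sensitivity-95% threshold lies
  above the specificity-95% threshold (population crossing when the class
  separation exceeds 2 × 1.645 latent s.d.). The pair is collapsed to its
  midpoint with a warning and flagged, so a reversed intermediate zone can
  never be emitted silently.
* **Undefined metrics** (empty denominator, e.g. PPV with no predicted
  positives) are NaN plus an explicit flag, never 0 or 1. Bootstrap
  aggregation drops undefined replicates per metric, reports the valid
  count, and flags the estimate unreliable when more than half were dropped.
* **Missingness** propagates; there is no imputation anywhere. Analyses use
  explicit complete-case subsets, and paired comparisons use the
  intersection of complete cases so within-replicate differences stay
  well-defined.
* **%p-tau217 scale**: stored as a percentage (×100). All rank-based
  statistics — AUC, threshold selection, triage labels — are invariant to
  this (tested), so the scale choice is cosmetic.

## Synthetic cohorts

No subject-level data are distributed; the generator produces cohorts with
the statistical structure the analysis needs:

* Disease state Bernoulli(prevalence) per cognitive group — defaults 0.15
  among cognitively unimpaired and 0.50 among impaired subjects, the
  operating prevalences that PPV/NPV depend on. An `exact_prevalence` flag
  allocates ⌈n·p⌋ positives deterministically for experiments that need
  exact class counts.
* Reference measures drawn from state-conditional Gaussians; Centiloid
  defaults mean (s.d.) 0.4 (20.3) for negatives and 91.4 (30.1) for
  positives, SUVR defaults 1.15 (0.10) vs 1.60 (0.30) (clipped positive).
* Each biomarker lives on a latent Gaussian scale
  `s·(d·state + √ρ·σ·z + √(1−ρ)·σ·ε)` with a severity term `z` shared across
  markers, independent noise `ε`, sign `s` per orientation, and binormal AUC
  Φ(d/(σ√2)). Default loadings 2.6 / 2.2 / 1.7 (plasma ratio, CSF
  p-tau181/Aβ42, CSF Aβ42/40) give AUCs ≈ 0.97 / 0.94 / 0.89, spanning the
  range where the plasma-vs-CSF comparison is interesting. ρ defaults to
  0.6 — a free simulation parameter chosen to make paired CIs visibly
  tighter than independent ones; no published joint plasma–CSF correlation
  informs it.
* The plasma ratio is decomposed into plausible component concentrations
  (log-normal non-phosphorylated tau around 30 pg/ml) so the
  covariate-adjustment sensitivity analysis has raw inputs; visual read and
  clinical diagnosis are the true state flipped with small error rates
  (defaults 2% and 10%, diagnosis forced negative in unimpaired subjects).
* Optional per-column missingness, an optional exponential transform to
  mimic skewed concentration scales (rank statistics unchanged, tested),
  and a single global seed driving every draw.

What the generator does **not** emulate: longitudinal trajectories beyond
simple repeat-visit tables, non-Gaussian heavy tails, assay batch effects,
covariate structure (age, APOE), or state-dependent missingness. Passing
tests therefore demonstrate correctness of the *procedures* under the
assumed data-generating process, not the clinical performance of any real
assay.

## Problem sizes

Unit and property tests run at n ≤ 2,000 with oracle suites at n ≤ 100;
constraint-attainment and determinism checks use a 2,000-subject cohort with
1,000 bootstrap replicates (the study-scale configuration); binormal
parameter recovery uses n = 5,000 per run. The acceptance script simulates
2,000 subjects with exactly 1,000 per class at separation d = 2.3
(AUC ≈ 0.95).

## Known limitations

* Percentile bootstrap CIs only (no BCa/studentized); no multiplicity
  adjustment across metrics.
* The DeLong CI is symmetric-normal and can be conservative near AUC = 1.
* The rank-sum test used for triage-group reference comparisons is one
  reasonable choice among several; exact p-values from other tests will
  differ.
* Cross-cohort transfer assumes the biomarker is on the same measured scale
  in both cohorts; a deliberate mis-scaling test demonstrates the
  calibration hazard rather than correcting it.
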