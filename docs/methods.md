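# Methods

This note documents the models, the synthetic data, the numerical choices and
the known limits of what the test suite demonstrates.

## Signal model and synthetic cohort

A respiratory-belt signal is modelled as a train of triangular inhale–exhale
events: one symmetric triangle per breathing period `T` (default 3–6 s per
subject, constant within a subject — belts record person-consistent event
shapes), occupying a `triangle_duty` fraction of the period (default 0.5–0.7).
The triangle is the simplest shape consistent with the spiky appearance of
belt recordings; its symmetry is a modelling convenience, and the duty cycle
is configurable.

**Waxing–waning.** Periodic-like breathing is produced by modulating the
per-breath peak amplitude with a slow sinusoid, `A·(1 + m·sin(2πt/T_mod))`,
`m ∈ [0, 1]`. A sinusoidal envelope is the minimal model of cyclical
amplitude behaviour; `T_mod` defaults to 30–60 s, inside the tens-of-seconds
range typical of periodic breathing. Mixed recordings are built from ten
segments whose pattern types match the subject's contribution deciles exactly
(segment modulation depths: normal 0, intermediate 0.5, periodic-like 0.9).
Segment granularity is a free choice (the underlying phenomenon has no
canonical segment length); ten segments makes the decile bookkeeping exact.

**Apneas.** An apnea is a stretch with no respiratory activity lasting
*strictly longer than three breathing cycles*; the generator inserts gaps of 5
cycles on a deterministic schedule (one per `60/rate` seconds of recording,
centred at half-interval offsets), so the inserted count in a recording of
known length is exact and can serve as ground truth. Label-conditional rates
default to 0 / 0.1 / 0.2 events·min⁻¹ for normal / intermediate /
periodic-like subjects. The detector standardizes the signal, computes a
moving standard deviation over one breathing period (a moving RMS would
misread the standardized baseline offset in quiet stretches as activity),
thresholds it at 0.1× the median envelope, and counts maximal sub-threshold
runs longer than three cycles. With zero observation noise it recovers the
inserted count exactly; with noise the threshold needs to sit above the noise
floor and is exposed as a parameter.

**Anthropometrics.** Per-label Gaussian draws around the pooled cohort moments
(BMI 28.8 ± 4.9 kg/m², WHR 0.92 ± 0.10, age 51.4 ± 11 y), shifted so the
periodic-like and intermediate groups are heavier, more centrally obese and
more often male than the normal group (BMI means 26.5/29.5/30.5, WHR means
0.87/0.94/0.96, male fractions 0.42/0.62/0.68 for normal/intermediate/
periodic-like). Only the pooled moments are empirically anchored; the label
shifts are free parameters of the generator, exposed in its configuration.
BMI and WHR fields are recomputed from the rounded weight/height/waist/hip so
the stored values satisfy the defining identities exactly.

**Deciles and labels.** Contribution deciles sum to 10. The expert label is
normal or periodic-like when that pattern's decile is ≥ 7 (the 70% rule) and
intermediate otherwise; the generator's decile samplers respect this by
construction. Two profiles exist: `study` mimics the wide, overlapping
composition of a real cohort; `separated` is the well-separated regime used
for end-to-end recovery experiments — near-pure compositions (periodic decile
∈ {0, 1} / {4, 5} / {9, 10} by label) and a tight nuisance morphology
(T ∈ 3.8–4.6 s, T_mod ∈ 36–44 s). The tight period band matters: letting T
range over a full octave moves breath energy across an entire wavelet level
and swamps the composition signal.

**Randomness.** One integer seed drives everything through a
`numpy.random.SeedSequence`; per-subject child streams make the cohort
reproducible bit-exactly and independent of generation order.

**Sampling rate.** Synthetic recordings default to 125 Sa/s, a 2³ decimation
of the 1000 Sa/s reference hardware rate. `drop_finest_for_rate` keeps the
retained-scale time spans aligned: at 1000 Sa/s the 7 finest DWT components
are dropped, at 125 Sa/s only 4, so "scales 5–7" always span ≈ 4–16 s.

## Wavelet granulation

Signals are standardized with the population (divide-by-n) standard deviation
before decomposition. The DWT is PyWavelets' `wavedec`; retained detail
components are re-indexed 1..K from the finest retained. "Scales 5, 6, 7"
refer to the retained indexing (absolute detail levels `drop_finest + 5..7`);
the alternative absolute reading is available by passing `drop_finest=0` and
absolute scale numbers. Quartiles use linear interpolation between order
statistics throughout the package (descriptors, boxplots, cut fitting), so
printed-precision checks are well defined. The mother-wavelet ranking
criterion is the IQR of all retained coefficients pooled per signal, averaged
over signals, descending; candidates whose filter length makes the requested
depth infeasible are excluded with a warning rather than failing the ranking.

## Rough-set core

Objects are row positions; the indiscernibility partition, lower/upper
approximations and the accuracy |lower|/|upper| follow the standard
definitions. The empty decision class is treated as vacuously crisp
(accuracy 1) to avoid a 0/0.

**Discretization.** Cuts induce left-closed, right-open intervals printed as
`[-Inf,0.921)` / `[0.921,Inf]`. Equal-width and equal-frequency cuts are
unsupervised; the supervised method greedily picks midpoints between
consecutive distinct values that maximize newly discerned pairs of objects
with different decisions, at most `c` cuts per attribute (O(n²) per candidate
— intended for the cohort-sized tables this package works with). An attribute
with one distinct value gets a single unbounded interval and a warning.

**Reducts.** The greedy heuristic grows the attribute set by positive-region
gain until the full-attribute positive region is reached (zero-gain ties are
broken by column order so the search always terminates) and then drops
single-attribute redundancies; because the positive region is monotone in the
attribute set, single-removal irredundancy implies no proper subset works, so
the result is a genuine (not necessarily globally shortest) reduct. The DAAR
heuristic scores candidates by how many not-yet-discerned different-decision
pairs they discern and accepts a candidate only if its gain beats the gain of
a random permutation of that candidate's values in at least (1 − α)·n_probes
of n_probes probes (defaults 100 probes, α = 0.05). Permuting the candidate —
rather than the decision — keeps the probe statistic on exactly the same pair
base as the true gain, which calibrates the test; the significance level is
additionally divided by the number of condition attributes (the dynamic
adjustment), keeping the chance of ever admitting a pure-noise attribute near
α for the whole search. When no candidate passes, the search stops, so DAAR
returns an *approximate* reduct on noisy tables by design; its backward
elimination preserves both the achieved positive region and the achieved
pair discernibility (on a noisy table the positive region alone can be empty,
which would make every attribute look redundant).

**Rule induction.** LEM2 covers each class's lower approximation with
minimal complexes (best pair = most of the current goal covered, ties to the
smaller attribute-value block); CN2 is a beam search (width 5, no significance
pruning) ranked by the entropy of a complex's *full-table* coverage — scoring
on full-table coverage rather than on the still-uncovered rows keeps emitted
rules globally pure when the data allow, which is what makes
specificity-first classification consistent on training data; AQ grows stars
(size 5) around seed examples against covered negatives. IND emits one rule
per indiscernibility block with the block-majority consequent (label ties go
to the alphabetically first class). Every rule stores its training support
and Laplace confidence with k = number of classes.

**Filtration and classification.** A model is rejected when it has fewer than
2 rules or mean Laplace confidence < 0.6; above 100 rules, the 100 largest
confidences are kept (ties by support, then original order). Classification
picks the most specific matching rule; ties break by Laplace confidence, then
support, then rule order — only specificity is substantive, the rest is a
documented deterministic chain. Unmatched objects get the training-majority
label; a test value outside every training interval is a no-match, never an
error.

## Experimental procedure

One run: subsample surplus zero-decile cases down to the rounded mean of the
counts of deciles 1..10, code the outcome with (d1, d2), split 85:15
stratified on the coded label (plain random when a class is too small to
stratify — stratification prevents degenerate folds at n ≈ 150), fit cuts on
the training part only, reduct, rules, filtration, score held-out cases.
Rejected models score 0, which makes filtration costly in the grid search, and
all-rejected grids produce a typed no-model result. Metrics are accuracy and
macro-averaged precision/recall/F1 over the fixed class set {A, B, C}
(absent classes contribute zero terms); they are computed from the raw
confusion counts so scikit-learn can serve as an independent oracle in tests.
Grid matrices report, per (d1, d2) cell, the best configuration's means.

## k-NN baseline

Features are the same decision tables with sex coded M=1/F=0; normalization
(one of none / maxabs / minmax to ⟨−1, 1⟩ / per-column standardization /
per-row unit length) is applied to the full table before cross-validation, as
a preprocessing step of the dataset. Neighbour search is scikit-learn's brute
k-NN under the Minkowski metric; 5×2 cross-validation (five independent
stratified 50:50 splits, each fold tested both ways) yields ten macro-F1
values summarized by min/mean/max/sd and a Gaussian 95% interval
mean ∓ 1.96·sd. The full factorial grid — 17 outcome ranges × 5
normalizations × 49 neighbour counts × 5 exponents — has 20825 cells; grid
runs rank by the largest F1 obtained. UMAP embeddings delegate to umap-learn
with a fixed random state.

## Cohort statistics

Kruskal–Wallis (tie-corrected, chi-square approximation) across the three
pattern groups; the pairwise comparison table uses two-sample Kruskal–Wallis,
which is the rank-sum test up to the approximation, matching the pairwise
layout convention. Sex-by-group association is a Pearson chi-square on the
2×3 table with 2 df. Boxplot summaries use interpolated quartiles and
1.5·IQR whiskers. P-values are uncorrected per variable by default (α = 0.05
convention); Holm correction is available behind a flag.

## Problem sizes used by the tests and the acceptance script

Recovery experiments run on 120-subject cohorts with 160-s recordings at
125 Sa/s (pipeline macro-F1), 20 + 20 pure-pattern signals of 120 s (IQR
contrast), 20 seeds of a 120-row noisy toy table (DAAR exclusion), 300
subjects without signals (cohort statistics), and one 20-min recording at
125 Sa/s (apnea recovery). These sizes were chosen so each experiment has
clearly sufficient power while the whole suite stays interactive.

## Limitations

- The generator reproduces morphology the pipeline consumes — triangular
  events, sinusoidal waxing–waning, flat apneas, label-shifted
  anthropometrics — and none of the physiology it does not: no airflow or
  tidal-volume modelling, no movement artifacts, no sleep staging, no
  realistic inter-breath variability. Passing recovery tests therefore
  demonstrates the pipeline's correctness and sensitivity under its own
  assumptions, not clinical performance.
- Published clinical accuracies cannot be reproduced without the private
  recordings; the package's accuracy figures describe synthetic cohorts only.
- LEM2/CN2/AQ follow the canonical formulations with fixed small beam/star
  sizes (5); no rule post-pruning beyond the confidence filtration.
- The supervised discretizer is quadratic in the number of objects.
- Fuzzy and dominance-based rough-set variants, variable-precision rough
  sets, wavelet-packet/CWT features and VAD-style apnea detection are out of
  scope.
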