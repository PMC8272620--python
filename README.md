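# respgran

Granular analysis of respiratory-belt breathing patterns: wavelet quartile
descriptors, rough-set rule models, a k-NN baseline, and cohort statistics —
exercised end to end on synthetic recordings.

## The problem

Chest-belt recordings of breathing show three broad regimes: **normal**
(similar breath amplitudes), **periodic-like** (cyclical waxing and waning of
amplitude, the daytime cousin of Cheyne–Stokes respiration, with or without
apneas), and **intermediate** mixtures where neither pure pattern reaches 70%
of the recording. Periodic breathing is a marker of poor cardiovascular
outcomes, but its assessment is usually a subjective visual call. This package
implements a transparent, rule-based pipeline that quantifies the *percentage
contribution* of each pattern in a recording, aimed at screening support
rather than black-box classification. Clinical recordings of this kind are
private, so the package ships a synthetic-cohort generator that reproduces the
signal morphology and cohort structure the method assumes, making every stage
testable offline.

## The method

1. **Granulation.** Each signal is standardized,
   `s[n] = (x[n] − mean(x)) / std(x)`, and decomposed with a multilevel
   discrete wavelet transform (default mother wavelet `rbio3.1`, chosen by the
   maximum-IQR spread criterion). The 7 finest components are dropped; from
   retained scales 5–7 (time spans ≈ 4–16 s, bracketing a breathing period)
   the quartiles Q1, Q2, Q3 and IQR = Q3 − Q1 summarize each scale. Together
   with age, sex, BMI and WHR this gives a 16-attribute decision table; the
   decision is a pattern's contribution decile (0–10).
2. **Outcome coding.** Deciles are mapped to three classes by cut pairs
   (d1, d2): A = [0, d1), B = [d1, d2), C = [d2, 10], with d1 ∈ 1..5,
   d2 − d1 ∈ 2..5, d2 < 9 (17 valid pairs).
3. **Rough-set modelling.** Attributes are discretized (equal width, equal
   frequency, or supervised global-discernibility cuts; 1–3 cuts), a reduct is
   computed (greedy positive-region heuristic, or a DAAR-style heuristic with
   a permutation-probe acceptance test), and IF–THEN rules are induced (LEM2,
   CN2, AQ, or one rule per indiscernibility class). Each rule carries its
   support and Laplace confidence `Lc = (n_correct + 1) / (n_matched + k)`.
   Models with fewer than 2 rules or mean Lc < 0.6 are rejected; at most 100
   rules are kept. At prediction time the most specific matching rule wins.
4. **Model search.** For each hyperparameter configuration: subsample surplus
   zero-decile cases, split 85:15, train, filter, score — repeated 10 times;
   grid search maximizes mean accuracy.
5. **Baselines and statistics.** A k-NN baseline (five normalization schemes ×
   k ∈ 2..50 × Minkowski p ∈ {1, 1.25, 1.5, 1.75, 2} × 17 outcome ranges =
   20825 configurations) evaluated with 5×2 cross-validation; UMAP 2-D
   embeddings for visualization; Kruskal–Wallis comparisons of anthropometrics
   across pattern groups and the chi-square sex association.

## Worked example

```python
from respgran.synthetic_cohort import generate_cohort
from respgran.wavelet_features import cohort_decision_table
from respgran.model_search import HyperParams, cross_validate

cohort = generate_cohort(120, (1/3, 1/3, 1/3), seed=0,
                         decile_profile="separated")
table = cohort_decision_table(cohort, "periodic-like")
hp = HyperParams(pattern="periodic-like", c=2, discretize="q",
                 reduct="g", rule="LEM2", d1=3, d2=6)
cv = cross_validate(table, hp, repeats=10, seed=0)
print(f"mean accuracy {cv.mean_accuracy:.3f}, mean macro-F1 {cv.mean_f1:.3f}, "
      f"median rules {cv.n_rules_median:.0f}")
```

prints

```
mean accuracy 0.935, mean macro-F1 0.931, median rules 9
```

i.e. on a well-separated synthetic cohort of 120 subjects the LEM2 model with
two equal-frequency cuts and outcome ranges (3, 6) recovers the held-out
periodic-like contribution class with ≈0.93 accuracy using a handful of rules
such as

```
IF Scale6_q1 is [-7.26221,-1.28311) AND Scale6_q3 is [0.534285,6.82169) THEN decision is B (21)
```

(the bracketed number is the rule's training support). Signals with strong
waxing–waning carry markedly wider coefficient distributions at scales 6–7,
which is exactly what these intervals pick up.

A command-line interface mirrors the library:

```bash
respgran simulate --n 30 --duration 120 --seed 1 --out cohort_dir
respgran featurize --cohort-dir cohort_dir --pattern normal --drop-finest 4 --out table.csv
respgran train --table table.csv --pattern normal --cuts 2 --discretize quantiles --rules LEM2
respgran stats --cohort cohort_dir/cohort.csv --out comparisons.csv
respgran knn --table table.csv --range 4,8 --norm standardize --k 28 --p 1
```

## Layout

- `src/respgran/synthetic_cohort.py` — signal and cohort generator, apnea
  detector, cohort file I/O
- `src/respgran/wavelet_features.py` — standardization, DWT scalograms,
  wavelet ranking, quartile descriptors, decision tables, outcome coding
- `src/respgran/rough_core.py` — partitions, approximations, discretization,
  reducts, rule induction, filtration, classification (from scratch)
- `src/respgran/model_search.py` — runs, 10-repeat cross-validation, grid
  search, metrics
- `src/respgran/knn_baseline.py` — normalizations, Minkowski k-NN, 5×2CV,
  UMAP export
- `src/respgran/cohort_stats.py` — Kruskal–Wallis, chi-square, boxplot
  summaries
- `docs/methods.md` — model assumptions, parameter choices, limitations
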