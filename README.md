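# distress-patterns

Machine-learning subtyping of **preoperative psychological distress** from
item-level questionnaire data, and its association with adverse
surgery-related outcomes.

Conventional screening dichotomises scale totals (PHQ-9 ≥ 10 or GAD-7 ≥ 10)
and flags only a small minority of surgical patients — too few, and too
coarsely, to predict objective outcomes such as postoperative
complications.  This package implements the item-level alternative: a
two-stage **UMAP → HDBSCAN** pipeline that first clusters the 16 PHQ-9 and
GAD-7 *items* into symptom clusters, reweights items so every symptom
cluster carries equal importance (weight = 1/cluster size), then embeds and
density-clusters *patients* into psychological distress patterns — keeping
a noise label for patients who fit no pattern, and merging clusters below a
minimum size into their nearest neighbour.  Discovered patterns (reference:
"normal psychological functioning") and cut-off status are then related to
short- and long-term outcomes with covariate-adjusted logistic models (odds
ratios, Wald 95% CIs) and linear models (β on a standardised 0–10 scale).

The cohort that motivated this analysis is not publicly available, so the
package ships a calibrated synthetic-cohort generator — a thresholded
latent-Gaussian (graded-response) model over four symptom blocks with six
latent classes, published mixing proportions, covariate marginals and
planted outcome effects — on which every stage is exercised and tested.
Intended users: biostatisticians and methods researchers reproducing or
extending density-based patient subtyping on ordinal questionnaire data.

## Worked example

```python
import distress_patterns as dp

cohort = dp.generate_cohort(dp.GeneratorConfig(n=2000, seed=7))
result = dp.run_discovery(cohort.items, dp.DiscoveryConfig(auto_scale=True))

print(f"symptom clusters: {result.symptom_clusters.n_clusters}")
print(f"patterns: {result.n_patterns}, noise: {100*result.noise_fraction:.2f}%")
for p in result.profiles:
    print(f"  [{p.pattern}] n={p.size:4d}  {p.name}")
```

prints

```
symptom clusters: 4
patterns: 6, noise: 1.30%
  [0] n= 551  phq1 + phq2 + phq6 + phq7 + phq8 + phq9 + gad1 + gad3 + gad4 + gad5 + gad6
  [1] n=  80  phq3 + phq4 + phq5 + gad4 + gad5 + gad6
  [2] n= 300  gad1 + gad2 + gad3 + gad7
  [3] n= 664  normal psychological functioning
  [4] n= 153  phq3 + phq4 + phq5 + gad1 + gad2 + gad3 + gad7
  [5] n= 226  phq3 + phq4 + phq5
```

The four symptom clusters are the planted item blocks
(somatic/vegetative, anxious, tension, depressive core); the six patterns
are named automatically by their elevated items — e.g. `[2]` is an
anxiety-only ("nervousness") group, `[5]` a sleep/eating group, `[0]` the
highly combined group, and 1.30% of patients fit no pattern (the planted
outlier fraction here is 2.2%; at this small n part of it is absorbed).

Association models against a month-6 outcome:

```python
forest = dp.run_association_suite(
    cohort.covariates, cohort.outcomes, result.assignment,
    result.pattern_names(), cohort.items)
sel = forest[(forest.outcome == "sleep_disturbance")
             & (forest.timepoint == "month6")
             & (forest.exposure_type == "patterns")]
```

```
gad1 + gad2 + gad3 + gad7                OR 1.74 (1.25-2.44) p=1.1e-03 n=1974
phq1 + phq2 + phq6 + phq7 + phq8 + phq9  OR 2.60 (1.98-3.42) p=9.6e-12 n=1974
phq3 + phq4 + phq5                       OR 2.22 (1.56-3.17) p=1.1e-05 n=1974
phq3 + phq4 + phq5 + gad1 + gad2 + gad3  OR 2.77 (1.87-4.12) p=4.1e-07 n=1974
phq3 + phq4 + phq5 + gad4 + gad5 + gad6  OR 2.37 (1.40-4.00) p=1.2e-03 n=1974
```

Each row is the adjusted odds ratio of month-6 sleep disturbance
(PSQI > 5) for one distress pattern versus the normal-functioning group;
the generator planted ORs of 2.2–3.0 on this outcome, and every interval
covers its planted value.  `n=1974` reflects the exclusion of the 26
noise-labelled patients from the analytic set.

There is also a command-line interface over the same stages:

```bash
distress-patterns simulate --n 10000 --seed 1 --out cohort/
distress-patterns discover --items cohort/items.csv --out run/
distress-patterns validate --fitted run/fitted_pipeline.pkl \
    --items validation_items.csv --out val/
distress-patterns full-run --n 10000 --seed 1 --out full/
```

Every command writes plain CSV/JSON plus a `manifest.json` of content
hashes; identical configurations reproduce byte-identical outputs.

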