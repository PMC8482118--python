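# sartkit

Trial-level analysis of the Sustained Attention to Response Task (SART)
for ageing research: per-cycle feature extraction, a cohort-level
"bad performance" threshold, an age-ordered multimodal visualization, and
a suite of logistic regression models testing whether poor single-cycle
SART performance at baseline predicts mobility decline, new falls and
cognitive decline four years later. A synthetic two-wave cohort generator
stands in for restricted epidemiological data, so the whole pipeline runs
and is tested end to end without any download.

Intended users: biostatisticians and cognitive-ageing researchers working
with continuous go/no-go data alongside longitudinal clinical outcomes
(gait speed, Timed Up-and-Go, falls, MMSE).

## The method

The SART shows the digits 1–9 in order, 23 times (207 presentations;
press for every digit, withhold on 3). For each 9-digit cycle *t* of
participant *i* the pipeline computes the mistake count
m<sub>it</sub> ∈ {0,…,9} (omissions + commissions), the error fraction
e<sub>it</sub> = m<sub>it</sub>/9, and the mean RT of correct presses.
Pooling all cycles with a computable mean RT across all participants,
a cycle is a **bad performance** when its error fraction exceeds

> cutoff = mean(e) + 2·sd(e),

i.e. when m<sub>it</sub> ≥ k where k is the smallest integer with
k/9 > cutoff. On default synthetic cohorts, as in the study cohort this
method is validated against, k = 4.

Three candidate predictors per participant — number of bad performances,
total mistakes, and mistakes in good performances — are compared in five
nested logistic models per binary outcome (TUG decline, UGS decline, new
faller, MMSE decline):

* model 1: predictor only
* model 2: + mean RT, SD RT
* model 3: + age, sex, education
* model 4: + anxiety, depression, antihypertensives, diabetes, smoking,
  drinking problem, physical activity (IPAQ)
* model 4a: + baseline usual gait speed

reporting OR = exp(β̂) with Wald 95% CIs and p-values, Spearman
collinearity screens, and CI-overlap comparisons between predictors.
See `docs/methods.md` for the full model description and the design
choices behind the synthetic generator.

## Worked example

```bash
sart simulate --n 1000 --seed 7 --out-dir demo/
sart extract --raw demo/sart_raw.csv --features-out demo/features.csv \
             --threshold-out demo/threshold.json
sart merge --cohort demo/cohort.csv --features demo/features.csv \
           --out demo/analysis.csv
sart analyze --table demo/analysis.csv --predictor bad_performances \
             --outcome tug_decline --out demo/results.json
```

prints

```
wrote 1000 streams to demo/sart_raw.csv and demo/cohort.csv
threshold: 4 mistakes/cycle (cutoff 0.3615); features for 1000 participants
merged analysis table: 799 participants -> demo/analysis.csv
tug_decline ~ bad_performances [model 1]: OR=1.380 (1.247; 1.527), p=4.733e-10, n=721
tug_decline ~ bad_performances [model 2]: OR=1.391 (1.255; 1.542), p=3.382e-10, n=721
tug_decline ~ bad_performances [model 3]: OR=1.403 (1.262; 1.559), p=3.527e-10, n=721
tug_decline ~ bad_performances [model 4]: OR=1.402 (1.256; 1.566), p=1.715e-09, n=721
tug_decline ~ bad_performances [model 4a]: OR=1.411 (1.263; 1.575), p=1.017e-09, n=716
```

Reading the output: the pooled mean + 2 SD rule lands at 4 mistakes per
cycle (cutoff 0.3615 in error-fraction units, i.e. 3.25 mistakes). Of the
1000 simulated participants, 799 attended both waves; 721 had a baseline
TUG under 12 s and complete data, the population at risk of TUG decline.
Each additional bad-performance cycle multiplies the odds of crossing the
12 s threshold four years later by ≈ 1.4 in this replicate, stable across
all adjustment levels — the behaviour the method is designed to exhibit
(the generator's true effect here is OR 1.287 plus positive age
confounding). `sart plot … --out fig.png` renders the spot-cloud
visualization; `sart report` formats fitted suites as comparison tables.

The library mirrors the CLI one-to-one (`sartkit.generate_cohort`,
`pooled_cycle_metrics`, `compute_threshold`, `features_table`,
`merge_waves`, `run_model_suite`, `compare_predictors`,
`build_plot_model`, …).

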