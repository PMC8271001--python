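# numgeo

Simulation and analysis pipeline for studies linking **numerosity
discrimination**, **non-symbolic geometric sequence prediction**, and
**formal (school-based) geometry** in primary-school children.

Developmental studies of this design collect three behavioural measures per
child — a 2AFC numerosity task analysed psychophysically, a
sequence-prediction task on an octagonal grid scored as first-attempt
accuracy, and a paper-and-pencil geometry battery normed into z-scores —
and then ask whether the two non-symbolic abilities predict formal geometry
once age and verbal reasoning are controlled.  `numgeo` implements that
entire analysis chain as a tested, reusable library, together with a
synthetic-cohort generator so every stage can be validated by parameter
recovery without access to any real data set.

## What it computes

**Psychometrics.**  Each child's 2AFC trials (probe numerosity 3–16 vs
test 9, method of constant stimuli, 3 × 42 = 126 trials) are fitted by
trial-level maximum likelihood with a cumulative Gaussian on the log axis,

&nbsp;&nbsp;&nbsp;&nbsp;P(report probe greater | x) = Φ((ln x − μ)/σ).

From the fit: PSE = e^μ; JND = e^μ(e^{z₇₅σ} − 1) with z₇₅ = Φ⁻¹(0.75)
(the numerosity difference between the 50% and 75% points); Weber fraction
WF = JND/9; normalized sensitivity = 1/WF.

**Reliability.**  Split-half "sample-with-replacement" bootstrap for
psychometric estimates (two independent full-size resamples per child per
iteration, estimates correlated across children, 10,000 iterations by
default), and Cronbach's α with Feldt confidence intervals for item-level
scores.

**Scoring.**  Sequence task: proportion of correct *first* attempts, per
run (3 scored predictions in run 1, 5 in run 2, eight sequences with fixed
complexity constants K).  Battery: factor-wise raw counts → grade-normed
z-scores → combined index (mean of the two z's).

**Inference.**  Zero-order and partial Pearson correlations (residual
regression, pairwise deletion), paired t-tests, and a priori sample-size
search for correlations with three power methods: the classic
normal-approximation planning formula, noncentral-t, and the fully exact
sample-correlation distribution.

**Simulation.**  A latent-trait cohort generator (configurable age slopes
and inter-trait correlation matrix) whose 2AFC noise is defined as
σ = ln(1 + 1/s)/z₇₅ so the analysis-side sensitivity estimator recovers the
generative sensitivity *s* exactly in expectation — the basis of all
parameter-recovery tests.

## Worked example

```bash
python examples/power_analysis.py
```

```
 normal-approx: n =  42  (achieved power 0.757)
           nct: n =  45  (achieved power 0.754)
       exact-r: n =  45  (achieved power 0.752)
```

The planning approximation says 42 children suffice to detect r = 0.34
with 75% power one-tailed; the exact methods show a true power of 0.75
actually needs 45 (see `docs/methods.md`).

```bash
python examples/full_pipeline.py
```

simulates a 49-child cohort (7 missing the battery) and prints the full
report, e.g.

```
         age  verbal_score  sensitivity  acc_run1  acc_run2  z_knowledge  z_visuospatial  combined_index
mean   9.450        13.382        4.506     0.656     0.738        0.135           0.237           0.186
sd     0.818         2.580        1.747     0.203     0.184        1.058           0.802           0.822
n     49.000        49.000       49.000    49.000    49.000       42.000          42.000          42.000

Run 1 vs run 2 accuracy, paired t-test:
  t(48) = 5.33, p = 0.0000
```

followed by the correlation grid (r, p and the pairwise-deletion n per
row, covariates listed for partials), the bootstrap reliability of the
sensitivity estimates (≈0.78 for this cohort) and the battery αs.  Other
examples: `simulate_cohort.py`, `fit_psychometric.py`,
`reliability_bootstrap.py`.

A thin CLI wraps the same pipeline:

```bash
numgeo simulate --seed 1 --out data/
numgeo analyze --data data/ --out results/
numgeo run --seed 1 --out results/
numgeo power --r 0.34 --power 0.75 --alpha 0.05 --tails 1
```

## Layout

```
src/numgeo/
  cohort.py         latent-trait cohort simulator + CSV writers
  psychometrics.py  2AFC cumulative-Gaussian MLE, JND/WF/sensitivity
  reliability.py    split-half bootstrap, Cronbach alpha (Feldt CI)
  scoring.py        sequence catalog, run scoring, battery z-scoring
  inference.py      correlations, paired t, power analysis
  pipeline.py       end-to-end orchestration, config, validation
  cli.py            thin click CLI
docs/methods.md     model and design notes
examples/           one narrative script per capability
```
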