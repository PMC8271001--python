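# Methods notes

This document records the generative model, the estimators, the numerical
choices and the open design decisions behind `numgeo`.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design being modelled

A cohort of ~49 children aged 8–10.9 years (grades 3–5) performs:

1. **Numerosity discrimination (2AFC, constant stimuli).**  Two dot
   patches; the test patch has 9 dots, the probe 3–16.  Three sessions of
   42 trials, every probe value presented equally often (9 times overall),
   order randomized per session.  Stimulus display parameters (0.2° dots,
   90% contrast, 40 cd/m² background, 7°×7° field at 7° eccentricity,
   500 ms presentation) are carried as protocol metadata only; nothing is
   rendered.
2. **Geometric sequence prediction.**  A character jumps over 8 positions
   of an octagonal grid following one of eight sequences, each with a
   fixed complexity constant: repeat (K5), repeat+2 (K7), 2arcs (K8),
   squares (K8), segments (K7), diagonals (K7), rectangles (K10), crosses
   (K7), presented in that fixed block order.  Run 1 cues five positions
   and scores the next 3 predictions; run 2 cues three and scores the
   remaining 5.  After an error the program restarts the sequence
   including the corrected position, so only first attempts are
   informative and only they are scored (24 run-1 and 40 run-2 responses
   per child).  The K values are imported constants — the
   minimal-description-length computation that defines them is outside the
   scope of this package.  The exact position walks of seven sequences are
   published only graphically; they are configurable placeholders here
   (only `repeat`, the clockwise +1 walk, is fixed by definition).
3. **Formal geometry battery.**  8 three-option "geometry knowledge" items
   and 24 three-option "visuo-spatial" items.  Factor-wise raw counts are
   z-scored against grade norms and combined.
4. **Verbal reasoning** enters only as a covariate (a WISC-style weighted
   score).

Roughly 7/49 children miss the battery; all analyses handle this by
pairwise deletion.

## Latent-trait generative model

Each child carries four latent traits: numerosity sensitivity `s_num`
(dimensionless, >0), geometry ability `g_geo`, formal-geometry ability
`f_formal` (both standardized), and verbal ability `v_verbal` (weighted
score scale).  With age drawn uniformly over the configured range,

    trait_i = mean_i + slope_i · (age − mid-age) + sd_i · ε_i,
    ε ~ N(0, C),

where `C` is the (symmetric, unit-diagonal, PSD-validated) residual
correlation matrix.  Marginal trait SDs therefore exceed `sd_i` when a
slope is non-zero; the moment tests account for this.  `s_num` is
truncated at 0.2 to keep the Weber model defined; with the default mean
4.19 and SD 1.39 the truncation is a >2.8σ event and negligible.

Defaults are the package's reference study conditions: n = 49, ages
8–10.9, sensitivity mean 4.19 / SD 1.39, verbal mean 12.9 / SD 3.11,
battery missingness 7/49.  (The conventional weighted-score scale is
mean 10, SD 3; the defaults follow the reference sample's observed
moments instead — both are configurable.)  Age slopes (0.43, 0.90, 1.14,
0 per year) were chosen once so that latent–age correlations fall near
0.25 / 0.6 / 0.7 / 0 — the qualitative pattern this design assumes — and
the residual correlation matrix encodes a plausible structure
(numerosity–formal 0.5, geometry–formal 0.4, numerosity–geometry 0.1,
verbal loading 0.3–0.35 on the symbolic measures).  These are generative
defaults, not estimates; every analysis stage works for any configured
values.

Grade is assigned from age with thresholds at 9.0 and 10.0 years
(configurable); the true grade–age composition of any real sample will
differ.

### 2AFC response model

P(report probe greater | probe x) = Φ(ln(x/9)/σ), with

    σ = ln(1 + 1/s_num) / z₇₅,   z₇₅ = Φ⁻¹(0.75) ≈ 0.6745.

This mapping is *defined* so that the analysis-side threshold chain
(JND = 50%→75% spacing, WF = JND/9, sensitivity = 1/WF) returns exactly
`s_num` when the fit is exact: at μ = ln 9,
JND = 9(e^{z₇₅σ} − 1) = 9/s_num.  The default observer has no lapse rate
(none is part of the modelled protocol); a symmetric lapse parameter is
available in both the generator and the fitter for sensitivity analyses.
A probe equal to the test (9 vs 9) is answered at chance even for a
noiseless observer.

### Sequence-task response model

First-attempt success probability at each scored location:

    p = g + (1 − g) · logistic(b₀ + a·g_geo + b·1[run 2] − c·(K − K_min)),

with guessing floor g = 1/8 (all eight grid positions selectable — the
protocol does not say the current position is excluded, so it is not),
ability slope a = 1, run-2 boost b = 0.42, complexity cost c = 0.25 per K
unit above K_min = 5, and baseline b₀ = 1.31.  The linear-in-K form is a
simplicity choice (only monotonicity is motivated).  The baseline and
boost were calibrated once against the reference group means (run-1
accuracy ≈ 0.68, run-2 ≈ 0.74) under the default cohort, before any test
was written, and then frozen.  Corrected re-attempts after the restart are
cued and are deliberately never emitted by the simulator, mirroring the
scoring rule.

### Battery response model

P(correct) = 1/3 + (2/3)·logistic(f_formal − d_item): the three-option
guessing floor plus a logistic item-response term.  Default difficulties
are evenly spaced over [−1.5, 1.5] per factor — synthetic fixtures, not
the published test's (proprietary) parameters.  Norm tables for z-scoring
are likewise synthetic: grade × factor means/SDs estimated from a large
simulated calibration cohort (default 900 children) under the same
generative settings.

### What the generator does **not** emulate

No reaction times, no item-content structure (battery items are
conditionally independent given ability), no sequence-specific strategies
or learning within the session beyond the run-2 boost, no
hysteresis/order effects, no age-varying Weber fractions within a child.
Passing recovery tests therefore demonstrates that the estimators are
consistent for this model family — not that real children satisfy it.

## Estimators

**Psychometric fit.**  Trial-level Bernoulli maximum likelihood over
(μ, σ) — the statistically standard choice when only "fitted with a
cumulative Gaussian" is specified; an aggregated least-squares mode exists
behind `FitOptions(method="lsq")` for sensitivity analysis.  The curve is
parameterized as the *increasing* probability of "probe greater" (the
complement of plotting "test greater"); JND magnitudes are identical and
the upward 50→75 spacing e^μ(e^{z₇₅σ} − 1) is used.  Numerics: L-BFGS-B
with analytic gradients, three σ starts (0.3, 0.1, 0.8), μ bounded to the
data's log-range ± 2, σ clamped to [0.01, 5.0] with `sigma_at_floor` /
`sigma_at_ceiling` flags; a ceiling σ flags the threshold unreliable, and
the sensitivity cap (10⁴) is flagged when hit.  All-identical responses
raise a degeneracy error (the location is unidentified); fewer than 10
trials or fewer than 2 distinct probes raise insufficient-data errors.  A
400×400 exhaustive grid search is provided as a brute-force cross-check
and the suite verifies optimizer/grid agreement within one lattice step.

**Split-half bootstrap.**  The phrase "two estimates from a random sample
as large as the data set, sampled with replacement" is read as: per
iteration and per child, two *independent full-size* with-replacement
resamples; the alternative disjoint-halves reading is available as
`mode="half"`.  Pearson correlation across children per iteration
(Spearman by option); `mean_r`/`se_r` are the mean and SD over
iterations.  Children are processed in sorted-id order, so the result is
independent of input ordering for a fixed seed.  Estimator failures on a
resample skip that child for that iteration with a logged count (or abort,
by option).  Identical estimate vectors short-circuit to r = 1 exactly, so
a noiseless estimator yields reliability 1.0 with zero floating-point
blur.

**Cronbach's α.**  k/(k−1)·(1 − Σ item variances / variance of totals)
with unbiased variances, listwise removal of incomplete rows (logged), and
the Feldt interval from (1−α̂)/(1−α) ~ F(n−1, (n−1)(k−1)) — a
conventional choice where the CI method is otherwise unspecified.

**Correlations.**  Partial correlations are *defined* as the Pearson
correlation of OLS residuals after regressing both variables on the
covariates (plus intercept), on cases complete for x, y and all covariates
(listwise within the request, pairwise across requests); p-values use
t with df = n − 2 − k, two-tailed.  The single-covariate recursion formula
serves as an independent oracle in the tests, never as the implementation.
No multiple-testing correction is applied (matching the modelled analysis
style); the report carries the number of tests so users can apply their
own.

**Paired t, Pearson r** wrap scipy's implementations with explicit
degenerate-input errors and pairwise deletion.

## Power analysis: the 42 vs 45 discrepancy

For the planning query (r = 0.34, power 0.75, α = 0.05, one-tailed) the
three methods disagree:

* the classic normal-approximation formula
  n = ((z₁₋α + z_power)·√(1−r²)/r)² = 41.15 → **42**;
* the noncentral-t method (T = r√(n−2)/√(1−r²), noncentrality of the same
  form) → **45**;
* exact integration of the sample-correlation density under bivariate
  normality → **45** (this routine reproduces the published exact value
  n = 138 for ρ = 0.3, two-tailed, power 0.95);
* Fisher-z would give 46.

The conventional planning value 42 is reproducible *only* by the normal
approximation, which is therefore the default method (this package's job
is to reproduce that planning convention); the exact methods are provided
and recommended for new designs, and the Monte-Carlo test in the suite
confirms the exact method's n brackets the target power.  The floor of the
search is n = 4 (the smallest size with positive degrees of freedom for
the test).

## Pipeline and reproducibility

One master seed drives everything.  Each stage (and each child within a
stage) derives its own `numpy` generator from
`SeedSequence([master, crc32(stage name), index])`, so adding a stage
never shifts existing streams and identical configs yield byte-identical
reports and CSVs.  Configs round-trip losslessly through JSON; the report
records a config hash.  Input tables are schema-validated on load with row
numbers and column names in every error (probe values outside [3, 16] are
rejected, runs must be 1 or 2); a missing battery file downgrades
gracefully to the no-battery analysis grid with a logged notice.

Problem sizes used by the verification suite are deliberately modest and
are the package's own choices: 200 observers per recovery condition (126
and 1260 trials), 200 bootstrap iterations when the estimator is a full
psychometric fit (10,000 remains the analysis default for cheap
estimators), n = 1000 children for latent-structure recovery against a
60,000-observer simulation oracle.

## Known limitations

* The normal-approximation power default intentionally reproduces a
  planning convention that undershoots the exact sample size; users
  planning new studies should pass `method="exact-r"`.
* Sequence position walks other than `repeat` are placeholders; analyses
  that depend on *which* grid positions are visited (none in this
  pipeline) would need the true walks.
* Norm tables and item difficulties are synthetic; combined-index values
  are comparable within a simulated cohort but not to any published test's
  normed scores.
* Grade-wise z-scoring against same-model calibration norms removes
  between-grade age variance from the combined index, so simulated
  age–battery correlations are attenuated relative to designs normed on
  external populations.
* The bootstrap reliability of psychometric estimates inherits any bias of
  the estimator on small resamples (126 trials); `se_r` reflects
  iteration-to-iteration spread, not sampling error across cohorts.
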