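# Methods

This note documents the models, statistical procedures and numerical
choices implemented in `pmdecode`, and what the synthetic data can and
cannot show about real recordings.

## Data model and time conventions

Firing rates are stored as trial × bin matrices (spikes/s) on a 40-ms grid
with bin 0 at sample onset; bins are half-open `[t, t + bin_ms)`.  The
delay starts 1,000 ms after sample onset in both tasks — in the perceptual
task the sample simply stays visible through this "perceptual delay".
Because the experimental delay varies 1,200–2,000 ms across trials, only
the sample period plus the first 1,200 ms of delay are stored (55 bins),
and the default analysis window is **240–1,200 ms after delay onset**
(24 bins), dropping the first 240 ms to avoid residual sensory transients.
Windows must align to the bin grid; misaligned windows are rejected, never
silently truncated.  All analyses except choice probability use correctly
performed trials only.

## Synthetic data generator

The generator is the package's definition of the study conditions, not a
tuning knob.  For neuron *i*, task τ, direction θ and bin *t* the expected
rate is

    λ = max(0, b + Δ·[τ = memory] + g_τ · cos(θ − φ_τ) · m(t, τ) + β·u),

with Poisson bin counts of mean λ·bin_ms/1000 stored as rates.

* **Cosine tuning** over the 4-direction grid is the minimal model that
  produces the feature-proximity structure (orthogonal directions
  intermediate between preferred and anti-preferred); four directions
  cannot constrain a richer tuning function.
* **Poisson counts** are the simplest physiologically standard noise
  model; overdispersion is not modelled by default.
* **Temporal dynamics** `m(t, τ)`: 1 for a stable code; for a dynamic code
  a per-neuron smooth positive modulation (low-pass-filtered Gaussian
  noise, mean 1, amplitude 0.9, correlation time 200 ms, clipped at 0),
  fixed across trials.  Different neurons are active at different delay
  epochs, so the population pattern drifts while within-window decoding
  stays high.
* **Behaviour**: a per-trial latent u ~ N(0, 1), shared between rates
  (coupling β, spikes/s per SD) and outcome
  (P(correct) = logistic(a₀ + a₁·u)), creates choice probability > 0.5
  when β > 0.
* **Topography**: neurons with tuning gain above 4 spikes/s draw their
  position from a cluster Gaussian when configured, otherwise uniformly
  over a 10 × 10 mm surface.

Defaults: 48 neurons, **40 recorded trials per condition** with
a₀ = 3.0 (≈93% correct), so that ≥30 *correct* trials per condition
survive for decoding with high probability; baseline 10 spikes/s; tuning
gain 8 spikes/s for strongly coding neurons.  These sizes were chosen once
for statistical power at desk scale; they emulate the decodable structure
of real prefrontal data, not its biophysics.  What passing tests show is
that the *pipeline* recovers known structure and is calibrated under the
null — not that real cortex satisfies cosine tuning, Poisson noise or a
one-dimensional behavioural latent.  The named fixtures (`null`,
`perceptual_only`, `mnemonic_only`, `shared_code`, `independent_codes`,
`dynamic_memory`, `clustered_topography`, `cp_positive`) fix one mechanism
each.  For the feature-proximity analyses, examples and tests use the
shared-code fixture at gain 1.5 spikes/s: that places 4-way decoding
accuracy in the 55–70% range where the decoder actually makes errors,
matching the intermediate-accuracy regime the analysis is about.

## Per-neuron statistics

*Discriminability* is the maximum over the six unordered direction pairs
of the rectified auROC (max(v, 1 − v) ∈ [0.5, 1]) between delay-mean rate
distributions; the preferred direction is the one with the highest mean
rate, ties broken toward the lowest angle for determinism.  Note the
max-over-pairs statistic is biased above 0.5 on pure noise — which is why
significance comes from a permutation test rather than the raw value: the
direction labels of all the task's trials are re-drawn (counts preserved)
500 times, and the neuron is significant when its real statistic reaches
or exceeds the surrogates' 99th percentile.  All permutation p-values use
the add-one estimator (1 + k)/(1 + n), so p is never 0.  An optional
Benjamini–Hochberg mode replaces the per-neuron percentile rule with FDR
control across neurons; it is off by default because with 500 surrogates
per-neuron p-values cannot resolve below 1/501.

The *PM-excess* test asks whether more neurons are significant in **both**
tasks than expected if the two significance flags were independent: both
flag vectors are shuffled independently **across the whole recorded
population** (10,000 surrogates of the doubly-flagged percentage).
Shuffling within the significant subset alone is degenerate — conditioned
on every member holding at least one flag, the observed overlap is the
minimum any rearrangement can produce — so the population-wide
randomization is the only version under which an excess is detectable.

*Choice probability* is the auROC between delay rates on correct vs error
trials whose sample moved in the neuron's (task-specific) preferred
direction, oriented so CP > 0.5 means higher rates on correct trials;
neurons with fewer than five correct or five error such trials are
excluded (absent, not an error).  The selectivity gate reuses the
permutation-test significance, and CP uses the same 240–1,200 ms delay
window as every other delay analysis.  Group tests are one-tailed Wilcoxon
signed-rank tests (per-task mean CP > 0.5; within-neuron memory − 
perceptual > 0).

## Population decoding

The pseudopopulation samples, per neuron and condition, 30 correct trials
and shuffles their within-condition order independently per neuron — this
destroys cross-neuron trial correlations by construction, so noise
correlations are explicitly out of scope.  Direction labels are first
rotated to the canonical {0°, 90°, 180°, 270°} frame (decoding is
invariant to this, which is tested).

The classifier is a Gaussian model with class-specific means and a single
pooled diagonal covariance (denominator N − C), uniform priors (training
sets are balanced by construction), prediction ties broken toward the
lowest class index, and a relative variance floor of 10⁻⁶ of the mean
pooled variance for degenerate features.  Preprocessing — per-feature
z-scoring plus one-way-ANOVA selection over the 8 condition levels at
α = 0.01 (the selection threshold is a package choice; it is configurable)
— is always fitted on the training rows of each fold.  The same gate,
fitted per training fold, is reused for the 4-class cross-task analysis.

Leave-one-out decoding is computed by an exact rank-one-downdate engine
that reproduces, fold for fold, what refitting preprocessing and
classifier on each 239-row training set yields; because the discriminant,
the ANOVA F statistic and the relative variance floor are all invariant to
per-feature affine maps, the fast path skips re-standardization without
changing any prediction (equivalence with the literal refit loop is
asserted in the tests, as is agreement with an independent
Gaussian-density oracle).

Uncertainty and chance: 100 neuron bootstraps (resampling neurons with
replacement; duplicated neurons re-draw their trials, so copies are not
redundant) give accuracy distributions; two accuracies are compared by
pooling their bootstrap values, reassigning them 1,000 times and ranking
the real mean difference (one-sided).  Chance levels re-run the full
pipeline — including fold-wise preprocessing — on label-shuffled trials.
Class-removal analyses compare each removed-class population against a
size-matched random downsample of the full population; sub-region analyses
downsample the outside population to the inside count.  Conditional
accuracies (direction given task-correct/-error) can be undefined when a
denominator is empty; they are reported as absent and skipped in
comparisons.  All percentages are on the 0–100 scale.

## Cross-temporal decoding and stability

For each pair of 40-ms training/testing windows, the 4-direction decoder
is trained on the training window's rates of each leave-one-out fold and
tested on the held-out trial's rates at the testing window; the
pseudotrial-to-source-trial mapping is fixed across windows.  A testing
window counts as *stable* for a training window when its accuracy (a) is
above chance and (b) is not significantly below the same-window accuracy
(bootstrap accuracy-difference test at α = 0.01 per comparison).  The
stability denominator is restricted to the analysed delay span
(240–1,200 ms after delay onset, 960 ms), and the millisecond equivalent
is the stable fraction times that span.

Two protocol reductions keep this tractable on one CPU: the
above-chance mask uses the percentile rule against map-level
label-shuffle surrogates (default 40 re-runs of the full map) rather than
a per-cell 1,000-surrogate rank, and the per-cell bootstrap count defaults
to 20 (both configurable).  The protocol shape — full-pipeline surrogates,
bootstrap difference tests — is preserved at reduced n.

## Error structure and topography

Decoding-error incidence is tabulated by circular offset
((decoded − true + 180) mod 360 − 180, folded so −180 ≡ 180) separately
per true-direction condition and then averaged, so the four offsets sum to
100%.  The 90-vs-180 comparison averages the +90 and −90 incidences within
each of 50 decoding repetitions (neuron bootstraps) and applies a paired
t-test across repetitions; a zero-variance difference is resolved by its
sign.  The label-swap control permutes direction labels between whole
conditions within each task per repetition — decodability is preserved,
the circular structure is not.

The per-neuron tuning profile re-indexes mean delay rates by offset from
the preferred direction and normalizes to the preferred rate (zero-rate
preferred neurons are excluded with a warning).  The preferred/anti
vs orthogonal contrast is summarized as the mean over neurons of
|r(pref) − r(anti)| / |r(+90) − r(−90)|; the denominator is a pure noise
difference for exact cosine tuning, so zero-denominator neurons are
excluded and the ratio should be read as order-of-magnitude only.

The topography test compares the observed mean pairwise distance among
neurons whose discriminability exceeds 0.75 with 1,000 surrogates in which
positions are shuffled among all of the subject's neurons; p is the
(add-one) fraction of surrogates *below* the observed mean, run per
subject, and is invariant to rigid motions of the coordinate frame.
Subjects with fewer than two qualifying neurons are skipped with a notice.

## Pipeline and determinism

`run_all` derives one seed per stage from the master seed via
`numpy.random.SeedSequence.spawn`, so stages are independently
reproducible and two runs with the same configuration produce
byte-identical reports (tested).  Every stochastic function accepts an
explicit seed or `numpy` generator.  Stage failures abort with the stage
name.  Report percentages, seeds and configuration are written to a
versioned JSON report plus per-neuron CSV tables.

## Known limitations

* Spike times, LFPs, eye position and overdispersed or correlated count
  noise are out of scope; rates on a fixed bin grid are the primitive.
* The pseudopopulation framework cannot address simultaneously recorded
  correlation structure.
* The generator's one-dimensional behavioural latent makes all
  choice-related variability perfectly shared across neurons; real CP
  structure is richer.
* Eligibility for decoding is a property of the shared trial table; with
  per-neuron trial lists (real multi-session data) the same ≥30-per-
  condition rule would instead drop individual neurons.
* With 500 surrogates the smallest attainable per-neuron p is 1/501, so
  family-wise corrections below that resolution are not meaningful.
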