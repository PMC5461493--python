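# pmdecode

Analysis pipeline for asking whether the *same* cortical neurons — and the
same population activity patterns — encode a visual feature while it is
being perceived and while it is held in working memory.

The experimental design it targets is a two-task delayed match-to-sample
paradigm with randomly interleaved trials: a moving random-dot sample
(1,000 ms, one of four directions 90° apart) is followed by a variable
delay (1,200–2,000 ms).  In the **memory** task the sample disappears and
its direction must be remembered; in the **perceptual** task it stays on
screen.  Neurons are recorded as trial × 40-ms-bin firing-rate matrices
with anatomical surface coordinates.  Because such recordings are not
always at hand, the package ships a synthetic-data generator that emulates
the full statistical structure of this design with known ground truth, so
every analysis stage is exercisable and testable offline.

## What it computes

**Per neuron.**  Direction *discriminability* in each task is the largest
rectified auROC between the delay-rate distributions of any pair of sample
directions,

```
auROC(a, b) = P(b > a) + ½·P(b = a)        (Mann–Whitney identity)
discriminability = max over the 6 direction pairs of max(v, 1 − v)
```

with significance from a 500-shuffle label-permutation test
(99th-percentile rule).  Neurons are classed **P** (perceptual-only),
**M** (mnemonic-only), **PM** (both) or **X** (neither); companion
statistics include the η² explained variance, the across-neuron Pearson
correlation of the two discriminabilities against a shuffle null, a
permutation test for an excess of PM neurons over independence, and choice
probability (auROC between correct- and error-trial delay rates at the
preferred direction).

**Population.**  Neurons recorded in different sessions are pooled into a
pseudopopulation (30 correct trials per condition, trial simultaneity
randomly assigned within condition).  A diagonal linear discriminant —
class means μ_c with one pooled diagonal covariance σ², score
−Σ_f (x_f − μ_{c,f})²/2σ²_f — decodes the 8 task × direction conditions
under leave-one-out cross-validation, with per-fold z-scoring and
8-level-ANOVA feature selection.  On top of this sit neuron bootstraps,
randomized-trial-label chance distributions, within/cross-task 2-fold
direction decoding, functional-class removal analyses, inside/outside
sub-region decoding, cross-temporal (train window × test window)
generalization maps with temporal-stability summaries, decoding-error
feature-proximity profiles with a label-swap control, and a
position-shuffle test for anatomical clustering of strong coders.

## Worked example

```bash
python examples/03_cross_temporal_stability.py
```

```
perceptual: same-window  74.1%  cross-window  74.4%  stable  97.6% ( 937 ms of 960 ms)
memory    : same-window  78.0%  cross-window  61.0%  stable  50.9% ( 488 ms of 960 ms)
```

The fixture behind this run has identical cosine tuning in both tasks, but
its memory-task code drifts smoothly over the delay.  Both codes decode
direction equally well *within* a 40-ms window (the diagonal), yet the
dynamic memory code generalizes poorly *across* windows: only half of the
analysed 960-ms delay counts as temporally stable, versus nearly all of it
for the stationary perceptual code.  The other example scripts
(`examples/01_…` to `05_…`) walk through neuron classification, task and
direction decoding with chance levels, choice probability, and the
feature-proximity and topography analyses, each printing the numbers it
computes and a line on how to read them.

A thin CLI mirrors the library for shell use:

```bash
pmdecode simulate --fixture shared_code --out data/ --seed 1
pmdecode discrim --data data/ --out discrim.csv
pmdecode run --seed 1 --out report/
```

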