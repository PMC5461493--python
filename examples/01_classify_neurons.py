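"""Classify single neurons as perceptual, mnemonic, both, or untuned.

Simulates a small population in which ~60% of neurons carry the same cosine
direction tuning in both tasks, then runs the per-neuron discriminability
pipeline: rectified max-pair auROC over delay rates, a 500-shuffle
permutation test per task, and the P/M/PM/X classification.
"""

from collections import Counter

from pmdecode import classify_neurons, discriminability_correlation, make_fixture, pm_excess_test

dataset, truth = make_fixture("shared_code", seed=1)
cls = classify_neurons(dataset, seed=0)

counts = Counter(c.neuron_class for c in cls)
n_tuned_true = sum(g.gain_mnemonic > 0 for g in truth)
print(f"neurons: {dataset.n_neurons}, truly tuned: {n_tuned_true}")
print("recovered classes:", dict(counts))

r, p = discriminability_correlation(cls, subset="all", rng=0)
print(f"perceptual-vs-mnemonic discriminability correlation r={r:.2f} (p={p:.3f})")

p_excess = pm_excess_test(cls, rng=0)
print(f"PM-excess permutation p={p_excess:.4f}")
print(
    "-> tuned neurons should land in PM (same code in both tasks), the"
    " correlation should be positive, and the PM share should exceed the"
    " independence expectation (small p)."
)
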