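"""Choice probability: does delay activity predict behavioural success?

Simulates neurons whose rates share a trial-latent fluctuation with the
behavioural outcome, then computes, for each direction-selective neuron,
the auROC between delay rates on correct vs. error preferred-direction
trials (CP), plus the population-level signed-rank tests.
"""

from pmdecode import classify_neurons, cp_group_tests, cp_table, make_fixture

dataset, _ = make_fixture("cp_positive", seed=4)
cls = classify_neurons(dataset, seed=0)
table = cp_table(dataset, cls)
stats = cp_group_tests(table)

print(f"neurons with CP (perceptual/memory): {stats['n_perceptual']}/{stats['n_memory']}")
print(
    f"mean CP perceptual = {stats['mean_cp_perceptual']:.3f} "
    f"(signed-rank p = {stats['p_perceptual']:.2e})"
)
print(
    f"mean CP memory     = {stats['mean_cp_memory']:.3f} "
    f"(signed-rank p = {stats['p_memory']:.2e})"
)
print(
    "-> CP > 0.5 means higher delay rates precede correct choices; the"
    " positive rate-behaviour coupling in the generator pushes both tasks"
    " above chance."
)
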