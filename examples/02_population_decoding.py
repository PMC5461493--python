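"""Decode task and direction from a pseudopopulation.

Builds a 240-pseudotrial population (30 trials x 8 conditions), decodes all
eight task x direction conditions with a diagonal linear discriminant under
leave-one-out cross-validation, and compares against a randomized-label
chance distribution.  Also runs the 2-fold within/cross-task direction
decoding that probes whether the perceptual and mnemonic codes generalize.
"""

import numpy as np

from pmdecode import (
    build_pseudopopulation,
    cross_task_decode,
    loo_decode,
    make_fixture,
    randomized_label_null,
    summarize,
)

# a code with task-specific preferred directions and rate offsets:
# directions are decodable within each task, and so is the task itself
dataset, _ = make_fixture("independent_codes", seed=3)
pp = build_pseudopopulation(dataset, rng=0)

res = summarize(loo_decode(pp))
print(f"task decoding accuracy:      {res.task_accuracy:.1f}%")
dir_ok = {k: round(float(v), 1) for k, v in res.dir_given_task_correct.items()}
print(f"direction | task correct:    {dir_ok}")

nulls = randomized_label_null(pp, n=50, rng=1)
null_task = np.mean([r.task_accuracy for r in nulls])
print(f"randomized-label task chance: {null_task:.1f}%")

acc = cross_task_decode(pp, rng=2)
for (train, test), a in acc.items():
    print(f"train {train:10s} -> test {test:10s}: {a:5.1f}%")
print(
    "-> with independent task codes, within-task direction decoding is high"
    " while cross-task transfer collapses toward the 25% chance level."
)
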