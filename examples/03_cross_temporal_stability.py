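"""Cross-temporal generalization: stable vs. dynamic delay codes.

Trains the direction decoder on each 40-ms delay window and tests it on
every other, for both tasks of a fixture whose memory-task code drifts over
time while its perceptual-task code is stationary.  The stability summary
is the share of delay test windows that are above chance and not
significantly below the same-window accuracy.
"""

import numpy as np

from pmdecode import Task, cross_temporal_decode, make_fixture, stability_stats

dataset, _ = make_fixture("dynamic_memory", seed=5)
delay_bins = np.arange(dataset.sample_ms // dataset.bin_ms, dataset.n_bins)

for task in (Task.PERCEPTUAL, Task.MEMORY):
    ct = cross_temporal_decode(
        dataset, task, rng=0, n_boot=6, n_null=15, windows=delay_bins
    )
    stab = stability_stats(ct, rng=1, n_perm=300)
    off_diag = ct.accuracy[~np.eye(ct.n_windows, dtype=bool)].mean()
    print(
        f"{task.value:10s}: same-window {np.diag(ct.accuracy).mean():5.1f}%  "
        f"cross-window {off_diag:5.1f}%  "
        f"stable {stab['delay_mean_percent_stable']:5.1f}% "
        f"({stab['delay_mean_ms_stable']:4.0f} ms of {stab['analysed_delay_span_ms']} ms)"
    )
print(
    "-> the dynamic memory code keeps a high same-window diagonal but"
    " generalizes poorly across windows, so its stable fraction is far"
    " below the stationary perceptual code's."
)
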