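"""Feature proximity of decoding errors, and anatomical clustering.

First: with cosine tuning, decoding errors should fall on directions 90
degrees from the truth more often than 180 degrees away — and a control
that swaps whole condition labels should abolish exactly that structure.
Second: a permutation test on pairwise distances asks whether neurons with
high discriminability cluster on the cortical surface.
"""

from pmdecode import Task, make_fixture, proximity_analysis, topography_cluster_test
from pmdecode.discriminability import classify_neurons

# intermediate-gain regime so the decoder actually makes errors
dataset, _ = make_fixture("shared_code", seed=2, gain=1.5)
real = proximity_analysis(dataset, rng=0, n_rep=12)
control = proximity_analysis(dataset, rng=0, n_rep=12, swap_labels=True)
for task in ("perceptual", "memory"):
    prof = {k: round(float(v), 1) for k, v in real[task]["mean_profile"].items()}
    print(f"{task}: incidence by offset {prof}  p(90>180)={real[task]['p_90_vs_180']:.1e}")
    print(f"{task}: after label swap       p(90>180)={control[task]['p_90_vs_180']:.2f}")

clustered, _ = make_fixture("clustered_topography", seed=8)
cls = classify_neurons(clustered, seed=0)
topo = topography_cluster_test(clustered, cls, Task.MEMORY, rng=0)
for subject, res in topo.items():
    print(
        f"subject {subject}: {res['n_high']} high-auROC neurons, "
        f"mean pairwise distance {res['observed_mean_distance_mm']:.2f} mm, p={res['p']:.3f}"
    )
print(
    "-> adjacent-direction (90 deg) errors dominate opposite-direction"
    " (180 deg) errors until the label swap destroys the circular"
    " structure; clustered strong coders give a small topography p."
)
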