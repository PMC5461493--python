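import numpy as np
import pytest

import pmdecode as pm
from pmdecode.data_model import Task
from pmdecode.structure_topography import (
    OFFSETS,
    error_incidence_profile,
    proximity_analysis,
    proximity_test,
    swap_direction_labels,
    topography_cluster_test,
    tuning_profile,
)


@pytest.fixture(scope="module")
def moderate_code():
    """Shared cosine code in the intermediate-accuracy regime (decoding errors exist)."""
    return pm.make_fixture("shared_code", seed=2, gain=1.5)


class TestErrorIncidence:
    def test_identity_confusion(self):
        prof = error_incidence_profile(np.eye(4) * 30)
        assert prof == {0: 100.0, 90: 0.0, -90: 0.0, 180: 0.0}

    def test_uniform_confusion(self):
        prof = error_incidence_profile(np.full((4, 4), 5))
        assert all(v == pytest.approx(25.0) for v in prof.values())

    def test_offsets_sum_to_100(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 30, size=(4, 4))
        prof = error_incidence_profile(counts)
        assert sum(prof.values()) == pytest.approx(100.0)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            error_incidence_profile(np.eye(8))


class TestProximityTest:
    def test_degenerate_constant_positive_difference(self):
        profiles = np.tile([60.0, 15.0, 15.0, 10.0], (5, 1))
        diff, p = proximity_test(profiles)
        assert diff == pytest.approx(5.0)
        assert p == 0.0

    def test_cosine_code_shows_proximity(self, moderate_code):
        ds, _ = moderate_code
        res = proximity_analysis(ds, rng=0, n_rep=12)
        for task in ("perceptual", "memory"):
            prof = res[task]["mean_profile"]
            near = 0.5 * (prof[90] + prof[-90])
            assert near > prof[180]
            assert res[task]["p_90_vs_180"] < 0.05

    def test_label_swap_abolishes_proximity(self, moderate_code):
        ds, _ = moderate_code
        res = proximity_analysis(ds, rng=0, n_rep=12, swap_labels=True)
        assert res["memory"]["p_90_vs_180"] > 0.05
        assert res["perceptual"]["p_90_vs_180"] > 0.05

    def test_swap_preserves_decodability(self, moderate_code):
        ds, _ = moderate_code
        plain = proximity_analysis(ds, rng=0, n_rep=6)
        swapped = proximity_analysis(ds, rng=0, n_rep=6, swap_labels=True)
        for task in ("perceptual", "memory"):
            a = plain[task]["mean_profile"][0]
            b = swapped[task]["mean_profile"][0]
            assert abs(a - b) < 8.0  # overall accuracy essentially unchanged


class TestSwapLabels:
    def test_swap_is_condition_permutation(self):
        rng = np.random.default_rng(0)
        dir_idx = np.repeat(np.arange(4), 30)
        task_idx = np.zeros_like(dir_idx)
        swapped = swap_direction_labels(dir_idx, task_idx, rng)
        assert np.array_equal(np.bincount(swapped), np.bincount(dir_idx))
        # whole conditions move together
        for d in range(4):
            assert len(np.unique(swapped[dir_idx == d])) == 1

    def test_identity_permutation_no_change(self):
        class FixedRng:
            def permutation(self, n):
                return np.arange(n)

        dir_idx = np.repeat(np.arange(4), 10)
        swapped = swap_direction_labels(dir_idx, np.zeros_like(dir_idx), FixedRng())
        assert np.array_equal(swapped, dir_idx)


class TestTuningProfile:
    def test_cosine_closed_form(self, shared_code, shared_code_classifications):
        ds, gt = shared_code
        res = tuning_profile(ds, shared_code_classifications, Task.MEMORY)
        norm = res["mean_normalized"]
        b, g = 10.0, 8.0
        assert norm[0] == pytest.approx(1.0)
        assert norm[90] == pytest.approx(b / (b + g), abs=0.06)
        assert norm[-90] == pytest.approx(b / (b + g), abs=0.06)
        assert norm[180] == pytest.approx((b - g) / (b + g), abs=0.06)
        # orthogonal rates are intermediate: 90-vs-180 paired test significant
        assert res["p_90_vs_180"] < 0.01

    def test_ratio_well_above_one_for_tuned(self, shared_code, shared_code_classifications):
        ds, _ = shared_code
        res = tuning_profile(ds, shared_code_classifications, Task.MEMORY)
        assert res["mean_ratio_pref_anti_vs_orthogonal"] > 2.0


class TestTopography:
    def _metric_cls(self, values):
        from pmdecode.discriminability import NeuronClassification

        return [
            NeuronClassification(
                neuron_id=f"n{i}",
                auroc_perceptual=v,
                auroc_mnemonic=v,
                pref_perceptual=0,
                pref_mnemonic=0,
                p_perceptual=1,
                p_mnemonic=1,
                sig_perceptual=False,
                sig_mnemonic=False,
                eta2_perceptual=0,
                eta2_mnemonic=0,
            )
            for i, v in enumerate(values)
        ]

    def test_clustered_fixture_significant(self):
        ds, gt = pm.make_fixture("clustered_topography", seed=8)
        metric = [1.0 if max(g.gain_perceptual, g.gain_mnemonic) > 4 else 0.55 for g in gt]
        res = topography_cluster_test(ds, self._metric_cls(metric), Task.MEMORY, rng=0)
        assert res["subject0"]["p"] < 0.05

    def test_rigid_motion_invariance(self):
        ds, gt = pm.make_fixture("clustered_topography", seed=8)
        metric = [1.0 if max(g.gain_perceptual, g.gain_mnemonic) > 4 else 0.55 for g in gt]
        cls = self._metric_cls(metric)
        p1 = topography_cluster_test(ds, cls, Task.MEMORY, rng=0)["subject0"]["p"]
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pm.Dataset(
            neurons=[
                pm.NeuronRecording(
                    neuron_id=n.neuron_id,
                    rates=n.rates,
                    position_mm=R @ n.position_mm + np.array([5.0, -2.0]),
                    subject_id=n.subject_id,
                )
                for n in ds.neurons
            ],
            trials=ds.trials,
            direction_set=ds.direction_set,
            sample_ms=ds.sample_ms,
        )
        p2 = topography_cluster_test(moved, cls, Task.MEMORY, rng=0)["subject0"]["p"]
        assert p1 == pytest.approx(p2)

    def test_two_coincident_high_neurons_extreme_p(self):
        ds, _ = pm.make_fixture("null", seed=1, n_neurons=20, n_trials_per_condition=3)
        for i, n in enumerate(ds.neurons):
            n.position_mm = np.array([0.0, 0.0]) if i < 2 else np.array([float(i), float(i)])
        metric = [1.0, 1.0] + [0.5] * 18
        res = topography_cluster_test(ds, self._metric_cls(metric), Task.MEMORY, n_shuffles=500, rng=0)
        assert res["subject0"]["p"] < 0.02

    def test_fewer_than_two_high_neurons_skipped(self, shared_code):
        ds, _ = shared_code
        metric = [0.5] * ds.n_neurons
        res = topography_cluster_test(ds, self._metric_cls(metric), Task.MEMORY, rng=0)
        assert res["subject0"]["skipped"]
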