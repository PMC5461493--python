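import numpy as np
import pytest

import pmdecode as pm
from pmdecode.data_model import Task
from pmdecode.population_decoding import (
    ConfusionMatrix,
    _two_fold_split,
    accuracy_difference_test,
    build_pseudopopulation,
    cross_task_decode,
    loo_decode,
    randomized_label_null,
    region_subset_decode,
    rotate_direction_labels,
    summarize,
)


class TestRotation:
    def test_offset_session_mapped_to_canonical(self):
        ds, _ = pm.make_fixture("null", seed=1, n_neurons=2, n_trials_per_condition=3)
        from dataclasses import replace

        shifted = pm.Dataset(
            neurons=ds.neurons,
            trials=[replace(t, direction=(t.direction + 30.0) % 360.0) for t in ds.trials],
            direction_set=(30.0, 120.0, 210.0, 300.0),
            sample_ms=ds.sample_ms,
        )
        rotated = rotate_direction_labels(shifted)
        assert rotated.direction_set == (0.0, 90.0, 180.0, 270.0)
        for orig, rot in zip(shifted.trials, rotated.trials):
            assert rot.direction == (orig.direction - 30.0) % 360.0

    def test_canonical_set_unchanged(self, shared_code):
        ds, _ = shared_code
        assert rotate_direction_labels(ds) is ds

    def test_decoding_invariant_under_rotation(self):
        ds, _ = pm.make_fixture("shared_code", seed=6, n_neurons=16)
        from dataclasses import replace

        shifted = pm.Dataset(
            neurons=ds.neurons,
            trials=[replace(t, direction=(t.direction + 60.0) % 360.0) for t in ds.trials],
            direction_set=(60.0, 150.0, 240.0, 330.0),
            sample_ms=ds.sample_ms,
        )
        conf_a = loo_decode(build_pseudopopulation(ds, rng=3))
        conf_b = loo_decode(build_pseudopopulation(rotate_direction_labels(shifted), rng=3))
        np.testing.assert_array_equal(conf_a.counts, conf_b.counts)


class TestPseudopopulation:
    def test_240_rows_30_per_condition(self, shared_code):
        ds, _ = shared_code
        pp = build_pseudopopulation(ds, rng=0)
        assert pp.n_pseudotrials == 240
        assert np.all(np.bincount(pp.condition) == 30)

    def test_insufficient_condition_trials_rejected(self, tiny_dataset_factory):
        # 29 usable trials in one condition -> ineligible
        tasks, dirs = [], []
        for task in ("perceptual", "memory"):
            for d in (0.0, 90.0, 180.0, 270.0):
                n = 29 if (task == "memory" and d == 0.0) else 30
                tasks += [task] * n
                dirs += [d] * n
        rng = np.random.default_rng(0)
        ds = tiny_dataset_factory([rng.poisson(5, size=(len(tasks), 55))], tasks, dirs)
        with pytest.raises(ValueError, match="29 usable"):
            build_pseudopopulation(ds, rng=0)

    def test_same_seed_reproducible(self, shared_code):
        ds, _ = shared_code
        a = build_pseudopopulation(ds, rng=5)
        b = build_pseudopopulation(ds, rng=5)
        np.testing.assert_array_equal(a.source_trial_idx, b.source_trial_idx)

    def test_columns_shuffle_trials_independently(self, shared_code):
        ds, _ = shared_code
        pp = build_pseudopopulation(ds, rng=0)
        assert not np.array_equal(pp.source_trial_idx[:, 0], pp.source_trial_idx[:, 1])


class TestSummarize:
    def test_identity_confusion(self):
        conf = ConfusionMatrix(np.eye(8, dtype=int) * 30, 8)
        res = summarize(conf)
        assert res.task_accuracy == 100.0
        assert res.dir_given_task_correct == {"perceptual": 100.0, "memory": 100.0}
        assert res.dir_given_task_error == {"perceptual": None, "memory": None}

    def test_uniform_confusion(self):
        conf = ConfusionMatrix(np.full((8, 8), 5, dtype=int), 8)
        res = summarize(conf)
        assert res.task_accuracy == 50.0
        assert res.dir_given_task_correct == {"perceptual": 25.0, "memory": 25.0}
        assert res.dir_given_task_error == {"perceptual": 25.0, "memory": 25.0}

    def test_hand_built_counts(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 0] = 20   # correct
        counts[0, 1] = 5    # same task, wrong direction
        counts[0, 4] = 5    # other task, same direction
        for i in range(1, 8):
            counts[i, i] = 30
        res = summarize(ConfusionMatrix(counts, 8))
        assert res.task_accuracy == pytest.approx(100 * 235 / 240)
        assert res.dir_given_task_correct["perceptual"] == pytest.approx(100 * 110 / 115)
        assert res.dir_given_task_error["perceptual"] == pytest.approx(100.0)

    def test_rows_sum_to_tested_trials(self, shared_code):
        ds, _ = shared_code
        conf = loo_decode(build_pseudopopulation(ds, rng=1))
        assert np.all(conf.counts.sum(axis=1) == 30)

    def test_summarize_matches_direct_counting_random(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 20, size=(8, 8))
        res = summarize(ConfusionMatrix(counts, 8))
        task_of = np.arange(8) // 4
        direct = sum(
            counts[i, j] for i in range(8) for j in range(8) if task_of[i] == task_of[j]
        )
        assert res.task_accuracy == pytest.approx(100 * direct / counts.sum())


class TestAccuracyDifference:
    def test_disjoint_distributions_floor(self):
        p = accuracy_difference_test([90] * 10, [50] * 10, n_perm=1000, rng=0)
        assert p == pytest.approx(1 / 1001)

    def test_identical_sets_near_half(self):
        p = accuracy_difference_test([60.0] * 10, [60.0] * 10, n_perm=500, rng=0)
        assert 0.3 < p <= 1.0

    def test_same_distribution_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = [
            accuracy_difference_test(
                rng.normal(60, 5, 20), rng.normal(60, 5, 20), n_perm=200, rng=rng
            )
            for _ in range(40)
        ]
        assert 0.3 < np.mean(ps) < 0.7


class TestNullDecoding:
    def test_task_and_condition_nulls_centred(self, null_fixture):
        ds, _ = null_fixture
        pp = build_pseudopopulation(ds, rng=2)
        nulls = randomized_label_null(pp, n=30, rng=3)
        task = np.mean([r.task_accuracy for r in nulls])
        cond = np.mean([r.condition_accuracy for r in nulls])
        assert abs(task - 50.0) < 3.0
        assert abs(cond - 12.5) < 2.0

    def test_shuffled_labels_break_decoding(self, shared_code):
        ds, _ = shared_code
        pp = build_pseudopopulation(ds, rng=2)
        real = summarize(loo_decode(pp)).condition_accuracy
        nulls = randomized_label_null(pp, n=10, rng=3)
        assert real > max(r.condition_accuracy for r in nulls)


class TestCrossTask:
    def test_two_fold_split_sizes(self):
        rng = np.random.default_rng(0)
        dir_idx = np.repeat(np.arange(4), 30)
        f0, f1 = _two_fold_split(dir_idx, 30, rng)
        assert len(f0) == len(f1) == 60
        assert len(np.intersect1d(f0, f1)) == 0

    def test_shared_code_generalizes(self, shared_code):
        ds, _ = shared_code
        pp = build_pseudopopulation(ds, rng=4)
        acc = cross_task_decode(pp, rng=5)
        within = (acc[("perceptual", "perceptual")] + acc[("memory", "memory")]) / 2
        cross = (acc[("perceptual", "memory")] + acc[("memory", "perceptual")]) / 2
        assert within > 80.0
        assert abs(within - cross) <= 5.0

    def test_independent_codes_do_not_generalize(self):
        ds, _ = pm.make_fixture("independent_codes", seed=3)
        pp = build_pseudopopulation(ds, rng=4)
        acc = cross_task_decode(pp, rng=5)
        within = (acc[("perceptual", "perceptual")] + acc[("memory", "memory")]) / 2
        cross = (acc[("perceptual", "memory")] + acc[("memory", "perceptual")]) / 2
        assert within > 80.0
        assert abs(cross - 25.0) <= 15.0


class TestClassRemoval:
    def test_empty_class_removal_no_effect(self, shared_code, shared_code_classifications):
        ds, _ = shared_code
        res = pm.class_removal_analysis(
            ds, shared_code_classifications, rng=0, n_boot=4, n_perm=200
        )
        # the shared-code fixture has (almost) no perceptual-only neurons
        assert res["P"]["n_removed"] <= 3
        assert abs(res["P"]["delta_condition"]) < 10.0
        # removing the PM class destroys condition decoding
        assert res["PM"]["delta_condition"] > 20.0
        assert res["PM"]["p_condition"] < 0.05


class TestRegionSubset:
    def test_clustered_region_beats_outside(self):
        ds, _ = pm.make_fixture("clustered_topography", seed=8)
        region = lambda p: np.linalg.norm(p - np.array([3.0, 3.0])) < 1.0
        res = region_subset_decode(ds, region, rng=0, n_boot=4)
        inside = np.mean([r.condition_accuracy for r in res["inside_boot"]])
        outside = np.mean([r.condition_accuracy for r in res["outside_boot"]])
        # the larger outside population is downsampled to the inside count
        assert res["n_inside"] == res["n_outside"]
        assert inside > outside

    def test_empty_region_rejected(self, shared_code):
        ds, _ = shared_code
        with pytest.raises(ValueError, match="no neurons"):
            region_subset_decode(ds, lambda p: False, rng=0)
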