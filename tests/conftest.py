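"""Shared fixtures: small synthetic datasets generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from pmdecode import Task, make_fixture
from pmdecode.data_model import BinnedRates, Dataset, NeuronRecording, Outcome, Trial


@pytest.fixture(scope="session")
def shared_code():
    """Stable task-shared cosine code; strong gains."""
    return make_fixture("shared_code", seed=1)


@pytest.fixture(scope="session")
def null_fixture():
    """All gains zero: nothing but Poisson noise."""
    return make_fixture("null", seed=2)


@pytest.fixture(scope="session")
def cp_fixture():
    return make_fixture("cp_positive", seed=4)


@pytest.fixture(scope="session")
def shared_code_classifications(shared_code):
    from pmdecode import classify_neurons

    ds, _ = shared_code
    return classify_neurons(ds, seed=10)


def build_tiny_dataset(
    rates_per_neuron: list[np.ndarray],
    tasks: list[str],
    directions: list[float],
    outcomes: list[str] | None = None,
    bin_ms: int = 40,
    sample_ms: int = 1000,
    direction_set=(0.0, 90.0, 180.0, 270.0),
) -> Dataset:
    """Hand-construct a dataset from explicit rate matrices and labels."""
    n_trials = len(tasks)
    outcomes = outcomes or ["correct"] * n_trials
    trials = [
        Trial(
            trial_id=i,
            task=Task(tasks[i]),
            direction=directions[i],
            outcome=Outcome(outcomes[i]),
            delay_ms=1500,
        )
        for i in range(n_trials)
    ]
    neurons = [
        NeuronRecording(
            neuron_id=f"n{j:03d}",
            rates=BinnedRates(np.asarray(vals, dtype=float), bin_ms=bin_ms, t0_ms=0),
        )
        for j, vals in enumerate(rates_per_neuron)
    ]
    return Dataset(neurons=neurons, trials=trials, direction_set=direction_set, sample_ms=sample_ms)


@pytest.fixture
def tiny_dataset_factory():
    return build_tiny_dataset
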