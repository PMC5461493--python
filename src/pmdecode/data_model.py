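"""Core domain types and the on-disk dataset format.

The experiment this package analyses is a two-task delayed match-to-sample
design: on each trial a random-dot sample moves in one of four directions
(90 degrees apart).  In the *memory* task the sample disappears after
1,000 ms and the direction must be held in working memory across a variable
delay (1,200-2,000 ms); in the *perceptual* task the sample stays on screen
through an equivalent "perceptual delay".  Neurons are recorded one session
at a time and stored as trial x time-bin matrices of firing rate.

Time convention: bins are half-open ``[t, t + bin_ms)`` with bin 0 starting
at sample onset (``t0_ms = 0``).  The delay starts at ``sample_ms``
(1,000 ms) in both tasks.  Only the sample period plus the first 1,200 ms of
the delay are stored, because all analyses are restricted to that span, and
the default analysis window drops the first 240 ms of the delay to avoid
residual sensory transients.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Task",
    "Outcome",
    "ConditionLabel",
    "Trial",
    "BinnedRates",
    "NeuronRecording",
    "Dataset",
    "WindowReference",
    "AnalysisWindow",
    "DEFAULT_DELAY_WINDOW",
    "DatasetFormatError",
    "window_bin_slice",
    "delay_mean_rate",
    "window_mean_matrix",
    "group_trials",
    "read_dataset",
    "write_dataset",
]


class Task(str, enum.Enum):
    """The two randomly interleaved task contexts."""

    PERCEPTUAL = "perceptual"
    MEMORY = "memory"


TASKS: tuple[Task, Task] = (Task.PERCEPTUAL, Task.MEMORY)


class Outcome(str, enum.Enum):
    CORRECT = "correct"
    ERROR = "error"


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset violates the schema."""


@dataclass(frozen=True)
class ConditionLabel:
    """One of the eight experimental conditions (task x sample direction)."""

    task: Task
    direction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "direction", float(self.direction) % 360.0)


@dataclass(frozen=True)
class Trial:
    trial_id: int
    task: Task
    direction: float
    outcome: Outcome
    delay_ms: int
    session_id: str = "s0"
    subject_id: str = "subject0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "outcome", Outcome(self.outcome))
        object.__setattr__(self, "direction", float(self.direction) % 360.0)
        if not 1200 <= int(self.delay_ms) <= 2000:
            raise ValueError(
                f"trial {self.trial_id}: delay_ms={self.delay_ms} outside [1200, 2000]"
            )

    @property
    def label(self) -> ConditionLabel:
        return ConditionLabel(self.task, self.direction)


@dataclass
class BinnedRates:
    """Trial x time-bin matrix of firing rates (spikes/s)."""

    values: np.ndarray
    bin_ms: int = 40
    t0_ms: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BinnedRates.values must be 2-D (trials x bins)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("firing rates must be finite")
        if np.any(self.values < 0):
            raise ValueError("firing rates must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class NeuronRecording:
    neuron_id: str
    rates: BinnedRates
    position_mm: np.ndarray = field(default_factory=lambda: np.zeros(2))
    subject_id: str = "subject0"

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float).reshape(2)


def _validate_direction_set(direction_set: Sequence[float]) -> tuple[float, ...]:
    dirs = tuple(float(d) % 360.0 for d in direction_set)
    if len(dirs) != 4 or len(set(dirs)) != 4:
        raise ValueError(f"direction_set must hold 4 distinct angles, got {dirs}")
    base = dirs[0]
    for d in dirs:
        if (d - base) % 90.0 != 0.0:
            raise ValueError(
                f"directions must be mutually separated by multiples of 90 deg, got {dirs}"
            )
    return tuple(sorted(dirs))


@dataclass
class Dataset:
    """A recorded (or simulated) set of neurons sharing one trial list.

    Every neuron's rate matrix is indexed by the same ``trials`` sequence and
    all neurons share ``bin_ms``/``t0_ms``.  ``provenance`` carries free-form
    metadata such as the generator seed.
    """

    neurons: list[NeuronRecording]
    trials: list[Trial]
    direction_set: tuple[float, ...]
    sample_ms: int = 1000
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.direction_set = _validate_direction_set(self.direction_set)
        allowed = set(self.direction_set)
        for t in self.trials:
            if t.direction not in allowed:
                raise ValueError(
                    f"trial {t.trial_id}: direction {t.direction} not in "
                    f"direction_set {self.direction_set}"
                )
        n_trials = len(self.trials)
        if self.neurons:
            bin_ms = self.neurons[0].rates.bin_ms
            t0 = self.neurons[0].rates.t0_ms
            n_bins = self.neurons[0].rates.n_bins
            for nr in self.neurons:
                if nr.rates.n_trials != n_trials:
                    raise DatasetFormatError(
                        f"neuron {nr.neuron_id}: rates has {nr.rates.n_trials} rows "
                        f"but the dataset has {n_trials} trials"
                    )
                if nr.rates.bin_ms != bin_ms or nr.rates.t0_ms != t0:
                    raise ValueError(
                        f"neuron {nr.neuron_id}: bin_ms/t0_ms differ from the dataset's"
                    )
                if nr.rates.n_bins != n_bins:
                    raise ValueError(
                        f"neuron {nr.neuron_id}: {nr.rates.n_bins} bins, expected {n_bins}"
                    )

    # -- convenience views -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def bin_ms(self) -> int:
        if not self.neurons:
            raise ValueError("dataset has no neurons")
        return self.neurons[0].rates.bin_ms

    @property
    def t0_ms(self) -> int:
        if not self.neurons:
            raise ValueError("dataset has no neurons")
        return self.neurons[0].rates.t0_ms

    @property
    def n_bins(self) -> int:
        if not self.neurons:
            raise ValueError("dataset has no neurons")
        return self.neurons[0].rates.n_bins

    def neuron_index(self, neuron_id: str) -> int:
        for i, nr in enumerate(self.neurons):
            if nr.neuron_id == neuron_id:
                return i
        raise KeyError(f"no neuron with id {neuron_id!r}")

    def trial_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in self.trials],
                "task": [t.task.value for t in self.trials],
                "direction_deg": [t.direction for t in self.trials],
                "outcome": [t.outcome.value for t in self.trials],
                "delay_ms": [t.delay_ms for t in self.trials],
                "session_id": [t.session_id for t in self.trials],
                "subject_id": [t.subject_id for t in self.trials],
            }
        )

    def rate_stack(self) -> np.ndarray:
        """All rates as one (neurons, trials, bins) array."""
        return np.stack([nr.rates.values for nr in self.neurons], axis=0)


class WindowReference(str, enum.Enum):
    SAMPLE_ONSET = "sample_onset"
    DELAY_ONSET = "delay_onset"


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window ``[start_ms, end_ms)`` relative to an event."""

    start_ms: int
    end_ms: int
    reference: WindowReference = WindowReference.DELAY_ONSET

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", WindowReference(self.reference))
        if not self.start_ms < self.end_ms:
            raise ValueError(f"window start {self.start_ms} must precede end {self.end_ms}")


#: The analysis window used throughout: 240-1,200 ms after delay onset.
DEFAULT_DELAY_WINDOW = AnalysisWindow(240, 1200, WindowReference.DELAY_ONSET)


def window_bin_slice(
    window: AnalysisWindow, *, bin_ms: int, t0_ms: int, n_bins: int, sample_ms: int
) -> slice:
    """Map a window to a slice of bin indices; rejects misaligned windows."""
    offset = sample_ms if window.reference is WindowReference.DELAY_ONSET else 0
    abs_start = window.start_ms + offset
    abs_end = window.end_ms + offset
    for edge in (abs_start, abs_end):
        if (edge - t0_ms) % bin_ms != 0:
            raise ValueError(
                f"window edge {edge} ms is not aligned to the {bin_ms}-ms bin grid"
            )
    i0 = (abs_start - t0_ms) // bin_ms
    i1 = (abs_end - t0_ms) // bin_ms
    if i0 < 0 or i1 > n_bins:
        raise ValueError(
            f"window [{abs_start}, {abs_end}) ms extends beyond the {n_bins} stored bins"
        )
    return slice(i0, i1)


def delay_mean_rate(
    dataset: Dataset,
    neuron_id: str,
    trial_id: int,
    window: AnalysisWindow | None = None,
) -> float:
    """Mean rate of one neuron on one trial over the (default delay) window."""
    window = window or DEFAULT_DELAY_WINDOW
    nr = dataset.neurons[dataset.neuron_index(neuron_id)]
    trial_ids = [t.trial_id for t in dataset.trials]
    try:
        row = trial_ids.index(trial_id)
    except ValueError:
        raise KeyError(f"no trial with id {trial_id}") from None
    try:
        sl = window_bin_slice(
            window,
            bin_ms=nr.rates.bin_ms,
            t0_ms=nr.rates.t0_ms,
            n_bins=nr.rates.n_bins,
            sample_ms=dataset.sample_ms,
        )
    except ValueError as exc:
        raise ValueError(f"trial {trial_id}: {exc}") from None
    return float(nr.rates.values[row, sl].mean())


def window_mean_matrix(
    dataset: Dataset, window: AnalysisWindow | None = None
) -> np.ndarray:
    """(n_trials, n_neurons) matrix of per-trial window-mean rates."""
    window = window or DEFAULT_DELAY_WINDOW
    sl = window_bin_slice(
        window,
        bin_ms=dataset.bin_ms,
        t0_ms=dataset.t0_ms,
        n_bins=dataset.n_bins,
        sample_ms=dataset.sample_ms,
    )
    return np.stack(
        [nr.rates.values[:, sl].mean(axis=1) for nr in dataset.neurons], axis=1
    )


_GROUP_FIELDS = {
    "task": lambda t: t.task.value,
    "direction": lambda t: t.direction,
    "outcome": lambda t: t.outcome.value,
}


def group_trials(
    dataset: Dataset, by: Sequence[str] = ("task", "direction")
) -> dict[tuple, np.ndarray]:
    """Partition trial indices by any combination of task/direction/outcome.

    Keys are tuples of the grouped field values (in ``by`` order); indices
    within a group follow trial-list order, so the grouping is deterministic.
    """
    for key in by:
        if key not in _GROUP_FIELDS:
            raise ValueError(f"unknown grouping key {key!r}; use {sorted(_GROUP_FIELDS)}")
    groups: dict[tuple, list[int]] = {}
    for i, t in enumerate(dataset.trials):
        key = tuple(_GROUP_FIELDS[k](t) for k in by)
        groups.setdefault(key, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in sorted(groups.items(), key=lambda kv: repr(kv[0]))}


# -- on-disk format --------------------------------------------------------
#
#   dataset.json            direction_set, bin_ms, t0_ms, sample_ms, provenance
#   trials.csv              trial_id,task,direction_deg,outcome,delay_ms,session_id,subject_id
#   neurons.csv             neuron_id,x_mm,y_mm,subject_id
#   rates/<neuron_id>.csv   one row per trial (trials.csv order), one column per bin


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    (path / "rates").mkdir(parents=True, exist_ok=True)
    meta = {
        "direction_set": list(dataset.direction_set),
        "bin_ms": int(dataset.bin_ms),
        "t0_ms": int(dataset.t0_ms),
        "sample_ms": int(dataset.sample_ms),
        "provenance": dataset.provenance,
    }
    (path / "dataset.json").write_text(json.dumps(meta, indent=1))
    dataset.trial_frame().to_csv(path / "trials.csv", index=False)
    pd.DataFrame(
        {
            "neuron_id": [nr.neuron_id for nr in dataset.neurons],
            "x_mm": [nr.position_mm[0] for nr in dataset.neurons],
            "y_mm": [nr.position_mm[1] for nr in dataset.neurons],
            "subject_id": [nr.subject_id for nr in dataset.neurons],
        }
    ).to_csv(path / "neurons.csv", index=False)
    n_bins = dataset.n_bins if dataset.neurons else 0
    cols = [f"t{dataset.t0_ms + i * dataset.bin_ms}" for i in range(n_bins)] if dataset.neurons else []
    for nr in dataset.neurons:
        pd.DataFrame(nr.rates.values, columns=cols).to_csv(
            path / "rates" / f"{nr.neuron_id}.csv", index=False
        )


def read_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    for required in ("dataset.json", "trials.csv", "neurons.csv"):
        if not (path / required).exists():
            raise DatasetFormatError(f"missing {required} in {path}")
    meta = json.loads((path / "dataset.json").read_text())
    trials_df = pd.read_csv(path / "trials.csv")
    required_cols = {
        "trial_id", "task", "direction_deg", "outcome", "delay_ms", "session_id", "subject_id",
    }
    if not required_cols.issubset(trials_df.columns):
        raise DatasetFormatError(
            f"trials.csv missing columns {sorted(required_cols - set(trials_df.columns))}"
        )
    trials = []
    for rec in trials_df.itertuples(index=False):
        try:
            trials.append(
                Trial(
                    trial_id=int(rec.trial_id),
                    task=Task(rec.task),
                    direction=float(rec.direction_deg),
                    outcome=Outcome(rec.outcome),
                    delay_ms=int(rec.delay_ms),
                    session_id=str(rec.session_id),
                    subject_id=str(rec.subject_id),
                )
            )
        except ValueError as exc:
            raise DatasetFormatError(f"trials.csv: {exc}") from None
    neurons_df = pd.read_csv(path / "neurons.csv")
    neurons = []
    for rec in neurons_df.itertuples(index=False):
        rates_file = path / "rates" / f"{rec.neuron_id}.csv"
        if not rates_file.exists():
            raise DatasetFormatError(f"missing rates file for neuron {rec.neuron_id}")
        values = pd.read_csv(rates_file).to_numpy(dtype=float)
        if values.shape[0] != len(trials):
            raise DatasetFormatError(
                f"neuron {rec.neuron_id}: rates file has {values.shape[0]} rows "
                f"but trials.csv lists {len(trials)} trials"
            )
        neurons.append(
            NeuronRecording(
                neuron_id=str(rec.neuron_id),
                rates=BinnedRates(values, bin_ms=int(meta["bin_ms"]), t0_ms=int(meta["t0_ms"])),
                position_mm=np.array([rec.x_mm, rec.y_mm], dtype=float),
                subject_id=str(rec.subject_id),
            )
        )
    try:
        return Dataset(
            neurons=neurons,
            trials=trials,
            direction_set=tuple(meta["direction_set"]),
            sample_ms=int(meta["sample_ms"]),
            provenance=dict(meta.get("provenance", {})),
        )
    except ValueError as exc:
        raise DatasetFormatError(str(exc)) from None
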