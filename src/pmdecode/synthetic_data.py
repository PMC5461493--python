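"""Synthetic delayed match-to-sample datasets with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: two randomly interleaved tasks (perceptual / memory), four sample
directions 90 degrees apart, Poisson spike counts in 40-ms bins over a
1,000-ms sample period plus the first 1,200 ms of the delay, cosine
direction tuning with independently controllable perceptual and mnemonic
gains, optional task-dependent preferred directions and firing-rate
offsets, temporally dynamic delay codes, a trial-latent variable coupling
rates to behavioural outcome (choice probability), and spatial clustering
of strongly tuned neurons (topography).

The expected rate of neuron *i* on a trial of task *tau* with direction
*theta* at bin *t* is::

    lambda = max(0, b + D*[tau=memory] + g_tau * cos(theta - phi_tau) * m(t, tau) + beta * u)

where ``m`` is 1 for a stable code and a smooth positive per-neuron
temporal modulation (mean 1, correlation time ``dynamics_tau_ms``) for a
dynamic one, and ``u ~ N(0, 1)`` is a per-trial latent shared between rates
and the behavioural outcome (``P(correct) = logistic(a0 + a1*u)``).  Bin
counts are Poisson with mean ``lambda * bin_ms / 1000`` and stored as rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .data_model import (
    BinnedRates,
    Dataset,
    NeuronRecording,
    Outcome,
    Task,
    Trial,
)

__all__ = ["NeuronGenParams", "GenConfig", "generate_dataset", "make_fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class NeuronGenParams:
    """Ground-truth generative parameters of one synthetic neuron."""

    baseline: float
    gain_perceptual: float
    gain_mnemonic: float
    pref_perceptual: float
    pref_mnemonic: float
    rate_offset_memory: float = 0.0
    dynamics: str = "stable"  # "stable" | "dynamic" (memory-task code)
    choice_coupling: float = 0.0
    position_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("baseline", "gain_perceptual", "gain_mnemonic", "choice_coupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dynamics not in ("stable", "dynamic"):
            raise ValueError(f"dynamics must be 'stable' or 'dynamic', got {self.dynamics!r}")


@dataclass
class GenConfig:
    """Study-condition parameters for :func:`generate_dataset`.

    ``class_mix`` gives the proportions of perceptual-only, mnemonic-only,
    both-task and untuned neurons.  Tuned neurons receive ``gain`` spikes/s
    of cosine tuning on top of ``baseline``; preferred directions are drawn
    from the direction set, with the mnemonic preference tied to the
    perceptual one unless ``independent_prefs`` is set.
    """

    n_neurons: int = 48
    n_trials_per_condition: int = 40
    direction_set: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    bin_ms: int = 40
    sample_ms: int = 1000
    stored_delay_ms: int = 1200
    seed: int = 0
    class_mix: dict = field(
        default_factory=lambda: {"P": 0.25, "M": 0.25, "PM": 0.25, "X": 0.25}
    )
    baseline: float = 10.0
    gain: float = 8.0
    independent_prefs: bool = False
    rate_offset_memory_sd: float = 0.0
    dynamic_memory: bool = False
    dynamics_tau_ms: float = 200.0
    dynamics_amplitude: float = 0.9
    choice_coupling: float = 0.0
    behav_intercept: float = 3.0  # logistic intercept a0: ~93% correct trials overall
    behav_slope: float = 1.0
    cluster: Optional[dict] = None  # {"center_mm": (x, y), "sd_mm": s}
    strong_gain_threshold: float = 4.0
    arena_mm: float = 10.0
    subject_id: str = "subject0"
    session_id: str = "s0"

    def __post_init__(self) -> None:
        if self.n_neurons <= 0 or self.n_trials_per_condition <= 0:
            raise ValueError("n_neurons and n_trials_per_condition must be positive")
        if len(self.direction_set) != 4:
            raise ValueError("direction_set must hold 4 directions")
        total = sum(self.class_mix.get(k, 0.0) for k in ("P", "M", "PM", "X"))
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        if self.sample_ms % self.bin_ms or self.stored_delay_ms % self.bin_ms:
            raise ValueError("sample_ms and stored_delay_ms must be multiples of bin_ms")


def _assign_classes(cfg: GenConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic class counts (largest-remainder), order shuffled by rng."""
    keys = ("P", "M", "PM", "X")
    raw = np.array([cfg.class_mix.get(k, 0.0) * cfg.n_neurons for k in keys])
    counts = np.floor(raw).astype(int)
    remainder = cfg.n_neurons - counts.sum()
    order = np.argsort(-(raw - counts))
    for j in range(remainder):
        counts[order[j % 4]] += 1
    labels = [k for k, c in zip(keys, counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


def _draw_params(cfg: GenConfig, rng: np.random.Generator) -> list[NeuronGenParams]:
    classes = _assign_classes(cfg, rng)
    dirs = np.asarray(cfg.direction_set, dtype=float)
    params = []
    for cls in classes:
        g_p = cfg.gain if cls in ("P", "PM") else 0.0
        g_m = cfg.gain if cls in ("M", "PM") else 0.0
        phi_p = float(rng.choice(dirs))
        phi_m = float(rng.choice(dirs)) if cfg.independent_prefs else phi_p
        offset = (
            float(rng.normal(0.0, cfg.rate_offset_memory_sd))
            if cfg.rate_offset_memory_sd > 0
            else 0.0
        )
        strong = max(g_p, g_m) > cfg.strong_gain_threshold
        if cfg.cluster is not None and strong:
            center = np.asarray(cfg.cluster["center_mm"], dtype=float)
            pos = rng.normal(center, cfg.cluster["sd_mm"], size=2)
        else:
            pos = rng.uniform(0.0, cfg.arena_mm, size=2)
        params.append(
            NeuronGenParams(
                baseline=cfg.baseline,
                gain_perceptual=g_p,
                gain_mnemonic=g_m,
                pref_perceptual=phi_p,
                pref_mnemonic=phi_m,
                rate_offset_memory=offset,
                dynamics="dynamic" if (cfg.dynamic_memory and (g_m > 0)) else "stable",
                choice_coupling=cfg.choice_coupling,
                position_mm=(float(pos[0]), float(pos[1])),
            )
        )
    return params


def _temporal_modulation(
    cfg: GenConfig, n_bins: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth positive modulation, mean ~1, correlation time dynamics_tau_ms."""
    sigma_bins = max(cfg.dynamics_tau_ms / cfg.bin_ms, 1e-6)
    z = gaussian_filter1d(rng.standard_normal(n_bins), sigma_bins, mode="wrap")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return np.clip(1.0 + cfg.dynamics_amplitude * z, 0.0, None)


def generate_dataset(cfg: GenConfig) -> tuple[Dataset, list[NeuronGenParams]]:
    """Simulate a dataset under ``cfg``; returns it with per-neuron ground truth."""
    rng = np.random.default_rng(cfg.seed)
    params = _draw_params(cfg, rng)

    n_bins = (cfg.sample_ms + cfg.stored_delay_ms) // cfg.bin_ms
    n_trials = 8 * cfg.n_trials_per_condition

    # trial table: balanced conditions, randomly interleaved
    tasks, directions = [], []
    for task in (Task.PERCEPTUAL, Task.MEMORY):
        for d in cfg.direction_set:
            tasks += [task] * cfg.n_trials_per_condition
            directions += [float(d)] * cfg.n_trials_per_condition
    order = rng.permutation(n_trials)
    tasks = [tasks[i] for i in order]
    directions = [directions[i] for i in order]
    delay_ms = rng.integers(1200, 2001, size=n_trials)

    u = rng.standard_normal(n_trials)  # trial latent shared with behaviour
    p_correct = expit(cfg.behav_intercept + cfg.behav_slope * u)
    correct = rng.random(n_trials) < p_correct

    trials = [
        Trial(
            trial_id=i,
            task=tasks[i],
            direction=directions[i],
            outcome=Outcome.CORRECT if correct[i] else Outcome.ERROR,
            delay_ms=int(delay_ms[i]),
            session_id=cfg.session_id,
            subject_id=cfg.subject_id,
        )
        for i in range(n_trials)
    ]

    is_mem = np.array([t is Task.MEMORY for t in tasks])
    theta = np.deg2rad(np.asarray(directions))
    dt_s = cfg.bin_ms / 1000.0

    neurons = []
    for i, p in enumerate(params):
        gain = np.where(is_mem, p.gain_mnemonic, p.gain_perceptual)
        pref = np.deg2rad(np.where(is_mem, p.pref_mnemonic, p.pref_perceptual))
        tuning = gain * np.cos(theta - pref)  # (n_trials,)
        mod = np.ones((n_trials, n_bins))
        if p.dynamics == "dynamic":
            mod[is_mem] = _temporal_modulation(cfg, n_bins, rng)[None, :]
        lam = (
            p.baseline
            + p.rate_offset_memory * is_mem
            + p.choice_coupling * u
        )[:, None] + tuning[:, None] * mod
        lam = np.clip(lam, 0.0, None)
        counts = rng.poisson(lam * dt_s)
        neurons.append(
            NeuronRecording(
                neuron_id=f"n{i:03d}",
                rates=BinnedRates(counts / dt_s, bin_ms=cfg.bin_ms, t0_ms=0),
                position_mm=np.asarray(p.position_mm),
                subject_id=cfg.subject_id,
            )
        )

    dataset = Dataset(
        neurons=neurons,
        trials=trials,
        direction_set=tuple(cfg.direction_set),
        sample_ms=cfg.sample_ms,
        provenance={"generator": "pmdecode.synthetic_data", "seed": cfg.seed},
    )
    return dataset, params


# -- named fixtures --------------------------------------------------------

FIXTURE_NAMES = (
    "null",
    "perceptual_only",
    "mnemonic_only",
    "shared_code",
    "independent_codes",
    "dynamic_memory",
    "clustered_topography",
    "cp_positive",
)


def fixture_config(name: str, seed: int = 0, **overrides) -> GenConfig:
    """Configuration behind each named fixture (see :func:`make_fixture`)."""
    base = dict(n_neurons=48, n_trials_per_condition=40, seed=seed)
    if name == "null":
        cfg = GenConfig(**base, class_mix={"P": 0, "M": 0, "PM": 0, "X": 1})
    elif name == "perceptual_only":
        cfg = GenConfig(**base, class_mix={"P": 0.5, "M": 0, "PM": 0, "X": 0.5})
    elif name == "mnemonic_only":
        cfg = GenConfig(**base, class_mix={"P": 0, "M": 0.5, "PM": 0, "X": 0.5})
    elif name == "shared_code":
        # identical tuning in both tasks: a temporally stable, task-shared code
        cfg = GenConfig(**base, class_mix={"P": 0, "M": 0, "PM": 0.625, "X": 0.375})
    elif name == "independent_codes":
        cfg = GenConfig(
            **base,
            class_mix={"P": 0, "M": 0, "PM": 0.625, "X": 0.375},
            independent_prefs=True,
            rate_offset_memory_sd=3.0,
        )
    elif name == "dynamic_memory":
        cfg = GenConfig(
            **base,
            class_mix={"P": 0, "M": 0, "PM": 0.625, "X": 0.375},
            dynamic_memory=True,
        )
    elif name == "clustered_topography":
        cfg = GenConfig(
            **base,
            class_mix={"P": 0.2, "M": 0.2, "PM": 0.2, "X": 0.4},
            cluster={"center_mm": (3.0, 3.0), "sd_mm": 0.8},
        )
    elif name == "cp_positive":
        cfg = GenConfig(
            **base,
            class_mix={"P": 0, "M": 0, "PM": 0.625, "X": 0.375},
            choice_coupling=3.0,
            behav_intercept=0.85,  # ~70% correct: enough error trials for CP
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return replace(cfg, **overrides) if overrides else cfg


def make_fixture(name: str, seed: int = 0, **overrides) -> tuple[Dataset, list[NeuronGenParams]]:
    """Small named datasets with documented ground truth, used across tests."""
    return generate_dataset(fixture_config(name, seed=seed, **overrides))
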