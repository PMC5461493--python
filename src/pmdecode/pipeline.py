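"""End-to-end orchestration: simulate -> classify -> CP -> decode -> report.

``run_all`` executes every analysis stage on a dataset (loaded from disk or
simulated), with stage-local random streams derived from one master seed so
that two runs with the same configuration and seed produce byte-identical
reports.  Results are written as a versioned JSON report plus per-neuron
CSV tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .choice_probability import cp_group_tests, cp_table
from .cross_temporal import cross_temporal_decode, stability_stats
from .data_model import Dataset, Task, read_dataset, write_dataset
from .discriminability import (
    classification_frame,
    classify_neurons,
    compare_task_tuning,
    discriminability_correlation,
    pm_excess_test,
)
from .population_decoding import (
    build_pseudopopulation,
    bootstrap_neurons,
    class_removal_analysis,
    cross_task_decode,
    loo_decode,
    null_pvalue,
    randomized_label_null,
    rotate_direction_labels,
    summarize,
)
from .structure_topography import proximity_analysis, topography_cluster_test
from .synthetic_data import fixture_config, generate_dataset

log = logging.getLogger("pmdecode")

REPORT_VERSION = 1

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": None,                 # dataset directory; or use "simulate"
    "simulate": {"fixture": "shared_code"},
    "discrim": {"n_shuffles": 500, "percentile": 99.0},
    "cp": {},
    "decode": {"n_boot": 20, "n_null": 100, "n_per_condition": 30, "alpha": 0.01},
    "cross_temporal": {
        "enabled": True,
        "n_boot": 10,
        "n_null": 30,
        "delay_windows_only": True,
        "tasks": ["perceptual", "memory"],
    },
    "structure": {"n_rep": 20},
    "topography": {"threshold": 0.75, "n_shuffles": 1000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    log.info("stage %s: starting", name)
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
    return result


def _get_dataset(config: dict, rng_seed: int) -> Dataset:
    if config.get("data"):
        return read_dataset(config["data"])
    sim = dict(config.get("simulate") or {"fixture": "shared_code"})
    fixture = sim.pop("fixture", None)
    sim.setdefault("seed", rng_seed)
    if fixture:
        cfg = fixture_config(fixture, **sim)
    else:
        from .synthetic_data import GenConfig

        cfg = GenConfig(**sim)
    dataset, _ = generate_dataset(cfg)
    return dataset


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Run the full analysis pipeline; returns (and writes) the report."""
    config = _merge(DEFAULT_CONFIG, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = int(config["seed"])
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ["simulate", "discrim", "decode", "xtemporal", "structure", "topography"],
            np.random.SeedSequence(master).spawn(6),
        )
    }

    dataset = _stage("load_data", _get_dataset, config, seeds["simulate"])
    dataset = rotate_direction_labels(dataset)
    log.info("dataset: %d neurons, %d trials", dataset.n_neurons, dataset.n_trials)
    report: dict = {
        "report_version": REPORT_VERSION,
        "pmdecode_version": __version__,
        "seed": master,
        "stage_seeds": seeds,
        "config": config,
        "n_neurons": dataset.n_neurons,
        "n_trials": dataset.n_trials,
    }

    # -- per-neuron discriminability and classification --------------------
    dcfg = config["discrim"]
    cls = _stage(
        "discrim",
        classify_neurons,
        dataset,
        n_shuffles=int(dcfg["n_shuffles"]),
        percentile=float(dcfg["percentile"]),
        seed=seeds["discrim"],
    )
    frame = classification_frame(cls)
    frame.to_csv(out_dir / "discrim.csv", index=False)
    counts = frame["neuron_class"].value_counts().to_dict()
    rng_d = np.random.default_rng(seeds["discrim"] + 1)
    r_all, p_all = discriminability_correlation(cls, "all", rng=rng_d)
    corr = {"r_all": r_all, "p_all": p_all}
    if sum(1 for c in cls if c.neuron_class == "PM") >= 3:
        r_pm, p_pm = discriminability_correlation(cls, "PM", rng=rng_d)
        corr |= {"r_pm": r_pm, "p_pm": p_pm}
    report["discrim"] = {
        "class_counts": {k: int(counts.get(k, 0)) for k in ("P", "M", "PM", "X")},
        "pm_excess_p": (
            pm_excess_test(cls, rng=rng_d) if any(c.neuron_class != "X" for c in cls) else None
        ),
        "correlation": corr,
    }
    report["task_tuning"] = compare_task_tuning(cls, dataset).drop(columns=["neuron_id"]).mean(numeric_only=True).to_dict()

    # -- choice probability ------------------------------------------------
    cp = _stage("cp", cp_table, dataset, cls)
    cp.to_csv(out_dir / "cp.csv", index=False)
    report["choice_probability"] = cp_group_tests(cp)

    # -- population decoding ----------------------------------------------
    pcfg = config["decode"]
    rng_dec = np.random.default_rng(seeds["decode"])
    n_pc = int(pcfg["n_per_condition"])
    alpha = float(pcfg["alpha"])
    pp = build_pseudopopulation(dataset, n_pc, rng_dec)
    conf = _stage("decode_loo", loo_decode, pp, alpha=alpha)
    point = summarize(conf)
    boot, _ = _stage(
        "decode_bootstrap",
        bootstrap_neurons,
        dataset,
        int(pcfg["n_boot"]),
        rng_dec,
        n_pc,
        alpha,
    )
    nulls = _stage("decode_null", randomized_label_null, pp, int(pcfg["n_null"]), rng_dec, alpha=alpha)
    xt = _stage("decode_cross_task", cross_task_decode, pp, rng_dec, alpha=alpha)
    removal = _stage("decode_class_removal", class_removal_analysis, dataset, cls, rng_dec,
                     n_boot=max(2, int(pcfg["n_boot"]) // 2), n_per_condition=n_pc, alpha=alpha)
    null_task = [r.task_accuracy for r in nulls]
    report["decode"] = {
        "confusion_counts": conf.counts,
        "point": asdict(point),
        "bootstrap_task_accuracy": [r.task_accuracy for r in boot],
        "null_task_accuracy_mean": float(np.mean(null_task)),
        "p_task_vs_null": null_pvalue(point.task_accuracy, null_task),
        "cross_task_accuracy": {f"{a}->{b}": v for (a, b), v in xt.items()},
        "class_removal": removal,
    }

    # -- cross-temporal ----------------------------------------------------
    xcfg = config["cross_temporal"]
    if xcfg.get("enabled", True):
        rng_x = np.random.default_rng(seeds["xtemporal"])
        windows = None
        if xcfg.get("delay_windows_only"):
            first = dataset.sample_ms // dataset.bin_ms
            windows = np.arange(first, dataset.n_bins)
        xres = {}
        for task_name in xcfg["tasks"]:
            ct = _stage(
                f"xtemporal_{task_name}",
                cross_temporal_decode,
                dataset,
                Task(task_name),
                rng_x,
                n_per_condition=n_pc,
                alpha=alpha,
                n_boot=int(xcfg["n_boot"]),
                n_null=int(xcfg["n_null"]),
                windows=windows,
            )
            stab = stability_stats(ct, rng=rng_x)
            np.savetxt(out_dir / f"xtemporal_{task_name}.csv", ct.accuracy, delimiter=",",
                       header=",".join(str(int(w)) for w in ct.window_start_ms))
            xres[task_name] = {
                "diag_mean_accuracy": float(np.diag(ct.accuracy).mean()),
                "delay_mean_percent_stable": stab["delay_mean_percent_stable"],
                "delay_mean_ms_stable": stab["delay_mean_ms_stable"],
            }
        report["cross_temporal"] = xres

    # -- proximity structure ----------------------------------------------
    scfg = config["structure"]
    rng_s = np.random.default_rng(seeds["structure"])
    prox = _stage("structure", proximity_analysis, dataset, rng_s,
                  n_rep=int(scfg["n_rep"]), n_per_condition=n_pc, alpha=alpha)
    report["structure"] = {
        t: {"mean_profile": v["mean_profile"], "p_90_vs_180": v["p_90_vs_180"]}
        for t, v in prox.items()
    }

    # -- topography --------------------------------------------------------
    tcfg = config["topography"]
    rng_t = np.random.default_rng(seeds["topography"])
    topo = {}
    for task in (Task.PERCEPTUAL, Task.MEMORY):
        topo[task.value] = _stage(
            f"topography_{task.value}",
            topography_cluster_test,
            dataset,
            cls,
            task,
            threshold=float(tcfg["threshold"]),
            n_shuffles=int(tcfg["n_shuffles"]),
            rng=rng_t,
        )
    report["topography"] = topo

    report = _to_jsonable(report)
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
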