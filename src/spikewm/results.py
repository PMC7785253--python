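"""Results-directory layout: writing a run and re-evaluating stored verdicts.

A results directory holds:

* ``config.yaml`` — the exact configuration used;
* ``spikes.csv`` — one row per somatic spike (``t_ms``, ``unit_1based``);
* ``efficacy_trace.csv`` — mean synaptic efficacy over present synapses;
* ``trajectory.csv`` — per-bin wheel speeds and integrated pose;
* ``weights.h5`` — dense ``J``/``C`` snapshots per phase boundary, with the
  snapshot time, phase and configuration as attributes;
* ``metrics.json`` — phases, per-phase rates, connectivity statistics,
  verdict, seed and config hash.

Everything ``evaluate`` needs is in ``spikes.csv`` + ``metrics.json`` +
``config.yaml``, so a verdict can be recomputed offline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import RunConfig, load_config, save_config
from .embodiment import SpikeRecord
from .experiments import ExperimentResult, evaluate

__all__ = ["write_result", "reevaluate"]


def write_result(result: ExperimentResult, cfg: RunConfig, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    result.spikes.to_dataframe().to_csv(out / "spikes.csv", index=False)
    result.trace.to_csv(out / "efficacy_trace.csv", index=False)
    result.trajectory.to_csv(out / "trajectory.csv", index=False)

    with h5py.File(out / "weights.h5", "w") as h5:
        h5.attrs["config_hash"] = result.config_hash
        h5.attrs["seed"] = result.seed
        for snap in result.snapshots:
            grp = h5.create_group(f"phase_{snap.phase_index:03d}")
            grp.create_dataset("J", data=snap.J)
            grp.create_dataset("C", data=snap.C)
            grp.attrs["t_ms"] = snap.t_ms
            grp.attrs["config"] = snap.config

    metrics = {
        "experiment": result.name,
        "seed": result.seed,
        "config_hash": result.config_hash,
        "phases": [
            {"t0_ms": t0, "t1_ms": t1, "config": c.value, "intensity": i}
            for (t0, t1, c, i) in result.phases
        ],
        "rates": result.rates.to_dict(orient="records"),
        "connection_stats": [
            dict(dataclasses.asdict(s.stats), t_ms=s.t_ms) for s in result.snapshots
        ],
        "verdict": result.verdict,
        "details": result.details,
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    return out


def reevaluate(results_dir) -> dict:
    """Recompute the stored verdict from a results directory alone."""
    out = Path(results_dir)
    with open(out / "metrics.json") as fh:
        metrics = json.load(fh)
    cfg = load_config(out / "config.yaml")
    spikes = SpikeRecord.from_dataframe(pd.read_csv(out / "spikes.csv"))
    phases = [(p["t0_ms"], p["t1_ms"], p["config"], p["intensity"])
              for p in metrics["phases"]]
    name = metrics["experiment"]
    if name is None:
        raise ValueError("results directory was not produced by a named experiment")
    dp = replace(cfg.decoder, n_units=cfg.network.n)
    verdict, details = evaluate(name, spikes, phases, dp, cfg.window_frac)
    return {"experiment": name, "verdict": verdict, "details": details,
            "stored_verdict": metrics["verdict"]}
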