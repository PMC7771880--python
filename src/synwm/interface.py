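"""Run configuration, output formats and the artifact manifest.

A run resolves a preset (or an explicit config file) plus a model backend
into trajectory tables, burst tables and a manifest recording the package
version, the fully resolved parameters, the seed and checksums of every
artifact, so that two runs with identical configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import synwm
from synwm.neural_mass import ConfigurationError, MassState, StimulusSchedule
from synwm.protocols import (
    ExperimentSpec,
    ModelSpec,
    build_stimulus,
    burst_train,
    load_preset,
    parse_model_config,
    preset_names,
    quiescent_state,
    run_protocol,
)

__all__ = ["RunConfig", "run", "write_trajectory", "read_trajectory"]

BACKENDS = ("mass", "rate", "network-micro", "network-meso", "network-none")


@dataclass
class RunConfig:
    """Fully specified simulation run."""

    preset: str = "two_item"
    model: str = "mass"
    protocol: str | None = None
    I_B: float | None = None
    t_total: float | None = None
    rtol: float = 1e-8
    seed: int = 0
    N_per_pop: int = 20000  # network backends only
    outdir: str = "synwm_out"

    def validate(self) -> list[str]:
        problems = []
        if self.model not in BACKENDS:
            problems.append(f"model must be one of {BACKENDS}, got {self.model!r}")
        if self.preset not in preset_names():
            problems.append(
                f"unknown preset {self.preset!r}; known: {', '.join(preset_names())}"
            )
        if self.t_total is not None and self.t_total <= 0:
            problems.append("t_total must be positive")
        if self.rtol <= 0:
            problems.append("rtol must be positive")
        return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_trajectory(traj, path: Path) -> None:
    """Write a trajectory as a tabular time series (bit-exact round trip)."""
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path: Path) -> pd.DataFrame:
    # round_trip parsing: values come back bit-identical to what was written
    return pd.read_csv(path, float_precision="round_trip")


def run(config: RunConfig) -> dict:
    """Execute a configured run and write the artifact bundle.

    Returns the manifest dictionary.
    """
    problems = config.validate()
    if problems:
        raise ConfigurationError("; ".join(problems))

    model = load_preset(config.preset)
    stim = (
        build_stimulus(
            ExperimentSpec(preset=config.preset, protocol=config.protocol, I_B=config.I_B)
        )
        if config.protocol
        else (
            model.stimulus
            if config.I_B is None
            else StimulusSchedule(I_B=config.I_B, pulses=model.stimulus.pulses)
        )
    )
    t_total = config.t_total if config.t_total is not None else model.t_total

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    if config.model == "mass":
        init = quiescent_state(model, I_B=stim.background(0.0))
        traj = run_protocol(
            model, stim, (0.0, t_total), init, rtol=config.rtol, dt_out=0.5
        )
        path = outdir / "trajectory.csv"
        write_trajectory(traj, path)
        artifacts["trajectory"] = path
        base = init.r[model.arch.exc_idx[0]] * 1e3
        rows = []
        for k in model.arch.exc_idx:
            bt = burst_train(traj, int(k), base, threshold_factor=2.0, min_separation=20.0)
            rows += [
                {"population": int(k), "t_ms": float(t), "peak_hz": float(h)}
                for t, h in zip(bt.times, bt.heights)
            ]
        bpath = outdir / "bursts.csv"
        pd.DataFrame(rows, columns=["population", "t_ms", "peak_hz"]).to_csv(
            bpath, index=False
        )
        artifacts["bursts"] = bpath
    elif config.model == "rate":
        from synwm.rate_model import RateState, integrate_rate

        init_m = quiescent_state(model, I_B=stim.background(0.0))
        init = RateState(r=init_m.r, x=init_m.x, u=init_m.u)
        traj = integrate_rate(
            model.arch, model.pops, model.stp, stim, (0.0, t_total), init,
            rtol=config.rtol, dt_out=0.5,
        )
        df = pd.DataFrame({"t_ms": traj.t})
        for k in range(traj.r.shape[0]):
            df[f"r_{k}"] = traj.r[k] * 1e3
        for j, k in enumerate(traj.exc_idx):
            df[f"x_{k}"] = traj.x[j]
            df[f"u_{k}"] = traj.u[j]
        path = outdir / "trajectory.csv"
        df.to_csv(path, index=False)
        artifacts["trajectory"] = path
    else:
        from synwm.qif_network import simulate_network

        mode = config.model.removeprefix("network-")
        raster, traces = simulate_network(
            model.pops, model.arch, model.stp, stim, config.N_per_pop,
            (0.0, t_total), stp_mode=mode, seed=config.seed,
        )
        rpath = outdir / "raster.csv"
        pd.DataFrame(
            {
                "t_ms": raster.times,
                "neuron": raster.neurons,
                "population": raster.populations,
            }
        ).to_csv(rpath, index=False)
        artifacts["raster"] = rpath
        df = pd.DataFrame({"t_ms": traces.t})
        for k in range(traces.r.shape[0]):
            df[f"r_{k}"] = traces.r[k] * 1e3
            df[f"v_{k}"] = traces.v[k]
        for j, k in enumerate(traces.exc_idx):
            df[f"x_{k}"] = traces.x[j]
            df[f"u_{k}"] = traces.u[j]
        path = outdir / "trajectory.csv"
        df.to_csv(path, index=False)
        artifacts["trajectory"] = path

    manifest = {
        "package": "synwm",
        "version": synwm.__version__,
        "config": asdict(config),
        "resolved": {
            "preset": model.name,
            "n_populations": model.arch.n_total,
            "J": model.arch.J.tolist(),
            "populations": [asdict(p) for p in model.pops],
            "stp": asdict(model.stp),
            "I_B": stim.I_B if np.isscalar(stim.I_B) else list(stim.I_B),
            "pulses": [asdict(p) for p in stim.pulses],
            "t_total": t_total,
        },
        "seed": config.seed,
        "checksums": {k: _sha256(v) for k, v in artifacts.items()},
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
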