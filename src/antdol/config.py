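"""YAML configuration files for simulations, scenarios, grids, and the
synthetic-tracking generator.

A simulation config mirrors ``SimConfig``::

    tasks: 2
    delta: 0.6          # scalar or per-task list
    eta: 7.0
    tau: 0.2
    T: 10000
    composition:
      - {label: X, count: 8, mu: 10.0, sigma: 0.1, alpha: 2.0}
      - {label: Y, count: 8, mu: 20.0, sigma: 0.1, alpha: 2.0}

A scenario config holds the two types plus campaign-level fields
(name, n, delta, eta, tau, T, replicates, mixed_ratio).  A synthetic-tracking
config is a flat mapping of ``SynthConfig`` fields.  A phase-grid config gives
``alpha_x`` / ``mu_x`` either as explicit lists or as {start, stop, num}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from antdol.experiments import PhaseGrid, Scenario, get_scenario
from antdol.synthetic import SynthConfig
from antdol.threshold_model import SimConfig, TypeParams

__all__ = [
    "load_sim_config",
    "load_scenario",
    "load_phase_grid",
    "load_synth_config",
    "dump_sim_config",
]


def _read(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def _type_params(entry: dict) -> tuple[TypeParams, int]:
    entry = dict(entry)
    count = int(entry.pop("count", 0))
    label = entry.pop("label")
    tp = TypeParams(
        label=label,
        mu=entry.pop("mu"),
        sigma=entry.pop("sigma", 0.1),
        alpha=entry.pop("alpha", 2.0),
    )
    if entry:
        raise ValueError(f"unknown type fields: {sorted(entry)}")
    return tp, count


def load_sim_config(path, seed: int | None = None) -> SimConfig:
    """Read a simulation config; ``seed`` overrides any seed in the file."""
    data = _read(path)
    comp = tuple(_type_params(e) for e in data["composition"])
    return SimConfig(
        composition=comp,
        m=int(data.get("tasks", 2)),
        delta=data.get("delta", 0.6),
        eta=float(data.get("eta", 7.0)),
        tau=float(data.get("tau", 0.2)),
        T=int(data.get("T", 10_000)),
        seed=int(data["seed"]) if seed is None and "seed" in data else int(seed or 0),
        initial_stimulus=data.get("initial_stimulus", 0.0),
    )


def dump_sim_config(config: SimConfig, path) -> None:
    """Echo a SimConfig back to YAML (for provenance next to CSV outputs)."""
    data = {
        "tasks": config.m,
        "delta": np.asarray(config.delta_vector()).tolist(),
        "eta": config.eta,
        "tau": config.tau,
        "T": config.T,
        "seed": config.seed,
        "initial_stimulus": np.asarray(config.initial_stimulus_vector()).tolist(),
        "composition": [
            {
                "label": tp.label,
                "count": count,
                "mu": np.asarray(tp.vectors(config.m)[0]).tolist(),
                "sigma": np.asarray(tp.vectors(config.m)[1]).tolist(),
                "alpha": np.asarray(tp.vectors(config.m)[2]).tolist(),
            }
            for tp, count in config.composition
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_scenario(source) -> Scenario:
    """A named built-in scenario, or a scenario YAML file."""
    if isinstance(source, str) and not Path(source).exists():
        return get_scenario(source)
    data = _read(source)
    tx, _ = _type_params({**data["type_x"], "count": 0})
    ty, _ = _type_params({**data["type_y"], "count": 0})
    kwargs = {
        k: data[k]
        for k in ("n", "delta", "eta", "tau", "T", "replicates", "seed")
        if k in data
    }
    if "mixed_ratio" in data:
        kwargs["mixed_ratio"] = tuple(data["mixed_ratio"])
    return Scenario(name=data.get("name", Path(str(source)).stem), type_x=tx, type_y=ty, **kwargs)


def _axis(spec_value) -> tuple[float, ...]:
    if isinstance(spec_value, dict):
        return tuple(np.linspace(spec_value["start"], spec_value["stop"], int(spec_value["num"])))
    return tuple(float(v) for v in spec_value)


def load_phase_grid(path) -> PhaseGrid:
    data = _read(path)
    kwargs = {}
    if "alpha_x" in data:
        kwargs["alpha_x"] = _axis(data["alpha_x"])
    if "mu_x" in data:
        kwargs["mu_x"] = _axis(data["mu_x"])
    if "type_y" in data:
        kwargs["type_y"] = _type_params({**data["type_y"], "count": 0})[0]
    for k in ("sigma_x", "n", "delta", "eta", "tau", "T", "replicates", "seed"):
        if k in data:
            kwargs[k] = data[k]
    return PhaseGrid(**kwargs)


def load_synth_config(path, seed: int | None = None) -> SynthConfig:
    data = _read(path)
    if seed is not None:
        data["seed"] = int(seed)
    for k in ("nest_center", "p_out", "mixing_shift", "labels"):
        if k in data:
            data[k] = tuple(data[k])
    return SynthConfig(**data)
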