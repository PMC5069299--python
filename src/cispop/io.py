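"""HDF5 / CSV / JSON readers and writers.

One HDF5 container holds a synthetic session: dual-alignment PSTHs, single
trials, and the generating ground truth.  Layout (schema version 1):

::

    /psth/target_aligned   (unit, condition, time)   spikes/s
    /psth/move_aligned     (unit, condition, time)
    /psth/target_time, /psth/move_time               ms
    /trials/<id>/spike_units, /trials/<id>/spike_times
    /trials/table          condition, delay, go, move, rt per trial
    /ground_truth/components, /ground_truth/weights, /ground_truth/labels
    attrs: schema_version, dt_ms, seed, config_json

Flat tables (trial table, component summaries) are CSV; configurations are
JSON.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd

from .containers import PopulationResponse, SingleTrialDataset
from .synthgen import ComponentSet, GeneratorConfig

__all__ = [
    "SCHEMA_VERSION",
    "write_session",
    "read_session",
    "trial_table",
    "write_config",
    "read_config",
]

SCHEMA_VERSION = 1


def config_to_json(config: GeneratorConfig) -> str:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return json.dumps(d, indent=2)


def config_from_json(text: str) -> GeneratorConfig:
    d = json.loads(text)
    for k in ("target_epoch", "move_epoch", "delays"):
        if k in d:
            d[k] = tuple(d[k])
    if isinstance(d.get("trial_counts"), dict):
        d["trial_counts"] = {float(k): int(v) for k, v in d["trial_counts"].items()}
    return GeneratorConfig(**d)


def write_config(path, config: GeneratorConfig) -> None:
    with open(path, "w") as fh:
        fh.write(config_to_json(config))


def read_config(path) -> GeneratorConfig:
    with open(path) as fh:
        return config_from_json(fh.read())


def write_session(path, population: PopulationResponse,
                  trials: SingleTrialDataset | None = None,
                  config: GeneratorConfig | None = None) -> None:
    """Write a session container (see module docstring for the layout)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if config is not None:
            f.attrs["dt_ms"] = config.dt
            f.attrs["seed"] = config.seed
            f.attrs["config_json"] = config_to_json(config)
        g = f.create_group("psth")
        g.create_dataset("target_aligned", data=population.target_rates)
        g.create_dataset("move_aligned", data=population.move_rates)
        g.create_dataset("target_time", data=population.target_time)
        g.create_dataset("move_time", data=population.move_time)
        if population.target_sem is not None:
            g.create_dataset("target_sem", data=population.target_sem)
            g.create_dataset("move_sem", data=population.move_sem)
        gt = population.ground_truth
        if gt is not None and gt.get("components") is not None:
            comp: ComponentSet = gt["components"]
            gg = f.create_group("ground_truth")
            gg.create_dataset("components", data=comp.x)
            gg.create_dataset("component_time", data=comp.time)
            gg.create_dataset("component_segment", data=comp.segment)
            gg.create_dataset("weights", data=gt["weights"])
            gg.create_dataset(
                "labels",
                data=np.array(comp.labels, dtype=h5py.string_dtype()))
            gg.attrs["scale"] = gt["scale"]
            gg.attrs["baseline"] = gt["baseline"]
            if gt.get("condition_speed") is not None:
                gg.create_dataset("condition_speed", data=gt["condition_speed"])
        if trials is not None:
            tg = f.create_group("trials")
            for i in range(trials.n_trials):
                ti = tg.create_group(str(i))
                ti.create_dataset("spike_units", data=trials.spike_units[i])
                ti.create_dataset("spike_times", data=trials.spike_times[i])
            tg.create_dataset("condition", data=trials.condition)
            tg.create_dataset("delay", data=trials.delay)
            tg.create_dataset("go_time", data=trials.go_time)
            tg.create_dataset("move_time", data=trials.move_time)
            tg.create_dataset("rt", data=trials.rt)
            tg.attrs["n_units"] = trials.n_units
            tg.attrs["dt"] = trials.dt


def read_session(path):
    """Read a session container -> (population, trials | None, config | None).

    Raises a schema error on version mismatch or truncated layout rather
    than returning partial data.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported session schema version {version!r} "
                f"(expected {SCHEMA_VERSION})")
        if "psth" not in f or "target_aligned" not in f["psth"]:
            raise ValueError("truncated session file: missing /psth group")
        g = f["psth"]
        population = PopulationResponse(
            target_rates=g["target_aligned"][...],
            move_rates=g["move_aligned"][...],
            target_time=g["target_time"][...],
            move_time=g["move_time"][...],
            target_sem=g["target_sem"][...] if "target_sem" in g else None,
            move_sem=g["move_sem"][...] if "move_sem" in g else None,
        )
        config = None
        if "config_json" in f.attrs:
            config = config_from_json(f.attrs["config_json"])
        if "ground_truth" in f:
            gg = f["ground_truth"]
            comp = ComponentSet(
                x=gg["components"][...],
                time=gg["component_time"][...],
                segment=gg["component_segment"][...],
                labels=[s.decode() if isinstance(s, bytes) else str(s)
                        for s in gg["labels"][...]],
            )
            residual = None
            if config is not None:
                # rebuild the analytic models so trials remain reproducible
                from .synthgen import ResidualModel, make_components

                comp = make_components(config)
                if config.residual_frac > 0:
                    residual = ResidualModel(config, config.n_units, config.rng(4))
            population.ground_truth = {
                "components": comp,
                "weights": gg["weights"][...],
                "scale": float(gg.attrs["scale"]),
                "baseline": float(gg.attrs["baseline"]),
                "model": comp.model,
                "residual_model": residual,
                "config": config,
                "condition_speed": (gg["condition_speed"][...]
                                    if "condition_speed" in gg else None),
            }
        trials = None
        if "trials" in f:
            tg = f["trials"]
            n = tg["condition"].shape[0]
            trials = SingleTrialDataset(
                spike_units=[tg[str(i)]["spike_units"][...] for i in range(n)],
                spike_times=[tg[str(i)]["spike_times"][...] for i in range(n)],
                condition=tg["condition"][...],
                delay=tg["delay"][...],
                go_time=tg["go_time"][...],
                move_time=tg["move_time"][...],
                rt=tg["rt"][...],
                n_units=int(tg.attrs["n_units"]),
                dt=float(tg.attrs["dt"]),
            )
    return population, trials, config


def trial_table(trials: SingleTrialDataset) -> pd.DataFrame:
    """Flat CSV-ready table of trial events."""
    return pd.DataFrame({
        "trial_id": np.arange(trials.n_trials),
        "condition_id": trials.condition,
        "delay_ms": trials.delay,
        "go_time_ms": trials.go_time,
        "move_time_ms": trials.move_time,
        "rt_ms": trials.rt,
    })
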