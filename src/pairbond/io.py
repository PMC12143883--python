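"""HDF5/CSV/YAML serialization shared by the generators and the pipeline.

Schema
------
Photometry session (HDF5): dataset ``trace`` (fluorescence, a.u.) with
attrs ``fs``, ``t0_s``, ``animal_id``, ``condition``, ``stimulus_label``,
``stimulus_onset_s``, ``epoch_end_s``. The event log is a CSV with
columns ``behavior,start_s,end_s``.

Sweep set (HDF5): one group per sweep (``sweep000`` …) holding dataset
``samples`` with attrs ``fs``, ``units`` and whichever of
``holding_mV``/``step_pA``/``stim_time_s`` apply; root attrs carry
``cell_id``, ``group``, ``protocol``.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from pairbond.photometry import BoutEvent, ExposureEpoch, PhotometryTrace
from pairbond.synthetic import LIFParams, PhotometrySession, SimConfig, Sweep, SweepSet

__all__ = [
    "save_session",
    "load_session",
    "save_event_log",
    "load_event_log",
    "save_sweep_set",
    "load_sweep_set",
    "load_sim_config",
    "dump_sim_config",
]


def save_session(path: str | Path, session: PhotometrySession) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trace", data=session.trace.samples)
        d.attrs["fs"] = session.trace.fs
        d.attrs["t0_s"] = session.trace.t0_s
        f.attrs["animal_id"] = session.animal_id
        f.attrs["condition"] = session.condition
        f.attrs["stimulus_label"] = session.epoch.stimulus_label
        f.attrs["stimulus_onset_s"] = session.epoch.stimulus_onset_s
        f.attrs["epoch_end_s"] = session.epoch.epoch_end_s
    save_event_log(Path(path).with_suffix(".events.csv"), session.bouts)


def load_session(path: str | Path) -> PhotometrySession:
    with h5py.File(path, "r") as f:
        trace = PhotometryTrace(
            samples=f["trace"][...],
            fs=float(f["trace"].attrs["fs"]),
            t0_s=float(f["trace"].attrs["t0_s"]),
        )
        epoch = ExposureEpoch(
            stimulus_label=str(f.attrs["stimulus_label"]),
            stimulus_onset_s=float(f.attrs["stimulus_onset_s"]),
            epoch_end_s=float(f.attrs["epoch_end_s"]),
        )
        animal = str(f.attrs["animal_id"])
        condition = str(f.attrs["condition"])
    bouts = load_event_log(Path(path).with_suffix(".events.csv"))
    return PhotometrySession(
        animal_id=animal, condition=condition, trace=trace, epoch=epoch, bouts=bouts
    )


def save_event_log(path: str | Path, bouts: list[BoutEvent]) -> None:
    pd.DataFrame(
        {
            "behavior": [b.behavior_label for b in bouts],
            "start_s": [b.start_s for b in bouts],
            "end_s": [b.end_s for b in bouts],
        }
    ).to_csv(path, index=False)


def load_event_log(path: str | Path) -> list[BoutEvent]:
    df = pd.read_csv(path)
    return [
        BoutEvent(behavior_label=r.behavior, start_s=float(r.start_s), end_s=float(r.end_s))
        for r in df.itertuples()
    ]


def save_sweep_set(path: str | Path, sweep_set: SweepSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["cell_id"] = sweep_set.cell_id
        f.attrs["group"] = sweep_set.group
        f.attrs["protocol"] = sweep_set.protocol
        for i, sw in enumerate(sweep_set.sweeps):
            g = f.create_group(f"sweep{i:03d}")
            g.create_dataset("samples", data=sw.samples)
            g.attrs["fs"] = sw.fs
            g.attrs["units"] = sw.units
            for attr in ("holding_mV", "step_pA", "stim_time_s"):
                val = getattr(sw, attr)
                if val is not None:
                    g.attrs[attr] = val


def load_sweep_set(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        sweeps = []
        for name in sorted(k for k in f.keys() if k.startswith("sweep")):
            g = f[name]
            sweeps.append(
                Sweep(
                    samples=g["samples"][...],
                    fs=float(g.attrs["fs"]),
                    units=str(g.attrs["units"]),
                    holding_mV=float(g.attrs["holding_mV"]) if "holding_mV" in g.attrs else None,
                    step_pA=float(g.attrs["step_pA"]) if "step_pA" in g.attrs else None,
                    stim_time_s=float(g.attrs["stim_time_s"]) if "stim_time_s" in g.attrs else None,
                )
            )
        return SweepSet(
            cell_id=str(f.attrs["cell_id"]),
            group=str(f.attrs["group"]),
            protocol=str(f.attrs["protocol"]),
            sweeps=sweeps,
        )


def load_sim_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return sim_config_from_dict(raw)


def sim_config_from_dict(raw: dict) -> SimConfig:
    raw = dict(raw)
    if "lif_params" in raw and isinstance(raw["lif_params"], dict):
        raw["lif_params"] = LIFParams(**raw["lif_params"])
    if "group_effects" in raw and isinstance(raw["group_effects"], dict):
        raw["group_effects"] = {
            tuple(k.split("|")): float(v) for k, v in raw["group_effects"].items()
        }
    if "bout_duration_s" in raw:
        raw["bout_duration_s"] = tuple(raw["bout_duration_s"])
    if "step_currents_pA" in raw:
        raw["step_currents_pA"] = tuple(raw["step_currents_pA"])
    known = {f.name for f in fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**raw)


def dump_sim_config(config: SimConfig, path: str | Path) -> None:
    out: dict = {}
    for f in fields(SimConfig):
        val = getattr(config, f.name)
        if f.name == "lif_params":
            val = vars(val)
        elif f.name == "group_effects":
            val = {"|".join(k): v for k, v in val.items()}
        elif f.name == "transient_amp":
            val = dict(val)
        elif isinstance(val, tuple):
            val = list(val)
        out[f.name] = val
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
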