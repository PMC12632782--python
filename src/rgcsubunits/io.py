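"""Plain-text serialisation of stimuli, traces, curves and parameters."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import StimulusField
from .synapse import ModelTraces

__all__ = [
    "write_traces",
    "read_table",
    "write_table",
    "write_params",
    "read_params",
    "write_stimulus_1d",
    "read_stimulus_1d",
]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_traces(traces: ModelTraces, path) -> Path:
    """Two-hemifield model traces as a delimited-text table."""
    df = pd.DataFrame({
        "t": traces.t,
        "stim_l": traces.stim[0], "stim_r": traces.stim[1],
        "e_raw_l": traces.e_raw[0], "e_raw_r": traces.e_raw[1],
        "i_l": traces.i[0], "i_r": traces.i[1],
        "n_l": traces.n[0], "n_r": traces.n[1],
        "e_out_l": traces.e_out[0], "e_out_r": traces.e_out[1],
        "e_total": traces.e_total, "i_total": traces.i_total, "rate": traces.rate,
    })
    return write_table(df, path)


def write_params(obj, path) -> Path:
    """Dataclass or mapping to JSON (arrays become lists)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path


def read_params(path) -> dict:
    return json.loads(Path(path).read_text())


def write_stimulus_1d(stim: StimulusField, path) -> Path:
    """1-D stimulus as delimited text: first column x (um), then one column per frame."""
    if stim.dims != 1:
        raise ValueError("text serialisation is for 1-D stimuli")
    df = pd.DataFrame(stim.values, columns=[f"t{k}" for k in range(stim.n_time)])
    df.insert(0, "x_um", stim.x)
    path = write_table(df, path)
    meta = {"dx": stim.dx, "dt": stim.dt, "background": stim.background}
    write_params(meta, Path(path).with_suffix(".meta.json"))
    return path


def read_stimulus_1d(path) -> StimulusField:
    df = read_table(path)
    meta = read_params(Path(path).with_suffix(".meta.json"))
    values = df.drop(columns="x_um").to_numpy()
    return StimulusField(values, dx=meta["dx"], dt=meta["dt"], background=meta["background"])
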