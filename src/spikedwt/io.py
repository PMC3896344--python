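"""Readers and writers for the package's delimited-text formats.

Spike-time tables are delimited text (tab or comma) with one row per spike
and the header::

    neuron_id  trial_id  condition  response_type  morph_type
    stimulus_onset_s  stimulus_offset_s  spike_time_s

Spike times are absolute seconds; rows of one (neuron_id, trial_id) pair
form one trial and must be in strictly increasing time order.  Voltage
traces are either two-column delimited text (time_s, mv) or a flat 32/64
bit float array with a JSON sidecar giving sampling rate and stimulus
timing.  Result tables mirror the per-coefficient / per-bin comparison
tables and are written as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SpikeTrain
from .detection import VoltageTrace

SPIKE_COLUMNS = ["neuron_id", "trial_id", "condition", "response_type",
                 "morph_type", "stimulus_onset_s", "stimulus_offset_s",
                 "spike_time_s"]


def read_spike_table(path) -> list[SpikeTrain]:
    """Parse a spike-time table into one SpikeTrain per (neuron, trial).

    Raises a descriptive error (naming the trial and data line) on a
    missing column, non-monotone or duplicate spike times within a trial,
    or stimulus onset not preceding offset.
    """
    def _float_or_nan(s: str):
        # builtin float() is correctly rounded; the python engine's own
        # converter can be off by one ulp, breaking exact round trips
        return float(s) if s.strip() else np.nan

    df = pd.read_csv(path, sep=None, engine="python", dtype={
        "neuron_id": str, "trial_id": str, "condition": str,
        "response_type": str, "morph_type": str},
        converters={"spike_time_s": _float_or_nan,
                    "stimulus_onset_s": float, "stimulus_offset_s": float})
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df.fillna({"response_type": "", "morph_type": ""})
    df["_line"] = np.arange(2, len(df) + 2)  # 1-based, after header

    trains = []
    for (neuron, trial), grp in df.groupby(["neuron_id", "trial_id"], sort=True):
        # a single blank spike_time_s row records a spike-free trial
        keep = grp["spike_time_s"].notna()
        times = grp.loc[keep, "spike_time_s"].to_numpy(dtype=float)
        lines = grp.loc[keep, "_line"].to_numpy()
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            bad = lines[np.flatnonzero(diffs <= 0)[0] + 1]
            kind = "duplicate" if np.any(diffs == 0) else "non-monotone"
            raise ValueError(
                f"{path}: {kind} spike time in trial {trial!r} of neuron "
                f"{neuron!r} (line {bad})")
        for col in ("condition", "response_type", "morph_type",
                    "stimulus_onset_s", "stimulus_offset_s"):
            if grp[col].nunique() > 1:
                raise ValueError(
                    f"{path}: inconsistent {col} within trial {trial!r} of "
                    f"neuron {neuron!r}")
        row = grp.iloc[0]
        if not row["stimulus_onset_s"] < row["stimulus_offset_s"]:
            raise ValueError(
                f"{path}: stimulus onset >= offset in trial {trial!r} of "
                f"neuron {neuron!r} (line {row['_line']})")
        trains.append(SpikeTrain(
            spike_times=times, neuron_id=str(neuron), trial_id=str(trial),
            condition=row["condition"], response_type=row["response_type"],
            morph_type=row["morph_type"],
            stimulus_onset=float(row["stimulus_onset_s"]),
            stimulus_offset=float(row["stimulus_offset_s"])))
    return trains


def write_spike_table(trains: Sequence[SpikeTrain], path) -> None:
    """Write trains to the spike-time table format (TSV). Empty trains are
    preserved as a single row with an empty spike_time_s field."""
    rows = []
    for tr in trains:
        base = dict(neuron_id=tr.neuron_id, trial_id=tr.trial_id,
                    condition=tr.condition, response_type=tr.response_type,
                    morph_type=tr.morph_type,
                    stimulus_onset_s=tr.stimulus_onset,
                    stimulus_offset_s=tr.stimulus_offset)
        if tr.n_spikes:
            rows.extend({**base, "spike_time_s": repr(float(t))}
                        for t in tr.spike_times)
        else:
            rows.append({**base, "spike_time_s": ""})
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_trace_text(path, stimulus_onset: float, stimulus_offset: float) -> VoltageTrace:
    """Read a two-column (time_s, mv) delimited trace; the sampling rate is
    inferred from the (uniform) time column."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, mv)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return VoltageTrace(samples=v, sampling_rate=1.0 / dt[0], t0=t[0],
                        stimulus_onset=stimulus_onset,
                        stimulus_offset=stimulus_offset)


def read_trace_binary(path, sidecar_path=None) -> VoltageTrace:
    """Read a flat float array plus JSON sidecar.

    The sidecar (default: ``<path>.json``) must provide ``sampling_rate_hz``,
    ``stimulus_onset_s`` and ``stimulus_offset_s``; optional keys are
    ``t0_s`` (default 0) and ``dtype`` ("float32" or "float64", default
    "float64").
    """
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    dtype = meta.get("dtype", "float64")
    if dtype not in ("float32", "float64"):
        raise ValueError(f"{sidecar}: unsupported dtype {dtype!r}")
    samples = np.fromfile(path, dtype=dtype)
    return VoltageTrace(samples=samples.astype(float),
                        sampling_rate=float(meta["sampling_rate_hz"]),
                        t0=float(meta.get("t0_s", 0.0)),
                        stimulus_onset=float(meta["stimulus_onset_s"]),
                        stimulus_offset=float(meta["stimulus_offset_s"]))


def write_comparison_table(result, path, comparison: str = "") -> None:
    """Write a per-coefficient (or per-bin) comparison result as TSV,
    mirroring the columns of the published result tables."""
    table = result.table.copy()
    table.insert(0, "comparison", comparison or f"{result.label_a} vs {result.label_b}")
    table["crit_p"] = result.crit_p
    float_cols = table.select_dtypes(float).columns
    table[float_cols] = table[float_cols].round(9)
    table.to_csv(path, sep="\t", index=False)


def write_rate_function(rf, path, dense: bool = False) -> None:
    """Export a rate function (binned by default, dense on request) as TSV."""
    if dense:
        df = pd.DataFrame({"time_s": rf.dense_times, "rate_hz": rf.dense})
    else:
        w = rf.window
        starts = w.start + w.bin_width_s * np.arange(w.n_bins)
        df = pd.DataFrame({"bin": np.arange(1, w.n_bins + 1),
                           "t_start_s": starts, "rate_hz": rf.binned})
    df.to_csv(path, sep="\t", index=False)
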