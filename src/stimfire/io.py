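"""CSV schemas and validation for spikes, pulses, trajectories and metrics.

Schemas (all plain CSV, header row required):

* spikes:      ``neuron_id, time_s``   — one row per spike
* stimulus:    ``pulse_id, time_s``    — one row per pulse
* trajectory:  ``t_s, x_cm, y_cm``     — one row per video sample
* features:    ``neuron_id, ap_duration_ms, onset_to_trough_ms,
  waveform_class, spontaneous_rate_sps``
* metrics:     ``subject_id, group, <metric columns>``

Ground-truth sidecars for simulated datasets are JSON files next to the CSVs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import ArenaGeometry, Trajectory
from .core import SpikeTrain, StimulusTrain
from .errors import ValidationError

__all__ = [
    "read_spike_trains",
    "write_spike_trains",
    "read_stimulus",
    "write_stimulus",
    "read_trajectory",
    "write_trajectory",
    "write_ground_truth",
    "validate_inputs",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_spike_trains(path: str | Path, duration_s: float | None = None) -> list[SpikeTrain]:
    """Read every neuron from a spike CSV.

    When ``duration_s`` is omitted the recording length is taken as the
    latest spike time across all neurons (rounded up to a whole second), so
    all trains share one duration.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["neuron_id", "time_s"], path)
    if duration_s is None:
        duration_s = float(np.ceil(df["time_s"].max())) if len(df) else 1.0
    trains = []
    for neuron_id, sub in df.groupby("neuron_id", sort=False):
        trains.append(
            SpikeTrain(
                times=sub["time_s"].to_numpy(dtype=float),
                duration_s=duration_s,
                neuron_id=str(neuron_id),
            )
        )
    return trains


def write_spike_trains(trains: list[SpikeTrain], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"neuron_id": t.neuron_id, "time_s": t.times}) for t in trains
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_stimulus(
    path: str | Path,
    frequency_hz: float = 0.5,
    pulse_duration_ms: float = 0.5,
    intensity_ma: float = 1.0,
) -> StimulusTrain:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["pulse_id", "time_s"], path)
    return StimulusTrain(
        pulse_times_s=df["time_s"].to_numpy(dtype=float),
        frequency_hz=frequency_hz,
        pulse_duration_ms=pulse_duration_ms,
        intensity_ma=intensity_ma,
    )


def write_stimulus(stim: StimulusTrain, path: str | Path) -> None:
    pd.DataFrame(
        {"pulse_id": np.arange(stim.n_pulses), "time_s": stim.pulse_times_s}
    ).to_csv(path, index=False, float_format="%.6f")


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "x_cm", "y_cm"], path)
    return Trajectory(
        t_s=df["t_s"].to_numpy(dtype=float),
        x_cm=df["x_cm"].to_numpy(dtype=float),
        y_cm=df["y_cm"].to_numpy(dtype=float),
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format="%.4f")


def write_ground_truth(payload: dict, path: str | Path) -> None:
    """JSON sidecar with generative parameters and labels for a simulated set."""

    def _default(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")


# ---------------------------------------------------------------------------
# validation reports


def _violations_spikes(df: pd.DataFrame) -> list[dict]:
    out = []
    for neuron_id, sub in df.groupby("neuron_id", sort=False):
        times = sub["time_s"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(times) <= 0)
        for b in bad:
            out.append(
                {
                    "row": int(sub.index[b + 1]),
                    "column": "time_s",
                    "message": f"neuron {neuron_id!r}: non-increasing spike time",
                }
            )
        neg = np.flatnonzero(times < 0)
        for b in neg:
            out.append(
                {
                    "row": int(sub.index[b]),
                    "column": "time_s",
                    "message": f"neuron {neuron_id!r}: negative spike time",
                }
            )
    return out


def _violations_stimulus(df: pd.DataFrame) -> list[dict]:
    times = df["time_s"].to_numpy(dtype=float)
    return [
        {"row": int(df.index[b + 1]), "column": "time_s", "message": "unordered pulse time"}
        for b in np.flatnonzero(np.diff(times) <= 0)
    ]


def _violations_trajectory(df: pd.DataFrame, arena: ArenaGeometry | None) -> list[dict]:
    out = []
    t = df["t_s"].to_numpy(dtype=float)
    for b in np.flatnonzero(np.diff(t) <= 0):
        out.append({"row": int(df.index[b + 1]), "column": "t_s", "message": "non-increasing sample time"})
    if arena is not None:
        inside = arena.contains(df["x_cm"].to_numpy(float), df["y_cm"].to_numpy(float))
        for b in np.flatnonzero(~inside):
            out.append(
                {"row": int(df.index[b]), "column": "x_cm/y_cm", "message": "position outside arena"}
            )
    return out


_SCHEMAS = {
    "spikes": (["neuron_id", "time_s"], _violations_spikes),
    "stimulus": (["pulse_id", "time_s"], _violations_stimulus),
    "trajectory": (["t_s", "x_cm", "y_cm"], None),  # handled specially (needs arena)
}


def validate_inputs(
    paths: dict[str, str | Path], arena: ArenaGeometry | None = None
) -> pd.DataFrame:
    """Validate a set of input CSVs against their schemas.

    ``paths`` maps schema names (``spikes``, ``stimulus``, ``trajectory``)
    to file paths.  Returns a tidy report with one row per violation
    (columns ``file, row, column, message``); an empty frame means all
    inputs are valid.  Unreadable files raise an I/O error.
    """
    rows = []
    for kind, path in paths.items():
        if kind not in _SCHEMAS:
            raise ValidationError(f"unknown input kind {kind!r}")
        path = Path(path)
        df = pd.read_csv(path)  # propagate I/O errors as-is
        columns, checker = _SCHEMAS[kind]
        missing = [c for c in columns if c not in df.columns]
        if missing:
            rows.append(
                {"file": str(path), "row": -1, "column": ",".join(missing), "message": "missing columns"}
            )
            continue
        if kind == "trajectory":
            found = _violations_trajectory(df, arena)
        else:
            found = checker(df)
        for v in found:
            rows.append({"file": str(path), **v})
    return pd.DataFrame(rows, columns=["file", "row", "column", "message"])
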