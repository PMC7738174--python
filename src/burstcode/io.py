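"""Readers, writers and run configuration.

All tabular interchange is columnar text with headers: spike trains as
``repeat,time_ms``, burst tables as
``repeat,burst_id,first_spike_ms,n_spikes,isi1_ms,...``, waveforms as
``tau_ms,value,sem,n`` and kernels as ``tau_ms,value``.  Stimulus traces are
either two-column text (``time_ms,value``) or a raw ``.npy`` array with a JSON
sidecar declaring the sampling period.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stimulus import StimulusTrace
from .triggered import TriggeredAverage

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_stimulus",
    "write_stimulus",
    "write_bursts",
    "write_waveform",
    "write_kernel",
    "RunConfig",
]


def read_spikes(path: str | Path) -> pd.DataFrame:
    """Read a ``repeat,time_ms`` spike table; validates and sorts within repeat."""
    df = pd.read_csv(path)
    for col in ("repeat", "time_ms"):
        if col not in df.columns:
            raise ValueError(f"spike file {path} is missing column '{col}'")
    if (df["time_ms"] < 0).any():
        raise ValueError("negative spike times")
    df = df.sort_values(["repeat", "time_ms"], kind="stable").reset_index(drop=True)
    dup = df.groupby("repeat")["time_ms"].apply(lambda t: t.duplicated().any())
    if dup.any():
        raise ValueError("duplicate spike timestamps within a repeat")
    return df[["repeat", "time_ms"]]


def write_spikes(spikes: pd.DataFrame, path: str | Path) -> None:
    spikes[["repeat", "time_ms"]].to_csv(path, index=False, float_format="%.4f")


def read_stimulus(path: str | Path, dt: float | None = None) -> StimulusTrace:
    """Read a stimulus trace from two-column text or ``.npy`` + JSON sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        dt = dt or float(meta.get("dt_ms", 1.0))
        refresh = meta.get("refresh_period_ms")
        return StimulusTrace(values, dt=dt, refresh_period=refresh)
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise ValueError(f"stimulus file {path} is missing column 'value'")
    if dt is None:
        if "time_ms" in df.columns and len(df) > 1:
            dt = float(np.diff(df["time_ms"].to_numpy()[:2])[0])
        else:
            dt = 1.0
    return StimulusTrace(df["value"].to_numpy(dtype=float), dt=dt)


def write_stimulus(trace: StimulusTrace, path: str | Path) -> None:
    t = np.arange(trace.n_samples) * trace.dt
    pd.DataFrame({"time_ms": t, "value": trace.values}).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_bursts(table: pd.DataFrame, path: str | Path, max_isis: int = 3) -> None:
    """Write a burst table with the first ``max_isis`` ISI columns."""
    cols = ["repeat", "burst_id", "first_spike_ms", "n_spikes"]
    cols += [f"isi{i}_ms" for i in range(1, max_isis + 1)]
    for extra in ("event_id", "exceptional_flag"):
        if extra in table.columns:
            cols.append(extra)
    table[cols].to_csv(path, index=False, float_format="%.4f")


def write_waveform(ta: TriggeredAverage, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "tau_ms": ta.tau,
            "value": ta.values,
            "sem": ta.sem if ta.sem is not None else np.nan,
            "n": ta.n_triggers,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_kernel(tau: np.ndarray, values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"tau_ms": tau, "value": values}).to_csv(
        path, index=False, float_format="%.6g"
    )


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run.

    Parameters the source analyses leave unstated (histogram binning, time
    discretization of the stimulus posterior, the ISI-resolution grid, phase
    bin width, minimum burst counts) live here with documented defaults.
    """

    # simulation block (used when no spike/stimulus files are given)
    simulate: bool = True
    T_ms: float = 120_000.0
    refresh_hz: float = 30.0
    n_rep: int = 30
    seed: int = 0

    # input files (used when simulate is False)
    spikes_path: str | None = None
    stimulus_path: str | None = None

    # burst segmentation
    threshold_ms: float | None = None  # manual override; None = automatic trough
    hist_range_ms: tuple[float, float] = (0.5, 2000.0)
    hist_log_bins: int = 80
    hist_smooth_bins: int = 5

    # analysis windows and grids
    dt: float = 1.0
    bta_window: tuple[int, int] = (-300, 25)
    rms_window: tuple[int, int] = (-200, 25)
    f16_half_width: int = 8
    time_bin_ms: float = 100.0 / 3.0
    dt_grid: tuple[float, ...] = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    phase_bins: int = 12
    percentile_groups: tuple[tuple[float, float], ...] = ((0, 10), (45, 55), (90, 100))

    # inclusion thresholds
    min_event_bursts: int = 2
    min_2spike: int = 1500
    min_3spike: int = 1200

    alignment: str = "first"
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        # YAML round-trips tuples as lists
        for key in ("hist_range_ms", "bta_window", "rms_window", "dt_grid"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "percentile_groups" in data and data["percentile_groups"] is not None:
            data["percentile_groups"] = tuple(tuple(g) for g in data["percentile_groups"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
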