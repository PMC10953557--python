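"""Plate data model and on-disk formats.

The plate model mirrors a 48-well multi-well MEA with 16 electrodes per
well (768 electrodes recorded simultaneously at 12.5 kHz).  Raw traces
live in an HDF5 container (``/traces`` in microvolts plus scalar
metadata), spike timestamps in plain CSV (``well, electrode,
timestamp_s``), and run configuration in a YAML file whose unknown keys
are rejected rather than ignored.

Wells are addressed row-major as ``A1``..``F8`` for a 48-well plate;
electrodes are indexed 0..15 within a well.  Timestamps are seconds
(double precision in memory, microsecond precision on disk — finer than
one sample at 12.5 kHz).
"""

from __future__ import annotations

import copy
import hashlib
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PlateLayout",
    "RawRecording",
    "SpikeTrainSet",
    "EpochPair",
    "FormatError",
    "well_names",
    "read_recording",
    "write_recording",
    "read_spike_table",
    "write_spike_table",
    "load_config",
    "default_config",
    "config_hash",
]


class FormatError(ValueError):
    """A container or table does not match the documented layout."""


def well_names(n_wells: int, n_cols: int = 8) -> list[str]:
    """Row-major well labels: A1..A8, B1..B8, ... for ``n_wells`` wells."""
    if n_wells <= 0:
        raise ValueError("n_wells must be positive")
    rows = string.ascii_uppercase
    names = []
    for i in range(n_wells):
        r, c = divmod(i, n_cols)
        names.append(f"{rows[r]}{c + 1}")
    return names


@dataclass
class PlateLayout:
    """Well/electrode topology plus treatment assignment.

    ``well_groups`` maps each well label to a group label (e.g.
    ``"vehicle"``, ``"lidocaine"``, or a compound name).  ``treatments``
    maps wells to ``(compound, concentration_uM, epochs)`` where
    ``epochs`` is a strictly increasing tuple of boundary times in
    seconds (e.g. ``(0, 300, 600)`` for a baseline and a treatment
    epoch).
    """

    plate_id: str
    n_wells: int = 48
    electrodes_per_well: int = 16
    well_groups: dict[str, str] = field(default_factory=dict)
    treatments: dict[str, tuple[str, float, tuple[float, ...]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.n_wells <= 0 or self.electrodes_per_well <= 0:
            raise ValueError("n_wells and electrodes_per_well must be positive")
        valid = set(self.wells)
        for w in self.well_groups:
            if w not in valid:
                raise ValueError(f"well_groups references unknown well {w!r}")
        for w, (_, conc, epochs) in self.treatments.items():
            if w not in valid:
                raise ValueError(f"treatments references unknown well {w!r}")
            eps = tuple(float(e) for e in epochs)
            if any(e < 0 for e in eps) or any(
                b <= a for a, b in zip(eps, eps[1:])
            ):
                raise ValueError(
                    f"epoch boundaries for well {w!r} must be non-negative "
                    f"and strictly increasing, got {eps}"
                )

    @property
    def wells(self) -> list[str]:
        return well_names(self.n_wells)

    @property
    def n_electrodes(self) -> int:
        return self.n_wells * self.electrodes_per_well

    @property
    def electrode_ids(self) -> list[tuple[str, int]]:
        return [
            (w, e) for w in self.wells for e in range(self.electrodes_per_well)
        ]

    def group_of(self, well: str) -> str:
        return self.well_groups.get(well, "untreated")

    def wells_in_group(self, group: str) -> list[str]:
        return [w for w in self.wells if self.group_of(w) == group]


@dataclass
class RawRecording:
    """Per-electrode voltage traces in microvolts.

    ``traces`` has shape (n_electrodes, n_samples); ``electrode_ids``
    are ``(well, electrode_index)`` pairs aligned with the rows.
    """

    traces: np.ndarray
    fs: float
    electrode_ids: list[tuple[str, int]]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (electrode x sample) array")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if len(self.electrode_ids) != self.traces.shape[0]:
            raise ValueError("electrode_ids must match the number of trace rows")
        if len(set(self.electrode_ids)) != len(self.electrode_ids):
            raise ValueError("electrode_ids must be unique")

    @property
    def n_electrodes(self) -> int:
        return self.traces.shape[0]

    @property
    def duration(self) -> float:
        return self.traces.shape[1] / self.fs

    def trace_for(self, electrode_id: tuple[str, int]) -> np.ndarray:
        return self.traces[self.electrode_ids.index(tuple(electrode_id))]


@dataclass
class SpikeTrainSet:
    """Sorted spike timestamps per electrode, in seconds.

    ``trains`` maps ``(well, electrode_index)`` to a sorted float array.
    ``waveforms`` optionally carries cutouts (events x samples, µV)
    aligned with the timestamps of each electrode.
    """

    trains: dict[tuple[str, int], np.ndarray]
    duration: float
    waveforms: dict[tuple[str, int], np.ndarray] | None = None
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        clean: dict[tuple[str, int], np.ndarray] = {}
        for key, ts in self.trains.items():
            ts = np.asarray(ts, dtype=np.float64)
            if ts.size:
                if np.any(np.diff(ts) <= 0):
                    raise ValueError(
                        f"timestamps for electrode {key} must be strictly "
                        "increasing (sorted, unique)"
                    )
                if ts[0] < 0 or ts[-1] > self.duration:
                    raise ValueError(
                        f"timestamps for electrode {key} fall outside "
                        f"[0, {self.duration}]"
                    )
                if self.dead_time > 0 and ts.size > 1:
                    if np.min(np.diff(ts)) < self.dead_time - 1e-12:
                        raise ValueError(
                            f"electrode {key} violates the {self.dead_time} s "
                            "dead time"
                        )
            clean[tuple(key)] = ts
        self.trains = clean

    @property
    def electrode_ids(self) -> list[tuple[str, int]]:
        return list(self.trains.keys())

    @property
    def n_spikes(self) -> int:
        return int(sum(ts.size for ts in self.trains.values()))

    def by_well(self) -> dict[str, dict[int, np.ndarray]]:
        out: dict[str, dict[int, np.ndarray]] = {}
        for (well, idx), ts in self.trains.items():
            out.setdefault(well, {})[idx] = ts
        return out

    def restrict(self, t_start: float, t_stop: float) -> "SpikeTrainSet":
        """Sub-set of spikes in [t_start, t_stop), re-zeroed at t_start."""
        if not 0 <= t_start < t_stop <= self.duration + 1e-9:
            raise ValueError("epoch window outside recording")
        trains = {
            k: ts[(ts >= t_start) & (ts < t_stop)] - t_start
            for k, ts in self.trains.items()
        }
        return SpikeTrainSet(trains, duration=t_stop - t_start)


@dataclass
class EpochPair:
    """A matched baseline/treatment pair of spike-train sets."""

    baseline: SpikeTrainSet
    treatment: SpikeTrainSet

    def __post_init__(self) -> None:
        if set(self.baseline.trains) != set(self.treatment.trains):
            raise ValueError(
                "baseline and treatment epochs must cover identical electrodes"
            )

    @property
    def electrode_ids(self) -> list[tuple[str, int]]:
        return self.baseline.electrode_ids


# ---------------------------------------------------------------------------
# Raw-trace container (HDF5 layout)
# ---------------------------------------------------------------------------

def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording to the chunked HDF5 layout.

    Layout: ``/traces`` (float32, chunked per electrode), ``/well`` and
    ``/electrode`` id vectors, root attributes ``fs`` and ``t0``.
    Traces are stored as float64 so the round trip is bit exact.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "traces",
            data=rec.traces,
            dtype="f8",
            chunks=(1, min(rec.traces.shape[1], 1 << 16)),
        )
        wells = np.array([w for w, _ in rec.electrode_ids], dtype="S8")
        elecs = np.array([e for _, e in rec.electrode_ids], dtype="i4")
        f.create_dataset("well", data=wells)
        f.create_dataset("electrode", data=elecs)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["t0"] = float(rec.t0)


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"recording container not found: {path}")
    with h5py.File(path, "r") as f:
        for name in ("traces", "well", "electrode"):
            if name not in f:
                raise FormatError(f"container missing dataset '{name}'")
        if "fs" not in f.attrs:
            raise FormatError("container missing attribute 'fs'")
        traces = f["traces"][:]
        wells = [w.decode() for w in f["well"][:]]
        elecs = [int(e) for e in f["electrode"][:]]
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs.get("t0", 0.0))
    ids = list(zip(wells, elecs))
    return RawRecording(traces=traces, fs=fs, electrode_ids=ids, t0=t0)


# ---------------------------------------------------------------------------
# Spike tables (CSV)
# ---------------------------------------------------------------------------

def write_spike_table(trains: SpikeTrainSet, path: str | Path) -> None:
    """Write one CSV row per spike: well, electrode, timestamp_s (µs precision)."""
    rows = []
    for (well, idx), ts in sorted(trains.trains.items()):
        for t in ts:
            rows.append((well, idx, f"{t:.6f}"))
    df = pd.DataFrame(rows, columns=["well", "electrode", "timestamp_s"])
    header = f"# duration_s={trains.duration:.6f}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_spike_table(
    path: str | Path, duration: float | None = None
) -> SpikeTrainSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"spike table not found: {path}")
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# duration_s="):
            file_dur = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            file_dur = None
            fh.seek(0)
            df = pd.read_csv(fh)
    expected = {"well", "electrode", "timestamp_s"}
    if not expected.issubset(df.columns):
        raise FormatError(
            f"spike table must have columns {sorted(expected)}, "
            f"got {list(df.columns)}"
        )
    if duration is None:
        duration = file_dur
    if duration is None:
        duration = float(df["timestamp_s"].max()) if len(df) else 1.0
    if len(df) and (df["timestamp_s"] < 0).any():
        raise ValueError("spike table contains negative timestamps")
    trains: dict[tuple[str, int], np.ndarray] = {}
    for (well, idx), sub in df.groupby(["well", "electrode"], sort=True):
        ts = sub["timestamp_s"].to_numpy(dtype=np.float64)
        if np.any(np.diff(ts) < 0):
            raise ValueError(f"unsorted timestamps for electrode ({well}, {idx})")
        trains[(str(well), int(idx))] = ts
    return SpikeTrainSet(trains=trains, duration=float(duration))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Full default run specification.  Values are echoed into the run log;
#: unknown keys in a user config are rejected.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "layout": {
        "plate_id": "plate-1",
        "n_wells": 48,
        "electrodes_per_well": 16,
    },
    "detection": {
        "band_low_hz": 250.0,
        "band_high_hz": 3000.0,
        "filter_order": 1,
        "threshold_sigma": 5.5,
        "dead_time_s": 0.001,
        "sigma_window_s": 10.0,
        "cutout_pre_s": 0.001,
        "cutout_post_s": 0.002,
    },
    "metrics": {
        "active_electrode_min_per_min": 1.0,
        "active_well_min_electrodes": 5,
        "correlogram_bin_s": 0.005,
        "correlogram_window_s": 0.1,
        "burst_max_isi_s": 0.1,
        "burst_min_spikes": 5,
        "network_burst_min_fraction": 0.25,
        "network_burst_window_s": 0.1,
    },
    "screening": {
        "mad_multiplier": 3.0,
        "hit_reference": "baseline",  # baseline | vehicle | tnf
        "log_base": 10,
        "robust_zprime": False,
        "bh_correction": False,
    },
    "tpob": {
        "highpass_hz": 100.0,
        "band_low_hz": 100.0,
        "band_high_hz": 600.0,
        "trial_window_s": 3.5,
        "blank_s": 0.05,
        "stft_window_s": 0.25,
        "stft_overlap": 0.5,
    },
    "simulator": {
        "fs_hz": 12500.0,
        "noise_sd_uv": 1.5,
        "spike_amplitude_uv": 12.0,
        "baseline_rate_hz": 1.0,
        "burst_rate_hz": 0.063,
        "burst_participation": 0.5,
        "intra_burst_rate_hz": 85.0,
        "burst_duration_s": 1.0,
        "fraction_active": 0.97,
        "rate_cv": 0.59,
        "baseline_epoch_s": 300.0,
        "treatment_epoch_s": 300.0,
    },
}


def _merge(defaults: dict, override: dict, trail: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{trail}{key}"
        if key not in defaults:
            valid = ", ".join(sorted(defaults))
            raise KeyError(
                f"unknown config key '{where}'; valid keys here: {valid}"
            )
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key '{where}' must be a mapping")
            out[key] = _merge(defaults[key], value, trail=where + ".")
        else:
            out[key] = value
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML run config, resolving every documented default.

    Unknown keys raise ``KeyError`` listing the valid keys at that
    level, so typos never silently fall back to defaults.
    """
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config file must contain a mapping")
    return _merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved config, for provenance blocks."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
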