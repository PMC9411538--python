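"""On-disk formats and configuration loading.

A session directory holds: ``lfp.bin`` (float32 little-endian) with a
``lfp.json`` sidecar (sampling rate, sample count, unit metadata),
``spikes.csv`` (unit_id, spike_time_s), ``waveforms.csv`` (unit_id,
sample_index, amplitude), ``trials.csv`` (onset_s, force_g, withdrawal,
latency_s) and, for synthetic sessions, ``ground_truth.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .session import RecordingSession, SessionValidationError, UnitData

__all__ = [
    "write_session",
    "load_session",
    "load_config",
    "build_dataclass",
    "config_hash",
    "write_table",
]


def write_table(df: pd.DataFrame, path, seed=None, config_sha=None) -> None:
    """Write a CSV with a provenance comment header (version, config, seed)."""
    path = Path(path)
    header = f"# evlock {__version__}"
    if config_sha is not None:
        header += f" config_sha={config_sha}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    # round_trip parsing so write -> read -> write is byte-identical
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_session(session: RecordingSession, out_dir, seed=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lfp32 = np.asarray(session.lfp, "<f4")
    lfp32.tofile(out / "lfp.bin")
    sidecar = {
        "evlock_version": __version__,
        "fs": session.fs,
        "n_samples": int(lfp32.size),
        "dtype": "<f4",
        "condition": session.condition,
        "units": [
            {
                "unit_id": u.unit_id,
                "fs_wave": u.fs_wave,
                "n_waveform_samples": int(len(u.waveform)),
                "waveform_class": u.waveform_class,
            }
            for u in session.units
        ],
    }
    (out / "lfp.json").write_text(json.dumps(sidecar, indent=1))
    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(
                [np.full(len(u.spike_times), u.unit_id, int) for u in session.units]
            )
            if session.units
            else np.array([], int),
            "spike_time_s": np.concatenate(
                [u.spike_times for u in session.units]
            )
            if session.units
            else np.array([]),
        }
    )
    write_table(spikes, out / "spikes.csv", seed=seed)
    wf_rows = []
    for u in session.units:
        for i, a in enumerate(u.waveform):
            wf_rows.append((u.unit_id, i, a))
    write_table(
        pd.DataFrame(wf_rows, columns=["unit_id", "sample_index", "amplitude"]),
        out / "waveforms.csv",
        seed=seed,
    )
    trials = session.trials[["onset_s", "force_g", "withdrawal", "latency_s"]]
    write_table(trials, out / "trials.csv", seed=seed)
    if session.ground_truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(session.ground_truth, indent=1, default=str)
        )


def load_session(session_dir) -> RecordingSession:
    """Read and validate a session directory; raises SessionValidationError."""
    d = Path(session_dir)
    for name in ("lfp.bin", "lfp.json", "spikes.csv", "waveforms.csv", "trials.csv"):
        if not (d / name).exists():
            raise SessionValidationError("MISSING_FILE", f"{name} not found in {d}")
    sidecar = json.loads((d / "lfp.json").read_text())
    fs = float(sidecar["fs"])
    if fs <= 0:
        raise SessionValidationError("BAD_FS", f"sidecar fs={fs} must be positive")
    lfp = np.fromfile(d / "lfp.bin", dtype=sidecar.get("dtype", "<f4")).astype(float)
    if lfp.size != int(sidecar["n_samples"]):
        raise SessionValidationError(
            "LENGTH_MISMATCH",
            f"lfp.bin has {lfp.size} samples, sidecar says {sidecar['n_samples']}",
        )
    spikes = read_table(d / "spikes.csv")
    waveforms = read_table(d / "waveforms.csv")
    trials = read_table(d / "trials.csv")
    units: list[UnitData] = []
    for meta in sidecar.get("units", []):
        uid = int(meta["unit_id"])
        st = spikes.loc[spikes["unit_id"] == uid, "spike_time_s"].to_numpy(float)
        if np.any(np.diff(st) < 0):
            raise SessionValidationError(
                "UNSORTED_SPIKES", f"unit {uid} spike times not ascending"
            )
        wf = (
            waveforms[waveforms["unit_id"] == uid]
            .sort_values("sample_index")["amplitude"]
            .to_numpy(float)
        )
        wc = meta.get("waveform_class")
        units.append(
            UnitData(uid, st, wf, float(meta["fs_wave"]),
                     None if wc is None else int(wc))
        )
    gt = None
    if (d / "ground_truth.json").exists():
        gt = json.loads((d / "ground_truth.json").read_text())
    session = RecordingSession(
        lfp=lfp,
        fs=fs,
        units=units,
        trials=trials,
        condition=sidecar.get("condition", "unknown"),
        ground_truth=gt,
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def build_dataclass(cls, data: dict | None):
    """Strict dataclass construction: unknown keys are rejected."""
    if data is None:
        return cls()
    if dataclasses.is_dataclass(data.__class__):
        return data
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list) and f.type and "tuple" in str(f.type):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_hash(config: dict) -> str:
    """Short stable hash of a resolved configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
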