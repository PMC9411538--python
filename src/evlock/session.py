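"""In-memory recording-session container and validation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIAL_COLUMNS = ["onset_s", "force_g", "withdrawal", "latency_s"]


class SessionValidationError(ValueError):
    """Raised when a session violates its structural invariants.

    ``code`` is a stable machine-readable identifier (e.g. ``MISSING_FILE``,
    ``LENGTH_MISMATCH``, ``UNSORTED_SPIKES``).
    """

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


@dataclass
class UnitData:
    """Sorted spikes and the mean extracellular waveform of one unit."""

    unit_id: int
    spike_times: np.ndarray  # seconds, ascending
    waveform: np.ndarray  # mean waveform samples
    fs_wave: float  # waveform sampling rate, Hz
    waveform_class: int | None = None  # ground-truth class if simulated


@dataclass
class RecordingSession:
    """One animal/day recording: LFP, sorted units, and the trial table.

    ``ground_truth`` holds the generating simulation configuration for
    synthetic sessions and is absent (``None``) for real data.
    """

    lfp: np.ndarray
    fs: float
    units: list[UnitData]
    trials: pd.DataFrame
    condition: str = "naive"
    ground_truth: dict | None = None

    @property
    def duration(self) -> float:
        return len(self.lfp) / self.fs

    def withdrawal_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["withdrawal"] == 1]

    def validate(self, pre_window: float = 3.0, post_window: float = 3.0) -> None:
        """Check all structural invariants; raise SessionValidationError."""
        if self.fs <= 0:
            raise SessionValidationError("BAD_FS", f"fs={self.fs} must be positive")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise SessionValidationError(
                "BAD_TRIALS", f"trial table missing columns {missing}"
            )
        onsets = self.trials["onset_s"].to_numpy(float)
        if np.any(np.diff(onsets) < 0):
            raise SessionValidationError("UNSORTED_TRIALS", "trial onsets not ascending")
        dur = self.duration
        for u in self.units:
            st = np.asarray(u.spike_times, float)
            if st.size and (st[0] < 0 or st[-1] > dur):
                raise SessionValidationError(
                    "SPIKES_OUT_OF_RANGE",
                    f"unit {u.unit_id} has spikes outside [0, {dur:.3f}] s",
                )
            if np.any(np.diff(st) < 0):
                raise SessionValidationError(
                    "UNSORTED_SPIKES", f"unit {u.unit_id} spike times not ascending"
                )
        bad = (onsets < pre_window) | (onsets > dur - post_window)
        if np.any(bad):
            # not fatal: flag the trials so downstream stages can drop them
            warnings.warn(
                f"{int(bad.sum())} trial(s) too close to the trace edge; flagged invalid",
                stacklevel=2,
            )
        self.trials = self.trials.assign(valid=~bad)
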