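"""Synthetic recording-session generator.

Produces sessions with the statistical structure the downstream analysis
assumes: a continuous LFP-like trace with stimulus-locked, band-specific
power increases; spike trains from excited / inhibited / unresponsive
units; biphasic mean waveforms from two template classes (broad and
narrow); trial tables over the 7-filament von Frey force set; and
up-down response sequences drawn from a logistic psychometric function.

Everything is deterministic given ``SimulationConfig.seed``.

Design notes
------------
The background is 1/f-shaped noise.  Each frequency band carries an
explicit comb of sinusoidal carriers (odd-integer frequencies, so that
every pairwise beat period divides 0.5 s).  Stimulus-locked power
changes multiply the carrier amplitude by ``sqrt(gain)`` inside the
evoked window, with 10-ms cosine ramps to avoid spectral splatter.
Deterministic carriers make the band-power ground truth analytic: a
power gain of g yields a normalized change of exactly 100*(g-1) percent
at carrier-dominated frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq
from scipy.special import expit

from .session import RecordingSession, UnitData

__all__ = [
    "Carrier",
    "UnitSpec",
    "SimulationConfig",
    "simulate_lfp",
    "simulate_spike_train",
    "simulate_waveform",
    "simulate_updown_responses",
    "simulate_session",
]


@dataclass(frozen=True)
class Carrier:
    """A sinusoidal band carrier: frequency (Hz) and peak amplitude."""

    freq: float
    amplitude: float


@dataclass(frozen=True)
class UnitSpec:
    """Generative description of one unit."""

    baseline_rate: float  # Hz
    response_kind: str = "none"  # excited | inhibited | none
    evoked_rate: float = 0.0  # Hz, rate inside the evoked window
    evoked_duration: float = 0.5  # s
    waveform_class: int = 1  # 1 (broad) or 2 (narrow)

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.evoked_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.evoked_duration < 0:
            raise ValueError("evoked_duration must be non-negative")
        if self.response_kind not in ("excited", "inhibited", "none"):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")
        if self.waveform_class not in (1, 2):
            raise ValueError("waveform_class must be 1 or 2")


def _default_carriers() -> dict[str, tuple[Carrier, ...]]:
    # Odd-integer combs: all pairwise difference frequencies are even, so
    # the summed power envelope is periodic with period 0.5 s and the 1-s
    # baseline / 2-s quantification means are phase-independent.  The gap
    # between the last beta carrier (23 Hz) and the first gamma carrier
    # (37 Hz) makes the wavelet-leakage dominance crossover at the 30-Hz
    # band edge steep, so band-specific gains stay attributable despite
    # the ~4-Hz spectral bandwidth of a 7-cycle wavelet there; the first
    # gamma carrier is stronger to hold the crossover near the edge.
    gamma = tuple(
        Carrier(float(f), 1.0 if f == 37 else 0.20) for f in range(37, 100, 2)
    )
    return {
        "theta": (Carrier(5.0, 1.0), Carrier(7.0, 1.0)),
        "alpha": (Carrier(9.0, 1.0), Carrier(11.0, 1.0), Carrier(13.0, 1.0)),
        "beta": tuple(Carrier(float(f), 1.0) for f in range(15, 24, 2)),
        "gamma": gamma,
    }


@dataclass
class SimulationConfig:
    """Full description of a synthetic session.

    The seed fully determines the output.  ``band_gain_profile`` maps a
    band name to the post-onset power multiplier applied to its carriers
    (1.0 = no effect); ``gain_by_force`` optionally overrides the profile
    per filament force.
    """

    fs_raw: float = 32000.0
    n_trials_per_filament: int = 5
    filament_forces: tuple[float, ...] = (0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4)
    band_gain_profile: dict[str, float] = field(
        default_factory=lambda: {"theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0}
    )
    gain_by_force: dict[float, dict[str, float]] | None = None
    band_carriers: dict[str, tuple[Carrier, ...]] = field(default_factory=_default_carriers)
    one_over_f_exponent: float = 1.0
    noise_sd: float = 0.05
    # slightly longer than the 2-s quantification window so wavelet
    # temporal smoothing of the offset does not bleed out of the window
    lfp_evoked_duration: float = 2.4
    ramp_time: float = 0.010
    unit_specs: list[UnitSpec] = field(default_factory=list)
    psychometric: tuple[float, float] = (0.4, 3.0)  # (threshold g, slope)
    trial_spacing: float = 7.0
    edge_margin: float = 4.0
    refractory: float = 0.001
    waveform_noise_sd: float = 0.02
    condition: str = "naive"
    seed: int = 0

    def __post_init__(self) -> None:
        forces = np.asarray(self.filament_forces, float)
        if np.any(np.diff(forces) <= 0):
            raise ValueError("filament forces must be strictly increasing")
        fmax = max(
            (c.freq for cs in self.band_carriers.values() for c in cs), default=0.0
        )
        if self.fs_raw <= 2.0 * fmax:
            raise ValueError(
                f"fs_raw={self.fs_raw} must exceed twice the highest carrier "
                f"frequency ({fmax} Hz)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def session_duration(self) -> float:
        n = self.n_trials_per_filament * len(self.filament_forces)
        return 2.0 * self.edge_margin + n * self.trial_spacing


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float,
                      f_floor: float = 0.5) -> np.ndarray:
    """Unit-variance noise with a 1/f**exponent power spectrum (flat below f_floor)."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, 1.0 / fs)
    shape = np.maximum(f, f_floor) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = irfft(spec * shape, n)
    return x / x.std()


def _gain_envelope(n: int, fs: float, onsets: np.ndarray, gains: np.ndarray,
                   duration: float, ramp: float) -> np.ndarray:
    """Multiplicative amplitude envelope: sqrt(gain) inside each evoked window,
    with raised-cosine ramps of length ``ramp`` at both edges."""
    env = np.ones(n)
    n_ramp = max(int(round(ramp * fs)), 1)
    up = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    for onset, g in zip(onsets, gains):
        if g == 1.0:
            continue
        a = np.sqrt(g) - 1.0
        i0 = int(round(onset * fs))
        i1 = int(round((onset + duration) * fs))
        env[i0 : i0 + n_ramp] += a * up
        env[i0 + n_ramp : i1 - n_ramp] += a
        env[i1 - n_ramp : i1] += a * up[::-1]
    return env


def simulate_lfp(
    config: SimulationConfig,
    onsets,
    onset_gains: list[dict[str, float]] | None = None,
) -> np.ndarray:
    """Synthesize the continuous trace at ``config.fs_raw``.

    ``onsets`` are stimulus times (s) at which the band gains apply.
    ``onset_gains`` optionally gives a per-onset band->gain mapping;
    otherwise ``config.band_gain_profile`` is used for every onset.
    Raises ValueError when an onset is too close to the trace edge.
    """
    fs = config.fs_raw
    duration = config.session_duration
    onsets = np.asarray(onsets, float)
    margin = max(config.lfp_evoked_duration, config.ramp_time)
    bad = (onsets < config.ramp_time) | (onsets > duration - margin)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"onset {onsets[i]:.3f} s too close to the trace edge "
            f"(valid range [{config.ramp_time}, {duration - margin:.3f}] s)"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng([config.seed, 0x1F])
    if config.noise_sd > 0:
        trace = config.noise_sd * _one_over_f_noise(
            rng, n, fs, config.one_over_f_exponent
        )
    else:
        rng.standard_normal(n)  # burn the stream so seeds stay comparable
        trace = np.zeros(n)
    for band in sorted(config.band_carriers):
        carriers = config.band_carriers[band]
        comp = np.zeros(n)
        for c in carriers:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            comp += c.amplitude * np.cos(2.0 * np.pi * c.freq * t + phase)
        if onset_gains is None:
            gains = np.full(len(onsets), config.band_gain_profile.get(band, 1.0))
        else:
            gains = np.array([g.get(band, 1.0) for g in onset_gains], float)
        if np.any(gains != 1.0):
            comp *= _gain_envelope(
                n, fs, onsets, gains, config.lfp_evoked_duration, config.ramp_time
            )
        trace += comp
    return trace


def _thin_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Remove spikes closer than ``refractory`` to the preceding kept spike."""
    while times.size > 1:
        short = np.diff(times) < refractory
        if not np.any(short):
            break
        # drop the later spike of each offending pair, then re-check
        drop = np.flatnonzero(short) + 1
        keep = np.ones(times.size, bool)
        keep[drop] = False
        times = times[keep]
    return times


def simulate_spike_train(
    spec: UnitSpec,
    onsets,
    duration: float,
    seed: int,
    refractory: float = 0.001,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike train for one unit (times in s, sorted).

    The rate is ``baseline_rate`` everywhere and ``evoked_rate`` inside
    [onset, onset + evoked_duration] for excited/inhibited kinds.  A 1-ms
    refractory period is enforced by thinning.
    """
    if spec.evoked_duration < 0:
        raise ValueError("evoked_duration must be non-negative")
    onsets = np.sort(np.asarray(onsets, float))
    rng = np.random.default_rng(seed)
    responsive = spec.response_kind in ("excited", "inhibited")
    rate_max = max(spec.baseline_rate, spec.evoked_rate if responsive else 0.0)
    if rate_max == 0.0:
        return np.empty(0)
    # homogeneous process at rate_max, then thin to the local rate
    n_draw = int(rate_max * duration + 10.0 * np.sqrt(rate_max * duration) + 50)
    gaps = rng.exponential(1.0 / rate_max, size=n_draw)
    times = np.cumsum(gaps)
    while times.size and times[-1] < duration:  # pragma: no cover - rare top-up
        extra = rng.exponential(1.0 / rate_max, size=n_draw)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    times = times[times < duration]
    if responsive and onsets.size:
        idx = np.searchsorted(onsets, times, side="right")
        inside = (idx > 0) & (times - onsets[np.maximum(idx - 1, 0)] < spec.evoked_duration)
        rate = np.where(inside, spec.evoked_rate, spec.baseline_rate)
    else:
        rate = np.full(times.size, spec.baseline_rate)
    keep = rng.random(times.size) < rate / rate_max
    times = times[keep]
    return _thin_refractory(times, refractory)


# Waveform templates: sums of three Gaussians (early peak, trough, late
# peak), parameterized in ms as (amp, center, width) triples.  Class 1 is
# broad (slow trough recovery, late and wide second peak); class 2 narrow.
WAVEFORM_TEMPLATES: dict[int, tuple[tuple[float, float, float], ...]] = {
    1: ((0.30, 0.90, 0.12), (-1.00, 1.35, 0.28), (0.50, 2.50, 0.50)),
    2: ((0.35, 0.95, 0.09), (-1.00, 1.25, 0.13), (0.40, 1.75, 0.25)),
}


def simulate_waveform(
    class_id: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs_wave: float = 32000.0,
    window_ms: float = 4.0,
    templates: dict[int, tuple[tuple[float, float, float], ...]] | None = None,
) -> np.ndarray:
    """Mean-waveform template for a class-1 (broad) or class-2 (narrow) unit."""
    templates = templates or WAVEFORM_TEMPLATES
    if class_id not in templates:
        raise ValueError(f"unknown waveform class {class_id}")
    n = int(round(window_ms * 1e-3 * fs_wave))
    t_ms = np.arange(n) / fs_wave * 1e3
    w = np.zeros(n)
    for amp, mu, sigma in templates[class_id]:
        w += amp * np.exp(-0.5 * ((t_ms - mu) / sigma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        w = w + rng.normal(0.0, noise_sd, size=n)
    return w


def psychometric_prob(force: float, threshold: float, slope: float) -> float:
    """Logistic withdrawal probability in log10(force)."""
    if np.isinf(slope):
        if force > threshold:
            return 1.0
        return 0.5 if force == threshold else 0.0
    return float(expit(slope * (np.log10(force) - np.log10(threshold))))


def simulate_updown_responses(
    true_threshold: float,
    slope: float,
    filament_set,
    start_force: float,
    max_steps: int = 50,
    seed: int = 0,
    n_after_reversal: int = 4,
) -> list[tuple[float, int]]:
    """One simulated up-down testing sequence: list of (force g, response 0/1).

    Stepping: down one filament after a positive response, up one after a
    negative.  The sequence ends ``n_after_reversal`` presentations after
    the first reversal, or when the staircase would step past a boundary
    of the filament set, or at ``max_steps``.
    """
    forces = np.asarray(sorted(filament_set), float)
    matches = np.flatnonzero(np.isclose(forces, start_force))
    if matches.size == 0:
        raise ValueError(f"start_force {start_force} not in the filament set")
    idx = int(matches[0])
    rng = np.random.default_rng(seed)
    seq: list[tuple[float, int]] = []
    first_reversal: int | None = None
    while len(seq) < max_steps:
        f = float(forces[idx])
        resp = int(rng.random() < psychometric_prob(f, true_threshold, slope))
        seq.append((f, resp))
        if len(seq) >= 2 and resp != seq[-2][1] and first_reversal is None:
            first_reversal = len(seq)
        if first_reversal is not None and len(seq) >= first_reversal + n_after_reversal:
            break
        nxt = idx - 1 if resp else idx + 1
        if nxt < 0 or nxt >= forces.size:
            break  # boundary reached; estimator applies the boundary convention
        idx = nxt
    return seq


def simulate_session(config: SimulationConfig) -> RecordingSession:
    """Generate a full session: LFP, units, and the trial table."""
    rng = np.random.default_rng([config.seed, 0x2A])
    forces = np.repeat(config.filament_forces, config.n_trials_per_filament)
    rng.shuffle(forces)
    n_tot = forces.size
    onsets = (
        config.edge_margin
        + np.arange(n_tot) * config.trial_spacing
        + rng.uniform(0.0, 0.5, size=n_tot)
    )
    thr, slope = config.psychometric
    p = np.array([psychometric_prob(f, thr, slope) for f in forces])
    withdrawal = (rng.random(n_tot) < p).astype(int)
    latency = np.where(
        withdrawal == 1, rng.uniform(0.1, 1.0, size=n_tot), np.nan
    )
    trials = pd.DataFrame(
        {
            "onset_s": onsets,
            "force_g": forces,
            "withdrawal": withdrawal,
            "latency_s": latency,
        }
    )
    wd = trials[trials["withdrawal"] == 1]
    wd_onsets = wd["onset_s"].to_numpy()
    if config.gain_by_force is not None:
        onset_gains = [
            {**config.band_gain_profile, **config.gain_by_force.get(f, {})}
            for f in wd["force_g"]
        ]
    else:
        onset_gains = None
    lfp = simulate_lfp(config, wd_onsets, onset_gains)
    units = []
    duration = config.session_duration
    for uid, spec in enumerate(config.unit_specs):
        st = simulate_spike_train(
            spec,
            wd_onsets,
            duration,
            seed=np.random.SeedSequence([config.seed, 0x3B, uid]).entropy,
            refractory=config.refractory,
        )
        wf = simulate_waveform(
            spec.waveform_class,
            noise_sd=config.waveform_noise_sd,
            seed=int(np.random.default_rng([config.seed, 0x4C, uid]).integers(2**31)),
        )
        units.append(
            UnitData(
                unit_id=uid,
                spike_times=st,
                waveform=wf,
                fs_wave=32000.0,
                waveform_class=spec.waveform_class,
            )
        )
    session = RecordingSession(
        lfp=lfp,
        fs=config.fs_raw,
        units=units,
        trials=trials,
        condition=config.condition,
        ground_truth=None,
    )
    session.ground_truth = _config_to_dict(config)
    session.validate()
    return session


def _config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable view of the generating configuration."""
    from dataclasses import asdict

    d = asdict(config)
    d["band_carriers"] = {
        b: [[c.freq, c.amplitude] for c in cs] for b, cs in config.band_carriers.items()
    }
    if d.get("gain_by_force"):
        d["gain_by_force"] = {str(k): v for k, v in d["gain_by_force"].items()}
    d["session_duration"] = config.session_duration
    return d
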