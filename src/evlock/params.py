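"""Analysis parameter containers.

All times are in seconds, frequencies in Hz, forces in grams. Defaults
reproduce the published analysis settings; every field can be overridden
from a YAML/JSON run configuration (see :mod:`evlock.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PreprocessParams:
    """Anti-alias filtering and decimation of the raw wide-band trace.

    The trace is low-pass filtered with a Chebyshev type I filter
    (``filter_order``, ``ripple_db`` dB passband ripple, passband edge at
    ``passband_edge`` Hz) and decimated to ``fs_out``.
    """

    filter_order: int = 3
    ripple_db: float = 0.5
    passband_edge: float = 200.0
    fs_out: float = 1000.0

    def validate(self, fs_raw: float) -> None:
        if fs_raw < 2.0 * self.passband_edge:
            raise ValueError(
                f"fs_raw={fs_raw} Hz violates Nyquist for the "
                f"{self.passband_edge} Hz passband edge"
            )
        if self.fs_out > fs_raw:
            raise ValueError("fs_out must not exceed fs_raw")
        if self.passband_edge >= self.fs_out / 2.0:
            raise ValueError("passband_edge must be below fs_out/2")


@dataclass(frozen=True)
class SpectrogramParams:
    """Morlet spectrogram and event-locked normalization settings.

    ``wavelet_base_param`` records the vendor-specific wavelet setting of
    the original analysis software for provenance only; the wavelet shape
    actually used is controlled by ``n_cycles`` (the mapping between the
    two parameterizations is not recoverable and is deliberately not
    guessed).
    """

    freq_min: float = 4.0
    freq_max: float = 100.0
    freq_step: float = 0.5
    time_resolution: float = 0.001
    n_cycles: float = 7.0
    wavelet_base_param: float = 0.8125  # provenance only, not used
    pre_window: float = 3.0
    post_window: float = 3.0
    baseline_window: float = 1.0
    quant_window: float = 2.0
    timecourse_bin: float = 0.1

    def __post_init__(self) -> None:
        if self.baseline_window > self.pre_window:
            raise ValueError("baseline_window must not exceed pre_window")
        if self.quant_window > self.post_window:
            raise ValueError("quant_window must not exceed post_window")
        if self.freq_min <= 0 or self.freq_max <= self.freq_min:
            raise ValueError("need 0 < freq_min < freq_max")


@dataclass(frozen=True)
class BandTable:
    """Frequency-band definitions. Edges are half-open: [lo, hi)."""

    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 14.0)
    beta: tuple[float, float] = (14.0, 30.0)
    gamma: tuple[float, float] = (30.0, 100.0)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "theta": self.theta,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
        }

    def __post_init__(self) -> None:
        bands = list(self.as_dict().values())
        for (lo, hi), (lo2, _hi2) in zip(bands, bands[1:]):
            if hi <= lo:
                raise ValueError("band edges must be increasing")
            if lo2 != hi:
                raise ValueError("bands must be contiguous (shared edges)")

    def edges(self, band: str) -> tuple[float, float]:
        table = self.as_dict()
        if band not in table:
            raise KeyError(f"unknown band {band!r}; known: {sorted(table)}")
        return table[band]


@dataclass(frozen=True)
class PSTHParams:
    """Peri-stimulus histogram and responsiveness-detection settings.

    ``baseline_mode`` selects how the baseline mean/SD entering the
    z-scores are estimated: ``"trial_averaged"`` (default) uses the
    baseline bins of the trial-averaged PSTH; ``"pooled_trials"`` pools
    per-trial baseline bin rates and scales the SD to the standard error
    of the trial-averaged rate.
    """

    bin_width: float = 0.25
    pre_window: float = 3.0
    post_window: float = 3.0
    z_threshold: float = 3.09
    min_rate: float = 1.0
    min_trials: int = 3
    baseline_mode: str = "trial_averaged"

    def __post_init__(self) -> None:
        for name in ("pre_window", "post_window"):
            w = getattr(self, name)
            n = w / self.bin_width
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of bin_width")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.baseline_mode not in ("trial_averaged", "pooled_trials"):
            raise ValueError("baseline_mode must be 'trial_averaged' or 'pooled_trials'")

    @property
    def n_pre_bins(self) -> int:
        return round(self.pre_window / self.bin_width)

    @property
    def n_post_bins(self) -> int:
        return round(self.post_window / self.bin_width)
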