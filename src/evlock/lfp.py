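"""Event-locked LFP spectral analysis.

Pipeline: Chebyshev-I anti-alias filtering + decimation of the raw
trace, complex Morlet spectrograms on a 0.5-Hz frequency grid, per-trial
baseline normalization to percent change, band-power summaries, 100-ms
time courses, and per-filament-force response curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import fft, ifft, next_fast_len, rfft, irfft, rfftfreq

from .params import BandTable, PreprocessParams, SpectrogramParams

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrogram",
    "NormalizedSpectrogram",
    "design_antialias_filter",
    "chebyshev1_magnitude",
    "preprocess_lfp",
    "morlet_spectrogram",
    "extract_and_normalize",
    "band_power_change",
    "band_timecourse",
    "band_power_by_force",
    "detect_onsets_piezo",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def design_antialias_filter(fs_raw: float, params: PreprocessParams):
    """Digital Chebyshev type I low-pass (b, a) at the stated parameters."""
    params.validate(fs_raw)
    return signal.cheby1(
        params.filter_order, params.ripple_db, params.passband_edge, btype="low",
        fs=fs_raw,
    )


def chebyshev1_magnitude(f, order: int, ripple_db: float, edge: float):
    """Analytic Chebyshev-I magnitude |H(f)| of the analog prototype.

    |H|^2 = 1 / (1 + eps^2 * T_n(f/edge)^2), eps^2 = 10^(ripple/10) - 1.
    """
    f = np.asarray(f, float)
    eps2 = 10.0 ** (ripple_db / 10.0) - 1.0
    tn = np.polynomial.chebyshev.chebval(f / edge, [0.0] * order + [1.0])
    return 1.0 / np.sqrt(1.0 + eps2 * tn**2)


def preprocess_lfp(
    raw_trace: np.ndarray,
    fs_raw: float,
    params: PreprocessParams = PreprocessParams(),
) -> np.ndarray:
    """Filter the raw trace and decimate to ``params.fs_out``.

    The filter is applied zero-phase in the frequency domain with exactly
    the designed magnitude |H(f)| (a forward-backward pass would square
    the magnitude and distort the passband contract), so event-locked
    timing is not lag-shifted.  Output length is
    ``floor(n_in * fs_out / fs_raw)``.
    """
    x = np.asarray(raw_trace, float)
    finite = np.isfinite(x)
    if not finite.all():
        i = int(np.flatnonzero(~finite)[0])
        raise ValueError(f"non-finite sample in raw trace at index {i}")
    b, a = design_antialias_filter(fs_raw, params)
    n = x.size
    nfft = next_fast_len(n)
    freqs = rfftfreq(nfft, 1.0 / fs_raw)
    _, h = signal.freqz(b, a, worN=freqs, fs=fs_raw)
    y = irfft(rfft(x, nfft) * np.abs(h), nfft)[:n]
    n_out = int(np.floor(n * params.fs_out / fs_raw))
    ratio = fs_raw / params.fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        y = y[:: int(round(ratio))]
    else:
        frac = Fraction(params.fs_out / fs_raw).limit_denominator(10000)
        y = signal.resample_poly(y, frac.numerator, frac.denominator)
    return y[:n_out]


# ---------------------------------------------------------------------------
# Morlet spectrogram
# ---------------------------------------------------------------------------

@dataclass
class Spectrogram:
    """Time x frequency power matrix (``power[freq, time]``, arbitrary
    units proportional to amplitude squared).

    ``edge_margins[i]`` is the number of samples at each end of row ``i``
    that lie inside the wavelet half-support and must not be analyzed.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    edge_margins: np.ndarray

    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.power.shape, bool)
        nt = self.power.shape[1]
        for i, m in enumerate(self.edge_margins):
            m = min(int(m), nt)
            mask[i, :m] = False
            mask[i, nt - m :] = False
        return mask


def morlet_spectrogram(
    trace: np.ndarray,
    fs: float,
    params: SpectrogramParams = SpectrogramParams(),
) -> Spectrogram:
    """Complex-Morlet power on the 0.5-Hz grid at 1-ms time resolution.

    The wavelet at frequency f is a Gaussian-envelope analytic carrier
    with sigma_t = n_cycles / (2 pi f); it is applied in the frequency
    domain as a Gaussian passband centered on f.  A unit-amplitude
    sinusoid at a grid frequency yields power 0.5 (its true mean power).
    """
    x = np.asarray(trace, float)
    freqs = np.arange(
        params.freq_min, params.freq_max + params.freq_step / 2, params.freq_step
    )
    if freqs[-1] >= fs / 2:
        raise ValueError(
            f"requested frequency {freqs[-1]} Hz is not below fs/2 = {fs / 2} Hz"
        )
    sigma_t_max = params.n_cycles / (2.0 * np.pi * freqs[0])
    if x.size / fs < 2.0 * 3.0 * sigma_t_max:
        raise ValueError(
            "trace shorter than the support of the longest wavelet "
            f"({2 * 3 * sigma_t_max:.2f} s at {freqs[0]} Hz)"
        )
    stride = max(int(round(params.time_resolution * fs)), 1)
    n = x.size
    nfft = next_fast_len(n)
    spec = fft(x, nfft)
    wfreqs = np.fft.fftfreq(nfft, 1.0 / fs)
    n_out = len(range(0, n, stride))
    power = np.empty((freqs.size, n_out), np.float64)
    margins = np.empty(freqs.size, int)
    for i, f in enumerate(freqs):
        sigma_t = params.n_cycles / (2.0 * np.pi * f)
        sigma_f = 1.0 / (2.0 * np.pi * sigma_t)
        # analytic wavelet: Gaussian passband on positive frequencies only;
        # gain sqrt(2) at center so |W|^2 equals mean power of a sinusoid
        gain = np.sqrt(2.0) * np.exp(-0.5 * ((wfreqs - f) / sigma_f) ** 2)
        gain[wfreqs < 0] = 0.0
        w = ifft(spec * gain)[:n:stride]
        power[i] = np.abs(w) ** 2
        margins[i] = int(np.ceil(3.0 * sigma_t * fs / stride))
    times = np.arange(0, n, stride) / fs
    return Spectrogram(
        power=power, freqs=freqs, times=times, fs=fs / stride, edge_margins=margins
    )


# ---------------------------------------------------------------------------
# event-locked normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedSpectrogram:
    """Trial-averaged percent-change spectrogram, time axis onset-relative."""

    matrix: np.ndarray  # [freq, time], percent change
    freqs: np.ndarray
    times: np.ndarray  # seconds relative to onset
    n_trials: int


def extract_and_normalize(
    spec: Spectrogram,
    onsets,
    params: SpectrogramParams = SpectrogramParams(),
) -> NormalizedSpectrogram:
    """Per-trial baseline normalization, then average across trials.

    For each trial and each frequency row, percent change is
    100 * (P(t, f) - mu) / mu with mu the mean power over the
    ``baseline_window`` immediately preceding the onset.
    """
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ValueError("no onsets supplied")
    fs = spec.fs
    n_pre = int(round(params.pre_window * fs))
    n_post = int(round(params.post_window * fs))
    n_base = int(round(params.baseline_window * fs))
    margin = int(spec.edge_margins.max())
    nt = spec.power.shape[1]
    acc = np.zeros((spec.freqs.size, n_pre + n_post))
    for onset in onsets:
        i0 = int(round((onset - spec.times[0]) * fs))
        if i0 - n_pre < margin or i0 + n_post > nt - margin:
            raise ValueError(
                f"onset at {onset:.3f} s lacks a full +/- window inside the "
                "valid spectrogram region"
            )
        seg = spec.power[:, i0 - n_pre : i0 + n_post]
        mu = seg[:, n_pre - n_base : n_pre].mean(axis=1, keepdims=True)
        if np.any(mu == 0.0):
            f_bad = spec.freqs[int(np.flatnonzero(mu[:, 0] == 0)[0])]
            raise ValueError(f"zero baseline power at {f_bad} Hz; cannot normalize")
        acc += 100.0 * (seg - mu) / mu
    acc /= onsets.size
    times = (np.arange(n_pre + n_post) - n_pre) / fs
    return NormalizedSpectrogram(
        matrix=acc, freqs=spec.freqs, times=times, n_trials=int(onsets.size)
    )


def _band_rows(nspec: NormalizedSpectrogram, band, bands: BandTable) -> np.ndarray:
    lo, hi = bands.edges(band) if isinstance(band, str) else band
    rows = (nspec.freqs >= lo) & (nspec.freqs < hi)
    if not rows.any():
        raise ValueError(f"no frequency rows in band {band!r}")
    return rows


def band_power_change(
    nspec: NormalizedSpectrogram,
    band,
    quant_window: float = 2.0,
    bands: BandTable = BandTable(),
) -> float:
    """Mean percent change over the band's rows and [0, quant_window) s."""
    rows = _band_rows(nspec, band, bands)
    cols = (nspec.times >= 0.0) & (nspec.times < quant_window)
    return float(nspec.matrix[np.ix_(rows, cols)].mean())


def band_timecourse(
    nspec: NormalizedSpectrogram,
    band,
    bin_width: float = 0.1,
    bands: BandTable = BandTable(),
    withdrawal_latencies=None,
) -> pd.DataFrame:
    """Band-mean percent change in consecutive bins over the whole window.

    Returns a frame with ``bin_center`` and ``pct_change``; a trailing
    partial bin is dropped with a logged warning.  When per-trial
    withdrawal latencies are supplied their median is attached as
    ``frame.attrs['median_withdrawal_s']`` for reference.
    """
    rows = _band_rows(nspec, band, bands)
    t0, t1 = nspec.times[0], nspec.times[-1] + 1.0 / _fs_of(nspec)
    n_bins = int(np.floor((t1 - t0) / bin_width + 1e-9))
    if (t1 - t0) - n_bins * bin_width > 1e-6:
        logger.warning(
            "bin width %.3f s does not divide the %.3f s window; dropping the "
            "partial final bin", bin_width, t1 - t0,
        )
    centers = t0 + (np.arange(n_bins) + 0.5) * bin_width
    vals = np.empty(n_bins)
    for i in range(n_bins):
        lo = t0 + i * bin_width
        cols = (nspec.times >= lo - 1e-9) & (nspec.times < lo + bin_width - 1e-9)
        vals[i] = nspec.matrix[np.ix_(rows, cols)].mean()
    out = pd.DataFrame({"bin_center": centers, "pct_change": vals})
    if withdrawal_latencies is not None and len(withdrawal_latencies):
        out.attrs["median_withdrawal_s"] = float(np.median(withdrawal_latencies))
    return out


def _fs_of(nspec: NormalizedSpectrogram) -> float:
    return 1.0 / float(np.median(np.diff(nspec.times)))


def band_power_by_force(per_animal_tables: list[pd.DataFrame], band: str | None = None
                        ) -> pd.DataFrame:
    """Aggregate per-animal (force_g, pct_change) tables across animals.

    Input: one frame per animal with columns ``force_g`` and
    ``pct_change`` (already averaged within animal).  Output: one row per
    force with the cross-animal mean and SEM (SEM is NaN for a single
    animal).  Forces absent from every animal are simply not present;
    forces present in only some animals aggregate over those animals.
    """
    if not per_animal_tables:
        raise ValueError("no per-animal tables supplied")
    frames = []
    for i, tab in enumerate(per_animal_tables):
        t = tab.copy()
        t["animal"] = i
        frames.append(t)
    allt = pd.concat(frames, ignore_index=True)
    grp = allt.groupby("force_g")["pct_change"]
    out = pd.DataFrame(
        {
            "mean_pct": grp.mean(),
            "sem_pct": grp.sem(ddof=1),
            "n_animals": grp.count(),
        }
    ).reset_index()
    if band is not None:
        out.insert(0, "band", band)
    return out


def group_forces(table: pd.DataFrame, forces) -> float:
    """Mean percent change over a force subset (e.g. weak {0.07, 0.16} g)."""
    sel = table[table["force_g"].isin(list(forces))]
    if sel.empty:
        warnings.warn(f"none of the forces {forces} present; returning NaN")
        return float("nan")
    return float(sel["mean_pct"].mean())


# ---------------------------------------------------------------------------
# optional plumbing: piezo threshold-crossing onset detector
# ---------------------------------------------------------------------------

def detect_onsets_piezo(
    trace: np.ndarray,
    fs: float,
    k_sd: float = 5.0,
    quiescent_window: float = 1.0,
    min_separation: float = 1.0,
) -> np.ndarray:
    """Threshold-crossing onset detection on a transducer channel.

    The threshold is ``k_sd`` times the SD of the first
    ``quiescent_window`` seconds.  Returns crossing times (s) separated
    by at least ``min_separation``.  Provided as plumbing only; analyses
    normally take onsets from the trial table.
    """
    x = np.asarray(trace, float)
    nq = int(quiescent_window * fs)
    thr = k_sd * x[:nq].std()
    above = np.abs(x) > thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    out: list[float] = []
    for c in crossings / fs:
        if not out or c - out[-1] >= min_separation:
            out.append(float(c))
    return np.asarray(out)
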