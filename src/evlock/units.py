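"""Single-unit response detection and waveform-based unit typing.

Responsiveness: trial-aligned PSTHs in 250-ms bins, z-scored against the
3-s pre-stimulation baseline; a unit is excited/inhibited when any
post-stimulation bin exceeds +/- 3.09 (P < 0.001 under a standard-normal
reference).  Typing: six firing/waveform parameters, clustered with
k-means (k=2) either on a 2-D t-SNE embedding of all six (exploratory)
or directly on (asymmetry, trough-to-return) (final).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .params import PSTHParams

logger = logging.getLogger(__name__)

__all__ = [
    "PSTH",
    "UnitResponse",
    "WaveformFeatures",
    "compute_psth",
    "zscore_psth",
    "classify_response",
    "apply_inclusion",
    "analyze_unit",
    "response_magnitudes",
    "extract_waveform_features",
    "cluster_unit_types",
]

FEATURE_NAMES = [
    "firing_rate",
    "isi_cv",
    "peak_to_peak",
    "peak_to_peak_time",
    "trough_to_return",
    "asymmetry",
]


@dataclass
class PSTH:
    """Trial-aligned binned firing rates for one unit."""

    rates: np.ndarray  # trial-averaged rate per bin, Hz
    counts: np.ndarray  # per-trial counts, shape (n_trials, n_bins)
    bin_centers: np.ndarray  # s, onset-relative
    bin_width: float
    n_trials: int


@dataclass
class UnitResponse:
    unit_id: int
    psth: PSTH | None
    z: np.ndarray | None  # per post-window bin
    label: str  # excited | inhibited | unresponsive | excluded
    z_max: float | None = None  # defined for excited units only
    z_min: float | None = None  # defined for inhibited units only
    mixed: bool = False  # bins beyond both thresholds


def compute_psth(
    spike_times,
    onsets,
    params: PSTHParams = PSTHParams(),
    session_duration: float | None = None,
) -> PSTH:
    """Counts per 250-ms bin per trial, converted to Hz and trial-averaged.

    Trials whose window extends past the recording are dropped with a
    warning.  Spike times must be sorted ascending.
    """
    st = np.asarray(spike_times, float)
    if np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted ascending")
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ValueError("at least one onset is required")
    if session_duration is not None:
        ok = (onsets - params.pre_window >= 0) & (
            onsets + params.post_window <= session_duration
        )
        if not ok.all():
            warnings.warn(
                f"dropping {int((~ok).sum())} trial(s) whose window extends "
                "past the recording"
            )
            onsets = onsets[ok]
        if onsets.size == 0:
            raise ValueError("no trials with a complete window remain")
    n_bins = params.n_pre_bins + params.n_post_bins
    rel_edges = -params.pre_window + np.arange(n_bins + 1) * params.bin_width
    edges = onsets[:, None] + rel_edges[None, :]  # (n_trials, n_bins+1)
    idx = np.searchsorted(st, edges.ravel()).reshape(edges.shape)
    counts = np.diff(idx, axis=1)
    rates = counts.mean(axis=0) / params.bin_width
    centers = rel_edges[:-1] + params.bin_width / 2.0
    return PSTH(
        rates=rates,
        counts=counts,
        bin_centers=centers,
        bin_width=params.bin_width,
        n_trials=int(onsets.size),
    )


def zscore_psth(psth: PSTH, params: PSTHParams = PSTHParams()) -> np.ndarray | None:
    """z-score of each post-window bin against the pre-stimulation baseline.

    Default ("trial_averaged"): mean and sample SD (ddof=1) over the
    baseline bins of the trial-averaged PSTH.  "pooled_trials": mean over
    all per-trial baseline bin rates, with the SD scaled by 1/sqrt(n_trials)
    to the standard error of a trial-averaged bin.  Returns None when the
    baseline SD is zero (degenerate; the unit is then excluded).
    """
    nb = params.n_pre_bins
    if params.baseline_mode == "trial_averaged":
        base = psth.rates[:nb]
        mu = base.mean()
        sd = base.std(ddof=1)
    else:
        per_trial = psth.counts[:, :nb] / psth.bin_width
        mu = per_trial.mean()
        sd = per_trial.std(ddof=1) / np.sqrt(psth.n_trials)
    if sd == 0.0:
        return None
    return (psth.rates[nb:] - mu) / sd


def classify_response(z: np.ndarray | None, params: PSTHParams = PSTHParams()
                      ) -> tuple[str, bool]:
    """Label from the post-window z-scores: (label, mixed flag).

    Excited if any bin > threshold, inhibited if any bin < -threshold;
    when both occur the bin with the larger |z| decides and the response
    is flagged mixed; otherwise unresponsive.
    """
    if z is None:
        return "excluded", False
    thr = params.z_threshold
    has_exc = bool(np.any(z > thr))
    has_inh = bool(np.any(z < -thr))
    if has_exc and has_inh:
        label = "excited" if z.max() >= -z.min() else "inhibited"
        return label, True
    if has_exc:
        return "excited", False
    if has_inh:
        return "inhibited", False
    return "unresponsive", False


def apply_inclusion(
    mean_rate: float, n_withdrawal_trials: int, params: PSTHParams = PSTHParams()
) -> bool:
    """Inclusion rule: session mean rate >= 1 Hz AND >= 3 withdrawal trials.

    Boundaries are inclusive (a 1.0-Hz unit with exactly 3 trials is in).
    """
    return mean_rate >= params.min_rate and n_withdrawal_trials >= params.min_trials


def analyze_unit(
    unit_id: int,
    spike_times,
    onsets,
    params: PSTHParams = PSTHParams(),
    session_duration: float | None = None,
) -> UnitResponse:
    """Full per-unit chain: inclusion, PSTH, z-scores, label, magnitudes."""
    st = np.asarray(spike_times, float)
    onsets = np.asarray(onsets, float)
    if session_duration is not None:
        mean_rate = st.size / session_duration
    else:
        mean_rate = st.size / max(onsets.max() + params.post_window, 1e-9)
    if not apply_inclusion(mean_rate, onsets.size, params):
        return UnitResponse(unit_id, None, None, "excluded")
    psth = compute_psth(st, onsets, params, session_duration)
    z = zscore_psth(psth, params)
    label, mixed = classify_response(z, params)
    z_max = float(z.max()) if label == "excited" else None
    z_min = float(z.min()) if label == "inhibited" else None
    return UnitResponse(unit_id, psth, z, label, z_max, z_min, mixed)


def response_magnitudes(responses: list[UnitResponse]) -> pd.DataFrame:
    """Per-unit table of labels and max/min z, for group-level comparison.

    Returns an empty frame (with columns) when there are no responsive
    units, as an explicit marker.
    """
    rows = []
    for r in responses:
        rows.append(
            {
                "unit_id": r.unit_id,
                "label": r.label,
                "z_max": r.z_max,
                "z_min": r.z_min,
                "mixed": r.mixed,
            }
        )
    out = pd.DataFrame(rows, columns=["unit_id", "label", "z_max", "z_min", "mixed"])
    return out


# ---------------------------------------------------------------------------
# waveform features
# ---------------------------------------------------------------------------

@dataclass
class WaveformFeatures:
    """The six firing/waveform parameters of one unit.

    ``asymmetry`` is (t_baseline->early_peak - t_late_peak->return) /
    (t_baseline->early_peak + t_late_peak->return); times in seconds.
    """

    unit_id: int
    firing_rate: float
    isi_cv: float
    peak_to_peak: float
    peak_to_peak_time: float
    trough_to_return: float
    asymmetry: float
    classifiable: bool = True

    def as_row(self) -> dict:
        return {
            "unit_id": self.unit_id,
            **{name: getattr(self, name) for name in FEATURE_NAMES},
            "classifiable": self.classifiable,
        }


def _cross_time(x: np.ndarray, i0: int, i1: int, level: float, fs: float,
                rising: bool) -> float | None:
    """First crossing of ``level`` in x[i0:i1], linearly interpolated; None if absent."""
    seg = x[i0:i1]
    if rising:
        hits = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    else:
        hits = np.flatnonzero((seg[:-1] > level) & (seg[1:] <= level))
    if hits.size == 0:
        return None
    j = int(hits[0])
    y0, y1 = seg[j], seg[j + 1]
    frac = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
    return (i0 + j + frac) / fs


def _last_cross_time(x: np.ndarray, i1: int, level: float, fs: float) -> float | None:
    """Last upward crossing of ``level`` before index i1 (interpolated)."""
    seg = x[:i1]
    hits = np.flatnonzero((seg[:-1] <= level) & (seg[1:] > level))
    if hits.size == 0:
        return None
    j = int(hits[-1])
    y0, y1 = seg[j], seg[j + 1]
    frac = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
    return (j + frac) / fs


def extract_waveform_features(
    mean_waveform: np.ndarray,
    fs_wave: float,
    spike_times,
    session_duration: float | None = None,
    unit_id: int = -1,
    baseline_samples: int = 10,
    return_eps_frac: float = 0.01,
) -> WaveformFeatures:
    """Compute the six unit parameters from a mean waveform + spike train.

    Baseline is the mean of the first ``baseline_samples`` samples.
    Landmarks: global trough; the flanking early and late positive peaks;
    baseline crossings located by linear interpolation.  When the decaying
    tail never re-crosses the baseline level, the return is taken where it
    comes within ``return_eps_frac`` of the peak-to-peak amplitude of it.
    Units with undetectable landmarks are flagged unclassifiable.
    """
    w = np.asarray(mean_waveform, float)
    st = np.asarray(spike_times, float)
    if session_duration is None:
        session_duration = st[-1] if st.size else 1.0
    firing_rate = st.size / session_duration
    if st.size >= 3:
        isi = np.diff(st)
        isi_cv = float(isi.std(ddof=1) / isi.mean()) if isi.mean() > 0 else 0.0
    else:
        isi_cv = 0.0

    nan = float("nan")

    def _unclassifiable() -> WaveformFeatures:
        return WaveformFeatures(
            unit_id, firing_rate, isi_cv, nan, nan, nan, nan, classifiable=False
        )

    base = w[:baseline_samples].mean()
    p2p = float(w.max() - w.min())
    i_trough = int(np.argmin(w))
    if w[i_trough] >= base or i_trough in (0, w.size - 1):
        return _unclassifiable()
    i_early = int(np.argmax(w[:i_trough]))
    i_late = i_trough + int(np.argmax(w[i_trough:]))
    if w[i_early] <= base or w[i_late] <= base:
        return _unclassifiable()
    t_early, t_late = i_early / fs_wave, i_late / fs_wave
    peak_to_peak_time = t_late - t_early

    # trough -> first return to baseline (upward crossing after the trough)
    t_return1 = _cross_time(w, i_trough, w.size, base, fs_wave, rising=True)
    if t_return1 is None:
        return _unclassifiable()
    trough_to_return = t_return1 - i_trough / fs_wave

    # departure from baseline before the early peak
    t_dep = _last_cross_time(w, i_early + 1, base, fs_wave)
    if t_dep is None:
        t_dep = 0.0
    t_base_early = t_early - t_dep

    # decay back to baseline after the late peak
    t_return2 = _cross_time(w, i_late, w.size, base, fs_wave, rising=False)
    if t_return2 is None:
        near = np.flatnonzero(w[i_late:] - base < return_eps_frac * p2p)
        if near.size == 0:
            return _unclassifiable()
        t_return2 = (i_late + int(near[0])) / fs_wave
    t_late_return = t_return2 - t_late

    denom = t_base_early + t_late_return
    asym = (t_base_early - t_late_return) / denom if denom > 0 else nan
    if not np.isfinite(asym):
        return _unclassifiable()
    return WaveformFeatures(
        unit_id,
        firing_rate,
        isi_cv,
        p2p,
        peak_to_peak_time,
        trough_to_return,
        asym,
    )


# ---------------------------------------------------------------------------
# unit-type clustering
# ---------------------------------------------------------------------------

def cluster_unit_types(
    features: pd.DataFrame | list[WaveformFeatures],
    mode: str = "final",
    seed: int = 0,
    perplexity: float | None = None,
) -> np.ndarray:
    """Cluster units into class 1 (broad) / class 2 (narrow).

    ``mode='final'`` (default): k-means (k=2, 50 restarts) on the
    standardized (asymmetry, trough_to_return) pair.  ``mode='exploratory'``:
    2-D t-SNE of all six standardized features followed by k-means.  The
    cluster with the larger mean trough-to-return time is class 1.
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame([f.as_row() for f in features])
    if "classifiable" in features.columns and not features["classifiable"].all():
        raise ValueError("unclassifiable units present; filter them out first")
    if len(features) < 2:
        raise ValueError("need at least two units to cluster")
    if mode not in ("final", "exploratory"):
        raise ValueError("mode must be 'final' or 'exploratory'")
    cols = ["asymmetry", "trough_to_return"] if mode == "final" else FEATURE_NAMES
    X = features[cols].to_numpy(float)
    if np.allclose(X, X[0]):
        raise ValueError("all features identical; no cluster structure")
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0  # constant feature carries no information
    Z = (X - X.mean(axis=0)) / sd
    if mode == "exploratory":
        n = len(features)
        if perplexity is None:
            perplexity = 30.0 if n >= 120 else max(2.0, n / 4.0)
        Z = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        ).fit_transform(Z)
    km = KMeans(n_clusters=2, n_init=50, random_state=seed).fit(Z)
    ttr = features["trough_to_return"].to_numpy(float)
    mean0 = ttr[km.labels_ == 0].mean()
    mean1 = ttr[km.labels_ == 1].mean()
    broad_cluster = 0 if mean0 >= mean1 else 1
    return np.where(km.labels_ == broad_cluster, 1, 2)
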