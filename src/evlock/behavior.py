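"""Behavioral quantification.

Dixon up-down 50% withdrawal thresholds on the von Frey filament set,
per-force stimulus-response curves, thermal withdrawal latencies with a
30-s cutoff, and capsaicin nocifensive-duration tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "UpDownSequence",
    "dixon_k",
    "updown_threshold",
    "response_curve",
    "thermal_latency_summary",
    "nocifensive_duration",
]

DEFAULT_FILAMENTS = (0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4)


@dataclass
class UpDownSequence:
    """One up-down testing sequence on an ordered filament set.

    ``forces`` and ``responses`` are the presented forces (g) and the
    positive/negative outcomes (1/0).  The step constant delta is the
    mean log10 spacing of the filament set (the 7-filament series is not
    log-uniform, so a single representative spacing is used).
    """

    forces: list[float]
    responses: list[int]
    filament_set: tuple[float, ...] = DEFAULT_FILAMENTS

    def __post_init__(self) -> None:
        if len(self.forces) != len(self.responses):
            raise ValueError("forces and responses must have equal length")
        if len(self.forces) == 0:
            raise ValueError("empty sequence")
        fs = np.asarray(sorted(self.filament_set), float)
        for f in self.forces:
            if not np.any(np.isclose(fs, f)):
                raise ValueError(f"presented force {f} g not in the filament set")

    @property
    def delta(self) -> float:
        logs = np.log10(np.sort(np.asarray(self.filament_set, float)))
        return float(np.mean(np.diff(logs)))

    @property
    def pattern(self) -> str:
        """Response pattern, X = positive (withdrawal), O = negative."""
        return "".join("X" if r else "O" for r in self.responses)

    def validate_stepping(self) -> None:
        """Check the staircase path: down one filament after X, up after O."""
        fs = np.sort(np.asarray(self.filament_set, float))
        idx = [int(np.flatnonzero(np.isclose(fs, f))[0]) for f in self.forces]
        for j in range(len(idx) - 1):
            expected = idx[j] - 1 if self.responses[j] else idx[j] + 1
            if idx[j + 1] != expected:
                raise ValueError(
                    f"malformed stepping at presentation {j + 1}: force "
                    f"{self.forces[j + 1]} g does not follow a "
                    f"{'positive' if self.responses[j] else 'negative'} response "
                    f"at {self.forces[j]} g"
                )


def _pattern_levels(pattern: str) -> np.ndarray:
    """Relative staircase levels (in step units) implied by a response pattern."""
    levels = [0]
    for ch in pattern[:-1]:
        levels.append(levels[-1] - 1 if ch == "X" else levels[-1] + 1)
    return np.asarray(levels, float)


def _ml_mu(x: np.ndarray, y: np.ndarray, sigma: float, lo: float, hi: float) -> float:
    """Maximum-likelihood 50% point of a probit psychometric with fixed sigma."""

    def nll(mu: float) -> float:
        p = norm.cdf((x - mu) / sigma)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


@lru_cache(maxsize=None)
def dixon_k(pattern: str) -> float:
    """Correction constant k for a response pattern (X/O string).

    Defined so the 50% threshold estimate is ``x_f + k * delta`` in log
    units, with x_f the final presented level.  Computed as the
    maximum-likelihood 50% point of a probit psychometric whose spread
    equals the step size, evaluated on the idealized uniform staircase
    implied by the pattern (the construction underlying the published
    up-down k tables); values are cached per pattern.
    """
    if not pattern or any(c not in "XO" for c in pattern):
        raise ValueError("pattern must be a non-empty string over {X, O}")
    if len(set(pattern)) == 1:
        raise ValueError("pattern without a reversal has no finite estimate")
    levels = _pattern_levels(pattern)
    y = np.array([1.0 if c == "X" else 0.0 for c in pattern])
    # probit convention: response probability rises with level, i.e. a
    # positive response is evidence the level is above threshold
    mu = _ml_mu(levels, y, 1.0, levels.min() - 5.0, levels.max() + 5.0)
    return float(mu - levels[-1])


def updown_threshold(
    seq: UpDownSequence,
    check_stepping: bool = True,
) -> float:
    """Dixon up-down 50% withdrawal threshold in grams.

    threshold = 10 ** (X_f + k * delta), with X_f the log10 of the final
    force, delta the mean log10 filament spacing, and k the
    pattern-dependent correction constant.  Boundary conventions:
    all-positive sequences return the lowest force, all-negative the
    highest.  The result is clipped to the filament range.
    """
    if check_stepping:
        seq.validate_stepping()
    fs = np.sort(np.asarray(seq.filament_set, float))
    responses = np.asarray(seq.responses, int)
    if np.all(responses == 1):
        return float(fs[0])
    if np.all(responses == 0):
        return float(fs[-1])
    k = dixon_k(seq.pattern)
    xf = np.log10(seq.forces[-1])
    thr = 10.0 ** (xf + k * seq.delta)
    return float(np.clip(thr, fs[0], fs[-1]))


def response_curve(trials: pd.DataFrame, group_cols: list[str] | None = None
                   ) -> pd.DataFrame:
    """Percent positive responses per filament force.

    ``trials`` needs columns ``force_g`` and ``withdrawal`` (0/1); any
    ``group_cols`` (e.g. laser state, condition) split the curve.
    """
    required = {"force_g", "withdrawal"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    keys = (group_cols or []) + ["force_g"]
    grp = trials.groupby(keys)["withdrawal"]
    out = pd.DataFrame(
        {
            "n_presented": grp.count(),
            "n_positive": grp.sum(),
        }
    ).reset_index()
    out["percent_positive"] = 100.0 * out["n_positive"] / out["n_presented"]
    return out


def aggregate_response_curves(per_animal: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-animal mean +/- SEM of per-animal percent-positive curves."""
    frames = []
    for i, tab in enumerate(per_animal):
        t = tab.copy()
        t["animal"] = i
        frames.append(t)
    allt = pd.concat(frames, ignore_index=True)
    grp = allt.groupby("force_g")["percent_positive"]
    return pd.DataFrame(
        {
            "mean_percent": grp.mean(),
            "sem_percent": grp.sem(ddof=1),
            "n_animals": grp.count(),
        }
    ).reset_index()


def thermal_latency_summary(latencies, cutoff: float = 30.0) -> dict:
    """Mean withdrawal latency with censoring at the cutoff time.

    Latencies above the cutoff are clipped (with a warning) and the
    ``censored`` flag reports whether any trial hit the cutoff.
    """
    lat = np.asarray(latencies, float)
    if lat.size == 0:
        raise ValueError("no latencies supplied")
    over = lat > cutoff
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} latenc(ies) exceeded the {cutoff} s cutoff; clipped"
        )
    lat = np.minimum(lat, cutoff)
    return {
        "mean_latency_s": float(lat.mean()),
        "n_trials": int(lat.size),
        "censored": bool(np.any(lat >= cutoff)),
    }


def nocifensive_duration(intervals, window: float = 300.0) -> float:
    """Total time (s) in nocifensive behavior within the observation window.

    ``intervals`` is a sequence of (start, stop) pairs in seconds.
    Overlapping intervals are merged before summing; intervals are
    clipped to [0, window].
    """
    iv = sorted((float(a), float(b)) for a, b in intervals)
    total = 0.0
    cur_start, cur_stop = None, None
    for a, b in iv:
        if b < a:
            raise ValueError(f"interval ({a}, {b}) has negative length")
        a, b = max(a, 0.0), min(b, window)
        if b <= a:
            continue
        if cur_stop is None or a > cur_stop:
            if cur_stop is not None:
                total += cur_stop - cur_start
            cur_start, cur_stop = a, b
        else:
            cur_stop = max(cur_stop, b)
    if cur_stop is not None:
        total += cur_stop - cur_start
    return total
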