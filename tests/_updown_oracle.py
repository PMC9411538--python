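"""Independent brute-force oracle for the up-down k-table formula.

Kept separate from the implementation on purpose: grid-search ML rather
than the package's bounded scalar optimizer.
"""

import numpy as np
from scipy.stats import norm

from evlock.behavior import DEFAULT_FILAMENTS


def oracle_threshold(forces, responses, filament_set=DEFAULT_FILAMENTS):
    levels = [0.0]
    for r in responses[:-1]:
        levels.append(levels[-1] - 1 if r else levels[-1] + 1)
    levels = np.asarray(levels)
    y = np.asarray(responses, float)
    grid = np.arange(levels.min() - 5, levels.max() + 5, 1e-4)
    # response probability rises with level relative to mu: P = Phi(level - mu)
    p = norm.cdf(levels[:, None] - grid[None, :])
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = (y[:, None] * np.log(p) + (1 - y[:, None]) * np.log(1 - p)).sum(axis=0)
    mu = grid[np.argmax(ll)]
    k = mu - levels[-1]
    logs = np.log10(np.sort(np.asarray(filament_set)))
    delta = np.mean(np.diff(logs))
    thr = 10 ** (np.log10(forces[-1]) + k * delta)
    return float(np.clip(thr, min(filament_set), max(filament_set)))


def valid_patterns(n=6):
    """All n-presentation 0/1 patterns containing at least one reversal."""
    pats = []
    for bits in range(2**n):
        p = [(bits >> i) & 1 for i in range(n)]
        if len(set(p)) == 2:
            pats.append(p)
    return pats
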