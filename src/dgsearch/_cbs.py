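"""Numerical kernels for circular binary segmentation.

The change-point statistic is the classical CBS arc statistic: for probes
x[0:m] and an arc x[i:j] (the "inside" of the circle cut at i and j),

    T(i, j) = |mean(x[i:j]) - mean(rest)| / sqrt(1/k + 1/(m - k)),  k = j - i,

maximised over all arcs whose inside and outside both contain at least
``min_width`` probes.  The statistic is left unscaled by sigma: permutation
p-values are invariant to a common scale factor, and the caller divides by a
noise estimate only for reporting.

Kernels are numba-jitted when numba imports cleanly; a vectorised numpy
fallback implements the same algorithm otherwise.  Results are deterministic
for a fixed seed within either backend.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _max_arc_stat_py(x: np.ndarray, min_width: int):
    """Vectorised max arc statistic; returns (t, i, j)."""
    m = x.size
    S = np.concatenate(([0.0], np.cumsum(x)))
    tot = S[m]
    best_t, best_i, best_j = 0.0, 0, 0
    for k in range(min_width, m - min_width + 1):
        d = S[k:m + 1] - S[:m - k + 1]  # window sums, starts 0..m-k
        t = np.abs(d / k - (tot - d) / (m - k)) / np.sqrt(1.0 / k + 1.0 / (m - k))
        idx = int(np.argmax(t))
        if t[idx] > best_t:
            best_t, best_i, best_j = float(t[idx]), idx, idx + k
    return best_t, best_i, best_j


def _perm_exceed_count_py(x: np.ndarray, obs: float, n_perm: int,
                          min_width: int, seed: int) -> int:
    # Mirrors the jitted kernel's Fisher-Yates stream so both paths agree.
    np.random.seed(seed)
    xp = x.copy()
    m = xp.size
    count = 0
    for _ in range(n_perm):
        for i in range(m - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            xp[i], xp[j] = xp[j], xp[i]
        t, _, _ = _max_arc_stat_py(xp, min_width)
        if t >= obs:
            count += 1
    return count


if _HAVE_NUMBA:

    @njit(cache=True)
    def _max_arc_stat_nb(x, min_width):  # pragma: no cover - numba
        m = x.size
        S = np.empty(m + 1)
        S[0] = 0.0
        for i in range(m):
            S[i + 1] = S[i] + x[i]
        tot = S[m]
        best_t = 0.0
        best_i = 0
        best_j = 0
        for k in range(min_width, m - min_width + 1):
            denom = np.sqrt(1.0 / k + 1.0 / (m - k))
            for i in range(m - k + 1):
                d = S[i + k] - S[i]
                t = abs(d / k - (tot - d) / (m - k)) / denom
                if t > best_t:
                    best_t = t
                    best_i = i
                    best_j = i + k
        return best_t, best_i, best_j

    @njit(cache=True)
    def _perm_exceed_count_nb(x, obs, n_perm, min_width, seed):  # pragma: no cover
        np.random.seed(seed)
        xp = x.copy()
        m = xp.size
        count = 0
        for _ in range(n_perm):
            for i in range(m - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                tmp = xp[i]
                xp[i] = xp[j]
                xp[j] = tmp
            t, bi, bj = _max_arc_stat_nb(xp, min_width)
            if t >= obs:
                count += 1
        return count

    def max_arc_stat(x, min_width):
        t, i, j = _max_arc_stat_nb(np.ascontiguousarray(x, dtype=np.float64),
                                   min_width)
        return float(t), int(i), int(j)

    def perm_exceed_count(x, obs, n_perm, min_width, seed):
        return int(_perm_exceed_count_nb(
            np.ascontiguousarray(x, dtype=np.float64),
            float(obs), int(n_perm), int(min_width), int(seed)))

else:  # pragma: no cover

    def max_arc_stat(x, min_width):
        return _max_arc_stat_py(np.asarray(x, dtype=np.float64), min_width)

    def perm_exceed_count(x, obs, n_perm, min_width, seed):
        return _perm_exceed_count_py(np.asarray(x, dtype=np.float64),
                                     float(obs), int(n_perm),
                                     int(min_width), int(seed))
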