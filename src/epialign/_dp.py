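"""Dynamic-programming kernels for the chromatin state aligner.

Plain-loop implementations compiled with numba when it is available; the
pure-Python definitions are used as-is otherwise.  Both the full-matrix fill
(needed for traceback) and a two-row score-only variant (O(min(n1, n2))
memory) are provided.  Scoring: match +(w1+w2), mismatch -eps_n*(w1+w2),
deletion -eps_d*w; ``floor`` clamps every cell at zero (local modes).
"""

from __future__ import annotations

import numpy as np


def _fill_matrix(s1, s2, w1, w2, eps_n, eps_d, floor):
    n1 = s1.shape[0]
    n2 = s2.shape[0]
    m = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    for k in range(1, n1 + 1):
        for l in range(1, n2 + 1):
            pair = w1[k - 1] + w2[l - 1]
            if s1[k - 1] == s2[l - 1]:
                diag = m[k - 1, l - 1] + pair
            else:
                diag = m[k - 1, l - 1] - eps_n * pair
            up = m[k - 1, l] - eps_d * w1[k - 1]
            left = m[k, l - 1] - eps_d * w2[l - 1]
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            if floor and best < 0.0:
                best = 0.0
            m[k, l] = best
    return m


def _score_two_row(s1, s2, w1, w2, eps_n, eps_d, floor):
    """Return (value at cell (n1, n2), maximum over all cells)."""
    n1 = s1.shape[0]
    n2 = s2.shape[0]
    prev = np.zeros(n2 + 1, dtype=np.float64)
    cur = np.zeros(n2 + 1, dtype=np.float64)
    best_all = 0.0
    for k in range(1, n1 + 1):
        cur[0] = 0.0
        for l in range(1, n2 + 1):
            pair = w1[k - 1] + w2[l - 1]
            if s1[k - 1] == s2[l - 1]:
                diag = prev[l - 1] + pair
            else:
                diag = prev[l - 1] - eps_n * pair
            up = prev[l] - eps_d * w1[k - 1]
            left = cur[l - 1] - eps_d * w2[l - 1]
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            if floor and best < 0.0:
                best = 0.0
            cur[l] = best
            if best > best_all:
                best_all = best
        prev, cur = cur, prev
    return prev[n2], best_all


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _fill_matrix = njit(cache=True)(_fill_matrix)
    _score_two_row = njit(cache=True)(_score_two_row)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
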