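"""Local alignment of compressed chromatin state sequences.

The aligner is a modified Smith-Waterman dynamic program over run-length
compressed state sequences.  An alignment is a set of triplets (f_i, u_1i,
u_2i): a status string F over {m, n, d1, d2} (match, mismatch, deletion in
S1, deletion in S2) with 1-based index vectors U1 and U2 into the two
sequences (0 marks the gap side of a deletion).  Step scores are built from
per-state weights W:

    match       +(W(k, S1) + W(l, S2))
    mismatch    -eps_n * (W(k, S1) + W(l, S2))
    deletion    -eps_d * W(k, S)

with mismatch and deletion penalties eps_n (default 1.5) and eps_d (default
1).  Three scoring modes are offered:

``endpoint``
    the zero-floored recursion read at the final cell (n1, n2) -- an
    end-anchored local score, and the default;
``max``
    classic Smith-Waterman: the maximum over all cells of the floored
    recursion (preferred by the tiling/scan workflows, where shared patterns
    sit anywhere inside a window);
``global``
    the unfloored recursion with zero boundaries, read at (n1, n2).

The discrepancy between an end-anchored score and a true local maximum is
inherent to the formulation; both are exposed and documented rather than
resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Optional

import numpy as np

from ._dp import _fill_matrix, _score_two_row
from .state_model import CompressedSequence, FrequencyTable, StateAlphabet

__all__ = [
    "WeightTable",
    "ScoreParams",
    "Alignment",
    "make_weights",
    "step_score",
    "align",
    "align_score",
    "alignment_score_of",
    "brute_force_align",
    "format_alignment",
    "AlignmentResourceError",
]

MODES = ("endpoint", "max", "global")

#: refuse full-traceback DP above this many cells (~20k x 20k)
MAX_TRACEBACK_CELLS = 4 * 10**8


class AlignmentResourceError(MemoryError):
    """Raised when a traceback matrix would be unreasonably large."""


@dataclass(frozen=True)
class WeightTable:
    """Per-state weights w(s) > 0; W(k, S) is the weight of the k-th state of S."""

    weights: np.ndarray  # index s-1 -> w(s)
    scheme: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty vector")
        if not np.all(w > 0):
            raise ValueError("all state weights must be strictly positive")
        if self.scheme == "equal" and not np.allclose(w, 1.0):
            raise ValueError("equal scheme requires all weights == 1")
        object.__setattr__(self, "weights", w)

    def w(self, state: int) -> float:
        if not 1 <= state <= self.weights.size:
            raise ValueError(f"state {state} outside weight table")
        return float(self.weights[state - 1])

    def for_sequence(self, seq: CompressedSequence) -> np.ndarray:
        """Positional weight vector W(., S)."""
        if len(seq) and seq.states.max() > self.weights.size:
            raise ValueError("sequence contains states outside the weight table")
        return self.weights[seq.states - 1] if len(seq) else np.empty(0)


def make_weights(
    scheme: str,
    alphabet: StateAlphabet,
    freq: Optional[FrequencyTable] = None,
    custom: Optional[dict[int, float]] = None,
) -> WeightTable:
    """Build a weight table.

    ``equal``
        every state weighs 1 (the published default).
    ``frequency``
        w(s) = -log f(s), rescaled so the frequency-weighted mean weight
        sum_s f(s) w(s) equals 1: positive, decreasing in frequency, and on
        the same scale as equal weights.  States absent from ``freq`` are
        assigned the largest observed weight (they are at most as common as
        the rarest observed state).
    ``custom``
        user-supplied strictly positive weights.
    """
    q = alphabet.size
    if scheme == "equal":
        return WeightTable(np.ones(q), scheme="equal")
    if scheme == "frequency":
        if freq is None:
            raise ValueError("frequency scheme requires a FrequencyTable")
        w = np.full(q, np.nan)
        for s, f in freq.items():
            if not 1 <= s <= q:
                raise ValueError(f"frequency table state {s} outside alphabet")
            if f <= 0:
                raise ValueError(f"state {s} has non-positive frequency {f}")
            w[s - 1] = -math.log(f)
        mean = sum(f * w[s - 1] for s, f in freq.items())
        if mean <= 0:
            raise ValueError(
                "degenerate frequency table: cannot rescale -log f weights"
            )
        w = w / mean
        w[np.isnan(w)] = np.nanmax(w)
        return WeightTable(w, scheme="frequency")
    if scheme == "custom":
        if custom is None:
            raise ValueError("custom scheme requires a weight mapping")
        w = np.ones(q)
        for s, v in custom.items():
            if not 1 <= s <= q:
                raise ValueError(f"custom weight state {s} outside alphabet")
            if v <= 0:
                raise ValueError(f"custom weight for state {s} must be positive")
            w[s - 1] = v
        return WeightTable(w, scheme="custom")
    raise ValueError(f"unknown weight scheme {scheme!r}")


@dataclass(frozen=True)
class ScoreParams:
    """Alignment parameters: penalties, weights, and scoring mode."""

    eps_n: float = 1.5
    eps_d: float = 1.0
    weights: Optional[WeightTable] = None  # None -> equal weights
    mode: str = "endpoint"

    def __post_init__(self) -> None:
        if self.eps_n < 0 or self.eps_d < 0:
            raise ValueError("penalty parameters must be non-negative")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def weight_vector(self, seq: CompressedSequence) -> np.ndarray:
        if self.weights is None:
            return np.ones(len(seq))
        return self.weights.for_sequence(seq)


@dataclass(frozen=True)
class Alignment:
    """An alignment (F, U1, U2) with its score and per-step scores.

    ``span1``/``span2`` are the 1-based inclusive index ranges of the two
    sequences covered by the alignment (None when empty).
    """

    F: tuple[str, ...]
    U1: np.ndarray
    U2: np.ndarray
    score: float
    step_scores: np.ndarray
    span1: Optional[tuple[int, int]]
    span2: Optional[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.F)


def step_score(
    status: str,
    k: int,
    l: int,
    s1: CompressedSequence,
    s2: CompressedSequence,
    params: Optional[ScoreParams] = None,
) -> float:
    """Score h(f, u1, u2, S1, S2) of one alignment step (1-based k, l)."""
    params = params or ScoreParams()
    w1 = params.weight_vector(s1)
    w2 = params.weight_vector(s2)
    if status in ("m", "n"):
        if not (1 <= k <= len(s1) and 1 <= l <= len(s2)):
            raise ValueError(f"indices ({k},{l}) out of range")
        equal = s1.states[k - 1] == s2.states[l - 1]
        if status == "m" and not equal:
            raise ValueError(f"match requested for unequal states at ({k},{l})")
        if status == "n" and equal:
            raise ValueError(f"mismatch requested for equal states at ({k},{l})")
        pair = w1[k - 1] + w2[l - 1]
        return float(pair if status == "m" else -params.eps_n * pair)
    if status == "d1":
        if not 1 <= k <= len(s1):
            raise ValueError(f"index {k} out of range in S1")
        return float(-params.eps_d * w1[k - 1])
    if status == "d2":
        if not 1 <= l <= len(s2):
            raise ValueError(f"index {l} out of range in S2")
        return float(-params.eps_d * w2[l - 1])
    raise ValueError(f"unknown alignment status {status!r}")


def _check_compatible(s1: CompressedSequence, s2: CompressedSequence) -> None:
    if (
        s1.alphabet is not None
        and s2.alphabet is not None
        and s1.alphabet != s2.alphabet
    ):
        raise ValueError("sequences use different state alphabets")


def _empty_alignment(score: float = 0.0) -> Alignment:
    return Alignment(
        F=(),
        U1=np.empty(0, dtype=np.int64),
        U2=np.empty(0, dtype=np.int64),
        score=float(score),
        step_scores=np.empty(0),
        span1=None,
        span2=None,
    )


def align_score(
    s1: CompressedSequence,
    s2: CompressedSequence,
    params: Optional[ScoreParams] = None,
) -> float:
    """Alignment score only, in O(min(n1, n2)) memory (no traceback)."""
    params = params or ScoreParams()
    _check_compatible(s1, s2)
    if len(s1) == 0 or len(s2) == 0:
        return 0.0
    w1 = params.weight_vector(s1).astype(np.float64)
    w2 = params.weight_vector(s2).astype(np.float64)
    endpoint, best = _score_two_row(
        s1.states, s2.states, w1, w2, params.eps_n, params.eps_d,
        params.mode != "global",
    )
    return float(best if params.mode == "max" else endpoint)


def align(
    s1: CompressedSequence,
    s2: CompressedSequence,
    params: Optional[ScoreParams] = None,
    return_matrix: bool = False,
):
    """Align two compressed state sequences; returns an :class:`Alignment`.

    With ``return_matrix=True`` also returns the (n1+1) x (n2+1) DP matrix.
    Traceback ties are broken in the order match > mismatch > deletion in S1
    > deletion in S2 > zero reset (favoring contiguous diagonals).
    """
    params = params or ScoreParams()
    _check_compatible(s1, s2)
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        aln = _empty_alignment()
        return (aln, np.zeros((n1 + 1, n2 + 1))) if return_matrix else aln
    if n1 * n2 > MAX_TRACEBACK_CELLS:
        raise AlignmentResourceError(
            f"traceback matrix {n1} x {n2} exceeds {MAX_TRACEBACK_CELLS} cells; "
            "use align_score() for a score-only run"
        )
    w1 = params.weight_vector(s1).astype(np.float64)
    w2 = params.weight_vector(s2).astype(np.float64)
    floor = params.mode != "global"
    m = _fill_matrix(s1.states, s2.states, w1, w2, params.eps_n, params.eps_d, floor)

    if params.mode == "max":
        flat = int(np.argmax(m))  # row-major: smallest k, then smallest l on ties
        k, l = divmod(flat, n2 + 1)
        score = float(m[k, l])
    else:
        k, l = n1, n2
        score = float(m[n1, n2])

    states1, states2 = s1.states, s2.states
    rev_f: list[str] = []
    rev_u1: list[int] = []
    rev_u2: list[int] = []
    rev_steps: list[float] = []
    while k > 0 and l > 0:
        v = m[k, l]
        pair = w1[k - 1] + w2[l - 1]
        if states1[k - 1] == states2[l - 1]:
            diag_step, diag_status = pair, "m"
        else:
            diag_step, diag_status = -params.eps_n * pair, "n"
        if v == m[k - 1, l - 1] + diag_step:
            rev_f.append(diag_status)
            rev_u1.append(k)
            rev_u2.append(l)
            rev_steps.append(diag_step)
            k -= 1
            l -= 1
        elif v == m[k - 1, l] - params.eps_d * w1[k - 1]:
            rev_f.append("d1")
            rev_u1.append(k)
            rev_u2.append(0)
            rev_steps.append(-params.eps_d * w1[k - 1])
            k -= 1
        elif v == m[k, l - 1] - params.eps_d * w2[l - 1]:
            rev_f.append("d2")
            rev_u1.append(0)
            rev_u2.append(l)
            rev_steps.append(-params.eps_d * w2[l - 1])
            l -= 1
        else:  # zero-reset cell (local modes)
            break

    f = tuple(reversed(rev_f))
    u1 = np.array(list(reversed(rev_u1)), dtype=np.int64)
    u2 = np.array(list(reversed(rev_u2)), dtype=np.int64)
    steps = np.array(list(reversed(rev_steps)))
    nz1 = u1[u1 > 0]
    nz2 = u2[u2 > 0]
    aln = Alignment(
        F=f,
        U1=u1,
        U2=u2,
        score=score,
        step_scores=steps,
        span1=(int(nz1.min()), int(nz1.max())) if nz1.size else None,
        span2=(int(nz2.min()), int(nz2.max())) if nz2.size else None,
    )
    return (aln, m) if return_matrix else aln


def alignment_score_of(
    f,
    u1,
    u2,
    s1: CompressedSequence,
    s2: CompressedSequence,
    params: Optional[ScoreParams] = None,
) -> float:
    """Recompute the score of an explicit alignment (F, U1, U2).

    Pure audit function: validates the structural invariants and returns the
    sum of per-step scores.
    """
    params = params or ScoreParams()
    f = tuple(f)
    u1 = np.asarray(u1, dtype=np.int64)
    u2 = np.asarray(u2, dtype=np.int64)
    if not (len(f) == u1.size == u2.size):
        raise ValueError("F, U1 and U2 must have equal lengths")
    last1 = last2 = 0
    total = 0.0
    for i, status in enumerate(f):
        a, b = int(u1[i]), int(u2[i])
        if status in ("m", "n"):
            if a == 0 or b == 0:
                raise ValueError(f"step {i}: {status} requires both indices nonzero")
        elif status == "d1":
            if a == 0 or b != 0:
                raise ValueError(f"step {i}: d1 requires U1 nonzero and U2 == 0")
        elif status == "d2":
            if b == 0 or a != 0:
                raise ValueError(f"step {i}: d2 requires U2 nonzero and U1 == 0")
        else:
            raise ValueError(f"step {i}: unknown status {status!r}")
        if a:
            if a <= last1:
                raise ValueError(f"step {i}: U1 not strictly increasing")
            last1 = a
        if b:
            if b <= last2:
                raise ValueError(f"step {i}: U2 not strictly increasing")
            last2 = b
        total += step_score(status, a, b, s1, s2, params)
    return total


def _enumerate_full(a, b, wa, wb, eps_n, eps_d):
    """Best score over all monotone edit paths consuming a and b completely.

    Deliberately unmemoized exponential recursion: the independent oracle.
    """
    if not a and not b:
        return 0.0
    best = -math.inf
    if a and b:
        pair = wa[-1] + wb[-1]
        step = pair if a[-1] == b[-1] else -eps_n * pair
        best = _enumerate_full(a[:-1], b[:-1], wa[:-1], wb[:-1], eps_n, eps_d) + step
    if a:
        cand = _enumerate_full(a[:-1], b, wa[:-1], wb, eps_n, eps_d) - eps_d * wa[-1]
        best = max(best, cand)
    if b:
        cand = _enumerate_full(a, b[:-1], wa, wb[:-1], eps_n, eps_d) - eps_d * wb[-1]
        best = max(best, cand)
    return best


def brute_force_align(
    s1: CompressedSequence,
    s2: CompressedSequence,
    params: Optional[ScoreParams] = None,
    max_len: int = 7,
) -> float:
    """Exhaustive-enumeration score for tiny sequences (test oracle).

    endpoint: max(0, best full-alignment score over all suffix pairs);
    max: same over all substring pairs; global: suffix pairs where one side
    is the whole sequence, no floor.
    """
    params = params or ScoreParams()
    n1, n2 = len(s1), len(s2)
    if n1 > max_len or n2 > max_len:
        raise ValueError(f"brute force limited to length {max_len}")
    a = tuple(int(x) for x in s1.states)
    b = tuple(int(x) for x in s2.states)
    wa = tuple(float(x) for x in params.weight_vector(s1))
    wb = tuple(float(x) for x in params.weight_vector(s2))
    en, ed = params.eps_n, params.eps_d

    if params.mode == "endpoint":
        best = 0.0
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                best = max(best, _enumerate_full(a[i:], b[j:], wa[i:], wb[j:], en, ed))
        return best
    if params.mode == "max":
        best = 0.0
        for i in range(n1 + 1):
            for k in range(i, n1 + 1):
                for j in range(n2 + 1):
                    for l in range(j, n2 + 1):
                        best = max(
                            best,
                            _enumerate_full(
                                a[i:k], b[j:l], wa[i:k], wb[j:l], en, ed
                            ),
                        )
        return best
    # global: zero boundaries make leading gaps on either side free
    best = -math.inf
    for i in range(n1 + 1):
        best = max(best, _enumerate_full(a[i:], b, wa[i:], wb, en, ed))
    for j in range(n2 + 1):
        best = max(best, _enumerate_full(a, b[j:], wa, wb[j:], en, ed))
    return best


def format_alignment(
    aln: Alignment,
    s1: CompressedSequence,
    s2: CompressedSequence,
    params: Optional[ScoreParams] = None,
    alphabet: Optional[StateAlphabet] = None,
) -> str:
    """Human-readable pairwise report: S1 row, status gutter, S2 row."""
    params = params or ScoreParams()
    alphabet = alphabet or s1.alphabet or s2.alphabet

    def name(seq, idx):  # idx 1-based; 0 -> gap
        if idx == 0:
            return "-"
        s = int(seq.states[idx - 1])
        return alphabet.label(s) if alphabet else str(s)

    top, mid, bot = [], [], []
    for status, a, b in zip(aln.F, aln.U1.tolist(), aln.U2.tolist()):
        t, u = name(s1, a), name(s2, b)
        width = max(len(t), len(u))
        marker = {"m": "|", "n": "."}.get(status, "-")
        top.append(t.rjust(width))
        mid.append(marker.rjust(width))
        bot.append(u.rjust(width))
    header = (
        f"score={aln.score:g} mode={params.mode} "
        f"eps_n={params.eps_n:g} eps_d={params.eps_d:g} "
        f"weights={params.weights.scheme if params.weights else 'equal'}"
    )
    if not aln.F:
        return header + "\n(empty alignment)"
    return "\n".join([header, " ".join(top), " ".join(mid), " ".join(bot)])
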