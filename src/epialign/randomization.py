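"""Permutation null model and normalized alignment scores.

Raw alignment scores of different query sequences are not comparable, so
each score is standardized against a negative control: the target's
(state, run length) segments are permuted uniformly -- preserving state
composition and segment-length distribution while destroying sequential
order -- and the query is re-aligned to B such randomizations.  The
normalized score is the z-score of the real alignment against that
empirical null.  The same segment permutation applied chromosome-wide
produces randomized epigenomes, and alternating real/randomized tiles
produce the two hybrid epigenomes used as semi-negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .aligner import ScoreParams, align_score
from .segmentation_io import GenomicRegion, SegmentationTrack, tile_genome
from .state_model import CompressedSequence

__all__ = [
    "NormalizedScore",
    "randomize_sequence",
    "normalized_score",
    "randomize_track",
    "make_hybrids",
]

#: floor on the null standard deviation when standardizing
TAU = 1e-8

RngLike = Union[np.random.Generator, int, None]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class NormalizedScore:
    """A raw alignment score standardized against a permutation null."""

    raw: float
    null_mean: float
    null_sd: float
    z: float
    B: int
    seed: Optional[int] = None
    degenerate_null: bool = False


def randomize_sequence(
    c: CompressedSequence, rng: RngLike = None
) -> CompressedSequence:
    """Uniformly permute a sequence's (state, run) segments, then re-merge.

    Any now-adjacent equal states are merged (their run lengths summed), so
    the result is a valid compressed sequence with the same state multiset
    up to such merges.
    """
    if len(c) == 0:
        raise ValueError("cannot randomize an empty sequence")
    rng = _as_rng(rng)
    perm = rng.permutation(len(c))
    states = c.states[perm]
    runs = c.run_lengths[perm]
    # merge adjacent equal states created by the permutation
    out_states: list[int] = []
    out_runs: list[int] = []
    for s, r in zip(states.tolist(), runs.tolist()):
        if out_states and out_states[-1] == s:
            out_runs[-1] += r
        else:
            out_states.append(s)
            out_runs.append(r)
    return CompressedSequence(
        np.array(out_states, dtype=np.int64),
        np.array(out_runs, dtype=np.int64),
        alphabet=c.alphabet,
    )


def normalized_score(
    query: CompressedSequence,
    target: CompressedSequence,
    params: Optional[ScoreParams] = None,
    B: int = 100,
    rng: RngLike = None,
) -> NormalizedScore:
    """z-score of align(query, target) against B target randomizations."""
    if len(query) == 0 or len(target) == 0:
        raise ValueError("query and target must be non-empty")
    if B < 2:
        raise ValueError("need B >= 2 randomizations")
    params = params or ScoreParams()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = _as_rng(rng)
    raw = align_score(query, target, params)
    null = np.array(
        [align_score(query, randomize_sequence(target, rng), params) for _ in range(B)]
    )
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    degenerate = sd < TAU
    z = (raw - mean) / max(sd, TAU)
    return NormalizedScore(
        raw=raw,
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        B=B,
        seed=None if seed is None else int(seed),
        degenerate_null=degenerate,
    )


def randomize_track(track: SegmentationTrack, rng: RngLike = None) -> SegmentationTrack:
    """Permute each chromosome's segments and re-lay them end-to-end.

    Per-state total annotated length and the segment-length distribution are
    preserved exactly; only the order is destroyed.
    """
    rng = _as_rng(rng)
    out: dict[str, np.ndarray] = {}
    for chrom, arr in track.intervals.items():
        if arr.shape[0] == 0:
            out[chrom] = arr.copy()
            continue
        lengths = arr[:, 1] - arr[:, 0]
        states = arr[:, 2]
        perm = rng.permutation(arr.shape[0])
        lengths = lengths[perm]
        states = states[perm]
        starts = int(arr[0, 0]) + np.concatenate(([0], np.cumsum(lengths)[:-1]))
        out[chrom] = np.column_stack((starts, starts + lengths, states))
    return SegmentationTrack(out, track.alphabet, bin_width=track.bin_width)


def _slice_track(track: SegmentationTrack, region: GenomicRegion) -> np.ndarray:
    """Rows of a track clipped to a region."""
    arr = track.intervals.get(region.chrom)
    if arr is None or arr.size == 0:
        return np.empty((0, 3), dtype=np.int64)
    keep = (arr[:, 1] > region.start) & (arr[:, 0] < region.end)
    rows = arr[keep].copy()
    if rows.size:
        rows[:, 0] = np.maximum(rows[:, 0], region.start)
        rows[:, 1] = np.minimum(rows[:, 1], region.end)
    return rows


def make_hybrids(
    real: SegmentationTrack,
    randomized: SegmentationTrack,
    bin_size: int = 500_000,
) -> tuple[SegmentationTrack, SegmentationTrack]:
    """Build the two alternating real/randomized hybrid epigenomes.

    Both tracks are tiled into ``bin_size`` windows; hybrid A takes real
    tiles at even indices (per chromosome) and randomized tiles at odd
    indices, hybrid B is the complementary phase.  Each tile's provenance is
    recorded on the returned tracks (``provenance[tile name]`` is ``"real"``
    or ``"randomized"``).
    """
    if set(real.chroms) != set(randomized.chroms):
        raise ValueError("real and randomized tracks cover different chromosomes")
    tiles = tile_genome(real, bin_size=bin_size)
    parts_a: dict[str, list[np.ndarray]] = {}
    parts_b: dict[str, list[np.ndarray]] = {}
    prov_a: dict[str, str] = {}
    prov_b: dict[str, str] = {}
    index_in_chrom: dict[str, int] = {}
    for tile in tiles:
        i = index_in_chrom.get(tile.chrom, 0)
        index_in_chrom[tile.chrom] = i + 1
        real_rows = _slice_track(real, tile)
        rand_rows = _slice_track(randomized, tile)
        if i % 2 == 0:
            a_rows, b_rows = real_rows, rand_rows
            prov_a[tile.display_name] = "real"
            prov_b[tile.display_name] = "randomized"
        else:
            a_rows, b_rows = rand_rows, real_rows
            prov_a[tile.display_name] = "randomized"
            prov_b[tile.display_name] = "real"
        parts_a.setdefault(tile.chrom, []).append(a_rows)
        parts_b.setdefault(tile.chrom, []).append(b_rows)
    hybrid_a = SegmentationTrack(
        {c: np.vstack(p) for c, p in parts_a.items()},
        real.alphabet,
        bin_width=real.bin_width,
        provenance=prov_a,
    )
    hybrid_b = SegmentationTrack(
        {c: np.vstack(p) for c, p in parts_b.items()},
        real.alphabet,
        bin_width=real.bin_width,
        provenance=prov_b,
    )
    return hybrid_a, hybrid_b
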