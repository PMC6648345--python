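"""Synthetic chromatin state segmentations with controlled structure.

The generator emulates the gross statistics of real multi-state
segmentations: a dominant quiescent state covering most of the genome in
long stretches, geometric (memoryless) dwell times per state, and -- as the
planted signal -- recurrent chromatin state motifs (short state successions
such as 'egeg') written into chosen genome tiles.  Everything is a pure
function of (config, seed), so every workflow is testable without
downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .randomization import RngLike, _as_rng
from .segmentation_io import SegmentationTrack, tile_genome
from .state_model import StateAlphabet, CompressedSequence, compress, RawStateSequence

__all__ = [
    "MotifSpec",
    "SimulationConfig",
    "simulate_track",
    "plant_motif",
    "simulate_cohort",
    "write_groups",
    "read_groups",
]


@dataclass(frozen=True)
class MotifSpec:
    """A recurrent state motif to plant: letters, copies per tile, target tiles."""

    letters: str
    tiles: tuple[int, ...]
    copies: int = 1
    run_bins: int = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Background model for one synthetic epigenome.

    The quiescent state is state Q; by default it holds 60% of the
    stationary mass and dwells 50 bins on average, against 3 bins for every
    other state -- long quiescent stretches over a busy foreground, as in
    real segmentations.
    """

    Q: int = 15
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    stationary: Optional[tuple[float, ...]] = None
    dwell_mean_bins: Optional[tuple[float, ...]] = None
    motifs: tuple[MotifSpec, ...] = ()
    bin_width: int = 200
    tile_size: int = 500_000
    seed: int = 0
    quiescent_mass: float = 0.6
    quiescent_dwell: float = 50.0
    foreground_dwell: float = 3.0

    def resolved_stationary(self) -> np.ndarray:
        if self.stationary is not None:
            p = np.asarray(self.stationary, dtype=float)
            if p.size != self.Q or abs(p.sum() - 1) > 1e-9 or p.min() < 0:
                raise ValueError("stationary must be a length-Q probability vector")
            return p
        p = np.full(self.Q, (1 - self.quiescent_mass) / max(self.Q - 1, 1))
        p[-1] = self.quiescent_mass if self.Q > 1 else 1.0
        return p

    def resolved_dwell(self) -> np.ndarray:
        if self.dwell_mean_bins is not None:
            d = np.asarray(self.dwell_mean_bins, dtype=float)
            if d.size != self.Q or d.min() < 1:
                raise ValueError("dwell means must be length Q and >= 1")
            return d
        d = np.full(self.Q, self.foreground_dwell)
        d[-1] = self.quiescent_dwell
        return d

    def alphabet(self) -> StateAlphabet:
        return StateAlphabet.roadmap15() if self.Q == 15 else StateAlphabet.from_size(self.Q)


def simulate_track(cfg: SimulationConfig) -> SegmentationTrack:
    """Draw one synthetic segmentation track (then plant cfg.motifs, if any).

    Per chromosome, successive (state, run) pairs are drawn with the state
    sampled from the stationary distribution conditioned on differing from
    the previous state and the run geometric with that state's mean dwell,
    until the chromosome is filled.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    stationary = cfg.resolved_stationary()
    dwell = cfg.resolved_dwell()
    alphabet = cfg.alphabet()
    intervals: dict[str, np.ndarray] = {}
    for chrom, length_bp in cfg.chrom_lengths.items():
        n_bins = -(-length_bp // cfg.bin_width)  # ceil
        states: list[int] = []
        runs: list[int] = []
        prev = 0
        filled = 0
        while filled < n_bins:
            p = stationary.copy()
            if prev:
                p[prev - 1] = 0.0
                total = p.sum()
                if total == 0.0:  # all mass on one state: runs just extend
                    p = stationary.copy()
                else:
                    p = p / total
            state = int(rng.choice(cfg.Q, p=p)) + 1
            run = int(rng.geometric(1.0 / dwell[state - 1]))
            run = min(run, n_bins - filled)
            if states and states[-1] == state:
                runs[-1] += run
            else:
                states.append(state)
                runs.append(run)
            filled += run
            prev = state
        starts_bins = np.concatenate(([0], np.cumsum(runs)[:-1]))
        starts = starts_bins * cfg.bin_width
        ends = np.minimum((starts_bins + np.array(runs)) * cfg.bin_width, length_bp)
        intervals[chrom] = np.column_stack((starts, ends, np.array(states)))
    track = SegmentationTrack(intervals, alphabet, bin_width=cfg.bin_width)
    for motif in cfg.motifs:
        track = plant_motif(
            track,
            motif.letters,
            motif.tiles,
            run_bins_per_state=motif.run_bins,
            rng=rng,
            copies=motif.copies,
            tile_size=cfg.tile_size,
        )
    return track


def _chrom_raw_bins(track: SegmentationTrack, chrom: str) -> np.ndarray:
    """Per-bin state array for a fully annotated chromosome."""
    arr = track.intervals[chrom]
    lengths_bp = arr[:, 1] - arr[:, 0]
    n_bins = np.maximum(1, np.round(lengths_bp / track.bin_width)).astype(np.int64)
    return np.repeat(arr[:, 2], n_bins)


def _raw_bins_to_intervals(
    raw: np.ndarray, bin_width: int, length_bp: int
) -> np.ndarray:
    c = compress(RawStateSequence(raw, bin_width=bin_width))
    starts_bins = np.concatenate(([0], np.cumsum(c.run_lengths)[:-1]))
    starts = starts_bins * bin_width
    ends = np.minimum((starts_bins + c.run_lengths) * bin_width, length_bp)
    return np.column_stack((starts, ends, c.states))


def plant_motif(
    track: SegmentationTrack,
    motif_letters: str,
    tile_indices: Sequence[int],
    run_bins_per_state: int = 2,
    rng: RngLike = None,
    copies: int = 1,
    tile_size: int = 500_000,
) -> SegmentationTrack:
    """Overwrite a state motif into chosen genome tiles at random offsets.

    The motif's state succession (each state lasting ``run_bins_per_state``
    bins) replaces the background in place, so chromosome lengths are
    unchanged and every planted tile's compressed sequence contains the
    motif as a contiguous substring.
    """
    rng = _as_rng(rng)
    alphabet = track.alphabet
    motif_states = np.array(
        [alphabet.state_of_letter(ch) for ch in motif_letters], dtype=np.int64
    )
    if motif_states.size > 1 and np.any(motif_states[1:] == motif_states[:-1]):
        raise ValueError("motif must not contain two equal adjacent states")
    motif_bins = np.repeat(motif_states, run_bins_per_state)
    tiles = tile_genome(track, bin_size=tile_size)
    raw = {chrom: _chrom_raw_bins(track, chrom) for chrom in track.chroms}
    for idx in tile_indices:
        tile = tiles[idx]
        tile_start = tile.start // track.bin_width
        tile_bins = tile.length // track.bin_width
        if motif_bins.size > tile_bins:
            raise ValueError(
                f"motif of {motif_bins.size} bins does not fit tile of {tile_bins}"
            )
        for _ in range(copies):
            off = int(rng.integers(0, tile_bins - motif_bins.size + 1))
            pos = tile_start + off
            raw[tile.chrom][pos : pos + motif_bins.size] = motif_bins
    intervals = {
        chrom: _raw_bins_to_intervals(
            bins, track.bin_width, int(track.intervals[chrom][-1, 1])
        )
        for chrom, bins in raw.items()
    }
    return SegmentationTrack(
        intervals, alphabet, bin_width=track.bin_width, provenance=track.provenance
    )


def simulate_cohort(
    n_per_group: int,
    groups: Sequence[str],
    shared_motif_per_group: dict[str, str],
    cfg: SimulationConfig,
    motif_tiles: Sequence[int] = (1,),
    copies: int = 2,
    run_bins_per_state: int = 2,
) -> list[tuple[SegmentationTrack, str]]:
    """Simulate a multi-group cohort with group-specific recurrent motifs.

    All tracks share the background parameters of ``cfg`` (with
    per-track seeds derived from ``cfg.seed``); each group's motif is
    planted in the same genomic tile(s) of every track in that group, at
    track-specific random offsets.  The synthetic analogue of comparing
    e.g. brain vs heart epigenomes at one gene.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    master = np.random.default_rng(cfg.seed)
    out: list[tuple[SegmentationTrack, str]] = []
    for label in groups:
        motif = shared_motif_per_group[label]
        for _ in range(n_per_group):
            seed = int(master.integers(0, 2**31 - 1))
            base_cfg = SimulationConfig(
                Q=cfg.Q,
                chrom_lengths=cfg.chrom_lengths,
                stationary=cfg.stationary,
                dwell_mean_bins=cfg.dwell_mean_bins,
                bin_width=cfg.bin_width,
                tile_size=cfg.tile_size,
                seed=seed,
                quiescent_mass=cfg.quiescent_mass,
                quiescent_dwell=cfg.quiescent_dwell,
                foreground_dwell=cfg.foreground_dwell,
            )
            track = simulate_track(base_cfg)
            track = plant_motif(
                track,
                motif,
                motif_tiles,
                run_bins_per_state=run_bins_per_state,
                rng=np.random.default_rng(seed + 1),
                copies=copies,
                tile_size=cfg.tile_size,
            )
            out.append((track, label))
    return out


def write_groups(path, names_labels: Sequence[tuple[str, str]]) -> None:
    """Write a two-column (sample, group) TSV."""
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for name, label in names_labels:
            fh.write(f"{name}\t{label}\n")


def read_groups(path) -> dict[str, str]:
    """Read a (sample, group) TSV back into a mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, label = line.split("\t")
            out[name] = label
    return out
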