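"""Read/write ChromHMM-style segmentation BED files; regions and genome tiling.

A segmentation track stores one epigenome's chromatin state annotation as
per-chromosome sorted, non-overlapping ``(start, end, state)`` intervals in
BED coordinates (0-based, half-open).  State labels in the input may be
ChromHMM ``E<k>``, mnemonic ``<k>_<name>``, or plain integers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .state_model import CompressedSequence, StateAlphabet

__all__ = [
    "GenomicRegion",
    "SegmentationTrack",
    "read_segmentation",
    "write_segmentation",
    "read_regions_bed",
    "extract_region",
    "tile_genome",
    "write_letter_fasta",
]

_LABEL_RE = re.compile(r"^(?:E(\d+)|(\d+)_.+|(\d+))$")


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval in BED coordinates (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need end > start >= 0)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def display_name(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


def parse_state_label(label: str, alphabet: Optional[StateAlphabet] = None) -> int:
    """Map a segmentation label ('E5', '15_Quies', '7') to a 1-based state index."""
    if alphabet is not None:
        try:
            return alphabet.state_of_label(label)
        except KeyError:
            pass
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse state label {label!r}")
    return int(next(g for g in m.groups() if g is not None))


@dataclass
class SegmentationTrack:
    """One epigenome's chromatin state annotation.

    ``intervals`` maps chromosome -> int64 array of shape (n, 3) with columns
    (start, end, state), sorted and non-overlapping.  Gaps between intervals
    are legal and mean "not annotated".  ``provenance`` optionally tags tiles
    (by region display name) as real/randomized in hybrid tracks.
    """

    intervals: dict[str, np.ndarray]
    alphabet: StateAlphabet
    bin_width: int = 200
    provenance: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, rows in self.intervals.items():
            arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            if np.any(arr[:, 1] <= arr[:, 0]):
                bad = int(np.argmax(arr[:, 1] <= arr[:, 0]))
                raise ValueError(
                    f"{chrom}: interval {bad} has start >= end "
                    f"({arr[bad, 0]}..{arr[bad, 1]})"
                )
            if arr.shape[0] > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
                bad = int(np.argmax(arr[1:, 0] < arr[:-1, 1]))
                raise ValueError(f"{chrom}: intervals {bad} and {bad + 1} overlap")
            if arr.size and (arr[:, 2].min() < 1 or arr[:, 2].max() > self.alphabet.size):
                raise ValueError(f"{chrom}: state index outside alphabet")
            clean[chrom] = arr
        self.intervals = clean

    @property
    def chroms(self) -> list[str]:
        return list(self.intervals)

    def chrom_length(self, chrom: str) -> int:
        """Annotated extent: end of the last interval."""
        arr = self._require(chrom)
        return int(arr[-1, 1]) if arr.size else 0

    def _require(self, chrom: str) -> np.ndarray:
        if chrom not in self.intervals:
            raise KeyError(f"chromosome {chrom!r} not in track")
        return self.intervals[chrom]


def read_segmentation(
    path,
    alphabet: Optional[StateAlphabet] = None,
    bin_width: int = 200,
) -> SegmentationTrack:
    """Parse a BED4 segmentation (chrom, start, end, state label).

    If no alphabet is supplied one is inferred: the largest parsed state
    index sets Q and labels default to ``E1..EQ``.  With a fixed alphabet,
    unknown labels raise.
    """
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    max_state = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated BED fields")
            chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            try:
                state = parse_state_label(label, alphabet)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
            if alphabet is not None and state > alphabet.size:
                raise ValueError(
                    f"{path}:{ln}: state {state} outside fixed alphabet"
                )
            max_state = max(max_state, state)
            per_chrom.setdefault(chrom, []).append((start, end, state))
    if alphabet is None:
        alphabet = StateAlphabet.from_size(max(max_state, 1))
    arrays = {
        chrom: np.array(rows, dtype=np.int64) for chrom, rows in per_chrom.items()
    }
    return SegmentationTrack(arrays, alphabet, bin_width=bin_width)


def write_segmentation(track: SegmentationTrack, path) -> None:
    """Write a track back to BED4 using the alphabet's state labels."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for start, end, state in track.intervals[chrom].tolist():
                fh.write(f"{chrom}\t{start}\t{end}\t{track.alphabet.label(state)}\n")


def read_regions_bed(path) -> list[GenomicRegion]:
    """Read query regions from a BED3/BED4 file."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected at least 3 BED fields")
            name = parts[3] if len(parts) > 3 else None
            regions.append(GenomicRegion(parts[0], int(parts[1]), int(parts[2]), name))
    return regions


def extract_region(track: SegmentationTrack, region: GenomicRegion) -> CompressedSequence:
    """Compressed state sequence of a region, run lengths in bin_width units.

    Intervals are clipped to the region; each clipped interval contributes a
    run of ``round(bp / bin_width)`` bins (minimum 1); adjacent equal states
    -- including across annotation gaps -- are merged.  A region covering no
    annotation yields an empty sequence.
    """
    arr = track._require(region.chrom)
    states: list[int] = []
    runs: list[int] = []
    if arr.size:
        lo = int(np.searchsorted(arr[:, 1], region.start, side="right"))
        for start, end, state in arr[lo:].tolist():
            if start >= region.end:
                break
            s, e = max(start, region.start), min(end, region.end)
            if e <= s:
                continue
            nbins = max(1, round((e - s) / track.bin_width))
            if states and states[-1] == state:
                runs[-1] += nbins
            else:
                states.append(state)
                runs.append(nbins)
    return CompressedSequence(
        np.array(states, dtype=np.int64),
        np.array(runs, dtype=np.int64),
        origin=region,
        alphabet=track.alphabet,
    )


def tile_genome(track: SegmentationTrack, bin_size: int = 500_000) -> list[GenomicRegion]:
    """Tile each chromosome into consecutive fixed-size windows.

    Windows are ``[0, bin), [bin, 2*bin), ...`` up to the annotated extent; a
    trailing partial window is kept iff it is at least half a window long.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    regions: list[GenomicRegion] = []
    for chrom in track.chroms:
        length = track.chrom_length(chrom)
        pos = 0
        while pos < length:
            end = min(pos + bin_size, length)
            if end - pos >= bin_size or end - pos >= bin_size / 2:
                regions.append(
                    GenomicRegion(chrom, pos, end, name=f"{chrom}:{pos}-{end}")
                )
            pos += bin_size
    return regions


def write_letter_fasta(
    named_seqs: Iterable[tuple[str, CompressedSequence]],
    alphabet: StateAlphabet,
    path,
) -> None:
    """Export letter-coded sequences as FASTA (input for motif discovery)."""
    from .state_model import to_letters

    seen: set[str] = set()
    with open(path, "w") as fh:
        for name, seq in named_seqs:
            if name in seen:
                raise ValueError(f"duplicate FASTA record name {name!r}")
            seen.add(name)
            if len(seq) == 0:
                raise ValueError(f"record {name!r} is empty")
            fh.write(f">{name}\n{to_letters(seq, alphabet)}\n")
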