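"""Chromatin state alphabets and run-length-compressed state sequences.

A chromatin state annotation (e.g. a ChromHMM segmentation) assigns one of Q
discrete states to every fixed-width genomic bin.  Because single states --
above all the quiescent/low state -- cover long uninterrupted stretches, the
alignment machinery operates not on the raw per-bin sequence but on its
run-length compression: the sequence of maximal-run state labels, with the run
sizes kept alongside.  This module provides the alphabet, the raw and
compressed sequence containers, conversion between them, the single-letter
coding used for motif export (states 1..15 -> 'a'..'o'), and state-frequency
estimation for frequency-based alignment weights.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

__all__ = [
    "StateAlphabet",
    "RawStateSequence",
    "CompressedSequence",
    "FrequencyTable",
    "compress",
    "decompress",
    "to_letters",
    "from_letters",
    "state_frequencies",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class StateAlphabet:
    """The Q chromatin states with their labels and single-letter codes.

    Parameters
    ----------
    labels
        One label per state, in state order (state 1 first).  Labels may be
        ChromHMM ``E<k>`` names or mnemonics such as ``15_Quies``.
    letters
        One character per state.  Defaults to ``'a', 'b', ...`` in state
        order for alphabets of up to 26 states, so that in the 15-state
        Roadmap model state 15 (quiescent) is ``'o'``.
    """

    labels: tuple[str, ...]
    letters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise ValueError("alphabet must contain at least one state")
        if any(not lab for lab in labels):
            raise ValueError("state labels must be non-empty")
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        letters = tuple(self.letters)
        if not letters:
            if len(labels) > len(_LETTERS):
                raise ValueError(
                    "default letters only cover up to 26 states; "
                    "pass explicit letters"
                )
            letters = tuple(_LETTERS[: len(labels)])
        if len(letters) != len(labels):
            raise ValueError("need exactly one letter per state")
        if any(len(c) != 1 for c in letters):
            raise ValueError("letters must be single characters")
        if len(set(letters)) != len(letters):
            raise ValueError("letters must be unique")
        object.__setattr__(self, "letters", letters)

    @property
    def size(self) -> int:
        """Number of states Q."""
        return len(self.labels)

    def label(self, state: int) -> str:
        self._check(state)
        return self.labels[state - 1]

    def letter(self, state: int) -> str:
        self._check(state)
        return self.letters[state - 1]

    def state_of_label(self, label: str) -> int:
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise KeyError(f"label {label!r} not in alphabet") from None

    def state_of_letter(self, letter: str) -> int:
        try:
            return self.letters.index(letter) + 1
        except ValueError:
            raise KeyError(f"letter {letter!r} not in alphabet") from None

    def _check(self, state: int) -> None:
        if not 1 <= int(state) <= self.size:
            raise ValueError(f"state {state} outside alphabet of size {self.size}")

    @classmethod
    def from_size(cls, q: int, prefix: str = "E") -> "StateAlphabet":
        """Generic alphabet with labels ``E1..EQ`` and default letters."""
        return cls(tuple(f"{prefix}{k}" for k in range(1, q + 1)))

    @classmethod
    def roadmap15(cls) -> "StateAlphabet":
        """The 15-state Roadmap/ChromHMM core model with mnemonic labels."""
        path = resources.files("epialign.data").joinpath("roadmap15.tsv")
        return cls.from_file(path)

    @classmethod
    def from_file(cls, path) -> "StateAlphabet":
        """Read a plain-text alphabet: one ``index<TAB>label<TAB>letter`` per line."""
        labels: list[str] = []
        letters: list[str] = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
                idx, label, letter = parts
                if int(idx) != len(labels) + 1:
                    raise ValueError(f"{path}:{ln}: state indices must be 1,2,...")
                labels.append(label)
                letters.append(letter)
        return cls(tuple(labels), tuple(letters))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for k, (label, letter) in enumerate(zip(self.labels, self.letters), 1):
                fh.write(f"{k}\t{label}\t{letter}\n")


def _as_state_array(states, alphabet: Optional[StateAlphabet]) -> np.ndarray:
    arr = np.asarray(states, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("states must be one-dimensional")
    if arr.size and arr.min() < 1:
        bad = int(np.argmax(arr < 1))
        raise ValueError(f"state index {arr[bad]} at position {bad} is not >= 1")
    if alphabet is not None and arr.size and arr.max() > alphabet.size:
        bad = int(np.argmax(arr > alphabet.size))
        raise ValueError(
            f"state index {arr[bad]} at position {bad} outside alphabet "
            f"of size {alphabet.size}"
        )
    return arr


@dataclass(frozen=True)
class RawStateSequence:
    """Uncompressed per-bin chromatin state sequence.

    ``states`` holds 1-based state indices, one per genomic bin of
    ``bin_width`` bp.  ``origin`` optionally records where the sequence came
    from as a ``(chrom, start)`` pair.
    """

    states: np.ndarray
    bin_width: int = 200
    origin: Optional[tuple[str, int]] = None
    alphabet: Optional[StateAlphabet] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", _as_state_array(self.states, self.alphabet))
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def __len__(self) -> int:
        return int(self.states.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RawStateSequence):
            return NotImplemented
        return (
            np.array_equal(self.states, other.states)
            and self.bin_width == other.bin_width
        )


@dataclass(frozen=True)
class CompressedSequence:
    """Run-length-compressed chromatin state sequence: the unit of alignment.

    ``states`` is the sequence of maximal-run state indices (no two adjacent
    entries equal); ``run_lengths`` records how many raw bins each entry
    collapsed.  The compressed length ``len(self)`` is the n that enters the
    dynamic program.
    """

    states: np.ndarray
    run_lengths: np.ndarray
    origin: Optional[object] = None  # GenomicRegion or (chrom, start)
    alphabet: Optional[StateAlphabet] = None

    def __post_init__(self) -> None:
        states = _as_state_array(self.states, self.alphabet)
        runs = np.asarray(self.run_lengths, dtype=np.int64)
        if runs.shape != states.shape:
            raise ValueError("run_lengths must match states in length")
        if runs.size and runs.min() < 1:
            raise ValueError("run lengths must be >= 1")
        if states.size > 1 and np.any(states[1:] == states[:-1]):
            bad = int(np.argmax(states[1:] == states[:-1]))
            raise ValueError(f"adjacent equal states at positions {bad},{bad + 1}")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "run_lengths", runs)

    def __len__(self) -> int:
        return int(self.states.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CompressedSequence):
            return NotImplemented
        return np.array_equal(self.states, other.states) and np.array_equal(
            self.run_lengths, other.run_lengths
        )

    @property
    def total_bins(self) -> int:
        """Raw length (in bins) this sequence compresses."""
        return int(self.run_lengths.sum())


def compress(raw: RawStateSequence) -> CompressedSequence:
    """Collapse maximal runs of equal states: ``abbcc`` becomes ``abc`` [1,2,2]."""
    s = raw.states
    if s.size == 0:
        return CompressedSequence(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            origin=raw.origin,
            alphabet=raw.alphabet,
        )
    boundaries = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [s.size]))
    return CompressedSequence(
        s[starts], ends - starts, origin=raw.origin, alphabet=raw.alphabet
    )


def decompress(c: CompressedSequence, bin_width: int = 200) -> RawStateSequence:
    """Inverse of :func:`compress`; expands each state by its run length."""
    origin = None
    if isinstance(c.origin, tuple):
        origin = c.origin
    return RawStateSequence(
        np.repeat(c.states, c.run_lengths),
        bin_width=bin_width,
        origin=origin,
        alphabet=c.alphabet,
    )


def to_letters(c: CompressedSequence, alphabet: StateAlphabet) -> str:
    """Letter-code a compressed sequence, one character per compressed state."""
    if len(c) == 0:
        return ""
    if c.states.max() > alphabet.size:
        raise ValueError(
            f"state {int(c.states.max())} has no letter in alphabet of size "
            f"{alphabet.size}"
        )
    lut = np.array(list(alphabet.letters))
    return "".join(lut[c.states - 1])


def from_letters(text: str, alphabet: StateAlphabet) -> CompressedSequence:
    """Build a compressed sequence (all run lengths 1) from a letter string.

    Convenience inverse of :func:`to_letters` for unit-run sequences; raises
    if the text encodes two equal adjacent states.
    """
    states = np.array([alphabet.state_of_letter(ch) for ch in text], dtype=np.int64)
    return CompressedSequence(
        states, np.ones(states.size, dtype=np.int64), alphabet=alphabet
    )


class FrequencyTable(Mapping):
    """Relative frequency of each chromatin state; values sum to 1."""

    def __init__(self, freqs: Mapping[int, float]):
        self._freqs = {int(k): float(v) for k, v in freqs.items()}
        if not self._freqs:
            raise ValueError("frequency table must not be empty")
        if any(v < 0 for v in self._freqs.values()):
            raise ValueError("frequencies must be non-negative")
        total = sum(self._freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1 (got {total})")

    def __getitem__(self, state: int) -> float:
        return self._freqs[int(state)]

    def __iter__(self):
        return iter(self._freqs)

    def __len__(self) -> int:
        return len(self._freqs)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}: {v:.4g}" for k, v in sorted(self._freqs.items()))
        return f"FrequencyTable({{{inner}}})"


def state_frequencies(
    seqs: Iterable[CompressedSequence],
    basis: str = "compressed_occurrences",
) -> FrequencyTable:
    """Estimate state frequencies over a collection of compressed sequences.

    With ``basis="compressed_occurrences"`` every compressed entry counts
    once (the scale on which the aligner operates); with ``basis="raw_bins"``
    each entry counts ``run_length`` times (genomic coverage).
    """
    if basis not in ("compressed_occurrences", "raw_bins"):
        raise ValueError(f"unknown basis {basis!r}")
    counts: dict[int, float] = {}
    for c in seqs:
        weights = c.run_lengths if basis == "raw_bins" else np.ones(len(c))
        for s, w in zip(c.states.tolist(), weights.tolist()):
            counts[s] = counts.get(s, 0.0) + w
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot estimate frequencies from all-empty input")
    return FrequencyTable({s: n / total for s, n in counts.items()})
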