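"""Heptad-register and sequence-profile annotation of myosin rod sequences.

The rod is a continuous coiled coil whose sequence follows the heptad
repeat abcdefg, interrupted four times by *skip* residues that each absorb
one extra register position.  Register letters are assigned from a single
anchor residue of known letter; a skip residue keeps the letter that plain
cycling would give it, and every residue downstream of a skip is shifted
back by one letter.

Also provided: a rolling net-charge profile (the rod's 28-residue charge
periodicity drives thick-filament packing) and sliding-window mutation
density profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MYH7_ROD_SKIPS",
    "RodSequence",
    "RegisterAssignment",
    "assign_register",
    "charge_profile",
    "mutation_density",
    "read_fasta_rod",
]

#: canonical skip residues of the human beta-cardiac myosin (MYH7) rod
MYH7_ROD_SKIPS = frozenset({1188, 1385, 1582, 1807})

_LETTERS = "abcdefg"
_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}  # H treated as neutral


@dataclass(frozen=True)
class RodSequence:
    """A rod segment in full-protein numbering.

    ``anchor`` pins the register: ``(residue_number, letter)``.  ``skips``
    holds skip residue numbers; entries outside the segment but between the
    anchor and a queried residue still shift the register, so the full
    canonical set can be supplied regardless of segment bounds.
    """

    residues: str
    start_number: int
    anchor: tuple[int, str]
    skips: frozenset[int] = field(default_factory=lambda: MYH7_ROD_SKIPS)

    def __post_init__(self) -> None:
        if self.start_number < 1:
            raise ValueError("start_number must be >= 1")
        a_num, a_letter = self.anchor
        if a_letter not in _LETTERS:
            raise ValueError(f"register letter must be one of {_LETTERS!r}")
        if not self.start_number <= a_num <= self.end_number:
            raise ValueError("anchor outside the sequence range")
        object.__setattr__(self, "skips", frozenset(self.skips))
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.residues) - 1

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RegisterAssignment:
    """Per-residue register letters; skip residues flagged noncanonical."""

    residue_numbers: np.ndarray
    letters: np.ndarray
    is_skip: np.ndarray

    def letter(self, residue: int) -> str:
        idx = np.nonzero(self.residue_numbers == residue)[0]
        if idx.size == 0:
            raise KeyError(f"residue {residue} outside assignment")
        return str(self.letters[idx[0]])


def _letter_index(seq: RodSequence, residue: int) -> int:
    a_num, a_letter = seq.anchor
    skips = np.array(sorted(seq.skips))
    n_below = int(np.count_nonzero(skips < residue) - np.count_nonzero(skips < a_num))
    return (_LETTERS.index(a_letter) + (residue - a_num) - n_below) % 7


def assign_register(seq: RodSequence) -> RegisterAssignment:
    """Assign a heptad letter to every residue of the segment.

    Letters cycle a..g from the anchor; each skip residue consumes one
    extra register slot, shifting all downstream residues back by one
    letter while itself keeping the letter plain cycling would assign.
    """
    numbers = np.arange(seq.start_number, seq.end_number + 1)
    letters = np.array([_LETTERS[_letter_index(seq, r)] for r in numbers])
    is_skip = np.isin(numbers, sorted(seq.skips))
    return RegisterAssignment(numbers, letters, is_skip)


def charge_profile(seq: RodSequence, window: int = 29) -> pd.DataFrame:
    """Rolling net charge (E/D = -1, K/R = +1, H = 0), centred window.

    The rod's native charge period is 28 residues; the default window is
    rounded up to 29 so it can be centred.  Only positions where the full
    window fits are reported.  Returns columns ``position`` and ``charge``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd (centred)")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    charges = np.array([_CHARGE.get(aa, 0) for aa in seq.residues], dtype=float)
    rolled = np.convolve(charges, np.ones(window), mode="valid")
    half = window // 2
    positions = np.arange(seq.start_number + half, seq.end_number - half + 1)
    return pd.DataFrame({"position": positions, "charge": rolled})


def mutation_density(
    positions,
    window: int,
    residue_range: tuple[int, int],
    normalize: bool = False,
) -> pd.DataFrame:
    """Sliding-window count of mutated positions over ``residue_range``.

    ``window`` is centred; counts at the range edges use the truncated part
    of the window that fits.  With ``normalize=True`` the count is divided
    by the window size actually covered (per-residue frequency).  An empty
    position list yields an all-zero profile.
    """
    first, last = residue_range
    if first > last:
        raise ValueError("empty residue range")
    positions = np.asarray(list(positions), dtype=int)
    if positions.size and (positions.min() < first or positions.max() > last):
        raise ValueError("mutation positions outside the residue range")
    half = window // 2
    grid = np.arange(first, last + 1)
    hits = np.zeros(grid.size)
    if positions.size:
        idx, counts = np.unique(positions, return_counts=True)
        hits[idx - first] = counts
    kernel = np.ones(2 * half + 1)
    density = np.convolve(hits, kernel, mode="same")
    if normalize:
        cover = np.convolve(np.ones(grid.size), kernel, mode="same")
        density = density / cover
    return pd.DataFrame({"position": grid, "density": density})


def read_fasta_rod(
    path,
    start_number: int,
    anchor: tuple[int, str],
    skips=MYH7_ROD_SKIPS,
) -> RodSequence:
    """Read the first record of a FASTA file as a rod segment."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return RodSequence(str(record.seq), start_number, anchor, frozenset(skips))
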