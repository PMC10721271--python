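"""Ab initio two-chain coiled-coil backbone construction.

A coiled coil is modelled as a helix wound on a helix (the Crick picture):
each chain's Calpha atoms trace a *minor* helix of radius ``minor_radius``
about a local helix axis, which itself winds as a *major* (super-)helix of
radius ``major_radius`` about the central z axis.  In the laboratory frame
the alpha-helix advances ``360 / residues_per_turn`` degrees per residue;
the supercoil rotation rate is set by the mismatch between that periodicity
and the local *frame periodicity* imposed by the motif pattern:

    omega0 = 360 * (1 / residues_per_turn - 1 / frame_periodicity)   [deg/res]

A canonical heptad motif spans 7 residues in 2 helical turns (frame
periodicity 3.5 res/turn), giving omega0 about -3.33 deg/residue — a
left-handed supercoil.  The myosin rod additionally contains *skip* residues
that locally unwind the coil: a skip is modelled by replacing four canonical
7-residue motifs with one 29-residue motif of 8 turns (29/8 = 3.625
res/turn, nearly straight).  Single-residue deletions are modelled the
opposite way, as a 27-residue motif that keeps the 8 turns of the span it
replaces (27/8 = 3.375 res/turn, locally overwound), so the mutant model
stays continuously helical while kinking back into register.

The piecewise-constant winding profile is low-pass filtered with a Gaussian
kernel whose width is ``smoothing_b`` times the chain length, so that motif
boundaries do not introduce discontinuous kinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import _pdbio

__all__ = [
    "CrickParameters",
    "Motif",
    "MotifKind",
    "MotifPattern",
    "BuiltModel",
    "make_pattern",
    "local_winding",
    "build",
    "write_model",
    "read_model",
]

#: residues and helical turns for each motif kind
_MOTIF_GEOMETRY = {
    "canonical": (7, 2.0),
    "skip": (29, 8.0),
    "deletion": (27, 8.0),
}


@dataclass(frozen=True)
class CrickParameters:
    """Geometric constants of the coiled-coil model.

    Parameters
    ----------
    residues_per_turn:
        Alpha-helical periodicity in the laboratory frame (residues/turn).
    rise:
        Axial translation per residue along the central axis (Å).
    interchain_rotation:
        Relative rotation of the two strands about the central axis (deg).
    major_radius:
        Distance of each local helix axis from the central axis (Å).
    minor_radius:
        Calpha distance from the local helix axis (Å).  Not printed for the
        myosin rod; 2.3 Å is the standard alpha-helix Calpha radius.
    smoothing_b:
        Dimensionless width of the Gaussian smoothing of the winding
        profile, as a fraction of chain length.
    """

    residues_per_turn: float = 3.617
    rise: float = 1.495
    interchain_rotation: float = 210.0
    major_radius: float = 4.9
    minor_radius: float = 2.3
    smoothing_b: float = 0.03

    def __post_init__(self) -> None:
        if self.residues_per_turn <= 0 or self.rise <= 0:
            raise ValueError("residues_per_turn and rise must be > 0")
        if self.major_radius <= 0 or self.minor_radius <= 0:
            raise ValueError("radii must be > 0")
        if not 0.0 <= self.interchain_rotation < 360.0:
            raise ValueError("interchain_rotation must lie in [0, 360)")
        if self.smoothing_b < 0:
            raise ValueError("smoothing_b must be >= 0")
        if self.minor_radius > self.major_radius:
            warnings.warn(
                "minor_radius exceeds major_radius: chains will interpenetrate",
                stacklevel=2,
            )


class MotifKind(str, Enum):
    CANONICAL = "canonical"
    SKIP = "skip"
    DELETION = "deletion"
    PARTIAL = "partial"  # terminal pad, canonical winding


@dataclass(frozen=True)
class Motif:
    kind: MotifKind
    length: int
    turns: float

    def __post_init__(self) -> None:
        if self.kind is not MotifKind.PARTIAL:
            exp_len, exp_turns = _MOTIF_GEOMETRY[self.kind.value]
            if (self.length, self.turns) != (exp_len, exp_turns):
                raise ValueError(
                    f"{self.kind.value} motif must be "
                    f"({exp_len} residues, {exp_turns} turns)"
                )
        elif not 0 < self.length < 7:
            raise ValueError("partial motif length must be in 1..6")

    @property
    def frame_periodicity(self) -> float:
        """Residues per turn in the frame rotating with the supercoil."""
        return self.length / self.turns


def _canonical_motif() -> Motif:
    return Motif(MotifKind.CANONICAL, 7, 2.0)


@dataclass(frozen=True)
class MotifPattern:
    """Ordered motifs tiling one chain of the coiled coil."""

    motifs: tuple[Motif, ...]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("pattern must contain at least one motif")

    @property
    def total_length(self) -> int:
        return sum(m.length for m in self.motifs)

    def per_residue_periodicity(self) -> np.ndarray:
        """Frame periodicity (res/turn) for every residue of the chain."""
        return np.concatenate(
            [np.full(m.length, m.frame_periodicity) for m in self.motifs]
        )

    def noncanonical_spans(self) -> list[tuple[int, int, MotifKind]]:
        """(start, stop) 0-based half-open residue spans of skip/deletion motifs."""
        spans = []
        pos = 0
        for m in self.motifs:
            if m.kind in (MotifKind.SKIP, MotifKind.DELETION):
                spans.append((pos, pos + m.length, m.kind))
            pos += m.length
        return spans


def make_pattern(
    chain_length: int,
    skip_sites: tuple[int, ...] = (),
    deletion_sites: tuple[int, ...] = (),
) -> MotifPattern:
    """Tile a chain with canonical motifs, replacing spans at the given sites.

    ``chain_length`` is the length of the canonical reference tiling (the
    wild-type span); sites are 1-based residue positions within it.  Each
    skip site replaces the four canonical motifs whose 28-residue union
    holds the site as centrally as possible (ties resolved toward the
    N-terminus) with one 29-residue motif; each deletion site likewise with
    one 27-residue motif.  The realised chain is therefore one residue
    longer per skip and one shorter per deletion.  A trailing remainder of
    fewer than 7 residues becomes a partial motif with canonical winding.
    """
    if chain_length < 7:
        raise ValueError("chain_length must be at least one heptad (7)")
    n_full = chain_length // 7
    remainder = chain_length % 7

    replacements: list[tuple[int, int, MotifKind]] = []  # motif-index spans
    for site, kind in [(s, MotifKind.SKIP) for s in skip_sites] + [
        (d, MotifKind.DELETION) for d in deletion_sites
    ]:
        if not 1 <= site <= chain_length:
            raise ValueError(f"site {site} outside chain 1..{chain_length}")
        m0 = (site - 1) // 7  # canonical motif holding the site
        candidates = [
            s for s in range(max(0, m0 - 3), m0 + 1) if s + 4 <= n_full
        ]
        if not candidates:
            raise ValueError(
                f"site {site} too close to the chain end to host a "
                f"4-heptad replacement span"
            )
        # site as central as possible within residues 7s+1 .. 7s+28
        start = min(candidates, key=lambda s: (abs(site - (7 * s + 14.5)), s))
        replacements.append((start, start + 4, kind))

    replacements.sort()
    for (a0, a1, _), (b0, b1, _) in zip(replacements, replacements[1:]):
        if b0 < a1:
            raise ValueError("noncanonical spans overlap")

    motifs: list[Motif] = []
    i = 0
    rep = iter(replacements)
    nxt = next(rep, None)
    while i < n_full:
        if nxt is not None and i == nxt[0]:
            kind = nxt[2]
            length, turns = _MOTIF_GEOMETRY[kind.value]
            motifs.append(Motif(kind, length, turns))
            i = nxt[1]
            nxt = next(rep, None)
        else:
            motifs.append(_canonical_motif())
            i += 1
    if remainder:
        motifs.append(Motif(MotifKind.PARTIAL, remainder, remainder / 3.5))
    return MotifPattern(tuple(motifs))


def local_winding(
    pattern: MotifPattern, params: CrickParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue supercoil rotation rate and frame periodicity.

    Returns ``(omega0, periodicity)`` where ``omega0`` is the supercoil
    azimuthal advance in degrees per residue (negative = left-handed) and
    ``periodicity`` the local frame periodicity in residues per turn.  The
    profile is piecewise constant over motifs; smoothing is applied by
    :func:`build`.
    """
    periodicity = pattern.per_residue_periodicity()
    omega0 = 360.0 * (1.0 / params.residues_per_turn - 1.0 / periodicity)
    return omega0, periodicity


@dataclass(frozen=True)
class BuiltModel:
    """Two-chain Calpha model with provenance.

    ``coords`` has shape (2, n_residues, 3); chain A first.  The central
    superhelical axis is the z axis and coordinates are in Å.
    """

    coords: np.ndarray
    residue_numbers: np.ndarray
    params: CrickParameters
    pattern: MotifPattern = field(repr=False)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


def _smooth(profile: np.ndarray, b: float) -> np.ndarray:
    if b <= 0:
        return profile
    sigma = b * profile.size
    return gaussian_filter1d(profile, sigma, mode="nearest")


def build(
    params: CrickParameters,
    pattern: MotifPattern,
    start_number: int = 1,
) -> BuiltModel:
    """Build the two-chain Calpha model for a motif pattern.

    Chain A residue *i* sits at minor radius from the local axis point
    ``(R cos Phi_i, R sin Phi_i, rise * i)``, with the supercoil azimuth
    ``Phi`` integrating the (smoothed) local winding profile and the minor
    phase advancing so that the laboratory-frame helical periodicity is
    ``residues_per_turn``.  Chain B is chain A rotated by
    ``interchain_rotation`` about the z axis (parallel, in-register dimer).
    """
    omega0_raw, _ = local_winding(pattern, params)
    omega0 = _smooth(omega0_raw, params.smoothing_b)
    n = omega0.size

    omega_lab = 360.0 / params.residues_per_turn
    omega1 = omega_lab - omega0  # minor phase rate relative to radial frame

    # integrate rates; residue 0 at azimuth 0, minor phase 0 (radially out)
    phi = np.deg2rad(np.concatenate(([0.0], np.cumsum(omega0[:-1]))))
    psi = np.deg2rad(np.concatenate(([0.0], np.cumsum(omega1[:-1]))))

    z = params.rise * np.arange(n)
    axis = np.stack(
        [
            params.major_radius * np.cos(phi),
            params.major_radius * np.sin(phi),
            z,
        ],
        axis=1,
    )
    # local radial/tangential frame in the horizontal plane
    u = np.stack([np.cos(phi), np.sin(phi), np.zeros(n)], axis=1)
    v = np.stack([-np.sin(phi), np.cos(phi), np.zeros(n)], axis=1)
    chain_a = axis + params.minor_radius * (
        np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * v
    )

    theta = np.deg2rad(params.interchain_rotation)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    chain_b = chain_a @ rot.T

    coords = np.stack([chain_a, chain_b])
    numbers = np.arange(start_number, start_number + n)
    return BuiltModel(coords, numbers, params, pattern)


def write_model(model: BuiltModel, path) -> None:
    """Write the model as a PDB file, chains A and B, one CA atom per residue."""
    _pdbio.write_ca_frames(path, model.coords[None], model.residue_numbers)


def read_model(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-chain CA-only PDB written by :func:`write_model`.

    Returns ``(coords, residue_numbers)`` with coords shaped
    (2, n_residues, 3).
    """
    frames, numbers, _ = _pdbio.read_frames(path)
    return frames[0], numbers
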