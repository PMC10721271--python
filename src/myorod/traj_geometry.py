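"""Coiled-coil geometry metrics on multi-frame coordinate sets.

The metrics mirror the standard per-residue descriptors of coiled-coil
trajectories:

* ``d_com`` — distance between the two chains' local centres, each centre
  being the unweighted centroid of a 7-Calpha window (3 residues N-terminal
  and 3 C-terminal of the marked residue).
* ``heptad_length`` — mean Calpha(i)->Calpha(i+7) distance over the window
  j in [i-3, i+3], averaged over chains.
* ``interheptad_angle`` — angle at vertex i of the triangle formed by
  Calpha(i-7), Calpha(i), Calpha(i+7), in degrees.
* ``helicity`` — fraction of residue-frames whose backbone (phi, psi)
  dihedrals fall in the alpha region.

Profiles report mean +/- SD across frames (and across runs when several
independent trajectories are aggregated), indexed by the trajectory's own
residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _pdbio

__all__ = [
    "CoiledCoilTrajectory",
    "GeometryProfile",
    "read_trajectory",
    "write_trajectory",
    "burn_in",
    "d_com",
    "d_com_profile",
    "heptad_length",
    "heptad_length_profile",
    "interheptad_angle",
    "interheptad_angle_profile",
    "helicity",
    "aggregate_runs",
    "DEFAULT_PHI_RANGE",
    "DEFAULT_PSI_RANGE",
]

#: alpha-region dihedral windows (degrees); configurable per call
DEFAULT_PHI_RANGE = (-100.0, -30.0)
DEFAULT_PSI_RANGE = (-80.0, -5.0)


@dataclass(frozen=True)
class CoiledCoilTrajectory:
    """Frames x 2 chains x residues of Calpha coordinates (Å).

    ``n_coords``/``c_coords`` optionally carry backbone amide N and carbonyl
    C positions of identical shape, enabling dihedral-based helicity.
    Frame *i* is at time ``i * frame_interval_ps``.
    """

    ca: np.ndarray
    residue_numbers: np.ndarray
    frame_interval_ps: float = 100.0
    n_coords: np.ndarray | None = None
    c_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca, dtype=float)
        if ca.ndim != 4 or ca.shape[1] != 2 or ca.shape[3] != 3:
            raise ValueError("ca must be shaped (frames, 2, residues, 3)")
        if ca.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.isfinite(ca).all():
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "ca", ca)
        object.__setattr__(
            self, "residue_numbers", np.asarray(self.residue_numbers, dtype=int)
        )

    @property
    def n_frames(self) -> int:
        return self.ca.shape[0]

    @property
    def n_residues(self) -> int:
        return self.ca.shape[2]

    @property
    def has_backbone(self) -> bool:
        return self.n_coords is not None and self.c_coords is not None

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps


@dataclass(frozen=True)
class GeometryProfile:
    """Per-residue mean and SD of a metric."""

    metric: str
    residue_numbers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def at(self, residue: int) -> tuple[float, float]:
        idx = np.nonzero(self.residue_numbers == residue)[0]
        if idx.size == 0:
            raise KeyError(f"residue {residue} not in profile")
        return float(self.mean[idx[0]]), float(self.sd[idx[0]])


def read_trajectory(path, frame_interval_ps: float = 100.0) -> CoiledCoilTrajectory:
    """Read a multi-model two-chain PDB file into a trajectory."""
    ca, numbers, backbone = _pdbio.read_frames(path)
    return CoiledCoilTrajectory(
        ca,
        numbers,
        frame_interval_ps,
        n_coords=None if backbone is None else backbone["N"],
        c_coords=None if backbone is None else backbone["C"],
    )


def write_trajectory(traj: CoiledCoilTrajectory, path) -> None:
    _pdbio.write_ca_frames(
        path, traj.ca, traj.residue_numbers, traj.n_coords, traj.c_coords
    )


def burn_in(traj: CoiledCoilTrajectory, discard_ps: float) -> CoiledCoilTrajectory:
    """Drop the equilibration frames with time < ``discard_ps``."""
    if discard_ps < 0:
        raise ValueError("discard must be >= 0")
    keep = traj.times_ps() >= discard_ps
    if not keep.any():
        raise ValueError("burn-in discards the entire trajectory")
    return replace(
        traj,
        ca=traj.ca[keep],
        n_coords=None if traj.n_coords is None else traj.n_coords[keep],
        c_coords=None if traj.c_coords is None else traj.c_coords[keep],
    )


def _residue_index(traj: CoiledCoilTrajectory, residue: int) -> int:
    idx = np.nonzero(traj.residue_numbers == residue)[0]
    if idx.size == 0:
        raise KeyError(f"residue {residue} not in trajectory")
    return int(idx[0])


def _window_centroids(ca: np.ndarray, half: int = 3) -> np.ndarray:
    """Centroid of the (2*half+1)-Calpha window at each interior residue.

    ca: (frames, 2, residues, 3) -> (frames, 2, residues - 2*half, 3)
    """
    w = 2 * half + 1
    csum = np.cumsum(ca, axis=2)
    tot = np.concatenate(
        [csum[:, :, w - 1 : w], csum[:, :, w:] - csum[:, :, :-w]], axis=2
    )
    return tot / w


def _dcom_frames(ca: np.ndarray) -> np.ndarray:
    cen = _window_centroids(ca)
    return np.linalg.norm(cen[:, 0] - cen[:, 1], axis=-1)  # (frames, residues-6)


def d_com_profile(traj: CoiledCoilTrajectory) -> GeometryProfile:
    """Inter-chain centre distance, all residues with full 7-Calpha windows."""
    if traj.n_residues < 7:
        raise ValueError("need at least 7 residues")
    vals = _dcom_frames(traj.ca)
    return GeometryProfile(
        "d_com",
        traj.residue_numbers[3:-3],
        vals.mean(axis=0),
        vals.std(axis=0, ddof=0),
    )


def d_com(traj: CoiledCoilTrajectory, residue: int) -> tuple[float, float]:
    """Mean +/- SD over frames of D_com at one residue."""
    return d_com_profile(traj).at(residue)


def _heptad_frames(ca: np.ndarray) -> np.ndarray:
    """Mean of |Ca(j)->Ca(j+7)| over j in [i-3, i+3], chains averaged.

    Valid at residues i with i-3 >= 0 and i+10 <= last (0-based), i.e. at
    indices 3 .. n-11.
    """
    d7 = np.linalg.norm(ca[:, :, 7:] - ca[:, :, :-7], axis=-1)  # (F,2,n-7)
    n7 = d7.shape[2]
    if n7 < 7:
        raise ValueError("chain too short for heptad-length windows")
    csum = np.cumsum(d7, axis=2)
    win = np.concatenate([csum[:, :, 6:7], csum[:, :, 7:] - csum[:, :, :-7]], axis=2)
    return (win / 7.0).mean(axis=1)  # (F, n-13)


def heptad_length_profile(traj: CoiledCoilTrajectory) -> GeometryProfile:
    vals = _heptad_frames(traj.ca)
    return GeometryProfile(
        "heptad_length",
        traj.residue_numbers[3 : traj.n_residues - 10],
        vals.mean(axis=0),
        vals.std(axis=0, ddof=0),
    )


def heptad_length(traj: CoiledCoilTrajectory, residue: int) -> tuple[float, float]:
    return heptad_length_profile(traj).at(residue)


def _angle_frames(ca: np.ndarray) -> np.ndarray:
    """Vertex angle (deg) at i between Ca(i-7), Ca(i), Ca(i+7); chains averaged."""
    a = ca[:, :, :-14]
    b = ca[:, :, 7:-7]
    c = ca[:, :, 14:]
    v1 = a - b
    v2 = c - b
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang.mean(axis=1)


def interheptad_angle_profile(traj: CoiledCoilTrajectory) -> GeometryProfile:
    if traj.n_residues < 15:
        raise ValueError("chain too short for interheptad angles")
    vals = _angle_frames(traj.ca)
    return GeometryProfile(
        "interheptad_angle",
        traj.residue_numbers[7:-7],
        vals.mean(axis=0),
        vals.std(axis=0, ddof=0),
    )


def interheptad_angle(traj: CoiledCoilTrajectory, residue: int) -> tuple[float, float]:
    return interheptad_angle_profile(traj).at(residue)


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral (deg) along axis p1->p2; arrays broadcast over leading dims."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def helicity(
    traj: CoiledCoilTrajectory,
    phi_range: tuple[float, float] = DEFAULT_PHI_RANGE,
    psi_range: tuple[float, float] = DEFAULT_PSI_RANGE,
) -> np.ndarray:
    """Fraction of helical residue-frames per chain, from backbone dihedrals.

    A residue is helical in a frame iff both phi and psi fall inside the
    alpha windows.  Terminal residues (no phi or no psi) are excluded from
    the denominator.  Returns an array of two fractions, chains A and B.
    """
    if not traj.has_backbone:
        raise ValueError("helicity requires backbone N and C coordinates")
    n_at, ca, c_at = traj.n_coords, traj.ca, traj.c_coords
    # phi(i) = C(i-1)-N(i)-CA(i)-C(i);  psi(i) = N(i)-CA(i)-C(i)-N(i+1)
    phi = _dihedral(c_at[:, :, :-1], n_at[:, :, 1:], ca[:, :, 1:], c_at[:, :, 1:])
    psi = _dihedral(n_at[:, :, :-1], ca[:, :, :-1], c_at[:, :, :-1], n_at[:, :, 1:])
    phi_i = phi[:, :, :-1]  # residues 1..n-2 (0-based interior)
    psi_i = psi[:, :, 1:]
    ok = (
        (phi_i >= phi_range[0])
        & (phi_i <= phi_range[1])
        & (psi_i >= psi_range[0])
        & (psi_i <= psi_range[1])
    )
    return ok.mean(axis=(0, 2))


def aggregate_runs(profiles: list[GeometryProfile]) -> GeometryProfile:
    """Between-run mean +/- SD of per-run mean profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least two runs to aggregate")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.metric != ref.metric or not np.array_equal(
            p.residue_numbers, ref.residue_numbers
        ):
            raise ValueError("profiles cover different metrics or residue ranges")
    means = np.stack([p.mean for p in profiles])
    return GeometryProfile(
        ref.metric,
        ref.residue_numbers,
        means.mean(axis=0),
        means.std(axis=0, ddof=1),
    )
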