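"""Synthetic inputs for every pipeline stage.

The generators emulate the statistical structure each analysis assumes, so
the whole pipeline is testable without experimental material:

* two-population Mant-ATP fluorescence decays for grouped fiber cohorts,
  with the patient group's fast-phase amplitude (DRX) raised by a relative
  ``drx_shift`` of 10-20 % while the total amplitude is conserved;
* ideal coiled-coil trajectories (exact built model plus isotropic Gaussian
  coordinate jitter);
* ideal alpha-helical backbones at prescribed (phi, psi) dihedrals;
* two-state sigmoidal CD melts;
* Hill-shaped force-pCa curves;
* two-Gaussian sarcomere line profiles.

Noise is additive i.i.d. Gaussian throughout, drawn from one explicit
per-call stream, so every generator is bit-reproducible given its seed and
zero-noise outputs lie exactly on their generating closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cc_builder
from .fiber_mech import ForcePCaCurve, HillFit, hill_model
from .mant_atp import DecayTrace, RelaxFit, decay_model
from .sarcomere_profile import LineProfile
from .traj_geometry import CoiledCoilTrajectory

__all__ = [
    "CohortSpec",
    "make_decay_cohort",
    "traces_to_df",
    "make_ideal_trajectory",
    "make_helical_backbone",
    "make_melt",
    "make_force_pca",
    "make_sarcomere_profiles",
    "default_times",
    "IDEAL_HELIX_PHI",
    "IDEAL_HELIX_PSI",
]

#: canonical alpha-helical backbone dihedrals (degrees)
IDEAL_HELIX_PHI = -62.0
IDEAL_HELIX_PSI = -41.0


@dataclass(frozen=True)
class CohortSpec:
    """Design of a two-group fiber cohort.

    ``drx_shift`` is the relative increase of the patient group's DRX
    proportion (P1), e.g. 0.10-0.20; the SRX proportion (P2) is reduced to
    keep P1 + P2 constant.  ``noise_sd`` is on the normalised fluorescence
    scale.
    """

    n_control: int
    n_patient: int
    drx_shift: float = 0.15
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_patient <= 0:
            raise ValueError("fiber counts must be > 0")
        if not 0.0 <= self.drx_shift < 1.0:
            raise ValueError("drx_shift must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_times(duration_s: float = 300.0, step_s: float = 5.0) -> np.ndarray:
    """Default acquisition grid: one frame every 5 s for 5 minutes."""
    return np.arange(0.0, duration_s + 0.5 * step_s, step_s)


def make_decay_cohort(
    spec: CohortSpec,
    base_fit: RelaxFit,
    times: np.ndarray | None = None,
    n_regions: int = 1,
    intensity_scale: float = 1000.0,
    background: float = 100.0,
) -> list[DecayTrace]:
    """Generate raw Mant-ATP chase traces for a control/patient cohort.

    Control traces follow the double-exponential model at ``base_fit``;
    patient traces have P1 scaled by (1 + drx_shift) with P1 + P2 held
    constant.  Gaussian noise of sd ``noise_sd`` is added on the normalised
    scale, then traces are dressed as raw intensities (scaled, with a
    constant background) so the full normalisation pipeline is exercised.
    """
    if times is None:
        times = default_times()
    times = np.asarray(times, dtype=float)
    p1, t1, p2, t2 = base_fit.p1, base_fit.t1, base_fit.p2, base_fit.t2
    if p1 < 0 or p2 < 0 or p1 + p2 > 1 or not t1 < t2:
        raise ValueError("base fit must satisfy P1, P2 >= 0, P1+P2 <= 1, T1 < T2")
    p1_pat = p1 * (1.0 + spec.drx_shift)
    p2_pat = (p1 + p2) - p1_pat
    if p2_pat < 0:
        raise ValueError(
            f"drx_shift {spec.drx_shift} pushes patient P1 past the P1+P2 budget"
        )

    rng = np.random.default_rng(spec.seed)
    traces = []
    for group, count, (q1, q2) in (
        ("control", spec.n_control, (p1, p2)),
        ("patient", spec.n_patient, (p1_pat, p2_pat)),
    ):
        clean = decay_model(times, q1, t1, q2, t2)
        for i in range(count):
            for r in range(n_regions):
                noisy = clean + rng.normal(0.0, spec.noise_sd, times.size)
                traces.append(
                    DecayTrace(
                        times,
                        intensity_scale * noisy + background,
                        np.full(times.size, background),
                        fiber_id=f"{group[:3]}_{i:04d}",
                        region_id=f"r{r + 1}",
                        group=group,
                    )
                )
    return traces


def traces_to_df(traces: list[DecayTrace]) -> pd.DataFrame:
    """Long-format table of raw traces (the trace-CSV schema)."""
    frames = [
        pd.DataFrame(
            {
                "time_s": t.time_s,
                "fiber_intensity": t.fiber_intensity,
                "background_intensity": t.background_intensity,
                "fiber_id": t.fiber_id,
                "region_id": t.region_id,
                "group": t.group,
                "isotype": t.isotype,
            }
        )
        for t in traces
    ]
    return pd.concat(frames, ignore_index=True)


def make_ideal_trajectory(
    params: cc_builder.CrickParameters,
    pattern: cc_builder.MotifPattern,
    n_frames: int,
    jitter_sd: float,
    seed: int = 0,
    frame_interval_ps: float = 100.0,
) -> CoiledCoilTrajectory:
    """Built model as frame 0 plus Gaussian coordinate jitter in later frames."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    model = cc_builder.build(params, pattern)
    rng = np.random.default_rng(seed)
    frames = np.repeat(model.coords[None], n_frames, axis=0)
    if n_frames > 1 and jitter_sd > 0:
        frames[1:] += rng.normal(0.0, jitter_sd, frames[1:].shape)
    return CoiledCoilTrajectory(frames, model.residue_numbers, frame_interval_ps)


# -- ideal backbone construction (NeRF internal-coordinate placement) --------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """Position of atom d given the a-b-c frame and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(dihedral),
            -np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helical_backbone(
    n_res: int,
    phi: float | np.ndarray = IDEAL_HELIX_PHI,
    psi: float | np.ndarray = IDEAL_HELIX_PSI,
    n_frames: int = 1,
    jitter_sd: float = 0.0,
    seed: int = 0,
    chain_separation: float = 10.0,
) -> CoiledCoilTrajectory:
    """Two-chain backbone (N, CA, C) built from prescribed dihedrals.

    ``phi``/``psi`` may be scalars or per-residue arrays; the omega
    dihedral is fixed trans (180 deg) and bond geometry is ideal.  The
    second chain is a translated copy (the metrics under test are
    per-chain).  Intended for dihedral-based helicity checks.
    """
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (n_res,))
    psi_arr = np.broadcast_to(np.asarray(psi, dtype=float), (n_res,))

    n_at = np.zeros((n_res, 3))
    ca = np.zeros((n_res, 3))
    c_at = np.zeros((n_res, 3))
    n_at[0] = [0.0, 0.0, 0.0]
    ca[0] = [_BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(_ANGLE_N_CA_C)
    c_at[0] = ca[0] + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        n_at[i] = _place(
            n_at[i - 1], ca[i - 1], c_at[i - 1], _BOND_C_N, _ANGLE_CA_C_N,
            psi_arr[i - 1],
        )
        ca[i] = _place(
            ca[i - 1], c_at[i - 1], n_at[i], _BOND_N_CA, _ANGLE_C_N_CA, 180.0
        )
        c_at[i] = _place(
            c_at[i - 1], n_at[i], ca[i], _BOND_CA_C, _ANGLE_N_CA_C, phi_arr[i]
        )

    offset = np.array([0.0, 0.0, chain_separation])
    ca2 = np.stack([ca, ca + offset])  # (2, n_res, 3)
    n2 = np.stack([n_at, n_at + offset])
    c2 = np.stack([c_at, c_at + offset])
    frames_ca = np.repeat(ca2[None], n_frames, axis=0)
    frames_n = np.repeat(n2[None], n_frames, axis=0)
    frames_c = np.repeat(c2[None], n_frames, axis=0)
    if n_frames > 1 and jitter_sd > 0:
        rng = np.random.default_rng(seed)
        frames_ca[1:] += rng.normal(0.0, jitter_sd, frames_ca[1:].shape)
        frames_n[1:] += rng.normal(0.0, jitter_sd, frames_n[1:].shape)
        frames_c[1:] += rng.normal(0.0, jitter_sd, frames_c[1:].shape)
    return CoiledCoilTrajectory(
        frames_ca,
        np.arange(1, n_res + 1),
        n_coords=frames_n,
        c_coords=frames_c,
    )


def make_melt(
    tm: float,
    slope: float,
    mre_folded: float,
    mre_unfolded: float,
    temps: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-state sigmoidal thermal melt; columns temperature_C and mre.

    At T = tm the signal is exactly the midpoint of the folded and
    unfolded baselines.
    """
    temps = np.asarray(temps, dtype=float)
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must strictly increase")
    mre = mre_unfolded + (mre_folded - mre_unfolded) / (
        1.0 + np.exp((temps - tm) / slope)
    )
    if noise_sd > 0:
        mre = mre + np.random.default_rng(seed).normal(0.0, noise_sd, temps.size)
    return pd.DataFrame({"temperature_C": temps, "mre": mre})


def make_force_pca(
    hill: HillFit,
    pcas: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    **curve_kwargs,
) -> ForcePCaCurve:
    """Hill-shaped force-pCa points plus Gaussian force noise (floored at 0)."""
    pcas = np.asarray(pcas, dtype=float)
    force = hill_model(pcas, hill.f_min, hill.f_max, hill.pca50, hill.n_h)
    if noise_sd > 0:
        force = force + np.random.default_rng(seed).normal(0.0, noise_sd, pcas.size)
    return ForcePCaCurve(pcas, np.maximum(force, 0.0), **curve_kwargs)


def make_sarcomere_profiles(
    n_sarcomeres: int,
    peak_separation_um: float = 0.8,
    peak_width_um: float = 0.15,
    amplitude: float = 1.0,
    baseline: float = 0.2,
    half_span_um: float = 1.2,
    step_um: float = 0.02,
    noise_sd: float = 0.0,
    max_offset_um: float = 0.1,
    seed: int = 0,
    myofibril_id: str = "m1",
) -> list[LineProfile]:
    """Two-Gaussian sarcomere line profiles with random axis offsets.

    Each profile has bright bands centred at +/- peak_separation_um / 2
    around the M-band minimum; the position axis of each sarcomere is
    shifted by a random offset (alignment is the downstream module's job).
    """
    rng = np.random.default_rng(seed)
    x = np.arange(-half_span_um, half_span_um + 0.5 * step_um, step_um)
    half_sep = peak_separation_um / 2.0
    profiles = []
    for i in range(n_sarcomeres):
        offset = rng.uniform(-max_offset_um, max_offset_um) if max_offset_um else 0.0
        inten = baseline + amplitude * (
            np.exp(-((x - half_sep) ** 2) / (2.0 * peak_width_um**2))
            + np.exp(-((x + half_sep) ** 2) / (2.0 * peak_width_um**2))
        )
        if noise_sd > 0:
            inten = inten + rng.normal(0.0, noise_sd, x.size)
        profiles.append(
            LineProfile(
                x + offset, inten, sarcomere_id=f"s{i + 1}",
                myofibril_id=myofibril_id,
            )
        )
    return profiles
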