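"""Simplified steady-state three-state contraction model.

Myosin heads exchange between the super-relaxed (SRX), disordered-relaxed
(DRX) and force-generating (FG) states along a linear scheme

    SRX  <-k1/k2->  DRX  <-k3*a(pCa)/k4->  FG

where attachment from DRX is gated by thin-filament activation, modelled as
a Hill function of [Ca2+].  Isometric force is proportional to the FG
occupancy.  This is an intentionally minimal surrogate for spatially
explicit sarcomere simulators: it has no filament lattice, compliance,
MyBPC or titin coupling, and its rate defaults are arbitrary plausible
values — it exists to explore the *direction* of the effect of shifting
heads from SRX to DRX on force and calcium sensitivity (pCa50), not to
reproduce any particular simulator's numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiber_mech import ForcePCaCurve, HillFit, fit_hill

__all__ = ["ThreeStateParams", "steady_state", "pca_curve", "fit_pca_curve"]


@dataclass(frozen=True)
class ThreeStateParams:
    """Rates (s^-1) and activation parameters of the three-state scheme.

    Defaults are surrogate values chosen only to sit in a physiological
    order of magnitude; none is a measured constant.
    """

    k_srx_to_drx: float = 0.2
    k_drx_to_srx: float = 0.8
    k_attach_max: float = 10.0
    k_detach: float = 20.0
    activation_pca50: float = 6.0
    activation_n: float = 3.0
    unitary_force: float = 1.0
    total_heads: float = 1.0

    def __post_init__(self) -> None:
        rates = (
            self.k_srx_to_drx,
            self.k_drx_to_srx,
            self.k_attach_max,
            self.k_detach,
        )
        if any(k < 0 for k in rates):
            raise ValueError("rates must be >= 0")
        if self.total_heads <= 0:
            raise ValueError("total_heads must be > 0")

    def activation(self, pca) -> np.ndarray:
        """Thin-filament activation in [0, 1], Hill in [Ca2+]."""
        pca = np.asarray(pca, dtype=float)
        return 1.0 / (1.0 + 10.0 ** (self.activation_n * (pca - self.activation_pca50)))


def rate_matrix(params: ThreeStateParams, pca: float) -> np.ndarray:
    """Generator matrix of the linear scheme at one pCa (states SRX, DRX, FG)."""
    ka = params.k_attach_max * float(params.activation(pca))
    k1, k2, k4 = params.k_srx_to_drx, params.k_drx_to_srx, params.k_detach
    return np.array(
        [
            [-k1, k2, 0.0],
            [k1, -(k2 + ka), k4],
            [0.0, ka, -k4],
        ]
    )


def steady_state(params: ThreeStateParams, pca: float):
    """Steady-state occupancies (SRX, DRX, FG) and isometric force at one pCa.

    Solves the null space of the rate matrix with the conservation
    constraint SRX + DRX + FG = 1.  Degenerate parameter sets whose chain
    is disconnected (all rates into a state zero) are rejected.
    """
    q = rate_matrix(params, pca)
    a = np.vstack([q, np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    occ, residual, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 3 or not np.all(np.isfinite(occ)):
        raise ValueError("degenerate rate scheme: steady state not unique")
    force = occ[2] * params.unitary_force * params.total_heads
    return occ, float(force)


def pca_curve(params: ThreeStateParams, pca_grid) -> ForcePCaCurve:
    """Steady-state force across a pCa grid, as a fit-ready curve."""
    pca_grid = np.asarray(pca_grid, dtype=float)
    forces = np.array([steady_state(params, p)[1] for p in pca_grid])
    return ForcePCaCurve(pca_grid, forces, fiber_id="srx-model", group="model")


def fit_pca_curve(params: ThreeStateParams, pca_grid) -> HillFit:
    """Hill-fit the model's force-pCa curve (pCa50, nH via fiber_mech)."""
    return fit_hill(pca_curve(params, pca_grid))
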