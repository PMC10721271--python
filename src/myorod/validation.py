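"""Recovery of Crick parameters from built coordinates.

Round-trip checks for the builder: each function re-measures one of the
model's generating constants directly from the Calpha coordinates, using
only generic geometry (regression, window centroids, unwrapped azimuths),
so a build can be validated against the parameters that produced it.
"""

from __future__ import annotations

import numpy as np

from .cc_builder import BuiltModel

__all__ = [
    "axis_points",
    "recover_rise",
    "recover_periodicity",
    "recover_major_radius",
    "recover_interchain_rotation",
]


def axis_points(chain: np.ndarray, half: int = 3) -> np.ndarray:
    """Local helix-axis estimates: centroids of 7-Calpha windows.

    Over a full frame period the minor-helix offsets cancel, leaving the
    superhelical axis.
    """
    w = 2 * half + 1
    kernel = np.ones(w) / w
    return np.stack(
        [np.convolve(chain[:, k], kernel, mode="valid") for k in range(3)], axis=1
    )


def recover_rise(model: BuiltModel) -> float:
    """Axial translation per residue: regression slope of z on residue index."""
    slopes = [
        np.polyfit(np.arange(chain.shape[0]), chain[:, 2], 1)[0]
        for chain in model.coords
    ]
    return float(np.mean(slopes))


def recover_periodicity(model: BuiltModel) -> float:
    """Laboratory-frame residues per turn of the minor helix.

    The Calpha offset from the local axis point rotates about the central
    axis once per helical turn; the unwrapped azimuth advance per residue
    converts to residues per turn.
    """
    vals = []
    for chain in model.coords:
        axis = axis_points(chain)
        offset = chain[3:-3] - axis
        theta = np.unwrap(np.arctan2(offset[:, 1], offset[:, 0]))
        slope = np.polyfit(np.arange(theta.size), theta, 1)[0]
        vals.append(2 * np.pi / abs(slope))
    return float(np.mean(vals))


def recover_major_radius(model: BuiltModel) -> float:
    """Mean distance of local helix-axis points from the central (z) axis."""
    vals = [
        np.hypot(axis_points(chain)[:, 0], axis_points(chain)[:, 1]).mean()
        for chain in model.coords
    ]
    return float(np.mean(vals))


def recover_interchain_rotation(model: BuiltModel) -> float:
    """Circular-mean azimuthal offset between the chains' axis points (deg)."""
    a = axis_points(model.coords[0])
    b = axis_points(model.coords[1])
    delta = np.arctan2(b[:, 1], b[:, 0]) - np.arctan2(a[:, 1], a[:, 0])
    return float(np.rad2deg(np.angle(np.exp(1j * delta).mean())) % 360)
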