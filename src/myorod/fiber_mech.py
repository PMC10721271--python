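"""Single muscle fiber mechanics: CSA, specific force, force-pCa Hill fits.

Fiber cross-sectional area is estimated as an ellipse from width and depth;
specific force is absolute force over CSA.  The force-pCa relation is fit
to the four-parameter Hill form standard in muscle mechanics,

    F(pCa) = F_min + (F_max - F_min) / (1 + 10^(nH * (pCa - pCa50))),

with pCa50 the calcium sensitivity (pCa at half-maximal active force) and
nH the steepness, a proxy for cross-bridge cooperativity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ForcePCaCurve",
    "HillFit",
    "csa",
    "specific_force",
    "hill_model",
    "fit_hill",
    "fit_fibers_csv",
]


@dataclass(frozen=True)
class ForcePCaCurve:
    """Force measurements of one fiber across activating solutions."""

    pca: np.ndarray
    force: np.ndarray
    width_um: float = 70.0
    depth_um: float = 70.0
    fiber_id: str = "fiber"
    group: str = "control"
    isotype: str = "beta/slow"

    def __post_init__(self) -> None:
        p = np.asarray(self.pca, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if np.any(p < 4.5) or np.any(p > 9.0):
            raise ValueError("pCa values must lie in [4.5, 9]")
        if np.any(f < 0):
            raise ValueError("forces must be >= 0")
        if self.width_um <= 0 or self.depth_um <= 0:
            raise ValueError("fiber width and depth must be > 0")
        object.__setattr__(self, "pca", p)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class HillFit:
    f_max: float
    f_min: float
    pca50: float
    n_h: float
    rss: float = 0.0
    converged: bool = True
    extrapolated: bool = False


def csa(width_um: float, depth_um: float) -> float:
    """Elliptical cross-sectional area (µm²) from fiber width and depth."""
    if width_um <= 0 or depth_um <= 0:
        raise ValueError("width and depth must be > 0")
    return math.pi * (width_um / 2.0) * (depth_um / 2.0)


def specific_force(force: float, area: float) -> float:
    """Force normalised to cross-sectional area."""
    if area <= 0:
        raise ValueError("area must be > 0")
    return force / area


def hill_model(pca, f_min, f_max, pca50, n_h):
    return f_min + (f_max - f_min) / (1.0 + 10.0 ** (n_h * (pca - pca50)))


def fit_hill(curve: ForcePCaCurve, normalize: bool = False) -> HillFit:
    """Least-squares 4-parameter Hill fit of a force-pCa curve.

    With ``normalize=True`` forces are first divided by the measured
    maximal (lowest-pCa) force, mirroring the usual submaximal-force
    normalisation; the fitted parameters are then on the normalised scale.
    Flat data (all forces equal) and non-convergent fits are flagged; a
    fitted pCa50 outside [4.5, 9] is flagged as an extrapolation.
    """
    pca = curve.pca
    force = curve.force.astype(float)
    if np.unique(pca).size < 5:
        raise ValueError("need at least 5 distinct pCa points")
    if normalize:
        fmax_meas = force[np.argmin(pca)]
        if fmax_meas <= 0:
            raise ValueError("maximal (lowest-pCa) force must be > 0 to normalise")
        force = force / fmax_meas

    rng = force.max() - force.min()
    if rng <= 0 or rng < 1e-9 * max(abs(force).max(), 1.0):
        return HillFit(np.nan, np.nan, np.nan, np.nan, 0.0, converged=False)

    half = force.min() + 0.5 * rng
    pca50_0 = float(pca[np.argmin(np.abs(force - half))])
    p0 = [force.min(), force.max(), pca50_0, 2.0]
    try:
        popt, _ = curve_fit(hill_model, pca, force, p0=p0, maxfev=20000)
    except RuntimeError:
        return HillFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)
    f_min, f_max, pca50, n_h = (float(v) for v in popt)
    if f_max < f_min:  # relabel the symmetric solution (nH < 0)
        f_min, f_max, n_h = f_max, f_min, -n_h
    rss = float(np.sum((hill_model(pca, *popt) - force) ** 2))
    return HillFit(
        f_max,
        f_min,
        pca50,
        n_h,
        rss,
        converged=bool(np.isfinite(popt).all()),
        extrapolated=not (4.5 <= pca50 <= 9.0),
    )


def fit_fibers_csv(path) -> pd.DataFrame:
    """Fit every fiber of a measurement CSV.

    Expected columns: fiber_id, group, isotype, width_um, depth_um, pCa,
    force.  Returns one row per fiber with CSA, maximal specific force,
    pCa50 and nH.
    """
    df = pd.read_csv(path)
    rows = []
    for fid, sub in df.groupby("fiber_id", sort=False):
        curve = ForcePCaCurve(
            sub["pCa"].to_numpy(),
            sub["force"].to_numpy(),
            width_um=float(sub["width_um"].iloc[0]),
            depth_um=float(sub["depth_um"].iloc[0]),
            fiber_id=str(fid),
            group=str(sub["group"].iloc[0]),
            isotype=str(sub["isotype"].iloc[0]),
        )
        fit = fit_hill(curve)
        area = csa(curve.width_um, curve.depth_um)
        rows.append(
            {
                "fiber_id": curve.fiber_id,
                "group": curve.group,
                "isotype": curve.isotype,
                "csa_um2": area,
                "specific_force_max": specific_force(float(curve.force.max()), area),
                "pca50": fit.pca50,
                "n_h": fit.n_h,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
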