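"""Circular-dichroism analysis: mean residue ellipticity, helicity, melts.

Machine ellipticity (millidegrees) converts to mean residue ellipticity

    MRE = theta_mdeg * MRW / (10 * pathlength_cm * concentration_mg_ml)

in deg cm^2 dmol^-1, with MRW the mean residue weight.  Percent helicity is
read off the 222 nm MRE magnitude against a full-helix reference of 36,000.
Melting temperature comes from a two-state (Boltzmann) sigmoid fit to the
thermal scan; the raw 50 %-crossing estimate is kept as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FULL_HELIX_MRE_222",
    "CdScan",
    "TmFit",
    "to_mre",
    "helicity_percent",
    "fit_tm",
    "tm_by_crossing",
]

#: MRE magnitude at 222 nm of a fully helical construct (deg cm^2 dmol^-1)
FULL_HELIX_MRE_222 = 36_000.0


@dataclass(frozen=True)
class CdScan:
    """One CD scan over wavelength (nm) or temperature (°C).

    ``signal_mdeg`` is the machine ellipticity in millidegrees.  The grid
    must be strictly monotone (either direction).
    """

    grid: np.ndarray
    signal_mdeg: np.ndarray
    pathlength_cm: float = 0.1
    concentration_mg_ml: float = 0.2
    n_residues: int = 419
    mean_residue_weight: float = 115.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        s = np.asarray(self.signal_mdeg, dtype=float)
        d = np.diff(g)
        if g.size < 2 or not ((d > 0).all() or (d < 0).all()):
            raise ValueError("grid must be strictly monotone")
        if self.pathlength_cm <= 0 or self.concentration_mg_ml <= 0:
            raise ValueError("pathlength and concentration must be > 0")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "signal_mdeg", s)


def to_mre(scan: CdScan) -> np.ndarray:
    """Mean residue ellipticity (deg cm^2 dmol^-1) at every grid point."""
    return (
        scan.signal_mdeg
        * scan.mean_residue_weight
        / (10.0 * scan.pathlength_cm * scan.concentration_mg_ml)
    )


def helicity_percent(
    mre_magnitude_222: float, reference: float = FULL_HELIX_MRE_222
) -> float:
    """Percent helical content from the unsigned 222 nm MRE.

    Linear in the magnitude: ``100 * |MRE_222| / reference``.  Values above
    100 % are reported as-is (with a warning), never clipped.
    """
    if mre_magnitude_222 < 0:
        raise ValueError("pass the MRE magnitude (>= 0), not the signed value")
    percent = 100.0 * mre_magnitude_222 / reference
    if percent > 100.0:
        warnings.warn(
            f"helicity {percent:.1f}% exceeds the full-helix reference",
            stacklevel=2,
        )
    return percent


@dataclass(frozen=True)
class TmFit:
    tm: float
    slope: float
    lower: float
    upper: float
    rss: float
    converged: bool


def _boltzmann(temp, lower, upper, tm, slope):
    return lower + (upper - lower) / (1.0 + np.exp((temp - tm) / slope))


def fit_tm(
    temps: np.ndarray,
    signal: np.ndarray,
    min_amplitude_frac: float = 0.05,
) -> TmFit:
    """Two-state sigmoid fit of a thermal melt; T_m is the fitted midpoint.

    ``signal`` may be raw ellipticity, MRE, or any affine rescaling — the
    baselines absorb it.  A curve whose transition amplitude is below
    ``min_amplitude_frac`` of the overall signal scale (or a fit that does
    not converge) is flagged as a failure.
    """
    temps = np.asarray(temps, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if temps.size < 10:
        raise ValueError("need at least 10 temperature points")
    order = np.argsort(temps)
    t_sorted, s_sorted = temps[order], signal[order]

    amp = s_sorted.max() - s_sorted.min()
    scale = max(np.abs(s_sorted).max(), 1e-12)
    if amp < min_amplitude_frac * scale:
        return TmFit(np.nan, np.nan, np.nan, np.nan, 0.0, converged=False)

    half = 0.5 * (s_sorted[0] + s_sorted[-1])
    tm0 = float(t_sorted[np.argmin(np.abs(s_sorted - half))])
    span = t_sorted[-1] - t_sorted[0]
    try:
        popt, _ = curve_fit(
            _boltzmann,
            t_sorted,
            s_sorted,
            p0=[s_sorted[-1], s_sorted[0], tm0, span / 20.0],
            maxfev=20000,
        )
    except RuntimeError:
        return TmFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)
    lower, upper, tm, slope = popt
    rss = float(np.sum((_boltzmann(t_sorted, *popt) - s_sorted) ** 2))
    ok = bool(t_sorted[0] <= tm <= t_sorted[-1] and np.isfinite(popt).all())
    return TmFit(float(tm), float(slope), float(lower), float(upper), rss, ok)


def tm_by_crossing(temps: np.ndarray, signal: np.ndarray) -> float:
    """Cross-check estimate: linear interpolation of the 50 % crossing."""
    temps = np.asarray(temps, dtype=float)
    signal = np.asarray(signal, dtype=float)
    order = np.argsort(temps)
    t, s = temps[order], signal[order]
    frac = (s - s[0]) / (s[-1] - s[0])
    idx = np.nonzero(np.diff(frac >= 0.5))[0]
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    return float(
        t[i] + (0.5 - frac[i]) * (t[i + 1] - t[i]) / (frac[i + 1] - frac[i])
    )
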