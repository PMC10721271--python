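"""Mant-ATP chase analysis: SRX/DRX proportions from fluorescence decays.

In a Mant-ATP chase, fluorescent ATP bound to myosin heads is chased with
dark ATP; heads in the disordered-relaxed state (DRX) release their
nucleotide roughly 5- to 10-fold faster than heads in the super-relaxed
state (SRX).  The background-corrected fiber fluorescence, normalised to the
last image before washout (t = 0), is fit to an unconstrained
double-exponential decay

    y(t) = 1 - P1 * (1 - exp(-t / T1)) - P2 * (1 - exp(-t / T2)),

where P1/T1 describe the fast (DRX) phase and P2/T2 the slow (SRX) phase.
Fits report phases ordered so that T1 < T2.

Sums of exponentials are ill-conditioned, so fitting uses variable
projection (amplitudes are linear given the time constants) from a grid of
time-constant starts, refined by full nonlinear least squares.  A batched
fitter of the same model serves cohort-scale work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DecayTrace",
    "NormalizedTrace",
    "RelaxFit",
    "decay_model",
    "normalize",
    "fit_decay",
    "fit_decay_batch",
    "fiber_summary",
    "drx_srx_ratio",
    "read_traces_csv",
    "fit_traces",
]

#: multi-start grid of time constants (s); amplitudes solved linearly
T1_STARTS = (5.0, 20.0, 60.0)
T2_STARTS = (100.0, 200.0, 400.0)


@dataclass(frozen=True)
class DecayTrace:
    """Raw fluorescence of one sampled region of one fiber."""

    time_s: np.ndarray
    fiber_intensity: np.ndarray
    background_intensity: np.ndarray
    fiber_id: str = "fiber"
    region_id: str = "r1"
    group: str = "control"
    isotype: str = "beta/slow"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.fiber_intensity, dtype=float)
        b = np.broadcast_to(
            np.asarray(self.background_intensity, dtype=float), f.shape
        ).copy()
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must strictly increase from 0")
        if not (np.isfinite(f).all() and np.isfinite(b).all()):
            raise ValueError("non-finite intensities")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "fiber_intensity", f)
        object.__setattr__(self, "background_intensity", b)


@dataclass(frozen=True)
class NormalizedTrace:
    time_s: np.ndarray
    value: np.ndarray
    fiber_id: str = "fiber"
    region_id: str = "r1"
    group: str = "control"
    isotype: str = "beta/slow"


@dataclass(frozen=True)
class RelaxFit:
    """Double-exponential fit; phases labelled so that T1 < T2.

    The fit is unconstrained: amplitudes may stray outside [0, 1] and are
    reported as fitted, never clipped.
    """

    p1: float
    t1: float
    p2: float
    t2: float
    rss: float = 0.0
    converged: bool = True
    n_points: int = 0
    fiber_id: str = "fiber"
    group: str = "control"
    isotype: str = "beta/slow"
    region_sd: dict = field(default_factory=dict)


def decay_model(t, p1, tau1, p2, tau2):
    """Normalised fluorescence of the two-population chase model."""
    t = np.asarray(t, dtype=float)
    return 1.0 - p1 * (1.0 - np.exp(-t / tau1)) - p2 * (1.0 - np.exp(-t / tau2))


def normalize(trace: DecayTrace) -> NormalizedTrace:
    """Background-subtract and normalise to the t = 0 image.

    value(t) = (fiber(t) - background(t)) / (fiber(0) - background(0)).
    Rejects traces whose corrected t = 0 intensity is not positive.
    """
    corrected = trace.fiber_intensity - trace.background_intensity
    if corrected[0] <= 0:
        raise ValueError(
            f"fiber {trace.fiber_id}/{trace.region_id}: corrected intensity "
            f"at t=0 is {corrected[0]:.3g} (must be > 0); trace rejected"
        )
    return NormalizedTrace(
        trace.time_s,
        corrected / corrected[0],
        trace.fiber_id,
        trace.region_id,
        trace.group,
        trace.isotype,
    )


def _amplitudes(t, y, tau1, tau2):
    """Least-squares amplitudes for fixed time constants (variable projection)."""
    basis = np.stack([1.0 - np.exp(-t / tau1), 1.0 - np.exp(-t / tau2)], axis=1)
    coef, *_ = np.linalg.lstsq(basis, 1.0 - y, rcond=None)
    resid = (1.0 - y) - basis @ coef
    return coef, float(resid @ resid)


def _ordered(p1, tau1, p2, tau2):
    if tau1 <= tau2:
        return p1, tau1, p2, tau2
    return p2, tau2, p1, tau1


def fit_decay(trace: NormalizedTrace) -> RelaxFit:
    """Unconstrained least-squares fit of the double-exponential model.

    Multi-start over a T1 x T2 grid with linearly solved amplitudes; the
    best start is refined with full 4-parameter nonlinear least squares
    (time constants in log space to stay positive).  Non-convergence from
    every start flags the fit.
    """
    t, y = trace.time_s, trace.value
    if t.size < 8:
        raise ValueError("need at least 8 time points to fit")

    best = None
    for tau1 in T1_STARTS:
        for tau2 in T2_STARTS:
            (a1, a2), rss = _amplitudes(t, y, tau1, tau2)
            if best is None or rss < best[4]:
                best = (a1, tau1, a2, tau2, rss)

    p1, tau1, p2, tau2, _ = best

    def resid(theta):
        q1, lt1, q2, lt2 = theta
        return decay_model(t, q1, np.exp(lt1), q2, np.exp(lt2)) - y

    converged = True
    try:
        sol = least_squares(
            resid,
            [p1, np.log(tau1), p2, np.log(tau2)],
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        p1, t1 = sol.x[0], float(np.exp(sol.x[1]))
        p2, t2 = sol.x[2], float(np.exp(sol.x[3]))
        rss = float(2 * sol.cost)
        converged = sol.status > 0 and np.isfinite(sol.x).all()
    except (ValueError, RuntimeError):
        t1, t2 = tau1, tau2
        rss = best[4]
        converged = False

    p1, t1, p2, t2 = _ordered(float(p1), t1, float(p2), t2)
    return RelaxFit(
        p1, t1, p2, t2, rss, converged, t.size,
        trace.fiber_id, trace.group, trace.isotype,
    )


def fit_decay_batch(time_s: np.ndarray, values: np.ndarray, n_iter: int = 40):
    """Fit the double-exponential model to many traces on a shared grid.

    Vectorised variable projection over the start grid followed by batched
    damped Gauss-Newton on (P1, log T1, P2, log T2) for all traces at once.
    Returns a DataFrame with columns p1, t1, p2, t2, rss (phases ordered
    T1 < T2).  Agrees with per-trace :func:`fit_decay` to fitting
    tolerance; exists because cohort-scale work fits tens of thousands of
    traces.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.atleast_2d(np.asarray(values, dtype=float))  # (n, m)
    n = y.shape[0]

    # grid + linear amplitudes, vectorised across traces
    best_rss = np.full(n, np.inf)
    theta = np.zeros((n, 4))
    target = 1.0 - y
    for tau1 in T1_STARTS:
        for tau2 in T2_STARTS:
            basis = np.stack(
                [1.0 - np.exp(-t / tau1), 1.0 - np.exp(-t / tau2)], axis=1
            )
            coef = np.linalg.lstsq(basis, target.T, rcond=None)[0].T  # (n, 2)
            rss = np.sum((target - coef @ basis.T) ** 2, axis=1)
            upd = rss < best_rss
            best_rss[upd] = rss[upd]
            theta[upd] = np.column_stack(
                [
                    coef[upd, 0],
                    np.full(upd.sum(), np.log(tau1)),
                    coef[upd, 1],
                    np.full(upd.sum(), np.log(tau2)),
                ]
            )

    lam = np.full(n, 1e-3)
    rss = best_rss

    def model_and_jac(th):
        p1, lt1, p2, lt2 = th[:, 0:1], th[:, 1:2], th[:, 2:3], th[:, 3:4]
        tau1, tau2 = np.exp(lt1), np.exp(lt2)
        e1 = np.exp(-t[None, :] / tau1)
        e2 = np.exp(-t[None, :] / tau2)
        pred = 1.0 - p1 * (1.0 - e1) - p2 * (1.0 - e2)
        # d pred / d logT = P * e * t/T  (chain rule through T = exp(logT))
        jac = np.stack(
            [
                -(1.0 - e1),
                p1 * e1 * t[None, :] / tau1,
                -(1.0 - e2),
                p2 * e2 * t[None, :] / tau2,
            ],
            axis=2,
        )  # (n, m, 4)
        return pred, jac

    for _ in range(n_iter):
        pred, jac = model_and_jac(theta)
        r = y - pred
        jtj = np.einsum("nmi,nmj->nij", jac, jac)
        jtr = np.einsum("nmi,nm->ni", jac, r)
        step = np.linalg.solve(
            jtj + (lam[:, None, None] * np.eye(4)[None]), jtr[..., None]
        )[..., 0]
        trial = theta + step
        pred_t, _ = model_and_jac(trial)
        rss_t = np.sum((y - pred_t) ** 2, axis=1)
        better = rss_t <= rss
        theta[better] = trial[better]
        rss = np.where(better, rss_t, rss)
        lam = np.where(better, lam * 0.3, lam * 5.0)

    p1, t1 = theta[:, 0], np.exp(theta[:, 1])
    p2, t2 = theta[:, 2], np.exp(theta[:, 3])
    swap = t1 > t2
    p1s = np.where(swap, p2, p1)
    t1s = np.where(swap, t2, t1)
    p2s = np.where(swap, p1, p2)
    t2s = np.where(swap, t1, t2)
    return pd.DataFrame({"p1": p1s, "t1": t1s, "p2": p2s, "t2": t2s, "rss": rss})


def fiber_summary(region_fits: list[RelaxFit]) -> RelaxFit:
    """Per-fiber parameters as the unweighted mean over converged regions."""
    good = [f for f in region_fits if f.converged]
    if not good:
        raise ValueError("all regions of the fiber failed to fit")
    arr = np.array([[f.p1, f.t1, f.p2, f.t2] for f in good])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(good) > 1 else np.zeros(4)
    ref = good[0]
    return RelaxFit(
        *mean,
        rss=float(np.mean([f.rss for f in good])),
        converged=True,
        n_points=ref.n_points,
        fiber_id=ref.fiber_id,
        group=ref.group,
        isotype=ref.isotype,
        region_sd={"p1": sd[0], "t1": sd[1], "p2": sd[2], "t2": sd[3]},
    )


def drx_srx_ratio(fit: RelaxFit) -> float:
    """DRX/SRX population ratio P1/P2; undefined (NaN) when P2 <= 0."""
    if fit.p2 <= 0:
        warnings.warn(
            f"fiber {fit.fiber_id}: P2 = {fit.p2:.3g} <= 0, DRX/SRX ratio undefined",
            stacklevel=2,
        )
        return float("nan")
    return fit.p1 / fit.p2


def read_traces_csv(path) -> list[DecayTrace]:
    """Read region traces from CSV.

    Expected columns: time_s, fiber_intensity, background_intensity,
    fiber_id, region_id, group, isotype.
    """
    df = pd.read_csv(path)
    traces = []
    for (fid, rid), sub in df.groupby(["fiber_id", "region_id"], sort=False):
        sub = sub.sort_values("time_s")
        traces.append(
            DecayTrace(
                sub["time_s"].to_numpy(),
                sub["fiber_intensity"].to_numpy(),
                sub["background_intensity"].to_numpy(),
                fiber_id=str(fid),
                region_id=str(rid),
                group=str(sub["group"].iloc[0]),
                isotype=str(sub["isotype"].iloc[0]),
            )
        )
    return traces


def fit_traces(traces: list[DecayTrace]) -> pd.DataFrame:
    """Normalise, fit and aggregate regions to one row per fiber.

    Regions whose normalisation or fit fails are dropped (counted in the
    ``n_failed_regions`` column); fibers with no surviving region are
    excluded.
    """
    by_fiber: dict[str, list[RelaxFit]] = {}
    failed: dict[str, int] = {}
    for trace in traces:
        try:
            fit = fit_decay(normalize(trace))
            if not fit.converged:
                raise ValueError("non-convergent")
        except ValueError:
            failed[trace.fiber_id] = failed.get(trace.fiber_id, 0) + 1
            continue
        by_fiber.setdefault(trace.fiber_id, []).append(fit)

    rows = []
    for fid, fits in by_fiber.items():
        summary = fiber_summary(fits)
        rows.append(
            {
                "fiber_id": fid,
                "group": summary.group,
                "isotype": summary.isotype,
                "p1": summary.p1,
                "t1": summary.t1,
                "p2": summary.p2,
                "t2": summary.t2,
                "drx_srx_ratio": drx_srx_ratio(summary),
                "n_regions": len(fits),
                "n_failed_regions": failed.get(fid, 0),
            }
        )
    return pd.DataFrame(rows)
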