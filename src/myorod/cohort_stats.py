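"""Cohort statistics: pooled controls, one-way ANOVA, Dunnett post hoc.

Measurements from several non-control groups are each compared against a
single (pooled) control group.  The omnibus test is a one-way ANOVA;
per-group comparisons use Dunnett's many-to-one procedure, whose adjusted
p-values come from the multivariate t distribution with the one-way
correlation structure (handles unbalanced designs such as 73 control vs
214 patient fibers).  Comparisons are two-sided; significance defaults to
alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DunnettResult", "pool_controls", "anova_dunnett"]


@dataclass(frozen=True)
class DunnettResult:
    f_statistic: float
    f_pvalue: float
    comparisons: pd.DataFrame  # group, n, mean_diff, statistic, p_adj, reject
    alpha: float
    control: str


def pool_controls(
    df: pd.DataFrame,
    control_labels,
    value: str = "value",
    group: str = "group",
    pooled_label: str = "control",
) -> pd.DataFrame:
    """Relabel several control groups as one pooled control group."""
    out = df.copy()
    out.loc[out[group].isin(set(control_labels)), group] = pooled_label
    return out


def anova_dunnett(
    df: pd.DataFrame,
    control: str = "control",
    value: str = "value",
    group: str = "group",
    alpha: float = 0.05,
    random_state: int | None = 0,
) -> DunnettResult:
    """One-way ANOVA with Dunnett's test of every group against control.

    ``df`` needs one row per observation with a value column and a group
    label column; the control group must be non-empty.  Groups with fewer
    than two observations are excluded with a warning.  ``random_state``
    seeds the quasi-Monte-Carlo evaluation of the multivariate-t
    probabilities so adjusted p-values are reproducible.
    """
    if control not in set(df[group]):
        raise ValueError(f"control group {control!r} not present")
    control_vals = df.loc[df[group] == control, value].to_numpy(dtype=float)
    if control_vals.size < 2:
        raise ValueError("control group needs at least 2 observations")

    names, samples = [], []
    for name, sub in df[df[group] != control].groupby(group, sort=True):
        vals = sub[value].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(
                f"group {name!r} has < 2 observations; excluded", stacklevel=2
            )
            continue
        names.append(name)
        samples.append(vals)
    if not samples:
        raise ValueError("no comparison group with >= 2 observations")

    f_stat, f_p = stats.f_oneway(control_vals, *samples)
    res = stats.dunnett(
        *samples,
        control=control_vals,
        alternative="two-sided",
        random_state=random_state,
    )
    table = pd.DataFrame(
        {
            "group": names,
            "n": [s.size for s in samples],
            "mean_diff": [s.mean() - control_vals.mean() for s in samples],
            "statistic": res.statistic,
            "p_adj": res.pvalue,
            "reject": res.pvalue < alpha,
        }
    )
    return DunnettResult(float(f_stat), float(f_p), table, alpha, control)
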