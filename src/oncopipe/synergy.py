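"""Median-effect modeling and Chou-Talalay combination-index analysis.

Single agents are fit to the median-effect equation fa/(1-fa) = (D/Dm)^m by
ordinary least squares on the linearized (log-log) form. For a combination
point with fraction affected fa, the dose of each drug alone that would produce
fa is Dx_i = Dm_i * (fa/(1-fa))^(1/m_i), and the two-term (mutually exclusive)
combination index is CI = d_a/Dx_a + d_b/Dx_b: CI < 1 synergism, CI = 1
additivity, CI > 1 antagonism.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MedianEffectFit",
    "CombinationPoint",
    "fit_median_effect",
    "combination_index",
    "analyze_combination",
]

FA_CLIP = (0.01, 0.99)
ADDITIVITY_TOL = 0.05


@dataclass
class MedianEffectFit:
    dm: float          # median-effect dose (units of the input doses)
    m: float           # shape
    r: float           # Pearson correlation of the linearized fit
    n_points: int

    def fa(self, dose):
        ratio = np.power(np.asarray(dose, dtype=float) / self.dm, self.m)
        return ratio / (1.0 + ratio)

    def dx(self, fa: float) -> float:
        """Dose of this drug alone producing fraction affected fa."""
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass
class CombinationPoint:
    dose_a: float
    dose_b: float
    fa: float
    ci: float
    label: str         # synergism | additive | antagonism


def fit_median_effect(doses, fa, clip: tuple = FA_CLIP) -> MedianEffectFit:
    """OLS fit of log10(fa/(1-fa)) against log10(dose).

    Points with fa outside the clip bounds are excluded with a warning
    (extreme fractions are unreliable on the logit scale); at least 3 usable
    points are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    usable = (fa > clip[0]) & (fa < clip[1]) & (doses > 0)
    if usable.sum() < len(fa):
        warnings.warn(f"excluding {int(len(fa) - usable.sum())} points with fa "
                      f"outside ({clip[0]}, {clip[1]}) or zero dose")
    doses, fa = doses[usable], fa[usable]
    if len(doses) < 3:
        raise ValueError("median-effect fit needs >= 3 points with usable fa")
    y = np.log10(fa / (1.0 - fa))
    x = np.log10(doses)
    if np.ptp(y) == 0:
        raise ValueError("all fa values identical: median-effect slope undefined")
    res = stats.linregress(x, y)
    m = res.slope
    if m <= 0:
        raise ValueError("non-positive median-effect slope: fa must increase with dose")
    dm = 10.0 ** (-res.intercept / m)
    return MedianEffectFit(dm=float(dm), m=float(m), r=float(res.rvalue),
                           n_points=len(doses))


def combination_index(dose_a: float, dose_b: float, fa: float,
                      fit_a: MedianEffectFit, fit_b: MedianEffectFit,
                      additivity_tol: float = ADDITIVITY_TOL) -> CombinationPoint:
    """Two-term combination index of a single combination point.

    A dose of 0 for either drug contributes nothing to the sum, so a point
    with one drug absent scores CI = 1 exactly when the other drug sits at its
    own Dx(fa). fa must lie strictly inside (0, 1).
    """
    if not 0.0 < fa < 1.0:
        raise ValueError("CI is undefined at fa = 0 (no inhibition) or fa = 1 "
                         "(complete inhibition)")
    ci = 0.0
    if dose_a > 0:
        ci += dose_a / fit_a.dx(fa)
    if dose_b > 0:
        ci += dose_b / fit_b.dx(fa)
    if abs(ci - 1.0) <= additivity_tol:
        label = "additive"
    elif ci < 1.0:
        label = "synergism"
    else:
        label = "antagonism"
    return CombinationPoint(float(dose_a), float(dose_b), float(fa), float(ci), label)


def analyze_combination(table: pd.DataFrame,
                        additivity_tol: float = ADDITIVITY_TOL
                        ) -> tuple[MedianEffectFit, MedianEffectFit, pd.DataFrame]:
    """Full synergy analysis of a (dose_a, dose_b, fa) table.

    Rows with exactly one zero dose are the single-agent series used for the
    median-effect fits; rows with both doses positive are scored for CI.
    Returns (fit_a, fit_b, ci_table).
    """
    required = {"dose_a", "dose_b", "fa"}
    if not required.issubset(table.columns):
        raise ValueError(f"combination table must have columns {sorted(required)}")
    single_a = table[(table["dose_a"] > 0) & (table["dose_b"] == 0)]
    single_b = table[(table["dose_b"] > 0) & (table["dose_a"] == 0)]
    combos = table[(table["dose_a"] > 0) & (table["dose_b"] > 0)]
    fit_a = fit_median_effect(single_a["dose_a"], single_a["fa"])
    fit_b = fit_median_effect(single_b["dose_b"], single_b["fa"])
    rows = []
    for _, row in combos.iterrows():
        fa = float(row["fa"])
        if not 0.0 < fa < 1.0:
            rows.append({"dose_a": row["dose_a"], "dose_b": row["dose_b"],
                         "fa": fa, "ci": math.nan, "label": "undefined"})
            continue
        pt = combination_index(row["dose_a"], row["dose_b"], fa, fit_a, fit_b,
                               additivity_tol)
        rows.append({"dose_a": pt.dose_a, "dose_b": pt.dose_b, "fa": pt.fa,
                     "ci": pt.ci, "label": pt.label})
    return fit_a, fit_b, pd.DataFrame(rows)
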