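"""Growth-rate-inhibition (GR) dose-response analysis.

GR values normalize drug response by the growth rate of untreated cells,
GR(c) = 2^(k(c)/k(0)) - 1 with k = log2(x_t/x_0)/t, which makes the metric
independent of cell doubling time: GR = 1 means no effect, GR = 0 complete
cytostasis, GR < 0 net cell loss. Per (cell line, drug) the module fits a
sigmoidal GR curve, derives GR50 (potency), GRmax (efficacy), GR_AOC (both,
fit-free), fits a four-parameter logistic to relative viability for the
absolute IC50, and applies drug-specific sensitivity cutoffs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import gr_hill

__all__ = [
    "GRCurveFit",
    "GRMetrics",
    "DEFAULT_SENSITIVITY_CUTOFFS_NM",
    "compute_gr_table",
    "fit_gr_curve",
    "gr_metrics_summary",
    "fit_viability_ic50",
    "classify_sensitivity",
    "analyze_plates",
]

#: Absolute-IC50 sensitivity cutoffs (nM), strict less-than.
DEFAULT_SENSITIVITY_CUTOFFS_NM = {
    "gedatolisib": 100.0,
    "alpelisib": 3000.0,
    "capivasertib": 3000.0,
    "everolimus": 50.0,
}

NOT_REACHED = ">max_tested"
BELOW_RANGE = "<min_tested"
UNSTABLE = "unstable"


@dataclass
class GRCurveFit:
    gr_inf: float
    gec50: float
    hill: float
    rss: float
    status: str          # ok | flat | not_reached | unstable
    n_points: int


@dataclass
class GRMetrics:
    gr50: float | str
    gr_max: float
    gr_aoc: float
    ic50: float | str | None = None
    sensitive: bool | None = None


def compute_gr_table(data: pd.DataFrame, background: float = 0.0) -> pd.DataFrame:
    """Compute per-concentration GR values and relative viability.

    ``data`` is a long-format plate table (cell_line, drug, conc_nM, replicate,
    signal_t0, signal_t, duration_h); conc_nM == 0 marks vehicle wells. Growth
    rates are computed from replicate-mean signals; wells with non-positive
    background-subtracted signal are excluded with a warning.
    """
    df = data.copy()
    for col in ("signal_t0", "signal_t"):
        df[col] = df[col] - background
    bad = (df["signal_t0"] <= 0) | (df["signal_t"] <= 0)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} wells with non-positive "
                      "background-subtracted signal")
        df = df[~bad]

    out = []
    for cl, cl_df in df.groupby("cell_line", sort=False):
        veh = cl_df[cl_df["conc_nM"] == 0]
        if veh.empty:
            raise ValueError(f"cell line {cl!r} has no vehicle (conc 0) wells")
        t = float(cl_df["duration_h"].iloc[0])
        x0_v, xt_v = veh["signal_t0"].mean(), veh["signal_t"].mean()
        k0 = math.log2(xt_v / x0_v) / t
        if k0 <= 0:
            raise ValueError(f"vehicle wells of {cl!r} show no growth (k(0) <= 0)")
        out.append((cl, veh["drug"].iloc[0], 0.0, 1.0, 1.0, len(veh)))
        treated = cl_df[cl_df["conc_nM"] > 0]
        for (drug, conc), grp in treated.groupby(["drug", "conc_nM"], sort=True):
            kc = math.log2(grp["signal_t"].mean() / grp["signal_t0"].mean()) / t
            gr = 2.0 ** (kc / k0) - 1.0
            rv = grp["signal_t"].mean() / xt_v
            out.append((cl, drug, float(conc), gr, rv, len(grp)))
    return pd.DataFrame(out, columns=["cell_line", "drug", "conc_nM", "gr_value",
                                      "relative_viability", "n_replicates"])


def _hits_bound(value: float, lo: float, hi: float, rtol: float = 1e-3) -> bool:
    span = hi - lo
    return (value - lo) < rtol * span or (hi - value) < rtol * span


def fit_gr_curve(conc: np.ndarray, gr: np.ndarray, alpha: float = 0.05) -> GRCurveFit:
    """Least-squares sigmoidal fit of GR values over nonzero concentrations.

    Bounds: gr_inf in [-1, 1], hill in (0.1, 5], gec50 in
    [min_conc/100, max_conc*100]. status='flat' when an F-test against the
    constant-GR model is non-significant at ``alpha``; 'unstable' when the
    optimizer fails or gec50/hill land on a bound.
    """
    conc = np.asarray(conc, dtype=float)
    gr = np.asarray(gr, dtype=float)
    mask = conc > 0
    conc, gr = conc[mask], gr[mask]
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct nonzero concentrations to fit")
    n = len(gr)
    lo = [-1.0, conc.min() / 100.0, 0.1]
    hi = [1.0, conc.max() * 100.0, 5.0]

    gr_mean = gr.mean()
    rss0 = float(np.sum((gr - gr_mean) ** 2))

    best = None
    for gec50_init in np.geomspace(conc.min(), conc.max(), 4):
        p0 = [max(-1.0, min(1.0, gr.min())), gec50_init, 1.0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(gr_hill, conc, gr, p0=p0,
                                             bounds=(lo, hi), maxfev=5000)
            rss = float(np.sum((gr_hill(conc, *popt) - gr) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        return GRCurveFit(np.nan, np.nan, np.nan, np.nan, "unstable", n)
    popt, rss1 = best

    # F-test vs constant model (3 vs 1 parameters)
    df1 = n - 3
    scale = max(rss0, 1.0)
    if df1 <= 0:
        p_flat = 1.0
    elif rss1 <= 1e-14 * scale:
        p_flat = 1.0 if rss0 <= 1e-14 * scale else 0.0
    else:
        fstat = ((rss0 - rss1) / 2.0) / (rss1 / df1)
        p_flat = float(stats.f.sf(max(fstat, 0.0), 2, df1))
    if p_flat >= alpha:
        return GRCurveFit(float(popt[0]), float(popt[1]), float(popt[2]), rss1, "flat", n)
    if _hits_bound(math.log(popt[1]), math.log(lo[1]), math.log(hi[1])) or \
       _hits_bound(popt[2], lo[2], hi[2]):
        return GRCurveFit(float(popt[0]), float(popt[1]), float(popt[2]), rss1, "unstable", n)
    return GRCurveFit(float(popt[0]), float(popt[1]), float(popt[2]), rss1, "ok", n)


def _gr50_from_fit(fit: GRCurveFit) -> float:
    """Analytic dose where the fitted curve crosses GR = 0.5 (inf if never)."""
    if fit.gr_inf >= 0.5:
        return math.inf
    ratio = (1.0 - fit.gr_inf) / (0.5 - fit.gr_inf) - 1.0
    if ratio <= 0:
        return math.inf
    return fit.gec50 * ratio ** (1.0 / fit.hill)


def _interp_crossing(conc: np.ndarray, gr: np.ndarray, level: float = 0.5) -> float:
    """First log-linear interpolated crossing of GR = level, inf if none."""
    order = np.argsort(conc)
    c, g = np.log10(conc[order]), gr[order]
    for i in range(len(g) - 1):
        lo_g, hi_g = g[i], g[i + 1]
        if (lo_g - level) * (hi_g - level) <= 0 and lo_g != hi_g:
            frac = (lo_g - level) / (lo_g - hi_g)
            return 10.0 ** (c[i] + frac * (c[i + 1] - c[i]))
    return math.inf


def gr_metrics_summary(fit: GRCurveFit, conc: np.ndarray, gr: np.ndarray) -> GRMetrics:
    """Derive GR50 / GRmax / GR_AOC from a curve fit and the raw GR values.

    GR50 comes from the fitted curve when the fit is usable (sentinel
    '>max_tested' if the crossing lies beyond max dose * 10, '<min_tested' if
    below min dose / 10); for unstable fits, log-linear interpolation on the
    raw values is the fallback, with sentinel 'unstable' when no raw crossing
    exists. GRmax is the mean raw GR at the highest tested dose. GR_AOC is the
    trapezoidal integral of (1 - GR) over log10 concentration on the raw
    per-dose means, with no curve fit and no range normalization.
    """
    conc = np.asarray(conc, dtype=float)
    gr = np.asarray(gr, dtype=float)
    mask = conc > 0
    conc, gr = conc[mask], gr[mask]
    per_dose = pd.Series(gr).groupby(pd.Series(conc)).mean()
    doses = per_dose.index.to_numpy(dtype=float)
    gr_mean = per_dose.to_numpy()

    gr_max = float(gr_mean[np.argmax(doses)])
    gr_aoc = float(np.trapezoid(1.0 - gr_mean, np.log10(doses)))

    if fit.status == "unstable":
        cross = _interp_crossing(doses, gr_mean)
        gr50: float | str = cross if math.isfinite(cross) else UNSTABLE
    else:
        cross = _gr50_from_fit(fit)
        if not math.isfinite(cross) or cross > doses.max() * 10.0:
            gr50 = NOT_REACHED
        elif cross < doses.min() / 10.0:
            gr50 = BELOW_RANGE
        else:
            gr50 = float(cross)
    return GRMetrics(gr50=gr50, gr_max=gr_max, gr_aoc=gr_aoc)


def _logistic4(conc, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + np.power(conc / ec50, hill))


def fit_viability_ic50(conc: np.ndarray, viability: np.ndarray) -> float | str:
    """Absolute IC50 from a four-parameter logistic fit on relative viability.

    The absolute IC50 is the dose where the fitted curve crosses viability =
    0.5 (not the inflection point); sentinel '>max_tested' when the fitted
    curve never reaches 0.5 within the tested range extended by one decade.
    """
    conc = np.asarray(conc, dtype=float)
    viability = np.asarray(viability, dtype=float)
    mask = conc > 0
    conc, viability = conc[mask], viability[mask]
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct nonzero concentrations to fit")
    lo = [0.0, 0.5, conc.min() / 100.0, 0.1]
    hi = [0.6, 1.5, conc.max() * 100.0, 5.0]
    best = None
    for ec50_init in np.geomspace(conc.min(), conc.max(), 4):
        p0 = [max(0.0, min(0.6, viability.min())), min(1.5, max(0.5, viability.max())),
              ec50_init, 1.0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(_logistic4, conc, viability, p0=p0,
                                             bounds=(lo, hi), maxfev=5000)
            rss = float(np.sum((_logistic4(conc, *popt) - viability) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        return NOT_REACHED
    bottom, top, ec50, hillc = best[0]
    if not (bottom < 0.5 < top):
        return NOT_REACHED
    ic50 = ec50 * ((top - 0.5) / (0.5 - bottom)) ** (1.0 / hillc)
    if ic50 > conc.max() * 10.0:
        return NOT_REACHED
    return float(ic50)


def classify_sensitivity(drug: str, ic50, cutoffs: dict | None = None) -> bool:
    """Strict less-than comparison of an absolute IC50 against the drug cutoff."""
    cutoffs = cutoffs if cutoffs is not None else DEFAULT_SENSITIVITY_CUTOFFS_NM
    if drug not in cutoffs:
        raise KeyError(f"no sensitivity cutoff configured for drug {drug!r}")
    if isinstance(ic50, str) or ic50 is None or not math.isfinite(ic50):
        return False
    return ic50 < cutoffs[drug]


def analyze_plates(data: pd.DataFrame, background: float = 0.0,
                   cutoffs: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-(cell line, drug) GR analysis of a plate table.

    Returns (gr_table, metrics_table); the metrics table has one row per pair
    with fit parameters, status, GR50/GRmax/GR_AOC, absolute IC50, and the
    sensitivity call where a cutoff is configured.
    """
    gr_table = compute_gr_table(data, background=background)
    rows = []
    treated = gr_table[gr_table["conc_nM"] > 0]
    for (cl, drug), grp in treated.groupby(["cell_line", "drug"], sort=False):
        conc = grp["conc_nM"].to_numpy()
        gr = grp["gr_value"].to_numpy()
        fit = fit_gr_curve(conc, gr)
        met = gr_metrics_summary(fit, conc, gr)
        ic50 = fit_viability_ic50(conc, grp["relative_viability"].to_numpy())
        try:
            sensitive = classify_sensitivity(drug, ic50, cutoffs)
        except KeyError:
            sensitive = None
        rows.append({"cell_line": cl, "drug": drug, "gr_inf": fit.gr_inf,
                     "gec50_nM": fit.gec50, "hill": fit.hill, "rss": fit.rss,
                     "fit_status": fit.status, "gr50_nM": met.gr50,
                     "gr_max": met.gr_max, "gr_aoc": met.gr_aoc,
                     "ic50_nM": ic50, "sensitive": sensitive})
    return gr_table, pd.DataFrame(rows)
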