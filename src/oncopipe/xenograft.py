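"""Xenograft efficacy analysis: tumor volumes, TGI, welfare flags, statistics.

Tumor volume uses the caliper formula V = L * W^2 / 2 with L the longest
dimension (inputs are swapped if entered in the wrong order). Tumor growth
inhibition (TGI) is baseline-adjusted by default,
TGI = 100 * (1 - dV_treated / dV_control) with dV = mean V(day) - mean V(0),
appropriate for studies randomized at an established tumor size; the simple
endpoint-ratio form 100 * (1 - V_t/V_c) is available behind ``formula``.
Animals losing strictly more than 20% of their day-0 body weight are flagged
for euthanasia. Between-arm comparison is a one-way ANOVA on volumes at the
requested day plus Holm-adjusted pairwise t-tests against the control arm.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "tumor_volume",
    "add_volumes",
    "volumes_at_day",
    "tgi",
    "body_weight_change",
    "group_compare",
    "significance_stars",
    "arm_summary",
]

WEIGHT_LOSS_LIMIT_PCT = -20.0
DAY_WINDOW = 2.0


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume V = L * W^2 / 2 (mm^3), enforcing L >= W."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor dimensions must be > 0")
    if width_mm > length_mm:
        warnings.warn("width > length: swapping to keep L the longest dimension")
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm * width_mm / 2.0


def add_volumes(study: pd.DataFrame) -> pd.DataFrame:
    """Append a volume_mm3 column to a measurement table."""
    df = study.copy()
    length = df[["length_mm", "width_mm"]].max(axis=1)
    width = df[["length_mm", "width_mm"]].min(axis=1)
    if (df["width_mm"] > df["length_mm"]).any():
        warnings.warn("some rows have width > length: dimensions normalized")
    if (width <= 0).any():
        raise ValueError("tumor dimensions must be > 0")
    df["volume_mm3"] = length * width * width / 2.0
    return df


def volumes_at_day(study: pd.DataFrame, day: float,
                   window: float = DAY_WINDOW) -> pd.Series:
    """Per-animal volume at (or carried forward to within +/- window of) a day."""
    df = study if "volume_mm3" in study.columns else add_volumes(study)
    eligible = df[df["day"] <= day + window].sort_values("day", kind="stable")
    last = eligible.groupby("animal").tail(1)
    last = last[(last["day"] - day).abs() <= window]
    if last.empty:
        raise ValueError(f"no animal has a measurement within +/-{window} days of {day}")
    return pd.Series(last["volume_mm3"].to_numpy(), index=last["animal"].to_numpy(),
                     name="volume_mm3")


def tgi(study: pd.DataFrame, day: float, control_arm: str,
        formula: str = "delta", window: float = DAY_WINDOW) -> pd.DataFrame:
    """Tumor growth inhibition per treated arm at a given day.

    Returns a table with raw and display (capped at 100 for regressing tumors)
    TGI per arm. Raises when the control arm shows no net growth (dV <= 0),
    under which the baseline-adjusted form is undefined.
    """
    df = add_volumes(study) if "volume_mm3" not in study.columns else study.copy()
    arms = df[["animal", "arm"]].drop_duplicates().set_index("animal")["arm"]
    v_day = volumes_at_day(df, day, window)
    v0 = volumes_at_day(df, float(df["day"].min()), window=0.0)
    rows = []
    mean_day = v_day.groupby(arms.reindex(v_day.index)).mean()
    mean_0 = v0.groupby(arms.reindex(v0.index)).mean()
    if control_arm not in mean_day.index:
        raise ValueError(f"control arm {control_arm!r} not measured at day {day}")
    if formula == "delta":
        dv = mean_day - mean_0
        dv_c = dv[control_arm]
        if dv_c <= 0:
            raise ValueError("control arm shows no net growth: delta-based TGI undefined")
        for arm in mean_day.index:
            raw = 100.0 * (1.0 - dv[arm] / dv_c)
            rows.append({"arm": arm, "day": day, "tgi_pct_raw": raw,
                         "tgi_pct": min(raw, 100.0)})
    elif formula == "ratio":
        v_c = mean_day[control_arm]
        if v_c <= 0:
            raise ValueError("control mean volume must be > 0")
        for arm in mean_day.index:
            raw = 100.0 * (1.0 - mean_day[arm] / v_c)
            rows.append({"arm": arm, "day": day, "tgi_pct_raw": raw,
                         "tgi_pct": min(raw, 100.0)})
    else:
        raise ValueError("formula must be 'delta' or 'ratio'")
    return pd.DataFrame(rows)


def body_weight_change(study: pd.DataFrame) -> pd.DataFrame:
    """Per-animal per-day body-weight percent change from day 0, with flags.

    The euthanasia flag fires when an animal has lost strictly more than 20%
    of its day-0 weight (change < -20).
    """
    df = study.copy()
    day0 = float(df["day"].min())
    w0 = df[df["day"] == day0].set_index("animal")["body_weight_g"]
    missing = set(df["animal"]) - set(w0.index)
    if missing:
        raise ValueError(f"animals without day-0 body weight: {sorted(missing)}")
    base = df["animal"].map(w0)
    df["weight_change_pct"] = 100.0 * (df["body_weight_g"] - base) / base
    df["euthanize_flag"] = df["weight_change_pct"] < WEIGHT_LOSS_LIMIT_PCT
    return df[["animal", "arm", "day", "body_weight_g", "weight_change_pct",
               "euthanize_flag"]]


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * < 0.05, ** < 0.01, *** < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_compare(study: pd.DataFrame, day: float, control_arm: str,
                  window: float = DAY_WINDOW) -> dict:
    """One-way ANOVA across arms at a day, plus Holm-adjusted t-tests vs control."""
    df = add_volumes(study) if "volume_mm3" not in study.columns else study.copy()
    arms = df[["animal", "arm"]].drop_duplicates().set_index("animal")["arm"]
    v = volumes_at_day(df, day, window)
    arm_of = arms.reindex(v.index)
    groups = {arm: v.loc[members.index].to_numpy()
              for arm, members in v.groupby(arm_of)}
    if len(groups) < 2:
        raise ValueError("group comparison needs >= 2 arms")
    for arm, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"arm {arm!r} has < 2 animals at day {day}")
    fstat, p_anova = stats.f_oneway(*groups.values())
    if np.isnan(fstat):  # zero within-group variance in every arm, identical means
        fstat, p_anova = 0.0, 1.0
    pairwise = []
    treated_arms = [a for a in groups if a != control_arm]
    raw_p = []
    for arm in treated_arms:
        t, p = stats.ttest_ind(groups[arm], groups[control_arm])
        raw_p.append(p if np.isfinite(p) else 1.0)
        pairwise.append({"arm": arm, "t": float(t) if np.isfinite(t) else 0.0})
    if raw_p:
        adj = multipletests(raw_p, method="holm")[1]
        for rec, p, padj in zip(pairwise, raw_p, adj):
            rec.update(p=float(p), p_holm=float(padj), stars=significance_stars(padj))
    return {"day": day, "anova_F": float(fstat), "anova_p": float(p_anova),
            "anova_stars": significance_stars(p_anova), "pairwise_vs_control": pairwise}


def arm_summary(study: pd.DataFrame) -> pd.DataFrame:
    """Mean volume +/- SEM and n per arm per day."""
    df = add_volumes(study) if "volume_mm3" not in study.columns else study.copy()
    g = df.groupby(["arm", "day"])["volume_mm3"]
    out = g.agg(mean_volume_mm3="mean", n="size").reset_index()
    out["sem_mm3"] = g.sem().to_numpy()
    return out
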