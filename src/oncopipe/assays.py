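"""Flow-cytometry summarization and qPCR ddCt relative expression.

Flow events are gated on the viability dye (amine-reactive dead-cell dye: low
signal = live), summarized as median fluorescence intensity (MFI) after
unstained-background subtraction for the phospho-channels and as the fraction
of EdU-positive cells, then normalized to the vehicle control (set at 1).
Positivity thresholds are the equal-posterior point of a two-component
Gaussian mixture fit to log intensity. qPCR relative expression follows the
ddCt method with the arithmetic mean of two reference-gene Cts (HPRT1, ACTB)
as the per-sample normalizer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

__all__ = [
    "mixture_threshold",
    "flow_summarize",
    "percent_inhibition",
    "ddct_expression",
]

REFERENCE_GENES = ("HPRT1", "ACTB")
FLOW_CHANNELS = ("prps6", "p4ebp1")
MIN_EVENTS = 100


def mixture_threshold(intensity: np.ndarray, seed: int = 0) -> float:
    """Separation threshold between the two modes of a log-intensity mixture.

    Fits a 2-component Gaussian mixture on log10 intensity and returns the
    point between the component means where the weighted component densities
    are equal (the valley). Falls back to the midpoint of the means when the
    densities do not cross between them.
    """
    x = np.log10(np.asarray(intensity, dtype=float).clip(min=1e-12)).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(x)
    means = gm.means_.ravel()
    order = np.argsort(means)
    m_lo, m_hi = means[order]
    w = gm.weights_[order]
    sd = np.sqrt(gm.covariances_.ravel())[order]

    def logdens_diff(v):
        lo = np.log(w[0]) - 0.5 * ((v - m_lo) / sd[0]) ** 2 - np.log(sd[0])
        hi = np.log(w[1]) - 0.5 * ((v - m_hi) / sd[1]) ** 2 - np.log(sd[1])
        return lo - hi

    if m_hi - m_lo < 1e-9 or logdens_diff(m_lo) * logdens_diff(m_hi) >= 0:
        cut = 0.5 * (m_lo + m_hi)
    else:
        cut = brentq(logdens_diff, m_lo, m_hi)
    return 10.0 ** cut


def _gate_live(events: pd.DataFrame, threshold: float) -> pd.DataFrame:
    return events[events["viability_dye"] < threshold]


def flow_summarize(events: pd.DataFrame, control: pd.DataFrame,
                   unstained: dict, seed: int = 0) -> dict:
    """Live-gated, control-normalized flow readouts for one treated condition.

    Gating thresholds (viability, EdU) are estimated on the pooled control +
    treated events so both conditions are gated identically. Returns a dict
    with normalized pRPS6/p4EBP1 MFI, normalized EdU+ fraction, the raw values
    per condition, and any floor warnings. All normalized outputs are
    invariant to rescaling every intensity by a positive constant.
    """
    pooled = pd.concat([control, events], ignore_index=True)
    live_cut = mixture_threshold(pooled["viability_dye"], seed=seed)
    live_t = _gate_live(events, live_cut)
    live_c = _gate_live(control, live_cut)
    for name, live in (("treated", live_t), ("control", live_c)):
        if len(live) < MIN_EVENTS:
            raise ValueError(f"only {len(live)} live {name} events after gating "
                             f"(< {MIN_EVENTS})")

    edu_cut = mixture_threshold(
        pd.concat([live_c["edu"], live_t["edu"]], ignore_index=True), seed=seed)
    edu_frac_t = float((live_t["edu"] > edu_cut).mean())
    edu_frac_c = float((live_c["edu"] > edu_cut).mean())
    if edu_frac_c <= 0:
        raise ValueError("control EdU+ fraction is 0: normalization undefined")

    result = {"live_gate": live_cut, "edu_gate": edu_cut,
              "edu_frac": {"control": edu_frac_c, "treated": edu_frac_t},
              "edu_norm": edu_frac_t / edu_frac_c,
              "mfi": {}, "mfi_norm": {}, "warnings": []}
    for ch in FLOW_CHANNELS:
        bg = unstained[ch]
        mfi_c = float(live_c[ch].median()) - bg
        mfi_t = float(live_t[ch].median()) - bg
        if mfi_t <= 0:
            result["warnings"].append(f"{ch}: treated MFI <= 0 after background "
                                      "subtraction, floored at 0")
            warnings.warn(result["warnings"][-1])
            mfi_t = 0.0
        if mfi_c <= 0:
            raise ValueError(f"{ch}: control MFI <= 0 after background subtraction")
        result["mfi"][ch] = {"control": mfi_c, "treated": mfi_t}
        result["mfi_norm"][ch] = mfi_t / mfi_c
    return result


def percent_inhibition(normalized_value: float) -> tuple[float, bool]:
    """Percent inhibition relative to control, 100 * (1 - normalized).

    Values above 1 (stimulation relative to control) report 0% inhibition with
    a stimulation flag.
    """
    if normalized_value < 0:
        raise ValueError("normalized value must be >= 0")
    if normalized_value > 1.0:
        return 0.0, True
    return 100.0 * (1.0 - normalized_value), False


def ddct_expression(ct: pd.DataFrame, target: str, control_condition: str,
                    reference_genes: tuple = REFERENCE_GENES) -> pd.DataFrame:
    """ddCt relative expression of ``target`` per condition vs the control.

    Per sample, dCt = Ct_target - mean(Ct of the reference genes); per
    condition, ddCt = mean dCt(condition) - mean dCt(control); relative
    expression = 2^(-ddCt). Averaging reference Cts arithmetically equals
    normalizing to the geometric mean of reference expression. Samples whose
    replicate Cts have SD > 1 cycle are flagged.
    """
    required = {"sample", "condition", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if not ct["ct"].between(0, 45, inclusive="neither").all():
        raise ValueError("Ct values must lie in (0, 45)")
    wide_sd = (ct.groupby(["sample", "gene"])["ct"].std().dropna() > 1.0)
    flagged = sorted({s for (s, _g), bad in wide_sd.items() if bad})
    if flagged:
        warnings.warn(f"replicate Ct SD > 1 cycle in samples: {flagged}")
    per = ct.groupby(["sample", "condition", "gene"])["ct"].mean().reset_index()
    wide = per.pivot_table(index=["sample", "condition"], columns="gene", values="ct")
    missing = [g for g in (target, *reference_genes) if g not in wide.columns]
    if missing:
        raise ValueError(f"genes missing from Ct table: {missing}")
    if wide[list(reference_genes)].isna().any().any() or wide[target].isna().any():
        raise ValueError("target and both reference genes must be measured in "
                         "every sample")
    dct = wide[target] - wide[list(reference_genes)].mean(axis=1)
    per_cond = dct.groupby(level="condition").mean()
    if control_condition not in per_cond.index:
        raise ValueError(f"control condition {control_condition!r} not in table")
    ddct = per_cond - per_cond[control_condition]
    out = pd.DataFrame({
        "condition": per_cond.index,
        "delta_ct": per_cond.to_numpy(),
        "ddct": ddct.to_numpy(),
        "rel_expression": np.power(2.0, -ddct.to_numpy()),
    })
    out["flagged_samples"] = [flagged] * len(out)
    return out
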