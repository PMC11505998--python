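"""Synthetic-data generators for every stage of the pipeline.

Each generator is the exact inverse of its analyzer at zero noise: dose-response
plates are built from a Hill-type GR curve so that recomputing GR values from the
simulated luminescence signals returns the generating curve; combination
experiments are built by numerically solving the Chou-Talalay combination-index
equation for the fraction affected; xenograft arms follow exponential volume
trajectories; expression cohorts carry a latent progression axis with known
per-gene loadings, batch shifts, and survival coupling.

All randomness flows through a single ``numpy.random.default_rng(seed)`` per
generator, so identical specs with identical seeds produce identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_LADDER_NM",
    "PlateSpec",
    "CohortSpec",
    "ExpressionCohort",
    "gen_dose_response",
    "gen_combination",
    "gen_xenograft",
    "gen_expression_cohort",
    "gen_assay_panel",
    "gr_hill",
]

#: Ten-point concentration ladder (nM) used throughout the in vitro assays.
DEFAULT_LADDER_NM = (1.4, 4.1, 12.0, 37.0, 111.0, 333.0, 1000.0, 3000.0, 9000.0, 27000.0)

VEHICLE_LABEL = "DMSO"


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def gr_hill(conc: np.ndarray, gr_inf: float, gec50: float, hill: float) -> np.ndarray:
    """Sigmoidal GR dose-response: GR(c) = gr_inf + (1 - gr_inf)/(1 + (c/gec50)^hill)."""
    conc = np.asarray(conc, dtype=float)
    return gr_inf + (1.0 - gr_inf) / (1.0 + np.power(conc / gec50, hill))


@dataclass(frozen=True)
class PlateSpec:
    """Design of a simulated two-timepoint viability plate experiment.

    gr_params maps (cell_line, drug) to (gr_inf, gec50_nM, hill): the lower
    plateau, the concentration of half-maximal GR effect, and the Hill slope of
    the latent GR curve. doubling_time_h sets the vehicle growth rate of each
    cell line; GR values are independent of it by construction.
    """

    cell_lines: tuple
    drugs: tuple
    concentrations: tuple = DEFAULT_LADDER_NM
    n_replicates: int = 3
    doubling_time_h: dict = field(default_factory=dict)
    gr_params: dict = field(default_factory=dict)
    noise_cv: float = 0.0
    seed: int = 0
    duration_h: float = 72.0
    baseline_rlu: float = 1000.0

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 1 or len(conc) < 1 or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be a strictly increasing ladder")
        if np.any(conc <= 0):
            raise ValueError("ladder concentrations must be positive (0 is reserved for vehicle)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for cl in self.cell_lines:
            td = self.doubling_time_h.get(cl, 24.0)
            if td <= 0:
                raise ValueError(f"doubling time for {cl} must be > 0 h")
        for key, (gr_inf, gec50, hill) in self.gr_params.items():
            if not -1.0 <= gr_inf <= 1.0:
                raise ValueError(f"gr_inf for {key} must lie in [-1, 1]")
            if gec50 <= 0 or hill <= 0:
                raise ValueError(f"gec50 and hill for {key} must be > 0")


def gen_dose_response(spec: PlateSpec) -> pd.DataFrame:
    """Simulate a long-format dose-response plate table.

    For each (cell line, drug, concentration) the treated growth rate is set so
    that the noise-free GR value equals the spec's Hill curve:
    k(c) = k(0) * log2(1 + GR(c)), with k(0) = 1/doubling_time (doublings/h).
    Signals at t0 and t grow as x(t) = x0 * 2^(k t); multiplicative log-normal
    noise with CV = noise_cv is applied per well. Vehicle (DMSO, conc 0) wells
    are included per cell line.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    t = spec.duration_h
    for cl in spec.cell_lines:
        k0 = 1.0 / spec.doubling_time_h.get(cl, 24.0)
        # vehicle wells
        for rep in range(spec.n_replicates):
            rows.append((cl, VEHICLE_LABEL, 0.0, rep, spec.baseline_rlu,
                         spec.baseline_rlu * 2.0 ** (k0 * t)))
        for drug in spec.drugs:
            try:
                gr_inf, gec50, hill = spec.gr_params[(cl, drug)]
            except KeyError:
                raise KeyError(f"gr_params missing entry for ({cl!r}, {drug!r})")
            for c in spec.concentrations:
                gr = float(gr_hill(np.array([c]), gr_inf, gec50, hill)[0])
                kc = k0 * math.log2(1.0 + gr)  # gr > -1 guaranteed by gr_inf >= -1 bound
                for rep in range(spec.n_replicates):
                    rows.append((cl, drug, float(c), rep, spec.baseline_rlu,
                                 spec.baseline_rlu * 2.0 ** (kc * t)))
    df = pd.DataFrame(rows, columns=["cell_line", "drug", "conc_nM", "replicate",
                                     "signal_t0", "signal_t"])
    df["duration_h"] = t
    n = len(df)
    df["signal_t0"] = df["signal_t0"] * _lognormal_factor(rng, spec.noise_cv, n)
    df["signal_t"] = df["signal_t"] * _lognormal_factor(rng, spec.noise_cv, n)
    return df


# ---------------------------------------------------------------------------
# drug combinations
# ---------------------------------------------------------------------------

def _median_effect_fa(dose: np.ndarray, dm: float, m: float) -> np.ndarray:
    """fa from the median-effect equation fa/(1-fa) = (D/Dm)^m."""
    ratio = np.power(np.asarray(dose, dtype=float) / dm, m)
    return ratio / (1.0 + ratio)


def _ci_at_fa(fa: float, dose_a: float, dose_b: float,
              dm_a: float, m_a: float, dm_b: float, m_b: float) -> float:
    odds = fa / (1.0 - fa)
    dx_a = dm_a * odds ** (1.0 / m_a)
    dx_b = dm_b * odds ** (1.0 / m_b)
    return dose_a / dx_a + dose_b / dx_b


def gen_combination(dm_a: float, m_a: float, dm_b: float, m_b: float,
                    interaction: float, doses, noise_cv: float = 0.0,
                    seed: int = 0, single_doses_a=None, single_doses_b=None) -> pd.DataFrame:
    """Simulate a single-agent + combination fraction-affected table.

    Single-agent rows follow the median-effect equation of each drug.
    Combination rows are constructed so that the two-term (mutually exclusive)
    combination index at each point equals ``interaction`` when noise-free: the
    fa solving  dose_a/Dx_a(fa) + dose_b/Dx_b(fa) = interaction  is found by
    root-bracketing on fa in (0, 1). Points whose solution would fall outside
    (0, 1) are clipped and flagged. Noise (CV = noise_cv) is multiplicative
    log-normal on the odds fa/(1-fa).
    """
    if dm_a <= 0 or dm_b <= 0 or m_a <= 0 or m_b <= 0:
        raise ValueError("median-effect parameters Dm and m must be > 0")
    if interaction <= 0:
        raise ValueError("interaction (target CI) must be > 0")
    rng = np.random.default_rng(seed)

    def ladder(dm):
        return dm * 2.0 ** np.arange(-3, 4)

    sa = np.asarray(single_doses_a if single_doses_a is not None else ladder(dm_a), float)
    sb = np.asarray(single_doses_b if single_doses_b is not None else ladder(dm_b), float)
    rows = []
    for d in sa:
        rows.append((d, 0.0, float(_median_effect_fa(d, dm_a, m_a)), "single_a", False))
    for d in sb:
        rows.append((0.0, d, float(_median_effect_fa(d, dm_b, m_b)), "single_b", False))
    eps = 1e-12
    for da, db in doses:
        f = lambda fa: _ci_at_fa(fa, da, db, dm_a, m_a, dm_b, m_b) - interaction
        clipped = False
        # CI(fa) is strictly decreasing in fa: +inf at fa->0, -> 0 at fa->1
        if f(eps) < 0:           # even tiny fa already below target: clip low
            fa, clipped = eps, True
        elif f(1.0 - eps) > 0:   # even fa ~ 1 above target: clip high
            fa, clipped = 1.0 - eps, True
        else:
            fa = brentq(f, eps, 1.0 - eps, xtol=1e-15)
        rows.append((float(da), float(db), float(fa), "combination", clipped))
    df = pd.DataFrame(rows, columns=["dose_a", "dose_b", "fa", "role", "clipped"])
    if noise_cv > 0:
        odds = df["fa"] / (1.0 - df["fa"])
        odds = odds * _lognormal_factor(rng, noise_cv, len(df))
        df["fa"] = odds / (1.0 + odds)
    return df


# ---------------------------------------------------------------------------
# xenografts
# ---------------------------------------------------------------------------

def gen_xenograft(arms, v0_mm3: float = 150.0, days=(0, 4, 7, 11, 14, 18, 21, 25, 28),
                  noise_cv: float = 0.0, dropout_rate: float = 0.0, seed: int = 0,
                  aspect_ratio: float = 1.6, body_weight_g: float = 20.0) -> pd.DataFrame:
    """Simulate a longitudinal xenograft measurement table.

    arms: list of (name, n_mice, growth_rate_per_day, treatment_effect); the
    net exponential rate of an arm is growth_rate - treatment_effect, so a
    treatment_effect equal to the growth rate gives a static tumor. Volumes
    V = v0 * exp(r * day) (log-normal noise, CV = noise_cv) are back-converted
    to caliper (L, W) with fixed aspect ratio L = 1.6 W via V = L W^2 / 2.
    Body weights drift with per-measurement noise scaled by noise_cv. Each
    animal drops out of later measurements with per-day hazard dropout_rate.
    """
    if not arms:
        raise ValueError("at least one arm is required")
    days = np.asarray(days, dtype=float)
    if v0_mm3 <= 0:
        raise ValueError("v0_mm3 must be > 0")
    if np.any(days < 0) or np.any(np.diff(days) <= 0):
        raise ValueError("days must be non-negative and increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for name, n_mice, growth_rate, effect in arms:
        if n_mice < 1:
            raise ValueError(f"arm {name!r} has no animals")
        r = growth_rate - effect
        for i in range(n_mice):
            animal = f"{name}_{i:02d}"
            drop_day = np.inf
            if dropout_rate > 0:
                drop_day = rng.exponential(1.0 / dropout_rate)
            bw = body_weight_g
            for d in days:
                if d > drop_day and d > days[0]:
                    break
                v = v0_mm3 * math.exp(r * d)
                v *= float(_lognormal_factor(rng, noise_cv, 1)[0])
                w = (2.0 * v / aspect_ratio) ** (1.0 / 3.0)
                length = aspect_ratio * w
                bw_obs = bw * float(_lognormal_factor(rng, 0.01 * (noise_cv > 0), 1)[0])
                rows.append((animal, name, float(d), length, w, bw_obs))
    return pd.DataFrame(rows, columns=["animal", "arm", "day", "length_mm",
                                       "width_mm", "body_weight_g"])


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic bulk expression cohort with a latent progression axis.

    Emulates a tumor cohort in which a one-dimensional progression axis
    (latent pseudotime) orders samples, histological grade is a coarse binning
    of that axis, gene modules load on it with per-gene strengths, technical
    batches shift expression additively in log space, and overall survival is
    coupled to the axis through a proportional-hazards link.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_batches: int = 3
    grade_levels: tuple = ("G1", "G2", "G3")
    pseudotime_range: tuple = (0.0, 100.0)
    module_loadings: np.ndarray | None = None  # per-gene, in [-1, 1]
    batch_shift_sd: float = 0.5
    survival_link: float = 1.0
    censor_rate: float = 0.3
    seed: int = 0
    dispersion: float = 0.1
    noncoding_frac: float = 0.05

    def __post_init__(self):
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("cohort needs >= 2 samples and >= 1 gene")
        if self.n_batches > self.n_samples:
            raise ValueError("n_batches cannot exceed n_samples")
        if not self.grade_levels:
            raise ValueError("grade_levels must be a non-empty ordered tuple")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.module_loadings is not None:
            lo = np.asarray(self.module_loadings, dtype=float)
            if lo.shape != (self.n_genes,):
                raise ValueError("module_loadings must have length n_genes")
            if np.any(np.abs(lo) > 1):
                raise ValueError("module_loadings must lie in [-1, 1]")


@dataclass
class ExpressionCohort:
    """Counts + metadata + annotation, with generator ground truth attached."""

    counts: pd.DataFrame          # genes x samples, non-negative integers
    samples: pd.DataFrame         # sample, grade, histology, batch, survival_time, event
    genes: pd.DataFrame           # gene, biotype
    truth: dict                   # pseudotime, loadings, batch_shifts, size_factors

    def __post_init__(self):
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts dimensions must match gene/sample tables")


def gen_expression_cohort(spec: CohortSpec) -> ExpressionCohort:
    """Simulate negative-binomial counts over a latent progression axis.

    log2 mean expression of gene g in sample i is
    baseline_g + loading_g * z_i + shift_{g, batch(i)} + log2(depth_i),
    with z the standardized latent pseudotime. Grades are equal-width bins of
    pseudotime over its range. Survival times are exponential with hazard
    proportional to exp(survival_link * z); a fraction censor_rate of subjects
    is censored uniformly before their event time.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    lo, hi = spec.pseudotime_range
    pt = rng.uniform(lo, hi, size=n)
    z = (pt - pt.mean()) / pt.std()

    loadings = (np.asarray(spec.module_loadings, dtype=float)
                if spec.module_loadings is not None
                else rng.uniform(-1.0, 1.0, size=g) * (rng.random(g) < 0.2))
    baseline = rng.uniform(1.0, 9.0, size=g)           # log2 scale
    batch = rng.integers(0, spec.n_batches, size=n)
    batch_shifts = rng.normal(0.0, spec.batch_shift_sd, size=(g, spec.n_batches)) \
        if spec.batch_shift_sd > 0 else np.zeros((g, spec.n_batches))
    depth = rng.lognormal(0.0, 0.2, size=n)            # library-size factors

    log2_mu = (baseline[:, None] + loadings[:, None] * z[None, :]
               + batch_shifts[:, batch] + np.log2(depth)[None, :])
    mu = np.power(2.0, log2_mu)
    # NB via gamma-Poisson: shape = 1/dispersion
    if spec.dispersion > 0:
        shape = 1.0 / spec.dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    # grades: equal-width bins of the latent axis
    edges = np.linspace(lo, hi, len(spec.grade_levels) + 1)
    grade_idx = np.clip(np.digitize(pt, edges[1:-1]), 0, len(spec.grade_levels) - 1)
    grades = np.asarray(spec.grade_levels)[grade_idx]
    histology = np.where(grade_idx < max(len(spec.grade_levels) - 1, 1),
                         "endometrioid", "serous")

    base_hazard = 1.0 / 1500.0   # per day; median OS a few years at z = 0
    hazard = base_hazard * np.exp(spec.survival_link * z)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < spec.censor_rate
    obs_time = np.where(censored, event_time * rng.random(n), event_time)
    event = (~censored).astype(int)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"GENE{j:05d}" for j in range(g)]
    biotype = np.where(rng.random(g) < spec.noncoding_frac, "lncRNA", "protein_coding")

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    samples_df = pd.DataFrame({
        "sample": sample_ids,
        "grade": grades,
        "histology": histology,
        "batch": [f"B{b}" for b in batch],
        "survival_time": np.round(obs_time, 1),
        "event": event,
    }).set_index("sample", drop=False)
    genes_df = pd.DataFrame({"gene": gene_ids, "biotype": biotype}).set_index("gene", drop=False)
    truth = {"pseudotime": pd.Series(pt, index=sample_ids),
             "loadings": pd.Series(loadings, index=gene_ids),
             "batch_shifts": batch_shifts,
             "depth": pd.Series(depth, index=sample_ids)}
    return ExpressionCohort(counts_df, samples_df, genes_df, truth)


# ---------------------------------------------------------------------------
# flow + qPCR assay panel
# ---------------------------------------------------------------------------

def gen_assay_panel(n_events: int = 20000, live_frac: float = 0.85,
                    edu_frac_ctrl: float = 0.5, edu_frac_treated: float = 0.25,
                    mfi_shift: float = 0.5, ct_effects: dict | None = None,
                    seed: int = 0):
    """Simulate per-event flow tables (control + treated) and a qPCR Ct table.

    Channel intensities are two-component log-normal mixtures: viability dye is
    low in live cells and high in dead cells; EdU is low in non-replicating and
    high in S-phase cells; pRPS6/p4EBP1 are unimodal with treated medians scaled
    by mfi_shift. Returns (control_events, treated_events, unstained_medians,
    ct_table). ct_effects maps gene -> Ct shift (cycles) in the treated
    condition; the Ct table carries the target genes plus HPRT1 and ACTB.
    """
    if n_events < 100:
        raise ValueError("n_events < 100: too few events for stable medians")
    for frac in (live_frac, edu_frac_ctrl, edu_frac_treated):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    background = {"viability_dye": 30.0, "edu": 50.0, "prps6": 60.0, "p4ebp1": 60.0}

    def events(condition, edu_frac, shift):
        live = rng.random(n_events) < live_frac
        viab = np.where(live,
                        rng.lognormal(math.log(100.0), 0.35, n_events),
                        rng.lognormal(math.log(8000.0), 0.35, n_events))
        edu_pos = rng.random(n_events) < edu_frac
        edu = np.where(edu_pos,
                       rng.lognormal(math.log(9000.0), 0.4, n_events),
                       rng.lognormal(math.log(150.0), 0.4, n_events))
        prps6 = rng.lognormal(math.log(2000.0 * shift), 0.4, n_events)
        p4ebp1 = rng.lognormal(math.log(1500.0 * shift), 0.4, n_events)
        return pd.DataFrame({
            "condition": condition,
            "viability_dye": viab + background["viability_dye"],
            "edu": edu + background["edu"],
            "prps6": prps6 + background["prps6"],
            "p4ebp1": p4ebp1 + background["p4ebp1"],
        })

    control = events("DMSO", edu_frac_ctrl, 1.0)
    treated = events("treated", edu_frac_treated, mfi_shift)
    unstained = dict(background)

    ct_effects = ct_effects or {}
    base_ct = {"HPRT1": 24.0, "ACTB": 18.0}
    targets = [gene for gene in ct_effects if gene not in base_ct] or ["PGR"]
    for i, gene in enumerate(targets):
        base_ct.setdefault(gene, 26.0 + i)
    ct_rows = []
    for condition in ("control", "treated"):
        for rep in range(3):
            for gene, base in base_ct.items():
                ct = base + (ct_effects.get(gene, 0.0) if condition == "treated" else 0.0)
                ct += rng.normal(0.0, 0.05)
                ct_rows.append((f"{condition}_{rep}", condition, gene, ct))
    ct_table = pd.DataFrame(ct_rows, columns=["sample", "condition", "gene", "ct"])
    return control, treated, unstained, ct_table
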