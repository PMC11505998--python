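# Methods

This note documents the models, defaults, and numerical choices behind each
`oncopipe` stage, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Growth-rate (GR) dose-response metrics

**Model.** The GR value normalizes drug response by the growth rate of
untreated cells: GR(c) = 2^(k(c)/k(0)) − 1 with k = log2(x_t/x_0)/t computed
from background-subtracted viability signals at treatment start (x_0) and end
(x_t, default 72 h). Growth rates are computed from replicate-*mean* signals
rather than per-replicate and then averaged: the log of a small noisy count is
biased and unstable, and averaging first stabilizes it. Vehicle wells define
k(0) per cell line; a non-growing vehicle (k(0) ≤ 0) is an error because the
normalization is then meaningless.

**Curve fit.** GR(c) = GR_inf + (1 − GR_inf)/(1 + (c/GEC50)^h), least squares
with bounds GR_inf ∈ [−1, 1], h ∈ (0.1, 5], GEC50 ∈ [min dose/100,
max dose·100], multi-start over four log-spaced GEC50 initializations. A fit
is labeled `flat` when an F-test against the constant-GR model is
non-significant at α = 0.05 (2 vs n−3 df), and `unstable` when the optimizer
fails or GEC50/h land on a bound (within 0.1 % of the bounded span, GEC50 on
the log scale). GR_inf = ±1 is *not* treated as bound-hitting: those are the
physically meaningful extremes (complete kill, no effect), not fitting
artifacts.

**Derived metrics.**
- GR50 solves the fitted curve = 0.5 analytically:
  GR50 = GEC50·[(1 − GR_inf)/(0.5 − GR_inf) − 1]^(1/h), defined only for
  GR_inf < 0.5. Crossings beyond max dose·10 report the sentinel
  `>max_tested`, below min dose/10 `<min_tested`. For unstable fits the
  fallback is log-linear interpolation of the raw per-dose means, with the
  sentinel `unstable` only when no raw crossing exists.
- GRmax is the mean raw GR at the highest tested dose (not the fitted
  plateau), so it reflects what was measured.
- GR_AOC is the trapezoidal integral of (1 − GR) over log10 dose on the raw
  per-dose means, with no curve fit and no normalization by the dose range;
  its units are "GR-depth × decades" (a 4.29-decade ladder at full cytostasis
  integrates to 4.29). It is invariant to replicate duplication and strictly
  increases when any GR value decreases.
- The absolute IC50 is the dose where a four-parameter logistic fit to
  relative viability crosses 0.5 — not the curve inflection. Sensitivity
  calls compare IC50 strictly (<) against per-drug cutoffs (default table:
  gedatolisib 100 nM, alpelisib 3000 nM, capivasertib 3000 nM, everolimus
  50 nM); sentinel IC50s are never sensitive. Strictness is applied uniformly
  because the cutoff definitions are stated as "less than" for one drug and
  bare numbers for the rest.

## Median-effect synergy analysis

Single agents are fit by ordinary least squares on the linearized
median-effect equation log10(fa/(1 − fa)) = m·log10 D − m·log10 Dm. Fractions
affected outside (0.01, 0.99) are excluded with a warning before
linearization — the logit explodes at the extremes and a single saturated
point can dominate the slope. At least three usable points are required.

The combination index uses the mutually exclusive (two-term) form,
CI = d_a/Dx_a + d_b/Dx_b with Dx_i = Dm_i·(fa/(1 − fa))^(1/m_i) — the default
of the classical synergy software this analysis mirrors. Points are labeled
additive within ±0.05 of CI = 1; the band acknowledges fit noise rather than
demanding exact equality. CI is undefined at fa = 0 or 1. Non-constant-ratio
designs are the default; constant-ratio designs need no special handling
because each point is scored independently.

## Flow-cytometry and qPCR readouts

Live gating uses the viability (dead-cell) dye: low signal = live, with the
threshold at the equal-posterior valley of a two-component Gaussian mixture on
log10 intensity, fit on the pooled control + treated events so both conditions
are gated identically. The EdU-positive threshold is estimated the same way on
the pooled live events. Phospho-channel readouts are median fluorescence
intensity of live events minus the unstained-control median, floored at zero
(with a warning); all readouts are divided by the vehicle-control value.
Percent inhibition is 100·(1 − normalized), floored at 0 with a stimulation
flag for normalized values above 1. All normalized outputs are invariant to
rescaling every intensity by a positive constant. Debris (scatter) gating is
out of scope; the event generator emits pre-filtered events.

ΔΔCt relative expression uses the arithmetic mean of the two reference-gene
Cts (HPRT1, ACTB) as the per-sample normalizer — equivalent to dividing by the
geometric mean of reference expression, the standard multi-reference rule.
ΔCt = Ct_target − mean(Ct_refs) per sample, ΔΔCt = mean ΔCt(condition) − mean
ΔCt(control), fold change = 2^(−ΔΔCt). Replicate Cts with SD > 1 cycle are
flagged. The statistic is exactly invariant under any per-sample additive Ct
shift applied to all genes.

## Xenograft efficacy

Volumes follow the caliper formula V = L·W²/2 with L the longest dimension;
swapped entries are normalized (and warned about) rather than rejected. TGI
defaults to the baseline-adjusted form TGI = 100·(1 − ΔV_t/ΔV_c) with
ΔV = mean V(day) − mean V(0), the appropriate choice for studies randomized at
an established tumor size (~100–200 mm³); the endpoint-ratio form
100·(1 − V_t/V_c) is available via `formula="ratio"`. Display TGI is capped at
100 % for regressing tumors while the raw value is retained. A non-growing
control arm makes ΔV-based TGI undefined and is an error, not a silent NaN.
Measurements are carried forward to a requested day within ±2 days (about half
the twice-weekly measurement interval), otherwise the animal is excluded from
that day. Welfare flags fire when body weight drops strictly more than 20 %
below day 0. Between-arm comparison is one-way ANOVA on volumes at the
requested day plus two-sided pairwise t-tests against control with Holm
adjustment, starred at 0.05/0.01/0.001.

## Transcriptomic trajectory analysis

**Preprocessing.** Genes are kept when annotated protein-coding and detected
(count ≥ 1) in ≥ 10 samples. Size factors are median-of-ratios against the
geometric-mean reference profile (computed on genes expressed everywhere);
the transform is log2(count/size factor + 1). This is a deliberate
simplification of a variance-stabilizing transform: every downstream step
(IQR ranking, PCA, Pearson correlation) depends only on a monotone
roughly-variance-stabilizing transform, not on the fitted dispersion trend of
any particular package. It is a fidelity gap for genes at very low counts,
where log2(x+1) under-stabilizes.

**Batch handling.** The dispersion separability criterion is
DSC = Db/Dw with Db² = Σ_b (n_b/N)·‖μ_b − μ‖² and
Dw² = Σ_b (n_b/N)·mean_{i∈b}‖x_i − μ_b‖², zero exactly when batch centroids
coincide; its permutation p shuffles batch labels (default 1000 draws).
Batch removal fits, per gene, expression ~ covariate + batch, with the batch
dummy columns first projected onto the orthogonal complement of the
[intercept + covariate] design. On balanced designs this equals the usual
two-step fit; under partial or complete aliasing it degrades gracefully — the
aliased batch direction has zero norm after projection and is dropped with a
warning, so the covariate contrast is protected exactly rather than split
arbitrarily between collinear columns. Only the fitted batch terms are
subtracted.

**Embedding and pseudotime.** PCA is computed by SVD on the per-gene-centered
matrix restricted to the 2000 highest-IQR genes (default), returning 5
components and the variance fraction of every component. Clusters are the
provided ordered grade labels (no de novo clustering); cluster centroids are
joined by a Euclidean minimum spanning tree, traversed outward from the seed
cluster (lowest grade) to order clusters, and the polyline through centroids
in that order initializes a single principal curve. Each iteration projects
samples orthogonally onto the curve, scatterplot-smooths every coordinate
along the projection ordering with a symmetric moving average spanning 20 %
of the samples, smooths the resulting ordered curve points once more with the
same window — the second pass removes the tangential wiggle left by averaging
a noisy cloud, without which the projections oscillate indefinitely — and
reparametrizes by cumulative arc length (100 curve points). Both curve ends
are extended along their tangents past the outermost projections so samples
beyond the smoothed ends do not tie at the endpoint. Iteration stops when the
mean projection shift falls below 1e-4 (or at 50 iterations, returning the
last iterate with a convergence flag and warning). Pseudotime is the raw arc
length of each sample's projection in PC coordinates — the units are as
arbitrary as any trajectory method's — anchored to 0 at the seed-cluster end,
flipping the axis if smoothing moved the seed cluster away from the minimum.

**Pseudotime–gene correlation.** To damp outlier influence, Pearson
correlations are computed over 20 random subsets each holding ⌈2N/3⌉ samples
(leave-one-third-out), and the median r per gene is reported. The p-value is
computed from the t-statistic of the *median r* at the subset size — the
alternative reading (median per-draw p) is available via
`p_mode="median_p"`; the two are nearly identical in practice because the
median-r draw and the median-p draw coincide up to ties. BH FDR is applied
across genes; genes constant in every draw are excluded with a flag. Note the
subset-size df makes the p mildly conservative relative to the full-sample
correlation, which is the safer direction for discovery lists.

**Preranked GSEA.** The enrichment score is the signed maximum deviation of
the weighted Kolmogorov–Smirnov walk (hit increments ∝ |stat|^weight, default
weight 1; miss increments 1/(N − |S|)). Deviation extrema occur only adjacent
to hits, so the implementation evaluates the 2|S| candidate deviations rather
than the full walk. For the degenerate set containing every gene, the miss
denominator is 0/0; the positional CDF i/N stands in for the miss curve so
the walk still ends at zero. The null permutes gene labels — the only valid
permutation unit for a preranked list — and the p-value is two-sided on |ES|,
p = (1 + #{|ES_null| ≥ |ES|})/(n_perm + 1): uniform under the null with
minimum attainable value 1/(n_perm + 1). A sign-conditional count over the
same denominator would double the false-positive rate, and a sign-conditional
denominator would raise the attainable minimum; the two-sided form avoids
both. NES divides ES by the mean |same-sign null ES|. BH FDR across sets;
sets overlapping the ranking by fewer than 5 genes are skipped.

**Survival.** Samples with missing survival are dropped first. Groups are the
median split of one gene's expression (high = strictly above the median; all
values tied at the median is an error). Kaplan–Meier curves and the two-group
log-rank test come from lifelines; with zero events the test is undefined and
p = 1 is returned by convention.

## Synthetic-data generators

Each generator is the exact inverse of its analyzer at zero noise, which is
what makes round-trip testing meaningful:

- **Plates**: treated growth rates are set to k(c) = k(0)·log2(1 + GR(c)) for
  the requested Hill-type GR curve, signals grow as x·2^(kt), and noise is
  multiplicative log-normal with unit mean (luminescence noise scales with
  signal). Default ladder: 1.4, 4.1, 12, 37, 111, 333, 1000, 3000, 9000,
  27000 nM; default duration 72 h. Vehicle wells are emitted per cell line.
- **Combinations**: single-agent fa follow the median-effect equation;
  combination fa are obtained by root-bracketing the CI equation so the
  noise-free CI equals the target exactly (no closed form exists once
  m_a ≠ m_b). For finite positive doses an interior root always exists, so
  clipping/flagging only triggers at the solver bracket (fa beyond 1e-12 of
  either end). Noise is log-normal on the odds fa/(1 − fa).
- **Xenografts**: per-animal exponential volumes v0·e^(rt) with arm-specific
  net rate, back-converted to (L, W) at fixed aspect ratio 1.6 (a typical
  subcutaneous elongation) after volume-scale log-normal noise; body weights
  get ~1 % measurement noise when volume noise is on; dropout is an
  exponential per-animal hazard.
- **Expression cohorts**: latent pseudotime ~ Uniform, standardized to z;
  log2 mean = baseline + loading·z + batch shift + log2(library depth);
  counts are gamma-Poisson (negative binomial) with dispersion 0.1 — a
  mid-range bulk RNA-seq value. Grades are equal-width bins of the latent
  axis; survival is exponential with hazard ∝ exp(link·z) and uniform early
  censoring at the requested rate; ~5 % of genes are flagged non-coding to
  exercise the biotype filter. Ground truth (pseudotime, loadings, batch
  shifts, depths) is returned alongside.
- **Assay panels**: per-event two-component log-normal mixtures for the
  viability and EdU channels, unimodal log-normals for the phospho channels
  (treated medians scaled by the target inhibition), additive channel
  backgrounds matching the unstained medians; Ct tables with two reference
  genes, 3 replicates, and 0.05-cycle replicate noise.

What the generators deliberately do **not** emulate: plate-position effects,
pharmacokinetics, immune/stromal admixture, multi-lineage or branching
progression, batch effects that interact with grade, informative censoring,
and flow spillover/compensation. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under their stated models, not
robustness to those real-data pathologies.

A note on calibration tests: the null-FDR check correlates genes against the
generator's latent axis, not an estimated trajectory — on a cohort with no
signal, an estimated trajectory is a function of the same noise being tested
(selection bias by construction), so only the ground-truth axis yields a
meaningful null.

## Problem sizes and defaults used in the shipped checks

Parameter-recovery checks use 50 plates at 5 % CV; trajectory recovery uses
cohorts of 300 samples × 2000 genes over 15–20 seeds; FDR calibration uses
15–20 null cohorts of 200 × 1000; GSEA calibration uses 500 random 50-gene
sets at 200 permutations (1000 for the planted set); the ANOVA type-I check
uses 1000 simulated three-arm studies; the end-to-end determinism check runs
the full pipeline twice at 100 samples × 250 genes. These sizes were chosen to
give stable estimates of each property at desk scale.

## Known limitations

- The log2(x+1) transform under-stabilizes very low counts relative to a
  dispersion-aware VST; rankings of weakly expressed genes are less reliable.
- The principal curve is single-lineage by design; branched progressions
  would need a different backbone.
- The resampled-correlation p uses the subset-size df and treats draws as
  exchangeable; it is not an exact permutation p.
- GR fits assume a monotone sigmoid; biphasic responses will be labeled
  `unstable` or fit poorly.
- Whether widely used GR calculators normalize GR_AOC by the dose range is
  not consistently documented; the unnormalized integral is used here and
  its units stated above.
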