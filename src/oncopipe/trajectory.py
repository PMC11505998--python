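"""Transcriptomic progression-trajectory analysis.

Bulk counts are filtered (protein-coding, minimum detection), normalized by
median-of-ratios size factors, and log2-transformed. Batch structure is
diagnosed with the dispersion separability criterion (DSC, ratio of
between-batch to within-batch dispersion with a permutation p-value) and
removed by a per-gene linear model that protects the biological covariate.
Samples are embedded by PCA on the top-IQR genes; an MST over grade-cluster
centroids seeds a single principal curve fitted by iterated
projection/smoothing, whose arc length is the per-sample pseudotime (0 at the
seed-cluster end). Downstream, genes are correlated with pseudotime through a
repeated leave-one-third-out resampling with BH FDR, gene sets are scored by a
weighted Kolmogorov-Smirnov preranked enrichment with a gene-permutation null,
and single-gene survival contrasts use a median-split Kaplan-Meier log-rank
test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

try:  # lifelines is the survival backend
    from lifelines.statistics import logrank_test as _logrank_test
    from lifelines import KaplanMeierFitter as _KMF
except ImportError:  # pragma: no cover
    _logrank_test = None
    _KMF = None

__all__ = [
    "preprocess_counts",
    "remove_batch",
    "dsc",
    "BatchDiagnostics",
    "pca_embed",
    "PCAResult",
    "infer_trajectory",
    "TrajectoryModel",
    "pseudotime_correlation",
    "gsea_preranked",
    "km_twogroup",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples input).

    The reference profile is the per-gene geometric mean over samples,
    computed on genes expressed in every sample; each sample's factor is the
    median ratio of its counts to the reference.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("a sample has all-zero counts: size factor undefined")
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError("no gene is expressed in every sample: "
                         "median-of-ratios reference undefined")
    logc = np.log(counts[positive])
    ref = logc.mean(axis=1)
    return np.exp(np.median(logc - ref[:, None], axis=0))


def preprocess_counts(counts: pd.DataFrame, gene_annotation: pd.DataFrame,
                      min_count: int = 1, min_samples: int = 10,
                      biotype: str = "protein_coding") -> tuple[pd.DataFrame, pd.Series]:
    """Filter, normalize, and log-transform a genes x samples count matrix.

    Keeps genes annotated with the requested biotype and detected at
    >= min_count in >= min_samples samples, divides by median-of-ratios size
    factors, and returns (log2(normalized + 1) matrix, size factors).
    """
    if "biotype" not in gene_annotation.columns:
        raise ValueError("gene annotation must carry a 'biotype' column")
    annot = gene_annotation.reindex(counts.index)
    if annot["biotype"].isna().any():
        raise ValueError("every gene in the count matrix must be annotated")
    coding = counts.loc[annot["biotype"] == biotype]
    detected = (coding >= min_count).sum(axis=1) >= min_samples
    filtered = coding.loc[detected]
    if filtered.empty:
        raise ValueError("no gene passes the detection filter")
    sf = size_factors(filtered.to_numpy())
    norm = filtered.to_numpy(dtype=float) / sf[None, :]
    logmat = pd.DataFrame(np.log2(norm + 1.0), index=filtered.index,
                          columns=filtered.columns)
    return logmat, pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# batch correction + DSC
# ---------------------------------------------------------------------------

def _dummies(factor: pd.Series) -> np.ndarray:
    d = pd.get_dummies(pd.Series(factor).astype(str), drop_first=True)
    return d.to_numpy(dtype=float)


def remove_batch(matrix: pd.DataFrame, batches, covariate: pd.Series) -> pd.DataFrame:
    """Subtract per-gene additive batch effects while protecting a covariate.

    ``batches`` is a single factor or a list of one or two factors (per
    sample). Per gene, the model expression ~ covariate + batch is fit by
    least squares with the batch design projected onto the orthogonal
    complement of [intercept + covariate dummies], so that a batch factor
    aliased with the covariate contributes nothing (the covariate term is
    protected); only the fitted batch terms are subtracted. A batch level with
    fewer than 2 samples triggers a warning but is kept.
    """
    Y = matrix.to_numpy(dtype=float)
    n = Y.shape[1]
    if isinstance(batches, (pd.Series, np.ndarray)):
        batch_list = [pd.Series(np.asarray(batches))]
    elif isinstance(batches, (list, tuple)) and len(batches) and np.isscalar(batches[0]):
        batch_list = [pd.Series(batches)]
    else:
        batch_list = [pd.Series(np.asarray(b)) for b in batches]
    for b in batch_list:
        small = b.value_counts()
        tiny = small[small < 2]
        if len(tiny):
            warnings.warn(f"batch level(s) with < 2 samples kept: {list(tiny.index)}")
    X_cov = np.column_stack([np.ones(n), _dummies(covariate)]) if covariate is not None \
        else np.ones((n, 1))
    X_batch = np.column_stack([_dummies(b) for b in batch_list])
    # project batch columns off the covariate design
    Q, _ = np.linalg.qr(X_cov)
    X_b_orth = X_batch - Q @ (Q.T @ X_batch)
    norms = np.linalg.norm(X_b_orth, axis=0)
    usable = norms > 1e-8 * math.sqrt(n)
    if not usable.all():
        warnings.warn("batch factor aliased with the covariate: aliased batch "
                      "term(s) forced to zero, covariate protected")
    X_b_orth = X_b_orth[:, usable]
    if X_b_orth.shape[1] == 0:
        return matrix.copy()
    coef, *_ = np.linalg.lstsq(X_b_orth, Y.T, rcond=None)
    adjusted = Y - (X_b_orth @ coef).T
    return pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)


@dataclass
class BatchDiagnostics:
    dsc: float
    p_perm: float | None
    n_perm: int


def _dsc_value(X: np.ndarray, codes: np.ndarray, n_batches: int) -> float:
    """DSC = Db/Dw on sample vectors X (samples x features)."""
    n = len(codes)
    mu = X.mean(axis=0)
    sq = np.einsum("ij,ij->i", X, X)
    db2 = 0.0
    dw2 = 0.0
    for b in range(n_batches):
        members = codes == b
        nb = int(members.sum())
        if nb == 0:
            continue
        mu_b = X[members].mean(axis=0)
        db2 += (nb / n) * float(np.sum((mu_b - mu) ** 2))
        dw2 += (nb / n) * float(sq[members].mean() - np.sum(mu_b ** 2))
    if dw2 <= 0:
        return 0.0 if db2 <= 0 else math.inf
    return math.sqrt(db2) / math.sqrt(dw2)


def dsc(matrix: pd.DataFrame, batches, n_perm: int = 1000,
        seed: int = 0) -> BatchDiagnostics:
    """Dispersion separability criterion of a batch factor, with permutation p.

    ``matrix`` is genes x samples (or any features x samples); samples are the
    points. Db is the size-weighted dispersion of batch centroids around the
    grand centroid, Dw the size-weighted mean within-batch dispersion. The
    permutation p-value shuffles batch labels n_perm times,
    p = (1 + #{DSC_perm >= DSC}) / (n_perm + 1); pass n_perm=0 to skip it.
    """
    codes, levels = pd.factorize(pd.Series(batches).astype(str))
    if len(levels) < 2:
        raise ValueError("DSC needs >= 2 batches")
    X = matrix.to_numpy(dtype=float).T
    observed = _dsc_value(X, codes, len(levels))
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            hits += _dsc_value(X, rng.permutation(codes), len(levels)) >= observed
        p = (1 + hits) / (n_perm + 1)
    return BatchDiagnostics(dsc=float(observed), p_perm=p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    embedding: pd.DataFrame           # samples x n_pc
    variance_ratio: np.ndarray        # all components, sums to 1
    selected_genes: pd.Index


def pca_embed(matrix: pd.DataFrame, n_top_iqr: int = 2000, n_pc: int = 5) -> PCAResult:
    """PCA of samples on the genes with the highest interquartile range.

    Selects min(n_top_iqr, n_genes) genes by IQR, centers per gene, and
    computes the SVD; returns sample coordinates on the first n_pc components
    and the variance fraction of every component.
    """
    n_genes, n_samples = matrix.shape
    if n_pc > min(n_genes, n_samples):
        raise ValueError("n_pc exceeds matrix rank bound")
    q75 = matrix.quantile(0.75, axis=1)
    q25 = matrix.quantile(0.25, axis=1)
    iqr = (q75 - q25)
    selected = iqr.sort_values(ascending=False, kind="stable").index[:min(n_top_iqr, n_genes)]
    X = matrix.loc[selected].to_numpy(dtype=float).T     # samples x genes
    X = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    total = var.sum()
    ratio = var / total if total > 0 else var
    coords = X @ vt[:n_pc].T
    emb = pd.DataFrame(coords, index=matrix.columns,
                       columns=[f"PC{i+1}" for i in range(n_pc)])
    return PCAResult(embedding=emb, variance_ratio=ratio, selected_genes=selected)


# ---------------------------------------------------------------------------
# MST + principal-curve pseudotime
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryModel:
    centroids: pd.DataFrame
    mst_edges: list
    curve: np.ndarray                 # ordered points in PC space
    pseudotime: pd.Series             # arc length, 0 at the seed end
    converged: bool
    n_iter: int
    cluster_order: list = field(default_factory=list)


def centroid_mst(centroids: pd.DataFrame) -> list:
    """Minimum spanning tree over cluster centroids by Euclidean distance."""
    G = nx.Graph()
    labels = list(centroids.index)
    pts = centroids.to_numpy(dtype=float)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            G.add_edge(a, labels[j], weight=float(np.linalg.norm(pts[i] - pts[j])))
    mst = nx.minimum_spanning_tree(G)
    return sorted(tuple(sorted(e)) for e in mst.edges)


def _project_to_polyline(points: np.ndarray, curve: np.ndarray):
    """Orthogonal projection of points onto a polyline.

    Returns (arc_lengths, projected_points): per point, the cumulative arc
    length of its nearest location on the curve and that location.
    """
    seg_a = curve[:-1]
    seg_v = curve[1:] - curve[:-1]
    seg_len = np.linalg.norm(seg_v, axis=1)
    keep = seg_len > 1e-12
    seg_a, seg_v, seg_len = seg_a[keep], seg_v[keep], seg_len[keep]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
    # points x segments
    diff = points[:, None, :] - seg_a[None, :, :]
    t = np.einsum("psd,sd->ps", diff, seg_v) / (seg_len ** 2)
    t = np.clip(t, 0.0, 1.0)
    proj = seg_a[None, :, :] + t[:, :, None] * seg_v[None, :, :]
    d2 = np.sum((points[:, None, :] - proj) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(points))
    arc = cum[best] + t[idx, best] * seg_len[best]
    return arc, proj[idx, best]


def _resample_polyline(pts: np.ndarray, k: int) -> np.ndarray:
    """Resample an ordered point sequence at k evenly spaced arc lengths."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return np.repeat(pts[:1], k, axis=0)
    grid = np.linspace(0.0, cum[-1], k)
    return np.column_stack([np.interp(grid, cum, pts[:, d]) for d in range(pts.shape[1])])


def _moving_average(values: np.ndarray, half: int) -> np.ndarray:
    """Symmetric rank-window moving average, truncated at the edges."""
    n = len(values)
    out = np.empty_like(values, dtype=float)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = values[lo:hi].mean(axis=0)
    return out


def _extend_curve(curve: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Extend both curve ends along their tangents past every projection.

    Prevents samples beyond the smoothed curve's ends from piling up at equal
    arc length (which would tie their pseudotimes).
    """
    def tangent(a, b):
        v = b - a
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    t0 = tangent(curve[1], curve[0])
    t1 = tangent(curve[-2], curve[-1])
    over0 = np.max((points - curve[0]) @ t0, initial=0.0)
    over1 = np.max((points - curve[-1]) @ t1, initial=0.0)
    total = np.sum(np.linalg.norm(np.diff(curve, axis=0), axis=1))
    pad = 0.01 * total
    head = curve[0] + (over0 + pad) * t0 if over0 > 0 else None
    tail = curve[-1] + (over1 + pad) * t1 if over1 > 0 else None
    parts = ([head] if head is not None else []) + [curve] + ([tail] if tail is not None else [])
    return np.vstack([p if p.ndim == 2 else p[None, :] for p in parts])


def infer_trajectory(embedding: pd.DataFrame, cluster_labels: pd.Series,
                     seed_cluster: str, span: float = 0.2, tol: float = 1e-4,
                     max_iter: int = 50, n_curve_points: int = 100) -> TrajectoryModel:
    """Single-lineage principal-curve pseudotime seeded by a cluster-centroid MST.

    The MST over cluster centroids is traversed outward from the seed cluster
    to order clusters; the polyline through centroids in that order
    initializes the curve. Each iteration (a) projects samples onto the
    current curve, (b) smooths each coordinate against projection rank with a
    symmetric moving average spanning ``span`` of the samples, and (c)
    reparametrizes by cumulative arc length, stopping when the mean projection
    shift drops below ``tol``. Pseudotime is the arc length of each sample's
    projection, anchored so the seed cluster sits at low values.
    """
    labels = pd.Series(cluster_labels)
    labels.index = embedding.index
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("trajectory inference needs >= 2 clusters")
    if (counts < 2).any():
        raise ValueError(f"cluster(s) with a single sample: "
                         f"{list(counts[counts < 2].index)}")
    if seed_cluster not in counts.index:
        raise ValueError(f"seed cluster {seed_cluster!r} not among labels")

    X = embedding.to_numpy(dtype=float)
    centroids = embedding.groupby(labels).mean()
    edges = centroid_mst(centroids)
    tree = nx.Graph(edges)
    for a, b in edges:
        tree[a][b]["weight"] = float(np.linalg.norm(
            centroids.loc[a].to_numpy() - centroids.loc[b].to_numpy()))
    dist = nx.single_source_dijkstra_path_length(tree, seed_cluster)
    order = sorted(dist, key=dist.get)
    curve = _resample_polyline(centroids.loc[order].to_numpy(dtype=float),
                               n_curve_points)

    n = len(X)
    half = max(1, int(round(span * n / 2)))
    prev_proj = None
    converged = False
    it = 0
    arc = np.zeros(n)
    for it in range(1, max_iter + 1):
        curve_ext = _extend_curve(curve, X)
        arc, proj = _project_to_polyline(X, curve_ext)
        if prev_proj is not None:
            shift = float(np.mean(np.linalg.norm(proj - prev_proj, axis=1)))
            if shift < tol:
                converged = True
                break
        prev_proj = proj
        rank = np.argsort(arc, kind="stable")
        smoothed = np.empty_like(X)
        for d in range(X.shape[1]):
            # scatterplot-smooth each coordinate along the ordering, then
            # smooth the ordered curve points once more: the second pass
            # removes the tangential wiggle left by averaging a noisy cloud,
            # which would otherwise keep projections oscillating
            smoothed[:, d] = _moving_average(
                _moving_average(X[rank, d], half), half)
        curve = _resample_polyline(smoothed, n_curve_points)
    if not converged:
        warnings.warn(f"principal curve did not converge in {max_iter} iterations")

    pt = arc - arc.min()
    pseudotime = pd.Series(pt, index=embedding.index, name="pseudotime")
    # anchor: seed cluster at the low-pseudotime end
    means = pseudotime.groupby(labels).mean()
    if means[seed_cluster] != means.min():
        pseudotime = pseudotime.max() - pseudotime
        curve = curve[::-1].copy()
    return TrajectoryModel(centroids=centroids, mst_edges=edges, curve=curve,
                           pseudotime=pseudotime, converged=converged,
                           n_iter=it, cluster_order=order)


# ---------------------------------------------------------------------------
# pseudotime-gene correlation
# ---------------------------------------------------------------------------

def pseudotime_correlation(matrix: pd.DataFrame, pseudotime: pd.Series,
                           n_draws: int = 20, frac_keep: float = 2.0 / 3.0,
                           seed: int = 0, p_mode: str = "p_of_median_r"
                           ) -> pd.DataFrame:
    """Resampled Pearson correlation of each gene with pseudotime.

    Each of ``n_draws`` draws keeps ceil(frac_keep * N) samples without
    replacement; the median per-gene r across draws is reported with a p-value
    from the t-statistic of the median r at the subset size (``p_mode=
    'median_p'`` reports the median per-draw p instead) and BH FDR across
    genes. Genes constant in every draw are excluded with a flag.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    pt = pseudotime.reindex(matrix.columns)
    if pt.isna().any():
        raise ValueError("pseudotime must be defined for every sample")
    rng = np.random.default_rng(seed)
    Y = matrix.to_numpy(dtype=float)
    t = pt.to_numpy(dtype=float)
    n = Y.shape[1]
    m = math.ceil(frac_keep * n)
    r_draws = np.empty((n_draws, Y.shape[0]))
    p_draws = np.empty_like(r_draws)
    for d in range(n_draws):
        idx = rng.choice(n, size=m, replace=False)
        ys = Y[:, idx]
        ts = t[idx]
        yc = ys - ys.mean(axis=1, keepdims=True)
        tc = ts - ts.mean()
        denom = np.sqrt(np.sum(yc ** 2, axis=1)) * np.sqrt(np.sum(tc ** 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (yc @ tc) / denom
        r_draws[d] = r
        with np.errstate(invalid="ignore", divide="ignore"):
            tt = r * np.sqrt((m - 2) / np.clip(1 - r ** 2, 1e-300, None))
        p_draws[d] = 2.0 * stats.t.sf(np.abs(tt), df=m - 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        median_r = np.nanmedian(r_draws, axis=0)
    valid = ~np.isnan(median_r)
    if p_mode == "median_p":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            p = np.nanmedian(p_draws, axis=0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            tt = median_r * np.sqrt((m - 2) / np.clip(1 - median_r ** 2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(tt), df=m - 2)
    fdr = np.full_like(p, np.nan)
    if valid.any():
        fdr[valid] = multipletests(p[valid], method="fdr_bh")[1]
    out = pd.DataFrame({"gene": matrix.index, "median_r": median_r, "p": p,
                        "fdr": fdr, "n_draws": n_draws,
                        "excluded_constant": ~valid}).set_index("gene", drop=False)
    if (~valid).any():
        warnings.warn(f"{int((~valid).sum())} constant gene(s) excluded from "
                      "correlation")
    return out


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n_total: int) -> float:
    """Signed enrichment score from sorted hit positions and their weights.

    The running deviation P_hit - P_miss changes only at hits; the extremum
    lies just before or just after a hit, so 2k candidate deviations suffice.
    When the set covers every gene (no misses), the positional CDF i/N stands
    in for the miss curve so the walk still ends at 0.
    """
    k = len(pos)
    order = np.argsort(pos)
    pos = pos[order]
    w = np.abs(weights[order])
    total_w = w.sum()
    if total_w <= 0:
        w = np.ones(k)
        total_w = float(k)
    w_cum = np.cumsum(w) / total_w
    n_miss = n_total - k
    j = np.arange(1, k + 1)
    if n_miss > 0:
        miss_after = (pos + 1 - j) / n_miss    # misses up to and incl. position pos
        miss_before = (pos - (j - 1)) / n_miss
    else:
        miss_after = (pos + 1) / n_total
        miss_before = pos / n_total
    dev_after = w_cum - miss_after
    dev_before = np.concatenate([[0.0], w_cum[:-1]]) - miss_before
    devs = np.concatenate([dev_after, dev_before])
    return float(devs[np.argmax(np.abs(devs))])


def gsea_preranked(ranked_stats: pd.Series, gene_sets: dict, n_perm: int = 1000,
                   weight: float = 1.0, min_size: int = 5, seed: int = 0
                   ) -> pd.DataFrame:
    """Weighted-KS preranked gene set enrichment with a gene-permutation null.

    ``ranked_stats`` maps gene -> ranking statistic (e.g. pseudotime
    correlation). Hit increments are proportional to |stat|^weight. The null
    permutes gene labels (random sets of the same size) n_perm times;
    p = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1), two-sided on |ES|, and
    NES = ES / mean |same-sign null ES|. BH FDR across sets.
    """
    if ranked_stats.index.duplicated().any():
        raise ValueError("duplicate gene ids in the ranked list")
    ranked = ranked_stats.sort_values(ascending=False, kind="stable")
    genes = ranked.index
    statv = np.abs(ranked.to_numpy(dtype=float)) ** weight
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        pos = np.array(sorted({gene_pos[g] for g in members if g in gene_pos}))
        k = len(pos)
        if k < min_size:
            warnings.warn(f"gene set {name!r} overlaps the ranking by {k} genes "
                          f"(< {min_size}): skipped")
            continue
        es = _es_from_positions(pos, statv[pos], n)
        # permutation null: random positions of the same size
        null_es = np.empty(n_perm)
        for i in range(n_perm):
            rpos = rng.choice(n, size=k, replace=False)
            null_es[i] = _es_from_positions(rpos, statv[rpos], n)
        # two-sided permutation p on |ES| (uniform under the null, minimum
        # attainable 1/(n_perm+1)); NES normalizes by the same-sign null mean
        hits = int(np.sum(np.abs(null_es) >= abs(es)))
        p = (1 + hits) / (n_perm + 1)
        same_sign = null_es * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
        n_same = int(same_sign.sum())
        denom = np.abs(null_es[same_sign]).mean() if n_same else np.nan
        nes = es / denom if denom and not np.isnan(denom) else np.nan
        rows.append({"gene_set": name, "es": es, "nes": nes, "p_perm": p,
                     "size": k})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_twogroup(expression: pd.Series, survival_time: pd.Series,
                event: pd.Series, split: str = "median") -> dict:
    """Two-group overall-survival contrast on one gene's expression.

    Samples with missing survival are removed first; groups are the median
    split of expression (high: strictly above the median). Returns the
    Kaplan-Meier curves per group and the two-group log-rank statistic and
    p-value (p = 1 by convention when no events occur).
    """
    df = pd.DataFrame({"x": expression, "time": survival_time, "event": event})
    df = df.dropna()
    if split != "median":
        raise ValueError("only the median split is supported")
    cut = df["x"].median()
    high = df["x"] > cut
    if high.all() or (~high).all():
        raise ValueError("median split produced an empty group (all values tied)")
    groups = {"low": df[~high], "high": df[high]}
    curves = {}
    if _KMF is None:  # pragma: no cover
        raise ImportError("lifelines is required for survival analysis")
    for name, g in groups.items():
        kmf = _KMF()
        kmf.fit(g["time"], event_observed=g["event"], label=name)
        curves[name] = kmf.survival_function_
    n_events = int(df["event"].sum())
    if n_events == 0:
        return {"n": {k: len(v) for k, v in groups.items()}, "n_events": 0,
                "logrank_stat": 0.0, "p": 1.0, "curves": curves}
    res = _logrank_test(groups["low"]["time"], groups["high"]["time"],
                        event_observed_A=groups["low"]["event"],
                        event_observed_B=groups["high"]["event"])
    return {"n": {k: len(v) for k, v in groups.items()}, "n_events": n_events,
            "logrank_stat": float(res.test_statistic), "p": float(res.p_value),
            "curves": curves}
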