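"""Expression analysis: clustering, centroid subtyping, moderated-t
differential expression, top-gene selection and gene-set over-representation.

The differential-expression test is the empirical-Bayes moderated t: the
per-gene pooled variance s_g^2 (d_g residual df) is shrunk toward a prior
(d0, s0^2) fitted by moment matching on log s_g^2 via digamma/trigamma
inversion, giving

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g    = delta_g / (s~_g * sqrt(1/n1 + 1/n2)),   df = d0 + d_g

with delta_g the mean log2 difference (first contrast group minus second).
When the observed log-variances are underdispersed relative to their
sampling noise the prior df is infinite and the common variance is the
arithmetic mean of the s_g^2 (so with identical gene variances the
moderated t reduces exactly to the ordinary pooled-variance t).

Clustering is Ward agglomeration applied directly to the 1 - Pearson
dissimilarity via the Lance-Williams update (the Ward.D convention), with
deterministic smallest-index tie-breaking.  Subtyping assigns each sample
the class whose standardized centroid it correlates with best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .io_formats import GeneSetCollection
from .stats import bh_adjust, hypergeometric_tail

__all__ = [
    "ModeratedTFit",
    "CentroidModel",
    "ward_pearson_cluster",
    "build_centroid_classifier",
    "classify_by_centroid",
    "moderated_t_test",
    "select_top_genes",
    "filter_de",
    "collapse_to_genes",
    "hypergeometric_enrichment",
]


@dataclass
class ModeratedTFit:
    """Empirical-Bayes variance prior and the per-gene inputs it was fit to."""

    d0: float                 # prior df (may be inf)
    s0_sq: float              # prior variance
    s_g_sq: np.ndarray        # per-gene pooled variances
    d_g: int                  # residual df (n1 + n2 - 2)


@dataclass
class CentroidModel:
    """Per-class mean standardized expression over a fixed probe list."""

    probes: pd.Index
    class_names: list[str]
    centroids: pd.DataFrame       # probes x classes
    ref_mean: pd.Series
    ref_sd: pd.Series


# ---------------------------------------------------------------------------
# clustering


def ward_pearson_cluster(expr: pd.DataFrame, k: int,
                         ) -> tuple[pd.Series, np.ndarray]:
    """Ward's linkage on the 1 - Pearson dissimilarity between samples.

    Agglomeration uses the Lance-Williams Ward update applied directly to
    the dissimilarities (Ward.D convention); equal-distance ties are broken
    by the smallest pair of cluster indices.  Returns (labels cut at k,
    scipy-style merge tree).  Labels are 0..k-1 in order of each cluster's
    first sample.
    """
    samples = list(expr.columns)
    n = len(samples)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    X = expr.to_numpy(dtype=float)
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = samples[int(np.argmax(sds == 0))]
        raise ValueError(f"sample {bad!r} has zero variance")
    D = 1.0 - np.corrcoef(X, rowvar=False)
    np.fill_diagonal(D, np.inf)

    active = {i: (i, 1) for i in range(n)}   # slot -> (cluster id, size)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4))
    labels_at_k: list[list[int]] | None = None
    if k == n:
        labels_at_k = [members[i] for i in range(n)]
    work = D.copy()
    for step in range(n - 1):
        slots = sorted(active)
        best = (np.inf, None, None)
        for ai, i in enumerate(slots):
            for j in slots[ai + 1:]:
                if work[i, j] < best[0] - 1e-15:
                    best = (work[i, j], i, j)
        dist, i, j = best
        ci, ni = active[i]
        cj, nj = active[j]
        new_id = n + step
        merges[step] = (min(ci, cj), max(ci, cj), dist, ni + nj)
        # Lance-Williams Ward.D update into slot i
        for m in slots:
            if m in (i, j):
                continue
            nm = active[m][1]
            work[i, m] = work[m, i] = (
                (ni + nm) * work[i, m] + (nj + nm) * work[j, m]
                - nm * dist) / (ni + nj + nm)
        members[new_id] = members.pop(ci) + members.pop(cj)
        active[i] = (new_id, ni + nj)
        del active[j]
        work[j, :] = work[:, j] = np.inf
        if len(active) == k:
            labels_at_k = [members[active[s][0]] for s in sorted(active)]
    if labels_at_k is None:
        labels_at_k = [members[active[s][0]] for s in sorted(active)]
    labels_at_k.sort(key=min)
    lab = np.empty(n, dtype=int)
    for c, mem in enumerate(labels_at_k):
        lab[mem] = c
    return pd.Series(lab, index=samples, name="cluster"), merges


# ---------------------------------------------------------------------------
# centroid subtyping


def build_centroid_classifier(reference_expr: pd.DataFrame, labels,
                              probes=None) -> CentroidModel:
    """Build per-class centroids of z-scored reference expression.

    Probes are standardized across the reference samples; each class (>= 2
    reference samples) contributes the mean z-profile of its samples.
    """
    labels = pd.Series(labels)
    if probes is None:
        probes = reference_expr.index
    probes = pd.Index(probes)
    missing = probes.difference(reference_expr.index)
    if len(missing):
        raise ValueError(f"probe {missing[0]!r} absent from reference")
    X = reference_expr.loc[probes, labels.index]
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance probe in reference; cannot standardize")
    Z = X.sub(mean, axis=0).div(sd, axis=0)
    class_names = sorted(labels.unique())
    cols = {}
    for cls in class_names:
        ids = labels.index[labels == cls]
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 reference samples")
        cols[cls] = Z[ids].mean(axis=1)
    return CentroidModel(probes, class_names, pd.DataFrame(cols), mean, sd)


def classify_by_centroid(model: CentroidModel, expr: pd.DataFrame,
                         ) -> pd.DataFrame:
    """Assign each sample the centroid class it correlates with best.

    Expression is z-scored per probe across the cohort being classified;
    missing model probes are dropped pairwise but at least 50% must be
    present.  Ties go to the first class in model order (with a warning).
    Returns a frame with columns (class, correlation).
    """
    present = model.probes.intersection(expr.index)
    if len(present) < 0.5 * len(model.probes):
        raise ValueError(
            f"only {len(present)}/{len(model.probes)} model probes present "
            "(>= 50% required)")
    X = expr.loc[present]
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    X = X.loc[keep]
    Z = X.sub(X.mean(axis=1), axis=0).div(sd[keep], axis=0)
    C = model.centroids.loc[X.index]
    out = []
    for s in expr.columns:
        z = Z[s].to_numpy()
        rs = np.array([np.corrcoef(z, C[c].to_numpy())[0, 1]
                       for c in model.class_names])
        best = float(np.max(rs))
        hits = np.flatnonzero(rs >= best - 1e-12)
        if len(hits) > 1:
            warnings.warn(f"sample {s!r}: correlation tie; first class "
                          "in model order kept")
        out.append((model.class_names[hits[0]], best))
    return pd.DataFrame(out, index=expr.columns,
                        columns=["class", "correlation"])


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log s_g^2 (scaled-inverse-chi-square prior)."""
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(np.mean(e))
    n = len(e)
    if n < 2:
        return np.inf, float(np.mean(s2))
    evar = float(np.mean((e - e_bar) ** 2) * n / (n - 1)
                 - special.polygamma(1, df / 2.0))
    if evar <= 0:
        # log-variances underdispersed vs sampling noise: common variance
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(expr: pd.DataFrame, group_labels, contrast=None,
                     ) -> tuple[pd.DataFrame, ModeratedTFit]:
    """Empirical-Bayes moderated t-test between two groups of samples.

    ``contrast=(A, B)`` fixes the direction (delta = mean_A - mean_B,
    fc = 2**delta); by default the two group labels in sorted order.
    Returns (per-probe result frame sorted by p, fit).  Requires >= 2
    samples per group and >= 2 probes.
    """
    groups = pd.Series(group_labels)
    levels = sorted(groups.unique()) if contrast is None else list(contrast)
    if len(levels) != 2:
        raise ValueError("moderated t requires exactly two groups")
    a_ids = groups.index[groups == levels[0]]
    b_ids = groups.index[groups == levels[1]]
    n1, n2 = len(a_ids), len(b_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    if len(expr) < 2:
        raise ValueError("need at least 2 probes")
    A = expr[a_ids].to_numpy(dtype=float)
    B = expr[b_ids].to_numpy(dtype=float)
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("expression matrix contains non-finite values")
    delta = A.mean(axis=1) - B.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df
    d0, s0_sq = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(delta == 0.0, 0.0, delta / se)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    result = pd.DataFrame({
        "delta": delta,
        "fc": 2.0 ** delta,
        "t_mod": t,
        "p_value": p,
        "q_value": bh_adjust(p),
        "direction": np.where(delta > 0, f"up_in_{levels[0]}",
                              np.where(delta < 0, f"up_in_{levels[1]}", "none")),
    }, index=expr.index)
    result = result.iloc[np.lexsort((expr.index, p))]
    fit = ModeratedTFit(d0, s0_sq, s2, df)
    return result, fit


def select_top_genes(de_result: pd.DataFrame, n_per_side: int = 500,
                     ) -> tuple[list[str], list[str]]:
    """The n most significant probes per direction (ties by probe id).

    Mirrors the "1000 most differentially expressed genes" selection: the
    smallest-p probes with positive delta and, separately, negative delta.
    Short sides are returned in full with a warning.
    """
    up_a = de_result[de_result["delta"] > 0]
    up_b = de_result[de_result["delta"] < 0]
    out = []
    for side in (up_a, up_b):
        ranked = side.iloc[np.lexsort((side.index, side["p_value"]))]
        if len(ranked) < n_per_side:
            warnings.warn(f"only {len(ranked)} probes available on one side "
                          f"(requested {n_per_side})")
        out.append(list(ranked.index[:n_per_side]))
    return out[0], out[1]


def filter_de(de_result: pd.DataFrame, p_max: float = 0.05,
              fc_min: float = 1.5) -> dict:
    """Count/list probes passing raw p < p_max and fold change > fc_min.

    Fold change is direction-symmetric: max(fc, 1/fc) is compared.  Returns
    per-direction probe lists and counts.
    """
    fc_sym = np.maximum(de_result["fc"], 1.0 / de_result["fc"])
    kept = de_result[(de_result["p_value"] < p_max) & (fc_sym > fc_min)]
    directions = [d for d in kept["direction"].unique() if d != "none"]
    lists = {d: list(kept.index[kept["direction"] == d])
             for d in sorted(directions)}
    return {"counts": {d: len(v) for d, v in lists.items()}, "lists": lists}


# ---------------------------------------------------------------------------
# gene-set over-representation


def collapse_to_genes(de_or_expr: pd.DataFrame, probe_genes: pd.Series,
                      expr: pd.DataFrame | None = None) -> pd.Series:
    """Choose one probe per gene (the highest-variance probe).

    Returns a Series gene -> representative probe.  ``expr`` supplies the
    variances; if omitted, ``de_or_expr`` itself must be an expression
    matrix.
    """
    mat = expr if expr is not None else de_or_expr
    variances = mat.var(axis=1, ddof=1)
    df = pd.DataFrame({"gene": probe_genes.loc[mat.index],
                       "var": variances})
    df = df.sort_values(["gene", "var"], ascending=[True, False],
                        kind="mergesort")
    best = df.groupby("gene", sort=True).head(1)
    return pd.Series(best.index.to_numpy(), index=best["gene"].to_numpy())


def hypergeometric_enrichment(gene_list, gene_sets: GeneSetCollection,
                              universe=None) -> pd.DataFrame:
    """Over-representation of each gene set in a gene list.

    p = P(X >= k) with X ~ Hypergeometric(N = |universe|, K = |set|,
    n = |list|); q by BH across sets.  The gene list must be drawn from the
    universe; sets are restricted to the universe first.
    """
    universe = frozenset(universe if universe is not None
                         else gene_sets.universe)
    if not universe:
        raise ValueError("empty universe")
    genes = frozenset(gene_list)
    stray = genes - universe
    if stray:
        raise ValueError(f"gene {sorted(stray)[0]!r} not in universe")
    restricted = gene_sets.restrict(universe)
    N, n = len(universe), len(genes)
    rows = []
    for name in sorted(restricted.sets):
        members = restricted.sets[name]
        K = len(members)
        k = len(members & genes)
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "list_size": n, "universe": N,
                     "p_value": hypergeometric_tail(N, K, n, k)})
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table = table.iloc[np.lexsort((table["set"], table["p_value"]))]
        table = table.reset_index(drop=True)
    return table
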