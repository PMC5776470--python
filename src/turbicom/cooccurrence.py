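"""Ensemble co-occurrence network inference from the rDNA fraction.

Five association measures — Pearson and Spearman correlation, mutual
information on equal-frequency-binned abundances, and Bray-Curtis and
symmetrized Kullback-Leibler dissimilarities between OTU profiles — are
computed on sample-wise relative abundances. Per metric, the strongest
co-presence and mutual-exclusion candidates are retained by an edge-count
threshold; candidate p-values come from a permutation null that shuffles
each OTU's counts across samples independently (optionally renormalizing
relative abundances afterwards, a guard against compositional artefacts).
Pairs whose supporting metrics disagree in sign or number fewer than two
are dropped, surviving p-values are merged by Fisher's method and
controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2, rankdata

from .datamodel import (
    CooccurrenceNetwork,
    OtuTable,
    Taxonomy,
    ValidationError,
    canonical_pair,
)

logger = logging.getLogger(__name__)

METRICS = (
    "pearson",
    "spearman",
    "mutual_information",
    "bray_curtis",
    "kullback_leibler",
)
CORRELATIONS = ("pearson", "spearman")
DISSIMILARITIES = ("bray_curtis", "kullback_leibler")
KL_PSEUDOCOUNT = 1e-6


def filter_min_occurrence(table: OtuTable, min_occ: int = 5) -> OtuTable:
    """Drop OTUs occurring (count > 0) in fewer than ``min_occ`` samples."""
    if min_occ < 1:
        raise ValidationError("min_occ must be >= 1")
    occ = (table.matrix() > 0).sum(axis=0)
    keep = [o for o, n in zip(table.otu_ids, occ) if n >= min_occ]
    if len(keep) < 2:
        raise ValidationError(
            f"fewer than 2 OTUs left after min-occurrence filter ({len(keep)})"
        )
    return table.subset_otus(keep)


# -- score matrices ----------------------------------------------------------

def _rank_columns(mat: np.ndarray) -> np.ndarray:
    return rankdata(mat, axis=0)


def _corr_matrix(mat: np.ndarray) -> np.ndarray:
    sd = mat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return corr


def _bin_codes(mat: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization per column (stable tie ordering)."""
    s = mat.shape[0]
    order = np.argsort(mat, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(s)[:, None], axis=0)
    return (ranks * n_bins) // s


def _mi_matrix(codes: np.ndarray, n_bins: int) -> np.ndarray:
    """Pairwise mutual information (nats) between binned columns."""
    s, o = codes.shape
    onehot = [(codes == b).astype(np.float32) for b in range(n_bins)]
    marg = [h.sum(axis=0) for h in onehot]  # per-column bin counts
    mi = np.zeros((o, o))
    for b1 in range(n_bins):
        for b2 in range(n_bins):
            joint = onehot[b1].T @ onehot[b2]  # counts n_{b1,b2} per pair
            outer = np.outer(marg[b1], marg[b2])
            with np.errstate(invalid="ignore", divide="ignore"):
                term = (joint / s) * np.log(joint * s / outer)
            mi += np.where(joint > 0, term, 0.0)
    return mi


def _profiles(mat: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    prof = mat + pseudocount
    return prof / prof.sum(axis=0, keepdims=True)


def _kl_matrix(mat: np.ndarray) -> np.ndarray:
    p = _profiles(mat, KL_PSEUDOCOUNT)
    logp = np.log(p)
    h = (p * logp).sum(axis=0)
    cross = p.T @ logp  # cross[i, j] = sum_s p_i log p_j
    kl = h[:, None] - cross
    return 0.5 * (kl + kl.T)


def association_scores(table: OtuTable, metric: str, n_bins: int = 4) -> pd.DataFrame:
    """Pairwise OTU association scores for one metric (OTU x OTU frame)."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    rel = table.relative_abundance().to_numpy()
    if metric == "pearson":
        mat = _corr_matrix(rel)
    elif metric == "spearman":
        mat = _corr_matrix(_rank_columns(rel))
    elif metric == "mutual_information":
        mat = _mi_matrix(_bin_codes(rel, n_bins), n_bins)
    elif metric == "bray_curtis":
        # canonical BC sum|x-y| / sum(x+y) on the relative-abundance columns
        mat = cdist(rel.T, rel.T, metric="braycurtis")
    else:  # kullback_leibler
        mat = _kl_matrix(rel)
    if metric in CORRELATIONS and np.isnan(mat).any():
        n_bad = int(np.isnan(np.diag(mat)).sum())
        if n_bad:
            logger.info("%d zero-variance OTUs excluded from %s", n_bad, metric)
    return pd.DataFrame(mat, index=table.otu_ids, columns=table.otu_ids)


def all_association_scores(table: OtuTable, n_bins: int = 4) -> dict[str, pd.DataFrame]:
    return {m: association_scores(table, m, n_bins) for m in METRICS}


# -- threshold selection -----------------------------------------------------

def select_threshold_edges(
    scores: dict[str, pd.DataFrame], n_top: int = 1000
) -> pd.DataFrame:
    """Per metric, retain the strongest co-presence and exclusion candidates.

    Correlations: most positive coefficients are co-presence, most negative
    mutual-exclusion. Dissimilarities: smallest are co-presence, largest
    mutual-exclusion. Mutual information is unsigned; candidates take their
    sign from the pair's Spearman coefficient and pairs with Spearman
    exactly 0 (or undefined) are sign-inconclusive and dropped. Ties at the
    retention boundary are all kept.
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    if "spearman" not in scores and "mutual_information" in scores:
        raise ValidationError("MI sign assignment requires spearman scores")
    any_frame = next(iter(scores.values()))
    otus = list(any_frame.columns)
    n = len(otus)
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    if n_top > n_pairs:
        logger.warning("n_top=%d exceeds %d pairs; retaining all", n_top, n_pairs)

    def _top(vals: np.ndarray, mask: np.ndarray, largest: bool) -> np.ndarray:
        """Boolean selector of the n_top strongest entries (ties kept)."""
        idx = np.where(mask)[0]
        if idx.size == 0:
            return np.zeros_like(mask)
        v = vals[idx]
        if idx.size <= n_top:
            thresh = v.min() if largest else v.max()
        else:
            v_sorted = np.sort(v)
            thresh = v_sorted[-n_top] if largest else v_sorted[n_top - 1]
        sel = np.zeros_like(mask)
        sel[idx] = v >= thresh if largest else v <= thresh
        return sel

    rows = []
    sp_vals = scores["spearman"].to_numpy()[iu] if "spearman" in scores else None
    for metric, frame in scores.items():
        vals = frame.to_numpy()[iu]
        valid = np.isfinite(vals)
        if metric in CORRELATIONS:
            pos = _top(vals, valid & (vals > 0), largest=True)
            neg = _top(vals, valid & (vals < 0), largest=False)
        elif metric == "mutual_information":
            sgn = np.sign(np.where(np.isfinite(sp_vals), sp_vals, 0.0))
            pos = _top(vals, valid & (sgn > 0), largest=True)
            neg = _top(vals, valid & (sgn < 0), largest=True)
        else:  # dissimilarities
            pos = _top(vals, valid, largest=False)
            neg = _top(vals, valid, largest=True) & ~pos
        for sel, sign in ((pos, "co-presence"), (neg, "mutual-exclusion")):
            for k in np.where(sel)[0]:
                ia, ib = int(iu[0][k]), int(iu[1][k])
                a, b = canonical_pair(otus[ia], otus[ib])
                rows.append((a, b, metric, float(vals[k]), sign, ia, ib))
    return pd.DataFrame(
        rows, columns=["otu_a", "otu_b", "metric", "score", "sign", "ia", "ib"]
    )


# -- permutation p-values ----------------------------------------------------

def _pair_score(x: np.ndarray, y: np.ndarray, metric: str, n_bins: int = 4) -> float:
    if metric == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if metric == "spearman":
        return float(np.corrcoef(rankdata(x), rankdata(y))[0, 1])
    if metric == "mutual_information":
        codes = _bin_codes(np.column_stack([x, y]), n_bins)
        return float(_mi_matrix(codes, n_bins)[0, 1])
    if metric == "bray_curtis":
        return float(np.abs(x - y).sum() / (x + y).sum())
    if metric == "kullback_leibler":
        return float(_kl_matrix(np.column_stack([x, y]))[0, 1])
    raise ValidationError(f"unknown metric {metric!r}")


def _more_extreme(null: np.ndarray, obs: float, metric: str, sign: str) -> np.ndarray:
    """Null values at least as extreme as ``obs`` in the edge's direction."""
    if metric == "mutual_information":
        return null >= obs  # magnitude-only
    dissim = metric in DISSIMILARITIES
    if sign == "co-presence":
        return null <= obs if dissim else null >= obs
    return null >= obs if dissim else null <= obs


def permutation_pvalue(
    table: OtuTable,
    edge,
    n_perm: int = 999,
    renormalize: bool = True,
    seed: int = 0,
    n_bins: int = 4,
) -> float:
    """Permutation p-value for one edge (reference implementation).

    ``edge`` is a mapping/row with otu_a, otu_b, metric, sign. Each OTU's
    counts are shuffled across samples independently; with ``renormalize``
    the two relative-abundance profiles are recomputed from the permuted
    counts and the per-sample totals they induce.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    counts = table.counts
    a, b, metric, sign = edge["otu_a"], edge["otu_b"], edge["metric"], edge["sign"]
    ca = counts[a].to_numpy(float)
    cb = counts[b].to_numpy(float)
    totals = counts.sum(axis=1).to_numpy(float)
    obs = _pair_score(ca / totals, cb / totals, metric, n_bins)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pa = rng.permutation(ca)
        pb = rng.permutation(cb)
        if renormalize:
            ta = totals - ca + pa
            tb = totals - cb + pb
            null[i] = _pair_score(pa / ta, pb / tb, metric, n_bins)
        else:
            null[i] = _pair_score(pa / totals, pb / totals, metric, n_bins)
    extreme = int(_more_extreme(null, obs, metric, sign).sum())
    return (1 + extreme) / (1 + n_perm)


def permutation_pvalues(
    table: OtuTable,
    candidates: pd.DataFrame,
    n_perm: int = 999,
    renormalize: bool = True,
    seed: int = 0,
    n_bins: int = 4,
    return_null: bool = False,
):
    """Vectorized permutation p-values for a candidate table.

    One independent permutation per OTU per replicate, shared across
    candidate edges (each pair still sees two independently shuffled
    profiles, so the marginal null per edge is the same as in
    :func:`permutation_pvalue`).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    counts = table.matrix().astype(float)
    s, o = counts.shape
    rng = np.random.default_rng(seed)
    cand = candidates.reset_index(drop=True)
    extreme = np.zeros(len(cand), dtype=np.int64)
    obs = cand["score"].to_numpy(float)
    null_store = np.empty((n_perm, len(cand)), dtype=np.float32) if return_null else None

    by_metric = {m: cand.index[cand["metric"] == m].to_numpy() for m in METRICS}
    # flat upper-triangle indices per candidate into the O x O score matrix
    flat = cand["ia"].to_numpy() * o + cand["ib"].to_numpy()
    need_ranks = by_metric["spearman"].size or by_metric["mutual_information"].size
    rel0 = counts / counts.sum(axis=1, keepdims=True)

    signs_ge = np.empty(len(cand), dtype=bool)  # True: extreme means null >= obs
    for metric in METRICS:
        rows = by_metric[metric]
        if rows.size:
            sign = cand.loc[rows, "sign"].to_numpy()
            if metric == "mutual_information":
                signs_ge[rows] = True
            elif metric in DISSIMILARITIES:
                signs_ge[rows] = sign == "mutual-exclusion"
            else:
                signs_ge[rows] = sign == "co-presence"

    for rep in range(n_perm):
        idx = np.argsort(rng.random((o, s)), axis=1)
        perm = np.take_along_axis(counts.T, idx, axis=1).T
        if renormalize:
            row = perm.sum(axis=1, keepdims=True)
            row[row == 0] = 1.0
            rel = perm / row
        else:
            rel = np.take_along_axis(rel0.T, idx, axis=1).T

        null = np.empty(len(cand))
        rows = by_metric["pearson"]
        if rows.size:
            null[rows] = _corr_matrix(rel).ravel()[flat[rows]]
        if need_ranks:
            ranks = _rank_columns(rel)
        rows = by_metric["spearman"]
        if rows.size:
            sp_mat = _corr_matrix(ranks)
            null[rows] = sp_mat.ravel()[flat[rows]]
        rows = by_metric["mutual_information"]
        if rows.size:
            mi_mat = _mi_matrix(_bin_codes(rel, n_bins), n_bins)
            null[rows] = mi_mat.ravel()[flat[rows]]
        rows = by_metric["bray_curtis"]
        if rows.size:
            bc_mat = cdist(rel.T, rel.T, metric="braycurtis")
            null[rows] = bc_mat.ravel()[flat[rows]]
        rows = by_metric["kullback_leibler"]
        if rows.size:
            null[rows] = _kl_matrix(rel).ravel()[flat[rows]]

        ge = null >= obs
        le = null <= obs
        extreme += np.where(signs_ge, ge, le)
        if null_store is not None:
            null_store[rep] = null

    out = cand.copy()
    out["p_value"] = (1 + extreme) / (1 + n_perm)
    if return_null:
        return out, null_store
    return out


# -- merging and FDR ---------------------------------------------------------

def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH q-values: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_merge(p_values) -> float:
    """Fisher's method: chi-square tail of -2 sum(log p) with 2k d.f."""
    p = np.asarray(p_values, dtype=float)
    stat = -2.0 * np.sum(np.log(p))
    return float(chi2.sf(stat, 2 * p.size))


def _null_log_p(cand: pd.DataFrame, null_scores: np.ndarray) -> np.ndarray:
    """-2 ln p of every null replicate within its own null distribution.

    Per candidate, each null score is rank-transformed in the candidate's
    extremity direction (p_t = #(null at least as extreme as null_t) /
    n_perm); feeds the empirical covariance Brown's method needs.
    """
    from scipy.stats import rankdata as _rankdata

    n_perm, n_cand = null_scores.shape
    keys = null_scores.astype(float).copy()
    metric = cand["metric"].to_numpy()
    sign = cand["sign"].to_numpy()
    # larger key = more extreme
    flip = np.zeros(n_cand, dtype=bool)
    for m in METRICS:
        cols = metric == m
        if m == "mutual_information":
            continue
        dissim = m in DISSIMILARITIES
        flip |= cols & (sign == ("co-presence" if dissim else "mutual-exclusion"))
    keys[:, flip] *= -1.0
    rank_min = _rankdata(keys, method="min", axis=0)
    p = (n_perm - rank_min + 1) / n_perm
    return -2.0 * np.log(p)


def brown_merge(obs_p, null_logp: np.ndarray) -> float:
    """Brown's dependence-adjusted combination of per-metric p-values.

    The statistic X = -2 sum(ln p) is referred to a scaled chi-square
    whose scale and degrees of freedom are matched to the empirical mean
    and variance of X over the shared permutation null, which absorbs the
    correlation between the association metrics.
    """
    p = np.asarray(obs_p, dtype=float)
    x_obs = -2.0 * np.sum(np.log(p))
    x_null = null_logp.sum(axis=1)
    mu = float(x_null.mean())
    var = float(x_null.var(ddof=1))
    if mu <= 0 or var <= 0:
        return fisher_merge(p)
    c = var / (2.0 * mu)
    df = 2.0 * mu * mu / var
    return float(chi2.sf(x_obs / c, df))


def merge_and_filter(
    candidates: pd.DataFrame,
    min_support: int = 2,
    q_threshold: float = 0.05,
    provenance: dict | None = None,
    null_scores: np.ndarray | None = None,
    method: str | None = None,
) -> CooccurrenceNetwork:
    """Combine per-metric candidates into the final network.

    Pairs with sign-discordant metric support ("inconclusive
    directionality") or support from fewer than ``min_support`` metrics are
    removed; surviving per-metric p-values are merged per pair — by Brown's
    dependence-adjusted method when the shared permutation null is supplied
    (``null_scores`` row-aligned to ``candidates``), else by Fisher's — and
    BH-FDR-controlled at ``q_threshold``.
    """
    if min_support < 2:
        raise ValidationError("min_support must be >= 2")
    if method is None:
        method = "brown" if null_scores is not None else "fisher"
    if method == "brown" and null_scores is None:
        raise ValidationError("Brown merging needs the null_scores matrix")
    cols = ["otu_a", "otu_b", "sign", "n_supporting_metrics", "supporting_metrics",
            "merged_p", "q_value"]
    if candidates.empty:
        return CooccurrenceNetwork(pd.DataFrame(columns=cols), provenance or {})
    cand = candidates.reset_index(drop=True)
    logp_null = _null_log_p(cand, null_scores) if method == "brown" else None
    rows = []
    for (a, b), grp in cand.groupby(["otu_a", "otu_b"], sort=True):
        signs = set(grp["sign"])
        if len(signs) != 1:
            continue  # inconclusive directionality
        # one entry per metric (a metric cannot support a pair twice)
        grp = grp.drop_duplicates(subset="metric")
        if len(grp) < min_support:
            continue
        metrics = sorted(grp["metric"])
        pvals = grp["p_value"].to_numpy()
        if method == "brown":
            merged = brown_merge(pvals, logp_null[:, grp.index.to_numpy()])
        else:
            merged = fisher_merge(pvals)
        rows.append(
            {
                "otu_a": a,
                "otu_b": b,
                "sign": signs.pop(),
                "n_supporting_metrics": len(metrics),
                "supporting_metrics": ",".join(metrics),
                "merged_p": merged,
            }
        )
    if not rows:
        return CooccurrenceNetwork(pd.DataFrame(columns=cols), provenance or {})
    edges = pd.DataFrame(rows)
    edges["q_value"] = benjamini_hochberg(edges["merged_p"].to_numpy())
    edges = edges[edges["q_value"] <= q_threshold].reset_index(drop=True)
    return CooccurrenceNetwork(edges[cols], provenance or {})


# -- end-to-end and summaries ------------------------------------------------

def infer_network(
    table: OtuTable,
    min_occ: int = 5,
    n_top: int = 1000,
    n_perm: int = 999,
    min_support: int = 2,
    q_threshold: float = 0.05,
    renormalize: bool = True,
    n_bins: int = 4,
    seed: int = 0,
) -> CooccurrenceNetwork:
    """Full ensemble inference on one (rDNA) table."""
    filtered = filter_min_occurrence(table, min_occ)
    # canonical column order: inference is invariant to input OTU order
    filtered = filtered.subset_otus(sorted(filtered.otu_ids))
    scores = all_association_scores(filtered, n_bins)
    cand = select_threshold_edges(scores, n_top)
    # pairs that cannot reach min_support or are sign-discordant would be
    # dropped at merge time anyway; skip their permutation work
    keep = cand.groupby(["otu_a", "otu_b"])["sign"].transform(
        lambda s: len(s) >= min_support and s.nunique() == 1
    )
    cand = cand[keep].reset_index(drop=True)
    cand, null_scores = permutation_pvalues(
        filtered, cand, n_perm=n_perm, renormalize=renormalize, seed=seed,
        n_bins=n_bins, return_null=True,
    )
    provenance = {
        "min_occ": min_occ,
        "n_top": n_top,
        "n_perm": n_perm,
        "min_support": min_support,
        "q_threshold": q_threshold,
        "renormalize": renormalize,
        "seed": seed,
        "fraction": table.fraction,
    }
    return merge_and_filter(cand, min_support, q_threshold, provenance, null_scores)


def network_summaries(
    network: CooccurrenceNetwork,
    taxonomy: Taxonomy | None = None,
    table: OtuTable | None = None,
) -> dict:
    """Edge counts, degree distribution, group-pair counts, per-lake signs."""
    edges = network.edges
    pos = edges["sign"] == "co-presence" if len(edges) else pd.Series(dtype=bool)
    out: dict = {
        "n_edges": int(len(edges)),
        "n_positive": int(pos.sum()) if len(edges) else 0,
        "n_negative": int((~pos).sum()) if len(edges) else 0,
        "n_otus_involved": len(network.nodes()),
        "median_degree": float(network.degrees().median()) if len(edges) else 0.0,
    }
    if taxonomy is not None and len(edges):
        pair_counts: dict[str, int] = {}
        for _, row in edges.iterrows():
            ga = taxonomy.group_of(row["otu_a"])
            gb = taxonomy.group_of(row["otu_b"])
            key = "|".join(sorted((ga, gb)))
            pair_counts[key] = pair_counts.get(key, 0) + 1
        out["group_pair_counts"] = dict(sorted(pair_counts.items()))
    if table is not None and len(edges):
        pooled = table.pooled_by_lake()
        frac = {}
        for lake in pooled.index:
            present = set(pooled.columns[pooled.loc[lake] > 0])
            both = edges[
                edges["otu_a"].isin(present) & edges["otu_b"].isin(present)
            ]
            if len(both):
                frac[str(lake)] = float((both["sign"] == "co-presence").mean())
        out["per_lake_positive_fraction"] = frac
    return out
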