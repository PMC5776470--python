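"""Phylogenetic structure of communities and of network edges.

MNTD (mean nearest taxon distance) is standardized against a tip-shuffle
null: shuffling the tip labels of the cophenetic matrix is equivalent to
drawing uniform random tip sets of the same richness from the pool, so the
null is vectorized that way. Negative SES (z) means phylogenetic
clustering, positive means overdispersion. Edge sets are compared by the
cophenetic distance of their OTU pairs with Welch's unequal-variance
t-test (closed form, Welch-Satterthwaite degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from skbio import DistanceMatrix, TreeNode

from .datamodel import CooccurrenceNetwork, OtuTable, ValidationError


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distance matrix."""
    return tree.tip_tip_distances()


def mntd(present_otus, dist: DistanceMatrix) -> float:
    """Mean distance of each present taxon to its nearest present neighbour."""
    present = sorted(set(present_otus))
    if len(present) < 2:
        raise ValidationError("MNTD needs at least 2 taxa")
    idx = [dist.index(o) for o in present]
    sub = dist.data[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


@dataclass
class SesMntdResult:
    sample_id: str
    mntd_obs: float
    null_mean: float
    null_sd: float
    z_score: float  # NaN when the null is degenerate
    p_rank: float
    n_null: int
    degenerate: bool = False


def _batch_mntd(dist: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """MNTD for a batch of index subsets (B x k) against a full matrix."""
    sub = dist[subsets[:, :, None], subsets[:, None, :]]
    b, k = subsets.shape
    sub[:, np.arange(k), np.arange(k)] = np.inf
    return sub.min(axis=2).mean(axis=1)


def ses_mntd(
    present_otus,
    dist: DistanceMatrix,
    n_null: int = 999,
    seed: int = 0,
    sample_id: str = "",
) -> SesMntdResult:
    """Standardized effect size of MNTD under the tip-shuffle null."""
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    present = sorted(set(present_otus))
    k = len(present)
    if k < 2:
        raise ValidationError("SES-MNTD needs at least 2 taxa")
    pool = len(dist.ids)
    obs = mntd(present, dist)
    rng = np.random.default_rng(seed)
    subsets = np.empty((n_null, k), dtype=np.intp)
    for i in range(n_null):
        subsets[i] = rng.choice(pool, size=k, replace=False)
    # chunk the batch to bound the B x k x k intermediate
    chunk = max(1, int(4e6 // max(k * k, 1)))
    null = np.concatenate(
        [_batch_mntd(dist.data, subsets[i : i + chunk]) for i in range(0, n_null, chunk)]
    )
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    degenerate = null_sd <= 1e-9 * max(null_mean, 1.0)
    z = float("nan") if degenerate else (obs - null_mean) / null_sd
    p_rank = (1 + int((null <= obs).sum())) / (n_null + 1)
    return SesMntdResult(
        sample_id=sample_id,
        mntd_obs=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        p_rank=float(p_rank),
        n_null=n_null,
        degenerate=degenerate,
    )


# -- edge-set comparison -----------------------------------------------------

def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, d.f. and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("Welch's t needs >= 2 observations per group")
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class EdgePhyloComparison:
    mean_dist_positive: float
    mean_dist_negative: float
    welch_t: float
    welch_df: float
    p: float
    n_positive: int
    n_negative: int


def edge_set_phylo_comparison(
    network: CooccurrenceNetwork, dist: DistanceMatrix
) -> EdgePhyloComparison:
    """Cophenetic distances of co-presence vs mutual-exclusion edge pairs."""
    edges = network.edges
    groups = {}
    for sign in ("co-presence", "mutual-exclusion"):
        sub = edges[edges["sign"] == sign]
        if len(sub) < 2:
            raise ValidationError(f"fewer than 2 {sign} edges")
        groups[sign] = np.array(
            [dist[row["otu_a"], row["otu_b"]] for _, row in sub.iterrows()]
        )
    t, df, p = welch_t(groups["co-presence"], groups["mutual-exclusion"])
    return EdgePhyloComparison(
        mean_dist_positive=float(groups["co-presence"].mean()),
        mean_dist_negative=float(groups["mutual-exclusion"].mean()),
        welch_t=t,
        welch_df=df,
        p=p,
        n_positive=len(groups["co-presence"]),
        n_negative=len(groups["mutual-exclusion"]),
    )


def community_vs_edge_ses(
    table: OtuTable,
    network: CooccurrenceNetwork,
    dist: DistanceMatrix,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-lake SES-MNTD for whole communities vs network-member subsets.

    Replicates are pooled per lake; subset (b) is the detected OTUs that
    participate in at least one network edge. Lakes whose subset has fewer
    than 2 members are flagged missing (NaN row) rather than dropped.
    """
    pooled = table.pooled_by_lake()
    members = set(network.nodes())
    ss = np.random.SeedSequence(seed)
    rows = []
    for lake, lake_seed in zip(pooled.index, ss.spawn(len(pooled.index))):
        detected = set(pooled.columns[pooled.loc[lake] > 0]) & set(dist.ids)
        # one seed for both subsets: the nulls are paired, and when the
        # network covers every detected OTU the two columns coincide
        s_lake = int(lake_seed.generate_state(1)[0] % 2**31)
        res_all = ses_mntd(detected, dist, n_null, s_lake, sample_id=str(lake))
        subset = detected & members
        if len(subset) >= 2:
            res_sub = ses_mntd(subset, dist, n_null, s_lake, sample_id=str(lake))
            z_sub, p_sub, n_sub = res_sub.z_score, res_sub.p_rank, len(subset)
        else:
            z_sub, p_sub, n_sub = np.nan, np.nan, len(subset)
        rows.append(
            {
                "lake": str(lake),
                "n_otus_all": len(detected),
                "z_all": res_all.z_score,
                "p_all": res_all.p_rank,
                "n_otus_network": n_sub,
                "z_network": z_sub,
                "p_network": p_sub,
            }
        )
    return pd.DataFrame(rows).set_index("lake")
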