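"""Beta-diversity structure along the gradient.

The centrepiece is the Raup-Crick dissimilarity under an
abundance-proportional null: for a pair of samples with richness n1 and n2
sharing s_obs OTUs, null assemblages of the same richness are drawn from
the full OTU pool without replacement with inclusion probability
proportional to each OTU's total abundance, and the dissimilarity is the
probability-scaled position of s_obs in the null distribution of shared
OTUs (ties get half weight, which centres the metric at 0.5 under its own
null). Ordination is non-metric MDS minimizing Kruskal stress-1; group
separation is ANOSIM on ranked dissimilarities; environmental fitting is
the squared multiple correlation of a variable with the ordination axes,
tested by permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .datamodel import OtuTable, Taxonomy, ValidationError
from .diversity import rarefy

logger = logging.getLogger(__name__)


# -- Raup-Crick -------------------------------------------------------------

def _null_presence(
    richness: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One null assemblage per sample: weighted sampling w/o replacement.

    Uses Gumbel-top-k keys: taking the ``k`` largest of log(w) + Gumbel
    noise is equivalent to successive draws without replacement with
    probability proportional to w.
    """
    n_samp, n_otu = len(richness), len(weights)
    keys = np.log(weights)[None, :] + rng.gumbel(size=(n_samp, n_otu))
    order = np.argsort(-keys, axis=1)
    pres = np.zeros((n_samp, n_otu), dtype=np.float32)
    for i, k in enumerate(richness):
        pres[i, order[i, :k]] = 1.0
    return pres


def raup_crick(
    table: OtuTable,
    n_reps: int = 999,
    seed: int = 0,
    pool_weights=None,
    null_weighting: str = "abundance",
) -> DistanceMatrix:
    """Raup-Crick dissimilarity with an abundance-proportional null.

    ``null_weighting`` selects how the null draws weight the OTU pool:
    ``"abundance"`` (total counts over the table, the default) or
    ``"occurrence"`` (number of samples an OTU occurs in). An explicit
    ``pool_weights`` vector (aligned to the table's OTUs) overrides both,
    which lets calibration experiments feed the exact generating weights.
    """
    if table.n_samples < 2:
        raise ValidationError("Raup-Crick needs at least 2 samples")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    counts = table.matrix()
    presence = (counts > 0)
    richness = presence.sum(axis=1)
    if np.any(richness == 0):
        empty = np.asarray(table.sample_ids)[richness == 0].tolist()
        raise ValidationError(f"samples with zero richness: {empty}")

    if pool_weights is not None:
        weights = np.asarray(pool_weights, dtype=float)
        if weights.shape != (table.n_otus,) or np.any(weights <= 0):
            raise ValidationError("pool_weights must be positive, one per OTU")
    elif null_weighting == "abundance":
        weights = counts.sum(axis=0).astype(float)
    elif null_weighting == "occurrence":
        weights = presence.sum(axis=0).astype(float)
    else:
        raise ValidationError(f"unknown null_weighting {null_weighting!r}")

    p32 = presence.astype(np.float32)
    s_obs = p32 @ p32.T
    rng = np.random.default_rng(seed)
    greater = np.zeros_like(s_obs)
    equal = np.zeros_like(s_obs)
    for _ in range(n_reps):
        null = _null_presence(richness, weights, rng)
        shared = null @ null.T
        greater += shared > s_obs
        equal += shared == s_obs
    # probability that a null pair shares more taxa than observed (ties
    # half-weighted): 1 for samples far more disjoint than the null, 0 for
    # far more similar, 0.5 on average under the null itself
    dis = (greater + 0.5 * equal) / n_reps
    dis = np.asarray((dis + dis.T) / 2.0, dtype=float)
    np.fill_diagonal(dis, 0.0)
    return DistanceMatrix(np.clip(dis, 0.0, 1.0), ids=table.sample_ids)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples on raw counts."""
    if table.n_samples < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    counts = table.matrix().astype(float)
    if np.any(counts.sum(axis=1) == 0):
        raise ValidationError("Bray-Curtis undefined for all-zero samples")
    dis = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(dis, ids=table.sample_ids)


# -- ordination -------------------------------------------------------------

@dataclass
class OrdinationResult:
    """NMDS coordinates with the achieved Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
    rescale: bool = True,
) -> OrdinationResult:
    """Non-metric MDS (SMACOF with isotonic regression on ranks).

    Best of ``n_restarts`` random initializations; coordinates are centred.
    Because a rank-based configuration is scale-free, the coordinates are
    by default rescaled so configuration distances are least-squares
    matched to the input dissimilarities; ordination spread (e.g. convex
    hull areas) then tracks dissimilarity magnitude, as with the
    half-change scaling of common ordination software. Stress and any
    scale-invariant statistic are unaffected.
    """
    n = dist.shape[0]
    if k < 1 or k >= n:
        raise ValidationError(f"k must be in [1, n_samples-1], got {k} for n={n}")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=tol,
        random_state=int(seed) % (2**32),
        normalized_stress=True,
        init="random",
    )
    coords = model.fit_transform(dist.data)
    coords = coords - coords.mean(axis=0, keepdims=True)
    if rescale:
        d_conf = pdist(coords)
        d_obs = dist.condensed_form()
        denom = float(np.dot(d_conf, d_conf))
        if denom > 0:
            coords = coords * (float(np.dot(d_conf, d_obs)) / denom)
    frame = pd.DataFrame(
        coords, index=list(dist.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=frame,
        stress=float(model.stress_),
        n_restarts=n_restarts,
        converged=bool(model.n_iter_ < max_iter),
    )


def anosim(
    dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """ANOSIM R and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2) on the
    ranked condensed dissimilarities, M = n(n-1)/2.
    """
    labels = np.asarray(list(groups))
    n = dist.shape[0]
    if len(labels) != n:
        raise ValidationError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if np.any(counts < 2):
        raise ValidationError(f"singleton groups not allowed: {uniq[counts < 2].tolist()}")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dist.data[iu])
    m = ranks.size

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r_obs), float(p)


def envfit(
    ordination: OrdinationResult, env, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """R^2 of an environmental vector fitted to the ordination axes.

    The coefficient of determination of the OLS regression of the variable
    on the (centred) axes, i.e. the squared maximal correlation with any
    direction in ordination space; p by permuting the variable over samples.
    """
    y = np.asarray(env, dtype=float)
    coords = ordination.coordinates.to_numpy()
    if y.shape[0] != coords.shape[0]:
        raise ValidationError("env vector length must match the ordination")
    if not np.all(np.isfinite(y)):
        raise ValidationError("env vector must be finite")
    if np.ptp(y) == 0:
        raise ValidationError("constant env vector: R^2 undefined")

    x = coords - coords.mean(axis=0, keepdims=True)
    # hat-matrix-free R^2 via least squares on centred y
    def r2_of(yv: np.ndarray) -> float:
        yc = yv - yv.mean()
        beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
        ss_res = np.sum((yc - x @ beta) ** 2)
        ss_tot = np.sum(yc**2)
        return 1.0 - ss_res / ss_tot

    r2 = r2_of(y)
    rng = np.random.default_rng(seed)
    count = sum(r2_of(rng.permutation(y)) >= r2 for _ in range(n_perm))
    p = (1 + count) / (1 + n_perm)
    return float(r2), float(p)


def convex_hull_area(points) -> float:
    """Area of the 2-D convex hull (0 for degenerate point sets)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an n x 2 matrix")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("non-finite coordinate in hull input")
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0  # collinear or coincident points


# -- rarity-inclusion profile ------------------------------------------------

@dataclass
class RarityProfile:
    """Hull area (beta-diversity) as rare OTUs are cumulatively included."""

    profile: pd.DataFrame  # columns: n_otus_included, hull_area, stress
    fraction: str


def abundance_ranked_otus(table: OtuTable) -> list[str]:
    """OTUs by decreasing total abundance, ties broken by OTU id."""
    totals = table.counts.sum(axis=0)
    order = sorted(totals.index, key=lambda o: (-totals[o], o))
    return order


def rarity_inclusion_profile(
    table: OtuTable,
    initial_top: int = 100,
    step: int = 50,
    n_reps: int = 999,
    seed: int = 0,
    nmds_restarts: int = 20,
) -> RarityProfile:
    """Convex-hull area of the NMDS as rarity is progressively included.

    Starts from the ``initial_top`` most abundant OTUs and adds ``step``
    OTUs at a time until the full table is reached; each prefix gets its
    own Raup-Crick matrix and 2-D NMDS.
    """
    if table.n_otus <= initial_top:
        raise ValidationError("table must have more OTUs than initial_top")
    ranked = abundance_ranked_otus(table)
    sizes = list(range(initial_top, table.n_otus, step))
    if sizes[-1] != table.n_otus:
        sizes.append(table.n_otus)
    ss = np.random.SeedSequence(seed)
    rows = []
    for m, sub_seed in zip(sizes, ss.spawn(len(sizes))):
        sub = table.subset_otus(ranked[:m])
        s1, s2 = sub_seed.spawn(2)
        dist = raup_crick(sub, n_reps=n_reps, seed=int(s1.generate_state(1)[0] % 2**31))
        ordn = nmds(
            dist, k=2, n_restarts=nmds_restarts,
            seed=int(s2.generate_state(1)[0] % 2**31),
        )
        rows.append((m, convex_hull_area(ordn.coordinates.to_numpy()), ordn.stress))
    frame = pd.DataFrame(rows, columns=["n_otus_included", "hull_area", "stress"])
    return RarityProfile(profile=frame, fraction=table.fraction)


# -- rare/abundant partition -------------------------------------------------

@dataclass
class AbundanceClassPartition:
    """Per-lake abundant/rare OTU sets at a relative-abundance cutoff."""

    abundant: dict[str, set[str]]
    rare: dict[str, set[str]]
    cutoff: float


def classify_rare_abundant(table: OtuTable, cutoff: float = 0.001) -> AbundanceClassPartition:
    """Partition detected OTUs per lake (replicates pooled) at a cutoff.

    Abundant iff relative abundance strictly exceeds the cutoff; rare iff
    detected but at or below it.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValidationError("cutoff must be in (0, 1)")
    pooled = table.pooled_by_lake()
    rel = pooled.div(pooled.sum(axis=1), axis=0)
    abundant, rare = {}, {}
    for lake in pooled.index:
        detected = pooled.columns[pooled.loc[lake] > 0]
        ab = set(detected[rel.loc[lake, detected] > cutoff])
        abundant[str(lake)] = ab
        rare[str(lake)] = set(detected) - ab
    return AbundanceClassPartition(abundant=abundant, rare=rare, cutoff=cutoff)


def shared_abundant_regression(
    partition: AbundanceClassPartition, reference_lake: str, env: dict
) -> tuple[float, int]:
    """OLS of |abundant(ref) & abundant(L)| on env(L) over the other lakes.

    Returns (R^2, slope sign in {-1, 0, +1}).
    """
    if reference_lake not in partition.abundant:
        raise ValidationError(f"reference lake {reference_lake!r} absent from partition")
    others = [l for l in partition.abundant if l != reference_lake]
    if len(others) < 3:
        raise ValidationError("need at least 3 non-reference lakes")
    ref = partition.abundant[reference_lake]
    x = np.array([float(env[l]) for l in others])
    y = np.array([len(ref & partition.abundant[l]) for l in others], dtype=float)
    if np.ptp(y) == 0:
        return 0.0, 0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    return float(r2), int(np.sign(slope))


# -- subsampling / rank abundance / fraction ratios --------------------------

def random_subsample_ordination(
    table_dna: OtuTable,
    table_rna: OtuTable,
    n_individuals: int,
    n_draws: int = 20,
    seed: int = 0,
    rc_reps: int = 199,
    with_ordination: bool = False,
    nmds_restarts: int = 8,
) -> pd.DataFrame:
    """Lake separation (ANOSIM R) of repeated random community subsamples.

    Every sample of each fraction is rarefied to ``n_individuals`` per
    draw, Raup-Crick is recomputed, and ANOSIM R by lake recorded; the
    distribution of R per fraction quantifies how robustly each fraction
    separates the lakes. 2-D NMDS per draw is optional (the statistic does
    not depend on it).
    """
    results = []
    ss = np.random.SeedSequence(seed)
    for table in (table_dna, table_rna):
        if n_individuals > int(table.sample_totals().min()):
            raise ValidationError("n_individuals exceeds the smallest sample total")
    for frac_seed, table in zip(ss.spawn(2), (table_dna, table_rna)):
        lakes = table.lakes().to_numpy()
        r_values = []
        for draw_seed in frac_seed.spawn(n_draws):
            s_raref, s_rc, s_an, s_nm = (
                int(s.generate_state(1)[0] % 2**31) for s in draw_seed.spawn(4)
            )
            rng = np.random.default_rng(s_raref)
            rows = [rarefy(r, n_individuals, rng) for r in table.matrix()]
            sub = OtuTable(
                pd.DataFrame(rows, index=table.sample_ids, columns=table.otu_ids),
                fraction=table.fraction,
                metadata=table.metadata,
            )
            dist = raup_crick(sub, n_reps=rc_reps, seed=s_rc)
            if with_ordination:
                nmds(dist, k=2, n_restarts=nmds_restarts, seed=s_nm)
            r, _ = anosim(dist, lakes, n_perm=199, seed=s_an)
            r_values.append(r)
        results.append(
            {
                "fraction": table.fraction,
                "mean_R": float(np.mean(r_values)),
                "sd_R": float(np.std(r_values, ddof=1)) if n_draws > 1 else 0.0,
                "n_draws": n_draws,
            }
        )
    return pd.DataFrame(results).set_index("fraction")


def rank_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances sorted by decreasing rank."""
    rel = table.relative_abundance().to_numpy()
    ranked = -np.sort(-rel, axis=1)
    return pd.DataFrame(
        ranked,
        index=table.sample_ids,
        columns=[f"rank_{i + 1}" for i in range(table.n_otus)],
    )


def rna_dna_group_ratio(
    table_dna: OtuTable,
    table_rna: OtuTable,
    taxonomy: Taxonomy,
    group_rank: str = "group",
) -> pd.Series:
    """Mean-over-lakes rRNA:rDNA relative-abundance ratio per taxon group.

    Lakes where the group has zero rDNA abundance are excluded (the ratio
    is undefined there, not infinite); a group undefined in every lake
    comes back as NaN.
    """
    groups = taxonomy.groups(group_rank)
    out = {}
    frames = {}
    for tab in (table_dna, table_rna):
        missing = sorted(set(tab.otu_ids) - set(groups.index))
        if missing:
            raise ValidationError(f"OTUs absent from taxonomy: {missing[:10]}")
        pooled = tab.pooled_by_lake()
        rel = pooled.div(pooled.sum(axis=1), axis=0)
        grouped = rel.T.groupby(groups.reindex(rel.columns)).sum().T
        frames[tab.fraction] = grouped
    dna, rna = frames["rDNA"], frames["rRNA"]
    all_groups = sorted(set(dna.columns) | set(rna.columns))
    for g in all_groups:
        d = dna.get(g)
        r = rna.get(g, pd.Series(0.0, index=dna.index))
        if d is None:
            out[g] = np.nan
            continue
        valid = d > 0
        out[g] = float((r[valid] / d[valid]).mean()) if valid.any() else np.nan
    return pd.Series(out, name="rna_dna_ratio")
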