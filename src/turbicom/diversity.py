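"""Rarefaction and alpha-diversity estimators.

Estimators follow the standard forms: bias-corrected Chao-1
(S_obs + F1(F1-1)/(2(F2+1))), inverse Simpson (1/sum p_i^2), bootstrap
richness (S_obs + sum (1-p_i)^N) and rooted Faith's PD (branch length of
the minimal subtree spanning the present tips and the root). Rarefaction
is an exact multivariate-hypergeometric subsample (without replacement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datamodel import OtuTable, ValidationError, check_tree_covers


def _as_counts(x) -> np.ndarray:
    arr = np.asarray(x)
    flt = arr.astype(float)
    if np.any(flt < 0) or np.any(flt != np.floor(flt)):
        raise ValidationError("counts must be non-negative integers")
    return arr.astype(np.int64)


def rarefy(sample_counts, depth: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Subsample a count vector without replacement to exactly ``depth``."""
    counts = _as_counts(sample_counts)
    total = int(counts.sum())
    if depth > total:
        raise ValidationError(f"rarefaction depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_table(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """One fixed rarefaction draw per sample (the multivariate workflow)."""
    rng = np.random.default_rng(seed)
    rows = [rarefy(row, depth, rng) for row in table.matrix()]
    counts = pd.DataFrame(rows, index=table.sample_ids, columns=table.otu_ids)
    return OtuTable(counts, fraction=table.fraction, metadata=table.metadata)


def chao1(sample_counts) -> float:
    """Bias-corrected Chao-1 richness estimate."""
    counts = _as_counts(sample_counts)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValidationError("Chao-1 needs at least one positive count")
    s_obs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def inverse_simpson(sample_counts) -> float:
    counts = _as_counts(sample_counts)
    total = counts.sum()
    if total == 0:
        raise ValidationError("inverse Simpson undefined for an empty sample")
    p = counts / total
    return float(1.0 / np.sum(p**2))


def bootstrap_richness(sample_counts) -> float:
    """S_obs plus the bootstrap correction sum_i (1 - p_i)^N."""
    counts = _as_counts(sample_counts)
    total = counts.sum()
    if total == 0:
        raise ValidationError("bootstrap richness undefined for an empty sample")
    counts = counts[counts > 0]
    p = counts / total
    return float(counts.size + np.sum((1.0 - p) ** total))


def faith_pd(tree: TreeNode, present_otus) -> float:
    """Rooted Faith's PD: branch length of the minimal spanning subtree."""
    present = set(present_otus)
    if not present:
        raise ValidationError("Faith's PD needs a non-empty community")
    check_tree_covers(tree, present)
    total = 0.0
    # postorder: a branch contributes iff its subtree holds a present tip
    has: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            has[id(node)] = node.name in present
        else:
            has[id(node)] = any(has[id(c)] for c in node.children)
        if node.parent is not None and has[id(node)] and node.length:
            total += node.length
    return float(total)


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    richness_boot: float
    chao1: float
    inv_simpson: float
    faith_pd: float
    rarefaction_depth: int
    n_draws: int


def rarefaction_curve(
    sample_counts, depths, n_draws: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean/sd of observed richness over ``n_draws`` rarefactions per depth."""
    depths = list(depths)
    if depths != sorted(depths):
        raise ValidationError("depths must be sorted ascending")
    rng = np.random.default_rng(seed)
    counts = _as_counts(sample_counts)
    rows = []
    for depth in depths:
        rich = [
            int(np.count_nonzero(rarefy(counts, depth, rng))) for _ in range(n_draws)
        ]
        rows.append((depth, float(np.mean(rich)), float(np.std(rich, ddof=0))))
    return pd.DataFrame(rows, columns=["depth", "mean_richness", "sd_richness"])


def alpha_diversity_table(
    table: OtuTable,
    tree: TreeNode | None,
    depth: int,
    n_draws: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Alpha-diversity estimates per sample, averaged over rarefaction draws."""
    check_tree_covers(tree, table.otu_ids) if tree is not None else None
    rng = np.random.default_rng(seed)
    otus = np.asarray(table.otu_ids)
    records = []
    for sid, row in zip(table.sample_ids, table.matrix()):
        vals = np.zeros((n_draws, 4))
        for d in range(n_draws):
            sub = rarefy(row, depth, rng)
            vals[d, 0] = bootstrap_richness(sub)
            vals[d, 1] = chao1(sub)
            vals[d, 2] = inverse_simpson(sub)
            vals[d, 3] = (
                faith_pd(tree, otus[sub > 0]) if tree is not None else np.nan
            )
        mean = vals.mean(axis=0)
        records.append(
            AlphaDiversityRecord(
                sample_id=sid,
                richness_boot=float(mean[0]),
                chao1=float(mean[1]),
                inv_simpson=float(mean[2]),
                faith_pd=float(mean[3]),
                rarefaction_depth=depth,
                n_draws=n_draws,
            )
        )
    return pd.DataFrame([r.__dict__ for r in records]).set_index("sample_id")
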