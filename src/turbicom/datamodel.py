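"""Shared domain types for turbidity-gradient community analysis.

The central container is :class:`OtuTable`, a samples-by-OTUs matrix of
non-negative integer counts with an attached nucleic-acid fraction label
(rDNA for the bulk community, rRNA for the putatively active one) and
optional per-sample metadata (lake, replicate, environmental variables).
Phylogenies are scikit-bio ``TreeNode`` objects and pairwise sample
dissimilarities are scikit-bio ``DistanceMatrix`` objects; this module adds
the validation both need before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

FRACTIONS = ("rDNA", "rRNA")

#: Metadata columns expected by gradient-aware stages. ``lake`` and
#: ``replicate`` are required; the numeric columns mirror the standard
#: limnological background variables (turbidity in NTU, temperature in deg C,
#: total phosphorus in ug/l, total nitrogen in mg/l, DOC in mg/l and the
#: dimensionless absorbance slope ratio).
METADATA_NUMERIC = ("turbidity", "temperature", "tp", "tn", "doc", "s_r")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected dialect."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes}")


class OtuTable:
    """Samples x OTUs count matrix for one nucleic-acid fraction.

    Parameters
    ----------
    counts:
        DataFrame with sample ids as the index and OTU ids as columns.
        Values must be non-negative integers. All-zero OTU columns are
        dropped at construction (every downstream null model assumes
        observable taxa); the number dropped is logged.
    fraction:
        ``"rDNA"`` or ``"rRNA"``.
    metadata:
        Optional DataFrame indexed by sample id with at least ``lake`` and
        ``replicate`` columns.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        fraction: str = "rDNA",
        metadata: pd.DataFrame | None = None,
    ) -> None:
        if fraction not in FRACTIONS:
            raise ValidationError(f"fraction must be one of {FRACTIONS}, got {fraction!r}")
        if not isinstance(counts, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame (samples x OTUs)")
        _check_unique(counts.index.astype(str), "sample ids")
        _check_unique(counts.columns.astype(str), "OTU ids")

        arr = counts.to_numpy()
        if arr.size == 0:
            raise ValidationError("count table is empty")
        if not np.all(np.isfinite(arr.astype(float))):
            raise ValidationError("count table contains non-finite values")
        flt = arr.astype(float)
        if np.any(flt < 0) or np.any(flt != np.floor(flt)):
            bad = np.argwhere((flt < 0) | (flt != np.floor(flt)))[0]
            raise ValidationError(
                "counts must be non-negative integers; offending cell at "
                f"sample {counts.index[bad[0]]!r}, OTU {counts.columns[bad[1]]!r}"
            )
        counts = counts.astype(np.int64)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)

        zero = counts.columns[(counts.to_numpy() == 0).all(axis=0)]
        if len(zero):
            logger.info("dropping %d all-zero OTU columns", len(zero))
            counts = counts.drop(columns=zero)
        if counts.shape[1] == 0:
            raise ValidationError("count table has no non-zero OTUs")

        if metadata is not None:
            metadata = metadata.copy()
            metadata.index = metadata.index.astype(str)
            missing = set(counts.index) - set(metadata.index)
            if missing:
                raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
            metadata = metadata.loc[counts.index]
        self.counts = counts
        self.fraction = fraction
        self.metadata = metadata

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Sample-wise relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            zero = totals.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total count: {zero}")
        return self.counts.div(totals, axis=0)

    # -- derived tables ----------------------------------------------------
    def subset_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        keep = [o for o in otu_ids if o in self.counts.columns]
        sub = self.counts[keep]
        nonempty = sub.sum(axis=1) > 0
        if not nonempty.all():
            dropped = sub.index[~nonempty].tolist()
            logger.warning("dropping samples with no OTUs left in subset: %s", dropped)
        sub = sub.loc[nonempty]
        meta = self.metadata.loc[sub.index] if self.metadata is not None else None
        return OtuTable(sub, fraction=self.fraction, metadata=meta)

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        sub = self.counts.loc[list(sample_ids)]
        meta = self.metadata.loc[sub.index] if self.metadata is not None else None
        return OtuTable(sub, fraction=self.fraction, metadata=meta)

    def lakes(self) -> pd.Series:
        if self.metadata is None or "lake" not in self.metadata:
            raise ValidationError("table has no 'lake' metadata")
        return self.metadata["lake"].astype(str)

    def pooled_by_lake(self) -> pd.DataFrame:
        """Replicates summed per lake -> lakes x OTUs count matrix."""
        return self.counts.groupby(self.lakes()).sum()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs, "
            f"fraction={self.fraction})"
        )


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table (one record per lake/replicate)."""
    for col in ("lake", "replicate"):
        if col not in metadata.columns:
            raise ValidationError(f"metadata missing required column {col!r}")
    if metadata.duplicated(subset=["lake", "replicate"]).any():
        raise ValidationError("metadata has duplicate (lake, replicate) records")
    if "turbidity" in metadata and (metadata["turbidity"].astype(float) < 0).any():
        raise ValidationError("turbidity must be >= 0 NTU")
    if "s_r" in metadata and (metadata["s_r"].astype(float) <= 0).any():
        raise ValidationError("s_r must be > 0")
    return metadata


def validate_tree(tree: TreeNode) -> TreeNode:
    """Check tip-label uniqueness and non-negative branch lengths."""
    tips = [t.name for t in tree.tips()]
    if any(n is None for n in tips):
        raise ValidationError("tree has unnamed tips")
    _check_unique(tips, "tree tip labels")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    return tree


def check_tree_covers(tree: TreeNode, otu_ids: Iterable[str]) -> None:
    """Ensure the tree's tip set covers every OTU of a table."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(otu_ids) - tips)
    if missing:
        raise ValidationError(f"OTUs missing from the tree: {missing[:10]}")


@dataclass
class Taxonomy:
    """OTU -> ranked lineage map plus a single group label for summaries."""

    lineages: pd.DataFrame  # index = OTU id, columns = ranks (+ 'group')

    RANKS = ("phylum", "class", "order", "family", "genus")

    def __post_init__(self) -> None:
        self.lineages.index = self.lineages.index.astype(str)
        _check_unique(self.lineages.index, "taxonomy OTU ids")
        known = self.lineages.reindex(columns=[c for c in self.lineages.columns])
        nonempty = known.notna() & (known.astype(str) != "")
        if not nonempty.any(axis=1).all():
            bad = self.lineages.index[~nonempty.any(axis=1)].tolist()
            raise ValidationError(
                f"OTUs with entirely empty lineages (use 'unclassified'): {bad[:10]}"
            )

    def group_of(self, otu_id: str, rank: str = "group") -> str:
        if otu_id not in self.lineages.index:
            raise ValidationError(f"OTU {otu_id!r} absent from taxonomy")
        if rank not in self.lineages.columns:
            raise ValidationError(f"rank {rank!r} absent from taxonomy")
        val = self.lineages.at[otu_id, rank]
        return str(val) if pd.notna(val) and str(val) else "unclassified"

    def groups(self, rank: str = "group") -> pd.Series:
        if rank not in self.lineages.columns:
            raise ValidationError(f"rank {rank!r} absent from taxonomy")
        ser = self.lineages[rank].astype(str)
        return ser.where(ser != "", "unclassified")


@dataclass
class CooccurrenceNetwork:
    """Signed OTU-OTU association network from ensemble inference.

    ``edges`` columns: otu_a, otu_b (canonical order otu_a < otu_b), sign
    ("co-presence"/"mutual-exclusion"), n_supporting_metrics,
    supporting_metrics (comma-joined), merged_p, q_value.
    """

    edges: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    EDGE_COLUMNS = (
        "otu_a",
        "otu_b",
        "sign",
        "n_supporting_metrics",
        "supporting_metrics",
        "merged_p",
        "q_value",
    )

    def __post_init__(self) -> None:
        missing = set(self.EDGE_COLUMNS) - set(self.edges.columns)
        if missing:
            raise ValidationError(f"edge table missing columns: {sorted(missing)}")
        e = self.edges
        if len(e):
            if (e["otu_a"] >= e["otu_b"]).any():
                raise ValidationError("edges must be canonically ordered otu_a < otu_b")
            if (e["n_supporting_metrics"] < 2).any():
                raise ValidationError("every edge needs >= 2 supporting metrics")
            if not e["sign"].isin(["co-presence", "mutual-exclusion"]).all():
                raise ValidationError("unknown edge sign")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes(self) -> list[str]:
        if not len(self.edges):
            return []
        return sorted(set(self.edges["otu_a"]) | set(self.edges["otu_b"]))

    def degrees(self) -> pd.Series:
        both = pd.concat([self.edges["otu_a"], self.edges["otu_b"]])
        return both.value_counts().sort_index()


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered OTU pair; rejects self-pairs."""
    if a == b:
        raise ValidationError(f"self-association {a!r} is not a valid edge")
    return (a, b) if a < b else (b, a)
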