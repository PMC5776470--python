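"""Readers and writers for the plain-text formats used by the pipeline.

Count tables come either as plain TSV (sample ids in the first column, OTU
ids in the header) or in the mothur "shared" dialect (leading label/Group/
numOtus columns, one row per sample); both are normalized to the internal
samples-as-rows orientation on read. Trees are newick via scikit-bio.
Edge lists go out as TSV or GraphML (via networkx). All writers emit UTF-8
with LF line endings and '.' decimal separators.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd
from skbio import TreeNode

from .datamodel import (
    CooccurrenceNetwork,
    FormatError,
    OtuTable,
    Taxonomy,
    ValidationError,
    validate_metadata,
    validate_tree,
)

logger = logging.getLogger(__name__)

_SHARED_LEAD = ["label", "Group", "numOtus"]


def read_otu_table(
    path: str | Path,
    fraction: str = "rDNA",
    metadata: pd.DataFrame | None = None,
) -> OtuTable:
    """Read a count table (plain TSV or mothur shared dialect)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a tab-separated table with >=2 columns")

    cols = list(df.columns)
    if cols[:3] == _SHARED_LEAD:
        # mothur shared: label, Group, numOtus, then one column per OTU
        df = df.set_index("Group").drop(columns=["label", "numOtus"])
    else:
        df = df.set_index(cols[0])
    try:
        counts = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric cell in count table: {exc}") from exc
    return OtuTable(counts, fraction=fraction, metadata=metadata)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.counts.to_csv(Path(path), sep="\t", index_label="sample")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(Path(path), sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return validate_metadata(meta)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(Path(path), sep="\t", index_label="sample")


def read_newick(path: str | Path) -> TreeNode:
    """Read one rooted, branch-length-bearing newick tree."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"cannot parse newick file {path}: {exc}") from exc
    return validate_tree(tree)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read an OTU taxonomy TSV.

    Two layouts are accepted: rank columns (otu, phylum, class, ..., group)
    or a two-column ``OTU<tab>k__...;p__...`` lineage string, which is split
    on ';' into ranks. A ``group`` column is synthesized from the first
    informative rank when absent.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: taxonomy needs >=2 columns")
    df = df.set_index(df.columns[0])
    if df.shape[1] == 1:
        ranks = list(Taxonomy.RANKS)
        parts = df.iloc[:, 0].str.split(";", expand=True)
        parts = parts.iloc[:, : len(ranks)]
        parts.columns = ranks[: parts.shape[1]]
        parts = parts.apply(lambda s: s.str.replace(r"^[a-z]__", "", regex=True).str.strip())
        df = parts
    if "group" not in df.columns:
        first = df.apply(
            lambda row: next((v for v in row if pd.notna(v) and str(v)), "unclassified"),
            axis=1,
        )
        df = df.assign(group=first)
    df = df.fillna("unclassified").replace("", "unclassified")
    return Taxonomy(df)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    taxonomy.lineages.to_csv(Path(path), sep="\t", index_label="otu")


# -- edge lists ------------------------------------------------------------

def write_edge_list(
    network: CooccurrenceNetwork, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        network.edges.loc[:, list(CooccurrenceNetwork.EDGE_COLUMNS)].to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        g = nx.Graph()
        for key, val in network.provenance.items():
            g.graph[str(key)] = str(val)
        for _, row in network.edges.iterrows():
            g.add_edge(
                row["otu_a"],
                row["otu_b"],
                sign=row["sign"],
                n_supporting_metrics=int(row["n_supporting_metrics"]),
                supporting_metrics=row["supporting_metrics"],
                merged_p=float(row["merged_p"]),
                q_value=float(row["q_value"]),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown edge-list format {format!r}")


def read_edge_list(path: str | Path, format: str = "tsv") -> CooccurrenceNetwork:
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"otu_a": str, "otu_b": str})
        if df.empty:
            df = pd.DataFrame(columns=list(CooccurrenceNetwork.EDGE_COLUMNS))
        return CooccurrenceNetwork(df)
    if format == "graphml":
        g = nx.read_graphml(path)
        rows = [
            {
                "otu_a": min(u, v),
                "otu_b": max(u, v),
                "sign": d["sign"],
                "n_supporting_metrics": int(d["n_supporting_metrics"]),
                "supporting_metrics": d["supporting_metrics"],
                "merged_p": float(d["merged_p"]),
                "q_value": float(d["q_value"]),
            }
            for u, v, d in g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=list(CooccurrenceNetwork.EDGE_COLUMNS))
        return CooccurrenceNetwork(df)
    raise ValueError(f"unknown edge-list format {format!r}")
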