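"""Readers, writers and the shared tabular data model.

The pipeline's native formats are plain text: tab-separated tables for
counts, taxonomy, metadata, distance matrices and network edge lists;
Newick for the phylogeny; GraphML (via networkx) for network export; JSON
for configuration and ground truth.  Count tables are oriented samples ×
ASVs, matching the metadata orientation.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("gutstruct")

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
_RANK_PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__", "s__"]


class ParseError(ValueError):
    """Malformed input file; the message locates the offending row/column."""


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path, min_reads: int = 10_000) -> pd.DataFrame:
    """Read a samples × ASVs count TSV and drop shallow samples.

    The header row holds ASV ids, the first column sample ids.  Samples
    with more than ``min_reads`` total reads are kept (a sample with
    exactly ``min_reads`` is dropped); the number of dropped samples is
    logged.  Pass ``min_reads=0`` to keep everything.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty count table")
    header = text.splitlines()[0].rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ParseError(f"{path}: duplicate ASV id {dup!r}")
    df = pd.read_csv(StringIO(text), sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()].index[0]
            raise ParseError(f"{path}: non-numeric count at sample {bad!r}, ASV {col!r}")
        if not np.allclose(vals, np.round(vals)) or (vals < 0).any():
            bad = vals.index[(vals != np.round(vals)) | (vals < 0)][0]
            raise ParseError(f"{path}: non-integer or negative count at sample {bad!r}, ASV {col!r}")
    counts = df.astype(np.int64)
    counts.index.name = None
    counts.columns.name = None
    totals = counts.sum(axis=1)
    keep = totals > min_reads
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_count_table: dropped %d/%d samples with <= %d reads",
                    n_dropped, len(counts), min_reads)
    return counts.loc[keep]


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# taxonomy


def parse_greengenes(lineage: str) -> dict:
    """Split a Greengenes-style lineage string into rank → label.

    Empty rank fields (``s__`` with nothing after it) are unassigned and
    omitted from the result.
    """
    out = {}
    for token in str(lineage).split(";"):
        token = token.strip()
        for rank, prefix in zip(RANKS, _RANK_PREFIXES):
            if token.startswith(prefix):
                label = token[len(prefix):].strip()
                if label:
                    out[rank] = label
    return out


def read_taxonomy(path) -> pd.DataFrame:
    """Read a two-column (asv_id, lineage) or pre-split per-rank TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate ASV id {dup!r} in taxonomy")
    df.index.name = None
    if "taxonomy" in df.columns:
        ranks = pd.DataFrame(
            [parse_greengenes(s) for s in df["taxonomy"]], index=df.index
        ).reindex(columns=RANKS)
        return ranks
    return df.reindex(columns=[c for c in RANKS if c in df.columns] +
                      [c for c in df.columns if c not in RANKS])


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t", index_label="asv_id")


def lowest_assigned(tax_row: pd.Series) -> str:
    """Lowest (most specific) assigned rank label of one ASV."""
    for rank in reversed(RANKS):
        val = tax_row.get(rank)
        if isinstance(val, str) and val:
            return val
    return "Unassigned"


def assign_display_names(counts: pd.DataFrame, tax: pd.DataFrame) -> pd.DataFrame:
    """Name each ASV "<lowest assigned taxon> ASV <rank>".

    The rank orders ASVs sharing the same lowest-assigned label by
    descending total read count; equal totals fall back to lexicographic
    ASV id.  Returns a copy of ``tax`` with ``display_name`` (and a
    ``lowest_taxon`` convenience column) added.
    """
    missing = counts.columns.difference(tax.index)
    if len(missing):
        raise KeyError(f"taxonomy missing ASVs: {list(missing[:5])}")
    tax = tax.loc[counts.columns].copy()
    tax["lowest_taxon"] = [lowest_assigned(tax.loc[a]) for a in tax.index]
    totals = counts.sum(axis=0)
    order = pd.DataFrame({
        "label": tax["lowest_taxon"],
        "total": totals.reindex(tax.index),
        "asv": tax.index,
    })
    order = order.sort_values(["label", "total", "asv"],
                              ascending=[True, False, True])
    rank_within = order.groupby("label").cumcount() + 1
    names = order["label"] + " ASV " + rank_within.astype(str)
    tax["display_name"] = names.reindex(tax.index)
    return tax


# ---------------------------------------------------------------------------
# metadata, distance matrices, trees


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r} in metadata")
    df.index.name = None
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: distance matrix row/column labels differ")
    arr = df.to_numpy(float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ParseError(f"{path}: distance matrix is not symmetric")
    df.index.name = None
    df.columns.name = None
    return df


def write_distance_matrix(d: pd.DataFrame, path) -> None:
    d.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ParseError(f"{path}: negative branch length on {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# network export

EDGE_COLUMNS = ["asv_a", "asv_b", "n_both", "fisher_p", "fisher_q",
                "rho", "rho_p", "rho_q"]


def export_network(network, clusters, path, format: str = "graphml") -> None:
    """Write an association network for external viewers.

    ``format`` is ``"graphml"`` or ``"edgelist"`` (TSV).  Nodes carry
    prevalence, total count, phylum and cluster id; edges carry the test
    statistics.  ``clusters`` may be None.
    """
    cluster_of = {}
    for c in clusters or []:
        for asv in c.members:
            cluster_of[asv] = c.cluster_id
    if format == "graphml":
        g = nx.Graph()
        for asv, attrs in network.nodes.iterrows():
            g.add_node(asv,
                       prevalence=float(attrs["prevalence"]),
                       total_count=int(attrs["total_count"]),
                       phylum=str(attrs["phylum"]),
                       cluster=str(cluster_of.get(asv, "")))
        for _, e in network.edges.iterrows():
            g.add_edge(e["asv_a"], e["asv_b"],
                       rho=float(e["rho"]), rho_q=float(e["rho_q"]),
                       fisher_q=float(e["fisher_q"]))
        nx.write_graphml(g, str(path))
    elif format == "edgelist":
        network.edges.reindex(columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
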