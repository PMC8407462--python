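"""Dual-criterion ASV association network and microbial clusters.

An edge between two ASVs requires both (i) significant cooccurrence —
Fisher's exact test on the 2x2 presence/absence table, BH FDR < 1e-6,
with the two ASVs found together *more* often than independence predicts
— and (ii) significant positive quantitative association — Spearman
correlation of log-transformed nonzero relative abundances on the
samples carrying both ASVs, BH FDR < 1e-3.  Only ASVs present in at
least 10% of samples are tested.  Clusters are extracted by merging
connected 3-cliques, splitting merged groups by phylum, re-attaching
same-taxon neighbors, and naming each cluster after its most abundant
member.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import prevalence, relative_abundance
from .io import lowest_assigned

logger = logging.getLogger("gutstruct")


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up q-values and rejection flags.

    Rejection is ``q < alpha`` (strict), matching the "FDR < threshold"
    convention used throughout.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < alpha


def prevalence_filter(counts: pd.DataFrame, min_prev: float = 0.10) -> list:
    """ASVs observed in at least ``min_prev`` of samples (>= comparison)."""
    if not 0 < min_prev <= 1:
        raise ValueError("min_prev must be in (0, 1]")
    prev = prevalence(counts)
    return list(prev.index[prev >= min_prev])


def cooccurrence_test(presence_a, presence_b):
    """Fisher's exact test on joint presence/absence of two ASVs.

    Returns (table, p, direction) where ``table`` is
    [[n_both, n_a_only], [n_b_only, n_neither]] and ``direction`` is +1
    when n_both exceeds its expectation under independence, else -1.
    A zero-variance vector (ASV always or never present) carries no
    cooccurrence information: p = 1.
    """
    a = np.asarray(presence_a, bool)
    b = np.asarray(presence_b, bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors must have equal length")
    n = len(a)
    n_both = int(np.sum(a & b))
    n_a_only = int(np.sum(a & ~b))
    n_b_only = int(np.sum(~a & b))
    n_neither = n - n_both - n_a_only - n_b_only
    table = np.array([[n_both, n_a_only], [n_b_only, n_neither]])
    expected_both = (n_both + n_a_only) * (n_both + n_b_only) / n
    direction = 1 if n_both > expected_both else -1
    if a.all() or (~a).all() or b.all() or (~b).all():
        return table, 1.0, direction
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return table, p, direction


def quantitative_test(log_abund_a, log_abund_b, min_overlap: int = 10):
    """Spearman correlation on the shared-presence samples.

    Inputs are per-sample log abundances with NaN marking absence; only
    samples where both are finite enter.  Returns (rho, p, n_overlap),
    or None when the overlap is below ``min_overlap`` or the ranks are
    constant (rho undefined).
    """
    a = np.asarray(log_abund_a, float)
    b = np.asarray(log_abund_b, float)
    mask = np.isfinite(a) & np.isfinite(b)
    n_overlap = int(mask.sum())
    if n_overlap < min_overlap:
        return None
    x, y = a[mask], b[mask]
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.debug("quantitative_test: constant ranks on overlap; pair excluded")
        return None
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n_overlap


@dataclass
class AssociationNetwork:
    nodes: pd.DataFrame        # index asv; prevalence, total_count, phylum
    edges: pd.DataFrame        # asv_a, asv_b, n_both, fisher_p/q, rho, rho_p/q
    pair_tests: pd.DataFrame   # every tested pair with both families' stats
    n_cooccurrence_hits: int = 0
    n_quantitative_hits: int = 0

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.index)
        g.add_edges_from(zip(self.edges["asv_a"], self.edges["asv_b"]))
        return g


@dataclass
class MicrobialCluster:
    cluster_id: int
    members: list
    phylum: str
    name: str
    attached: list = field(default_factory=list)  # joined by the same-taxon rule


def _log_nonzero_abundance(counts: pd.DataFrame, asvs) -> pd.DataFrame:
    """Natural log of relative abundance, NaN where the ASV is absent."""
    rel = relative_abundance(counts)[list(asvs)]
    with np.errstate(divide="ignore"):
        return np.log(rel.where(rel > 0))


def build_network(counts: pd.DataFrame, tax: pd.DataFrame,
                  fdr_cooc: float = 1e-6, fdr_quant: float = 1e-3,
                  min_prev: float = 0.10, min_overlap: int = 10,
                  criterion: str = "intersection") -> AssociationNetwork:
    """Test all eligible ASV pairs and keep the dual-criterion edges.

    BH correction is applied separately within the cooccurrence family
    (all tested pairs) and the quantitative family (pairs with enough
    overlap).  ``criterion`` "intersection" (default) requires both
    tests; "union" accepts either (positive direction/rho still
    required).  Per-criterion hit counts are kept for reporting.
    """
    asvs = prevalence_filter(counts, min_prev)
    if len(asvs) < 2:
        raise ValueError("fewer than 2 ASVs pass the prevalence filter")
    presence = counts[asvs].to_numpy() > 0
    logab = _log_nonzero_abundance(counts, asvs).to_numpy()
    pairs = list(itertools.combinations(range(len(asvs)), 2))

    records = []
    for i, j in pairs:
        table, fp, direction = cooccurrence_test(presence[:, i], presence[:, j])
        quant = quantitative_test(logab[:, i], logab[:, j], min_overlap)
        rho, rp, n_ov = quant if quant is not None else (np.nan, np.nan, int((presence[:, i] & presence[:, j]).sum()))
        records.append((asvs[i], asvs[j], table[0, 0], fp, direction, rho, rp, n_ov))
    tests = pd.DataFrame(records, columns=["asv_a", "asv_b", "n_both", "fisher_p",
                                           "direction", "rho", "rho_p", "n_overlap"])

    tests["fisher_q"], _ = bh_fdr(tests["fisher_p"].to_numpy(), fdr_cooc)
    quant_mask = tests["rho_p"].notna().to_numpy()
    rho_q = np.full(len(tests), np.nan)
    if quant_mask.any():
        rho_q[quant_mask], _ = bh_fdr(tests.loc[quant_mask, "rho_p"].to_numpy(), fdr_quant)
    tests["rho_q"] = rho_q

    cooc_hit = (tests["fisher_q"] < fdr_cooc) & (tests["direction"] > 0)
    quant_hit = (tests["rho_q"] < fdr_quant) & (tests["rho"] > 0)
    if criterion == "intersection":
        keep = cooc_hit & quant_hit
    elif criterion == "union":
        keep = cooc_hit | quant_hit
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    edges = tests.loc[keep].reset_index(drop=True)

    tax_sub = tax.loc[asvs]
    nodes = pd.DataFrame({
        "prevalence": prevalence(counts)[asvs],
        "total_count": counts[asvs].sum(axis=0),
        "phylum": tax_sub["phylum"].fillna("Unassigned"),
    })
    logger.info("build_network: %d nodes, %d edges (%d cooccurrence, %d quantitative hits)",
                len(nodes), len(edges), int(cooc_hit.sum()), int(quant_hit.sum()))
    return AssociationNetwork(nodes=nodes, edges=edges, pair_tests=tests,
                              n_cooccurrence_hits=int(cooc_hit.sum()),
                              n_quantitative_hits=int(quant_hit.sum()))


def find_clusters(net: AssociationNetwork, tax: pd.DataFrame,
                  min_size: int = 3) -> list:
    """Extract named microbial clusters from the association network.

    1. enumerate 3-cliques; 2. merge cliques sharing a node; 3. split
    each merged group into phylum-consistent connected components;
    4. attach remaining network nodes adjacent to a member and carrying
    the member's lowest-taxon label; 5. name each cluster by the display
    taxon of its highest-total-count member; drop clusters smaller than
    ``min_size``.
    """
    g = net.graph()
    # edges that sit in at least one triangle; two 3-cliques sharing a node
    # are connected through it, so merged groups = connected components of
    # the triangle-edge subgraph
    tri_edges = [(u, v) for u, v in g.edges
                 if not set(g[u]).isdisjoint(g[v])]
    if not tri_edges:
        return []
    tri_graph = nx.Graph(tri_edges)
    groups = [sorted(comp) for comp in nx.connected_components(tri_graph)]

    phylum = tax["phylum"].fillna("Unassigned")
    lowest = pd.Series({a: lowest_assigned(tax.loc[a]) for a in tax.index})
    totals = net.nodes["total_count"]
    display = tax["display_name"] if "display_name" in tax.columns else lowest

    clusters = []
    in_cluster: set = set()
    for members in groups:
        # split into phylum-consistent connected components
        for ph in sorted(set(phylum[m] for m in members)):
            sub = g.subgraph([m for m in members if phylum[m] == ph])
            for comp in nx.connected_components(sub):
                clusters.append((sorted(comp), ph))
                in_cluster.update(comp)
    # attach same-taxon neighbors not already in a cluster
    final = []
    attached_all: set = set()
    for cid, (members, ph) in enumerate(sorted(clusters, key=lambda c: c[0])):
        attached = []
        for m in members:
            for nb in g.neighbors(m):
                if nb in in_cluster or nb in attached_all or nb in attached:
                    continue
                if lowest[nb] == lowest[m]:
                    attached.append(nb)
        attached_all.update(attached)
        full = members + sorted(attached)
        if len(full) < min_size:
            continue
        top = max(full, key=lambda a: (totals[a], a))
        final.append(MicrobialCluster(cluster_id=len(final), members=full,
                                      phylum=ph, name=str(display[top]),
                                      attached=sorted(attached)))
    return final


def negative_associations(counts: pd.DataFrame, fdr: float = 1e-3,
                          min_prev: float = 0.10,
                          min_overlap: int = 10) -> pd.DataFrame:
    """Quantitatively *negatively* associated ASV pairs (rho < 0, BH
    within the negative family).  Reported separately from the network;
    never part of clusters."""
    asvs = prevalence_filter(counts, min_prev)
    logab = _log_nonzero_abundance(counts, asvs).to_numpy()
    records = []
    for i, j in itertools.combinations(range(len(asvs)), 2):
        quant = quantitative_test(logab[:, i], logab[:, j], min_overlap)
        if quant is None:
            continue
        rho, p, n_ov = quant
        if rho < 0:
            records.append((asvs[i], asvs[j], rho, p, n_ov))
    neg = pd.DataFrame(records, columns=["asv_a", "asv_b", "rho", "rho_p", "n_overlap"])
    if len(neg):
        neg["rho_q"], reject = bh_fdr(neg["rho_p"].to_numpy(), fdr)
        neg = neg.loc[reject].reset_index(drop=True)
    else:
        neg["rho_q"] = []
    return neg


def write_clusters(clusters, path) -> None:
    rows = [(c.cluster_id, m, c.phylum, c.name, m in c.attached)
            for c in clusters for m in c.members]
    pd.DataFrame(rows, columns=["cluster", "member", "phylum", "name", "attached"]
                 ).to_csv(path, sep="\t", index=False)
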