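"""Community-level summaries: abundance, prevalence, richness, weighted
UniFrac, principal-coordinate analysis and age-window smoothing.

Weighted UniFrac is the unnormalized form: for two communities A and B it
sums, over every branch b of a rooted tree, ``length(b) * |P_A(b) - P_B(b)|``
where ``P_X(b)`` is the fraction of community X's total mass carried by
leaves descending from b.  No rarefaction is performed; distances are
computed on full relative abundances.

PCoA is classical scaling: double-center -D^2/2, eigendecompose, keep
axes with positive eigenvalues in descending order.  Negative eigenvalues
are reported but their axes are dropped (no Cailliez correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, cdist, squareform
from skbio import TreeNode

from .io import RANKS


def relative_abundance(counts: pd.DataFrame, tax: pd.DataFrame | None = None,
                       level: str = "asv") -> pd.DataFrame:
    """Per-sample relative abundances, optionally aggregated to a rank.

    Aggregation sums counts within each taxon of ``level`` first, then
    divides by the sample total, so rows always sum to 1.  ASVs
    unassigned at ``level`` are pooled under "Unassigned".
    """
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total reads")
    if level == "asv":
        agg = counts
    else:
        if level not in RANKS:
            raise ValueError(f"unknown taxonomic level {level!r}")
        if tax is None:
            raise ValueError("taxonomy required for non-ASV levels")
        labels = tax.loc[counts.columns, level].fillna("Unassigned")
        agg = counts.T.groupby(labels.values).sum().T
    return agg.div(totals, axis=0)


def prevalence(counts: pd.DataFrame, tax: pd.DataFrame | None = None,
               level: str = "asv") -> pd.Series:
    """Fraction of samples in which each taxon has nonzero reads.

    At aggregated levels a taxon is present in a sample when any member
    ASV is (the union rule; equivalent to a nonzero aggregated count).
    """
    if level == "asv":
        agg = counts
    else:
        if tax is None:
            raise ValueError("taxonomy required for non-ASV levels")
        labels = tax.loc[counts.columns, level].fillna("Unassigned")
        agg = counts.T.groupby(labels.values).sum().T
    return (agg > 0).mean(axis=0)


def observed_richness(counts: pd.DataFrame) -> pd.Series:
    """Number of ASVs with nonzero reads per sample (the alpha diversity
    used throughout: observed richness, no rarefaction)."""
    return (counts > 0).sum(axis=1)


# ---------------------------------------------------------------------------
# weighted UniFrac


def _branch_mass_matrix(tree: TreeNode, rel: pd.DataFrame):
    """Branch lengths and per-sample descendant mass for every branch.

    Returns ``(lengths, mass)`` with ``mass`` of shape (n_branches,
    n_samples): row b holds, for each sample, the fraction of its mass
    descending through branch b.  Computed by one postorder accumulation.
    """
    leaves = {leaf.name for leaf in tree.tips()}
    missing = set(rel.columns) - leaves
    if missing:
        raise KeyError(f"ASVs absent from tree: {sorted(missing)[:5]}")
    n = rel.shape[0]
    abund = {asv: rel[asv].to_numpy(float) for asv in rel.columns}
    zero = np.zeros(n)
    lengths, rows = [], []
    node_mass: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            m = abund.get(node.name, zero).copy()
        else:
            m = zero.copy()
            for child in node.children:
                m = m + node_mass.pop(id(child))
        node_mass[id(node)] = m
        if node is not tree:
            lengths.append(node.length or 0.0)
            rows.append(m)
    return np.asarray(lengths), np.asarray(rows)


def weighted_unifrac(tree: TreeNode, rel_a: pd.Series, rel_b: pd.Series) -> float:
    """Unnormalized weighted UniFrac between two relative-abundance vectors."""
    rel = pd.DataFrame([rel_a, rel_b])
    lengths, mass = _branch_mass_matrix(tree, rel)
    return float(np.sum(lengths * np.abs(mass[:, 0] - mass[:, 1])))


def distance_matrix(tree: TreeNode, counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise weighted UniFrac over all samples of a count table."""
    rel = relative_abundance(counts)
    lengths, mass = _branch_mass_matrix(tree, rel)
    # weighted L1 between columns of `mass` = cityblock on length-scaled rows
    x = (mass * lengths[:, None]).T
    d = squareform(pdist(x, metric="cityblock"))
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


def cross_distance_matrix(tree: TreeNode, counts_query: pd.DataFrame,
                          counts_ref: pd.DataFrame) -> pd.DataFrame:
    """Weighted UniFrac between every query and every reference sample.

    Both tables must live in the same ASV space (leaves of ``tree``)."""
    rel = relative_abundance(pd.concat([counts_query, counts_ref]))
    lengths, mass = _branch_mass_matrix(tree, rel)
    x = (mass * lengths[:, None]).T
    nq = counts_query.shape[0]
    d = cdist(x[:nq], x[nq:], metric="cityblock")
    return pd.DataFrame(d, index=counts_query.index, columns=counts_ref.index)


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class Ordination:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: pd.DataFrame          # samples × kept axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # per kept axis, of positive inertia
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def pcoa(d: pd.DataFrame, n_axes: int | None = None) -> Ordination:
    """Classical scaling of a symmetric distance matrix.

    Axes with eigenvalues <= 0 (numerically: below ``1e-10 * max``) are
    dropped; any genuinely negative eigenvalues are kept in
    ``negative_eigenvalues`` for inspection.
    """
    arr = d.to_numpy(float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = arr.shape[0]
    if n_axes is not None and n_axes > n - 1:
        raise ValueError("n_axes must be <= n_samples - 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (arr ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_sum = eigvals[positive].sum()
    k = coords.shape[1]
    prop = (eigvals[positive][:k] / pos_sum) if pos_sum > 0 else np.zeros(k)
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    return Ordination(
        coordinates=pd.DataFrame(coords, index=index,
                                 columns=[f"PC{i+1}" for i in range(k)]),
        eigenvalues=eigvals,
        proportion_explained=prop,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


def write_ordination(ord_: Ordination, path) -> None:
    with open(path, "w") as fh:
        fh.write("# eigenvalues\t" + "\t".join(f"{v:.10g}" for v in ord_.eigenvalues) + "\n")
        fh.write("# proportion_explained\t" +
                 "\t".join(f"{v:.10g}" for v in ord_.proportion_explained) + "\n")
        ord_.coordinates.to_csv(path, sep="\t", index_label="sample_id", mode="a")


# ---------------------------------------------------------------------------
# moving average


def moving_average(x, y, window: float, grid=None) -> pd.DataFrame:
    """Mean of ``y`` in sliding windows of ``x`` (e.g. diversity over age).

    For each grid point a the mean of ``y`` over samples with
    ``x`` in [a - window/2, a + window/2) is reported; empty windows
    produce no row.  The default grid is every integer between min(x)
    and max(x).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if grid is None:
        grid = np.arange(np.floor(x.min()), np.ceil(x.max()) + 1)
    rows = []
    for a in np.asarray(grid, float):
        mask = (x >= a - window / 2) & (x < a + window / 2)
        if mask.any():
            rows.append((a, float(y[mask].mean()), int(mask.sum())))
    return pd.DataFrame(rows, columns=["x", "mean", "n"])
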