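import numpy as np
import pandas as pd
import pytest

from gutstruct import io as gio
from gutstruct import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for unit tests: 150 samples, 80 ASVs, 2 blocks."""
    spec = synthetic.CohortSpec(n_samples=150, n_asvs=80, n_clusters=2,
                                cluster_size=4, seed=101)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def big_cohort():
    """The recovery-benchmark cohort: 800 samples at generator defaults."""
    spec = synthetic.CohortSpec(n_samples=800, seed=42)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def big_network(big_cohort):
    from gutstruct import conetwork
    counts, tax, tree, meta, truth = big_cohort
    tax = gio.assign_display_names(counts, tax)
    net = conetwork.build_network(counts, tax)
    return net, conetwork.find_clusters(net, tax)


@pytest.fixture()
def toy_counts():
    return pd.DataFrame([[10, 30, 60], [5, 0, 2], [100, 0, 0]],
                        index=["s1", "s2", "s3"],
                        columns=["a1", "a2", "a3"])


def random_tree_and_abundances(rng, n_leaves=8, n_samples=2):
    """A random rooted binary tree plus random leaf proportion vectors."""
    from skbio import TreeNode
    leaves = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        for c in (a, b):
            c.length = float(rng.uniform(0.05, 1.0))
        nodes.append(TreeNode(children=[a, b]))
    tree = nodes[0]
    names = [f"L{i}" for i in range(n_leaves)]
    props = rng.dirichlet(np.ones(n_leaves), size=n_samples)
    rel = pd.DataFrame(props, columns=names,
                       index=[f"S{k}" for k in range(n_samples)])
    return tree, rel


def naive_weighted_unifrac(tree, rel_a, rel_b):
    """Independent oracle: explicit per-branch |P_A - P_B| summation using
    leaf-set enumeration for every branch."""
    total = 0.0
    for node in tree.traverse(include_self=False):
        leaves = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        pa = float(sum(rel_a.get(name, 0.0) for name in leaves))
        pb = float(sum(rel_b.get(name, 0.0) for name in leaves))
        total += (node.length or 0.0) * abs(pa - pb)
    return total
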