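"""Synthetic gut-microbiome cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage can be exercised and scored against a planted
truth without sequencing data:

* a two-enterotype mixture (default 60/40) whose genus profiles follow
  the study-population values (Bacteroides enterotype: Bacteroides
  35.3%, Faecalibacterium 14.2%, Prevotella 2%; Prevotella enterotype:
  Prevotella 37.1%, Faecalibacterium 11.7%, Bacteroides 10.4%), which
  also induces the cohort-level Bacteroides-Prevotella anticorrelation;
* per-sample genus composition drawn from a Dirichlet around the
  enterotype profile, with log-normal ASV-level noise within genera;
* planted cooccurrence blocks: sets of same-genus ASVs sharing a
  log-normal latent factor, producing joint presence/absence and
  positive rank correlation of their nonzero abundances;
* planted host-factor effects: a named factor is shifted by
  ``beta`` factor-standard-deviations per standard deviation of an
  ASV's log relative abundance;
* host metadata: age ~ N(55.6, 15.0), 77.5% female, BMI, stool
  frequency, and 17 food-group intakes driven by two latent diet axes,
  the second negatively coupled to age;
* multinomial read counts at log-normal library sizes (mean 30,000,
  safely above the 10,000-read inclusion threshold).

Everything is drawn from a single seeded generator: the same spec and
seed reproduce bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as gio

# genus -> (phylum, share of n_asvs, fraction of the minor mass)
_GENERA = {
    "Bacteroides":      ("Bacteroidetes",  0.18, 0.00),
    "Prevotella":       ("Bacteroidetes",  0.10, 0.00),
    "Faecalibacterium": ("Firmicutes",     0.14, 0.00),
    "Oscillospira":     ("Firmicutes",     0.10, 0.17),
    "Ruminococcus":     ("Firmicutes",     0.08, 0.15),
    "Blautia":          ("Firmicutes",     0.08, 0.13),
    "Roseburia":        ("Firmicutes",     0.07, 0.13),
    "Coprococcus":      ("Firmicutes",     0.06, 0.11),
    "Parabacteroides":  ("Bacteroidetes",  0.06, 0.11),
    "Bifidobacterium":  ("Actinobacteria", 0.05, 0.08),
    "Sutterella":       ("Proteobacteria", 0.04, 0.06),
    "Streptococcus":    ("Firmicutes",     0.04, 0.06),
}

_FAMILY_OF_PHYLUM = {
    "Bacteroidetes": ("Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Firmicutes": ("Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Actinobacteria": ("Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Proteobacteria": ("Betaproteobacteria", "Burkholderiales", "Alcaligenaceae"),
}

# the two enterotype genus profiles; minor genera share the leftover mass
_MAJOR_PROFILE = {
    0: {"Bacteroides": 0.353, "Faecalibacterium": 0.142, "Prevotella": 0.020},
    1: {"Prevotella": 0.371, "Faecalibacterium": 0.117, "Bacteroides": 0.104},
}

FOOD_GROUPS = [
    "grain", "rice", "noodles", "bread", "snacks", "meat", "fish", "eggs",
    "dairy", "vegetables", "kimchi", "seaweed", "soybean", "fruits",
    "mushrooms", "beverages", "tea_coffee",
]

# loadings of the two latent diet axes on the 17 food groups; axis 2
# contrasts a Westernized pattern (noodles/snacks/meat) with a
# traditional one (vegetables/seaweed/soybean)
_DIET_LOADINGS_1 = {"grain": 2.2, "rice": 1.8, "bread": 1.4, "eggs": 0.9,
                    "dairy": 0.9, "fruits": 0.8, "mushrooms": 0.7}
_DIET_LOADINGS_2 = {"noodles": 0.9, "snacks": 0.9, "meat": 0.8,
                    "vegetables": -0.9, "seaweed": -0.9, "soybean": -0.8,
                    "kimchi": -0.4, "fish": -0.3}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_samples: int = 890
    n_asvs: int = 250
    et_proportions: tuple = (0.60, 0.40)
    n_clusters: int = 5
    cluster_size: int = 6
    effect_table: list | None = None     # (asv-or-genus, factor, beta); None -> defaults
    age_mean: float = 55.6
    age_sd: float = 15.0
    frac_female: float = 0.775
    library_size_mean: float = 30_000.0
    library_size_sigma: float = 0.3
    genus_concentration: float = 40.0    # Dirichlet concentration of genus shares
    asv_sigma: float = 0.8               # log-normal ASV-level noise SD
    block_sigma: float = 1.1             # shared log-normal block-factor SD
    block_rel_abundance: float = 2.5e-4  # target mean relative abundance per block ASV
    age_diet_coupling: float = 0.53      # Pearson coupling of diet axis 2 to -age
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.et_proportions) - 1) > 1e-9 or min(self.et_proportions) < 0:
            raise ValueError("et_proportions must be a probability vector")
        if not 0 <= self.frac_female <= 1:
            raise ValueError("frac_female must lie in [0, 1]")
        for name in ("n_samples", "n_asvs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_clusters < 0 or (self.n_clusters and self.cluster_size < 3):
            raise ValueError("planted blocks need >= 3 ASVs each")
        if self.n_clusters * self.cluster_size > self.n_asvs:
            raise ValueError("cluster_size * n_clusters exceeds n_asvs")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    et_labels: pd.Series
    cluster_membership: dict            # asv_id -> block id (absent = none)
    planted_effects: list               # dicts: asv, factor, beta, direction
    diet_axes: pd.DataFrame             # per-sample latent diet factor scores
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "et_labels": self.et_labels.astype(int).to_dict(),
            "cluster_membership": self.cluster_membership,
            "planted_effects": self.planted_effects,
            "diet_axes": self.diet_axes.round(6).to_dict(orient="index"),
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


def _genus_profiles() -> dict:
    """Full per-enterotype genus mean-abundance vectors."""
    profiles = {}
    for et, major in _MAJOR_PROFILE.items():
        leftover = 1.0 - sum(major.values())
        minor_total = sum(w for _, _, w in _GENERA.values())
        prof = {}
        for genus, (_, _, w_minor) in _GENERA.items():
            prof[genus] = major.get(genus, leftover * w_minor / minor_total)
        profiles[et] = prof
    return profiles


def _allocate_asvs(spec: CohortSpec):
    """Deterministic ASV layout: ids, genus, within-genus base weights,
    and planted-block membership."""
    shares = np.array([s for _, s, _ in _GENERA.values()])
    raw = shares / shares.sum() * spec.n_asvs
    n_per = np.maximum(np.floor(raw).astype(int), 2)
    while n_per.sum() < spec.n_asvs:           # largest-remainder top-up
        n_per[np.argmax(raw - n_per)] += 1
    while n_per.sum() > spec.n_asvs:
        over = np.where(n_per > 2)[0]
        n_per[over[np.argmin((raw - n_per)[over])]] -= 1

    genera = list(_GENERA)
    minor_hosts = [g for g in genera if _GENERA[g][2] > 0]
    if spec.n_clusters > len(minor_hosts):
        raise ValueError(f"at most {len(minor_hosts)} planted blocks supported")
    block_host = {b: minor_hosts[b] for b in range(spec.n_clusters)}
    for b, g in block_host.items():
        if n_per[genera.index(g)] < spec.cluster_size + 1:
            raise ValueError(f"genus {g} too small for a block of {spec.cluster_size}")

    profiles = _genus_profiles()
    asv_ids, genus_of, weights, block_of = [], [], [], {}
    i = 0
    for gi, genus in enumerate(genera):
        m = n_per[gi]
        ids = [f"ASV_{i + k + 1:04d}" for k in range(m)]
        i += m
        block = next((b for b, g in block_host.items() if g == genus), None)
        block_ranks = set(range(1, spec.cluster_size + 1)) if block is not None else set()
        mean_profile = (profiles[0][genus] + profiles[1][genus]) / 2
        w_block = min(spec.block_rel_abundance / mean_profile, 0.5 / max(len(block_ranks), 1))
        free = [k for k in range(m) if k not in block_ranks]
        w_free = np.array([(k + 1) ** -1.3 for k in free])
        w_free = w_free / w_free.sum() * (1 - w_block * len(block_ranks))
        w = np.empty(m)
        for idx, k in enumerate(free):
            w[k] = w_free[idx]
        for k in block_ranks:
            w[k] = w_block
        for k, asv in enumerate(ids):
            asv_ids.append(asv)
            genus_of.append(genus)
            weights.append(w[k])
            if k in block_ranks:
                block_of[asv] = block
    return asv_ids, genus_of, np.array(weights), block_of


def _make_taxonomy(asv_ids, genus_of) -> pd.DataFrame:
    rows = {}
    seen: dict = {}
    for asv, genus in zip(asv_ids, genus_of):
        phylum = _GENERA[genus][0]
        cls, order, fam = _FAMILY_OF_PHYLUM[phylum]
        seen[genus] = seen.get(genus, 0) + 1
        # the leading Faecalibacterium ASVs carry a species assignment so
        # that display naming exercises the species-level grouping
        species = "prausnitzii" if genus == "Faecalibacterium" and seen[genus] <= 3 else None
        rows[asv] = {"kingdom": "Bacteria", "phylum": phylum, "class": cls,
                     "order": order, "family": fam, "genus": genus,
                     "species": species}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=gio.RANKS)


def generate_tree(asv_ids, genus_of_asv, seed: int = 0) -> TreeNode:
    """Random rooted binary tree whose same-genus ASVs form clades.

    Leaves of one genus are coalesced pairwise at random before genus
    subtrees are joined, so UniFrac distances reflect the taxonomy.
    All branch lengths are positive.
    """
    if len(asv_ids) < 2:
        raise ValueError("need at least 2 ASVs")
    if len(set(asv_ids)) != len(asv_ids):
        raise ValueError("duplicate ASV ids")
    rng = np.random.default_rng(seed)

    def join_random(nodes, scale):
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            for child in (a, b):
                if child.length is None:
                    child.length = float(rng.exponential(scale) + 0.01)
            parent = TreeNode(children=[a, b])
            nodes.append(parent)
        return nodes[0]

    by_genus: dict = {}
    for asv, genus in zip(asv_ids, genus_of_asv):
        by_genus.setdefault(genus, []).append(TreeNode(name=asv))
    genus_roots = []
    for genus in by_genus:
        root = join_random(by_genus[genus], scale=0.05)
        if root.length is None:
            root.length = float(rng.exponential(0.3) + 0.05)
        genus_roots.append(root)
    if len(genus_roots) == 1:
        tree = genus_roots[0]
        tree.length = None
        return tree
    tree = join_random(genus_roots, scale=0.3)
    tree.length = None
    return tree


def _default_effects(asv_ids, genus_of, weights, block_of,
                     target_rel: float = 2e-3) -> list:
    """Three ASV-BMI effects on non-block ASVs from three genera whose
    abundance does not separate the enterotypes.

    Each effect lands on the genus member whose expected relative
    abundance is closest to ``target_rel``: abundant enough to be
    detected everywhere, but a small enough share of the community that
    coupling a host factor to it does not leak into every other ASV
    through the compositional closure.
    """
    profiles = _genus_profiles()
    anchors = []
    for genus in ("Faecalibacterium", "Oscillospira", "Ruminococcus"):
        mean_profile = (profiles[0][genus] + profiles[1][genus]) / 2
        candidates = [(abs(mean_profile * w - target_rel), asv)
                      for asv, g, w in zip(asv_ids, genus_of, weights)
                      if g == genus and asv not in block_of]
        anchors.append(min(candidates)[1])
    betas = [0.5, 0.5, -0.5]
    return [(asv, "bmi", beta) for asv, beta in zip(anchors, betas)]


def generate_cohort(spec: CohortSpec):
    """Draw one cohort.

    Returns ``(counts, taxonomy, tree, metadata, truth)``: a samples x
    ASVs integer count table, per-ASV rank assignments, a rooted tree
    over the ASVs, per-sample host metadata, and the planted ground
    truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_asvs

    asv_ids, genus_of, weights, block_of = _allocate_asvs(spec)
    tax = _make_taxonomy(asv_ids, genus_of)
    tree = generate_tree(asv_ids, genus_of, seed=spec.seed + 1)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # enterotype labels and per-sample genus shares
    et = rng.choice(len(spec.et_proportions), size=n, p=spec.et_proportions)
    profiles = _genus_profiles()
    genera = list(_GENERA)
    genus_idx = np.array([genera.index(g) for g in genus_of])
    prof_matrix = np.array([[profiles[e][g] for g in genera] for e in (0, 1)])
    g_shares = np.empty((n, len(genera)))
    for e in (0, 1):
        rows = np.flatnonzero(et == e)
        if len(rows):
            g_shares[rows] = rng.dirichlet(spec.genus_concentration * prof_matrix[e],
                                           size=len(rows))

    # ASV-level noise, shared block factors, planted effect bookkeeping
    eps = np.exp(rng.normal(-spec.asv_sigma ** 2 / 2, spec.asv_sigma, size=(n, m)))
    raw = g_shares[:, genus_idx] * weights[None, :] * eps
    if spec.n_clusters:
        z_block = rng.normal(size=(n, spec.n_clusters))
        factors = np.exp(spec.block_sigma * z_block - spec.block_sigma ** 2 / 2)
        col_of = {a: i for i, a in enumerate(asv_ids)}
        for asv, b in block_of.items():
            raw[:, col_of[asv]] *= factors[:, b]
    rel = raw / raw.sum(axis=1, keepdims=True)

    # multinomial counts at log-normal library sizes
    mu = np.log(spec.library_size_mean) - spec.library_size_sigma ** 2 / 2
    libsizes = np.maximum(
        rng.lognormal(mu, spec.library_size_sigma, size=n).astype(int), 1)
    counts = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(libsizes[i], rel[i])
    counts = pd.DataFrame(counts, index=sample_ids, columns=asv_ids)

    # host metadata
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), 20, 90).round(1)
    female = rng.random(n) < spec.frac_female
    z_age = (age - age.mean()) / age.std()
    c = spec.age_diet_coupling
    diet1 = rng.normal(size=n)
    diet2 = -c * z_age + np.sqrt(1 - c ** 2) * rng.normal(size=n)
    food = {}
    for fg in FOOD_GROUPS:
        intake = (2.0 + _DIET_LOADINGS_1.get(fg, 0.0) * diet1
                  + _DIET_LOADINGS_2.get(fg, 0.0) * diet2
                  + 0.8 * rng.normal(size=n))
        food[fg] = np.clip(intake, 0, None).round(3)
    bmi = rng.normal(23.5, 3.2, size=n)
    stool_freq = rng.integers(1, 6, size=n)

    effects = spec.effect_table
    if effects is None:
        effects = _default_effects(asv_ids, genus_of, weights, block_of)
    meta = pd.DataFrame({"age": age,
                         "sex": np.where(female, "female", "male"),
                         "bmi": bmi, "stool_frequency": stool_freq,
                         **food},
                        index=sample_ids)
    planted = []
    col_index = {a: i for i, a in enumerate(asv_ids)}
    for entry in effects:
        asv, factor, beta, *rest = entry
        stratum = rest[0] if rest else None   # optional ("column", value) restriction
        if asv not in col_index:
            raise ValueError(f"effect ASV {asv} does not exist")
        # couple the factor to the ASV-specific component of log abundance:
        # the observed link is then attributable to the named ASV rather
        # than to the genus or enterotype axes its abundance rides on
        logeps = np.log(eps[:, col_index[asv]])
        zx = (logeps - logeps.mean()) / logeps.std()
        base_sd = meta[factor].std()
        mask = np.ones(n, bool) if stratum is None \
            else (meta[stratum[0]] == stratum[1]).to_numpy()
        meta.loc[mask, factor] = meta.loc[mask, factor] + beta * base_sd * zx[mask]
        planted.append({"asv": asv, "factor": factor, "beta": float(beta),
                        "direction": "+" if beta > 0 else "-",
                        "stratum": list(stratum) if stratum else None})

    truth = GroundTruth(
        et_labels=pd.Series(et, index=sample_ids, name="enterotype"),
        cluster_membership=dict(block_of),
        planted_effects=planted,
        diet_axes=pd.DataFrame({"diet1": diet1, "diet2": diet2}, index=sample_ids),
        params={k: v for k, v in asdict(spec).items() if k != "effect_table"},
    )
    return counts, tax, tree, meta, truth


def write_cohort(out_dir, counts, tax, tree, meta, truth) -> None:
    """Write the four standard inputs plus the ground-truth JSON."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_count_table(counts, out / "counts.tsv")
    gio.write_taxonomy(tax, out / "taxonomy.tsv")
    gio.write_tree(tree, out / "tree.nwk")
    gio.write_metadata(meta, out / "metadata.tsv")
    truth.to_json(out / "ground_truth.json")
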