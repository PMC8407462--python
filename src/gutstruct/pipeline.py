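"""End-to-end orchestration: simulate/read -> diversity -> enterotypes ->
cooccurrence network -> host associations, with a JSON summary.

A single config seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so each stage is individually
reproducible; the same config and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, conetwork, enterotypes, host, io as gio, synthetic

logger = logging.getLogger("gutstruct")


@dataclass
class PipelineConfig:
    out_dir: str = "gutstruct_out"
    # either simulate a cohort ...
    simulate: bool = True
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    # ... or read the four standard inputs
    counts_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    # stage parameters (study defaults)
    min_reads: int = 10_000
    min_prev: float = 0.10
    fdr_cooc: float = 1e-6
    fdr_quant: float = 1e-3
    fdr_prev: float = 0.1
    fdr_assoc: float = 0.2
    K: int = 2
    n_axes: int = 10      # PCoA axes kept in the written ordination
    et_axes: int = 3      # axes used by the enterotype mixture fit
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_prev", "fdr_cooc", "fdr_quant", "fdr_prev", "fdr_assoc"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.K < 1 or self.n_axes < 1 or self.et_axes < 1 or self.n_perm < 1:
            raise ValueError("K, n_axes, et_axes and n_perm must be positive")
        if not self.simulate:
            for name in ("counts_path", "taxonomy_path", "tree_path", "metadata_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or nonexistent: {p}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Derive per-stage 31-bit seeds from the pipeline seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def age_groups(age: pd.Series) -> pd.Series:
    """Decade bins used for the demographic prevalence screen."""
    edges = [0, 40, 50, 60, 70, 200]
    labels = ["<40", "40s", "50s", "60s", "70+"]
    return pd.cut(age, bins=edges, labels=labels, right=False).astype(str)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage, write per-stage tables under ``config.out_dir``
    and return the summary dict (also written as summary.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    summary: dict = {"seed": config.seed, "stage_seeds": seeds}

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        spec = synthetic.CohortSpec(**{"seed": seeds[0], **config.cohort})
        counts, tax, tree, meta, truth = synthetic.generate_cohort(spec)
        synthetic.write_cohort(out / "inputs", counts, tax, tree, meta, truth)
        logger.info("simulate: %d samples x %d ASVs", *counts.shape)
    else:
        counts = gio.read_count_table(config.counts_path, min_reads=config.min_reads)
        tax = gio.read_taxonomy(config.taxonomy_path)
        tree = gio.read_tree(config.tree_path)
        meta = gio.read_metadata(config.metadata_path).loc[counts.index]
        truth = None
    tax = gio.assign_display_names(counts, tax)
    summary["n_samples"], summary["n_asvs"] = map(int, counts.shape)

    # ---- community metrics ------------------------------------------------
    genus_ab = community.relative_abundance(counts, tax, level="genus")
    phylum_ab = community.relative_abundance(counts, tax, level="phylum")
    richness = community.observed_richness(counts)
    d = community.distance_matrix(tree, counts)
    gio.write_distance_matrix(d, out / "weighted_unifrac.tsv")
    ordn = community.pcoa(d, n_axes=config.n_axes)
    community.write_ordination(ordn, out / "pcoa.tsv")
    summary["pcoa_axis1_proportion"] = float(ordn.proportion_explained[0])
    summary["mean_phylum_abundance"] = phylum_ab.mean(axis=0).round(4).to_dict()

    # ---- enterotypes ------------------------------------------------------
    model = enterotypes.fit_enterotypes(d, counts, tax, K=config.K,
                                        n_axes=config.et_axes, seed=seeds[1])
    et_counts = model.labels.value_counts().sort_index()
    summary["enterotypes"] = {model.genus_labels[k]: int(v)
                              for k, v in et_counts.items()}
    f_stat, p_perm = enterotypes.permanova(d, model.labels, n_perm=config.n_perm,
                                           seed=seeds[2])
    summary["permanova_enterotype"] = {"pseudo_F": f_stat, "p": p_perm}
    model.labels.to_frame().assign(
        genus=[model.genus_labels[k] for k in model.labels]
    ).to_csv(out / "enterotypes.tsv", sep="\t", index_label="sample_id")

    # ---- cooccurrence network --------------------------------------------
    net = conetwork.build_network(counts, tax, fdr_cooc=config.fdr_cooc,
                                  fdr_quant=config.fdr_quant,
                                  min_prev=config.min_prev)
    clusters = conetwork.find_clusters(net, tax)
    negatives = conetwork.negative_associations(counts, fdr=config.fdr_quant,
                                                min_prev=config.min_prev)
    gio.export_network(net, clusters, out / "network.graphml", format="graphml")
    gio.export_network(net, clusters, out / "edges.tsv", format="edgelist")
    conetwork.write_clusters(clusters, out / "clusters.tsv")
    negatives.to_csv(out / "negative_edges.tsv", sep="\t", index=False)
    summary["network"] = {
        "n_nodes": int(len(net.nodes)), "n_edges": int(len(net.edges)),
        "n_cooccurrence_hits": net.n_cooccurrence_hits,
        "n_quantitative_hits": net.n_quantitative_hits,
        "n_clusters": len(clusters),
        "cluster_names": [c.name for c in clusters],
        "n_negative_edges": int(len(negatives)),
    }

    # ---- host associations ------------------------------------------------
    eligible = conetwork.prevalence_filter(counts, config.min_prev)
    presence = counts[eligible] > 0
    groups = age_groups(meta["age"])
    screen_age = host.prevalence_enrichment(presence, groups, alpha=config.fdr_prev)
    screen_sex = host.prevalence_enrichment(presence, meta["sex"], alpha=config.fdr_prev)
    screen = pd.concat([screen_age, screen_sex], ignore_index=True)
    screen.to_csv(out / "prevalence_screen.tsv", sep="\t", index=False)
    summary["prevalence_screen_calls"] = int((screen["direction"] != "").sum())

    pca = host.diet_pca(meta[synthetic.FOOD_GROUPS])
    pca.loadings.to_csv(out / "diet_loadings.tsv", sep="\t")
    pca.scores.to_csv(out / "diet_scores.tsv", sep="\t", index_label="sample_id")
    from scipy import stats as sstats
    rho_age_pc2 = sstats.spearmanr(meta["age"], pca.scores["PC2"])
    summary["diet_pc2_age_spearman"] = {"rho": float(rho_age_pc2.statistic),
                                        "p": float(rho_age_pc2.pvalue)}

    factors = meta[["bmi", "stool_frequency"]].copy()
    factors["diet_PC1"] = pca.scores["PC1"]
    factors["diet_PC2"] = pca.scores["PC2"]
    assoc = host.associate(counts[eligible], factors, age=meta["age"],
                           fdr=config.fdr_assoc)
    assoc.table.to_csv(out / "associations.tsv", sep="\t", index=False)
    summary["significant_associations"] = int((assoc.table["q"] < config.fdr_assoc).sum())

    age_div = host.age_diversity_correlation(richness, meta["age"], meta["sex"])
    age_div.to_csv(out / "age_diversity.tsv", sep="\t", index=False)
    summary["age_diversity"] = age_div.set_index("stratum")[["rho", "p"]] \
        .round(6).to_dict(orient="index")
    age_ab = host.age_abundance_correlation(counts[eligible], meta["age"],
                                            fdr=config.fdr_assoc)
    age_ab.to_csv(out / "age_abundance.tsv", sep="\t", index=False)
    summary["age_abundance_calls"] = int(age_ab["significant"].sum()) if len(age_ab) else 0

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    return summary
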