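#!/usr/bin/env python
"""Host-factor analyses on the reference cohort.

Demographic prevalence screening (hypergeometric, FDR < 0.1 by decade
bin and sex), age-diversity and age-abundance Spearman correlations,
diet-pattern PCA of the 17 food groups, and the winsorized
age-conditioned linear association of ASV abundance with host factors
(FDR < 0.2).  Planted ASV-BMI effects are scored against ground truth.
Outputs land in results/host/.
"""

import json
from pathlib import Path

from scipy.stats import spearmanr

from gutstruct import community, conetwork, host, synthetic
from gutstruct import io as gio
from gutstruct.pipeline import age_groups

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "host"


def main() -> None:
    counts = gio.read_count_table(ROOT / "cohort" / "counts.tsv")
    meta = gio.read_metadata(ROOT / "cohort" / "metadata.tsv").loc[counts.index]
    truth = json.loads((ROOT / "cohort" / "ground_truth.json").read_text())
    OUT.mkdir(parents=True, exist_ok=True)

    eligible = conetwork.prevalence_filter(counts, 0.10)
    presence = counts[eligible] > 0
    screen = host.prevalence_enrichment(presence, age_groups(meta["age"]), alpha=0.1)
    screen.to_csv(OUT / "prevalence_screen_age.tsv", sep="\t", index=False)
    host.direction_matrix(screen).to_csv(OUT / "prevalence_direction_age.tsv", sep="\t")
    print(f"prevalence screen (decade bins): "
          f"{int((screen['direction'] != '').sum())} calls at FDR < 0.1")

    richness = community.observed_richness(counts)
    age_div = host.age_diversity_correlation(richness, meta["age"], meta["sex"])
    age_div.to_csv(OUT / "age_diversity.tsv", sep="\t", index=False)
    for _, row in age_div.iterrows():
        print(f"age-diversity Spearman [{row['stratum']}]: rho = "
              f"{row['rho']:.3f}, p = {row['p']:.2g}")
    smoothed = community.moving_average(meta["age"], richness, window=10)
    smoothed.to_csv(OUT / "age_diversity_moving_average.tsv", sep="\t", index=False)

    pca = host.diet_pca(meta[synthetic.FOOD_GROUPS])
    pca.loadings.to_csv(OUT / "diet_loadings.tsv", sep="\t")
    pca.scores.to_csv(OUT / "diet_scores.tsv", sep="\t", index_label="sample_id")
    rho = spearmanr(meta["age"], pca.scores["PC2"])
    top = pca.loadings["PC1"].abs().nlargest(3).index.tolist()
    print(f"diet PC1 dominated by {top}; PC2 vs age: rho = "
          f"{rho.statistic:.3f} (p = {rho.pvalue:.2g})")

    factors = meta[["bmi", "stool_frequency"]].copy()
    factors["diet_PC1"] = pca.scores["PC1"]
    factors["diet_PC2"] = pca.scores["PC2"]
    res = host.associate(counts[eligible], factors, age=meta["age"], fdr=0.2)
    res.table.to_csv(OUT / "associations.tsv", sep="\t", index=False)
    hits = res.table[res.table["q"] < 0.2]
    print(f"{len(hits)} ASV-factor associations at FDR < 0.2")
    planted = {(e["asv"], e["factor"]) for e in truth["planted_effects"]}
    found = {(r["asv"], r["factor"]) for _, r in hits.iterrows()}
    print(f"planted effects recovered: {len(planted & found)}/{len(planted)}")


if __name__ == "__main__":
    main()
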