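#!/usr/bin/env python
"""Cross-cohort enterotype comparisons.

Two parts.  (1) The published worked examples: Yates-corrected 2x2
chi-squared tests of the reference enterotype ratio (536/354) against
foreign cohorts reconstructed from printed sizes and Bacteroides-ET
percentages.  (2) A synthetic external cohort: nearest-neighbor label
transfer on cross UniFrac distances, PERMANOVA on the pooled matrix,
and the average-distance Mann-Whitney comparison within an enterotype.
"""

import json
from pathlib import Path

import pandas as pd

from gutstruct import community, enterotypes, synthetic
from gutstruct import io as gio

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "comparison"
SEED = 20240902

FOREIGN = {  # printed cohort size and Bacteroides-ET share
    "beijing_hangzhou": (412, 0.794),
    "shanghai": (25, 0.880),
    "spain": (40, 0.900),
    "chile": (41, 0.732),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, (size, pct) in FOREIGN.items():
        n_b = round(size * pct)
        stat, p = enterotypes.compare_et_proportions((536, 354), (n_b, size - n_b))
        rows.append({"cohort": name, "n": size, "bacteroides_et": n_b,
                     "chi2": stat, "p": p})
        print(f"{name:>18}: {100 * pct:.1f}% Bacteroides ET, chi2 p = {p:.3g}")
    pd.DataFrame(rows).to_csv(OUT / "published_chi2.tsv", sep="\t", index=False)

    counts = gio.read_count_table(ROOT / "cohort" / "counts.tsv")
    tree = gio.read_tree(ROOT / "cohort" / "tree.nwk")
    truth = json.loads((ROOT / "cohort" / "ground_truth.json").read_text())
    ref_labels = pd.Series(truth["et_labels"]).reindex(counts.index)

    q_counts, *_, q_truth = synthetic.generate_cohort(
        synthetic.CohortSpec(n_samples=200, seed=SEED))
    q_counts.index = ["Q" + s for s in q_counts.index]
    q_truth.et_labels.index = q_counts.index
    d_cross = community.cross_distance_matrix(tree, q_counts, counts)
    transferred = enterotypes.assign_enterotype_nn(ref_labels, d_cross)
    acc = float((transferred == q_truth.et_labels).mean())
    print(f"nearest-neighbor transfer accuracy on the synthetic external "
          f"cohort: {acc:.3f}")

    pooled = community.distance_matrix(tree, pd.concat([counts, q_counts]))
    cohort_of = ["ref"] * len(counts) + ["query"] * len(q_counts)
    f_stat, p = enterotypes.permanova(pooled, cohort_of, n_perm=999, seed=1)
    print(f"PERMANOVA reference vs external: pseudo-F = {f_stat:.2f}, p = {p:.3g}")

    d_ref = pooled.iloc[:len(counts), :len(counts)]
    u, p_mw, *_ = enterotypes.avg_distance_test(
        d_cross, d_ref, ref_labels, transferred, target_et=0)
    print(f"average-distance Mann-Whitney (Bacteroides ET): U = {u:.0f}, "
          f"p = {p_mw:.3g}")
    json.dump({"nn_accuracy": acc, "permanova_p": p, "avg_distance_p": p_mw},
              open(OUT / "synthetic_comparison.json", "w"), indent=1)


if __name__ == "__main__":
    main()
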