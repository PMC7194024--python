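"""Population structure and selection-signature scan.

On the pooled, QC'd, LD-pruned panel: PCA of the variance-standardised
genomic relationship matrix, the average-IBS population tree, and
pairwise Weir-Cockerham FST scans of the main population against each
other population with the mean + 3 SD outlier rule.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from conngen.io import read_plink1
from conngen.qc import PruneParams, ld_prune
from conngen.structure import fst_scan, grm, pca, population_tree

SEED = 1


def main():
    pooled = read_plink1(ROOT / "scratch" / "panel" / "qc_pooled")
    pruned = pooled.subset(variant_idx=ld_prune(pooled, PruneParams()))
    res_dir = ROOT / "results"

    res = pca(grm(pruned, method=2), k=10)
    var = pd.DataFrame(
        {
            "component": [f"PC{i+1}" for i in range(10)],
            "variance_pct": 100 * res.variance_fractions[:10],
        }
    )
    var.to_csv(res_dir / "pca_variance.tsv", sep="\t", index=False)
    coords = res.coordinates.iloc[:, :3].copy()
    coords.insert(0, "population", pooled.samples.set_index("id")["population"])
    coords.to_csv(res_dir / "pca_coordinates.tsv", sep="\t")

    tree = population_tree(pruned, subsample=50, seed=SEED)
    (res_dir / "population_tree.nwk").write_text(tree.newick + "\n")
    tree.distance.to_csv(res_dir / "population_distances.tsv", sep="\t")

    fst_rows = []
    for other in ("FIN", "PRI"):
        scan = fst_scan(pruned.for_population("NWS"), pruned.for_population(other))
        fst_rows.append(
            {
                "pair": f"NWS vs {other}",
                "fst_all_mean": scan.mean,
                "fst_all_sd": scan.sd,
                "selected_pct": 100 * len(scan.outliers) / max(len(scan.table), 1),
                "fst_selected_mean": scan.selected_mean,
                "fst_selected_sd": scan.selected_sd,
                "n_snps": len(scan.table),
            }
        )
    fst = pd.DataFrame(fst_rows)
    fst.to_csv(res_dir / "fst_summary.tsv", sep="\t", index=False)

    print("variance explained by the first three components: "
          + ", ".join(f"{v:.2f}%" for v in var["variance_pct"][:3]))
    print("\npopulation tree:", tree.newick)
    print("average-IBS distances:")
    print(tree.distance.round(4).to_string())
    print("\npairwise FST (mean + 3 SD outlier rule):")
    print(fst.round(4).to_string(index=False))
    print("\nwrote results/pca_variance.tsv, pca_coordinates.tsv, "
          "population_tree.nwk, population_distances.tsv, fst_summary.tsv")


if __name__ == "__main__":
    main()
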