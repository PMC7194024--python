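"""Within-population diversity, ROH, and the four inbreeding estimators.

Per population: polymorphic-SNP proportion and MAF spectrum, observed
and expected heterozygosity, average pairwise IBS distance (on the
LD-pruned pooled panel), the ROH scan with its descriptive summary and
length categories, and the inbreeding estimators F_E, F_G, F_ROH plus
pedigree F for the recorded pedigree.
"""

from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from conngen.diversity import (
    ROHParams,
    heterozygosity,
    ibs_distance,
    inbreeding_excess_hom,
    inbreeding_grm,
    inbreeding_roh,
    inbreeding_pedigree,
    maf_spectrum,
    roh_length_categories,
    roh_scan,
    roh_summary,
)
from conngen.io import read_pedigree, read_plink1
from conngen.qc import PruneParams, QCThresholds, apply_qc, ld_prune

POPULATIONS = ("NWS", "FIN", "PRI")


def main():
    panel = read_plink1(ROOT / "scratch" / "panel" / "panel")
    pooled = read_plink1(ROOT / "scratch" / "panel" / "qc_pooled")
    pruned = pooled.subset(variant_idx=ld_prune(pooled, PruneParams()))

    summary_rows, spectrum_rows, f_tables, roh_sums, roh_cats = [], [], [], [], []
    for pop in POPULATIONS:
        qcd = read_plink1(ROOT / "scratch" / "panel" / f"qc_{pop}")
        raw = panel.for_population(pop)

        no_maf, _ = apply_qc(raw, QCThresholds(maf_min=0.0))
        poly, hist = maf_spectrum(no_maf)
        hist.insert(0, "population", pop)
        spectrum_rows.append(hist)

        no_hwe, _ = apply_qc(raw, QCThresholds(hwe_p_min=np.nextafter(0, 1)))
        het = heterozygosity(no_hwe)

        sub = pruned.for_population(pop)
        sim_m, _ = ibs_distance(sub)
        iu = np.triu_indices(sub.n_samples, k=1)
        dst = float(1.0 - np.nanmean(sim_m.values[iu]))

        segments = roh_scan(qcd, ROHParams())
        rsum = roh_summary(segments, qcd)
        roh_sums.append(rsum)
        cats = roh_length_categories(segments)
        cats.insert(0, "population", pop)
        roh_cats.append(cats)

        f = pd.DataFrame(
            {
                "F_E": inbreeding_excess_hom(qcd),
                "F_G": inbreeding_grm(qcd),
                "F_ROH": inbreeding_roh(segments, qcd),
            }
        )
        f.insert(0, "population", pop)
        f_tables.append(f)

        summary_rows.append(
            {
                "population": pop,
                "polymorphic_pct": 100 * poly,
                "Ho": het.mean_ho,
                "Ho_sd": het.sd_ho,
                "He": het.mean_he,
                "He_sd": het.sd_he,
                "Dst": dst,
                "F_E": f["F_E"].mean(),
                "F_G": f["F_G"].mean(),
                "F_ROH": f["F_ROH"].mean(),
            }
        )

    pedigree = read_pedigree(ROOT / "scratch" / "panel" / "pedigree.txt")
    f_ped = inbreeding_pedigree(pedigree)
    genotyped = panel.samples["id"][panel.samples["id"].isin(f_ped.index)]

    res = ROOT / "results"
    pd.concat(spectrum_rows).to_csv(res / "maf_spectrum.tsv", sep="\t", index=False)
    pd.concat(roh_sums).to_csv(res / "roh_summary.tsv", sep="\t", index=False)
    pd.concat(roh_cats).to_csv(res / "roh_length_categories.tsv", sep="\t", index=False)
    f_all = pd.concat(f_tables)
    f_all.index.name = "id"
    f_all.to_csv(res / "inbreeding_individual.tsv", sep="\t")
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(res / "population_summary.tsv", sep="\t", index=False)

    print("population diversity summary:")
    print(summary.round(4).to_string(index=False))
    print(f"\npedigree F, genotyped animals: mean "
          f"{f_ped[genotyped].mean():.4f} (sd {f_ped[genotyped].std():.4f}), "
          f"all recorded: mean {f_ped.mean():.4f}")
    print("\nROH summary:")
    print(pd.concat(roh_sums).round(2).to_string(index=False))
    print("\nwrote results/population_summary.tsv, maf_spectrum.tsv, "
          "roh_summary.tsv, roh_length_categories.tsv, inbreeding_individual.tsv")


if __name__ == "__main__":
    main()
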