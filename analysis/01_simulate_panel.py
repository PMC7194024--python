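"""Simulate the reference three-population SNP panel.

Runs the forward Wright-Fisher scenario (large NWS-like composite, small
bottlenecked FIN-like breed split 80 generations ago, large PRI-like
composite split 30 generations ago), applies the array-style
ascertainment screen, and writes the PLINK fileset, the recorded
pedigree and the autozygosity truth under scratch/panel for the
downstream analysis steps.
"""

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from conngen.io import write_pedigree, write_plink1
from conngen.sim import ascertain_panel, simulate, study_config

SEED = 1


def main():
    out = simulate(study_config(seed=SEED))
    panel = ascertain_panel(out.genotypes)
    dest = ROOT / "scratch" / "panel"
    dest.mkdir(parents=True, exist_ok=True)
    write_plink1(panel, dest / "panel")
    write_pedigree(out.pedigree, dest / "pedigree.txt")
    truth = {
        iid: tracts for iid, tracts in out.truth["autozygosity"].items()
    }
    (dest / "truth.json").write_text(json.dumps(truth))

    print(f"simulated {out.genotypes.n_samples} animals x "
          f"{out.genotypes.n_variants} raw markers")
    print(f"ascertained panel: {panel.n_variants} SNPs "
          f"({panel.n_variants / out.genotypes.n_variants:.1%} of raw)")
    for pop in panel.populations:
        n = (panel.samples["population"] == pop).sum()
        print(f"  {pop}: {n} genotyped animals")
    print(f"recorded pedigree: {len(out.pedigree.records)} animals")
    print(f"wrote {dest}/panel.bed/.bim/.fam, pedigree.txt, truth.json")


if __name__ == "__main__":
    main()
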