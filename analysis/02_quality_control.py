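"""SNP quality control, per population and pooled.

Applies the sequential filters (position/sex chromosome, MAF < 0.01,
call rate < 95%, HWE exact p < 1e-15) to each population separately and
to the pooled panel, writes the removal report shaped like a standard
panel-QC table, and stores the filtered filesets for the later steps.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from conngen.io import read_plink1, write_plink1
from conngen.qc import QCThresholds, apply_qc, per_population_qc


def main():
    panel = read_plink1(ROOT / "scratch" / "panel" / "panel")
    thresholds = QCThresholds()
    rows = []
    for pop, (filtered, report) in per_population_qc(panel, thresholds).items():
        write_plink1(filtered, ROOT / "scratch" / "panel" / f"qc_{pop}")
        rows.append({"population": pop, "n_animals": filtered.n_samples,
                     **report.to_frame().iloc[0].to_dict()})
    pooled, report = apply_qc(panel, thresholds)
    write_plink1(pooled, ROOT / "scratch" / "panel" / "qc_pooled")
    rows.append({"population": "ALL", "n_animals": pooled.n_samples,
                 **report.to_frame().iloc[0].to_dict()})

    table = pd.DataFrame(rows)
    out = ROOT / "results" / "qc_report.tsv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, sep="\t", index=False)
    print("SNP quality control (sequential filters):")
    print(table.to_string(index=False))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
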