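"""Generate the synthetic study cohort and summarise its composition.

Three AML patients are multiplexed per run (diagnosis and first remission),
each planted with a CH clone that persists in remission, a dominant
leukemic clone and an LOH subclone.  Writes a cell-composition table and
the germline profiles; per-cell matrices are regenerated on demand by the
later scripts rather than stored.
"""

from collections import Counter

import pandas as pd

from _common import outdir, study_runs
from scmrd.io import write_germline_vcf

out = outdir("01_simulate")
rows = []
for timepoint, (matrix, antibody, profiles, truth) in study_runs().items():
    comp = Counter(
        (truth.patient_of[bc], truth.clone_of[bc])
        for bc in matrix.barcodes
        if bc not in truth.doublets
    )
    for (pid, clone), n in sorted(comp.items()):
        rows.append({"timepoint": timepoint, "patient": pid, "clone": clone,
                     "n_cells": n})
    rows.append({"timepoint": timepoint, "patient": "-", "clone": "doublet",
                 "n_cells": len(truth.doublets)})
    if timepoint == "diagnosis":
        write_germline_vcf(profiles, out / "germline_profiles.vcf")

table = pd.DataFrame(rows)
table.to_csv(out / "cell_composition.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print(f"\nWrote {out}/cell_composition.tsv and germline_profiles.vcf")
print("(per-barcode truth labels are regenerated on demand; write them with "
      "scmrd.io.write_truth_json if needed)")
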