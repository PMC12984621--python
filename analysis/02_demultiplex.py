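"""Demultiplex the diagnosis run and audit the assignments against truth.

Reports per-patient cell yields, removal reasons and the retained-singlet
assignment accuracy.
"""

from collections import Counter

import pandas as pd

from _common import demuxed_partitions, outdir, study_runs

out = outdir("02_demux")
run = study_runs()["diagnosis"]
result, truth = demuxed_partitions(run)

# per-match summary (the full per-barcode table is large; regenerate via
# scmrd.demux.demultiplex_run when needed)
summary = pd.DataFrame(
    [
        {
            "best_match": str(a.best_match),
            "n": 1,
            "mean_genotyped_snps": a.n_genotyped_snps,
            "mean_discrepancies": a.n_discrepancies,
            "removed": a.barcode not in {
                bc for part, _ in result.partitions.values() for bc in part.barcodes
            },
        }
        for a in result.assignments
    ]
).groupby(["best_match", "removed"], as_index=False).agg(
    n=("n", "sum"),
    mean_genotyped_snps=("mean_genotyped_snps", "mean"),
    mean_discrepancies=("mean_discrepancies", "mean"),
)
summary.to_csv(out / "assignment_summary.tsv", sep="\t", index=False)

kept = {bc for part, _ in result.partitions.values() for bc in part.barcodes}
singlets = [a for a in result.assignments
            if a.barcode in kept and a.barcode not in truth.doublets]
accuracy = sum(a.best_match == truth.patient_of[a.barcode] for a in singlets)
print("per-patient yields:",
      {pid: part[0].n_cells for pid, part in result.partitions.items()})
print("removal reasons:", dict(Counter(r for _, r in result.removed)))
print(f"retained singlets: {len(singlets)}, correctly assigned: "
      f"{100 * accuracy / len(singlets):.2f}%")
print(f"conservation: {result.n_assigned} assigned + {len(result.removed)} removed "
      f"= {run[0].n_cells} barcodes")
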