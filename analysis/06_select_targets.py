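"""Apply the five selection criteria and rank MRD targets per patient.

Pairs each patient's demultiplexed diagnosis sample with their remission
sample, evaluates criteria c1-c5 for every surviving candidate and writes
the criteria table plus the selected targets.  The expected outcome per
patient: the leukemic IDH2/SRSF2/RUNX1 variants are eligible, the CH
DNMT3A variant fails c2 (persists) and c3 (normal phenotype), and the
LOH-lost TET2 variant fails c4.
"""

import json

import pandas as pd

from _common import demuxed_partitions, outdir, study_runs
from scmrd.pipeline import analyze_patient

out = outdir("06_select")
runs = study_runs()
diag, _ = demuxed_partitions(runs["diagnosis"])
rem, _ = demuxed_partitions(runs["remission"])

rows = []
selected = {}
for pid in sorted(diag.partitions):
    matrix, antibody = diag.partitions[pid]
    rem_matrix = rem.partitions[pid][0] if pid in rem.partitions else None
    analysis = analyze_patient(pid, matrix, antibody, rem_matrix)
    selected[pid] = analysis.selected_variant_ids
    for r in analysis.criteria:
        rows.append(
            {
                "patient": pid,
                "variant": r.variant_id,
                "gene": r.gene,
                "diagnosis_vaf_pct": round(r.diagnosis_vaf or 0.0, 2),
                "remission_vaf_pct": (
                    round(r.remission_vaf, 3) if r.remission_vaf is not None else None
                ),
                "c1_large_clone": r.c1_large_clone,
                "c2_cleared": r.c2_cleared,
                "c3_aberrant_clone": r.c3_aberrant_clone,
                "c4_not_lost": r.c4_not_lost,
                "c5_not_blacklisted": r.c5_not_blacklisted,
                "eligible": r.eligible,
            }
        )

table = pd.DataFrame(rows)
table.to_csv(out / "criteria_table.tsv", sep="\t", index=False)
(out / "selected_targets.json").write_text(json.dumps(selected, indent=1))
print(table.to_string(index=False))
print("\nselected targets:", selected)
print(f"Written to {out}/criteria_table.tsv and selected_targets.json")
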