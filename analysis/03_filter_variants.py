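"""Variant filtering per demultiplexed patient.

Writes the per-variant filter decisions and zygosity-aware pseudobulk VAFs
for the diagnosis run.  Germline SNPs fall to the population-frequency
filter; the planted somatic variants survive.
"""

import pandas as pd

from _common import demuxed_partitions, outdir, study_runs
from scmrd.scfilter import apply_variant_filters, pseudobulk_vaf

out = outdir("03_filter")
result, _ = demuxed_partitions(study_runs()["diagnosis"])

rows = []
for pid, (matrix, _) in sorted(result.partitions.items()):
    report = apply_variant_filters(matrix)
    for vid in matrix.variant_ids:
        rec = matrix.variants[matrix.variant_index(vid)]
        failed = report.failed_filters(vid)
        rows.append(
            {
                "patient": pid,
                "variant": vid,
                "gene": rec.gene or "SNP",
                "surviving": vid in report.surviving,
                "failed_filters": ";".join(failed),
                "pseudobulk_vaf_pct": (
                    round(pseudobulk_vaf(matrix, vid), 3)
                    if vid in report.surviving
                    else None
                ),
            }
        )

table = pd.DataFrame(rows)
table.to_csv(out / "filter_report.tsv", sep="\t", index=False)
surviving = table[table.surviving]
print(surviving.to_string(index=False))
print(f"\n{len(surviving)} surviving candidates across "
      f"{surviving.patient.nunique()} patients "
      f"({sorted(surviving.gene.unique())}); full report in {out}/filter_report.tsv")
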