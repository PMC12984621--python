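"""Per-clone immunophenotypes from CLR-transformed antibody counts.

The DfN reference band comes from each run's own wildtype population.
Writes clone-level marker positivity and the immature/aberrant flags that
feed selection criterion #3: leukemic clones are CD34+/CD117+ with
cross-lineage CD7, CH clones profile as normal.
"""

import pandas as pd

from _common import demuxed_partitions, outdir, study_runs
from scmrd.immuno import (
    ImmunoConfig,
    classify_aberrant,
    clone_immunophenotype,
    clr_matrix,
    derive_reference_ranges,
)
from scmrd.clones import infer_clones
from scmrd.scfilter import apply_variant_filters

out = outdir("05_immuno")
result, _ = demuxed_partitions(study_runs()["diagnosis"])

rows = []
for pid, (matrix, antibody) in sorted(result.partitions.items()):
    report = apply_variant_filters(matrix)
    clones = infer_clones(matrix.subset_variants(report.surviving))
    clr = clr_matrix(antibody)
    cfg = ImmunoConfig(
        reference_ranges=derive_reference_ranges(
            clr[clones.wildtype.cell_indices], antibody.markers
        )
    )
    for clone in clones.all_clones:
        profile = clone_immunophenotype(clone, clr, antibody.markers, cfg)
        classify_aberrant(profile, cfg)
        rows.append(
            {
                "patient": pid,
                "clone": clone.clone_id,
                "n_cells": clone.n_cells,
                "positive_markers": ";".join(
                    m for m, pos in profile.positivity.items() if pos
                ),
                "immature": profile.immature,
                "aberrant": profile.aberrant,
                "matched_rules": ";".join(profile.matched_rules),
            }
        )

table = pd.DataFrame(rows)
table.to_csv(out / "immunophenotypes.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print(f"\nWritten to {out}/immunophenotypes.tsv")
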