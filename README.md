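# scmrd

Single-cell multi-omics guided selection and monitoring of measurable
residual disease (MRD) targets in acute myeloid leukemia (AML).

Roughly half of AML patients — in particular those whose leukemias carry
only myelodysplasia-related (MR) or clonal-hematopoiesis (CH) gene
mutations — lack a validated molecular marker for sensitive MRD monitoring,
because a mutation found in bulk material may trace a pre-leukemic clone
that persists through remission rather than the leukemia itself. This
package implements, end to end, a pipeline that resolves that ambiguity at
single-cell resolution and then tracks the chosen marker longitudinally:

1. **Demultiplexing** (`scmrd.demux`) — patients pooled into one
   single-cell DNA+protein run are separated by germline SNP genotypes with
   a per-locus likelihood model covering singlet and doublet profiles, and
   removal rules (genotyped in <30 % of SNPs, ≥10 or ≥30 % discrepancies,
   doublet, ambiguous).
2. **Genotyping and variant filtering** (`scmrd.scfilter`) — cells are
   genotyped per locus (depth ≥10, GQ ≥30, mutated at cell allele fraction
   ≥35 %, homozygous ≥90 %), and candidates filtered: ≥3 mutated cells, not
   synonymous, not homopolymer-adjacent, no second variant within 300 bp,
   ≥6 mutated cells unless co-occurring, ≥1 homozygous cell (expected under
   allelic dropout), not germline (population AF ≥0.1 % or user-flagged).
   Pseudobulk VAF is zygosity-aware:
   `VAF = (n_HET + 2·n_HOM) / (2·n_informative)`.
3. **Clonal reconstruction** (`scmrd.clones`) — cells sharing a complete
   multi-locus genotype form clones; dropout-signature subgroups are
   absorbed; clones are ordered by genotype precedence into a parent–child
   graph with loss-of-heterozygosity (LOH) events annotated
   (HET→WT = alt allele lost, HET→HOM = ref allele lost).
4. **Immunophenotyping** (`scmrd.immuno`) — 17-marker antibody counts are
   CLR-transformed per cell; clone-mean CLR drives marker positivity,
   immaturity (CD34+ and/or CD117+) and aberrancy via a
   different-from-normal band plus declarative LAIP rules and cross-lineage
   markers.
5. **Five-criterion selection** (`scmrd.selection`) — a target must be
   (c1) in a large clone at diagnosis (aggregate VAF ≥10 %, one mutated
   allele in 20 % blasts), (c2) cleared to <1 % VAF after induction,
   (c3) carried only by immature, aberrant clones, (c4) never missing or
   LOH-lost in a more advanced clone, and (c5) outside genes known to turn
   negative at relapse (NRAS/KRAS/FLT3). Eligible targets rank by assay
   LoD when available, else by diagnosis VAF.
6. **Monitoring** (`scmrd.mrd`, `scmrd.ecngs`) — ddPCR positivity against
   `LoD = mean + 3.08·σ` of 20 wildtype wells (rule-of-three `3/n` floor
   when DNA is limiting), relapse as a confirmed negative→positive
   conversion or a ≥10-fold rise between positives, and lead-time
   comparison against conventional methods; plus a strand-aware
   beta-binomial error-corrected NGS caller (posterior <1 %, ≥3 unique
   alternative observations) with sensitivity probing.

No patient-level data is distributed; `scmrd.synthio` generates fully
labelled synthetic cohorts (clone trees with LOH, allelic dropout, missing
genotypes, doublets, stage-specific antibody counts, ddPCR droplet series,
strand-specific sequencing error) so every stage is tested against planted
truth.

## Worked example

```python
from scmrd.pipeline import analyze_patient
from scmrd.synthio import default_patient, generate_patient_sample

patient = default_patient("P1")
diag, antibody, truth = generate_patient_sample(patient, "diagnosis", 2000, seed=11)
rem, _, _ = generate_patient_sample(patient, "remission", 800, seed=12)
analysis = analyze_patient("P1", diag, antibody, rem)
for r in analysis.criteria:
    print(r.gene, [r.c1_large_clone, r.c2_cleared, r.c3_aberrant_clone,
                   r.c4_not_lost, r.c5_not_blacklisted],
          round(r.diagnosis_vaf, 1), r.remission_vaf)
print("selected:", [t.gene for t in analysis.targets])
```

prints

```
DNMT3A [True, False, False, True, True] 36.0 7.27
IDH2 [True, True, True, True, True] 30.1 0.0
SRSF2 [True, True, True, True, True] 30.6 0.0
TET2 [True, True, True, False, True] 17.4 0.0
RUNX1 [True, True, True, True, True] 12.6 0.0
selected: ['SRSF2', 'IDH2', 'RUNX1']
```

The planted CH variant (DNMT3A) is rejected because it persists in
remission (c2) and sits in a clone with a normal immunophenotype (c3); the
LOH-lost variant (TET2) is rejected because a more advanced subclone lost
it (c4); the leukemia-specific variants are eligible and ranked by
diagnosis VAF.

The numbered scripts under `analysis/` run the same study step by step
(simulate → demultiplex → filter → clones → immunophenotype → select →
monitor → error-corrected calling) and write their tables under
`results/`.

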