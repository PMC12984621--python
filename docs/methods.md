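# Methods

This note documents the models, thresholds and design choices behind
`scmrd`, what the synthetic-data generator does and does not emulate, and
the numerical details a maintainer would need.

## Demultiplexing model

Patients multiplexed into one run are separated by germline SNP genotypes.
The database holds one expected alt-allele-dosage vector per patient and
one per unordered patient pair; the doublet profile is the per-locus mean
dosage of the two patients. Observations are genotype codes in {0, 1, 2};
the per-locus observation model puts probability `1 − ε` on the genotypes
within 0.5 of the expected dosage (shared equally when the dosage is
half-integer) and `ε` on the rest, with genotyping error rate `ε = 0.01`
by default. For integer dosages this reduces to the familiar symmetric
model (`1 − ε` on the expected genotype, `ε/2` elsewhere). Missing loci
contribute nothing; cells are assigned to the maximum-likelihood profile,
and ties are removed as ambiguous rather than broken — consistent with the
removal-heavy QC stance of the rest of the pipeline.

Removal rules (all configurable, disjunctive — any violation removes):
genotyped in fewer than 30 % of database SNPs; at least 10 genotype
discrepancies with the best match; discrepancy fraction at least 30 %;
best match is a doublet profile. A discrepancy is a non-missing genotype
outside the best profile's consistent set. The disjunctive reading is the
stricter of the two grammatically possible combinations of these rules and
is the default.

## Genotyping and variant filters

A cell × locus entry is `MISSING` when depth < 10 or genotype quality
< 30; otherwise the cell is mutated when its allele fraction reaches 35 %
(`HOM` at 90 %, `HET` below). The 35 % threshold is read as a *cell-level*
allele-fraction gate — an aggregate reading would contradict the fact that
remission pseudobulk VAFs fall well below 1 % — and the alternative remains
a configuration change (`min_cell_af`). The 90 % HET/HOM boundary is this
package's choice; no published boundary exists.

Variant filters are independent predicates of the unfiltered matrix, so
their order cannot change the surviving set (property-tested): ≥3 mutated
cells; not synonymous; not homopolymer-adjacent (a precomputed annotation
flag, not re-derived from a reference genome); no other candidate within
300 bp on the same chromosome — both members of a close pair are removed,
since there is no principled way to pick one — unless that pair
co-occurs; ≥6 mutated cells unless the variant belongs to a co-occurring
pair; at least one homozygous cell; not germline (population allele
frequency ≥ 0.1 % or user-flagged). "Co-occurring" is defined here as a
pair of variants mutated together in ≥3 cells, plus any user-declared
pairs.

Two notes on the homozygous-cell filter. It exists because per-allele
dropout (ADO) guarantees that a genuinely mutated variant will show
apparent homozygotes, so a variant with none is suspect. That logic
presupposes ADO: on dropout-free data the filter would veto every
heterozygous variant, so the no-noise identity checks in the test suite
run with `min_hom_cells=0` while all noisy-data tests keep the default
of 1.

Pseudobulk VAF is zygosity-aware: `100 · (n_HET + 2·n_HOM) /
(2·n_informative)`, over cells passing the entry-level QC only. Panel
uniformity is the fraction of amplicons with mean coverage ≥ 0.2× the
panel mean (the standard vendor definition); runs below 80 % are flagged
and known variants missing from the filtered output can be force-called
(`force_call`), which bypasses the variant-level filters but never the
cell-level QC, and fails explicitly for loci the panel does not cover.

## Clone inference and the clone graph

Cells with a complete genotype over the surviving variants are grouped by
exact genotype. ADO produces satellite groups around every real clone that
differ only by HET→HOM or HET→WT flips; groups with that signature are
absorbed into the larger source clone when smaller than 30 % of it
(`ado_absorb_fraction`). The absorption is deliberately symmetric — the
published rationale concerns apparent homozygotes, but per-allele dropout
produces apparent wildtypes at the same rate, and unabsorbed WT-side
satellites would masquerade as LOH subclones. A genuine LOH subclone
survives absorption either by its size (≥30 % of the source clone) or by
carrying its own acquired variants, and the threshold is config-exposed
because nothing in the data can distinguish a small pure-LOH subclone from
dropout; tests exercise both sides of the threshold. Groups below
`min_clone_size` (default 6 cells, echoing the 6-cell variant filter) are
dropped and their cells left unassigned. Cells with missing entries are
assigned only when consistent with exactly one clone at every non-missing
site. The fully wildtype population is reported separately and anchors the
graph.

Parent assignment: clones are placed smallest mutated set first; a
candidate parent must have every mutated variant either persisting in the
child or LOH-lost (HET parent → WT child); among candidates the one
inheriting the most mutations wins, with fewer LOH losses as tie-break.
Ties between incomparable candidates are recorded and flag the graph
non-tree. One consequence: a child that lost a variant but gained nothing,
descending from a parent of equal mutated-set size, is genuinely ambiguous
against the forward-acquisition reading, and the forward reading is
preferred; with any acquired variant or a HOM signature the LOH edge is
recovered. Every edge is validated on build (inheritance or recorded LOH
explains each parental mutation) and the graph is checked acyclic.

LOH calls: HET(parent) → WT(child) means the alt allele was lost;
HET → HOM means the ref allele was lost. Nothing is derivable where the
parent is wildtype.

## Immunophenotyping

Antibody counts are compositional, so each cell is centred-log-ratio
transformed with pseudocount 1 (`CLR_i = log(c_i + 1) − mean_j log(c_j +
1)`; rows sum to zero). A clone's immunophenotype is its per-marker mean
CLR; positivity compares the clone mean against per-marker cutoffs, so a
minority subpopulation above the cutoff does not flip the clone-level
call. By default the cutoffs and the different-from-normal (DfN) reference
band are the central-95 % per-cell CLR percentiles of the run's own
wildtype population — the natural internal control, since those cells are
the mutation-free normal residue. Immaturity is CD34 and/or CD117
positivity. Aberrancy fires on any of: a cross-lineage (lymphoid) marker
positive on a myeloid clone; a declarative LAIP rule
(required-positive/required-negative marker lists, encoding
patient-specific aberrant combinations); any clone-mean CLR outside its
DfN band. All gates are configuration; no clinical numeric gates are
published, so recovery tests rely on generator-known truth rather than
clinical cutoffs.

## Selection criteria

`eligible ⇔ c1 ∧ c2 ∧ c3 ∧ c4 ∧ c5`, no exceptions. Choices made where
the wording admits two readings: c1's "VAF ≥ 10 % across clones" is the
aggregate pseudobulk VAF with all clones pooled (a per-largest-clone mode
is configurable); c3 requires *all* variant-carrying diagnosis clones to
be immature and aberrant (an any-clone mode is configurable); c2
re-genotypes the remission matrix even when the variant fell out of the
remission output, so absence at a covered locus means VAF 0, while an
uncovered locus makes the variant not assessable and therefore ineligible.
The blacklist is gene-level and editable, defaulting to {NRAS, KRAS,
FLT3}. Ranking prefers ascending validated assay LoD when supplied
(sensitivity-first), else descending diagnosis VAF.

## ddPCR monitoring

`LoD = mean + 3.08·σ` over the wildtype wells (one-tailed z for
α = 0.001), with σ the sample standard deviation (n−1; the denominator is
not published and the difference is far below assay noise). The
rule-of-three threshold is `100 · 3 / n` percent for `n` assessable allele
observations (two per diploid genome equivalent; a genome-equivalents mode
is configurable) and replaces the LoD only when DNA is limiting *and* the
RoT is larger. Positivity is `VAF ≥ threshold` with a detected (non-zero)
VAF; at exactly the threshold the positivity and negativity definitions
overlap and positive wins (configurable), matching the positivity clause.

Relapse scanning merges tissues chronologically: "conversion" fires at the
first negative→positive transition confirmed by any later positive (no
confirmation window is imposed, as none is published), "tenfold" at the
first adjacent pair of positives with a ≥10-fold rise (adjacent in the
merged series; a same-tissue-only and an any-positive-pair mode would be
small variations, and adjacency is the default because it is the most
conservative reading that still fires on the published examples). The
detection day is the first sample indicating relapse — the conversion
sample, or the second member of the tenfold pair. Calls are prefix-stable:
appending later samples never changes an already-made call. Lead time per
comparator method is the signed difference `ddPCR day − comparator day`;
methods that never detected MRD are skipped.

## Error-corrected NGS caller

The background at a site is a per-strand beta-binomial (mean error rate
`μ`, overdispersion `ρ`) fitted by method of moments from ≥3 reference
samples, with an optional trimmed mean so a contaminated reference
inflates the dispersion rather than the mean, and a floor of `μ ≥ 1e-6`
so all-zero panels stay usable. The "posterior error probability" of an
observation is operationalised as the background upper-tail probability
`P(X ≥ k)`, evaluated per strand; the two strands are combined by taking
the *worse* (larger) tail, so support confined to one strand can never be
called — the strand-aware AND that suppresses strand-biased artifacts.
This tail formulation stands in for the unpublished details of the
original caller's posterior and is isolated in one function so an
alternative (e.g. a Bayes-factor form) is swappable; it is validated
against its own exact-summation oracle, not against any external
implementation. A call requires tail < 1 % on both strands and ≥3 unique
alternative observations (UAO, distinct consensus families). Reads are
classified binarily as supporting/non-supporting, so insertions and
phased variants need no special handling.

Numerics: `scipy.stats.betabinom.sf` is computed as `1 − cdf` and loses
all precision below ~1e-10, so tails smaller than 1e-6 are re-summed
directly from the log-gamma form of the pmf with early termination (the
pmf is decreasing throughout the summed range). The exact-tail test oracle
agrees to 1e-10 on n ≤ 50.

`sensitivity_probe` scans the minimal total supporting reads `k` (split
across strands proportionally to depth, totals held fixed, UAO = k) for
which the caller fires, and verifies it fires at `k_min` and not at
`k_min − 1`. At a fixed error *rate* the absolute `k_min` grows with depth
(the background count grows too) while the detectable VAF fraction
`k_min / (2·depth)` shrinks — the quantity that actually measures
sensitivity.

## Synthetic data generator

The generator is the study-condition oracle: it emits genotype matrices,
antibody counts, germline profiles and truth labels for parameter-recovery
testing.

*Cohort defaults* (all config-exposed): 3 patients per multiplexed run,
50 germline SNPs (HWE at allele frequencies 0.2–0.8), ADO 5 % per allele
at heterozygous sites, 5 % missing entries, 5 % doublets, depth ~
Poisson(80), negative-binomial antibody counts (size 8). Each default
patient plants a CH clone (DNMT3A, 10 % at diagnosis, persisting at 15 %
in remission, normal-like phenotype), a dominant leukemic clone (adds
IDH2/SRSF2/TET2, 35 %, blast phenotype: CD34/CD117 high with
cross-lineage CD7) and an advanced subclone (adds RUNX1 and loses TET2 by
LOH of the alt allele, 25 %); 30 % of diagnosis cells are normal, 85 % at
remission. That makes three subclones at diagnosis and one at remission,
60 % blasts at diagnosis, a leukemic aggregate VAF of 30 %, and clears the
leukemia after induction — the clonal-dynamics regime the selection
criteria were designed for. Sample sizes in tests (2,000 diagnosis / 800
remission cells; 6,000–10,000-barcode multiplexes) are scaled-down but
statistically comfortable versions of real runs.

*Mechanics.* Doublets merge two component cells by pooling allele
observations; ADO drops each allele of a heterozygous site independently
(alt lost → apparent WT, ref lost → apparent HOM, both → missing).
Genotype calls are emitted consistently with the default genotyping
thresholds: the observed allele fraction is the pooled-dosage fraction
plus Gaussian noise, clipped into the called genotype's bin, so
re-applying the genotyping rule reproduces the emitted calls exactly.
ddPCR series draw mutant counts binomially at `true VAF + assay
false-positive rate` over pooled replicate alleles. EC-NGS counts per
strand are true-variant binomial draws plus beta-binomial error draws;
each supporting read is one consensus family, so UAO equals total support.

*What is not emulated* — and hence what passing tests do not show about
real data: amplicon-level coverage structure and panel dropout beyond the
global missing rate; genotype-quality miscalibration (GQ is binary
good/bad); doublet-specific antibody artifacts beyond count addition;
within-clone immunophenotype drift beyond marker-mean differences; UMI
family-size distributions and consensus errors; PCR-well-level ddPCR
chemistry (droplet counts are reduced to pooled binomial draws). Recovery
rates on this generator are best-case for these axes.

## Known limitations

- Clone inference is exact-genotype grouping with an ADO-absorption
  heuristic, not a probabilistic mixture model; heavily missing cells are
  conservatively unassigned.
- A small pure-LOH subclone below the absorption threshold is
  indistinguishable from dropout by construction; the threshold is the
  only dial.
- The EC-NGS posterior is a tail-probability stand-in (see above).
- DfN references derived from the run's own wildtype cells assume those
  cells are phenotypically normal; in heavily infiltrated samples an
  external reference should be supplied via configuration.
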