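"""Synthetic single-cell multi-omics cohorts with known ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: multiplexed cell x variant genotype matrices with allelic dropout
(ADO), missing genotypes and doublets; overdispersed antibody counts per
clone; germline SNP profiles per patient; ddPCR droplet series along
responder/relapse VAF trajectories; and strand-specific error-corrected NGS
read counts.  The generator emits :class:`TruthLabels` so parameter-recovery
tests can compare every inference against the planted truth.

The default cohort mirrors the study conditions this pipeline targets: a
few AML patients multiplexed per run, each with a clonal hierarchy rooted in
a clonal-hematopoiesis (CH) clone that persists in remission, a dominant
leukemic clone carrying the MRD-suitable variants, and a more advanced
subclone that has lost one variant through loss of heterozygosity (LOH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .demux import GermlineProfile
from .ecngs import EcngsSite
from .matrix import AntibodyCounts, CellGenotypeMatrix, Genotype, VariantRecord
from .mrd import DdpcrAssay, MrdSeries
from .scfilter import FilterConfig

__all__ = [
    "DEFAULT_MARKERS",
    "CloneSpec",
    "PatientSpec",
    "CohortConfig",
    "TruthLabels",
    "resolve_clone_genotypes",
    "generate_multiplex_run",
    "generate_patient_sample",
    "simulate_ddpcr_series",
    "simulate_ecngs_counts",
    "simulate_ecngs_sites",
    "default_patient",
    "default_cohort",
    "relapse_trajectory",
    "stable_trajectory",
]

DEFAULT_MARKERS = (
    "CD3", "CD7", "CD11b", "CD13", "CD14", "CD15", "CD19", "CD22", "CD33",
    "CD34", "CD38", "CD45", "CD56", "CD64", "CD117", "CD123", "HLA-DR",
)

# Mature mononuclear-cell baseline vs immature blast phenotype (CD34/CD117
# high, cross-lineage CD7). Values are expected antibody-oligo counts.
NORMAL_MARKER_MEANS: dict[str, float] = {
    "CD3": 60, "CD7": 8, "CD11b": 50, "CD13": 60, "CD14": 40, "CD15": 45,
    "CD19": 6, "CD22": 6, "CD33": 80, "CD34": 3, "CD38": 60, "CD45": 250,
    "CD56": 5, "CD64": 30, "CD117": 3, "CD123": 10, "HLA-DR": 70,
}
BLAST_MARKER_MEANS: dict[str, float] = {
    "CD3": 3, "CD7": 60, "CD11b": 15, "CD13": 70, "CD14": 8, "CD15": 15,
    "CD19": 4, "CD22": 5, "CD33": 70, "CD34": 120, "CD38": 80, "CD45": 80,
    "CD56": 6, "CD64": 20, "CD117": 100, "CD123": 40, "HLA-DR": 90,
}

NORMAL_CLONE = "normal"


@dataclass(frozen=True)
class CloneSpec:
    """One node of a patient's clonal tree.

    ``somatic_variants`` are the variants newly acquired by this clone (all
    heterozygous on acquisition); ``loh_events`` are ``(variant_id, lost)``
    pairs with ``lost`` in {"ref", "alt"} applied on top of the inherited
    genotype.  Fractions are of all cells in the sample at each timepoint;
    the remainder is the wildtype (normal) population.
    """

    clone_id: str
    parent_id: str | None
    somatic_variants: tuple[str, ...]
    diagnosis_fraction: float
    remission_fraction: float = 0.0
    loh_events: tuple[tuple[str, str], ...] = ()


@dataclass
class PatientSpec:
    patient_id: str
    variants: dict[str, VariantRecord]
    clones: list[CloneSpec]
    marker_means: dict[str, dict[str, float]]  # clone_id (incl "normal") -> marker -> mean
    leukemic_variant_ids: tuple[str, ...] = ()
    ch_variant_ids: tuple[str, ...] = ()
    loh_lost_variant_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clone ids")
        known = set(ids)
        n_roots = 0
        for c in self.clones:
            if c.parent_id is None:
                n_roots += 1
            elif c.parent_id not in known:
                raise ValueError(f"clone {c.clone_id} has unknown parent {c.parent_id}")
            for v in c.somatic_variants:
                if v not in self.variants:
                    raise ValueError(f"clone {c.clone_id} uses undefined variant {v}")
        if self.clones and n_roots == 0:
            raise ValueError("clone tree has no root")
        # reject cycles: resolving genotypes walks parents and will loop
        resolve_clone_genotypes(self)
        for tp in ("diagnosis", "remission"):
            total = sum(self.fraction(c, tp) for c in self.clones)
            if total > 1.0 + 1e-9:
                raise ValueError(f"{tp} clone fractions sum to {total} > 1")

    @staticmethod
    def fraction(clone: CloneSpec, timepoint: str) -> float:
        if timepoint == "diagnosis":
            return clone.diagnosis_fraction
        if timepoint == "remission":
            return clone.remission_fraction
        raise ValueError(f"unknown timepoint {timepoint!r}")


def resolve_clone_genotypes(patient: PatientSpec) -> dict[str, dict[str, Genotype]]:
    """Accumulate each clone's genotype over the patient's somatic variants.

    Walks the tree root-to-leaf: acquisitions enter as HET; an LOH event
    losing the ref allele turns HET into HOM, losing the alt allele turns
    HET into WT.  The wildtype population is included under ``"normal"``.
    """
    by_id = {c.clone_id: c for c in patient.clones}
    resolved: dict[str, dict[str, Genotype]] = {}

    def resolve(cid: str, seen: frozenset[str]) -> dict[str, Genotype]:
        if cid in resolved:
            return resolved[cid]
        if cid in seen:
            raise ValueError(f"clone tree contains a cycle through {cid}")
        clone = by_id[cid]
        base = (
            {v: g for v, g in resolve(clone.parent_id, seen | {cid}).items()}
            if clone.parent_id is not None
            else {v: Genotype.WT for v in patient.variants}
        )
        for v in clone.somatic_variants:
            base[v] = Genotype.HET
        for v, lost in clone.loh_events:
            if lost == "ref":
                base[v] = Genotype.HOM
            elif lost == "alt":
                base[v] = Genotype.WT
            else:
                raise ValueError(f"lost allele must be 'ref' or 'alt', got {lost!r}")
        resolved[cid] = base
        return base

    for c in patient.clones:
        resolve(c.clone_id, frozenset())
    resolved[NORMAL_CLONE] = {v: Genotype.WT for v in patient.variants}
    return resolved


@dataclass
class CohortConfig:
    """Generator settings for one multiplexed run.

    Noise parameters: ``ado_rate`` is the per-allele dropout probability at
    heterozygous sites, ``missing_rate`` the per-cell-per-locus missing
    probability, ``doublet_rate`` the probability that an emitted barcode
    contains two cells.  All randomness flows from ``seed``.
    """

    patients: list[PatientSpec]
    n_cells: int = 6000
    n_germline_snps: int = 50
    ado_rate: float = 0.05
    missing_rate: float = 0.05
    doublet_rate: float = 0.05
    af_sd: float = 0.05
    depth_mean: float = 80.0
    nb_dispersion: float = 8.0
    markers: tuple[str, ...] = DEFAULT_MARKERS
    timepoints: Mapping[str, str] | str = "diagnosis"
    patient_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ado_rate", "missing_rate", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.patients:
            raise ValueError("at least one patient is required")
        if self.patient_weights is not None and len(self.patient_weights) != len(
            self.patients
        ):
            raise ValueError("patient_weights length mismatch")

    def timepoint_of(self, patient_id: str) -> str:
        if isinstance(self.timepoints, str):
            return self.timepoints
        return self.timepoints.get(patient_id, "diagnosis")


@dataclass
class TruthLabels:
    """Ground-truth record per emitted barcode plus planted-variant roles."""

    patient_of: dict[str, str | tuple[str, str]]
    clone_of: dict[str, str | tuple[str, str]]
    doublets: set[str]
    leukemic_variants: dict[str, tuple[str, ...]]
    ch_variants: dict[str, tuple[str, ...]]
    loh_lost_variants: dict[str, tuple[str, ...]]
    relapse_day: dict[str, int | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_of": {k: list(v) if isinstance(v, tuple) else v for k, v in self.patient_of.items()},
            "clone_of": {k: list(v) if isinstance(v, tuple) else v for k, v in self.clone_of.items()},
            "doublets": sorted(self.doublets),
            "leukemic_variants": {k: list(v) for k, v in self.leukemic_variants.items()},
            "ch_variants": {k: list(v) for k, v in self.ch_variants.items()},
            "loh_lost_variants": {k: list(v) for k, v in self.loh_lost_variants.items()},
            "relapse_day": self.relapse_day,
        }


# ---------------------------------------------------------------------------
# genotype matrix generation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _germline_snps(
    n_snps: int, patients: Sequence[PatientSpec], rng: np.random.Generator
) -> tuple[list[VariantRecord], np.ndarray]:
    """Common SNP records plus per-patient genotypes drawn under HWE."""
    records = []
    for i in range(n_snps):
        ref, alt = rng.choice(4, size=2, replace=False)
        records.append(
            VariantRecord(
                chrom="1",
                pos=1_000_000 + 10_000 * i,
                ref=str(_BASES[ref]),
                alt=str(_BASES[alt]),
                gene="",
                consequence="intron_variant",
                pop_af=float(np.round(rng.uniform(0.05, 0.5), 3)),
            )
        )
    freqs = rng.uniform(0.2, 0.8, size=n_snps)
    genotypes = rng.binomial(2, freqs[None, :], size=(len(patients), n_snps))
    return records, genotypes.astype(np.int8)


def generate_multiplex_run(
    config: CohortConfig,
) -> tuple[CellGenotypeMatrix, AntibodyCounts, list[GermlineProfile], TruthLabels]:
    """Generate one multiplexed run: genotypes, antibody counts, germline
    profiles and truth labels.

    Doublet barcodes merge two component cells by summing allele
    observations (allele fraction = pooled alt dosage over pooled alleles)
    before genotype calling, and sum their antibody counts.  ADO is applied
    per allele at heterozygous sites before merging; a site with both
    alleles dropped, or hit by the missingness process, is MISSING.
    """
    rng = np.random.default_rng(config.seed)
    thresholds = FilterConfig()
    patients = config.patients
    n_pat = len(patients)

    snp_records, snp_genos = _germline_snps(config.n_germline_snps, patients, rng)
    profiles = [
        GermlineProfile(
            patient_id=p.patient_id,
            loci=[(r.chrom, r.pos, r.ref, r.alt) for r in snp_records],
            genotypes=snp_genos[i],
        )
        for i, p in enumerate(patients)
    ]

    somatic_records: list[VariantRecord] = []
    somatic_ids: list[str] = []  # globally unique chrom:pos:ref>alt ids
    for p in patients:
        for rec in p.variants.values():
            somatic_records.append(rec)
            somatic_ids.append(rec.variant_id)
    if len(set(somatic_ids)) != len(somatic_ids):
        raise ValueError("somatic variant loci must be unique across patients")
    variants = snp_records + somatic_records
    n_var = len(variants)
    n_snp = len(snp_records)

    # dosage templates per (patient, clone)
    template_keys: list[tuple[str, str]] = []
    template_rows: list[np.ndarray] = []
    marker_rows: list[np.ndarray] = []
    for i, p in enumerate(patients):
        clone_genos = resolve_clone_genotypes(p)
        global_ids = {local: rec.variant_id for local, rec in p.variants.items()}
        for cid, geno in clone_genos.items():
            row = np.zeros(n_var, dtype=np.int8)
            row[:n_snp] = snp_genos[i]
            geno_by_global = {global_ids[local]: g for local, g in geno.items()}
            for j, vid in enumerate(somatic_ids):
                if vid in geno_by_global:
                    row[n_snp + j] = int(geno_by_global[vid])
            template_keys.append((p.patient_id, cid))
            template_rows.append(row)
            means = p.marker_means.get(cid) or p.marker_means[NORMAL_CLONE]
            marker_rows.append(np.array([means[m] for m in config.markers]))
    templates = np.vstack(template_rows)
    marker_means = np.vstack(marker_rows)
    template_index = {k: i for i, k in enumerate(template_keys)}

    # per-patient clone sampling distributions at the patient's timepoint
    clone_choices: list[list[int]] = []
    clone_probs: list[np.ndarray] = []
    for p in patients:
        tp = config.timepoint_of(p.patient_id)
        ids = [c.clone_id for c in p.clones] + [NORMAL_CLONE]
        fr = [PatientSpec.fraction(c, tp) for c in p.clones]
        fr.append(max(0.0, 1.0 - sum(fr)))
        clone_choices.append([template_index[(p.patient_id, cid)] for cid in ids])
        clone_probs.append(np.asarray(fr) / sum(fr))

    weights = (
        np.asarray(config.patient_weights, dtype=float)
        if config.patient_weights is not None
        else np.ones(n_pat)
    )
    weights = weights / weights.sum()

    n = config.n_cells
    is_doublet = rng.random(n) < config.doublet_rate
    n_components = np.where(is_doublet, 2, 1)
    total_components = int(n_components.sum())

    comp_patient = rng.choice(n_pat, size=total_components, p=weights)
    comp_template = np.empty(total_components, dtype=np.int64)
    for i in range(n_pat):
        mask = comp_patient == i
        if mask.any():
            comp_template[mask] = rng.choice(
                clone_choices[i], size=int(mask.sum()), p=clone_probs[i]
            )

    dosage = templates[comp_template].astype(np.int8)  # components x variants

    # per-allele dropout at heterozygous sites
    het = dosage == 1
    drop_ref = het & (rng.random(dosage.shape) < config.ado_rate)
    drop_alt = het & (rng.random(dosage.shape) < config.ado_rate)
    comp_missing = drop_ref & drop_alt
    comp_alt = np.where(het & drop_alt & ~drop_ref, 0, dosage).astype(np.int16)
    comp_alt = np.where(het & drop_ref & ~drop_alt, 2, comp_alt)
    comp_alleles = np.full(dosage.shape, 2, dtype=np.int16)
    comp_alt[comp_missing] = 0
    comp_alleles[comp_missing] = 0

    # merge components into barcodes
    owner = np.repeat(np.arange(n), n_components)
    alt_sum = np.zeros((n, n_var), dtype=np.int16)
    allele_sum = np.zeros((n, n_var), dtype=np.int16)
    np.add.at(alt_sum, owner, comp_alt)
    np.add.at(allele_sum, owner, comp_alleles)

    missing = allele_sum == 0
    missing |= rng.random((n, n_var)) < config.missing_rate
    with np.errstate(invalid="ignore", divide="ignore"):
        af_true = np.where(missing, 0.0, alt_sum / np.maximum(allele_sum, 1))

    genotype = np.where(
        af_true >= thresholds.hom_af,
        Genotype.HOM,
        np.where(af_true >= thresholds.min_cell_af, Genotype.HET, Genotype.WT),
    ).astype(np.int8)
    genotype[missing] = Genotype.MISSING

    # observed allele fraction: noisy, but clipped inside the called bin so
    # that re-applying the genotyping rule reproduces the emitted call
    af = np.clip(af_true + rng.normal(0.0, config.af_sd, size=af_true.shape), 0.0, 1.0)
    eps = 1e-6
    lo = np.select(
        [genotype == Genotype.HOM, genotype == Genotype.HET],
        [thresholds.hom_af, thresholds.min_cell_af],
        0.0,
    )
    hi = np.select(
        [genotype == Genotype.HOM, genotype == Genotype.HET],
        [1.0, thresholds.hom_af - eps],
        thresholds.min_cell_af - eps,
    )
    af = np.clip(af, lo, hi)
    af[missing] = 0.0

    depth = np.maximum(
        rng.poisson(config.depth_mean, size=(n, n_var)), thresholds.min_depth
    ).astype(np.int32)
    depth[missing] = rng.integers(0, thresholds.min_depth, size=int(missing.sum()))
    gq = np.full((n, n_var), 99, dtype=np.int16)
    gq[missing] = 0

    barcodes = [f"BC{i:06d}" for i in range(n)]
    matrix = CellGenotypeMatrix(
        barcodes=barcodes,
        variants=variants,
        genotype=genotype,
        depth=depth,
        gq=gq,
        af=af.astype(np.float32),
    )

    # antibody counts (negative binomial; doublets sum their components)
    mu = marker_means[comp_template]
    r = config.nb_dispersion
    comp_counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-6)))
    counts = np.zeros((n, len(config.markers)), dtype=np.int64)
    np.add.at(counts, owner, comp_counts)
    antibody = AntibodyCounts(
        barcodes=barcodes, markers=list(config.markers), counts=counts
    )

    # truth labels
    patient_of: dict[str, str | tuple[str, str]] = {}
    clone_of: dict[str, str | tuple[str, str]] = {}
    doublets: set[str] = set()
    comp_ptr = 0
    for i, bc in enumerate(barcodes):
        k = int(n_components[i])
        pids = [patients[comp_patient[comp_ptr + j]].patient_id for j in range(k)]
        cids = [template_keys[comp_template[comp_ptr + j]][1] for j in range(k)]
        comp_ptr += k
        if k == 1:
            patient_of[bc] = pids[0]
            clone_of[bc] = cids[0]
        else:
            doublets.add(bc)
            order = np.argsort(pids)
            patient_of[bc] = (pids[order[0]], pids[order[1]])
            clone_of[bc] = (cids[order[0]], cids[order[1]])

    truth = TruthLabels(
        patient_of=patient_of,
        clone_of=clone_of,
        doublets=doublets,
        leukemic_variants={p.patient_id: p.leukemic_variant_ids for p in patients},
        ch_variants={p.patient_id: p.ch_variant_ids for p in patients},
        loh_lost_variants={p.patient_id: p.loh_lost_variant_ids for p in patients},
    )
    return matrix, antibody, profiles, truth


def generate_patient_sample(
    patient: PatientSpec,
    timepoint: str,
    n_cells: int,
    seed: int,
    **overrides,
) -> tuple[CellGenotypeMatrix, AntibodyCounts, TruthLabels]:
    """Single-patient, doublet-free sample (post-demultiplexing view)."""
    config = CohortConfig(
        patients=[patient],
        n_cells=n_cells,
        doublet_rate=0.0,
        timepoints=timepoint,
        seed=seed,
        **overrides,
    )
    matrix, antibody, _, truth = generate_multiplex_run(config)
    return matrix, antibody, truth


# ---------------------------------------------------------------------------
# default study-condition cohort
# ---------------------------------------------------------------------------


def default_patient(patient_id: str, index: int = 0) -> PatientSpec:
    """The default clonal architecture planted in every synthetic patient.

    A CH clone (persisting in remission, normal-like phenotype) founds a
    dominant leukemic clone carrying three additional variants, whose child
    subclone gains a fourth variant and loses one of the inherited variants
    through LOH of the alt allele.  Diagnosis: 70 % mutated cells (60 %
    blasts); remission: leukemia eradicated, CH persists at 15 %.
    """
    off = 10_000 * index
    variants = {
        "dnmt3a": VariantRecord("2", 25_457_242 + off, "C", "T", gene="DNMT3A",
                                protein_change="p.R882H"),
        "idh2": VariantRecord("15", 90_631_934 + off, "C", "T", gene="IDH2",
                              protein_change="p.R140Q"),
        "srsf2": VariantRecord("17", 74_732_959 + off, "C", "A", gene="SRSF2",
                               protein_change="p.P95H"),
        "tet2": VariantRecord("4", 106_157_698 + off, "C", "T", gene="TET2",
                              protein_change="p.Q1523*", consequence="stop_gained"),
        "runx1": VariantRecord("21", 36_206_711 + off, "G", "T", gene="RUNX1",
                               protein_change="p.S303*", consequence="stop_gained"),
    }
    clones = [
        CloneSpec("CH", None, ("dnmt3a",), diagnosis_fraction=0.10,
                  remission_fraction=0.15),
        CloneSpec("blast1", "CH", ("idh2", "srsf2", "tet2"),
                  diagnosis_fraction=0.35),
        CloneSpec("blast2", "blast1", ("runx1",), diagnosis_fraction=0.25,
                  loh_events=(("tet2", "alt"),)),
    ]
    marker_means = {
        NORMAL_CLONE: dict(NORMAL_MARKER_MEANS),
        "CH": dict(NORMAL_MARKER_MEANS),
        "blast1": dict(BLAST_MARKER_MEANS),
        "blast2": dict(BLAST_MARKER_MEANS),
    }
    return PatientSpec(
        patient_id=patient_id,
        variants=variants,
        clones=clones,
        marker_means=marker_means,
        leukemic_variant_ids=(variants["idh2"].variant_id,
                              variants["srsf2"].variant_id),
        ch_variant_ids=(variants["dnmt3a"].variant_id,),
        loh_lost_variant_ids=(variants["tet2"].variant_id,),
    )


def default_cohort(n_patients: int = 3, seed: int = 0, **overrides) -> CohortConfig:
    """Study-condition multiplex: ``n_patients`` patients, 50 germline SNPs,
    5 % ADO / 5 % missing / 5 % doublets."""
    patients = [default_patient(f"P{i+1}", index=i) for i in range(n_patients)]
    return CohortConfig(patients=patients, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# longitudinal bulk simulators
# ---------------------------------------------------------------------------


def simulate_ddpcr_series(
    trajectory: Sequence[tuple[int, str, float]],
    assay: DdpcrAssay,
    replicates: int = 3,
    dna_copies_per_well: int = 10_000,
    seed: int = 0,
    false_positive_rate: float | None = None,
    dna_limited: Sequence[bool] | None = None,
) -> MrdSeries:
    """Simulate pooled-replicate ddPCR measurements along a VAF trajectory.

    ``trajectory`` lists ``(day, tissue, true_vaf_percent)`` with strictly
    increasing days per tissue.  Mutant allele counts are binomial draws at
    ``true_vaf + false-positive rate`` over ``replicates x copies``
    assessable alleles; the false-positive rate defaults to the assay's mean
    wildtype-well VAF.
    """
    days = {}
    for day, tissue, _ in trajectory:
        days.setdefault(tissue, []).append(day)
    for tissue, ds in days.items():
        if any(b <= a for a, b in zip(ds, ds[1:])):
            raise ValueError(f"trajectory days not strictly increasing in {tissue}")
    rng = np.random.default_rng(seed)
    if false_positive_rate is None:
        wells = assay.wildtype_well_vafs
        false_positive_rate = float(np.mean(wells)) / 100.0 if wells else 0.0

    alleles = replicates * dna_copies_per_well
    measurements = []
    allele_list = []
    for day, tissue, true_vaf in trajectory:
        p = min(1.0, true_vaf / 100.0 + false_positive_rate)
        mutant = rng.binomial(alleles, p)
        measurements.append((day, tissue, 100.0 * mutant / alleles))
        allele_list.append(alleles)
    return MrdSeries.from_measurements(
        measurements, lod=assay.lod, alleles=allele_list, dna_limited=dna_limited
    )


def relapse_trajectory() -> tuple[list[tuple[int, str, float]], int]:
    """A molecular-relapse scenario: clearance after induction, then an
    exponential re-expansion crossing the detection threshold.

    Returns the trajectory and the true relapse day (first day the true VAF
    re-crosses 10x its post-induction nadir).
    """
    points = [
        (0, "BM", 25.0),
        (35, "BM", 0.004),
        (90, "PB", 0.004),
        (150, "PB", 0.05),
        (210, "PB", 0.8),
        (270, "PB", 6.0),
    ]
    return points, 150


def stable_trajectory() -> tuple[list[tuple[int, str, float]], None]:
    """A non-relapse scenario: stable low-level positivity (no 10-fold rise,
    no negative-to-positive conversion)."""
    points = [
        (0, "BM", 30.0),
        (35, "BM", 0.1),
        (90, "PB", 0.1),
        (150, "PB", 0.1),
        (210, "PB", 0.1),
        (270, "PB", 0.1),
        (330, "PB", 0.1),
    ]
    return points, None


# ---------------------------------------------------------------------------
# error-corrected NGS simulator
# ---------------------------------------------------------------------------


def _betabinom_draws(
    n: int, mu: float, rho: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if mu <= 0:
        return np.zeros(size, dtype=np.int64)
    if rho <= 1e-12:
        return rng.binomial(n, mu, size=size)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return rng.binomial(n, rng.beta(a, b, size=size))


def simulate_ecngs_sites(
    n_sites: int,
    true_vaf: float,
    depth_per_strand: int,
    error_rate_per_strand: float,
    dispersion: float = 1e-4,
    seed: int = 0,
) -> list[EcngsSite]:
    """Strand-specific supporting counts for many independent sites.

    Supporting reads are true-variant binomial draws plus beta-binomial
    error draws per strand; every supporting read is one consensus family,
    so the unique-alternative-observation count equals total support.
    """
    if depth_per_strand <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate_per_strand < 1.0:
        raise ValueError("error rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sites = []
    n = depth_per_strand
    p_true = true_vaf / 100.0
    strand_counts = np.column_stack(
        [
            rng.binomial(n, p_true, size=n_sites)
            + _betabinom_draws(n, error_rate_per_strand, dispersion, n_sites, rng)
            for _ in range(2)
        ]
    )
    supp = np.minimum(strand_counts, n)
    for i in range(n_sites):
        f, r = int(supp[i, 0]), int(supp[i, 1])
        sites.append(
            EcngsSite(
                variant=f"site{i}",
                fwd_supporting=f,
                fwd_total=n,
                rev_supporting=r,
                rev_total=n,
                uao=f + r,
            )
        )
    return sites


def simulate_ecngs_counts(
    true_vaf: float,
    depth_per_strand: int,
    error_rate_per_strand: float,
    dispersion: float = 1e-4,
    seed: int = 0,
) -> EcngsSite:
    """One site's strand-specific counts (see :func:`simulate_ecngs_sites`)."""
    return simulate_ecngs_sites(
        1, true_vaf, depth_per_strand, error_rate_per_strand, dispersion, seed
    )[0]
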