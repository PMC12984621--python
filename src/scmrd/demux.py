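"""Germline-SNP demultiplexing of multiplexed single-cell runs.

Patients pooled into one run are separated by their germline SNP profiles.
A database holds one expected genotype vector per patient plus one per
unordered patient pair (the expected doublet profile: the per-locus mean
allele dosage of the two patients).  Each cell is assigned to the profile
maximising a per-locus categorical likelihood with a symmetric genotyping
error rate, then removal rules drop poorly genotyped cells, cells
discrepant with their best match, doublets and ambiguous assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import AntibodyCounts, CellGenotypeMatrix, Genotype

__all__ = [
    "GermlineProfile",
    "DemuxConfig",
    "DemuxDB",
    "DemuxAssignment",
    "DemuxResult",
    "build_profile_database",
    "score_cell",
    "apply_demux_qc",
    "demultiplex_run",
]

REMOVED = "REMOVED"


@dataclass
class GermlineProfile:
    """One patient's germline SNP genotypes (alt-allele dosage per locus)."""

    patient_id: str
    loci: list[tuple[str, int, str, str]]  # (chrom, 1-based pos, ref, alt)
    genotypes: np.ndarray  # 0/1/2 alt copies per locus

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(self.loci) != self.genotypes.size:
            raise ValueError("locus list and genotype vector length differ")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError(f"duplicate loci in profile {self.patient_id}")
        if self.genotypes.size and (
            self.genotypes.min() < 0 or self.genotypes.max() > 2
        ):
            raise ValueError("germline genotypes must be 0, 1 or 2")

    @property
    def locus_ids(self) -> list[str]:
        return [f"{c}:{p}:{r}>{a}" for c, p, r, a in self.loci]


@dataclass
class DemuxConfig:
    """Cell-removal thresholds (defaults are the pipeline's settings)."""

    min_genotyped_fraction: float = 0.30
    max_discrepancies: int = 10
    max_discrepancy_fraction: float = 0.30
    genotyping_error_rate: float = 0.01


@dataclass
class DemuxDB:
    """Expected-genotype database over singlet and doublet profiles."""

    loci: list[tuple[str, int, str, str]]
    keys: list[str | tuple[str, str]]
    expected_dosage: np.ndarray  # profiles x loci, may be half-integer
    log_probs: np.ndarray  # profiles x loci x 3
    support: np.ndarray  # profiles x loci x 3 bool: genotypes consistent with profile
    error_rate: float

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [f"{c}:{p}:{r}>{a}" for c, p, r, a in self.loci]

    def is_doublet_key(self, key) -> bool:
        return isinstance(key, tuple)


def _observation_model(dosage: np.ndarray, error_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus probabilities over observed genotypes {0,1,2}.

    Genotypes within 0.5 of the expected dosage form the consistent support
    set and share probability ``1 - eps``; the remainder share ``eps``.
    For integer dosages this is the symmetric error model (1 - eps on the
    expected genotype, eps/2 elsewhere).
    """
    codes = np.arange(3)[None, :]
    support = np.abs(codes - dosage[:, None]) <= 0.5
    n_in = support.sum(axis=1, keepdims=True)
    probs = np.where(
        support,
        (1.0 - error_rate) / n_in,
        error_rate / np.maximum(3 - n_in, 1),
    )
    return np.log(probs), support


def build_profile_database(
    profiles: Sequence[GermlineProfile],
    error_rate: float = 0.01,
) -> DemuxDB:
    """Build singlet + doublet expected genotype profiles.

    All patients must share one locus set.  Indistinguishable (identical)
    patient profiles trigger a warning.  The doublet profile for a pair is
    the per-locus mean of the two patients' allele dosages.
    """
    if len(profiles) < 2:
        raise ValueError("demultiplexing needs >= 2 patient profiles")
    loci = profiles[0].loci
    for p in profiles[1:]:
        if p.loci != loci:
            raise ValueError("all patients must share the same SNP locus set")
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            if np.array_equal(profiles[i].genotypes, profiles[j].genotypes):
                warnings.warn(
                    "indistinguishable patients: "
                    f"{profiles[i].patient_id} and {profiles[j].patient_id}",
                    stacklevel=2,
                )

    keys: list[str | tuple[str, str]] = []
    dosages = []
    for p in profiles:
        keys.append(p.patient_id)
        dosages.append(p.genotypes.astype(float))
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            pair = tuple(sorted((profiles[i].patient_id, profiles[j].patient_id)))
            keys.append(pair)  # type: ignore[arg-type]
            dosages.append(
                (profiles[i].genotypes + profiles[j].genotypes).astype(float) / 2.0
            )

    dosage_arr = np.vstack(dosages)
    logp = np.empty((len(keys), len(loci), 3))
    support = np.empty((len(keys), len(loci), 3), dtype=bool)
    for k, d in enumerate(dosage_arr):
        logp[k], support[k] = _observation_model(d, error_rate)
    return DemuxDB(
        loci=list(loci),
        keys=keys,
        expected_dosage=dosage_arr,
        log_probs=logp,
        support=support,
        error_rate=error_rate,
    )


@dataclass
class DemuxAssignment:
    barcode: str
    best_match: str | tuple[str, str]
    n_genotyped_snps: int
    n_discrepancies: int
    discrepancy_fraction: float
    log_likelihood: float
    reason: str | None = None  # populated when best_match == REMOVED


def _loglik_matrix(obs: np.ndarray, db: DemuxDB) -> np.ndarray:
    """Log-likelihood of every cell (rows of ``obs``) under every profile."""
    n_cells = obs.shape[0]
    ll = np.zeros((n_cells, len(db.keys)))
    for g in range(3):
        ind = (obs == g).astype(float)  # cells x loci
        ll += ind @ db.log_probs[:, :, g].T
    return ll


def score_cell(
    cell_genotypes: np.ndarray, db: DemuxDB, barcode: str = ""
) -> DemuxAssignment:
    """Assign one cell to the best-matching singlet or doublet profile.

    ``cell_genotypes`` holds per-locus codes (0/1/2, ``-1`` missing) in the
    database locus order.  Ties in the best log-likelihood are conservative:
    the cell is removed as ambiguous.
    """
    obs = np.asarray(cell_genotypes, dtype=np.int8)[None, :]
    genotyped = obs[0] >= 0
    n_geno = int(genotyped.sum())
    if n_geno == 0:
        return DemuxAssignment(
            barcode, REMOVED, 0, 0, 0.0, float("-inf"), reason="no informative SNPs"
        )
    ll = _loglik_matrix(obs, db)[0]
    order = np.argsort(ll)[::-1]
    best = int(order[0])
    if len(order) > 1 and abs(ll[best] - ll[int(order[1])]) < 1e-9:
        return DemuxAssignment(
            barcode, REMOVED, n_geno, 0, 0.0, float(ll[best]), reason="ambiguous"
        )
    consistent = db.support[best][np.arange(db.n_loci), np.clip(obs[0], 0, 2)]
    n_disc = int((~consistent & genotyped).sum())
    return DemuxAssignment(
        barcode,
        db.keys[best],
        n_geno,
        n_disc,
        n_disc / n_geno,
        float(ll[best]),
    )


def apply_demux_qc(
    assignment: DemuxAssignment,
    total_db_snps: int,
    config: DemuxConfig | None = None,
) -> tuple[bool, str | None]:
    """Keep/remove decision for one assignment.

    A cell is removed when genotyped in < 30 % of database SNPs, when it has
    >= 10 genotype discrepancies with its best match, when the discrepancy
    fraction is >= 30 %, or when the best match is a doublet profile.  Any
    rule violation removes (the strict disjunctive reading).
    """
    cfg = config or DemuxConfig()
    if assignment.best_match == REMOVED:
        return False, assignment.reason
    if total_db_snps > 0 and (
        assignment.n_genotyped_snps / total_db_snps < cfg.min_genotyped_fraction
    ):
        return False, "low genotyping fraction"
    if assignment.n_discrepancies >= cfg.max_discrepancies:
        return False, "discrepancy count"
    if assignment.discrepancy_fraction >= cfg.max_discrepancy_fraction:
        return False, "discrepancy fraction"
    if isinstance(assignment.best_match, tuple):
        return False, "doublet"
    return True, None


@dataclass
class DemuxResult:
    assignments: list[DemuxAssignment]
    partitions: dict[str, tuple[CellGenotypeMatrix, AntibodyCounts]]
    removed: list[tuple[str, str]]  # (barcode, reason)

    @property
    def n_assigned(self) -> int:
        return sum(m.n_cells for m, _ in self.partitions.values())


def demultiplex_run(
    matrix: CellGenotypeMatrix,
    antibody_counts: AntibodyCounts,
    db: DemuxDB,
    config: DemuxConfig | None = None,
) -> DemuxResult:
    """Partition a multiplexed run into per-patient matrices.

    Every input barcode lands in exactly one output partition or in the
    removal report (conservation).  Scoring is vectorised over cells.
    """
    cfg = config or DemuxConfig()
    if matrix.barcodes != antibody_counts.barcodes:
        raise ValueError("barcode mismatch between genotype and antibody matrices")

    # map database loci onto matrix columns
    cols = [matrix.variant_index(lid) for lid in db.locus_ids]
    obs = matrix.genotype[:, cols]
    genotyped = obs >= 0
    n_geno = genotyped.sum(axis=1)

    ll = _loglik_matrix(obs, db)
    order = np.argsort(ll, axis=1)
    best = order[:, -1]
    runner = order[:, -2] if ll.shape[1] > 1 else best
    tied = np.abs(ll[np.arange(len(best)), best] - ll[np.arange(len(best)), runner]) < 1e-9

    # discrepancies of each cell with its best profile
    clip_obs = np.clip(obs, 0, 2)
    consistent = db.support[best[:, None], np.arange(db.n_loci)[None, :], clip_obs]
    n_disc = (~consistent & genotyped).sum(axis=1)

    assignments: list[DemuxAssignment] = []
    kept_by_patient: dict[str, list[int]] = {}
    removed: list[tuple[str, str]] = []
    for i, bc in enumerate(matrix.barcodes):
        if n_geno[i] == 0:
            a = DemuxAssignment(
                bc, REMOVED, 0, 0, 0.0, float("-inf"), reason="no informative SNPs"
            )
        elif tied[i]:
            a = DemuxAssignment(
                bc,
                REMOVED,
                int(n_geno[i]),
                0,
                0.0,
                float(ll[i, best[i]]),
                reason="ambiguous",
            )
        else:
            a = DemuxAssignment(
                bc,
                db.keys[best[i]],
                int(n_geno[i]),
                int(n_disc[i]),
                float(n_disc[i] / n_geno[i]),
                float(ll[i, best[i]]),
            )
        assignments.append(a)
        keep, reason = apply_demux_qc(a, db.n_loci, cfg)
        if keep:
            kept_by_patient.setdefault(str(a.best_match), []).append(i)
        else:
            removed.append((bc, reason or "removed"))

    partitions = {
        pid: (matrix.subset_cells(idx), antibody_counts.subset_cells(idx))
        for pid, idx in kept_by_patient.items()
    }
    result = DemuxResult(assignments=assignments, partitions=partitions, removed=removed)
    assert result.n_assigned + len(removed) == matrix.n_cells
    return result
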