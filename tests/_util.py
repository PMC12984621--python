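"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from scmrd.matrix import CellGenotypeMatrix, Genotype, VariantRecord

# allele fractions consistent with each genotype call under default thresholds
_AF = {
    Genotype.WT: 0.0,
    Genotype.HET: 0.5,
    Genotype.HOM: 1.0,
    Genotype.MISSING: 0.0,
}


def make_matrix(
    genotype_rows: list[list[int]], variants: list[VariantRecord]
) -> CellGenotypeMatrix:
    """Build a matrix from genotype codes with QC values consistent with the
    default genotyping thresholds (depth 100 / GQ 99, failing QC for MISSING)."""
    geno = np.asarray(genotype_rows, dtype=np.int8)
    n, m = geno.shape
    missing = geno == Genotype.MISSING
    af = np.vectorize(lambda g: _AF[Genotype(int(g))])(geno).astype(np.float32)
    depth = np.where(missing, 0, 100).astype(np.int32)
    gq = np.where(missing, 0, 99).astype(np.int16)
    return CellGenotypeMatrix(
        barcodes=[f"C{i:04d}" for i in range(n)],
        variants=variants,
        genotype=geno,
        depth=depth,
        gq=gq,
        af=af,
    )


def simple_variants(n: int, chrom: str = "7", start: int = 1_000_000,
                    spacing: int = 10_000) -> list[VariantRecord]:
    """n well-separated missense variants on one chromosome."""
    return [
        VariantRecord(chrom, start + i * spacing, "A", "T", gene=f"G{i}")
        for i in range(n)
    ]


def filter_toy_fixture() -> tuple[CellGenotypeMatrix, dict[str, str]]:
    """Eight candidate variants, each but one violating exactly one designed
    variant filter; returns the matrix and variant_id -> designed-violation.

    Mutated-cell sets are laid out so that no unintended co-occurrence
    (>= 3 shared mutated cells) exempts the strict-count or proximity
    filters for the designed violators.
    """
    W, H, M = int(Genotype.WT), int(Genotype.HET), int(Genotype.HOM)
    variants = [
        VariantRecord("1", 10_000, "A", "T", gene="CLEAN"),
        VariantRecord("3", 20_000, "A", "T", gene="LOW3"),
        VariantRecord("5", 30_000, "A", "T", gene="SYN",
                      consequence="synonymous_variant"),
        VariantRecord("2", 5_000, "A", "T", gene="HPOLY", homopolymer_adjacent=True),
        VariantRecord("2", 5_200, "A", "T", gene="PROX"),
        VariantRecord("6", 40_000, "A", "T", gene="LOW6"),
        VariantRecord("8", 50_000, "A", "T", gene="NOHOM"),
        VariantRecord("9", 60_000, "A", "T", gene="GERM", pop_af=0.002),
    ]
    n_cells = 30
    geno = np.full((n_cells, len(variants)), W, dtype=int)

    def mutate(col: int, cells: range, hom_first: bool = True) -> None:
        for j, c in enumerate(cells):
            geno[c, col] = M if (hom_first and j == 0) else H

    mutate(0, range(0, 10))        # CLEAN: 10 cells, 1 HOM
    mutate(1, range(28, 30), hom_first=False)  # LOW3: 2 cells
    mutate(2, range(0, 10))        # SYN
    mutate(3, range(10, 20))       # HPOLY (disjoint from PROX cells)
    mutate(4, range(0, 7))         # PROX: within 300 bp of HPOLY
    mutate(5, range(20, 25))       # LOW6: 5 cells, disjoint from all others
    mutate(6, range(10, 20), hom_first=False)  # NOHOM: 10 HET, no HOM
    mutate(7, range(0, 10))        # GERM: population AF 0.2 %
    matrix = make_matrix(geno.tolist(), variants)
    designed = {
        variants[1].variant_id: "min_mutated_cells",
        variants[2].variant_id: "synonymous",
        variants[3].variant_id: "homopolymer",
        variants[4].variant_id: "proximity",
        variants[5].variant_id: "min_mutated_cells_strict",
        variants[6].variant_id: "hom_cells",
        variants[7].variant_id: "germline",
    }
    return matrix, designed
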