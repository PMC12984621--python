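"""Core in-memory containers for single-cell DNA + protein data.

The central object is :class:`CellGenotypeMatrix`: per-cell, per-locus
genotype calls together with the read depth, genotype quality and cell-level
allele fraction that produced them.  Genotypes are stored as small integer
codes (:class:`Genotype`) in a dense ``int8`` matrix; ``MISSING`` entries
carry no genotype and are excluded from all downstream statistics.

:class:`AntibodyCounts` holds the raw oligo-conjugated antibody (AOC) counts
for the surface-marker panel; normalisation lives in :mod:`scmrd.immuno`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "VariantRecord",
    "CellGenotypeMatrix",
    "AntibodyCounts",
]


class Genotype(IntEnum):
    """Integer genotype codes for a diploid locus."""

    MISSING = -1
    WT = 0
    HET = 1
    HOM = 2


@dataclass(frozen=True)
class VariantRecord:
    """A single candidate variant with the annotations the filters consume.

    ``pop_af`` is a gnomAD-style population allele frequency (``None`` when
    the variant is absent from the population database).  ``germline_flag``
    marks variants labelled germline in a user-provided VCF.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    protein_change: str = ""
    consequence: str = "missense_variant"
    pop_af: float | None = None
    homopolymer_adjacent: bool = False
    germline_flag: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"population AF out of [0,1]: {self.pop_af}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def synonymous(self) -> bool:
        return "synonymous" in self.consequence


@dataclass
class CellGenotypeMatrix:
    """Dense cell x variant genotype matrix with per-entry QC values.

    Attributes
    ----------
    barcodes
        Cell barcode per row.
    variants
        :class:`VariantRecord` per column.
    genotype
        ``int8`` codes from :class:`Genotype`.
    depth, gq, af
        Read depth, genotype quality and allele fraction per entry.  Entries
        coded ``MISSING`` keep their (failing) depth/GQ values so that the
        genotyping rule can be re-applied.
    """

    barcodes: list[str]
    variants: list[VariantRecord]
    genotype: np.ndarray
    depth: np.ndarray
    gq: np.ndarray
    af: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.barcodes), len(self.variants)
        for name in ("genotype", "depth", "gq", "af"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n, m):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n, m)}"
                )
            setattr(self, name, arr)
        if self.af.size and (np.nanmin(self.af) < 0 or np.nanmax(self.af) > 1):
            raise ValueError("allele fractions must lie in [0, 1]")
        self.genotype = self.genotype.astype(np.int8, copy=False)

    # -- shape -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, index: Sequence[int] | np.ndarray) -> "CellGenotypeMatrix":
        index = np.asarray(index)
        return CellGenotypeMatrix(
            barcodes=[self.barcodes[i] for i in index],
            variants=self.variants,
            genotype=self.genotype[index],
            depth=self.depth[index],
            gq=self.gq[index],
            af=self.af[index],
        )

    def subset_variants(self, variant_ids: Iterable[str]) -> "CellGenotypeMatrix":
        wanted = list(variant_ids)
        cols = [self.variant_index(v) for v in wanted]
        return CellGenotypeMatrix(
            barcodes=self.barcodes,
            variants=[self.variants[c] for c in cols],
            genotype=self.genotype[:, cols],
            depth=self.depth[:, cols],
            gq=self.gq[:, cols],
            af=self.af[:, cols],
        )


@dataclass
class AntibodyCounts:
    """Raw antibody-oligo counts: cells x surface markers."""

    barcodes: list[str]
    markers: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.markers)):
            raise ValueError("counts shape does not match barcodes x markers")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("antibody counts must be non-negative")

    def subset_cells(self, index: Sequence[int] | np.ndarray) -> "AntibodyCounts":
        index = np.asarray(index)
        return AntibodyCounts(
            barcodes=[self.barcodes[i] for i in index],
            markers=self.markers,
            counts=self.counts[index],
        )
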