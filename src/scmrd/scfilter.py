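"""Cell-level genotyping, variant-level filtering and pseudobulk VAF.

The genotyping rule turns raw (depth, genotype quality, allele fraction)
triples into ``WT``/``HET``/``HOM``/``MISSING`` calls; the variant filters
then remove artefact-prone and germline candidates.  Each filter is an
independent predicate of the *unfiltered* matrix, so the surviving set does
not depend on the order in which filters are listed; the proximity filter is
pairwise over the full candidate list for the same reason.

Pseudobulk VAF is computed from mutated-cell fractions with zygosity
weighting: a heterozygous cell contributes one alternate allele, a
homozygous cell two, out of two alleles per informative cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .matrix import CellGenotypeMatrix, Genotype

__all__ = [
    "FilterConfig",
    "FilterReport",
    "ForcedCall",
    "genotype_cell_entry",
    "regenotype",
    "apply_variant_filters",
    "pseudobulk_vaf",
    "panel_uniformity",
    "force_call",
]


@dataclass
class FilterConfig:
    """Thresholds for genotyping and variant filtering.

    Defaults follow the vendor-pipeline settings used throughout:
    depth >= 10, GQ >= 30, cell allele fraction >= 35 % to call a cell
    mutated (>= 90 % for homozygous), >= 3 mutated cells, >= 6 mutated cells
    unless co-occurring, 300 bp mutual proximity, population AF >= 0.1 %
    treated as germline, and >= 1 homozygous cell (expected under allelic
    dropout).  Panel uniformity below 80 % flags a run as prone to false
    negatives.
    """

    min_depth: int = 10
    min_gq: int = 30
    min_cell_af: float = 0.35
    hom_af: float = 0.90
    min_mutated_cells: int = 3
    min_mutated_cells_strict: int = 6
    proximity_bp: int = 300
    max_pop_af: float = 0.001
    min_hom_cells: int = 1
    cooccur_min_cells: int = 3
    uniformity_floor: float = 0.80
    uniformity_rel_coverage: float = 0.2


FILTER_NAMES = (
    "min_mutated_cells",
    "synonymous",
    "homopolymer",
    "proximity",
    "min_mutated_cells_strict",
    "hom_cells",
    "germline",
)


def genotype_cell_entry(
    depth: int, gq: float, allele_fraction: float, config: FilterConfig | None = None
) -> Genotype:
    """Genotype one cell x variant entry.

    ``MISSING`` when depth or genotype quality fail QC; otherwise the cell is
    called mutated when the allele fraction reaches ``min_cell_af`` (``HOM``
    at ``hom_af`` and above, ``HET`` below), else ``WT``.
    """
    cfg = config or FilterConfig()
    if not 0.0 <= allele_fraction <= 1.0:
        raise ValueError("allele fraction must lie in [0, 1]")
    if depth < cfg.min_depth or gq < cfg.min_gq:
        return Genotype.MISSING
    if allele_fraction >= cfg.hom_af:
        return Genotype.HOM
    if allele_fraction >= cfg.min_cell_af:
        return Genotype.HET
    return Genotype.WT


def regenotype(matrix: CellGenotypeMatrix, config: FilterConfig | None = None) -> np.ndarray:
    """Vectorised :func:`genotype_cell_entry` over a whole matrix."""
    cfg = config or FilterConfig()
    geno = np.where(
        matrix.af >= cfg.hom_af,
        Genotype.HOM,
        np.where(matrix.af >= cfg.min_cell_af, Genotype.HET, Genotype.WT),
    )
    missing = (matrix.depth < cfg.min_depth) | (matrix.gq < cfg.min_gq)
    geno = np.where(missing, Genotype.MISSING, geno)
    return geno.astype(np.int8)


@dataclass
class FilterReport:
    """Ordered pass/fail record per candidate variant."""

    decisions: dict[str, list[tuple[str, bool]]]
    surviving: list[str]
    cooccurring: set[frozenset[str]] = field(default_factory=set)

    def failed_filters(self, variant_id: str) -> list[str]:
        return [name for name, ok in self.decisions[variant_id] if not ok]


def _cooccurring_pairs(
    matrix: CellGenotypeMatrix,
    declared: Iterable[tuple[str, str]] | None,
    min_cells: int,
) -> set[frozenset[str]]:
    """Variant pairs mutated together in >= ``min_cells`` cells, plus any
    user-declared pairs."""
    mutated = matrix.genotype >= Genotype.HET  # cells x variants
    pairs: set[frozenset[str]] = set()
    ids = matrix.variant_ids
    co = mutated.astype(np.int32).T @ mutated.astype(np.int32)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if co[i, j] >= min_cells:
                pairs.add(frozenset((ids[i], ids[j])))
    for a, b in declared or ():
        pairs.add(frozenset((a, b)))
    return pairs


def apply_variant_filters(
    matrix: CellGenotypeMatrix,
    declared_cooccurring: Iterable[tuple[str, str]] | None = None,
    config: FilterConfig | None = None,
) -> FilterReport:
    """Run every variant-level filter and record each decision.

    A variant survives iff all filters pass.  The co-occurrence exemption
    applies to the strict mutated-cell count and, pair-wise, to the 300 bp
    proximity filter.
    """
    cfg = config or FilterConfig()
    ids = matrix.variant_ids
    mutated = matrix.genotype >= Genotype.HET
    hom = matrix.genotype == Genotype.HOM
    n_mut = mutated.sum(axis=0)
    n_hom = hom.sum(axis=0)

    pairs = _cooccurring_pairs(matrix, declared_cooccurring, cfg.cooccur_min_cells)
    in_cooccur = {v for p in pairs for v in p}

    # proximity: any other candidate within proximity_bp on the same chrom,
    # unless that particular pair is co-occurring
    proximal = np.zeros(len(ids), dtype=bool)
    for i, vi in enumerate(matrix.variants):
        for j, vj in enumerate(matrix.variants):
            if i == j or vi.chrom != vj.chrom:
                continue
            if abs(vi.pos - vj.pos) <= cfg.proximity_bp:
                if frozenset((ids[i], ids[j])) not in pairs:
                    proximal[i] = True

    decisions: dict[str, list[tuple[str, bool]]] = {}
    surviving: list[str] = []
    for i, (vid, v) in enumerate(zip(ids, matrix.variants)):
        checks = [
            ("min_mutated_cells", int(n_mut[i]) >= cfg.min_mutated_cells),
            ("synonymous", not v.synonymous),
            ("homopolymer", not v.homopolymer_adjacent),
            ("proximity", not proximal[i]),
            (
                "min_mutated_cells_strict",
                int(n_mut[i]) >= cfg.min_mutated_cells_strict or vid in in_cooccur,
            ),
            ("hom_cells", int(n_hom[i]) >= cfg.min_hom_cells),
            (
                "germline",
                not (
                    (v.pop_af is not None and v.pop_af >= cfg.max_pop_af)
                    or v.germline_flag
                ),
            ),
        ]
        decisions[vid] = checks
        if all(ok for _, ok in checks):
            surviving.append(vid)
    return FilterReport(decisions=decisions, surviving=surviving, cooccurring=pairs)


def pseudobulk_vaf(matrix: CellGenotypeMatrix, variant_id: str) -> float | None:
    """Zygosity-aware pseudobulk VAF in percent.

    ``VAF = 100 * (n_HET + 2 * n_HOM) / (2 * n_informative)``.  Returns
    ``None`` (not assessable) when no cell carries a genotype at the locus.
    """
    col = matrix.genotype[:, matrix.variant_index(variant_id)]
    informative = col != Genotype.MISSING
    n_inf = int(informative.sum())
    if n_inf == 0:
        return None
    n_het = int((col == Genotype.HET).sum())
    n_hom = int((col == Genotype.HOM).sum())
    return 100.0 * (n_het + 2 * n_hom) / (2 * n_inf)


def panel_uniformity(
    per_amplicon_mean_coverage: Sequence[float],
    config: FilterConfig | None = None,
) -> tuple[float, bool]:
    """Fraction of amplicons with mean coverage >= 0.2x the panel mean.

    Returns ``(uniformity, low_uniformity_flag)``; a flagged run warrants
    force-calling of known variants missing from the filtered output.
    """
    cfg = config or FilterConfig()
    cov = np.asarray(per_amplicon_mean_coverage, dtype=float)
    if cov.size == 0:
        raise ValueError("empty coverage vector")
    uniformity = float(np.mean(cov >= cfg.uniformity_rel_coverage * cov.mean()))
    return uniformity, uniformity < cfg.uniformity_floor


@dataclass
class ForcedCall:
    variant_id: str
    genotypes: np.ndarray
    vaf: float | None
    forced: bool = True


def force_call(
    matrix: CellGenotypeMatrix, variant_id: str, config: FilterConfig | None = None
) -> ForcedCall:
    """Genotype a known variant, bypassing the variant-level filters.

    Cell-level QC (depth/GQ/allele fraction) still applies.  A locus absent
    from the panel cannot be rescued and raises ``KeyError('not in panel')``.
    """
    try:
        col = matrix.variant_index(variant_id)
    except KeyError:
        raise KeyError(f"not in panel: {variant_id}") from None
    geno = regenotype(matrix, config)[:, col]
    informative = geno != Genotype.MISSING
    if informative.sum() == 0:
        vaf: float | None = None
    else:
        n_het = int((geno == Genotype.HET).sum())
        n_hom = int((geno == Genotype.HOM).sum())
        vaf = 100.0 * (n_het + 2 * n_hom) / (2 * int(informative.sum()))
    return ForcedCall(variant_id=variant_id, genotypes=geno, vaf=vaf, forced=True)
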