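"""Five-criterion MRD target selection over candidate variants.

A candidate variant is an eligible MRD target when it (1) sits in a large
clone at diagnosis — aggregate pseudobulk VAF of at least 10 %, one mutated
allele in 20 % blasts; (2) clears to below 1 % VAF after the first induction
course; (3) is carried only by clones with a distinct, immature and
aberrant immunophenotype; (4) is not missing or LOH-lost in any more
advanced clone; and (5) is not in a gene known to occasionally turn
negative at relapse (RAS-pathway and FLT3 by default).

Eligible targets are ranked by validated assay sensitivity (ascending LoD)
when assay LoDs are supplied, otherwise by descending diagnosis VAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .clones import CloneGraph
from .immuno import ImmunophenotypeProfile
from .matrix import CellGenotypeMatrix, Genotype
from .scfilter import FilterConfig, force_call, pseudobulk_vaf

__all__ = [
    "Blacklist",
    "CriteriaConfig",
    "CriteriaResult",
    "evaluate_criteria",
    "select_targets",
]

DEFAULT_BLACKLIST = frozenset({"NRAS", "KRAS", "FLT3"})


@dataclass(frozen=True)
class Blacklist:
    """Genes whose mutations may disappear at relapse."""

    genes: frozenset[str] = DEFAULT_BLACKLIST

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def with_gene(self, gene: str) -> "Blacklist":
        return Blacklist(self.genes | {gene})


@dataclass
class CriteriaConfig:
    min_diagnosis_vaf: float = 10.0  # percent, aggregate across clones
    max_remission_vaf: float = 1.0  # percent (exclusive bound)
    aggregate_vaf: bool = True  # False: largest single carrying clone
    require_all_clones_aberrant: bool = True  # False: any carrying clone suffices


@dataclass
class CriteriaResult:
    variant_id: str
    gene: str
    c1_large_clone: bool
    diagnosis_vaf: float | None
    c2_cleared: bool
    remission_vaf: float | None
    c3_aberrant_clone: bool
    c3_clone_ids: list[str]
    c4_not_lost: bool
    c4_violating_clones: list[str]
    c5_not_blacklisted: bool
    not_assessable: str | None = None  # reason when a criterion could not be judged

    @property
    def eligible(self) -> bool:
        return (
            self.not_assessable is None
            and self.c1_large_clone
            and self.c2_cleared
            and self.c3_aberrant_clone
            and self.c4_not_lost
            and self.c5_not_blacklisted
        )

    @property
    def failed_criteria(self) -> list[str]:
        failed = []
        for name, ok in (
            ("c1", self.c1_large_clone),
            ("c2", self.c2_cleared),
            ("c3", self.c3_aberrant_clone),
            ("c4", self.c4_not_lost),
            ("c5", self.c5_not_blacklisted),
        ):
            if not ok:
                failed.append(name)
        if self.not_assessable:
            failed.append(f"not_assessable:{self.not_assessable}")
        return failed


def _largest_clone_vaf(variant_id: str, graph: CloneGraph) -> float:
    total = sum(c.n_cells for c in graph.clones.values())
    if total == 0:
        return 0.0
    best = 0.0
    for c in graph.clones.values():
        g = c.genotype.get(variant_id, Genotype.WT)
        if g >= Genotype.HET:
            dosage = 2 if g == Genotype.HOM else 1
            best = max(best, 100.0 * dosage * c.n_cells / (2.0 * total))
    return best


def evaluate_criteria(
    variant_id: str,
    diagnosis_matrix: CellGenotypeMatrix,
    remission_matrix: CellGenotypeMatrix | None,
    clone_graph: CloneGraph,
    immuno_profiles: Mapping[str, ImmunophenotypeProfile],
    blacklist: Blacklist | None = None,
    config: CriteriaConfig | None = None,
    filter_config: FilterConfig | None = None,
) -> CriteriaResult:
    """Evaluate all five criteria for one diagnosis-run candidate.

    The remission VAF is re-genotyped from the remission matrix even when
    the variant fell out of the remission variant list (absence from a
    covered panel locus means VAF 0); a variant at a locus the remission
    panel does not cover is not assessable and therefore ineligible.
    """
    blk = blacklist or Blacklist()
    cfg = config or CriteriaConfig()
    gene = diagnosis_matrix.variants[diagnosis_matrix.variant_index(variant_id)].gene

    not_assessable: str | None = None
    if cfg.aggregate_vaf:
        diag_vaf = pseudobulk_vaf(diagnosis_matrix, variant_id)
    else:
        diag_vaf = _largest_clone_vaf(variant_id, clone_graph)
    c1 = diag_vaf is not None and diag_vaf >= cfg.min_diagnosis_vaf

    rem_vaf: float | None = None
    c2 = False
    if remission_matrix is None:
        not_assessable = "no remission run"
    else:
        try:
            rem_vaf = force_call(remission_matrix, variant_id, filter_config).vaf
        except KeyError:
            not_assessable = "locus not covered in remission panel"
        else:
            if rem_vaf is None:
                not_assessable = "no informative remission cells"
            else:
                c2 = rem_vaf < cfg.max_remission_vaf

    carriers = [
        c
        for c in clone_graph.clones.values()
        if not c.is_wildtype and c.genotype.get(variant_id, Genotype.WT) >= Genotype.HET
    ]
    carrier_ids = [c.clone_id for c in carriers]
    flags = []
    for cid in carrier_ids:
        p = immuno_profiles.get(cid)
        flags.append(bool(p and p.assessable and p.immature and p.aberrant))
    if not carriers:
        c3 = False
    elif cfg.require_all_clones_aberrant:
        c3 = all(flags)
    else:
        c3 = any(flags)

    violating = []
    for parent_id, child_id in clone_graph.graph.edges():
        parent = clone_graph.clones[parent_id]
        child = clone_graph.clones[child_id]
        if (
            parent.genotype.get(variant_id, Genotype.WT) >= Genotype.HET
            and child.genotype.get(variant_id, Genotype.WT) == Genotype.WT
        ):
            violating.append(child_id)
    c4 = not violating

    c5 = gene not in blk

    return CriteriaResult(
        variant_id=variant_id,
        gene=gene,
        c1_large_clone=c1,
        diagnosis_vaf=diag_vaf,
        c2_cleared=c2,
        remission_vaf=rem_vaf,
        c3_aberrant_clone=c3,
        c3_clone_ids=carrier_ids,
        c4_not_lost=c4,
        c4_violating_clones=violating,
        c5_not_blacklisted=c5,
        not_assessable=not_assessable,
    )


def select_targets(
    results: Sequence[CriteriaResult],
    assay_lods: Mapping[str, float] | None = None,
) -> list[CriteriaResult]:
    """Rank eligible candidates into an MRD target list.

    With assay LoDs the most sensitive assay ranks first (ascending LoD,
    candidates without an LoD last); otherwise candidates rank by descending
    diagnosis VAF.  Ineligible candidates are excluded; their per-criterion
    failure reasons stay on the :class:`CriteriaResult` records.
    """
    eligible = [r for r in results if r.eligible]
    if assay_lods:
        eligible.sort(
            key=lambda r: (assay_lods.get(r.variant_id, float("inf")), r.variant_id)
        )
    else:
        eligible.sort(key=lambda r: (-(r.diagnosis_vaf or 0.0), r.variant_id))
    return eligible
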