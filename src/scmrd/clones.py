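"""Genotype-defined clone inference, developmental ordering and LOH calls.

Cells sharing a complete multi-locus genotype over the surviving somatic
variants form a clone.  Small genotype groups that differ from a larger
clone only by heterozygous-to-homozygous or heterozygous-to-wildtype flips
are attributed to allelic dropout and absorbed, because per-allele dropout
produces exactly those apparent genotypes; a genuine LOH subclone is kept
separate when it is large relative to its source clone or also carries its
own acquired variants.

Clones are ordered into a parent-child graph by genotype precedence: a
parent's mutated variants must either persist in the child or be lost
through an LOH event (heterozygous parent, wildtype child = alt allele
lost; homozygous child = ref allele lost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .matrix import CellGenotypeMatrix, Genotype

__all__ = [
    "Clone",
    "CloneConfig",
    "CloneResult",
    "CloneGraph",
    "infer_clones",
    "build_clone_graph",
    "detect_loh",
    "count_subclones",
]

WILDTYPE_CLONE = "wildtype"


@dataclass
class CloneConfig:
    min_clone_size: int = 6
    # a flips-only genotype group is absorbed into its source clone when its
    # size is below this fraction of the source clone's size
    ado_absorb_fraction: float = 0.3


@dataclass
class Clone:
    clone_id: str
    genotype: dict[str, Genotype]  # complete: no MISSING entries
    n_cells: int
    cell_indices: np.ndarray
    parent: str | None = None
    loh_events: list[tuple[str, str]] = field(default_factory=list)
    stage: str = ""

    @property
    def mutated_set(self) -> frozenset[str]:
        return frozenset(v for v, g in self.genotype.items() if g >= Genotype.HET)

    @property
    def is_wildtype(self) -> bool:
        return not self.mutated_set


@dataclass
class CloneResult:
    clones: list[Clone]  # non-wildtype
    wildtype: Clone | None
    unassigned: np.ndarray  # cell indices
    assignment: dict[str, str | None]  # barcode -> clone_id or None

    @property
    def all_clones(self) -> list[Clone]:
        return ([self.wildtype] if self.wildtype else []) + self.clones


def _flips_only(larger: tuple, smaller: tuple) -> bool:
    """True when ``smaller`` differs from ``larger`` only at sites where
    ``larger`` is HET and ``smaller`` is HOM or WT (an ADO signature)."""
    differs = False
    for a, b in zip(larger, smaller):
        if a == b:
            continue
        if a == Genotype.HET and b in (Genotype.WT, Genotype.HOM):
            differs = True
        else:
            return False
    return differs


def infer_clones(
    matrix: CellGenotypeMatrix, config: CloneConfig | None = None
) -> CloneResult:
    """Group cells into clones over the matrix's (post-filter) variants.

    Complete cells are grouped by exact genotype; ADO-signature groups are
    absorbed (see module docstring); groups below ``min_clone_size`` are
    dropped and their cells left unassigned.  Cells with missing genotypes
    are assigned when consistent with exactly one clone at every non-missing
    site, otherwise unassigned.  The fully wildtype population is reported
    separately.
    """
    cfg = config or CloneConfig()
    vids = matrix.variant_ids
    n = matrix.n_cells
    if n == 0 or not vids:
        return CloneResult([], None, np.arange(n), {bc: None for bc in matrix.barcodes})

    geno = matrix.genotype
    complete = ~(geno == Genotype.MISSING).any(axis=1)

    groups: dict[tuple, list[int]] = {}
    for i in np.flatnonzero(complete):
        groups.setdefault(tuple(int(g) for g in geno[i]), []).append(i)

    # largest groups seed clones; ADO-signature groups merge into them
    accepted: list[tuple[tuple, list[int]]] = []
    for key, members in sorted(groups.items(), key=lambda kv: -len(kv[1])):
        target = None
        best_size = 0
        for akey, amembers in accepted:
            if _flips_only(akey, key) and len(members) < cfg.ado_absorb_fraction * len(
                amembers
            ):
                if len(amembers) > best_size:
                    target, best_size = amembers, len(amembers)
        if target is not None:
            target.extend(members)
        else:
            accepted.append((key, members))

    clones: list[Clone] = []
    wildtype: Clone | None = None
    unassigned: list[int] = []
    idx = 0
    for key, members in accepted:
        genotype = {v: Genotype(g) for v, g in zip(vids, key)}
        is_wt = all(g == Genotype.WT for g in key)
        if not is_wt and len(members) < cfg.min_clone_size:
            unassigned.extend(members)
            continue
        clone = Clone(
            clone_id=WILDTYPE_CLONE if is_wt else f"clone{idx}",
            genotype=genotype,
            n_cells=len(members),
            cell_indices=np.asarray(sorted(members)),
        )
        if is_wt:
            wildtype = clone
        else:
            idx += 1
            clones.append(clone)

    # incomplete cells: unique-consistency assignment
    all_clones = ([wildtype] if wildtype else []) + clones
    clone_keys = [
        np.array([int(c.genotype[v]) for v in vids], dtype=np.int8) for c in all_clones
    ]
    extra: dict[int, list[int]] = {k: [] for k in range(len(all_clones))}
    for i in np.flatnonzero(~complete):
        row = geno[i]
        observed = row != Genotype.MISSING
        if not observed.any():
            unassigned.append(i)
            continue
        matches = [
            k
            for k, key in enumerate(clone_keys)
            if np.array_equal(row[observed], key[observed])
        ]
        if len(matches) == 1:
            extra[matches[0]].append(i)
        else:
            unassigned.append(i)

    for k, clone in enumerate(all_clones):
        if extra[k]:
            clone.cell_indices = np.asarray(
                sorted(clone.cell_indices.tolist() + extra[k])
            )
            clone.n_cells = len(clone.cell_indices)

    assignment: dict[str, str | None] = {bc: None for bc in matrix.barcodes}
    for clone in all_clones:
        for i in clone.cell_indices:
            assignment[matrix.barcodes[int(i)]] = clone.clone_id

    total = sum(c.n_cells for c in all_clones) + len(unassigned)
    assert total == n, "clone partition does not conserve cells"
    return CloneResult(
        clones=clones,
        wildtype=wildtype,
        unassigned=np.asarray(sorted(unassigned)),
        assignment=assignment,
    )


def detect_loh(parent: Clone, child: Clone) -> list[tuple[str, str]]:
    """LOH events turning the parent's genotype into the child's.

    A heterozygous parent site that is wildtype in the child lost the alt
    allele; one that is homozygous in the child lost the ref allele.  No LOH
    is derivable at sites where the parent is wildtype.
    """
    events = []
    for v, pg in parent.genotype.items():
        cg = child.genotype.get(v, Genotype.WT)
        if pg == Genotype.HET and cg == Genotype.WT:
            events.append((v, "alt"))
        elif pg == Genotype.HET and cg == Genotype.HOM:
            events.append((v, "ref"))
    return events


def _precedes(parent: Clone, child: Clone) -> bool:
    """Every mutated parent variant persists in the child or is LOH-lost."""
    if parent.genotype == child.genotype:
        return False
    for v, pg in parent.genotype.items():
        if pg >= Genotype.HET:
            cg = child.genotype.get(v, Genotype.WT)
            if cg >= Genotype.HET:
                continue
            if pg == Genotype.HET and cg == Genotype.WT:
                continue  # alt allele lost (LOH)
            return False
    return True


@dataclass
class CloneGraph:
    clones: dict[str, Clone]
    graph: nx.DiGraph
    non_tree: bool = False
    ambiguous: dict[str, list[str]] = field(default_factory=dict)

    def descendants(self, clone_id: str) -> set[str]:
        return nx.descendants(self.graph, clone_id)


def build_clone_graph(result: CloneResult) -> CloneGraph:
    """Order clones by developmental precedence.

    Clones are placed smallest mutated set first; each clone's parent is the
    already-placed clone passing the precedence test that maximises the
    number of inherited mutations (fewest LOH losses on ties).  Clones whose
    best parent is the wildtype population root there.  Ties between
    incomparable candidates are recorded and flag the graph as non-tree.
    """
    all_clones = result.all_clones
    if not all_clones:
        raise ValueError("no clones to order")
    wt = result.wildtype
    if wt is None:
        # synthesise an empty root so every clone has an anchor
        vids = list(all_clones[0].genotype)
        wt = Clone(
            clone_id=WILDTYPE_CLONE,
            genotype={v: Genotype.WT for v in vids},
            n_cells=0,
            cell_indices=np.array([], dtype=int),
        )
        all_clones = [wt] + result.clones

    graph = nx.DiGraph()
    for c in all_clones:
        graph.add_node(c.clone_id, n_cells=c.n_cells)

    order = sorted(
        (c for c in all_clones if c.clone_id != wt.clone_id),
        key=lambda c: (len(c.mutated_set), -c.n_cells, c.clone_id),
    )
    placed = [wt]
    ambiguous: dict[str, list[str]] = {}
    non_tree = False
    for c in order:
        candidates = [p for p in placed if _precedes(p, c)]
        scored = sorted(
            candidates,
            key=lambda p: (
                -len(p.mutated_set & c.mutated_set),
                len(detect_loh(p, c)),
                p.clone_id,
            ),
        )
        best = scored[0]
        ties = [
            p
            for p in scored[1:]
            if len(p.mutated_set & c.mutated_set)
            == len(best.mutated_set & c.mutated_set)
            and len(detect_loh(p, c)) == len(detect_loh(best, c))
        ]
        if ties:
            non_tree = True
            ambiguous[c.clone_id] = [best.clone_id] + [p.clone_id for p in ties]
        c.parent = best.clone_id
        c.loh_events = detect_loh(best, c)
        graph.add_edge(best.clone_id, c.clone_id, loh=c.loh_events)
        placed.append(c)

    # validity: every edge is explained by inheritance or recorded LOH
    for u, v, data in graph.edges(data=True):
        parent, child = next(c for c in all_clones if c.clone_id == u), next(
            c for c in all_clones if c.clone_id == v
        )
        lost = {vid for vid, _ in data["loh"]}
        for vid in parent.mutated_set:
            assert vid in child.mutated_set or vid in lost, (
                f"edge {u}->{v} unexplained at {vid}"
            )
    assert nx.is_directed_acyclic_graph(graph)
    return CloneGraph(
        clones={c.clone_id: c for c in all_clones},
        graph=graph,
        non_tree=non_tree,
        ambiguous=ambiguous,
    )


def count_subclones(result: CloneResult | Sequence[Clone]) -> int:
    """Number of non-wildtype clones."""
    clones = result.clones if isinstance(result, CloneResult) else list(result)
    return sum(1 for c in clones if not c.is_wildtype)
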