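"""Antibody-count normalisation and clone immunophenotyping.

Surface-marker counts are compositional (sequencing depth per cell is
arbitrary), so they are centred log-ratio (CLR) transformed per cell:
``CLR_i = log(c_i + pc) - mean_j log(c_j + pc)``.  A clone's immunophenotype
is the per-marker mean CLR over its cells; marker positivity, immaturity
(CD34 and/or CD117 positive) and aberrancy are then threshold decisions.

Aberrancy combines a different-from-normal (DfN) check — any clone-mean CLR
outside the reference range of the normal population — with declarative
leukemia-associated-immunophenotype (LAIP) rules and cross-lineage marker
positivity (lymphoid markers on a myeloid clone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clones import Clone
from .matrix import AntibodyCounts

__all__ = [
    "LaipRule",
    "ImmunophenotypeProfile",
    "ImmunoConfig",
    "clr_transform",
    "clr_matrix",
    "derive_reference_ranges",
    "clone_immunophenotype",
    "classify_aberrant",
]

IMMATURITY_MARKERS = ("CD34", "CD117")
CROSS_LINEAGE_MARKERS = ("CD3", "CD7", "CD19", "CD22", "CD56")


def clr_transform(counts_row: Sequence[float], pseudocount: float = 1.0) -> np.ndarray:
    """Centred log-ratio of one cell's marker counts (sums to zero)."""
    row = np.asarray(counts_row, dtype=float)
    if row.size == 0:
        raise ValueError("need at least one marker")
    logs = np.log(row + pseudocount)
    return logs - logs.mean()


def clr_matrix(antibody: AntibodyCounts, pseudocount: float = 1.0) -> np.ndarray:
    """Row-wise CLR over a whole antibody-count matrix."""
    logs = np.log(antibody.counts.astype(float) + pseudocount)
    return logs - logs.mean(axis=1, keepdims=True)


@dataclass(frozen=True)
class LaipRule:
    """A declarative leukemia-associated immunophenotype."""

    rule_id: str
    required_positive: tuple[str, ...] = ()
    required_negative: tuple[str, ...] = ()


@dataclass
class ImmunoConfig:
    pseudocount: float = 1.0
    positivity_thresholds: dict[str, float] | None = None  # marker -> CLR cutoff
    reference_ranges: dict[str, tuple[float, float]] | None = None
    laip_rules: tuple[LaipRule, ...] = ()
    cross_lineage_markers: tuple[str, ...] = CROSS_LINEAGE_MARKERS
    immaturity_markers: tuple[str, ...] = IMMATURITY_MARKERS


@dataclass
class ImmunophenotypeProfile:
    clone_id: str
    markers: list[str]
    mean_clr: np.ndarray
    positivity: dict[str, bool]
    immature: bool | None = None
    aberrant: bool | None = None
    matched_rules: list[str] = field(default_factory=list)
    assessable: bool = True


def derive_reference_ranges(
    reference_clr: np.ndarray,
    markers: Sequence[str],
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> dict[str, tuple[float, float]]:
    """Per-marker CLR reference band from a normal cell population.

    The band spans the given per-cell percentiles (default the central
    95 %); clone means outside it are different-from-normal.  The upper
    bound doubles as the default marker-positivity cutoff.
    """
    lo, hi = np.percentile(reference_clr, percentiles, axis=0)
    return {m: (float(lo[i]), float(hi[i])) for i, m in enumerate(markers)}


def clone_immunophenotype(
    clone: Clone,
    cell_clr: np.ndarray,
    markers: Sequence[str],
    config: ImmunoConfig | None = None,
) -> ImmunophenotypeProfile:
    """Per-marker mean CLR over the clone's cells, with positivity calls.

    Positivity is a property of the clone mean, so a minority subpopulation
    above the cutoff does not flip the clone-level call.  A clone with no
    antibody data yields a not-assessable profile.
    """
    cfg = config or ImmunoConfig()
    markers = list(markers)
    if clone.n_cells == 0 or cell_clr.shape[0] == 0:
        return ImmunophenotypeProfile(
            clone.clone_id, markers, np.full(len(markers), np.nan), {}, assessable=False
        )
    mean_clr = cell_clr[clone.cell_indices].mean(axis=0)
    thresholds = cfg.positivity_thresholds
    if thresholds is None:
        if cfg.reference_ranges is None:
            raise ValueError("no positivity thresholds or reference ranges configured")
        thresholds = {m: cfg.reference_ranges[m][1] for m in markers}
    positivity = {m: bool(mean_clr[i] >= thresholds[m]) for i, m in enumerate(markers)}
    return ImmunophenotypeProfile(clone.clone_id, markers, mean_clr, positivity)


def classify_aberrant(
    profile: ImmunophenotypeProfile,
    config: ImmunoConfig,
) -> ImmunophenotypeProfile:
    """Flag a clone profile as immature and/or aberrant.

    Immature: positive for CD34 and/or CD117.  Aberrant when any configured
    rule fires: a cross-lineage marker is positive, a LAIP rule matches, or
    a marker's clone-mean CLR falls outside its DfN reference range.  The
    matched rule ids are recorded; adding rules can only add matches.
    """
    if not profile.assessable:
        raise ValueError("profile not assessable")
    if config.reference_ranges is None:
        raise ValueError("no DfN reference")
    matched: list[str] = []
    for m in config.cross_lineage_markers:
        if profile.positivity.get(m, False):
            matched.append(f"cross_lineage:{m}")
    for rule in config.laip_rules:
        if all(profile.positivity.get(m, False) for m in rule.required_positive) and all(
            not profile.positivity.get(m, False) for m in rule.required_negative
        ):
            matched.append(f"laip:{rule.rule_id}")
    for i, m in enumerate(profile.markers):
        lo, hi = config.reference_ranges[m]
        if not (lo <= profile.mean_clr[i] <= hi):
            matched.append(f"dfn:{m}")
    profile.immature = any(
        profile.positivity.get(m, False) for m in config.immaturity_markers
    )
    profile.aberrant = bool(matched)
    profile.matched_rules = matched
    return profile
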