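"""End-to-end driver: diagnose, select a target, monitor.

``analyze_patient`` is the per-patient core (filter -> clones -> graph ->
immunophenotypes -> five-criterion selection) reused by the analysis
scripts, the tests and ``run_pipeline``.  ``run_pipeline`` strings the full
study together on synthetic data: a multiplexed diagnosis run and a
multiplexed remission run are generated and demultiplexed, each patient is
analysed, and the chosen target is monitored along a longitudinal ddPCR
scenario with relapse calling and a lead-time comparison against
conventional methods.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clones import CloneGraph, CloneResult, build_clone_graph, infer_clones
from .config import RunConfig
from .demux import DemuxResult, build_profile_database, demultiplex_run
from .immuno import (
    ImmunoConfig,
    ImmunophenotypeProfile,
    classify_aberrant,
    clone_immunophenotype,
    clr_matrix,
    derive_reference_ranges,
)
from .matrix import AntibodyCounts, CellGenotypeMatrix
from .mrd import DdpcrAssay, MrdCall, MrdSeries, call_relapse, lead_time
from .scfilter import FilterReport, apply_variant_filters
from .selection import Blacklist, CriteriaResult, evaluate_criteria, select_targets
from .synthio import (
    CohortConfig,
    TruthLabels,
    generate_multiplex_run,
    relapse_trajectory,
    simulate_ddpcr_series,
)

__all__ = ["PatientAnalysis", "PatientReport", "analyze_patient", "run_pipeline"]


@dataclass
class PatientAnalysis:
    """Diagnosis + remission analysis for one patient."""

    patient_id: str
    filter_report: FilterReport
    clone_result: CloneResult
    clone_graph: CloneGraph
    immuno_profiles: dict[str, ImmunophenotypeProfile]
    criteria: list[CriteriaResult]
    targets: list[CriteriaResult]

    @property
    def selected_variant_ids(self) -> list[str]:
        return [t.variant_id for t in self.targets]


def analyze_patient(
    patient_id: str,
    diagnosis: CellGenotypeMatrix,
    antibody: AntibodyCounts,
    remission: CellGenotypeMatrix | None,
    config: RunConfig | None = None,
    assay_lods: Mapping[str, float] | None = None,
    blacklist: Blacklist | None = None,
    immuno_config: ImmunoConfig | None = None,
) -> PatientAnalysis:
    """Filter variants, reconstruct clones, immunophenotype them and apply
    the five selection criteria.

    The different-from-normal reference is derived from the run's own
    wildtype (mutation-free) cell population unless reference ranges are
    supplied in ``immuno_config``.
    """
    cfg = config or RunConfig()
    report = apply_variant_filters(diagnosis, config=cfg.filters)
    surviving = diagnosis.subset_variants(report.surviving)
    clone_result = infer_clones(surviving, cfg.clones)
    graph = build_clone_graph(clone_result)

    icfg = immuno_config or ImmunoConfig()
    clr = clr_matrix(antibody, icfg.pseudocount)
    if icfg.reference_ranges is None:
        if clone_result.wildtype is None or clone_result.wildtype.n_cells < 2:
            raise ValueError("no DfN reference: wildtype population too small")
        icfg.reference_ranges = derive_reference_ranges(
            clr[clone_result.wildtype.cell_indices], antibody.markers
        )

    profiles: dict[str, ImmunophenotypeProfile] = {}
    for clone in clone_result.all_clones:
        profile = clone_immunophenotype(clone, clr, antibody.markers, icfg)
        if profile.assessable:
            classify_aberrant(profile, icfg)
            clone.stage = (
                "immature blast"
                if profile.immature
                else ("mutated mature" if not clone.is_wildtype else "normal")
            )
        profiles[clone.clone_id] = profile

    criteria = [
        evaluate_criteria(
            vid,
            diagnosis,
            remission,
            graph,
            profiles,
            blacklist=blacklist,
            config=cfg.criteria,
            filter_config=cfg.filters,
        )
        for vid in report.surviving
    ]
    targets = select_targets(criteria, assay_lods)
    return PatientAnalysis(
        patient_id=patient_id,
        filter_report=report,
        clone_result=clone_result,
        clone_graph=graph,
        immuno_profiles=profiles,
        criteria=criteria,
        targets=targets,
    )


@dataclass
class PatientReport:
    patient_id: str
    n_cells_diagnosis: int
    n_cells_remission: int
    n_subclones_diagnosis: int
    selected_targets: list[str]
    criteria_table: list[dict]
    mrd_lod: float | None = None
    relapse: MrdCall | None = None
    lead_times: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def run_pipeline(
    cohort: CohortConfig,
    config: RunConfig | None = None,
    comparator_offsets: Mapping[str, int] | None = None,
) -> dict[str, PatientReport]:
    """Full synthetic study for every patient in the cohort.

    Generates and demultiplexes one diagnosis and one remission multiplexed
    run (seeds derived from the cohort seed), analyses each patient, then
    monitors the top-ranked target along a molecular-relapse ddPCR scenario.
    Conventional-method detection days for the lead-time comparison default
    to fixed offsets after the ddPCR detection day.
    """
    cfg = config or RunConfig()
    ss = np.random.SeedSequence(cohort.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    diag_cfg = CohortConfig(**{**_cohort_kwargs(cohort), "timepoints": "diagnosis", "seed": seeds[0]})
    rem_cfg = CohortConfig(**{**_cohort_kwargs(cohort), "timepoints": "remission", "seed": seeds[1]})

    reports: dict[str, PatientReport] = {}
    diag_parts, _ = _generate_and_demux(diag_cfg, cfg)
    rem_parts, _ = _generate_and_demux(rem_cfg, cfg)

    for p in cohort.patients:
        pid = p.patient_id
        if pid not in diag_parts:
            continue
        diag_matrix, diag_ab = diag_parts[pid]
        rem_matrix = rem_parts[pid][0] if pid in rem_parts else None
        analysis = analyze_patient(pid, diag_matrix, diag_ab, rem_matrix, cfg)

        mrd_lod = None
        relapse = None
        leads: dict[str, int] = {}
        if analysis.targets:
            rng = np.random.default_rng(seeds[2])
            wells = tuple(np.abs(rng.normal(0.010, 0.005, size=20)))
            assay = DdpcrAssay(
                target=analysis.targets[0].variant_id, wildtype_well_vafs=wells
            )
            trajectory, _ = relapse_trajectory()
            series = simulate_ddpcr_series(trajectory, assay, seed=seeds[3])
            relapse = call_relapse(series, fold=cfg.relapse_fold)
            mrd_lod = assay.lod
            if relapse.relapse and relapse.relapse_day is not None:
                offsets = comparator_offsets or {"MFC": 90, "WT1": 60}
                comparator_days = {
                    m: relapse.relapse_day + off for m, off in offsets.items()
                }
                leads = lead_time(relapse.relapse_day, comparator_days)

        reports[pid] = PatientReport(
            patient_id=pid,
            n_cells_diagnosis=diag_matrix.n_cells,
            n_cells_remission=rem_matrix.n_cells if rem_matrix is not None else 0,
            n_subclones_diagnosis=len(analysis.clone_result.clones),
            selected_targets=analysis.selected_variant_ids,
            criteria_table=[
                {
                    "variant": r.variant_id,
                    "gene": r.gene,
                    "c1": r.c1_large_clone,
                    "c2": r.c2_cleared,
                    "c3": r.c3_aberrant_clone,
                    "c4": r.c4_not_lost,
                    "c5": r.c5_not_blacklisted,
                    "eligible": r.eligible,
                    "diagnosis_vaf": r.diagnosis_vaf,
                    "remission_vaf": r.remission_vaf,
                }
                for r in analysis.criteria
            ],
            mrd_lod=mrd_lod,
            relapse=relapse,
            lead_times=leads,
        )
    return reports


def _cohort_kwargs(cohort: CohortConfig) -> dict:
    return {
        "patients": cohort.patients,
        "n_cells": cohort.n_cells,
        "n_germline_snps": cohort.n_germline_snps,
        "ado_rate": cohort.ado_rate,
        "missing_rate": cohort.missing_rate,
        "doublet_rate": cohort.doublet_rate,
        "af_sd": cohort.af_sd,
        "depth_mean": cohort.depth_mean,
        "nb_dispersion": cohort.nb_dispersion,
        "markers": cohort.markers,
        "patient_weights": cohort.patient_weights,
    }


def _generate_and_demux(
    cohort: CohortConfig, cfg: RunConfig
) -> tuple[dict[str, tuple[CellGenotypeMatrix, AntibodyCounts]], DemuxResult]:
    matrix, antibody, profiles, _ = generate_multiplex_run(cohort)
    db = build_profile_database(profiles, error_rate=cfg.demux.genotyping_error_rate)
    result = demultiplex_run(matrix, antibody, db, cfg.demux)
    return result.partitions, result
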