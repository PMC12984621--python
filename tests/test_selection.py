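"""Five-criterion target selection and ranking."""

import numpy as np
import pytest

from scmrd.clones import Clone, CloneGraph, CloneResult, build_clone_graph
from scmrd.immuno import ImmunophenotypeProfile
from scmrd.matrix import Genotype, VariantRecord
from scmrd.pipeline import analyze_patient
from scmrd.selection import (
    Blacklist,
    CriteriaConfig,
    CriteriaResult,
    evaluate_criteria,
    select_targets,
)
from scmrd.synthio import default_patient, generate_patient_sample

from _util import make_matrix

W, H, M = int(Genotype.WT), int(Genotype.HET), int(Genotype.HOM)


def _profile(cid, immature=True, aberrant=True):
    p = ImmunophenotypeProfile(
        clone_id=cid, markers=["CD34"], mean_clr=np.zeros(1), positivity={"CD34": True}
    )
    p.immature, p.aberrant = immature, aberrant
    return p


def _setup(gene="IDH2", diag_het_frac=0.96, rem_het_cells=1, rem_cells=200,
           immature=True, aberrant=True, lost_in_child=False):
    """Build diagnosis/remission matrices, a clone graph and profiles for a
    single candidate variant."""
    v = [VariantRecord("15", 90_000_000, "C", "T", gene=gene)]
    vid = v[0].variant_id
    n_diag = 100
    n_mut = int(round(diag_het_frac * n_diag))
    diag = make_matrix([[H]] * n_mut + [[W]] * (n_diag - n_mut), v)
    rem = make_matrix([[H]] * rem_het_cells + [[W]] * (rem_cells - rem_het_cells), v)

    wt = Clone("wildtype", {vid: Genotype.WT}, n_diag - n_mut,
               np.arange(n_mut, n_diag))
    carrier = Clone("clone0", {vid: Genotype.HET}, n_mut, np.arange(n_mut))
    clones = [carrier]
    profiles = {"clone0": _profile("clone0", immature, aberrant)}
    if lost_in_child:
        # child inherits "mid", acquires "extra" and loses the candidate
        carrier.genotype["mid"] = Genotype.HET
        carrier.genotype["extra"] = Genotype.WT
        wt.genotype["mid"] = Genotype.WT
        wt.genotype["extra"] = Genotype.WT
        child = Clone(
            "clone1",
            {vid: Genotype.WT, "mid": Genotype.HET, "extra": Genotype.HET},
            10,
            np.arange(10),
        )
        clones.append(child)
        profiles["clone1"] = _profile("clone1")
    graph = build_clone_graph(CloneResult(clones, wt, np.array([]), {}))
    return vid, diag, rem, graph, profiles


def test_worked_example_high_diagnosis_low_remission_passes_c1_c2():
    # one mutated allele in nearly all cells at diagnosis (VAF ~48 %),
    # a single residual heterozygous cell of 200 at remission (VAF 0.25 %)
    vid, diag, rem, graph, profiles = _setup(diag_het_frac=0.96, rem_het_cells=1)
    r = evaluate_criteria(vid, diag, rem, graph, profiles)
    assert r.diagnosis_vaf == pytest.approx(48.0)
    assert r.remission_vaf == pytest.approx(0.25)
    assert r.c1_large_clone and r.c2_cleared
    assert r.eligible


def test_persisting_variant_fails_c2():
    vid, diag, rem, graph, profiles = _setup(rem_het_cells=180, rem_cells=200)
    r = evaluate_criteria(vid, diag, rem, graph, profiles)
    assert r.remission_vaf == pytest.approx(45.0)
    assert not r.c2_cleared and not r.eligible
    assert "c2" in r.failed_criteria


def test_low_diagnosis_vaf_fails_c1():
    vid, diag, rem, graph, profiles = _setup(diag_het_frac=0.15)
    r = evaluate_criteria(vid, diag, rem, graph, profiles)
    assert r.diagnosis_vaf == pytest.approx(7.5)
    assert not r.c1_large_clone


def test_blacklisted_gene_fails_c5():
    vid, diag, rem, graph, profiles = _setup(gene="FLT3")
    r = evaluate_criteria(vid, diag, rem, graph, profiles)
    assert not r.c5_not_blacklisted and not r.eligible


def test_non_aberrant_carrier_clone_fails_c3():
    vid, diag, rem, graph, profiles = _setup(aberrant=False)
    r = evaluate_criteria(vid, diag, rem, graph, profiles)
    assert not r.c3_aberrant_clone


def test_any_clone_mode_is_lenient():
    vid, diag, rem, graph, profiles = _setup()
    profiles["clone0"].aberrant = True
    # add a second non-aberrant carrier
    extra = Clone("clone9", {vid: Genotype.HET}, 8, np.arange(8))
    graph.clones["clone9"] = extra
    graph.graph.add_edge("wildtype", "clone9", loh=[])
    profiles["clone9"] = _profile("clone9", immature=False, aberrant=False)
    strict = evaluate_criteria(vid, diag, rem, graph, profiles)
    lenient = evaluate_criteria(
        vid, diag, rem, graph, profiles,
        config=CriteriaConfig(require_all_clones_aberrant=False),
    )
    assert not strict.c3_aberrant_clone and lenient.c3_aberrant_clone


def test_loh_lost_variant_fails_c4():
    vid, diag, rem, graph, profiles = _setup(lost_in_child=True)
    r = evaluate_criteria(vid, diag, rem, graph, profiles)
    assert not r.c4_not_lost
    assert r.c4_violating_clones == ["clone1"]


def test_missing_remission_run_not_assessable():
    vid, diag, _, graph, profiles = _setup()
    r = evaluate_criteria(vid, diag, None, graph, profiles)
    assert r.not_assessable == "no remission run"
    assert not r.eligible


def test_eligible_is_strict_conjunction():
    vid, diag, rem, graph, profiles = _setup()
    r = evaluate_criteria(vid, diag, rem, graph, profiles)
    assert r.eligible == all(
        [r.c1_large_clone, r.c2_cleared, r.c3_aberrant_clone, r.c4_not_lost,
         r.c5_not_blacklisted]
    )


def test_blacklist_growth_only_shrinks_eligible_set():
    vid, diag, rem, graph, profiles = _setup(gene="IDH2")
    base = evaluate_criteria(vid, diag, rem, graph, profiles)
    grown = evaluate_criteria(
        vid, diag, rem, graph, profiles, blacklist=Blacklist().with_gene("IDH2")
    )
    assert base.eligible and not grown.eligible


def _result(vid, gene="IDH2", vaf=30.0):
    return CriteriaResult(
        variant_id=vid, gene=gene, c1_large_clone=True, diagnosis_vaf=vaf,
        c2_cleared=True, remission_vaf=0.0, c3_aberrant_clone=True,
        c3_clone_ids=[], c4_not_lost=True, c4_violating_clones=[],
        c5_not_blacklisted=True,
    )


def test_ranking_by_assay_lod_prefers_most_sensitive():
    dnmt3a, idh2 = _result("v_dnmt3a", "DNMT3A"), _result("v_idh2", "IDH2")
    ranked = select_targets(
        [idh2, dnmt3a], assay_lods={"v_dnmt3a": 0.039, "v_idh2": 0.06}
    )
    assert [r.variant_id for r in ranked] == ["v_dnmt3a", "v_idh2"]


def test_ranking_without_lods_uses_diagnosis_vaf():
    a, b = _result("va", vaf=20.0), _result("vb", vaf=40.0)
    assert [r.variant_id for r in select_targets([a, b])] == ["vb", "va"]


def test_single_eligible_returned_alone_and_none_gives_empty():
    only = _result("v1")
    assert select_targets([only]) == [only]
    failed = _result("v2")
    failed.c2_cleared = False
    assert select_targets([failed]) == []
    assert "c2" in failed.failed_criteria


def test_synthetic_cohort_selects_leukemic_rejects_ch_and_loh():
    patient = default_patient("P1")
    diag, ab, truth = generate_patient_sample(patient, "diagnosis", 2000, seed=77)
    rem, _, _ = generate_patient_sample(patient, "remission", 800, seed=78)
    analysis = analyze_patient("P1", diag, ab, rem)
    selected = set(analysis.selected_variant_ids)
    assert truth.leukemic_variants["P1"][0] in selected
    by_vid = {r.variant_id: r for r in analysis.criteria}
    ch = truth.ch_variants["P1"][0]
    assert ch not in selected and "c2" in by_vid[ch].failed_criteria
    loh = truth.loh_lost_variants["P1"][0]
    assert loh not in selected and "c4" in by_vid[loh].failed_criteria
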