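"""Clone inference, developmental ordering and LOH detection."""

import numpy as np
import pytest

from scmrd.clones import (
    Clone,
    CloneConfig,
    build_clone_graph,
    count_subclones,
    detect_loh,
    infer_clones,
)
from scmrd.matrix import Genotype
from scmrd.scfilter import FilterConfig, apply_variant_filters
from scmrd.synthio import default_patient, generate_patient_sample

from _util import make_matrix, simple_variants

W, H, M = int(Genotype.WT), int(Genotype.HET), int(Genotype.HOM)


def _clone(cid, genotype, n=10, parent=None):
    return Clone(
        clone_id=cid,
        genotype={k: Genotype(v) for k, v in genotype.items()},
        n_cells=n,
        cell_indices=np.arange(n),
        parent=parent,
    )


def _somatic(matrix, patient):
    return matrix.subset_variants([r.variant_id for r in patient.variants.values()])


def test_noise_free_recovers_planted_clones_exactly():
    patient = default_patient("P1")
    matrix, _, truth = generate_patient_sample(
        patient, "diagnosis", 1200, seed=21, ado_rate=0.0, missing_rate=0.0
    )
    result = infer_clones(_somatic(matrix, patient))
    assert count_subclones(result) == 3
    truth_sizes = {}
    for bc in matrix.barcodes:
        truth_sizes[truth.clone_of[bc]] = truth_sizes.get(truth.clone_of[bc], 0) + 1
    inferred_sizes = sorted(c.n_cells for c in result.clones)
    assert inferred_sizes == sorted(
        v for k, v in truth_sizes.items() if k != "normal"
    )
    assert result.wildtype.n_cells == truth_sizes["normal"]
    assert len(result.unassigned) == 0


def test_two_genotype_groups_make_two_clones():
    v = simple_variants(2)
    rows = [[H, W]] * 8 + [[H, H]] * 8
    result = infer_clones(make_matrix(rows, v))
    assert count_subclones(result) == 2


def test_assignment_accuracy_under_ado(diagnosis_sample):
    patient, matrix, _, truth = diagnosis_sample
    result = infer_clones(_somatic(matrix, patient))
    # map inferred clones to truth clones by majority vote, then score
    correct = total = 0
    for clone in result.all_clones:
        labels = [truth.clone_of[matrix.barcodes[int(i)]] for i in clone.cell_indices]
        majority = max(set(labels), key=labels.count)
        correct += sum(1 for l in labels if l == majority)
        total += len(labels)
    assert total >= 0.7 * matrix.n_cells  # most cells are assigned
    assert correct / total >= 0.95


def test_small_hom_subgroup_absorbed_large_one_kept():
    v = simple_variants(1)
    # 100 HET cells + 10 apparent-HOM cells: dropout signature, absorbed
    rows = [[H]] * 100 + [[M]] * 10
    result = infer_clones(make_matrix(rows, v), CloneConfig(ado_absorb_fraction=0.3))
    assert count_subclones(result) == 1
    assert result.clones[0].n_cells == 110
    # 50 HOM cells against 100 HET: above the absorption threshold, a
    # genuine LOH subclone is kept separate
    rows = [[H]] * 100 + [[M]] * 50
    result = infer_clones(make_matrix(rows, v), CloneConfig(ado_absorb_fraction=0.3))
    assert count_subclones(result) == 2


def test_groups_below_min_size_unassigned():
    v = simple_variants(1)
    rows = [[H]] * 20 + [[M]] * 3  # HOM group too small to stand alone...
    result = infer_clones(make_matrix(rows, v), CloneConfig(ado_absorb_fraction=0.3))
    assert count_subclones(result) == 1  # ...absorbed into the HET clone
    matrix = make_matrix([[H, W]] * 20 + [[W, H]] * 4, simple_variants(2))
    result = infer_clones(matrix, CloneConfig(min_clone_size=6))
    assert count_subclones(result) == 1
    assert len(result.unassigned) == 4


def test_missing_cells_assigned_when_uniquely_consistent():
    v = simple_variants(2)
    rows = [[H, W]] * 10 + [[H, H]] * 10 + [[H, -1]] * 3 + [[-1, H]] * 3
    result = infer_clones(make_matrix(rows, v))
    # [H, -1] is consistent with both clones -> unassigned;
    # [-1, H] only with the double mutant -> assigned
    sizes = sorted(c.n_cells for c in result.clones)
    assert sizes == [10, 13]
    assert len(result.unassigned) == 3


def test_cell_and_variant_order_invariance():
    patient = default_patient("P1")
    matrix, _, _ = generate_patient_sample(patient, "diagnosis", 500, seed=22)
    somatic = _somatic(matrix, patient)
    base = infer_clones(somatic)
    rng = np.random.default_rng(0)
    perm = rng.permutation(somatic.n_cells)
    shuffled = somatic.subset_cells(perm)
    alt = infer_clones(shuffled)
    assert sorted(c.n_cells for c in alt.clones) == sorted(
        c.n_cells for c in base.clones
    )
    vperm = list(rng.permutation(somatic.variant_ids))
    alt2 = infer_clones(somatic.subset_variants(vperm))
    assert sorted(c.n_cells for c in alt2.clones) == sorted(
        c.n_cells for c in base.clones
    )


def test_conservation_of_cells(diagnosis_sample):
    patient, matrix, _, _ = diagnosis_sample
    result = infer_clones(_somatic(matrix, patient))
    assigned = sum(c.n_cells for c in result.all_clones)
    assert assigned + len(result.unassigned) == matrix.n_cells


# -- graph building ----------------------------------------------------------


def test_subset_chain_graph():
    from scmrd.clones import CloneResult

    wt = _clone("wildtype", {"a": W, "b": W}, n=30)
    ca = _clone("A", {"a": H, "b": W}, n=20)
    cab = _clone("AB", {"a": H, "b": H}, n=10)
    result = CloneResult([ca, cab], wt, np.array([]), {})
    g = build_clone_graph(result)
    assert set(g.graph.edges()) == {("wildtype", "A"), ("A", "AB")}
    assert not g.non_tree


def test_branching_clones_both_root_at_wildtype():
    from scmrd.clones import CloneResult

    wt = _clone("wildtype", {"a": W, "b": W}, n=30)
    ca = _clone("A", {"a": H, "b": W}, n=20)
    cb = _clone("B", {"a": W, "b": H}, n=10)
    g = build_clone_graph(CloneResult([ca, cb], wt, np.array([]), {}))
    assert set(g.graph.edges()) == {("wildtype", "A"), ("wildtype", "B")}


def test_loh_edge_annotated():
    from scmrd.clones import CloneResult

    wt = _clone("wildtype", {"a": W, "b": W, "c": W}, n=30)
    parent = _clone("P", {"a": H, "b": H, "c": W}, n=20)
    child = _clone("C", {"a": H, "b": W, "c": H}, n=10)  # lost b, gained c
    g = build_clone_graph(CloneResult([parent, child], wt, np.array([]), {}))
    assert ("P", "C") in g.graph.edges()
    assert g.graph.edges[("P", "C")]["loh"] == [("b", "alt")]


def test_detect_loh_opposite_events():
    parent = _clone("p", {"v1": H, "v2": H})
    child = _clone("c", {"v1": W, "v2": M})
    assert detect_loh(parent, child) == [("v1", "alt"), ("v2", "ref")]
    assert detect_loh(parent, parent) == []
    wt_parent = _clone("w", {"v1": W, "v2": W})
    assert detect_loh(wt_parent, child) == []


def test_count_subclones_remission_matches_truth(remission_sample):
    patient, matrix, _, truth = remission_sample
    report = apply_variant_filters(matrix)
    result = infer_clones(matrix.subset_variants(report.surviving))
    # leukemia eradicated: only the persisting CH clone remains
    assert count_subclones(result) == 1
    n_ch_truth = sum(1 for c in truth.clone_of.values() if c == "CH")
    assert result.clones[0].n_cells == pytest.approx(n_ch_truth, rel=0.15)


def test_no_cells_gives_empty_result():
    v = simple_variants(1)
    result = infer_clones(make_matrix([[W]], v).subset_cells(np.array([], dtype=int)))
    assert result.clones == [] and result.wildtype is None
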