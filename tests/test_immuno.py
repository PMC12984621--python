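"""CLR transform, clone immunophenotypes and aberrancy classification."""

import numpy as np
import pytest

from scmrd.clones import Clone
from scmrd.immuno import (
    ImmunoConfig,
    LaipRule,
    classify_aberrant,
    clone_immunophenotype,
    clr_matrix,
    clr_transform,
    derive_reference_ranges,
)
from scmrd.matrix import AntibodyCounts, Genotype


def _clone(indices, cid="c"):
    return Clone(
        clone_id=cid,
        genotype={"v": Genotype.HET},
        n_cells=len(indices),
        cell_indices=np.asarray(indices),
    )


def test_equal_counts_give_zero_clr():
    assert clr_transform([7, 7, 7, 7]) == pytest.approx([0, 0, 0, 0])


def test_clr_matches_direct_formula():
    counts = np.array([1.0, 1.0, 1.0, 8.0])
    clr = clr_transform(counts, pseudocount=0.0)
    logs = np.log(counts)
    expected = logs - logs.mean()
    assert clr == pytest.approx(expected)
    assert clr.sum() == pytest.approx(0.0, abs=1e-12)


def test_clr_permutation_equivariance():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 200, size=10)
    perm = rng.permutation(10)
    assert clr_transform(counts)[perm] == pytest.approx(clr_transform(counts[perm]))


def test_clr_rows_sum_to_zero():
    rng = np.random.default_rng(1)
    ab = AntibodyCounts(
        barcodes=[f"b{i}" for i in range(50)],
        markers=[f"m{j}" for j in range(17)],
        counts=rng.integers(0, 500, size=(50, 17)),
    )
    sums = clr_matrix(ab).sum(axis=1)
    assert np.allclose(sums, 0.0, atol=1e-10)


def _reference_setup(rng, n_ref=500):
    markers = ["CD34", "CD117", "CD7", "CD33", "CD45"]
    normal_means = np.array([3.0, 3.0, 8.0, 80.0, 250.0])
    ref_counts = rng.poisson(normal_means, size=(n_ref, 5))
    ab = AntibodyCounts(
        barcodes=[f"r{i}" for i in range(n_ref)], markers=markers, counts=ref_counts
    )
    ref_clr = clr_matrix(ab)
    ranges = derive_reference_ranges(ref_clr, markers)
    return markers, ranges


def test_clone_of_identical_cells_profiles_as_single_cell():
    markers = ["CD34", "CD117", "CD7"]
    counts = np.tile([50, 60, 5], (10, 1))
    ab = AntibodyCounts([f"b{i}" for i in range(10)], markers, counts)
    clr = clr_matrix(ab)
    cfg = ImmunoConfig(positivity_thresholds={m: 0.0 for m in markers})
    profile = clone_immunophenotype(_clone(range(10)), clr, markers, cfg)
    assert profile.mean_clr == pytest.approx(clr[0])


def test_positive_and_negative_marker_calls():
    rng = np.random.default_rng(2)
    markers, ranges = _reference_setup(rng)
    # CD117+/CD34- clone
    clone_counts = rng.poisson([3.0, 120.0, 8.0, 80.0, 250.0], size=(40, 5))
    ab = AntibodyCounts([f"b{i}" for i in range(40)], markers, clone_counts)
    cfg = ImmunoConfig(reference_ranges=ranges)
    profile = clone_immunophenotype(_clone(range(40)), clr_matrix(ab), markers, cfg)
    assert profile.positivity["CD117"] and not profile.positivity["CD34"]


def test_minority_subpopulation_does_not_flip_clone_call():
    rng = np.random.default_rng(3)
    markers, ranges = _reference_setup(rng)
    # 70 % CD34-low cells, 30 % CD34-high: the clone mean stays negative
    low = rng.poisson([3.0, 100.0, 8.0, 80.0, 250.0], size=(70, 5))
    high = rng.poisson([60.0, 100.0, 8.0, 80.0, 250.0], size=(30, 5))
    ab = AntibodyCounts(
        [f"b{i}" for i in range(100)], markers, np.vstack([low, high])
    )
    cfg = ImmunoConfig(reference_ranges=ranges)
    profile = clone_immunophenotype(_clone(range(100)), clr_matrix(ab), markers, cfg)
    assert not profile.positivity["CD34"]
    assert profile.positivity["CD117"]


def test_empty_clone_not_assessable():
    markers = ["CD34"]
    profile = clone_immunophenotype(
        _clone([]), np.zeros((0, 1)), markers, ImmunoConfig(positivity_thresholds={"CD34": 0})
    )
    assert not profile.assessable
    with pytest.raises(ValueError, match="not assessable"):
        classify_aberrant(profile, ImmunoConfig(reference_ranges={"CD34": (0, 1)}))


def _profile(markers, positivity, mean_clr=None):
    from scmrd.immuno import ImmunophenotypeProfile

    return ImmunophenotypeProfile(
        clone_id="c",
        markers=list(markers),
        mean_clr=np.asarray(mean_clr if mean_clr is not None else [0.0] * len(markers)),
        positivity=dict(positivity),
    )


def test_cross_lineage_marker_makes_immature_clone_aberrant():
    markers = ["CD34", "CD117", "CD7"]
    ranges = {m: (-1.0, 1.0) for m in markers}
    profile = _profile(markers, {"CD34": True, "CD117": False, "CD7": True})
    out = classify_aberrant(profile, ImmunoConfig(reference_ranges=ranges))
    assert out.immature and out.aberrant
    assert "cross_lineage:CD7" in out.matched_rules


def test_normal_profile_neither_immature_nor_aberrant():
    markers = ["CD34", "CD117", "CD7"]
    ranges = {m: (-1.0, 1.0) for m in markers}
    profile = _profile(markers, {m: False for m in markers})
    out = classify_aberrant(profile, ImmunoConfig(reference_ranges=ranges))
    assert not out.immature and not out.aberrant and out.matched_rules == []


def test_laip_rule_fires_by_id():
    markers = ["CD34", "CD117", "CD7"]
    ranges = {m: (-1.0, 1.0) for m in markers}
    rule = LaipRule("cd34_cd117", required_positive=("CD34", "CD117"))
    profile = _profile(markers, {"CD34": True, "CD117": True, "CD7": False})
    out = classify_aberrant(
        profile,
        ImmunoConfig(reference_ranges=ranges, laip_rules=(rule,),
                     cross_lineage_markers=()),
    )
    assert out.aberrant and "laip:cd34_cd117" in out.matched_rules


def test_dfn_out_of_range_marker_is_aberrant():
    markers = ["CD34", "CD45"]
    ranges = {"CD34": (-1.0, 1.0), "CD45": (-0.5, 0.5)}
    profile = _profile(markers, {m: False for m in markers}, mean_clr=[0.0, -2.0])
    out = classify_aberrant(profile, ImmunoConfig(reference_ranges=ranges))
    assert out.aberrant and "dfn:CD45" in out.matched_rules


def test_missing_reference_ranges_error():
    profile = _profile(["CD34"], {"CD34": False})
    with pytest.raises(ValueError, match="no DfN reference"):
        classify_aberrant(profile, ImmunoConfig())


def test_adding_rules_is_monotone():
    markers = ["CD34", "CD117", "CD7"]
    ranges = {m: (-1.0, 1.0) for m in markers}
    profile = _profile(markers, {"CD34": True, "CD117": True, "CD7": True})
    base_cfg = ImmunoConfig(reference_ranges=ranges)
    base = classify_aberrant(profile, base_cfg)
    more = classify_aberrant(
        _profile(markers, profile.positivity),
        ImmunoConfig(
            reference_ranges=ranges,
            laip_rules=(LaipRule("extra", required_positive=("CD34",)),),
        ),
    )
    assert set(base.matched_rules) <= set(more.matched_rules)
    assert not (base.aberrant and not more.aberrant)
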