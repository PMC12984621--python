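"""Generator correctness: planted truth, noise statistics, determinism."""

import numpy as np
import pytest
from scipy import stats

from scmrd.matrix import Genotype
from scmrd.synthio import (
    CloneSpec,
    CohortConfig,
    PatientSpec,
    default_cohort,
    default_patient,
    generate_multiplex_run,
    generate_patient_sample,
    resolve_clone_genotypes,
    simulate_ddpcr_series,
    simulate_ecngs_counts,
    simulate_ecngs_sites,
)
from scmrd.mrd import DdpcrAssay


def _single_clone_patient(loh=()):
    from scmrd.matrix import VariantRecord
    from scmrd.synthio import NORMAL_CLONE, NORMAL_MARKER_MEANS, BLAST_MARKER_MEANS

    variants = {
        "a": VariantRecord("2", 1_000_000, "C", "T", gene="GA"),
        "b": VariantRecord("3", 2_000_000, "C", "T", gene="GB"),
    }
    clones = [
        CloneSpec("c1", None, ("a", "b"), diagnosis_fraction=1.0, loh_events=loh)
    ]
    return PatientSpec(
        patient_id="P1",
        variants=variants,
        clones=clones,
        marker_means={NORMAL_CLONE: dict(NORMAL_MARKER_MEANS),
                      "c1": dict(BLAST_MARKER_MEANS)},
    )


def test_noise_free_cells_match_clone_genotype_exactly():
    patient = _single_clone_patient()
    matrix, _, truth = generate_patient_sample(
        patient, "diagnosis", 200, seed=1,
        ado_rate=0.0, missing_rate=0.0, n_germline_snps=5,
    )
    somatic = matrix.subset_variants(
        [patient.variants["a"].variant_id, patient.variants["b"].variant_id]
    )
    assert (somatic.genotype == Genotype.HET).all()
    assert not truth.doublets


def test_loh_losing_ref_allele_yields_hom_alt_cells():
    patient = _single_clone_patient(loh=(("a", "ref"),))
    matrix, _, _ = generate_patient_sample(
        patient, "diagnosis", 200, seed=2,
        ado_rate=0.0, missing_rate=0.0, n_germline_snps=5,
    )
    col = matrix.genotype[:, matrix.variant_index(patient.variants["a"].variant_id)]
    assert (col[col != Genotype.MISSING] == Genotype.HOM).all()


def test_doublet_fraction_within_exact_binomial_interval():
    cfg = default_cohort(3, seed=7, n_cells=10_000, doublet_rate=0.05)
    _, _, _, truth = generate_multiplex_run(cfg)
    lo, hi = stats.binom.interval(0.99, 10_000, 0.05)
    assert lo <= len(truth.doublets) <= hi


def test_doublets_carry_union_of_two_patients_germline_genotypes():
    cfg = default_cohort(2, seed=9, n_cells=4000, doublet_rate=0.2,
                         ado_rate=0.0, missing_rate=0.0)
    matrix, _, profiles, truth = generate_multiplex_run(cfg)
    snp_cols = [matrix.variant_index(lid) for lid in profiles[0].locus_ids]
    geno_by_pid = {p.patient_id: p.genotypes for p in profiles}
    cross = [
        bc for bc in truth.doublets
        if isinstance(truth.patient_of[bc], tuple)
        and truth.patient_of[bc][0] != truth.patient_of[bc][1]
    ]
    assert cross
    bc = cross[0]
    i = matrix.barcodes.index(bc)
    obs = matrix.genotype[i, snp_cols]
    pa, pb = truth.patient_of[bc]
    expected_dosage = (geno_by_pid[pa] + geno_by_pid[pb]) / 2.0
    # observed genotype must be one of the two codes flanking the mean dosage
    for g, d in zip(obs, expected_dosage):
        assert abs(int(g) - d) <= 0.5


def test_clone_fractions_converge_to_configured(diagnosis_sample):
    patient, matrix, _, truth = diagnosis_sample
    counts = {}
    for bc in matrix.barcodes:
        counts[truth.clone_of[bc]] = counts.get(truth.clone_of[bc], 0) + 1
    n = matrix.n_cells
    expected = {"CH": 0.10, "blast1": 0.35, "blast2": 0.25, "normal": 0.30}
    for cid, frac in expected.items():
        assert counts[cid] / n == pytest.approx(frac, abs=0.03)


def test_identical_seed_identical_cohort():
    a = generate_multiplex_run(default_cohort(2, seed=5, n_cells=500))
    b = generate_multiplex_run(default_cohort(2, seed=5, n_cells=500))
    assert np.array_equal(a[0].genotype, b[0].genotype)
    assert np.array_equal(a[0].af, b[0].af)
    assert np.array_equal(a[1].counts, b[1].counts)
    assert a[3].patient_of == b[3].patient_of


def test_invalid_clone_tree_rejected():
    from scmrd.matrix import VariantRecord
    from scmrd.synthio import NORMAL_CLONE, NORMAL_MARKER_MEANS

    variants = {"a": VariantRecord("2", 100, "C", "T", gene="GA")}
    with pytest.raises(ValueError, match="unknown parent"):
        PatientSpec(
            "P1", variants,
            [CloneSpec("c1", "ghost", ("a",), diagnosis_fraction=0.5)],
            {NORMAL_CLONE: dict(NORMAL_MARKER_MEANS)},
        )
    with pytest.raises(ValueError, match="fractions sum"):
        PatientSpec(
            "P1", variants,
            [CloneSpec("c1", None, ("a",), diagnosis_fraction=0.7),
             CloneSpec("c2", None, (), diagnosis_fraction=0.7)],
            {NORMAL_CLONE: dict(NORMAL_MARKER_MEANS)},
        )


def test_probability_bounds_enforced():
    with pytest.raises(ValueError, match="ado_rate"):
        CohortConfig(patients=[default_patient("P1")], ado_rate=1.5)


def test_resolve_clone_genotypes_accumulates_and_applies_loh():
    patient = default_patient("P1")
    genos = resolve_clone_genotypes(patient)
    assert genos["CH"]["dnmt3a"] == Genotype.HET
    assert genos["blast1"]["dnmt3a"] == Genotype.HET
    assert genos["blast1"]["tet2"] == Genotype.HET
    assert genos["blast2"]["tet2"] == Genotype.WT  # alt allele lost
    assert genos["blast2"]["runx1"] == Genotype.HET
    assert all(g == Genotype.WT for g in genos["normal"].values())


# -- longitudinal simulators -------------------------------------------------


def _assay(mean=0.0, sd=0.0):
    if sd == 0.0:
        return DdpcrAssay(target="t", lod_override=max(mean, 1e-6))
    rng = np.random.default_rng(0)
    return DdpcrAssay(target="t", wildtype_well_vafs=tuple(np.abs(rng.normal(mean, sd, 20))))


def test_ddpcr_zero_vaf_zero_noise_measures_zero():
    series = simulate_ddpcr_series(
        [(0, "PB", 0.0), (30, "PB", 0.0)], _assay(), seed=1, false_positive_rate=0.0
    )
    assert all(s.vaf == 0.0 for s in series.samples)
    assert not any(s.positive for s in series.samples)


def test_ddpcr_high_vaf_within_binomial_interval():
    series = simulate_ddpcr_series(
        [(0, "BM", 50.0)], _assay(), replicates=1, dna_copies_per_well=10_000,
        seed=3, false_positive_rate=0.0,
    )
    lo, hi = stats.binom.interval(0.99, 10_000, 0.5)
    assert lo / 100.0 <= series.samples[0].vaf <= hi / 100.0


def test_ddpcr_rejects_non_increasing_days():
    with pytest.raises(ValueError, match="strictly increasing"):
        simulate_ddpcr_series([(10, "PB", 0.1), (10, "PB", 0.1)], _assay(), seed=0)


def test_ecngs_zero_vaf_zero_error_no_support():
    site = simulate_ecngs_counts(0.0, 10_000, 0.0, seed=4)
    assert site.fwd_supporting == 0 and site.rev_supporting == 0


def test_ecngs_error_rate_sets_mean_support():
    # Poisson limit: depth 10,000 at error 1e-4 averages ~1 supporting/strand
    sites = simulate_ecngs_sites(2000, 0.0, 10_000, 1e-4, dispersion=0.0, seed=5)
    mean_fwd = np.mean([s.fwd_supporting for s in sites])
    assert mean_fwd == pytest.approx(1.0, abs=0.1)


def test_ecngs_true_vaf_sets_expected_support():
    sites = simulate_ecngs_sites(2000, 0.1, 10_000, 0.0, seed=6)
    mean = np.mean([s.fwd_supporting for s in sites])
    assert mean == pytest.approx(10.0, rel=0.05)
    assert all(s.uao == s.fwd_supporting + s.rev_supporting for s in sites)
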