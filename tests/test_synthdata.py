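import numpy as np
import pytest

from tgdrep.clonotypes import call_major_clonotypes, classify_architecture, compute_vdj_usage, translate_cdr3
from tgdrep.model import Chain, SubjectGroup, TriState
from tgdrep.synthdata import (
    CohortProfile,
    EffectConfig,
    JunctionParams,
    MutationModel,
    SimulationTruth,
    TruthMutation,
    default_library,
    observe_vaf,
    plant_public_clonotype,
    simulate_cohort,
    simulate_patient_metadata,
    simulate_rearrangement,
    study_mimic_profiles,
    true_vaf,
)


class TestSegmentLibrary:
    def test_anchors_are_conserved_residues(self):
        lib = default_library()
        for name in lib.names(Chain.TRG, __import__("tgdrep.model", fromlist=["SegmentClass"]).SegmentClass.V) + \
                    lib.names(Chain.TRD, __import__("tgdrep.model", fromlist=["SegmentClass"]).SegmentClass.V):
            seg = lib.get(name)
            codon = seg.sequence[3 * seg.anchor_offset: 3 * seg.anchor_offset + 3]
            assert translate_cdr3(codon)[1] == "C", name

    def test_j_segments_end_cdr3_with_phe_and_kk_motifs(self):
        lib = default_library()
        for name, kk in [("TRGJ1", True), ("TRGJ2", True), ("TRGJP", True),
                         ("TRGJP1", False), ("TRGJP2", False),
                         ("TRDJ1", False), ("TRDJ3", False)]:
            seg = lib.get(name)
            part = seg.sequence[: 3 * seg.anchor_offset + 3]
            aa = translate_cdr3(part)[1]
            assert aa.endswith("F"), name
            assert ("KK" in aa) is kk, name


class TestRearrangement:
    def test_degenerate_parameters_give_fixed_germline_junction(self):
        params = JunctionParams(trim_p=1.0, insert_lambda=0.0)
        weights = {"V": {"TRGV9": 1.0}, "J": {"TRGJP": 1.0}}
        clones = {simulate_rearrangement(Chain.TRG, weights, params,
                                         np.random.default_rng(s)).cdr3_nt
                  for s in range(5)}
        assert len(clones) == 1
        (nt,) = clones
        assert translate_cdr3(nt)[1] == "CALWEVELGKKIKVF"

    def test_same_seed_identical_clonotype(self):
        a = simulate_rearrangement(Chain.TRD, {}, rng=np.random.default_rng(9))
        b = simulate_rearrangement(Chain.TRD, {}, rng=np.random.default_rng(9))
        assert a == b

    def test_productive_fraction_in_expected_band(self):
        rng = np.random.default_rng(20240901)
        draws = [simulate_rearrangement(Chain.TRG, {}, rng=rng) for _ in range(10_000)]
        frac = sum(c.productive for c in draws) / len(draws)
        assert 0.25 <= frac <= 0.45

    def test_cdr3_lengths_span_realistic_ranges(self):
        rng = np.random.default_rng(3)
        gamma = [simulate_rearrangement(Chain.TRG, {}, rng=rng) for _ in range(2000)]
        delta = [simulate_rearrangement(Chain.TRD, {}, rng=rng) for _ in range(2000)]
        glens = [len(c.cdr3_aa) for c in gamma if c.productive]
        dlens = [len(c.cdr3_aa) for c in delta if c.productive]
        assert 9 <= np.median(glens) <= 16
        assert 14 <= np.median(dlens) <= 21


class TestPlants:
    def test_variants_distinct_but_synonymous(self, rng):
        variants = plant_public_clonotype("CALWEVRELGKKIKVF", "TRGV9", "TRGJP", 3, rng)
        nts = {v.cdr3_nt for v in variants}
        assert len(nts) == 3
        assert all(translate_cdr3(nt)[1] == "CALWEVRELGKKIKVF" for nt in nts)

    def test_single_variant(self, rng):
        (v,) = plant_public_clonotype("CAF", "TRGV9", "TRGJP", 1, rng)
        assert v.cdr3_aa == "CAF"

    def test_nonstandard_residue_rejected(self, rng):
        with pytest.raises(ValueError, match="non-standard"):
            plant_public_clonotype("CABF", "TRGV9", "TRGJP", 1, rng)


class TestCohort:
    def test_fixed_seed_bit_identical(self):
        profiles = study_mimic_profiles(n_indolent=2, n_symptomatic=1, n_hstcl=1,
                                        n_controls=2, read_depth=10_000,
                                        background_clonotypes=60)
        a_reps, a_truth = simulate_cohort(profiles, seed=5)
        b_reps, b_truth = simulate_cohort(profiles, seed=5)
        for ra, rb in zip(a_reps, b_reps):
            assert [(c.cdr3_nt, c.read_count) for c in ra.clonotypes] == \
                   [(c.cdr3_nt, c.read_count) for c in rb.clonotypes]
        assert a_truth.publicity == b_truth.publicity
        assert [(m.patient_id, m.true_vaf) for m in a_truth.mutations] == \
               [(m.patient_id, m.true_vaf) for m in b_truth.mutations]

    def test_planted_mass_over_one_rejected(self):
        profile = CohortProfile(group=SubjectGroup.HSTCL, n_samples=1,
                                sample_prefix="x",
                                dominant_clone_freqs={Chain.TRD: [0.7, 0.4]})
        with pytest.raises(ValueError, match="planted mass"):
            simulate_cohort([profile], seed=1)

    def test_hstcl_preset_is_monoclonal(self, small_cohort):
        reps, _ = small_cohort
        by_sample = {}
        for rep in reps:
            by_sample.setdefault(rep.sample_id, {})[rep.chain] = rep
        chains = by_sample["hstcl1"]
        arch = classify_architecture(call_major_clonotypes(chains[Chain.TRG]),
                                     call_major_clonotypes(chains[Chain.TRD]))
        assert arch.label.value == "monoclonal"

    def test_control_preset_has_no_major_clones(self):
        profiles = study_mimic_profiles(n_indolent=0, n_symptomatic=0, n_hstcl=0,
                                        n_controls=4, read_depth=50_000,
                                        background_clonotypes=300)
        for seed in range(3):
            reps, _ = simulate_cohort(profiles, seed=50 + seed, mutation_model=None)
            for rep in reps:
                assert len(call_major_clonotypes(rep)) == 0

    def test_indolent_modal_usage_is_vg9_jgp(self, small_cohort):
        reps, _ = small_cohort
        ind_gamma = [r for r in reps if r.chain is Chain.TRG
                     and r.subject_group is SubjectGroup.indolent_LGLL]
        majors = [call_major_clonotypes(r) for r in ind_gamma]
        usage = compute_vdj_usage(majors, SubjectGroup.indolent_LGLL)
        assert usage.top_combination() == ("TRGV9", "TRGJP")

    def test_planted_frequency_recovered_within_multinomial_error(self, small_cohort):
        reps, truth = small_cohort
        by_key = {(r.sample_id, r.chain): r for r in reps}
        checked = 0
        for plant in truth.planted:
            rep = by_key[(plant.sample_id, plant.chain)]
            observed = sum(c.frequency for c in rep.clonotypes
                           if c.cdr3_nt == plant.cdr3_nt)
            se = np.sqrt(plant.target_frequency * (1 - plant.target_frequency)
                         / rep.total_reads)
            assert abs(observed - plant.target_frequency) <= 5 * se + 1e-9, plant
            checked += 1
        assert checked > 5


class TestVafModel:
    def test_true_vaf_formula(self):
        assert true_vaf(0.65, 1.0, "het") == pytest.approx(0.325)
        assert true_vaf(0.87, 1.0, "hom") == pytest.approx(0.87)

    def test_observed_vaf_binomial_noise_at_depth_5000(self, rng):
        tv = true_vaf(0.65, 1.0, "het")
        obs = [observe_vaf(tv, 5000, rng) for _ in range(50)]
        se = np.sqrt(tv * (1 - tv) / 5000)
        assert all(abs(o - tv) < 5 * se for o in obs)

    def test_large_depth_limit(self, rng):
        tv = 0.4321
        assert abs(observe_vaf(tv, 1_000_000, rng) - tv) < 0.002


class TestPatientMetadata:
    def _truth(self, n_sympt=4, n_ind=4):
        groups = {}
        fractions = {}
        mutations = []
        for i in range(n_sympt):
            pid = f"sym{i}"
            groups[pid] = SubjectGroup.symptomatic_LGLL
            fractions[pid] = 0.5
            mutations.append(TruthMutation(pid, "STAT3", "het", 1.0, 0.5,
                                           true_vaf(0.5, 1.0, "het")))
        for i in range(n_ind):
            pid = f"ind{i}"
            groups[pid] = SubjectGroup.indolent_LGLL
            fractions[pid] = 0.6
        return SimulationTruth(groups=groups, planted=[], publicity={},
                               clone_fractions=fractions, mutations=mutations)

    def test_stat3_effects_are_deterministic_at_default_config(self, rng):
        records, calls = simulate_patient_metadata(self._truth(), rng=rng)
        stat3_ids = {c.patient_id for c in calls if c.gene.value == "STAT3"}
        for record in records:
            if record.patient_id in stat3_ids:
                assert record.marker("CD56") is TriState.negative
                assert record.flag("neutropenia") is TriState.positive

    def test_indolent_patients_vd2_vg9_positive_by_default(self, rng):
        records, _ = simulate_patient_metadata(self._truth(), rng=rng)
        for record in records:
            if record.course.value == "indolent":
                assert record.marker("Vd2") is TriState.positive
                assert record.marker("Vg9") is TriState.positive

    def test_observed_vaf_near_truth(self, rng):
        _, calls = simulate_patient_metadata(self._truth(), rng=rng)
        for call in calls:
            assert call.vaf == pytest.approx(0.25, abs=0.03)

    def test_bad_effect_probability_rejected(self, rng):
        cfg = EffectConfig(indolent_cd56_pos=1.4)
        with pytest.raises(ValueError, match="outside"):
            simulate_patient_metadata(self._truth(), cfg, rng)


class TestMutationAssignment:
    def test_group_gene_pattern(self):
        profiles = study_mimic_profiles(n_indolent=4, n_symptomatic=4, n_hstcl=2,
                                        n_controls=2, read_depth=5_000,
                                        background_clonotypes=40)
        _, truth = simulate_cohort(profiles, seed=8,
                                   mutation_model=MutationModel())
        for m in truth.mutations:
            group = truth.groups[m.patient_id]
            if group is SubjectGroup.symptomatic_LGLL:
                assert m.gene == "STAT3"
            else:
                assert m.gene == "STAT5B"
            assert m.true_vaf == pytest.approx(
                true_vaf(m.clone_fraction, m.ccf, m.zygosity))
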