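import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tgdrep.clonotypes import MajorClonotypeSet, call_major_clonotypes
from tgdrep.model import Chain, Clonotype, DegenerateInputError, Repertoire, SubjectGroup, TgdrepError
from tgdrep.publicity import (
    OverlapMetric,
    PublicityLabel,
    build_recurrence_matrix,
    classify_publicity,
    cluster_repertoires,
    count_shared_major_sequences,
    enrich_matrix,
    normality_gate,
    repertoire_distance,
    screen_catalog,
)
from tgdrep.publicity import test_enrichment as enrichment_test


def _rep(sample, group, aa_freqs, chain=Chain.TRG):
    clones = [Clonotype(chain=chain, v_name="TRGV9", j_name="TRGJP",
                        cdr3_aa=aa, frequency=f, productive=True)
              for aa, f in aa_freqs.items()]
    return Repertoire(sample, chain, group, clones)


def _mset(sample, aa_freqs, chain=Chain.TRG):
    rep = _rep(sample, SubjectGroup.indolent_LGLL, aa_freqs, chain)
    return call_major_clonotypes(rep, 0.05)


PAT = SubjectGroup.indolent_LGLL
CTR = SubjectGroup.control


class TestRecurrenceMatrix:
    def test_cells_carry_frequencies_and_occurrences(self):
        majors = [_mset("p1", {"CAAF": 0.5}), _mset("p2", {"CAAF": 0.3, "CADF": 0.2})]
        reps = [
            _rep("p1", PAT, {"CAAF": 0.5, "CAXF": 0.01}),
            _rep("p2", PAT, {"CAAF": 0.3, "CADF": 0.2}),
            _rep("c1", CTR, {"CAAF": 0.002}),
            _rep("c2", CTR, {"CAYF": 0.001}),
        ]
        m = build_recurrence_matrix(majors, reps)
        assert m.query_sequences[0] == "CAAF"  # most recurrent first
        assert m.row("CAAF").tolist() == [0.5, 0.3, 0.002, 0.0]
        assert m.patient_occurrences[0] == 2 and m.control_occurrences[0] == 1
        # private sequence has exactly one nonzero cell
        assert np.count_nonzero(m.row("CADF")) == 1

    def test_nt_variants_with_same_aa_are_summed(self):
        rep = Repertoire("p1", Chain.TRG, PAT, [
            Clonotype(chain=Chain.TRG, v_name="TRGV9", j_name="TRGJP",
                      cdr3_nt="TGTGCCTTT", cdr3_aa="CAF", frequency=0.3, productive=True),
            Clonotype(chain=Chain.TRG, v_name="TRGV9", j_name="TRGJP",
                      cdr3_nt="TGCGCCTTC", cdr3_aa="CAF", frequency=0.2, productive=True),
        ])
        m = build_recurrence_matrix([_mset("p1", {"CAF": 0.5})], [rep])
        assert m.row("CAF")[0] == pytest.approx(0.5)

    def test_empty_query_set_rejected(self):
        with pytest.raises(DegenerateInputError):
            build_recurrence_matrix([MajorClonotypeSet("p1", Chain.TRG)], [])

    def test_matches_brute_force_on_synthetic_cohort(self, small_cohort):
        reps, _ = small_cohort
        gam = [r for r in reps if r.chain is Chain.TRG]
        patients = [r for r in gam if r.is_patient]
        majors = [call_major_clonotypes(r) for r in patients]
        m = build_recurrence_matrix(majors, gam)
        # brute force: all-pairs string comparison
        for i, seq in enumerate(m.query_sequences):
            for j, rep in enumerate(gam):
                expected = sum(c.frequency for c in rep.clonotypes if c.cdr3_aa == seq)
                assert m.cells[i, j] == pytest.approx(expected, abs=1e-12)


class TestPublicity:
    def _matrix(self):
        majors = [_mset("p1", {"SHAREDPAT": 0.3, "ONLYP1": 0.2}),
                  _mset("p2", {"SHAREDPAT": 0.4, "INCTRL": 0.2}),
                  _mset("p3", {"SHAREDPAT": 0.1})]
        reps = [
            _rep("p1", PAT, {"SHAREDPAT": 0.3, "ONLYP1": 0.2}),
            _rep("p2", PAT, {"SHAREDPAT": 0.4, "INCTRL": 0.2}),
            _rep("p3", PAT, {"SHAREDPAT": 0.1}),
            _rep("c1", CTR, {"INCTRL": 0.001}),
            _rep("c2", CTR, {"INCTRL": 0.002}),
            _rep("c3", CTR, {"INCTRL": 0.001}),
        ]
        return build_recurrence_matrix(majors, reps)

    def test_three_way_classification(self):
        calls = {c.sequence: c.label for c in classify_publicity(self._matrix())}
        assert calls["SHAREDPAT"] is PublicityLabel.private_to_disease
        assert calls["INCTRL"] is PublicityLabel.public
        assert calls["ONLYP1"] is PublicityLabel.private_to_patient

    def test_labels_partition_the_query_set(self):
        matrix = self._matrix()
        calls = classify_publicity(matrix)
        assert sorted(c.sequence for c in calls) == sorted(matrix.query_sequences)
        assert all(isinstance(c.label, PublicityLabel) for c in calls)

    def test_requires_controls(self):
        majors = [_mset("p1", {"CAAF": 0.5})]
        matrix = build_recurrence_matrix(majors, [_rep("p1", PAT, {"CAAF": 0.5})])
        with pytest.raises(TgdrepError, match="control"):
            classify_publicity(matrix)


class TestSharedMajorSequences:
    def test_counts_patients_not_entries(self):
        majors = [_mset("p1", {"CAAF": 0.3}),
                  _mset("p2", {"CAAF": 0.4, "CADF": 0.2}),
                  _mset("p3", {"CADF": 0.5})]
        shared = count_shared_major_sequences(majors)
        assert shared == {"CAAF": 2, "CADF": 2}

    def test_needs_two_patients(self):
        with pytest.raises(TgdrepError):
            count_shared_major_sequences([_mset("p1", {"CAAF": 0.3})])


class TestEnrichment:
    def test_canonical_exact_example(self):
        res = enrichment_test([0.3, 0.2, 0.1], [0.0, 0.0, 0.0])
        assert res.p_one_sided == pytest.approx(0.05)
        assert not res.significant  # p < alpha is strict

    def test_all_zero_convention(self):
        assert enrichment_test([0.0, 0.0], [0.0, 0.0, 0.0]).p_one_sided == 1.0

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=5),
           st.lists(st.floats(0.0, 1.0), min_size=3, max_size=5),
           st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, x, y, k):
        p1 = enrichment_test(x, y).p_one_sided
        p2 = enrichment_test([k * v for v in x], [k * v for v in y]).p_one_sided
        assert p1 == pytest.approx(p2)

    def test_enrich_matrix_flags_planted_signal(self):
        majors = [_mset(f"p{i}", {"HOT": 0.3}) for i in range(4)]
        reps = ([_rep(f"p{i}", PAT, {"HOT": 0.2 + 0.05 * i}) for i in range(4)]
                + [_rep(f"c{i}", CTR, {"COLD": 0.01}) for i in range(9)])
        m = build_recurrence_matrix(majors, reps)
        (res,) = enrich_matrix(m)
        assert res.sequence == "HOT" and res.significant


class TestNormalityGate:
    def test_normal_sample_passes(self, rng):
        normal, p = normality_gate(rng.normal(size=500))
        assert normal and p > 0.05

    def test_exponential_sample_fails(self, rng):
        normal, _ = normality_gate(rng.exponential(size=500))
        assert not normal

    def test_calibration_over_repeated_normal_draws(self):
        rng = np.random.default_rng(77)
        passes = sum(normality_gate(rng.normal(size=60))[0] for _ in range(400))
        # pass rate ~ 0.95; 400-draw binomial 99.9% band
        assert 0.90 <= passes / 400 <= 0.99

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            normality_gate([1.0, 1.0, 1.0, 1.0])


class TestClustering:
    def test_identical_repertoires_distance_zero(self):
        a = _rep("a", CTR, {"CAAF": 0.6, "CADF": 0.4})
        b = _rep("b", CTR, {"CAAF": 0.6, "CADF": 0.4})
        assert repertoire_distance(a, b, OverlapMetric.morisita_horn) == pytest.approx(0.0)
        assert repertoire_distance(a, b, OverlapMetric.jaccard_aa) == pytest.approx(0.0)

    def test_disjoint_repertoires_distance_one(self):
        a = _rep("a", CTR, {"CAAF": 1.0})
        b = _rep("b", CTR, {"CADF": 1.0})
        assert repertoire_distance(a, b, OverlapMetric.jaccard_aa) == 1.0
        assert repertoire_distance(a, b, OverlapMetric.morisita_horn) == 1.0

    def test_empty_repertoire_excluded_with_warning(self):
        reps = [_rep("a", CTR, {"CAAF": 1.0}), _rep("b", CTR, {"CAAF": 0.9, "CADF": 0.1}),
                _rep("c", CTR, {"CADF": 1.0}),
                Repertoire("empty", Chain.TRG, CTR, [])]
        with pytest.warns(UserWarning, match="empty"):
            result = cluster_repertoires(reps)
        assert "empty" not in result.sample_ids

    def test_requires_three_repertoires(self):
        with pytest.raises(TgdrepError):
            cluster_repertoires([_rep("a", CTR, {"CAAF": 1.0}),
                                 _rep("b", CTR, {"CAAF": 1.0})])


class TestCatalogScreen:
    def test_empty_catalog_empty_report(self, tmp_path):
        cat = tmp_path / "cat.tsv"
        cat.write_text("")
        assert screen_catalog([_mset("p1", {"CAAF": 0.5})], cat) == []

    def test_planted_match_reported_with_carriers(self, tmp_path):
        cat = tmp_path / "cat.tsv"
        cat.write_text("CALWEVRELGKKIKVF\tphosphoantigen-reactive\nbadrow\n")
        majors = [_mset(p, {"CALWEVRELGKKIKVF": 0.3}) for p in ("pt7", "pt8", "pt10")]
        with pytest.warns(UserWarning, match="malformed"):
            matches = screen_catalog(majors, cat)
        (m,) = matches
        assert m.sample_ids == ["pt10", "pt7", "pt8"]
        assert m.annotation == "phosphoantigen-reactive"

    def test_disjoint_catalog_no_overlap(self, tmp_path, gamma_majors):
        cat = tmp_path / "cat.tsv"
        cat.write_text("CASSLGTDTQYF\tCMV pp65\nCASSIRSSYEQYF\tEBV BMLF1\n")
        assert screen_catalog(gamma_majors, cat) == []
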