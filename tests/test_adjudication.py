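"""Naranjo, WHO-UMC, severity, mechanism, review merge, ATC lookup and the
machine-assessed adjudication path."""

import pytest

from icutrigger.adjudication import (ADRRecord, Detection, Mechanism, NaranjoAnswers,
                                     NaranjoCategory, ReviewDecision, Severity,
                                     WhoCausality, atc_lookup, classify_mechanism,
                                     classify_severity, merge_reviews, naranjo_category,
                                     naranjo_score, who_causality)

U, Y, N = "unknown", "yes", "no"


def answers(**overrides) -> NaranjoAnswers:
    base = [U] * 10
    for q, v in overrides.items():
        base[int(q[1:]) - 1] = v
    return NaranjoAnswers(tuple(base))


class TestNaranjo:
    def test_all_unknown_scores_zero(self):
        assert naranjo_score(answers()) == 0

    def test_yes_q1_to_q4(self):
        assert naranjo_score(answers(q1=Y, q2=Y, q3=Y, q4=Y)) == 1 + 2 + 1 + 2

    def test_negative_answers_subtract(self):
        # published points: Q2 no = -1, Q4 no = -1, Q5 yes (alternative
        # causes present) = -1, Q5 no = +2
        assert naranjo_score(answers(q2=N, q4=N, q5=Y)) == -3
        assert naranjo_score(answers(q2=N, q4=N, q5=N)) == 0

    def test_wrong_length_fatal(self):
        with pytest.raises(ValueError):
            NaranjoAnswers(("yes",) * 9)

    @pytest.mark.parametrize("score,expected", [
        (-4, NaranjoCategory.DOUBTFUL), (0, NaranjoCategory.DOUBTFUL),
        (1, NaranjoCategory.POSSIBLE), (4, NaranjoCategory.POSSIBLE),
        (5, NaranjoCategory.PROBABLE), (6, NaranjoCategory.PROBABLE),
        (8, NaranjoCategory.PROBABLE), (9, NaranjoCategory.DEFINITE),
        (13, NaranjoCategory.DEFINITE),
    ])
    def test_category_bands(self, score, expected):
        assert naranjo_category(score) is expected

    def test_breakpoints_exactly_at_0_4_8(self):
        cats = [naranjo_category(s) for s in range(-4, 14)]
        changes = [s for s, (a, b) in zip(range(-3, 14), zip(cats, cats[1:])) if a is not b]
        assert changes == [1, 5, 9]


class TestWhoCausality:
    def test_alternatives_present_gives_possible(self):
        assert who_causality(Y, "present", "unknown") is WhoCausality.POSSIBLE

    def test_insufficient_data_unassessable(self):
        assert who_causality(Y, data_sufficient=False) is WhoCausality.UNASSESSABLE_UNCLASSIFIABLE

    def test_excluded_alternatives_with_dechallenge_probable(self):
        assert who_causality(Y, "excluded", "positive", "none") is WhoCausality.PROBABLE

    def test_full_evidence_chain_certain(self):
        assert who_causality(Y, "excluded", "positive", "positive") is WhoCausality.CERTAIN

    def test_no_temporal_relation_unlikely(self):
        assert who_causality("no", "present") is WhoCausality.UNLIKELY

    def test_unknown_temporality_conditional(self):
        assert who_causality("unknown") is WhoCausality.CONDITIONAL_UNCLASSIFIED

    def test_contradictory_rechallenge_fatal(self):
        with pytest.raises(ValueError, match="contradictory"):
            who_causality(Y, rechallenge="positive", data_sufficient=False)

    def test_adding_evidence_never_weakens(self):
        strength = {WhoCausality.CERTAIN: 5, WhoCausality.PROBABLE: 4,
                    WhoCausality.POSSIBLE: 3}
        chain = [
            who_causality(Y, "unknown", "none"),
            who_causality(Y, "unknown", "positive"),
            who_causality(Y, "excluded", "positive"),
            who_causality(Y, "excluded", "positive", "positive"),
        ]
        assert all(strength[b] >= strength[a] for a, b in zip(chain, chain[1:]))


class TestSeverityMechanism:
    def test_no_intervention_is_mild(self):
        assert classify_severity(False, False, False) is Severity.MILD

    def test_therapy_change_is_moderate(self):
        assert classify_severity(True, True, False) is Severity.MODERATE

    def test_life_threatening_is_severe(self):
        assert classify_severity(True, True, True) is Severity.SEVERE

    @pytest.mark.parametrize("dose,pred,expected", [
        (True, True, Mechanism.A),
        (False, False, Mechanism.B),
        (True, False, Mechanism.B),
        (False, True, Mechanism.B),
    ])
    def test_type_a_requires_both_facts(self, dose, pred, expected):
        assert classify_mechanism(dose, pred) is expected


def _adr(**overrides) -> ADRRecord:
    base = dict(
        patient_id="P1", drug_name="regular insulin", atc_code="A10AB01",
        reaction="Hypoglycemia", onset_day=3,
        detection=Detection.trigger("blood_glucose_lt_50"),
        severity=Severity.MODERATE, mechanism=Mechanism.A,
        naranjo_score=4, naranjo_category=NaranjoCategory.POSSIBLE,
        who_causality=WhoCausality.POSSIBLE,
    )
    base.update(overrides)
    return ADRRecord(**base)


class TestMergeReviews:
    def test_identical_reviews_merge_to_same(self):
        a = ReviewDecision("r1", _adr())
        b = ReviewDecision("r2", _adr())
        assert merge_reviews(a, b) == _adr()
        assert merge_reviews(b, a) == _adr()  # symmetric

    def test_third_review_breaks_severity_divergence(self):
        a = ReviewDecision("r1", _adr(severity=Severity.MILD))
        b = ReviewDecision("r2", _adr(severity=Severity.SEVERE))
        third = ReviewDecision("r3", _adr(severity=Severity.MODERATE))
        assert merge_reviews(a, b, third).severity is Severity.MODERATE

    def test_divergence_without_third_names_field(self):
        a = ReviewDecision("r1", _adr(naranjo_score=4,
                                      naranjo_category=NaranjoCategory.POSSIBLE))
        b = ReviewDecision("r2", _adr(naranjo_score=6,
                                      naranjo_category=NaranjoCategory.PROBABLE))
        with pytest.raises(ValueError, match="naranjo_category"):
            merge_reviews(a, b)

    def test_different_adrs_cannot_merge(self):
        a = ReviewDecision("r1", _adr())
        b = ReviewDecision("r2", _adr(patient_id="P2"))
        with pytest.raises(ValueError, match="different ADRs"):
            merge_reviews(a, b)

    def test_category_must_match_score(self):
        with pytest.raises(ValueError, match="inconsistent"):
            _adr(naranjo_score=7, naranjo_category=NaranjoCategory.POSSIBLE)


class TestAtcLookup:
    @pytest.mark.parametrize("drug,code", [
        ("Regular insulin", "A10AB01"),
        ("Enoxaparin", "B01AB05"),
        ("morphine", "N02AA01"),
        ("SULFAMETHOXAZOLE + TRIMETHOPRIM", "J01EE01"),
    ])
    def test_known_drugs(self, drug, code):
        assert atc_lookup(drug) == code

    def test_unknown_drug_empty_code_with_warning(self):
        with pytest.warns(UserWarning, match="unknowndrug"):
            assert atc_lookup("unknowndrug") == ""


class TestMachineAdjudication:
    def test_every_ground_truth_adr_is_recovered_with_equal_classification(
            self, large_cohort, large_adrs):
        """The machine path reconstructs every embedded ADR from the raw
        record and assigns identical severity / mechanism / causality."""
        _, truth = large_cohort
        gt = {(g.patient_id, g.drug_name, g.onset_day): g for g in truth.adrs}
        assert len(large_adrs) == len(truth.adrs)
        for a in large_adrs:
            g = gt[(a.patient_id, a.drug_name, a.onset_day)]
            assert a.reaction == g.reaction
            assert a.severity.value == g.severity
            assert a.mechanism.value == g.mechanism
            assert a.naranjo_score == g.naranjo_score
            assert a.naranjo_category.value == g.naranjo_category
            assert a.who_causality.value == g.who_causality
            assert a.assessed_by == "machine"

    def test_detection_source_matches_embedded_signature(self, large_cohort, large_adrs):
        _, truth = large_cohort
        gt = {(g.patient_id, g.drug_name, g.onset_day): g for g in truth.adrs}
        for a in large_adrs:
            g = gt[(a.patient_id, a.drug_name, a.onset_day)]
            if g.signature_trigger is None:
                assert a.detection.source == "NON_TRIGGER_REVIEW"
            else:
                assert a.detection == Detection.trigger(g.signature_trigger)

    def test_atc_codes_populated(self, study_adrs):
        assert study_adrs, "expected some ADRs in the default cohort"
        assert all(len(a.atc_code) == 7 for a in study_adrs)
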