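"""Alert engine: the six check classes, aggregation, overrides."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmsched import (
    PatientCase,
    PrescriptionItem,
    Routine,
    apply_override,
    check_contraindications,
    check_dose,
    check_duplication,
    check_food_and_observations,
    check_nu_pairs,
    generate_case,
    resolve_principles,
    review_prescription,
)

DAY = Routine(wake_time=7 * 60, sleep_time=22 * 60)


def make_case(items, conditions=frozenset(), weight=70.0, case_id="t",
              qualifiers=()):
    return PatientCase(
        case_id=case_id, age=40.0, weight=weight, sex="unspecified",
        conditions=frozenset(conditions), condition_qualifiers=tuple(qualifiers),
        routine=DAY, prescription=tuple(items),
    )


def rx(drug, amount=1.0, n=1, **kw):
    return PrescriptionItem(drug=drug, dose_amount=amount, doses_per_day=n, **kw)


class TestNuPairs:
    def test_aspirin_warfarin_pair_is_blocking(self, kb):
        alerts = check_nu_pairs((rx("ASPIRIN 500 MG", 500), rx("WARFARIN 2.5 MG", 2.5)), kb)
        assert len(alerts) == 1
        assert alerts[0].alert_type == "nu_interaction"
        assert alerts[0].severity == "blocking"
        assert alerts[0].items_involved == (0, 1)

    def test_single_item_has_no_pairs(self, kb):
        assert check_nu_pairs((rx("ASPIRIN 500 MG", 500),), kb) == []

    def test_one_item_matching_two_others_gives_two_alerts(self, kb):
        # warfarin clashes with aspirin only in the fixture KB, so plant the
        # aspirin principle in two distinct items via duplicated products:
        items = (rx("WARFARIN 2.5 MG", 2.5), rx("ASPIRIN 500 MG", 500),
                 rx("Aspirin 500 mg ", 500))
        # product names canonicalize identically -> same principle twice
        alerts = check_nu_pairs(items, kb)
        assert len(alerts) == 2
        assert {a.items_involved for a in alerts} == {(0, 1), (0, 2)}

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.sampled_from(
        ["ASPIRIN 500 MG", "WARFARIN 2.5 MG", "DIGOXIN 0.25 MG",
         "OMEPRAZOLE 20 MG", "ENALAPRIL 10 MG", "MYLANTA PLUS"]),
        min_size=0, max_size=12))
    def test_matches_brute_force_double_loop(self, kb, names):
        """The engine's pair scan equals an independently written O(n^2)
        enumeration over item pairs and NU rules."""
        items = tuple(rx(n) for n in names)
        got = {(a.items_involved, frozenset()) for a in check_nu_pairs(items, kb)}
        nu_pairs = [r.pair for r in kb.interactions if r.rule_type == "NU"]
        expected = set()
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                pi = resolve_principles(items[i], kb)
                pj = resolve_principles(items[j], kb)
                for pair in nu_pairs:
                    pa, pb = sorted(pair)
                    if (pa in pi and pb in pj) or (pb in pi and pa in pj):
                        expected.add(((i, j), frozenset()))
        assert got == expected


class TestContraindications:
    def test_cirrhosis_plus_atorvastatin_blocks(self, kb):
        case = make_case([rx("ATORVASTATIN CALCIUM 20 MG", 20)],
                         conditions={"severe_hepatic_disease"})
        alerts = check_contraindications(case, kb)
        assert len(alerts) == 1
        assert alerts[0].severity == "blocking" and not alerts[0].overridden

    def test_override_note_pre_overrides_the_alert(self, kb):
        case = make_case(
            [rx("CARBAMAZEPINE 200 MG", 200, n=2,
                clinical_override_note="risk accepted")],
            conditions={"pregnancy"},
            qualifiers=(("pregnancy", "weeks", 12.0),),
        )
        alerts = check_contraindications(case, kb)
        assert len(alerts) == 1
        assert alerts[0].overridden
        assert alerts[0].justification == "risk accepted"

    def test_no_conditions_no_alerts(self, kb):
        case = make_case([rx("ATORVASTATIN CALCIUM 20 MG", 20)])
        assert check_contraindications(case, kb) == []


class TestDuplication:
    def test_shared_principle_flagged(self, kb):
        items = (rx("ASPIRIN 500 MG", 500), rx("aspirin 500 MG", 500))
        alerts = check_duplication(items, kb)
        assert len(alerts) == 1
        assert alerts[0].alert_type == "duplication"

    def test_distinct_items_clean(self, kb):
        items = tuple(rx(n) for n in [
            "ENALAPRIL 10 MG", "PARACETAMOL 500 MG", "LOSARTAN 50 MG",
            "AMLODIPINE 5 MG", "HYDROCHLOROTHIAZIDE 25 MG", "SERTRALINE 50 MG",
            "CETIRIZINE 10 MG", "COLECALCIFEROL 1000 IU", "OMEPRAZOLE 20 MG",
            "DIGOXIN 0.25 MG"])
        assert check_duplication(items, kb) == []

    def test_two_statins_share_atc_subgroup(self, kb):
        items = (rx("ATORVASTATIN CALCIUM 20 MG", 20), rx("SIMVASTATIN 20 MG", 20))
        alerts = check_duplication(items, kb)
        assert len(alerts) == 1
        assert "C10AA" in alerts[0].message
        assert alerts[0].severity == "warning"


class TestDoseChecks:
    def test_pediatric_overdose_flagged(self, kb):
        # 13 kg child, fixture cap 10 mg/kg/day, 200 mg once = 15.4 mg/kg/day
        case = make_case([rx("AZITHROMYCIN SUSPENSION", 200.0)], weight=13.0)
        alerts = check_dose(case, kb)
        assert [a.alert_type for a in alerts] == ["overdose"]

    def test_dose_exactly_at_limit_is_compliant(self, kb):
        case = make_case([rx("AZITHROMYCIN SUSPENSION", 130.0)], weight=13.0)
        assert check_dose(case, kb) == []

    def test_no_limits_no_alerts(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", 10)])
        assert check_dose(case, kb) == []

    def test_underdose_flagged(self, kb):
        # amoxicillin fixture min 20 mg/kg/day; 100 mg once in 21 kg = 4.8
        case = make_case([rx("AMOXICILLIN SUSPENSION", 100.0)], weight=21.0)
        assert [a.alert_type for a in check_dose(case, kb)] == ["underdose"]

    def test_missing_weight_yields_cannot_evaluate_info_alert(self, kb):
        case = make_case([rx("AZITHROMYCIN SUSPENSION", 200.0)], weight=None)
        alerts = check_dose(case, kb)
        assert len(alerts) == 1
        assert alerts[0].severity == "info"
        assert "cannot evaluate" in alerts[0].message

    def test_single_dose_cap(self, kb):
        case = make_case([rx("PARACETAMOL 500 MG", 1500.0)])
        alerts = check_dose(case, kb)
        assert len(alerts) == 1 and "single dose" in alerts[0].message


class TestFoodAndObservations:
    def test_empty_stomach_info_alert(self, kb):
        alerts = check_food_and_observations((rx("OMEPRAZOLE 20 MG", 20),), kb)
        assert [a.alert_type for a in alerts] == ["food_relation"]
        assert alerts[0].severity == "info"

    def test_alendronate_posture_observation(self, kb):
        alerts = check_food_and_observations(
            (rx("ALENDRONATE SODIUM 70 MG", 70),), kb)
        types = [a.alert_type for a in alerts]
        assert "observation" in types  # posture instruction
        assert "food_relation" in types  # empty stomach
        posture = [a for a in alerts if a.alert_type == "observation"][0]
        assert "upright" in posture.message

    def test_plain_drug_emits_nothing(self, kb):
        assert check_food_and_observations((rx("ENALAPRIL 10 MG", 10),), kb) == []


class TestReviewAggregation:
    def test_case01_contains_exactly_the_planted_nu_alert(self, kb, cases_by_class):
        report = review_prescription(cases_by_class["nu_pair"].case, kb)
        assert report.alerts_of_type("nu_interaction")
        assert report.has_unresolved_blocking

    def test_clean_prescription_has_no_blocking(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", 10), rx("PARACETAMOL 500 MG", 500)])
        report = review_prescription(case, kb)
        assert not report.has_unresolved_blocking
        assert report.alerts == ()

    def test_overdose_and_contraindication_both_present(self, kb):
        case = make_case(
            [rx("AZITHROMYCIN SUSPENSION", 200.0),
             rx("ATORVASTATIN CALCIUM 20 MG", 20)],
            conditions={"severe_hepatic_disease"}, weight=13.0,
        )
        report = review_prescription(case, kb)
        assert {"overdose", "contraindication"} <= report.alert_types

    def test_blocking_alerts_sort_first_and_ids_are_stable(self, kb):
        case = make_case(
            [rx("OMEPRAZOLE 20 MG", 20), rx("ASPIRIN 500 MG", 500),
             rx("WARFARIN 2.5 MG", 2.5)])
        report = review_prescription(case, kb)
        severities = [a.severity for a in report.alerts]
        assert severities == sorted(severities,
                                    key={"blocking": 0, "warning": 1, "info": 2}.get)
        assert [a.alert_id for a in report.alerts] == \
               [f"A{i+1}" for i in range(len(report.alerts))]

    def test_review_is_deterministic_byte_for_byte(self, kb, cases):
        for pc in cases:
            r1 = review_prescription(pc.case, kb)
            r2 = review_prescription(pc.case, kb)
            assert r1.to_json() == r2.to_json()

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_clean_synthetic_cases_trigger_zero_alerts(self, kb, seed):
        pc = generate_case("none", seed)
        assert review_prescription(pc.case, kb).alerts == ()


class TestOverrides:
    def test_override_single_blocking_clears_gate(self, kb, cases_by_class):
        report = review_prescription(cases_by_class["nu_pair"].case, kb)
        blocking = [a for a in report.alerts if a.severity == "blocking"]
        assert len(blocking) == 1
        updated = apply_override(report, blocking[0].alert_id, "reviewed")
        assert not updated.has_unresolved_blocking
        kept = updated.alerts_of_type("nu_interaction")[0]
        assert kept.message == blocking[0].message  # record retained

    def test_override_one_of_two_blocking_keeps_gate(self, kb):
        case = make_case(
            [rx("ASPIRIN 500 MG", 500), rx("WARFARIN 2.5 MG", 2.5),
             rx("ATORVASTATIN CALCIUM 20 MG", 20)],
            conditions={"severe_hepatic_disease"})
        report = review_prescription(case, kb)
        blocking = [a for a in report.alerts if a.severity == "blocking"]
        assert len(blocking) == 2
        updated = apply_override(report, blocking[0].alert_id, "ok")
        assert updated.has_unresolved_blocking

    def test_override_info_alert_changes_only_the_flag(self, kb):
        case = make_case([rx("OMEPRAZOLE 20 MG", 20)])
        report = review_prescription(case, kb)
        updated = apply_override(report, report.alerts[0].alert_id, "noted")
        assert updated.alerts[0].overridden
        assert updated.alerts[0].message == report.alerts[0].message
        assert not updated.has_unresolved_blocking

    def test_unknown_alert_id_raises(self, kb, cases_by_class):
        report = review_prescription(cases_by_class["nu_pair"].case, kb)
        with pytest.raises(KeyError):
            apply_override(report, "A999", "nope")
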