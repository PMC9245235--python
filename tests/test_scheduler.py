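"""GA scheduler: constraints, penalty fitness, evolution, oracle, learning."""

import numpy as np
import pytest

from pharmsched import (
    BlockingAlertsError,
    GAConfig,
    PatientCase,
    PenaltyWeights,
    PrescriptionItem,
    PreferenceStore,
    Routine,
    apply_override,
    audit_schedule,
    brute_force_schedule,
    build_constraints,
    evolve,
    fitness,
    record_intervention,
    review_prescription,
)
from pharmsched.scheduler import HARD_CLASSES
from pharmsched.timeutil import circular_diff, parse_clock

DAY = Routine(wake_time=7 * 60, sleep_time=22 * 60,
              meal_times=((parse_clock("07:30"), "breakfast"),
                          (parse_clock("12:30"), "lunch"),
                          (parse_clock("19:30"), "dinner")))


def make_case(items, routine=DAY, case_id="t", **kw):
    return PatientCase(
        case_id=case_id, age=40.0, weight=70.0, sex="unspecified",
        conditions=frozenset(kw.pop("conditions", ())),
        condition_qualifiers=(), routine=routine, prescription=tuple(items),
    )


def reviewed_constraints(case, kb, override_all=False):
    report = review_prescription(case, kb)
    if override_all:
        for a in report.alerts:
            if a.severity == "blocking" and not a.overridden:
                report = apply_override(report, a.alert_id, "test override")
    return build_constraints(case, kb, report)


def rx(drug, amount=1.0, n=None, interval=None, fixed=None, **kw):
    return PrescriptionItem(drug=drug, dose_amount=amount, doses_per_day=n,
                            interval_hours=interval, fixed_times=fixed, **kw)


class TestBuildConstraints:
    def test_digoxin_antacid_yields_pairwise_min_intervals(self, kb):
        case = make_case([rx("DIGOXIN 0.25 MG", n=1), rx("MYLANTA PLUS", n=3)])
        cs = reviewed_constraints(case, kb)
        pair = [p for p in cs.pairs if p.klass == "pair_interval"]
        assert len(pair) == 3  # 1 digoxin dose x 3 antacid doses
        assert all(p.min_minutes == 120 for p in pair)
        assert all("S rule" in p.source for p in pair)

    def test_empty_stomach_anchors_windows_before_meals(self, kb):
        case = make_case([rx("OMEPRAZOLE 20 MG", n=1)])
        cs = reviewed_constraints(case, kb)
        food = [w for w in cs.windows if w.klass == "food"]
        assert len(food) == 1
        # lead 30, width 60: a window ends 30 min before each meal
        assert (parse_clock("06:00"), parse_clock("07:01")) in food[0].allowed

    def test_routine_only_prescription_has_awake_and_spacing_only(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", n=2)])
        cs = reviewed_constraints(case, kb)
        assert [w.klass for w in cs.windows] == ["sleep"]
        assert cs.pairs == ()
        assert len(cs.spacings) == 1

    def test_unresolved_blocking_alerts_refuse_scheduling(self, kb):
        case = make_case([rx("ASPIRIN 500 MG", 500, n=1),
                          rx("WARFARIN 2.5 MG", 2.5, n=1)])
        report = review_prescription(case, kb)
        with pytest.raises(BlockingAlertsError, match="nu_interaction"):
            build_constraints(case, kb, report)

    def test_every_constraint_carries_provenance(self, kb, cases):
        for pc in cases:
            cs = reviewed_constraints(pc.case, kb, override_all=True)
            for group in (cs.windows, cs.pairs, cs.spacings, cs.pins):
                assert all(c.source for c in group)


class TestFitness:
    def test_fully_compliant_schedule_scores_zero(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", n=1)])
        cs = reviewed_constraints(case, kb)
        total, breakdown = fitness([20], cs)  # slot 20 = 10:00, awake
        assert total == 0.0
        assert all(v == 0.0 for v in breakdown.values())

    def test_interval_shortfall_is_linear_in_minutes(self, kb):
        case = make_case([rx("DIGOXIN 0.25 MG", n=1), rx("MYLANTA PLUS", n=1)])
        cs = reviewed_constraints(case, kb)
        w = PenaltyWeights(pair_interval=1.0, sleep=0.0)
        # doses 60 min apart under a 120-min rule -> shortfall 60
        total, breakdown = fitness([16, 18], cs, weights=w)
        assert breakdown["pair_interval"] == 60.0

    def test_doubling_weights_doubles_total(self, kb):
        case = make_case([rx("DIGOXIN 0.25 MG", n=1), rx("MYLANTA PLUS", n=3)])
        cs = reviewed_constraints(case, kb)
        chrom = [2, 3, 4, 5]  # deliberately in-sleep and clustered
        w1 = PenaltyWeights()
        t1, _ = fitness(chrom, cs, weights=w1)
        t2, _ = fitness(chrom, cs, weights=w1.scaled(2.0))
        assert t1 > 0
        assert t2 == pytest.approx(2.0 * t1)

    def test_spacing_wraps_the_day_cyclically(self, kb):
        # two doses at 07:00 and 21:30: day-gap 870, wrap-gap 570; target 720
        case = make_case([rx("ENALAPRIL 10 MG", n=2)])
        cs = reviewed_constraints(case, kb)
        w = PenaltyWeights(sleep=0.0, spacing=1.0)
        total, breakdown = fitness([14, 43], cs, weights=w)
        assert breakdown["spacing"] == pytest.approx((870 - 720 - 60) + (720 - 570 - 60))


class TestEvolve:
    def test_unconstrained_single_dose_hits_zero(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", n=1)])
        cs = reviewed_constraints(case, kb)
        result = evolve(cs, GAConfig(random_seed=1))
        assert result.fitness == 0.0 and result.feasible
        t = dict(result.schedule)["ENALAPRIL 10 MG"][0]
        assert 7 * 60 <= t < 22 * 60  # any awake slot is acceptable

    def test_min_interval_case_schedules_feasibly(self, kb, cases_by_class):
        pc = cases_by_class["min_interval"]
        cs = reviewed_constraints(pc.case, kb)
        result = evolve(cs, GAConfig(random_seed=42))
        assert result.feasible
        digoxin = dict(result.schedule)["DIGOXIN 0.25 MG"]
        antacid = dict(result.schedule)["MYLANTA PLUS"]
        for a in digoxin:
            for b in antacid:
                assert circular_diff(a, b) >= 120

    def test_infeasible_pins_report_violations(self, kb):
        # both items pinned to the same slot while an S rule demands 120 min
        case = make_case([
            rx("DIGOXIN 0.25 MG", n=1, fixed=(parse_clock("08:00"),)),
            rx("MYLANTA PLUS", n=1, fixed=(parse_clock("08:00"),)),
        ])
        cs = reviewed_constraints(case, kb)
        result = evolve(cs, GAConfig(random_seed=3, generations=60))
        assert not result.feasible
        assert result.fitness > 0
        hard = [v for v in result.violations if v["class"] in HARD_CLASSES]
        assert hard
        # any best compromise violates pin and/or pair by 120 min in total
        assert sum(v["magnitude"] for v in hard) == pytest.approx(120.0)

    def test_best_fitness_monotonically_non_increasing(self, kb, cases):
        for pc in cases:
            cs = reviewed_constraints(pc.case, kb, override_all=True)
            result = evolve(cs, GAConfig(random_seed=11, generations=40))
            hist = result.fitness_history
            assert all(b <= a for a, b in zip(hist, hist[1:]))

    def test_identical_seed_identical_result(self, kb, cases_by_class):
        pc = cases_by_class["sleep_protection"]
        cs = reviewed_constraints(pc.case, kb)
        r1 = evolve(cs, GAConfig(random_seed=99))
        r2 = evolve(cs, GAConfig(random_seed=99))
        assert r1.to_json() == r2.to_json()

    def test_feasible_result_passes_independent_audit(self, kb, cases):
        for pc in cases:
            cs = reviewed_constraints(pc.case, kb, override_all=True)
            result = evolve(cs, GAConfig(random_seed=42))
            assert result.feasible
            assert audit_schedule(result.times_by_gene(cs), cs) == []

    def test_missing_seed_rejected(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", n=1)])
        cs = reviewed_constraints(case, kb)
        with pytest.raises(ValueError, match="seed"):
            evolve(cs, GAConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(crossover_rate=1.5)
        with pytest.raises(ValueError):
            GAConfig(population_size=10, elitism_count=10)
        with pytest.raises(ValueError):
            GAConfig(slot_minutes=7)


class TestBruteForce:
    def test_single_dose_optimum_zero(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", n=1)])
        cs = reviewed_constraints(case, kb)
        result = brute_force_schedule(cs)
        assert result.fitness == 0.0

    def test_two_items_with_spacing_rule_optimum_zero(self, kb):
        case = make_case([rx("DIGOXIN 0.25 MG", n=1), rx("MYLANTA PLUS", n=1)])
        cs = reviewed_constraints(case, kb)
        result = brute_force_schedule(cs)
        assert result.fitness == 0.0
        times = dict(result.schedule)
        assert circular_diff(times["DIGOXIN 0.25 MG"][0],
                             times["MYLANTA PLUS"][0]) >= 120

    def test_overconstrained_optimum_equals_hand_computed_shortfall(self, kb):
        # pins force a 60-min gap; the S rule wants 120 -> minimal shortfall 60
        case = make_case([
            rx("DIGOXIN 0.25 MG", n=1, fixed=(parse_clock("08:00"),)),
            rx("MYLANTA PLUS", n=1, fixed=(parse_clock("09:00"),)),
        ])
        cs = reviewed_constraints(case, kb)
        result = brute_force_schedule(cs)
        w = PenaltyWeights()
        assert result.fitness == pytest.approx(60 * w.pair_interval)

    def test_search_space_guard(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", n=3),
                          rx("PARACETAMOL 500 MG", n=3)])
        cs = reviewed_constraints(case, kb)
        with pytest.raises(ValueError, match="guard"):
            brute_force_schedule(cs, slot_minutes=30)


class TestPreferenceLearning:
    def test_isolation_edit_induces_rule_kept_on_rerun(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", n=1),
                          rx("PARACETAMOL 500 MG", n=2)])
        cs = reviewed_constraints(case, kb)
        result = evolve(cs, GAConfig(random_seed=5))
        store = PreferenceStore()
        # user moves enalapril far from both paracetamol doses
        others = dict(result.schedule)["PARACETAMOL 500 MG"]
        target = max(range(0, 1440, 30),
                     key=lambda t: min(circular_diff(t, o) for o in others))
        record_intervention(result, cs, {"ENALAPRIL 10 MG": [target]}, store,
                            origin="edit-1")
        assert len(store.rules) == 1
        rule = store.rules[0]
        assert rule.kind == "administer_alone"
        assert rule.separation_minutes >= 60

        report = review_prescription(case, kb)
        cs2 = build_constraints(case, kb, report, preferences=store)
        assert any(p.klass == "preference" for p in cs2.pairs)
        rerun = evolve(cs2, GAConfig(random_seed=5))
        ena = dict(rerun.schedule)["ENALAPRIL 10 MG"]
        para = dict(rerun.schedule)["PARACETAMOL 500 MG"]
        assert min(circular_diff(a, b) for a in ena for b in para) >= \
            rule.separation_minutes

    def test_empty_edit_leaves_store_unchanged(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", n=1)])
        cs = reviewed_constraints(case, kb)
        result = evolve(cs, GAConfig(random_seed=5))
        store = PreferenceStore()
        record_intervention(result, cs, {}, store)
        assert store.rules == []

    def test_unknown_item_in_edit_raises(self, kb):
        case = make_case([rx("ENALAPRIL 10 MG", n=1)])
        cs = reviewed_constraints(case, kb)
        result = evolve(cs, GAConfig(random_seed=5))
        with pytest.raises(KeyError):
            record_intervention(result, cs, {"GHOST": [300]}, PreferenceStore())

    def test_conflicting_later_rule_wins_but_both_stored(self, kb):
        from pharmsched import PreferenceRule

        store = PreferenceStore()
        store.append(PreferenceRule(scope="X", kind="administer_alone",
                                    separation_minutes=30))
        store.append(PreferenceRule(scope="X", kind="administer_alone",
                                    separation_minutes=90))
        assert len(store.rules) == 2  # append-only
        effective = store.effective_rules()
        assert len(effective) == 1
        assert effective[0].separation_minutes == 90

    def test_store_round_trips(self, tmp_path):
        from pharmsched import PreferenceRule

        store = PreferenceStore()
        store.append(PreferenceRule(scope="X", kind="administer_alone",
                                    separation_minutes=45, origin="edit-9"))
        path = tmp_path / "prefs.json"
        store.save(path)
        loaded = PreferenceStore.load(path)
        assert loaded.rules == store.rules


class TestHardSoftSeparation:
    def test_hard_weights_dominate_soft(self):
        w = PenaltyWeights()
        soft_max = max(getattr(w, c) for c in ("spacing", "busy", "preference"))
        for c in HARD_CLASSES:
            assert getattr(w, c) >= 1000 * soft_max / max(soft_max, 1.0)

    def test_q8h_child_sleep_stays_hard_spacing_absorbs(self, kb, cases_by_class):
        """Sleep protection: the q8h regimen compresses into the awake day;
        the sleep window is never violated, spacing deviation is tolerated."""
        pc = cases_by_class["sleep_protection"]
        cs = reviewed_constraints(pc.case, kb)
        result = evolve(cs, GAConfig(random_seed=42))
        assert result.feasible
        assert result.breakdown["sleep"] == 0.0
        times = dict(result.schedule)["AMOXICILLIN SUSPENSION"]
        awake = [(7 * 60, 21 * 60)]
        assert all(awake[0][0] <= t < awake[0][1] for t in times)
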