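"""Alert engine: cross prescription and patient profile against the KB.

The engine only reports — it never removes a drug from the prescription.
Blocking alerts gate the scheduler until a user explicitly overrides them
with a justification; an overridden alert keeps its full record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .model import (
    KnowledgeBase,
    PatientCase,
    PrescriptionItem,
    resolve_principles,
)

__all__ = [
    "Alert",
    "AlertReport",
    "ALERT_TYPES",
    "DEFAULT_SEVERITY",
    "check_nu_pairs",
    "check_contraindications",
    "check_duplication",
    "check_dose",
    "check_min_intervals",
    "check_food_and_observations",
    "review_prescription",
    "apply_override",
]

ALERT_TYPES = (
    "nu_interaction",
    "contraindication",
    "duplication",
    "overdose",
    "underdose",
    "food_relation",
    "observation",
    "min_interval_needed",
)

#: Package convention, overridable per rule in the KB (``severity`` field).
DEFAULT_SEVERITY = {
    "nu_interaction": "blocking",
    "contraindication": "blocking",
    "duplication": "warning",
    "overdose": "warning",
    "underdose": "warning",
    "food_relation": "info",
    "observation": "info",
    "min_interval_needed": "info",
}

_SEVERITY_RANK = {"blocking": 0, "warning": 1, "info": 2}

#: Strict-inequality dose comparisons allow this much relative float noise;
#: a dose exactly at the limit is compliant.
DOSE_RTOL = 1e-9


@dataclass(frozen=True)
class Alert:
    """One finding of the engine; immutable apart from override bookkeeping."""

    alert_id: str
    alert_type: str
    severity: str
    items_involved: tuple[int, ...]
    message: str
    overridden: bool = False
    justification: str | None = None

    def to_dict(self) -> dict:
        return {
            "alert_id": self.alert_id,
            "alert_type": self.alert_type,
            "severity": self.severity,
            "items_involved": list(self.items_involved),
            "message": self.message,
            "overridden": self.overridden,
            "justification": self.justification,
        }


@dataclass(frozen=True)
class AlertReport:
    """All alerts for one case, stably ordered (blocking first)."""

    case_id: str
    alerts: tuple[Alert, ...] = ()

    @property
    def has_unresolved_blocking(self) -> bool:
        return any(a.severity == "blocking" and not a.overridden for a in self.alerts)

    def alerts_of_type(self, alert_type: str) -> list[Alert]:
        return [a for a in self.alerts if a.alert_type == alert_type]

    @property
    def alert_types(self) -> frozenset[str]:
        return frozenset(a.alert_type for a in self.alerts)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "alerts": [a.to_dict() for a in self.alerts],
            "has_unresolved_blocking": self.has_unresolved_blocking,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def _alert(alert_type: str, items: tuple[int, ...], message: str,
           severity: str | None = None, overridden: bool = False,
           justification: str | None = None) -> Alert:
    return Alert(
        alert_id="",  # assigned after sorting in review_prescription
        alert_type=alert_type,
        severity=severity or DEFAULT_SEVERITY[alert_type],
        items_involved=items,
        message=message,
        overridden=overridden,
        justification=justification,
    )


def check_nu_pairs(prescription: tuple[PrescriptionItem, ...],
                   kb: KnowledgeBase) -> list[Alert]:
    """One alert per unordered principle pair matching an NU rule across items."""
    nu_rules = {r.pair: r for r in kb.rules_of_type("NU")}
    principles = [resolve_principles(item, kb) for item in prescription]
    alerts = []
    seen: set[tuple[frozenset[str], tuple[int, int]]] = set()
    for i in range(len(prescription)):
        for j in range(i + 1, len(prescription)):
            for pa in sorted(principles[i]):
                for pb in sorted(principles[j]):
                    pair = frozenset({pa, pb})
                    rule = nu_rules.get(pair)
                    if rule is None or (pair, (i, j)) in seen:
                        continue
                    seen.add((pair, (i, j)))
                    msg = rule.message or (
                        f"{pa} and {pb} should not be used concomitantly"
                    )
                    alerts.append(
                        _alert(
                            "nu_interaction", (i, j),
                            f"{prescription[i].drug} + {prescription[j].drug}: {msg}",
                            severity=rule.severity,
                        )
                    )
    return alerts


def check_contraindications(case: PatientCase, kb: KnowledgeBase) -> list[Alert]:
    """One alert per (item, condition) hit; override notes pre-override it."""
    alerts = []
    for i, item in enumerate(case.prescription):
        drug = kb.find_drug(item.drug)
        for condition in sorted(drug.contraindicated_conditions & case.conditions):
            overridden = item.clinical_override_note is not None
            alerts.append(
                _alert(
                    "contraindication", (i,),
                    f"{item.drug} is contraindicated for condition "
                    f"'{condition}'",
                    overridden=overridden,
                    justification=item.clinical_override_note,
                )
            )
    return alerts


def check_duplication(prescription: tuple[PrescriptionItem, ...],
                      kb: KnowledgeBase) -> list[Alert]:
    """Two-tier therapeutic duplication.

    Exact tier: a principle delivered by two or more distinct items (warning).
    Class tier: two items sharing a 5-character ATC prefix — same chemical
    subgroup — without sharing a principle (warning, softer message).
    """
    principles = [resolve_principles(item, kb) for item in prescription]
    alerts = []
    by_principle: dict[str, list[int]] = {}
    for i, ps in enumerate(principles):
        for p in ps:
            by_principle.setdefault(p, []).append(i)
    for principle in sorted(by_principle):
        items = by_principle[principle]
        if len(items) >= 2:
            names = ", ".join(prescription[i].drug for i in items)
            alerts.append(
                _alert(
                    "duplication", tuple(items),
                    f"therapeutic duplication: {principle} delivered by {names}",
                )
            )
    for i in range(len(prescription)):
        for j in range(i + 1, len(prescription)):
            if principles[i] & principles[j]:
                continue  # already flagged at the exact tier
            a = kb.find_drug(prescription[i].drug).atc_code
            b = kb.find_drug(prescription[j].drug).atc_code
            if a and b and a[:5] == b[:5]:
                alerts.append(
                    _alert(
                        "duplication", (i, j),
                        f"possible class duplication: {prescription[i].drug} and "
                        f"{prescription[j].drug} share ATC subgroup {a[:5]}",
                    )
                )
    return alerts


def check_dose(case: PatientCase, kb: KnowledgeBase) -> list[Alert]:
    """Over/underdose against per-kg daily limits and the single-dose cap.

    A dose exactly at a limit is compliant (strict inequality up to float
    noise).  A per-kg limit with no patient weight yields an explicit
    "cannot evaluate" info alert, never silence.
    """
    alerts = []
    for i, item in enumerate(case.prescription):
        drug = kb.find_drug(item.drug)
        per_kg_limits = (drug.max_daily_dose_per_kg, drug.min_daily_dose_per_kg)
        if any(v is not None for v in per_kg_limits) and case.weight is None:
            alerts.append(
                _alert(
                    "overdose", (i,),
                    f"{item.drug}: cannot evaluate per-kg dose limits, patient "
                    "weight missing",
                    severity="info",
                )
            )
            continue
        daily = item.dose_amount * item.daily_frequency
        if drug.max_daily_dose_per_kg is not None:
            per_kg = daily / case.weight
            if per_kg > drug.max_daily_dose_per_kg * (1 + DOSE_RTOL):
                alerts.append(
                    _alert(
                        "overdose", (i,),
                        f"{item.drug}: {per_kg:.2f} per kg/day exceeds maximum "
                        f"{drug.max_daily_dose_per_kg:g} per kg/day",
                    )
                )
        if drug.min_daily_dose_per_kg is not None:
            per_kg = daily / case.weight
            if per_kg < drug.min_daily_dose_per_kg * (1 - DOSE_RTOL):
                alerts.append(
                    _alert(
                        "underdose", (i,),
                        f"{item.drug}: {per_kg:.2f} per kg/day is below minimum "
                        f"{drug.min_daily_dose_per_kg:g} per kg/day",
                    )
                )
        if drug.max_single_dose is not None and \
                item.dose_amount > drug.max_single_dose * (1 + DOSE_RTOL):
            alerts.append(
                _alert(
                    "overdose", (i,),
                    f"{item.drug}: single dose {item.dose_amount:g} exceeds "
                    f"maximum {drug.max_single_dose:g}",
                )
            )
    return alerts


def check_min_intervals(prescription: tuple[PrescriptionItem, ...],
                        kb: KnowledgeBase) -> list[Alert]:
    """Info alerts for drug–drug S rules matched across distinct items.

    The scheduler consumes the same rules as hard spacing constraints; the
    alert makes the requirement visible in the review report.
    """
    s_rules = [
        r for r in kb.rules_of_type("S")
        if r.principle_a not in kb.food_tokens and r.principle_b not in kb.food_tokens
    ]
    principles = [resolve_principles(item, kb) for item in prescription]
    alerts = []
    for i in range(len(prescription)):
        for j in range(i + 1, len(prescription)):
            for rule in s_rules:
                hit = (rule.principle_a in principles[i] and rule.principle_b in principles[j]) or \
                      (rule.principle_b in principles[i] and rule.principle_a in principles[j])
                if hit:
                    msg = rule.message or "a minimum interval between doses is required"
                    alerts.append(
                        _alert(
                            "min_interval_needed", (i, j),
                            f"{prescription[i].drug} + {prescription[j].drug}: "
                            f"keep at least {rule.min_interval_minutes} min "
                            f"between doses ({msg})",
                            severity=rule.severity,
                        )
                    )
    return alerts


def check_food_and_observations(prescription: tuple[PrescriptionItem, ...],
                                kb: KnowledgeBase) -> list[Alert]:
    """Info alerts for food relations, O rules and administration guidance."""
    alerts = []
    principles = [resolve_principles(item, kb) for item in prescription]
    for i, item in enumerate(prescription):
        drug = kb.find_drug(item.drug)
        fr = drug.food_relation
        if fr.kind == "empty_stomach":
            alerts.append(
                _alert(
                    "food_relation", (i,),
                    f"{item.drug}: take on an empty stomach, at least "
                    f"{fr.lead_minutes} min before a meal",
                )
            )
        elif fr.kind == "with_food":
            alerts.append(
                _alert(
                    "food_relation", (i,),
                    f"{item.drug}: take with food (within {fr.lag_minutes} min "
                    "of a meal)",
                )
            )
        for obs in drug.administration_observations:
            alerts.append(_alert("observation", (i,), f"{item.drug}: {obs}"))
    # O rules: principle↔food guidance or principle-pair guidance
    for rule in kb.rules_of_type("O"):
        a_food = rule.principle_a in kb.food_tokens
        b_food = rule.principle_b in kb.food_tokens
        if a_food or b_food:
            principle = rule.principle_b if a_food else rule.principle_a
            for i, ps in enumerate(principles):
                if principle in ps:
                    alerts.append(
                        _alert("observation", (i,),
                               f"{prescription[i].drug}: {rule.message}",
                               severity=rule.severity)
                    )
        else:
            for i in range(len(prescription)):
                for j in range(i + 1, len(prescription)):
                    hit = (rule.principle_a in principles[i] and rule.principle_b in principles[j]) or \
                          (rule.principle_b in principles[i] and rule.principle_a in principles[j])
                    if hit:
                        alerts.append(
                            _alert("observation", (i, j),
                                   f"{prescription[i].drug} + "
                                   f"{prescription[j].drug}: {rule.message}",
                                   severity=rule.severity)
                        )
    return alerts


def review_prescription(case: PatientCase, kb: KnowledgeBase) -> AlertReport:
    """Run every check and aggregate into a stably ordered report.

    Ordering: blocking, then warning, then info; within a severity by first
    involved item, then alert type, then message.  Idempotent and
    deterministic: identical inputs serialize byte-for-byte identically.
    """
    collected: list[Alert] = []
    collected += check_nu_pairs(case.prescription, kb)
    collected += check_contraindications(case, kb)
    collected += check_duplication(case.prescription, kb)
    collected += check_dose(case, kb)
    collected += check_min_intervals(case.prescription, kb)
    collected += check_food_and_observations(case.prescription, kb)
    collected.sort(
        key=lambda a: (
            _SEVERITY_RANK[a.severity],
            min(a.items_involved) if a.items_involved else -1,
            a.alert_type,
            a.message,
        )
    )
    numbered = tuple(
        replace(a, alert_id=f"A{n + 1}") for n, a in enumerate(collected)
    )
    return AlertReport(case_id=case.case_id, alerts=numbered)


def apply_override(report: AlertReport, alert_id: str,
                   justification: str) -> AlertReport:
    """Mark one alert overridden; content and ordering are untouched."""
    ids = [a.alert_id for a in report.alerts]
    if alert_id not in ids:
        raise KeyError(f"alert id {alert_id!r} not in report (has {ids})")
    updated = tuple(
        replace(a, overridden=True, justification=justification)
        if a.alert_id == alert_id else a
        for a in report.alerts
    )
    return AlertReport(case_id=report.case_id, alerts=updated)
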