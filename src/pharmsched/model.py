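"""Typed domain model and I/O for the drug knowledge base and patient case.

The knowledge base holds medicinal products (:class:`DrugRecord`) and typed
relations between active principles (:class:`InteractionRule`).  Rules follow
the NU / S / O taxonomy used throughout the package:

* **NU** (no-use): contraindication-grade relations — a principle pair that
  must not be used concomitantly.
* **S** (scheduling): a minimum time span, in minutes, required between
  administrations of two principles (or timing tied to the patient routine).
* **O** (observation): free-text administration guidance (e.g. posture
  instructions) that maximizes the drug's effect.

All clock times are minutes since midnight (see :mod:`pharmsched.timeutil`);
files on disk use ``"HH:MM"`` strings.  Canonical principle names are
uppercase and accent-stripped, so Portuguese/English brand and generic
spellings compare equal.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

from .timeutil import (
    MINUTES_PER_DAY,
    complement,
    format_clock,
    merge_intervals,
    parse_clock,
    split_interval,
)

__all__ = [
    "KBValidationError",
    "CaseValidationError",
    "LookupError_",
    "canonical_name",
    "FoodRelation",
    "DrugRecord",
    "InteractionRule",
    "Routine",
    "PrescriptionItem",
    "PatientCase",
    "KnowledgeBase",
    "BUILTIN_CONDITIONS",
    "DEFAULT_FOOD_TOKENS",
    "load_knowledge_base",
    "save_knowledge_base",
    "load_case",
    "save_case",
    "import_drug_table",
    "awake_windows",
    "resolve_principles",
]


class KBValidationError(ValueError):
    """Knowledge-base file violates the schema or referential integrity."""


class CaseValidationError(ValueError):
    """Patient case file violates the schema."""


class LookupError_(KeyError):
    """A prescription references a product absent from the knowledge base."""


#: Condition codes shipped with the package.  A KB file may extend the set
#: through its ``conditions`` list.
BUILTIN_CONDITIONS = frozenset(
    {
        "pregnancy",
        "breastfeeding",
        "severe_hepatic_disease",
        "renal_impairment",
        "peptic_ulcer",
        "asthma",
        "epilepsy",
        "diabetes",
        "hypertension",
        "glaucoma",
    }
)

#: Tokens that may stand in for ``principle_b`` in a principle↔food rule.
DEFAULT_FOOD_TOKENS = frozenset({"FOOD", "MILK", "DAIRY", "ALCOHOL"})

_FOOD_KINDS = ("empty_stomach", "with_food", "none")


def canonical_name(name: str) -> str:
    """Canonicalize a product or principle name.

    Uppercases, strips accents and trademark glyphs, collapses whitespace.
    """
    text = unicodedata.normalize("NFKD", str(name))
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = text.replace("®", "").replace("™", "")
    return " ".join(text.upper().split())


@dataclass(frozen=True)
class FoodRelation:
    """Relation of a product to meals.

    ``empty_stomach`` with ``lead_minutes=L`` means the dose belongs at least
    ``L`` minutes before a meal; ``with_food`` with ``lag_minutes=G`` means
    within ``G`` minutes of a meal.
    """

    kind: str = "none"
    lead_minutes: int = 0
    lag_minutes: int = 0

    def __post_init__(self):
        if self.kind not in _FOOD_KINDS:
            raise KBValidationError(
                f"food_relation.kind must be one of {_FOOD_KINDS}, got {self.kind!r}"
            )
        if self.lead_minutes < 0 or self.lag_minutes < 0:
            raise KBValidationError("food_relation lead/lag minutes must be >= 0")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "lead_minutes": self.lead_minutes,
            "lag_minutes": self.lag_minutes,
        }

    @classmethod
    def from_dict(cls, d: dict | None) -> "FoodRelation":
        if d is None:
            return cls()
        return cls(
            kind=d.get("kind", "none"),
            lead_minutes=int(d.get("lead_minutes", 0)),
            lag_minutes=int(d.get("lag_minutes", 0)),
        )


@dataclass(frozen=True)
class DrugRecord:
    """One medicinal product and the attributes the checks consume.

    Dose limits are optional; per-kg limits are in amount/kg/day and compared
    against ``dose_amount × doses_per_day / weight``.  ``indication`` is
    stored as metadata only and participates in no automated check.
    """

    product_name: str
    active_principles: frozenset[str]
    atc_code: str | None = None
    max_daily_dose_per_kg: float | None = None
    max_single_dose: float | None = None
    min_daily_dose_per_kg: float | None = None
    food_relation: FoodRelation = field(default_factory=FoodRelation)
    administration_observations: tuple[str, ...] = ()
    contraindicated_conditions: frozenset[str] = frozenset()
    indication: str | None = None

    def __post_init__(self):
        if not self.active_principles:
            raise KBValidationError(
                f"drug {self.product_name!r}: active_principles must be non-empty"
            )
        for attr in ("max_daily_dose_per_kg", "max_single_dose", "min_daily_dose_per_kg"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise KBValidationError(
                    f"drug {self.product_name!r}: {attr} must be > 0, got {v}"
                )
        if (
            self.min_daily_dose_per_kg is not None
            and self.max_daily_dose_per_kg is not None
            and self.min_daily_dose_per_kg > self.max_daily_dose_per_kg
        ):
            raise KBValidationError(
                f"drug {self.product_name!r}: min_daily_dose_per_kg exceeds max"
            )
        if self.atc_code is not None and len(self.atc_code) != 7:
            raise KBValidationError(
                f"drug {self.product_name!r}: ATC code must be 7 characters, "
                f"got {self.atc_code!r}"
            )

    def to_dict(self) -> dict:
        return {
            "product_name": self.product_name,
            "atc_code": self.atc_code,
            "active_principles": sorted(self.active_principles),
            "max_daily_dose_per_kg": self.max_daily_dose_per_kg,
            "max_single_dose": self.max_single_dose,
            "min_daily_dose_per_kg": self.min_daily_dose_per_kg,
            "food_relation": self.food_relation.to_dict(),
            "administration_observations": list(self.administration_observations),
            "contraindicated_conditions": sorted(self.contraindicated_conditions),
            "indication": self.indication,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrugRecord":
        try:
            name = d["product_name"]
            principles = d["active_principles"]
        except KeyError as exc:
            raise KBValidationError(f"drug record missing field {exc}") from exc
        return cls(
            product_name=str(name),
            atc_code=d.get("atc_code"),
            active_principles=frozenset(canonical_name(p) for p in principles),
            max_daily_dose_per_kg=d.get("max_daily_dose_per_kg"),
            max_single_dose=d.get("max_single_dose"),
            min_daily_dose_per_kg=d.get("min_daily_dose_per_kg"),
            food_relation=FoodRelation.from_dict(d.get("food_relation")),
            administration_observations=tuple(d.get("administration_observations", ())),
            contraindicated_conditions=frozenset(
                d.get("contraindicated_conditions", ())
            ),
            indication=d.get("indication"),
        )


@dataclass(frozen=True)
class InteractionRule:
    """Typed, unordered relation between two principles (or principle↔food).

    ``min_interval_minutes`` is required (and > 0) exactly for drug–drug S
    rules; NU and O rules carry none.  ``severity`` optionally overrides the
    alert engine's default severity for the rule's alert.
    """

    principle_a: str
    principle_b: str
    rule_type: str
    min_interval_minutes: int | None = None
    message: str = ""
    severity: str | None = None

    def __post_init__(self):
        if self.rule_type not in ("NU", "S", "O"):
            raise KBValidationError(
                f"rule ({self.principle_a}, {self.principle_b}): rule_type must "
                f"be NU, S or O, got {self.rule_type!r}"
            )
        if self.rule_type == "NU" and self.min_interval_minutes is not None:
            raise KBValidationError(
                f"NU rule ({self.principle_a}, {self.principle_b}) must not "
                "carry min_interval_minutes"
            )
        if self.severity is not None and self.severity not in (
            "blocking",
            "warning",
            "info",
        ):
            raise KBValidationError(
                f"rule ({self.principle_a}, {self.principle_b}): invalid "
                f"severity {self.severity!r}"
            )

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.principle_a, self.principle_b})

    def to_dict(self) -> dict:
        d = {
            "principle_a": self.principle_a,
            "principle_b": self.principle_b,
            "rule_type": self.rule_type,
            "message": self.message,
        }
        if self.min_interval_minutes is not None:
            d["min_interval_minutes"] = self.min_interval_minutes
        if self.severity is not None:
            d["severity"] = self.severity
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionRule":
        try:
            a, b, t = d["principle_a"], d["principle_b"], d["rule_type"]
        except KeyError as exc:
            raise KBValidationError(f"interaction rule missing field {exc}") from exc
        interval = d.get("min_interval_minutes")
        return cls(
            principle_a=canonical_name(a),
            principle_b=canonical_name(b),
            rule_type=str(t),
            min_interval_minutes=None if interval is None else int(interval),
            message=str(d.get("message", "")),
            severity=d.get("severity"),
        )


@dataclass(frozen=True)
class Routine:
    """A patient's prototypical day: sleep, commitments and meals.

    The sleep interval runs from ``sleep_time`` to ``wake_time`` and may wrap
    midnight (a night worker sleeping 07:30–14:30 does not wrap; the common
    22:00–07:00 sleeper does).  Busy intervals may wrap as well.
    """

    wake_time: int
    sleep_time: int
    busy_intervals: tuple[tuple[int, int, str], ...] = ()
    meal_times: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        for t in (self.wake_time, self.sleep_time):
            if not 0 <= t < MINUTES_PER_DAY:
                raise CaseValidationError(f"routine time {t} out of [0, 1440)")
        if self.wake_time == self.sleep_time:
            raise CaseValidationError(
                "wake_time equals sleep_time: sleep interval is ambiguous "
                "(covers the full day or none of it)"
            )

    def sleep_intervals(self) -> list[tuple[int, int]]:
        """The sleep interval, normalized to non-wrapping pieces."""
        return split_interval(self.sleep_time, self.wake_time)

    def to_dict(self) -> dict:
        return {
            "wake_time": format_clock(self.wake_time),
            "sleep_time": format_clock(self.sleep_time),
            "busy_intervals": [
                {"start": format_clock(s), "end": format_clock(e), "label": lab}
                for s, e, lab in self.busy_intervals
            ],
            "meal_times": [
                {"time": format_clock(t), "label": lab} for t, lab in self.meal_times
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Routine":
        try:
            wake = parse_clock(d["wake_time"])
            sleep = parse_clock(d["sleep_time"])
        except KeyError as exc:
            raise CaseValidationError(f"routine missing field {exc}") from exc
        busy = tuple(
            (parse_clock(b["start"]), parse_clock(b["end"]), str(b.get("label", "")))
            for b in d.get("busy_intervals", ())
        )
        meals = tuple(
            (parse_clock(m["time"]), str(m.get("label", "")))
            for m in d.get("meal_times", ())
        )
        return cls(wake_time=wake, sleep_time=sleep, busy_intervals=busy, meal_times=meals)


@dataclass(frozen=True)
class PrescriptionItem:
    """One prescribed product with its posology.

    Exactly one of ``doses_per_day`` / ``interval_hours`` is given.  The day
    need not divide evenly by ``interval_hours``; the scheduler's spacing
    tolerance absorbs the remainder.  ``clinical_override_note`` documents a
    risk knowingly accepted by clinical decision; a contraindication alert for
    such an item is emitted pre-overridden, never suppressed.
    """

    drug: str
    dose_amount: float
    doses_per_day: int | None = None
    interval_hours: float | None = None
    fixed_times: tuple[int, ...] | None = None
    clinical_override_note: str | None = None

    def __post_init__(self):
        if (self.doses_per_day is None) == (self.interval_hours is None):
            raise CaseValidationError(
                f"item {self.drug!r}: exactly one of doses_per_day / "
                "interval_hours must be specified"
            )
        if self.doses_per_day is not None and self.doses_per_day < 1:
            raise CaseValidationError(f"item {self.drug!r}: doses_per_day must be >= 1")
        if self.interval_hours is not None and self.interval_hours <= 0:
            raise CaseValidationError(f"item {self.drug!r}: interval_hours must be > 0")
        if self.dose_amount <= 0:
            raise CaseValidationError(f"item {self.drug!r}: dose_amount must be > 0")
        if self.fixed_times is not None and len(self.fixed_times) != self.n_doses:
            raise CaseValidationError(
                f"item {self.drug!r}: fixed_times must list one time per dose "
                f"({self.n_doses} expected, {len(self.fixed_times)} given)"
            )

    @property
    def n_doses(self) -> int:
        """Number of administrations scheduled on the prototypical day."""
        if self.doses_per_day is not None:
            return self.doses_per_day
        return max(1, round(24.0 / self.interval_hours))

    @property
    def daily_frequency(self) -> float:
        """Administrations per day as used by dose arithmetic (may be fractional)."""
        if self.doses_per_day is not None:
            return float(self.doses_per_day)
        return 24.0 / self.interval_hours

    def to_dict(self) -> dict:
        d: dict = {"drug": self.drug, "dose_amount": self.dose_amount}
        if self.doses_per_day is not None:
            d["doses_per_day"] = self.doses_per_day
        if self.interval_hours is not None:
            d["interval_hours"] = self.interval_hours
        if self.fixed_times is not None:
            d["fixed_times"] = [format_clock(t) for t in self.fixed_times]
        if self.clinical_override_note is not None:
            d["clinical_override_note"] = self.clinical_override_note
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PrescriptionItem":
        try:
            drug = d["drug"]
            amount = d["dose_amount"]
        except KeyError as exc:
            raise CaseValidationError(f"prescription item missing field {exc}") from exc
        fixed = d.get("fixed_times")
        return cls(
            drug=str(drug),
            dose_amount=float(amount),
            doses_per_day=d.get("doses_per_day"),
            interval_hours=d.get("interval_hours"),
            fixed_times=None if fixed is None else tuple(parse_clock(t) for t in fixed),
            clinical_override_note=d.get("clinical_override_note"),
        )


@dataclass(frozen=True)
class PatientCase:
    """Demographics, physiological conditions, routine and prescription."""

    case_id: str
    age: float
    weight: float | None
    sex: str
    conditions: frozenset[str]
    condition_qualifiers: tuple[tuple[str, str, float], ...]  # (code, key, value)
    routine: Routine
    prescription: tuple[PrescriptionItem, ...]

    def __post_init__(self):
        if self.sex not in ("F", "M", "unspecified"):
            raise CaseValidationError(f"sex must be F, M or unspecified, got {self.sex!r}")
        if self.weight is not None and self.weight <= 0:
            raise CaseValidationError("weight must be > 0 when given")
        qualified = {code for code, _, _ in self.condition_qualifiers}
        if not qualified <= self.conditions:
            raise CaseValidationError(
                f"qualifiers given for absent conditions: {sorted(qualified - self.conditions)}"
            )

    def to_dict(self) -> dict:
        conds = []
        quals = {(c, k): v for c, k, v in self.condition_qualifiers}
        for code in sorted(self.conditions):
            q = {k: v for (c, k), v in quals.items() if c == code}
            conds.append({"code": code, "qualifiers": q} if q else code)
        return {
            "case_id": self.case_id,
            "patient": {
                "age": self.age,
                "weight": self.weight,
                "sex": self.sex,
                "conditions": conds,
            },
            "routine": self.routine.to_dict(),
            "prescription": [item.to_dict() for item in self.prescription],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientCase":
        try:
            patient = d["patient"]
            routine = d["routine"]
            rx = d["prescription"]
        except KeyError as exc:
            raise CaseValidationError(f"case missing section {exc}") from exc
        conditions: set[str] = set()
        qualifiers: list[tuple[str, str, float]] = []
        for entry in patient.get("conditions", ()):
            if isinstance(entry, str):
                conditions.add(entry)
            else:
                code = entry["code"]
                conditions.add(code)
                for k, v in entry.get("qualifiers", {}).items():
                    qualifiers.append((code, str(k), float(v)))
        return cls(
            case_id=str(d.get("case_id", "")),
            age=float(patient["age"]),
            weight=None if patient.get("weight") is None else float(patient["weight"]),
            sex=str(patient.get("sex", "unspecified")),
            conditions=frozenset(conditions),
            condition_qualifiers=tuple(sorted(qualifiers)),
            routine=Routine.from_dict(routine),
            prescription=tuple(PrescriptionItem.from_dict(i) for i in rx),
        )


@dataclass(frozen=True)
class KnowledgeBase:
    """Validated drug knowledge base: products, typed rules, vocabularies."""

    drugs: tuple[DrugRecord, ...]
    interactions: tuple[InteractionRule, ...]
    food_tokens: frozenset[str] = DEFAULT_FOOD_TOKENS
    conditions: frozenset[str] = BUILTIN_CONDITIONS

    def __post_init__(self):
        seen: dict[str, str] = {}
        for drug in self.drugs:
            key = canonical_name(drug.product_name)
            if key in seen:
                raise KBValidationError(
                    f"duplicate product name {drug.product_name!r} "
                    f"(collides with {seen[key]!r})"
                )
            seen[key] = drug.product_name
        known = {p for drug in self.drugs for p in drug.active_principles}
        for rule in self.interactions:
            for side, principle in (("principle_a", rule.principle_a),
                                    ("principle_b", rule.principle_b)):
                if principle in known or principle in self.food_tokens:
                    continue
                if side == "principle_a":
                    raise KBValidationError(
                        f"rule {side}={principle!r} resolves to no drug's "
                        "active principle"
                    )
                raise KBValidationError(
                    f"rule {side}={principle!r} resolves to no drug's active "
                    "principle and is not a declared food token"
                )
            if rule.rule_type == "S" and rule.principle_b not in self.food_tokens \
                    and rule.principle_a not in self.food_tokens:
                if not rule.min_interval_minutes or rule.min_interval_minutes <= 0:
                    raise KBValidationError(
                        f"drug–drug S rule ({rule.principle_a}, {rule.principle_b}) "
                        "requires min_interval_minutes > 0"
                    )
        for drug in self.drugs:
            unknown = drug.contraindicated_conditions - self.conditions
            if unknown:
                raise KBValidationError(
                    f"drug {drug.product_name!r}: unknown condition codes "
                    f"{sorted(unknown)}"
                )

    def find_drug(self, product_name: str) -> DrugRecord:
        key = canonical_name(product_name)
        for drug in self.drugs:
            if canonical_name(drug.product_name) == key:
                return drug
        raise LookupError_(f"product {product_name!r} not in knowledge base")

    def has_drug(self, product_name: str) -> bool:
        try:
            self.find_drug(product_name)
            return True
        except LookupError_:
            return False

    def rules_of_type(self, rule_type: str) -> list[InteractionRule]:
        return [r for r in self.interactions if r.rule_type == rule_type]

    def to_dict(self) -> dict:
        return {
            "drugs": [d.to_dict() for d in self.drugs],
            "interactions": [r.to_dict() for r in self.interactions],
            "food_tokens": sorted(self.food_tokens),
            "conditions": sorted(self.conditions - BUILTIN_CONDITIONS),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnowledgeBase":
        drugs = tuple(DrugRecord.from_dict(x) for x in d.get("drugs", ()))
        rules = tuple(InteractionRule.from_dict(x) for x in d.get("interactions", ()))
        tokens = DEFAULT_FOOD_TOKENS | {canonical_name(t) for t in d.get("food_tokens", ())}
        conditions = BUILTIN_CONDITIONS | set(d.get("conditions", ()))
        return cls(drugs=drugs, interactions=rules, food_tokens=frozenset(tokens),
                   conditions=frozenset(conditions))


# ---------------------------------------------------------------------------
# I/O


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load and validate a ``kb.json`` knowledge base file."""
    path = Path(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise KBValidationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise KBValidationError(f"{path}: top level must be a JSON object")
    return KnowledgeBase.from_dict(raw)


def save_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(kb.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_case(path: str | Path, kb: KnowledgeBase | None = None) -> PatientCase:
    """Load a ``case.json`` file; with ``kb`` given, cross-validate references."""
    path = Path(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CaseValidationError(f"{path}: not valid JSON: {exc}") from exc
    case = PatientCase.from_dict(raw)
    if kb is not None:
        unknown = case.conditions - kb.conditions
        if unknown:
            raise CaseValidationError(
                f"{path}: unknown condition codes {sorted(unknown)}"
            )
        for item in case.prescription:
            if not kb.has_drug(item.drug):
                raise LookupError_(
                    f"{path}: prescription references unknown product {item.drug!r}"
                )
    return case


def save_case(case: PatientCase, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(case.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


#: Expected columns of the CSV drug-table import.  List-valued columns are
#: semicolon-separated.
DRUG_CSV_COLUMNS = (
    "product_name",
    "atc_code",
    "active_principles",
    "max_daily_dose_per_kg",
    "max_single_dose",
    "min_daily_dose_per_kg",
    "food_relation",
    "food_lead_minutes",
    "food_lag_minutes",
    "administration_observations",
    "contraindicated_conditions",
    "indication",
)


def import_drug_table(path: str | Path) -> tuple[DrugRecord, ...]:
    """Import drug records from a CSV table (documented column names)."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"product_name", "active_principles"} - set(df.columns)
    if missing:
        raise KBValidationError(f"drug table missing required columns {sorted(missing)}")

    def _num(value: str) -> float | None:
        return float(value) if value.strip() else None

    def _split(value: str) -> list[str]:
        return [p.strip() for p in value.split(";") if p.strip()]

    records = []
    for _, row in df.iterrows():
        records.append(
            DrugRecord(
                product_name=row["product_name"],
                atc_code=row.get("atc_code", "").strip() or None,
                active_principles=frozenset(
                    canonical_name(p) for p in _split(row["active_principles"])
                ),
                max_daily_dose_per_kg=_num(row.get("max_daily_dose_per_kg", "")),
                max_single_dose=_num(row.get("max_single_dose", "")),
                min_daily_dose_per_kg=_num(row.get("min_daily_dose_per_kg", "")),
                food_relation=FoodRelation(
                    kind=row.get("food_relation", "").strip() or "none",
                    lead_minutes=int(_num(row.get("food_lead_minutes", "")) or 0),
                    lag_minutes=int(_num(row.get("food_lag_minutes", "")) or 0),
                ),
                administration_observations=tuple(
                    _split(row.get("administration_observations", ""))
                ),
                contraindicated_conditions=frozenset(
                    _split(row.get("contraindicated_conditions", ""))
                ),
                indication=row.get("indication", "").strip() or None,
            )
        )
    return tuple(records)


# ---------------------------------------------------------------------------
# Operations


def awake_windows(routine: Routine) -> list[tuple[int, int]]:
    """Ordered non-wrapping intervals in which the patient is awake.

    The union of the returned intervals is the 24 h day minus the sleep
    interval; wrap-around sleep is split at midnight.
    """
    sleep = routine.sleep_intervals()
    windows = complement(merge_intervals(sleep))
    if not windows:
        raise CaseValidationError("sleep interval covers the entire day")
    return windows


def resolve_principles(item: PrescriptionItem, kb: KnowledgeBase) -> frozenset[str]:
    """Canonical active-principle set of a prescription item's product.

    All cross-item comparison happens at the principle level, never at the
    product-name level, so combination products (several principles in one
    product) interact through each constituent.
    """
    return kb.find_drug(item.drug).active_principles
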