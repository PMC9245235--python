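"""Built-in hypothetical cases, synthetic case generation, synthetic ratings.

Ten hypothetical patient cases ship as package fixtures (``case01`` …
``case10``), each planting one inconsistency or analysis situation — an
avoid-concomitant-use pair, day/night routines, a minimum-interval pair, a
contraindication, a pediatric overdose, a food relation, sleep protection
under a q8h regimen, a risk accepted by clinical decision, and drugs needing
specific administration guidance — together with a minimal fixture knowledge
base containing exactly the drugs, rules and limits the cases need.

All numeric thresholds in the fixture KB (per-kg dose limits, minimum
intervals, food lead times) are FIXTURE VALUES chosen for the test harness,
not clinical guidance.

The synthetic generator plants the same inconsistency classes into randomly
drawn clean prescriptions, and produces paired ordinal ratings with a
calibrated expected agreement for exercising the kappa statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .agreement import RatingMatrix
from .model import KnowledgeBase, PatientCase

__all__ = [
    "ERROR_CLASSES",
    "PlantedCase",
    "SyntheticRatingSpec",
    "fixture_kb",
    "fixture_dir",
    "builtin_cases",
    "generate_case",
    "generate_ratings",
]

#: The ten planted situation labels, in fixture order.
ERROR_CLASSES = (
    "nu_pair",
    "daytime_routine",
    "night_routine",
    "min_interval",
    "contraindication",
    "overdose",
    "food_relation",
    "sleep_protection",
    "override_risk",
    "specific_guidelines",
)

#: Alert class each planted situation is expected to emit.  Routine-centred
#: situations plant a scheduling challenge, not an alert: their expectation
#: is the empty set (the measurable event is a feasible schedule).
EXPECTED_ALERTS = {
    "nu_pair": frozenset({"nu_interaction"}),
    "daytime_routine": frozenset(),
    "night_routine": frozenset(),
    "min_interval": frozenset({"min_interval_needed"}),
    "contraindication": frozenset({"contraindication"}),
    "overdose": frozenset({"overdose"}),
    "food_relation": frozenset({"food_relation"}),
    "sleep_protection": frozenset(),
    "override_risk": frozenset({"contraindication"}),
    "specific_guidelines": frozenset({"observation"}),
}


@dataclass(frozen=True)
class PlantedCase:
    """A patient case with machine-checkable ground truth attached."""

    case: PatientCase
    planted_error_class: str
    expected_alert_types: frozenset[str]
    expected_feasible: bool

    def __post_init__(self):
        if self.planted_error_class not in ERROR_CLASSES + ("none",):
            raise ValueError(
                f"unknown planted class {self.planted_error_class!r}"
            )


@dataclass(frozen=True)
class SyntheticRatingSpec:
    """Specification for paired synthetic ordinal ratings.

    ``target_agreement`` is the expected weighted kappa of the generated
    pair (any weight scheme — the copy-mixture construction makes the
    expectation scheme-free).
    """

    n_units: int
    marginals: tuple[float, ...]
    target_agreement: float
    seed: int

    def __post_init__(self):
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if abs(sum(self.marginals) - 1.0) > 1e-9:
            raise ValueError(f"marginals must sum to 1, got {sum(self.marginals)}")
        if any(m < 0 for m in self.marginals):
            raise ValueError("marginals must be non-negative")


def fixture_dir() -> Path:
    return Path(resources.files("pharmsched") / "fixtures")


def fixture_kb() -> KnowledgeBase:
    """The minimal knowledge base the ten built-in cases require."""
    with open(fixture_dir() / "kb.json") as fh:
        return KnowledgeBase.from_dict(json.load(fh))


def builtin_cases() -> list[PlantedCase]:
    """The ten shipped hypothetical cases, ids ``case01`` … ``case10``.

    Each fixture file carries an ``expected`` block with its planted class,
    expected alert types and expected scheduling feasibility.
    """
    cases = []
    for n in range(1, 11):
        with open(fixture_dir() / f"case{n:02d}.json") as fh:
            raw = json.load(fh)
        expected = raw.pop("expected")
        cases.append(
            PlantedCase(
                case=PatientCase.from_dict(raw),
                planted_error_class=expected["planted_error_class"],
                expected_alert_types=frozenset(expected["expected_alert_types"]),
                expected_feasible=bool(expected["expected_feasible"]),
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Synthetic case generation

# Clean pool: no interaction rules, no dose limits, no food relations, no
# observations, pairwise-distinct principles and ATC subgroups — a clean
# prescription drawn from it triggers zero alerts by construction.
_CLEAN_POOL = (
    ("ENALAPRIL 10 MG", 10.0),
    ("PARACETAMOL 500 MG", 500.0),
    ("LOSARTAN 50 MG", 50.0),
    ("AMLODIPINE 5 MG", 5.0),
    ("HYDROCHLOROTHIAZIDE 25 MG", 25.0),
    ("SERTRALINE 50 MG", 50.0),
    ("CETIRIZINE 10 MG", 10.0),
    ("COLECALCIFEROL 1000 IU", 1000.0),
)


def _random_routine(rng: np.random.Generator, kind: str = "day") -> dict:
    if kind == "night":
        return {
            "wake_time": "14:30",
            "sleep_time": "07:30",
            "busy_intervals": [
                {"start": "22:00", "end": "06:00", "label": "night shift"}
            ],
            "meal_times": [
                {"time": "15:00", "label": "first meal"},
                {"time": "21:00", "label": "pre-shift meal"},
                {"time": "06:30", "label": "post-shift meal"},
            ],
        }
    wake = 6 * 60 + int(rng.integers(0, 5)) * 30  # 06:00–08:00
    sleep = 21 * 60 + int(rng.integers(0, 5)) * 30  # 21:00–23:00
    busy = []
    if kind == "busy_day":
        busy = [
            {"start": "08:00", "end": "12:00", "label": "work"},
            {"start": "13:00", "end": "18:00", "label": "work"},
        ]
    fmt = lambda m: f"{m // 60:02d}:{m % 60:02d}"
    return {
        "wake_time": fmt(wake),
        "sleep_time": fmt(sleep),
        "busy_intervals": busy,
        "meal_times": [
            {"time": fmt(wake + 30), "label": "breakfast"},
            {"time": "12:30", "label": "lunch"},
            {"time": fmt(sleep - 120), "label": "dinner"},
        ],
    }


def generate_case(error_class: str, seed: int) -> PlantedCase:
    """Generate a reproducible case planting exactly one inconsistency.

    ``error_class`` is one of :data:`ERROR_CLASSES` or ``"none"`` for a
    clean case whose review yields zero alerts by construction.
    """
    if error_class not in ERROR_CLASSES + ("none",):
        raise ValueError(
            f"unknown error class {error_class!r}; "
            f"valid: {ERROR_CLASSES + ('none',)}"
        )
    rng = np.random.default_rng(seed)
    n_base = int(rng.integers(3, 9))  # 3–8 clean drugs
    pool_idx = rng.choice(len(_CLEAN_POOL), size=n_base, replace=False)
    prescription = [
        {
            "drug": _CLEAN_POOL[i][0],
            "dose_amount": _CLEAN_POOL[i][1],
            "doses_per_day": int(rng.integers(1, 4)),
        }
        for i in sorted(int(x) for x in pool_idx)
    ]
    age = float(rng.integers(25, 80))
    weight = float(rng.integers(50, 95))
    sex = ["F", "M"][int(rng.integers(0, 2))]
    conditions: list = []
    routine_kind = "day"
    feasible = True

    if error_class == "nu_pair":
        prescription += [
            {"drug": "ASPIRIN 500 MG", "dose_amount": 500.0, "doses_per_day": 1},
            {"drug": "WARFARIN 2.5 MG", "dose_amount": 2.5, "doses_per_day": 1},
        ]
    elif error_class == "min_interval":
        prescription += [
            {"drug": "DIGOXIN 0.25 MG", "dose_amount": 0.25, "doses_per_day": 1},
            {"drug": "MYLANTA PLUS", "dose_amount": 10.0, "doses_per_day": 3},
        ]
    elif error_class == "contraindication":
        conditions = ["severe_hepatic_disease"]
        prescription += [
            {"drug": "ATORVASTATIN CALCIUM 20 MG", "dose_amount": 20.0,
             "doses_per_day": 1},
        ]
    elif error_class == "overdose":
        age = float(rng.integers(1, 6))
        weight = float(rng.integers(10, 21))
        # one daily administration exceeding the fixture 10 mg/kg/day cap
        dose = float(int(weight * 10 * 1.5))
        prescription = prescription[:3] + [
            {"drug": "AZITHROMYCIN SUSPENSION", "dose_amount": dose,
             "doses_per_day": 1},
        ]
    elif error_class == "food_relation":
        prescription += [
            {"drug": "OMEPRAZOLE 20 MG", "dose_amount": 20.0, "doses_per_day": 1},
        ]
    elif error_class == "override_risk":
        sex = "F"
        conditions = [{"code": "pregnancy",
                       "qualifiers": {"weeks": int(rng.integers(6, 36))}}]
        prescription += [
            {"drug": "CARBAMAZEPINE 200 MG", "dose_amount": 200.0,
             "doses_per_day": 2,
             "clinical_override_note":
                 "Seizure control prioritized; risk accepted by clinical "
                 "decision."},
        ]
    elif error_class == "specific_guidelines":
        prescription += [
            {"drug": "ALENDRONATE SODIUM 70 MG", "dose_amount": 70.0,
             "doses_per_day": 1},
        ]
        routine_kind = "day"
    elif error_class == "daytime_routine":
        routine_kind = "busy_day"
    elif error_class == "night_routine":
        routine_kind = "night"
    elif error_class == "sleep_protection":
        age = float(rng.integers(3, 12))
        weight = float(rng.integers(14, 40))
        prescription = prescription[:2] + [
            {"drug": "AMOXICILLIN SUSPENSION", "dose_amount": 250.0,
             "interval_hours": 8},
        ]

    raw = {
        "case_id": f"synthetic-{error_class}-{seed}",
        "patient": {"age": age, "weight": weight, "sex": sex,
                    "conditions": conditions},
        "routine": _random_routine(rng, routine_kind),
        "prescription": prescription,
    }
    return PlantedCase(
        case=PatientCase.from_dict(raw),
        planted_error_class=error_class,
        expected_alert_types=(
            frozenset() if error_class == "none" else EXPECTED_ALERTS[error_class]
        ),
        expected_feasible=feasible,
    )


def generate_ratings(spec: SyntheticRatingSpec) -> RatingMatrix:
    """Paired ratings whose expected weighted kappa equals the target level.

    Construction: rater A draws from the marginals; with probability
    ``p = target_agreement`` rater B copies A, otherwise B draws
    independently from the same marginals.  Then ``O = p·diag(π) +
    (1-p)·ππᵀ``, so for any disagreement weights the expected kappa is
    exactly ``p``.  Negative targets are unreachable by this mixture.
    """
    p = spec.target_agreement
    if not 0.0 <= p <= 1.0:
        raise ValueError(
            f"target agreement {p} unreachable by the copy-mixture "
            "construction (needs 0 <= target <= 1)"
        )
    rng = np.random.default_rng(spec.seed)
    categories = tuple(range(1, len(spec.marginals) + 1))
    a = rng.choice(categories, size=spec.n_units, p=spec.marginals)
    independent = rng.choice(categories, size=spec.n_units, p=spec.marginals)
    copy_mask = rng.random(spec.n_units) < p
    b = np.where(copy_mask, a, independent)
    return RatingMatrix(
        rater_a=tuple(int(x) for x in a),
        rater_b=tuple(int(x) for x in b),
        categories=categories,
    )
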