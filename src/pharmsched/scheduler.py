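"""Genetic-algorithm medication scheduler over the discretized day.

The solution space is the set of clock-time assignments, one per
(item, dose) pair, on a slot grid (default 30 min, 48 slots/day).  A
candidate schedule is scored by a weighted linear penalty sum over violation
classes; a schedule is *feasible* when every hard class scores exactly zero.

Penalty classes
---------------
hard (weights >= 1000x the soft weights, so any hard violation dominates):
    ``sleep``          minutes from a dose inside the sleep window to the
                       nearest awake minute
    ``pair_interval``  shortfall, in minutes, of the circular gap between two
                       doses under a drug–drug minimum-interval (S) rule
    ``pin``            circular distance from a dose to its mandated fixed time
    ``food``           distance from a dose to its nearest meal-anchored
                       window (empty-stomach / with-food relations)
soft:
    ``spacing``        deviation of intra-item gaps from the target spacing
                       beyond a tolerance (doses wrap the day cyclically)
    ``busy``           distance from a dose inside a busy interval to the
                       nearest free minute (work hours discourage, not forbid)
    ``preference``     learned user-preference rules (always soft; only KB
                       rules can be hard)

The GA never claims optimality: it returns the best individual ever seen,
with its violation list, even when infeasible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .alerts import AlertReport
from .model import (
    KnowledgeBase,
    PatientCase,
    awake_windows,
    resolve_principles,
)
from .timeutil import (
    MINUTES_PER_DAY,
    circular_diff,
    complement,
    distance_to_intervals,
    format_clock,
    merge_intervals,
    point_in_intervals,
    split_interval,
)

__all__ = [
    "HARD_CLASSES",
    "SOFT_CLASSES",
    "PenaltyWeights",
    "GAConfig",
    "WindowConstraint",
    "PairConstraint",
    "SpacingConstraint",
    "PinConstraint",
    "ConstraintSet",
    "PreferenceRule",
    "PreferenceStore",
    "ScheduleResult",
    "BlockingAlertsError",
    "build_constraints",
    "fitness",
    "evolve",
    "brute_force_schedule",
    "audit_schedule",
    "record_intervention",
]

HARD_CLASSES = ("sleep", "pair_interval", "pin", "food")
SOFT_CLASSES = ("spacing", "busy", "preference")

#: Default spacing tolerance: intra-item gaps within +/- 60 min of target are
#: not penalized, which absorbs the compression of q8h regimens into an awake
#: day while the sleep window stays hard.
SPACING_TOLERANCE_MIN = 60

#: Width (minutes) of the allowed window anchored before a meal for
#: empty-stomach products: [meal - lead - width, meal - lead].
FOOD_WINDOW_WIDTH = 60


class BlockingAlertsError(RuntimeError):
    """Scheduling was requested while blocking alerts remain unresolved."""


@dataclass(frozen=True)
class PenaltyWeights:
    """Per-class penalty weights (per minute of violation magnitude)."""

    sleep: float = 1000.0
    pair_interval: float = 1000.0
    pin: float = 1000.0
    food: float = 1000.0
    spacing: float = 1.0
    busy: float = 0.5
    preference: float = 1.0

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in HARD_CLASSES + SOFT_CLASSES}

    def scaled(self, factor: float) -> "PenaltyWeights":
        return PenaltyWeights(**{k: v * factor for k, v in self.as_dict().items()})


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the evolutionary search.

    ``mutation_rate=None`` uses the 1/chromosome-length convention.  The seed
    is mandatory: every run must be reproducible.
    """

    slot_minutes: int = 30
    population_size: int = 200
    generations: int = 300
    crossover_rate: float = 0.9
    mutation_rate: float | None = None
    elitism_count: int = 2
    tournament_size: int = 3
    random_seed: int | None = None
    weights: PenaltyWeights = field(default_factory=PenaltyWeights)

    def __post_init__(self):
        if MINUTES_PER_DAY % self.slot_minutes != 0:
            raise ValueError("slot_minutes must divide 1440")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be < population_size")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")

    @property
    def n_slots(self) -> int:
        return MINUTES_PER_DAY // self.slot_minutes

    def to_dict(self) -> dict:
        return {
            "slot_minutes": self.slot_minutes,
            "population_size": self.population_size,
            "generations": self.generations,
            "crossover_rate": self.crossover_rate,
            "mutation_rate": self.mutation_rate,
            "elitism_count": self.elitism_count,
            "tournament_size": self.tournament_size,
            "random_seed": self.random_seed,
            "weights": self.weights.as_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        d = dict(d)
        weights = d.pop("weights", None)
        cfg = cls(**d) if weights is None else cls(
            **d, weights=PenaltyWeights(**weights)
        )
        return cfg


# ---------------------------------------------------------------------------
# Constraints


@dataclass(frozen=True)
class WindowConstraint:
    """Doses of ``item_index`` (or all items if None) must lie inside
    ``allowed`` intervals; magnitude = distance to the nearest allowed minute."""

    klass: str
    allowed: tuple[tuple[int, int], ...]
    item_index: int | None
    source: str
    weight_scale: float = 1.0


@dataclass(frozen=True)
class PairConstraint:
    """Circular gap between genes ``gene_a`` and ``gene_b`` must be >=
    ``min_minutes``; magnitude = shortfall in minutes."""

    klass: str
    gene_a: int
    gene_b: int
    min_minutes: int
    source: str
    weight_scale: float = 1.0


@dataclass(frozen=True)
class SpacingConstraint:
    """Sorted gaps between an item's doses (cyclic around the day) should sit
    within ``tolerance`` of ``target_minutes``; magnitude = excess deviation."""

    item_index: int
    genes: tuple[int, ...]
    target_minutes: float
    tolerance: int
    source: str


@dataclass(frozen=True)
class PinConstraint:
    """Gene must equal the mandated clock time; magnitude = circular distance."""

    gene: int
    minute: int
    source: str


@dataclass(frozen=True)
class ConstraintSet:
    """Everything the fitness function needs, with provenance per constraint."""

    case_id: str
    item_labels: tuple[str, ...]
    genes: tuple[tuple[int, int], ...]  # (item_index, dose_index) per gene
    windows: tuple[WindowConstraint, ...]
    pairs: tuple[PairConstraint, ...]
    spacings: tuple[SpacingConstraint, ...]
    pins: tuple[PinConstraint, ...]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    def genes_of_item(self, item_index: int) -> list[int]:
        return [g for g, (i, _) in enumerate(self.genes) if i == item_index]


# ---------------------------------------------------------------------------
# Preference learning


@dataclass(frozen=True)
class PreferenceRule:
    """A soft constraint learned from a user's manual schedule edit."""

    scope: str  # canonical product name
    kind: str  # administer_alone | preferred_window
    separation_minutes: int | None = None
    window: tuple[int, int] | None = None
    weight: float = 1.0
    origin: str = ""
    sequence: int = 0

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "kind": self.kind,
            "separation_minutes": self.separation_minutes,
            "window": None if self.window is None else list(self.window),
            "weight": self.weight,
            "origin": self.origin,
            "sequence": self.sequence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreferenceRule":
        window = d.get("window")
        return cls(
            scope=d["scope"],
            kind=d["kind"],
            separation_minutes=d.get("separation_minutes"),
            window=None if window is None else (int(window[0]), int(window[1])),
            weight=float(d.get("weight", 1.0)),
            origin=str(d.get("origin", "")),
            sequence=int(d.get("sequence", 0)),
        )


class PreferenceStore:
    """Append-only store of learned preference rules with provenance.

    When several rules share (scope, kind), the newest (highest sequence)
    wins ties; older rules are retained for audit.
    """

    def __init__(self, rules: list[PreferenceRule] | None = None):
        self.rules: list[PreferenceRule] = list(rules or [])

    def append(self, rule: PreferenceRule) -> PreferenceRule:
        numbered = replace(rule, sequence=len(self.rules) + 1)
        self.rules.append(numbered)
        return numbered

    def effective_rules(self) -> list[PreferenceRule]:
        by_key: dict[tuple[str, str], PreferenceRule] = {}
        for rule in self.rules:  # later entries overwrite: newest wins
            by_key[(rule.scope, rule.kind)] = rule
        return [by_key[k] for k in sorted(by_key)]

    @classmethod
    def load(cls, path: str | Path) -> "PreferenceStore":
        path = Path(path)
        if not path.exists():
            return cls()
        with open(path) as fh:
            raw = json.load(fh)
        return cls([PreferenceRule.from_dict(d) for d in raw.get("rules", [])])

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"rules": [r.to_dict() for r in self.rules]}, fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Constraint construction


def _food_windows(relation, meal_times: list[int]) -> list[tuple[int, int]]:
    """Meal-anchored allowed intervals for a food relation."""
    windows: list[tuple[int, int]] = []
    for meal in meal_times:
        if relation.kind == "empty_stomach":
            lead = relation.lead_minutes
            start, end = meal - lead - FOOD_WINDOW_WIDTH, meal - lead
        else:  # with_food
            lag = relation.lag_minutes or 30
            start, end = meal - lag, meal + lag
        windows.extend(split_interval(start % MINUTES_PER_DAY,
                                      (end + 1) % MINUTES_PER_DAY))
    return merge_intervals(windows)


def build_constraints(case: PatientCase, kb: KnowledgeBase,
                      alert_report: AlertReport,
                      preferences: PreferenceStore | None = None) -> ConstraintSet:
    """Translate case + KB + routine into the scheduler's constraint set.

    Refuses to build while blocking alerts remain unresolved: the workflow
    requires the reviewer to intervene or explicitly accept the risk first.
    Every constraint records the rule, routine element, or prescription field
    it derives from.
    """
    if alert_report.has_unresolved_blocking:
        blocking = [
            f"{a.alert_id}:{a.alert_type}" for a in alert_report.alerts
            if a.severity == "blocking" and not a.overridden
        ]
        raise BlockingAlertsError(
            f"cannot schedule: unresolved blocking alerts {blocking}"
        )
    if sum(item.n_doses for item in case.prescription) == 0:
        raise ValueError("prescription has no doses to schedule")

    genes: list[tuple[int, int]] = []
    for i, item in enumerate(case.prescription):
        genes.extend((i, k) for k in range(item.n_doses))
    gene_index = {pair: g for g, pair in enumerate(genes)}

    awake = tuple(awake_windows(case.routine))
    windows: list[WindowConstraint] = [
        WindowConstraint(
            klass="sleep", allowed=awake, item_index=None,
            source=f"routine: sleep {format_clock(case.routine.sleep_time)}–"
                   f"{format_clock(case.routine.wake_time)}",
        )
    ]

    busy_union: list[tuple[int, int]] = []
    for s, e, _label in case.routine.busy_intervals:
        busy_union.extend(split_interval(s, e))
    if busy_union:
        free = complement(merge_intervals(busy_union))
        if free:
            windows.append(
                WindowConstraint(
                    klass="busy", allowed=tuple(free), item_index=None,
                    source="routine: busy intervals "
                           + ", ".join(
                               f"{format_clock(s)}–{format_clock(e)} ({lab})"
                               for s, e, lab in case.routine.busy_intervals
                           ),
                )
            )

    meal_minutes = [t for t, _ in case.routine.meal_times]
    for i, item in enumerate(case.prescription):
        drug = kb.find_drug(item.drug)
        if drug.food_relation.kind != "none" and meal_minutes:
            allowed = _food_windows(drug.food_relation, meal_minutes)
            windows.append(
                WindowConstraint(
                    klass="food", allowed=tuple(allowed), item_index=i,
                    source=f"{item.drug}: food relation "
                           f"{drug.food_relation.kind}",
                )
            )

    pins: list[PinConstraint] = []
    for i, item in enumerate(case.prescription):
        if item.fixed_times:
            for k, t in enumerate(sorted(item.fixed_times)):
                pins.append(
                    PinConstraint(
                        gene=gene_index[(i, k)], minute=t,
                        source=f"{item.drug}: mandated time {format_clock(t)}",
                    )
                )

    principles = [resolve_principles(item, kb) for item in case.prescription]
    pairs: list[PairConstraint] = []
    s_rules = [
        r for r in kb.rules_of_type("S")
        if r.principle_a not in kb.food_tokens and r.principle_b not in kb.food_tokens
    ]
    for i in range(len(case.prescription)):
        for j in range(i + 1, len(case.prescription)):
            for rule in s_rules:
                hit = (rule.principle_a in principles[i] and rule.principle_b in principles[j]) or \
                      (rule.principle_b in principles[i] and rule.principle_a in principles[j])
                if not hit:
                    continue
                for ga in (g for g, (it, _) in enumerate(genes) if it == i):
                    for gb in (g for g, (it, _) in enumerate(genes) if it == j):
                        pairs.append(
                            PairConstraint(
                                klass="pair_interval", gene_a=ga, gene_b=gb,
                                min_minutes=rule.min_interval_minutes,
                                source=f"S rule ({rule.principle_a}, "
                                       f"{rule.principle_b}) >= "
                                       f"{rule.min_interval_minutes} min",
                            )
                        )

    spacings: list[SpacingConstraint] = []
    for i, item in enumerate(case.prescription):
        if item.n_doses >= 2:
            if item.interval_hours is not None:
                target = item.interval_hours * 60.0
            else:
                target = MINUTES_PER_DAY / item.n_doses
            spacings.append(
                SpacingConstraint(
                    item_index=i,
                    genes=tuple(g for g, (it, _) in enumerate(genes) if it == i),
                    target_minutes=target,
                    tolerance=SPACING_TOLERANCE_MIN,
                    source=f"{item.drug}: target spacing {target:g} min "
                           f"± {SPACING_TOLERANCE_MIN} min",
                )
            )

    if preferences is not None:
        from .model import canonical_name

        label_by_item = {canonical_name(it.drug): i
                         for i, it in enumerate(case.prescription)}
        for rule in preferences.effective_rules():
            i = label_by_item.get(rule.scope)
            if i is None:
                continue
            if rule.kind == "administer_alone" and rule.separation_minutes:
                for ga in (g for g, (it, _) in enumerate(genes) if it == i):
                    for gb in (g for g, (it, _) in enumerate(genes) if it != i):
                        pairs.append(
                            PairConstraint(
                                klass="preference", gene_a=ga, gene_b=gb,
                                min_minutes=rule.separation_minutes,
                                source=f"preference #{rule.sequence} "
                                       f"({rule.origin}): administer "
                                       f"{rule.scope} alone",
                                weight_scale=rule.weight,
                            )
                        )
            elif rule.kind == "preferred_window" and rule.window is not None:
                allowed = tuple(split_interval(*rule.window))
                windows.append(
                    WindowConstraint(
                        klass="preference", allowed=allowed, item_index=i,
                        source=f"preference #{rule.sequence} ({rule.origin}): "
                               f"preferred window for {rule.scope}",
                        weight_scale=rule.weight,
                    )
                )

    return ConstraintSet(
        case_id=case.case_id,
        item_labels=tuple(item.drug for item in case.prescription),
        genes=tuple(genes),
        windows=tuple(windows),
        pairs=tuple(pairs),
        spacings=tuple(spacings),
        pins=tuple(pins),
    )


# ---------------------------------------------------------------------------
# Fitness (vectorized over a population)


class FitnessEvaluator:
    """Evaluates populations of slot-index chromosomes against a ConstraintSet.

    Window penalties are precomputed as per-slot lookup tables; pair, pin and
    spacing penalties are computed vectorized per call.
    """

    def __init__(self, cs: ConstraintSet, weights: PenaltyWeights,
                 slot_minutes: int):
        if MINUTES_PER_DAY % slot_minutes != 0:
            raise ValueError("slot_minutes must divide 1440")
        self.cs = cs
        self.weights = weights
        self.slot_minutes = slot_minutes
        self.n_slots = MINUTES_PER_DAY // slot_minutes
        slot_times = np.arange(self.n_slots) * slot_minutes
        # per-class, per-gene, per-slot penalty tables for window constraints
        self._tables: dict[str, np.ndarray] = {}
        for wc in cs.windows:
            table = np.array(
                [distance_to_intervals(int(t), list(wc.allowed)) for t in slot_times],
                dtype=np.float64,
            ) * wc.weight_scale
            genes = (
                range(cs.n_genes) if wc.item_index is None
                else cs.genes_of_item(wc.item_index)
            )
            full = self._tables.setdefault(
                wc.klass, np.zeros((cs.n_genes, self.n_slots))
            )
            for g in genes:
                full[g] += table

    def __call__(self, population: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Return (totals, per-class magnitudes) for an (N, L) slot array."""
        pop = np.atleast_2d(np.asarray(population, dtype=np.int64))
        n, L = pop.shape
        if L != self.cs.n_genes:
            raise ValueError(
                f"chromosome length {L} != number of genes {self.cs.n_genes}"
            )
        times = pop * self.slot_minutes
        mags = {c: np.zeros(n) for c in HARD_CLASSES + SOFT_CLASSES}

        for klass, table in self._tables.items():
            # gather per-gene slot penalties and sum over genes
            mags[klass] += table[np.arange(L)[None, :], pop].sum(axis=1)

        for pc in self.cs.pairs:
            d = np.abs(times[:, pc.gene_a] - times[:, pc.gene_b])
            circ = np.minimum(d, MINUTES_PER_DAY - d)
            mags[pc.klass] += np.maximum(0, pc.min_minutes - circ) * pc.weight_scale

        for pin in self.cs.pins:
            d = np.abs(times[:, pin.gene] - pin.minute)
            mags["pin"] += np.minimum(d, MINUTES_PER_DAY - d)

        for sp in self.cs.spacings:
            ts = np.sort(times[:, list(sp.genes)], axis=1)
            gaps = np.diff(ts, axis=1)
            wrap = (MINUTES_PER_DAY - (ts[:, -1] - ts[:, 0]))[:, None]
            all_gaps = np.concatenate([gaps, wrap], axis=1)
            dev = np.maximum(0, np.abs(all_gaps - sp.target_minutes) - sp.tolerance)
            mags["spacing"] += dev.sum(axis=1)

        w = self.weights.as_dict()
        totals = sum(w[c] * mags[c] for c in mags)
        return totals, mags


def fitness(chromosome, constraints: ConstraintSet,
            weights: PenaltyWeights | None = None,
            slot_minutes: int = 30) -> tuple[float, dict[str, float]]:
    """Total penalty and weighted per-class breakdown for one chromosome.

    The total is linear in the weights: doubling every weight exactly doubles
    the total.  Zero iff no constraint is violated.
    """
    weights = weights or PenaltyWeights()
    evaluator = FitnessEvaluator(constraints, weights, slot_minutes)
    totals, mags = evaluator(np.asarray(chromosome)[None, :])
    w = weights.as_dict()
    breakdown = {c: float(w[c] * mags[c][0]) for c in mags}
    return float(totals[0]), breakdown


# ---------------------------------------------------------------------------
# Results


@dataclass(frozen=True)
class ScheduleResult:
    """Best-found schedule with its penalty breakdown and violation list."""

    case_id: str
    schedule: tuple[tuple[str, tuple[int, ...]], ...]  # (item label, sorted minutes)
    fitness: float
    breakdown: dict[str, float]
    violations: tuple[dict, ...]
    feasible: bool
    generations_run: int
    seed: int | None
    slot_minutes: int
    fitness_history: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "schedule": [
                {"item": label, "times": [format_clock(t) for t in times]}
                for label, times in self.schedule
            ],
            "fitness": self.fitness,
            "breakdown": dict(self.breakdown),
            "violations": [dict(v) for v in self.violations],
            "feasible": self.feasible,
            "generations_run": self.generations_run,
            "seed": self.seed,
            "slot_minutes": self.slot_minutes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def times_by_gene(self, cs: ConstraintSet) -> list[int]:
        by_item = {i: list(times) for i, (_, times) in enumerate(self.schedule)}
        counters = {i: 0 for i in by_item}
        out = []
        for item_index, _dose in cs.genes:
            out.append(by_item[item_index][counters[item_index]])
            counters[item_index] += 1
        return out


def _assemble_result(cs: ConstraintSet, chromosome: np.ndarray, total: float,
                     mags: dict[str, float], weights: PenaltyWeights,
                     slot_minutes: int, generations_run: int,
                     seed: int | None, history: list[float]) -> ScheduleResult:
    times = chromosome * slot_minutes
    per_item: dict[int, list[int]] = {i: [] for i in range(cs.n_items)}
    for g, (item_index, _) in enumerate(cs.genes):
        per_item[item_index].append(int(times[g]))
    schedule = tuple(
        (cs.item_labels[i], tuple(sorted(per_item[i]))) for i in range(cs.n_items)
    )
    w = weights.as_dict()
    breakdown = {c: float(w[c] * mags[c]) for c in mags}
    feasible = all(breakdown[c] == 0.0 for c in HARD_CLASSES)
    violations = tuple(
        audit_schedule([int(t) for t in times], cs, include_soft=True)
    )
    return ScheduleResult(
        case_id=cs.case_id,
        schedule=schedule,
        fitness=float(total),
        breakdown=breakdown,
        violations=violations,
        feasible=feasible,
        generations_run=generations_run,
        seed=seed,
        slot_minutes=slot_minutes,
        fitness_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# Genetic algorithm


def evolve(constraints: ConstraintSet, config: GAConfig) -> ScheduleResult:
    """Run the seeded GA and return the best individual ever seen.

    Elitist: the best-so-far fitness is non-increasing across generations.
    Early-stops when a zero-penalty individual appears.  Ties among
    equal-fitness individuals break toward the lexicographically smallest
    slot vector, making the result deterministic for a given seed.
    """
    if config.random_seed is None:
        raise ValueError("GAConfig.random_seed is mandatory for evolve()")
    if constraints.n_genes == 0:
        raise ValueError("constraint set has zero doses")

    rng = np.random.default_rng(config.random_seed)
    evaluator = FitnessEvaluator(constraints, config.weights, config.slot_minutes)
    n_slots = config.n_slots
    L = constraints.n_genes
    P = config.population_size
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / L

    pop = rng.integers(0, n_slots, size=(P, L))
    totals, _ = evaluator(pop)

    def lex(ind: np.ndarray) -> tuple:
        return tuple(int(x) for x in ind)

    best_idx = min(range(P), key=lambda i: (totals[i], lex(pop[i])))
    best = pop[best_idx].copy()
    best_fit = float(totals[best_idx])
    history = [best_fit]
    generations_run = 0

    for gen in range(config.generations):
        if best_fit == 0.0:
            break
        generations_run = gen + 1
        order = sorted(range(P), key=lambda i: (totals[i], lex(pop[i])))
        elites = pop[order[: config.elitism_count]].copy()

        n_children = P - config.elitism_count
        # tournament selection (k-way, lowest penalty wins)
        contenders = rng.integers(0, P, size=(2 * n_children, config.tournament_size))
        winners = contenders[
            np.arange(2 * n_children),
            np.argmin(totals[contenders], axis=1),
        ]
        parents_a = pop[winners[:n_children]]
        parents_b = pop[winners[n_children:]]
        # uniform crossover
        do_cx = rng.random(n_children) < config.crossover_rate
        mask = rng.random((n_children, L)) < 0.5
        children = np.where(do_cx[:, None] & mask, parents_b, parents_a)
        # per-gene mutation: resample a random slot
        mut_mask = rng.random((n_children, L)) < mut_rate
        random_slots = rng.integers(0, n_slots, size=(n_children, L))
        children = np.where(mut_mask, random_slots, children)

        pop = np.concatenate([elites, children], axis=0)
        totals, _ = evaluator(pop)

        gen_best = min(range(P), key=lambda i: (totals[i], lex(pop[i])))
        cand_fit = float(totals[gen_best])
        if cand_fit < best_fit or (cand_fit == best_fit and lex(pop[gen_best]) < lex(best)):
            best_fit = cand_fit
            best = pop[gen_best].copy()
        history.append(best_fit)

    _, best_mags = evaluator(best[None, :])
    mags = {c: float(v[0]) for c, v in best_mags.items()}
    return _assemble_result(
        constraints, best, best_fit, mags, config.weights, config.slot_minutes,
        generations_run, config.random_seed, history,
    )


BRUTE_FORCE_GUARD = 10_000_000


def brute_force_schedule(constraints: ConstraintSet, slot_minutes: int = 30,
                         weights: PenaltyWeights | None = None) -> ScheduleResult:
    """Exhaustive minimum of the same fitness function (test oracle).

    Enumerates the full slot grid in lexicographic order, so the returned
    optimum is the lexicographically smallest optimal schedule.  Refuses
    spaces above 10^7 combinations.
    """
    weights = weights or PenaltyWeights()
    n_slots = MINUTES_PER_DAY // slot_minutes
    L = constraints.n_genes
    size = n_slots**L
    if size > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"search space {n_slots}^{L} = {size} exceeds the "
            f"{BRUTE_FORCE_GUARD} brute-force guard"
        )
    evaluator = FitnessEvaluator(constraints, weights, slot_minutes)

    best_total = np.inf
    best_chrom: np.ndarray | None = None
    # chunk over the first gene to bound memory; lex order preserved
    tail = n_slots ** (L - 1)
    tail_grid = np.stack(
        np.meshgrid(*([np.arange(n_slots)] * (L - 1)), indexing="ij"), axis=-1
    ).reshape(tail, L - 1) if L > 1 else np.zeros((1, 0), dtype=np.int64)
    for first in range(n_slots):
        chunk = np.concatenate(
            [np.full((tail_grid.shape[0], 1), first, dtype=np.int64), tail_grid],
            axis=1,
        )
        totals, _ = evaluator(chunk)
        idx = int(np.argmin(totals))  # first occurrence = lex smallest in chunk
        if totals[idx] < best_total:
            best_total = float(totals[idx])
            best_chrom = chunk[idx].copy()
            if best_total == 0.0:
                break

    _, mags = evaluator(best_chrom[None, :])
    mags = {c: float(v[0]) for c, v in mags.items()}
    return _assemble_result(
        constraints, best_chrom, best_total, mags, weights, slot_minutes,
        generations_run=0, seed=None, history=[best_total],
    )


# ---------------------------------------------------------------------------
# Independent constraint audit (not the fitness code path)


def audit_schedule(times_by_gene: list[int], cs: ConstraintSet,
                   include_soft: bool = False) -> list[dict]:
    """Re-check every constraint directly against concrete clock times.

    Walks the constraint set with plain interval/distance arithmetic —
    deliberately not the table-based fitness evaluator — and reports each
    violation with its class, magnitude in minutes, and provenance.
    """
    violations: list[dict] = []

    def add(klass: str, magnitude: float, source: str, detail: str):
        violations.append(
            {"class": klass, "magnitude": float(magnitude),
             "source": source, "detail": detail}
        )

    for wc in cs.windows:
        if wc.klass in SOFT_CLASSES and not include_soft:
            continue
        genes = (
            range(cs.n_genes) if wc.item_index is None
            else cs.genes_of_item(wc.item_index)
        )
        for g in genes:
            t = times_by_gene[g]
            if not point_in_intervals(t, list(wc.allowed)):
                add(
                    wc.klass,
                    distance_to_intervals(t, list(wc.allowed)) * wc.weight_scale,
                    wc.source,
                    f"dose of {cs.item_labels[cs.genes[g][0]]} at "
                    f"{format_clock(t)} outside allowed windows",
                )

    for pc in cs.pairs:
        if pc.klass in SOFT_CLASSES and not include_soft:
            continue
        gap = circular_diff(times_by_gene[pc.gene_a], times_by_gene[pc.gene_b])
        if gap < pc.min_minutes:
            add(
                pc.klass,
                (pc.min_minutes - gap) * pc.weight_scale,
                pc.source,
                f"gap {gap} min between "
                f"{cs.item_labels[cs.genes[pc.gene_a][0]]} and "
                f"{cs.item_labels[cs.genes[pc.gene_b][0]]} is below "
                f"{pc.min_minutes} min",
            )

    for pin in cs.pins:
        d = circular_diff(times_by_gene[pin.gene], pin.minute)
        if d > 0:
            add(
                "pin", d, pin.source,
                f"dose at {format_clock(times_by_gene[pin.gene])} deviates "
                f"from mandated {format_clock(pin.minute)}",
            )

    if include_soft:
        for sp in cs.spacings:
            ts = sorted(times_by_gene[g] for g in sp.genes)
            gaps = [b - a for a, b in zip(ts, ts[1:])]
            gaps.append(MINUTES_PER_DAY - (ts[-1] - ts[0]))
            for gap in gaps:
                dev = abs(gap - sp.target_minutes) - sp.tolerance
                if dev > 0:
                    add(
                        "spacing", dev, sp.source,
                        f"{cs.item_labels[sp.item_index]}: gap {gap} min vs "
                        f"target {sp.target_minutes:g} min",
                    )

    return violations


# ---------------------------------------------------------------------------
# Learning from user interventions


def record_intervention(result: ScheduleResult, cs: ConstraintSet,
                        user_edit: dict[str, list[int]],
                        store: PreferenceStore,
                        origin: str = "") -> PreferenceStore:
    """Induce soft preference rules from a user's manual schedule edit.

    ``user_edit`` maps item labels to the clock times the user moved them to.
    When an edited item ends up separated from every other item's doses by at
    least 30 minutes, an ``administer_alone`` rule with that separation is
    appended (soft — preferences never override KB safety rules).  The store
    is append-only; provenance and ordering are preserved.
    """
    from .model import canonical_name

    if not user_edit:
        return store
    labels = {canonical_name(lbl): i for i, lbl in enumerate(cs.item_labels)}
    new_times: dict[int, list[int]] = {}
    for label, times in user_edit.items():
        key = canonical_name(label)
        if key not in labels:
            raise KeyError(f"user edit references unknown item {label!r}")
        new_times[labels[key]] = sorted(int(t) for t in times)

    merged: dict[int, list[int]] = {
        i: list(times) for i, (_, times) in enumerate(result.schedule)
    }
    merged.update(new_times)

    stamp = origin or f"edit@{time.strftime('%Y-%m-%dT%H:%M:%S')}"
    for item_index in new_times:
        others = [
            t for i, ts in merged.items() if i != item_index for t in ts
        ]
        if not others:
            continue
        separation = min(
            circular_diff(t, o) for t in merged[item_index] for o in others
        )
        if separation >= 30:
            store.append(
                PreferenceRule(
                    scope=canonical_name(cs.item_labels[item_index]),
                    kind="administer_alone",
                    separation_minutes=int(separation),
                    weight=1.0,
                    origin=stamp,
                )
            )
    return store
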