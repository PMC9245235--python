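# Methods

## Scope and workflow

`pharmsched` models one review cycle over one prototypical 24 h day: load a
drug knowledge base and a patient case, emit alerts, let the reviewer
override blocking alerts with a justification, translate everything into
scheduling constraints, and minimize a penalty function with a genetic
algorithm. Multi-day calendars, pharmacokinetic modelling, adherence
tracking and any connection to external drug databases are out of scope; the
knowledge base is user-supplied or the packaged fixture set.

## Domain representation

Clock times are integers, minutes since midnight, with half-open intervals
`[start, end)`; intervals that wrap midnight are split at 00:00, which makes
the night-shift routine (sleep 07:30–14:30, work 22:00–06:00) a first-class
citizen rather than an edge case. Product and principle names are
canonicalized (uppercase, accent-stripped, trademark glyphs removed) so
Portuguese and English brand/generic spellings compare equal; all cross-item
reasoning happens on active-principle sets, never on product names. Files
are JSON with a small documented schema (plus a CSV import for the drug
table only) because diffable fixtures matter more here than a database
schema. Condition codes are a closed shipped vocabulary (pregnancy,
severe_hepatic_disease, renal_impairment, …) extensible per KB file. The
`indication` field of a drug record is stored as metadata and participates
in no automated check.

## Alert engine

Eight alert types are emitted: `nu_interaction`, `contraindication`,
`duplication`, `overdose`, `underdose`, `food_relation`, `observation`,
`min_interval_needed`. Severity defaults (NU and contraindication blocking;
duplication and dose warnings; the rest informational) are a package
convention, overridable per rule in the KB. Design choices worth noting:

- **Duplication is two-tier**: exact (a principle delivered by ≥ 2 items)
  and class-level (two items sharing a 5-character ATC prefix, i.e. the same
  chemical subgroup, warning only). "Duplicity" is otherwise
  under-operationalized; the two tiers capture both readings.
- **Dose checks are strict inequalities** with relative tolerance 1e-9: a
  dose exactly at the per-kg or single-dose limit is compliant. A per-kg
  limit with no patient weight produces an explicit "cannot evaluate" info
  alert rather than silence.
- **The engine only reports.** It never withdraws a drug; a
  contraindication knowingly accepted (`clinical_override_note`) is emitted
  pre-overridden, retaining the full record.
- Reports are stably ordered (blocking → warning → info, then by item,
  type, message) and alert ids are assigned after ordering, so identical
  inputs serialize byte-for-byte identically.

## Scheduling constraints and fitness

One gene per (item, dose); `interval_hours` prescriptions get
`round(24/interval)` doses with target spacing `interval × 60` min, so a
day that does not divide evenly is absorbed by the spacing tolerance rather
than rejected. The penalty classes:

| class | tier | magnitude (minutes) | default weight |
|-------|------|---------------------|----------------|
| sleep | hard | distance from a dose inside sleep to the nearest awake minute | 1000 |
| pair_interval | hard | shortfall of the circular gap under an S rule | 1000 |
| pin | hard | circular distance to a mandated fixed time | 1000 |
| food | hard | distance to the nearest meal-anchored window | 1000 |
| spacing | soft | intra-item gap deviation beyond ±60 min tolerance | 1 |
| busy | soft | distance out of a busy interval to free time | 0.5 |
| preference | soft | learned-rule violation, scaled by rule weight | 1 |

All distances are graded (distance-to-allowed-region rather than a binary
flag) so the GA receives a gradient toward feasibility. Gaps between an
item's doses are computed cyclically around the day — the last dose to the
next day's first dose counts — so end-of-day clustering is not rewarded.
Feasibility means exactly zero hard-class penalty; spacing is deliberately
a soft class, because a q8h pediatric regimen must compress into the awake
day while the sleep window stays inviolable. Work hours are modeled as
discouraged, not forbidden. Food windows: `empty_stomach` with lead L
allows `[meal − L − 60, meal − L]` before any meal; `with_food` with lag G
allows `[meal − G, meal + G]`. The 60 min empty-stomach window width and
the ±60 min spacing tolerance are package defaults chosen as clinically
sensible slack at the 30 min grid; both are ordinary constants, overridable
in code.

Hard weights sit ≥ 10³ above soft weights so one minute of hard violation
outweighs any realistic soft total (a day holds at most 1440 soft-minutes
per class at weight ≤ 1). Only KB rules and the routine can produce hard
constraints; learned user preferences are always soft, so user habits can
never override safety spacing.

## Genetic algorithm

Defaults: 30 min slots (48/day), population 200, ≤ 300 generations,
tournament selection (k = 3), uniform crossover at rate 0.9, per-gene
mutation 1/L resampling a uniform random slot, elitism 2, early stop at
fitness 0, mandatory seed (numpy `default_rng`). Ties among equal-fitness
individuals break toward the lexicographically smallest slot vector, making
runs bit-reproducible. The result always reports the best individual ever
seen with its per-class breakdown, the violation list, and the best-fitness
history (non-increasing by construction; asserted in tests).

Two independent verification paths exist deliberately: the vectorized
fitness evaluator used by the search, and `audit_schedule`, a plain
re-check of every constraint against concrete clock times used to confirm
claimed feasibility; `brute_force_schedule` enumerates the full grid (with
a 10⁷-combination guard) as an exhaustive oracle over the identical fitness
function. On randomized instances with ≤ 3 genes the GA reaches the
exhaustive optimum in ≥ 95/100 seeded runs and can never beat it.

## Preference learning

A user edit that isolates a drug from all other doses by ≥ 30 min induces an
`administer_alone` rule with the observed separation, appended to an
append-only store with provenance; when several rules share (scope, kind)
the newest wins, older entries remain for audit. Rules re-enter subsequent
runs as soft pairwise constraints.

## IARF and agreement statistics

IARF totals sum codes 1/2/3 over the ten items; code 9 ("I do not know") is
excluded from the sum and reported as `n_unknown`, prominently, since a
partially-unknown total is not comparable to a complete one — how unknowns
should enter a total is genuinely open, and exclusion-plus-flag is the
conservative choice. Item 10 maps to the adequate / partially adequate /
inadequate classification.

Weighted kappa uses disagreement weights (linear `|i−j|/(k−1)` as the
default for 3-level ordinal ratings; quadratic and identity provided — the
scheme is a mandatory explicit parameter in the API because no single
convention can be presumed). Degenerate marginals (chance agreement = 1)
raise an explicit error instead of returning 0. The asymptotic CI implements
the Fleiss–Cohen–Everitt large-sample variance, cross-checked in the test
suite against `statsmodels.stats.inter_rater.cohens_kappa` to 10 decimal
places; a percentile bootstrap is offered because review studies often have
n ≈ 10 units, far below asymptotic comfort. Interpretation bands are applied
after half-up rounding to two decimals, the resolution at which the printed
closed bands (0.21–0.40, 0.41–0.60, …) tile the line.

## Synthetic data

`generate_case` draws 3–8 drugs from a clean pool (no rules, limits, food
relations or shared ATC subgroups — zero alerts by construction) and plants
exactly one inconsistency of the requested class; the three routine-centred
classes plant a scheduling challenge instead of an alert, so their expected
alert set is empty and the measurable event is a feasible schedule.
`generate_ratings` uses a copy-mixture: rater B copies rater A with
probability p, else draws independently from the same marginals, giving
`O = p·diag(π) + (1−p)ππᵀ` and hence expected kappa exactly p under *any*
disagreement weighting — which is what makes the CI coverage simulation
(500 replicates, n = 1000, true κ = 0.48) well-posed. Negative targets are
unreachable by this construction and rejected.

What the synthetic data does **not** emulate: real prescription length and
drug-frequency distributions, correlated comorbidities, dose-unit
heterogeneity, free-text sig ambiguity, or rater-specific bias structure.
Passing tests therefore demonstrate the engine's logic and the scheduler's
constraint handling, not clinical coverage of a real formulary.

## Fixture values

The ten built-in cases encode the published scenario descriptions; every
numeric threshold the scenarios need but do not state (azithromycin
10 mg/kg/day cap, digoxin–aluminum hydroxide 120 min interval,
alendronate–levothyroxine 30 min interval, 30 min food leads, amoxicillin
20–90 mg/kg/day band) is a FIXTURE VALUE for the test harness, not clinical
guidance. The fixture KB holds 21 products — only what the cases and the
generator require.

## Problem sizes and numerical choices

The shipped validation runs use the ten fixture cases (1–2 items, ≤ 5 doses
each) at the default GA budget; the oracle-equivalence study uses 100
instances of ≤ 3 genes at 48 slots so exhaustive enumeration stays well
under the brute-force guard; the coverage study uses 500 × n = 1000
replicates. Dose-limit comparisons use relative tolerance 1e-9; fitness
comparisons in tests use absolute 1e-9; the kappa degenerate-marginal guard
triggers below |1 − p_e| < 1e-12.

## Known limitations

- One prototypical day: weekly regimens (e.g. alendronate) are modeled as
  their administration day.
- The GA provides no optimality certificate beyond the small-instance
  oracle study; for large prescriptions it reports the best found.
- Preference induction recognizes isolation edits only; richer edit
  semantics (preferred windows from repeated user placements) are stubbed
  by the `preferred_window` rule kind but not induced automatically.
- Severity grading is a convention, not evidence-graded; the KB may
  override it per rule.
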