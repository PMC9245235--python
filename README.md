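# pharmsched

Decision support for **pharmacotherapy review**: given a drug knowledge base
and a patient profile, `pharmsched` finds prescription inconsistencies
(drug–drug interactions, contraindications, therapeutic duplication, dose
range violations, food-timing requirements) and then assigns a clock time to
every dose of every drug with a **genetic algorithm** that respects the
patient's daily routine and the spacing constraints between interacting
drugs. It is written for clinical pharmacists and pharmacoinformatics
researchers who need a scriptable, reproducible review-and-scheduling engine
rather than an interactive web system.

## The model

The knowledge base relates **active principles** (products are always
resolved to their principle sets, so combination products interact through
each constituent) under three rule types:

| rule | meaning |
|------|---------|
| **NU** (no-use) | contraindication-grade: the pair must not be used concomitantly |
| **S** (scheduling) | a minimum time span, in minutes, required between administrations |
| **O** (observation) | administration guidance that maximizes the drug's effect |

The **alert engine** crosses the prescription and the patient's conditions
against these rules plus per-kg dose limits and food relations; blocking
alerts gate the scheduler until a reviewer explicitly overrides them with a
justification (the engine never removes a drug on its own).

The **scheduler** works on one prototypical 24 h day discretized into slots
(default 30 min, 48 slots). A candidate schedule is a vector
x ∈ {0,…,47}^L with one gene per (item, dose). Its quality is a weighted
penalty sum over violation classes

    F(x) = Σ_c  w_c · Σ_v  m_v(x)

where the magnitude m_v is measured in minutes (interval shortfall, distance
to an allowed window, spacing deviation beyond tolerance). Hard classes —
sleep window, pairwise minimum intervals, mandated fixed times, meal-anchored
food windows — carry weights ≥ 10³× the soft classes (intra-item spacing,
busy hours, learned preferences), so any hard violation dominates every soft
trade-off; a schedule is *feasible* iff every hard class scores exactly 0.
A seeded elitist GA (population 200, tournament selection, uniform
crossover, per-gene mutation, early stop at F = 0) minimizes F and always
returns the best solution found, with the violation list, even when the
constraints cannot all be met.

The package also ships the **IARF** review-quality instrument (ten items
coded 1/2/3/9, all-"No" optimum = 10 points) and **weighted Cohen's kappa**
κ = 1 − Σw·O / Σw·E with linear/quadratic/identity disagreement weights,
Fleiss–Cohen–Everitt asymptotic confidence intervals, a bootstrap
alternative, and the standard interpretation bands (0.21–0.40 "reasonable",
0.41–0.60 "moderate", …).

## Worked example

Ten hypothetical cases ship as fixtures (`pharmsched.builtin_cases()`),
each planting one inconsistency class. Reviewing the digoxin + antacid case
and scheduling it:

```sh
$ pharmsched review --kb src/pharmsched/fixtures/kb.json \
      --case src/pharmsched/fixtures/case04.json
case case04: 1 alert(s)
  A1 info     min_interval_needed  DIGOXIN 0.25 MG + MYLANTA PLUS: keep at
     least 120 min between doses (antacids reduce digoxin absorption; ...)

$ pharmsched schedule --kb src/pharmsched/fixtures/kb.json \
      --case src/pharmsched/fixtures/case04.json --seed 42 --out sched.json
```

`sched.json` then contains a feasible assignment, e.g.

```json
{"schedule": [{"item": "DIGOXIN 0.25 MG", "times": ["09:00"]},
              {"item": "MYLANTA PLUS", "times": ["07:00", "14:00", "21:30"]}],
 "fitness": 30.0, "feasible": true,
 "breakdown": {"pair_interval": 0.0, "sleep": 0.0, "spacing": 30.0, "...": 0.0}}
```

every antacid dose sits ≥ 120 min from the digoxin dose and inside the awake
day; the residual 30 belongs to the soft spacing class (the three antacid
doses cannot be exactly 8 h apart inside a 15 h waking day). The exit-code
contract (0 clean / 2 blocking alerts remain / 1 error) makes the review a
scriptable gate: `pharmsched schedule` on the aspirin + warfarin case exits
2 and writes nothing until an overrides file acknowledges the risk.

`pharmsched validate --seed 42` runs the whole pipeline over the ten cases
and prints the detection and proper-schedule percentages (100.0% / 100.0%);
`pharmsched kappa ratings.csv --weights linear` and
`pharmsched iarf score responses.csv` expose the validation instruments;
`pharmsched gen-cases --class nu_pair --n 50 --seed 7 --out dir/` produces
synthetic planted cases.

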