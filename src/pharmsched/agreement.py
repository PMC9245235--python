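"""IARF questionnaire scoring and weighted-kappa rater agreement.

The IARF (Pharmacotherapy Review Assessment Index) is a 10-item instrument
for judging the quality of a pharmacotherapy review.  Each item is coded
1 (No), 2 (Yes, but acceptable), 3 (Yes) or 9 (I do not know); 1 is always
the optimal answer, so an optimal review sums to exactly 10 points.  Item 10
additionally classifies the review as adequate / partially adequate /
inadequate.

Agreement between two raters over the ordinal classification set
{adequate=1, partially adequate=2, inadequate=3} is measured with weighted
Cohen's kappa,

    kappa = 1 - sum(w_ij O_ij) / sum(w_ij E_ij),

with disagreement weights ``w`` (linear ``|i-j|/(k-1)`` by default),
observed proportions ``O`` and chance-expected proportions ``E`` from the
marginals.  Identity weights reduce to unweighted Cohen's kappa.  The
asymptotic confidence interval uses the Fleiss–Cohen–Everitt large-sample
variance; a percentile bootstrap is offered for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "IARF_CODES",
    "IARFResponse",
    "IARFScore",
    "RatingMatrix",
    "KappaUndefinedError",
    "score_iarf",
    "weighted_kappa",
    "kappa_ci",
    "interpret_kappa",
]

IARF_CODES = (1, 2, 3, 9)
_N_ITEMS = 10

_CLASSIFICATION = {1: "adequate", 2: "partially_adequate", 3: "inadequate",
                   9: "unknown"}

#: Interpretation bands (closed intervals on the 2-decimal scale).
KAPPA_BANDS = (
    (-1.00, 0.00, "poor"),
    (0.01, 0.20, "slight"),
    (0.21, 0.40, "reasonable"),
    (0.41, 0.60, "moderate"),
    (0.61, 0.80, "substantial"),
    (0.81, 1.00, "almost perfect"),
)


class KappaUndefinedError(ValueError):
    """Kappa is undefined (degenerate marginals: observed equals expected
    agreement with no room for chance correction)."""


@dataclass(frozen=True)
class IARFResponse:
    """One completed IARF questionnaire: exactly ten coded answers."""

    items: tuple[int, ...]

    def __post_init__(self):
        if len(self.items) != _N_ITEMS:
            raise ValueError(
                f"IARF response must have exactly {_N_ITEMS} items, "
                f"got {len(self.items)}"
            )
        bad = [c for c in self.items if c not in IARF_CODES]
        if bad:
            raise ValueError(f"invalid IARF codes {bad}; allowed {IARF_CODES}")


@dataclass(frozen=True)
class IARFScore:
    """Summed IARF score with unknown-count and the item-10 classification.

    ``n_unknown > 0`` marks an incomplete assessment: code-9 items are
    excluded from the sum, so totals are not comparable across responses
    with different unknown counts.
    """

    total: int
    n_unknown: int
    classification: str


def score_iarf(response: IARFResponse | list[int] | tuple[int, ...]) -> IARFScore:
    """Score a response: sum of codes over answered items (9 excluded).

    With zero unknowns the total ranges 10–30 and equals 10 exactly when
    every answer is the optimal "No".
    """
    if not isinstance(response, IARFResponse):
        response = IARFResponse(items=tuple(int(c) for c in response))
    answered = [c for c in response.items if c != 9]
    return IARFScore(
        total=sum(answered),
        n_unknown=_N_ITEMS - len(answered),
        classification=_CLASSIFICATION[response.items[-1]],
    )


@dataclass(frozen=True)
class RatingMatrix:
    """Paired ordinal ratings of the same units by two raters."""

    rater_a: tuple[int, ...]
    rater_b: tuple[int, ...]
    categories: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self):
        if len(self.rater_a) != len(self.rater_b):
            raise ValueError(
                f"rating vectors differ in length: {len(self.rater_a)} vs "
                f"{len(self.rater_b)}"
            )
        if len(self.rater_a) < 2:
            raise ValueError("need at least 2 rated units")
        cats = set(self.categories)
        bad = (set(self.rater_a) | set(self.rater_b)) - cats
        if bad:
            raise ValueError(f"ratings {sorted(bad)} outside categories {self.categories}")

    @property
    def n(self) -> int:
        return len(self.rater_a)

    def contingency(self) -> np.ndarray:
        """k×k count table, rows = rater A, columns = rater B."""
        k = len(self.categories)
        index = {c: i for i, c in enumerate(self.categories)}
        table = np.zeros((k, k))
        for a, b in zip(self.rater_a, self.rater_b):
            table[index[a], index[b]] += 1
        return table


def _disagreement_weights(k: int, scheme: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if scheme == "linear":
        return np.abs(i - j) / (k - 1)
    if scheme == "quadratic":
        return ((i - j) / (k - 1)) ** 2
    if scheme == "identity":
        return (i != j).astype(float)
    raise ValueError(f"unknown weight scheme {scheme!r}; "
                     "use linear, quadratic or identity")


def _kappa_parts(m: RatingMatrix, weights: str):
    table = m.contingency()
    n = table.sum()
    p = table / n
    w = _disagreement_weights(len(m.categories), weights)
    v = 1.0 - w  # agreement weights
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    e = np.outer(row, col)
    po = float((v * p).sum())
    pe = float((v * e).sum())
    if abs(1.0 - pe) < 1e-12:
        raise KappaUndefinedError(
            "kappa undefined: chance-expected agreement equals 1 "
            "(degenerate marginals — a rater uses a single category)"
        )
    kappa = (po - pe) / (1.0 - pe)
    return table, p, v, row, col, po, pe, kappa


def weighted_kappa(m: RatingMatrix, weights: str) -> float:
    """Weighted Cohen's kappa with the given disagreement-weight scheme.

    ``weights`` is mandatory: "linear" (the package default for 3-level
    ordinal ratings), "quadratic", or "identity" (= unweighted Cohen's
    kappa).  Symmetric in the raters and invariant to unit order.
    """
    *_, kappa = _kappa_parts(m, weights)
    return float(kappa)


def _asymptotic_se(m: RatingMatrix, weights: str) -> tuple[float, float]:
    """(kappa, standard error) via the Fleiss–Cohen–Everitt variance."""
    _, p, v, row, col, po, pe, kappa = _kappa_parts(m, weights)
    vbar_rows = (v * col[None, :]).sum(axis=1)  # E_b[v | a = i]
    vbar_cols = (v * row[:, None]).sum(axis=0)  # E_a[v | b = j]
    inner = (v - (vbar_rows[:, None] + vbar_cols[None, :]) * (1.0 - kappa)) ** 2
    var = ((p * inner).sum() - (kappa - pe * (1.0 - kappa)) ** 2) / (
        m.n * (1.0 - pe) ** 2
    )
    return float(kappa), float(np.sqrt(max(var, 0.0)))


def kappa_ci(m: RatingMatrix, weights: str, level: float = 0.95,
             method: str = "asymptotic", n_boot: int = 2000,
             seed: int | None = None) -> dict:
    """Confidence interval for weighted kappa.

    ``method="asymptotic"`` uses the Fleiss–Cohen–Everitt large-sample
    standard error (normal quantiles); ``method="bootstrap"`` resamples unit
    pairs (percentile interval), preferable for small n.  Bounds are clipped
    to [-1, 1]; the method name is recorded in the returned dict.
    """
    from scipy import stats

    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if method == "asymptotic":
        kappa, se = _asymptotic_se(m, weights)
        z = stats.norm.ppf(0.5 + level / 2.0)
        lower, upper = kappa - z * se, kappa + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        kappa = weighted_kappa(m, weights)
        a = np.asarray(m.rater_a)
        b = np.asarray(m.rater_b)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, m.n, size=m.n)
            try:
                reps.append(
                    weighted_kappa(
                        RatingMatrix(tuple(a[idx]), tuple(b[idx]), m.categories),
                        weights,
                    )
                )
            except KappaUndefinedError:
                continue
        if not reps:
            raise KappaUndefinedError("all bootstrap replicates degenerate")
        alpha = 1.0 - level
        lower, upper = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return {
        "kappa": float(kappa),
        "lower": float(max(-1.0, lower)),
        "upper": float(min(1.0, upper)),
        "level": level,
        "method": method,
        "weights": weights,
        "n": m.n,
    }


def interpret_kappa(value: float) -> str:
    """Map a kappa value to its interpretation band.

    The value is rounded half-up to two decimals first, so the printed
    closed bands tile the line: 0.40 is "reasonable", 0.41 is "moderate".
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"kappa {value} outside [-1, 1]")
    rounded = float(
        Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )
    for lo, hi, label in KAPPA_BANDS:
        if lo <= rounded <= hi:
            return label
    raise AssertionError(f"unreachable: {rounded} matched no band")
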