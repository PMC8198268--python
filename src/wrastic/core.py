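"""WRASTIC-HI aggregation, hazard typing and degradation-state classification.

The index for one lake is

    WRASTIC-HI = (W*wW + R*wR + A*wA + a*wa + S*wS + T*wT + I*wI + C*wC)
                 x (slope + aspect + permeability)

where the parenthesised weighted sum is the WRASTIC value and the second
factor is the Hazard Index (HI) sum.  The HI sum selects one of three lake
types (propensity to accumulate pollutants), and each type carries its own
WRASTIC thresholds for the three-way degradation state (natural /
semi-degraded / degraded).  All arithmetic is integer, so results are
bit-exact.

Note the symbol collision in the published formula: "S" names both the
watershed-size indicator and the slope hazard factor.  They are held in
distinct types here (IndicatorScores.S vs HazardScores.slope).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IndicatorScores",
    "WeightScheme",
    "HazardScores",
    "HazardType",
    "TypeRule",
    "ClassThresholds",
    "State",
    "DegradationResult",
    "BatchResult",
    "CalibrationResult",
    "DEFAULT_WEIGHTS",
    "LITERAL_WEIGHTS",
    "DEFAULT_TYPE_RULE",
    "DEFAULT_THRESHOLDS",
    "compute_wrastic",
    "hi_sum",
    "assign_hi_type",
    "classify",
    "evaluate_lake",
    "evaluate_batch",
    "calibrate",
]

INDICATORS = ("W", "R", "A", "a", "S", "T", "I", "C")

#: Valid grade ranges per indicator.
_GRADE_RANGES = {
    "W": (0, 4),
    "R": (1, 5),
    "A": (1, 5),
    "a": (1, 5),
    "S": (1, 5),
    "T": (0, 5),
    "I": (0, 5),
    "C": (1, 5),
}


class State(str, Enum):
    NATURAL = "natural"
    SEMI_DEGRADED = "semi_degraded"
    DEGRADED = "degraded"


_STATE_ORDER = {State.NATURAL: 0, State.SEMI_DEGRADED: 1, State.DEGRADED: 2}


class HazardType(int, Enum):
    TYPE_1 = 1
    TYPE_2 = 2
    TYPE_3 = 3


@dataclass(frozen=True)
class IndicatorScores:
    """The seven WRASTIC indicator grades (agriculture split into land-use A
    and irrigation a, as in the reference tables)."""

    W: int
    R: int
    A: int
    a: int
    S: int
    T: int
    I: int
    C: int

    def __post_init__(self) -> None:
        for name in INDICATORS:
            v = getattr(self, name)
            lo, hi = _GRADE_RANGES[name]
            if not isinstance(v, (int,)) or isinstance(v, bool) or not lo <= v <= hi:
                raise ValueError(
                    f"indicator {name} grade must be an integer in {lo}..{hi}, got {v!r}"
                )


@dataclass(frozen=True)
class WeightScheme:
    """Multipliers of the weighted sum.  The default transposes the printed
    agricultural sub-weights (land-use 3, irrigation 5): the literal printed
    assignment misclassifies reference lakes, see :func:`calibrate`."""

    wW: int = 3
    wR: int = 3
    wA: int = 3
    wa: int = 5
    wS: int = 1
    wT: int = 1
    wI: int = 4
    wC: int = 1

    def __post_init__(self) -> None:
        for name in INDICATORS:
            w = getattr(self, "w" + name)
            if not isinstance(w, int) or isinstance(w, bool) or w <= 0:
                raise ValueError(f"weight w{name} must be a positive integer, got {w!r}")

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_WEIGHTS = WeightScheme()
#: The weight assignment exactly as printed (agricultural land 5, irrigation 3).
LITERAL_WEIGHTS = WeightScheme(wA=5, wa=3)


@dataclass(frozen=True)
class HazardScores:
    """Slope, aspect and soil-permeability grades of the HI term.

    The slope rubric yields {1, 3, 4, 5}, but grades 1-5 are accepted: the
    reference table prints a slope grade 2 for one lake (reachable through
    the rounded-mean zonal aggregation).
    """

    slope: int
    aspect: int
    permeability: int

    def __post_init__(self) -> None:
        if self.slope not in (1, 2, 3, 4, 5):
            raise ValueError(f"slope grade must be in 1..5, got {self.slope!r}")
        if self.aspect not in (1, 3, 5):
            raise ValueError(f"aspect grade must be in {{1,3,5}}, got {self.aspect!r}")
        if self.permeability not in (1, 3, 5):
            raise ValueError(
                f"permeability grade must be in {{1,3,5}}, got {self.permeability!r}"
            )


@dataclass(frozen=True)
class TypeRule:
    """Monotone sum-threshold rule mapping the HI sum to a lake type:
    sum <= t1 -> type 1, t1 < sum <= t2 -> type 2, sum > t2 -> type 3."""

    t1: int = 9
    t2: int = 12

    def __post_init__(self) -> None:
        if not (3 <= self.t1 < self.t2 <= 15):
            raise ValueError(f"require 3 <= t1 < t2 <= 15, got ({self.t1}, {self.t2})")

    def hazard_type(self, hi: int) -> HazardType:
        if hi <= self.t1:
            return HazardType.TYPE_1
        if hi <= self.t2:
            return HazardType.TYPE_2
        return HazardType.TYPE_3


DEFAULT_TYPE_RULE = TypeRule()


@dataclass(frozen=True)
class ClassThresholds:
    """Per-type WRASTIC bounds: (natural upper, semi-degraded upper); the
    degraded class is the remainder.  Values above 100 clamp to degraded."""

    bounds: dict[HazardType, tuple[int, int]]

    def __post_init__(self) -> None:
        prev = None
        for t in (HazardType.TYPE_1, HazardType.TYPE_2, HazardType.TYPE_3):
            a, b = self.bounds[t]
            if not 0 < a < b <= 100:
                raise ValueError(f"bounds for {t} must satisfy 0 < a < b <= 100")
            if prev is not None and (a > prev[0] or b > prev[1]):
                raise ValueError("bounds must be non-increasing across types 1->3")
            prev = (a, b)


DEFAULT_THRESHOLDS = ClassThresholds(
    bounds={
        HazardType.TYPE_1: (30, 63),
        HazardType.TYPE_2: (27, 58),
        HazardType.TYPE_3: (21, 44),
    }
)


@dataclass(frozen=True)
class DegradationResult:
    wrastic_value: int
    hi_sum: int
    hi_type: HazardType
    state: State
    class_percentages: dict[State, float] | None = None

    def to_record(self) -> dict:
        rec = {
            "wrastic": self.wrastic_value,
            "hi_sum": self.hi_sum,
            "hi_type": int(self.hi_type),
            "state": self.state.value,
        }
        if self.class_percentages is not None:
            for s in State:
                rec[f"pct_{s.value}"] = self.class_percentages.get(s, 0.0)
        return rec


def compute_wrastic(scores: IndicatorScores, weights: WeightScheme = DEFAULT_WEIGHTS) -> int:
    """The weighted indicator sum (integer)."""
    return sum(getattr(scores, n) * getattr(weights, "w" + n) for n in INDICATORS)


def hi_sum(h: HazardScores) -> int:
    """Hazard Index sum (slope + aspect + permeability), range 3-15."""
    return h.slope + h.aspect + h.permeability


def assign_hi_type(h: HazardScores, rule: TypeRule = DEFAULT_TYPE_RULE) -> HazardType:
    """Lake type 1-3 (pollutant-accumulation propensity) from the HI sum."""
    return rule.hazard_type(hi_sum(h))


def classify(
    wrastic_value: int,
    hi_type: HazardType,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> State:
    """Three-way degradation state from the WRASTIC value and lake type."""
    if wrastic_value < 0:
        raise ValueError(f"WRASTIC value must be non-negative, got {wrastic_value}")
    natural_hi, semi_hi = thresholds.bounds[HazardType(hi_type)]
    if wrastic_value <= natural_hi:
        return State.NATURAL
    if wrastic_value <= semi_hi:
        return State.SEMI_DEGRADED
    return State.DEGRADED


def evaluate_lake(
    scores: IndicatorScores,
    hazards: HazardScores,
    weights: WeightScheme = DEFAULT_WEIGHTS,
    rule: TypeRule = DEFAULT_TYPE_RULE,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> DegradationResult:
    """Full per-lake evaluation: index value, HI sum, type and state."""
    v = compute_wrastic(scores, weights)
    h = hi_sum(hazards)
    t = rule.hazard_type(h)
    return DegradationResult(v, h, t, classify(v, t, thresholds))


# -- batch evaluation ---------------------------------------------------------

REQUIRED_COLUMNS = list(INDICATORS) + ["slope", "aspect", "permeability"]


@dataclass(frozen=True)
class BatchResult:
    table: pd.DataFrame
    counts: dict[str, int]
    by_protected: pd.DataFrame | None
    by_morphologic_unit: pd.DataFrame | None

    def summary(self) -> dict:
        out = {"counts": dict(self.counts), "n_lakes": int(len(self.table))}
        if self.by_protected is not None:
            out["by_protected"] = {
                str(k): {c: int(v) for c, v in row.items()}
                for k, row in self.by_protected.iterrows()
            }
        if self.by_morphologic_unit is not None:
            out["by_morphologic_unit"] = {
                str(k): {c: int(v) for c, v in row.items()}
                for k, row in self.by_morphologic_unit.iterrows()
            }
        return out


def _row_scores(row) -> tuple[IndicatorScores, HazardScores]:
    scores = IndicatorScores(**{n: int(row[n]) for n in INDICATORS})
    hazards = HazardScores(
        slope=int(row["slope"]),
        aspect=int(row["aspect"]),
        permeability=int(row["permeability"]),
    )
    return scores, hazards


def evaluate_batch(
    table: pd.DataFrame,
    weights: WeightScheme = DEFAULT_WEIGHTS,
    rule: TypeRule = DEFAULT_TYPE_RULE,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> BatchResult:
    """Evaluate every lake of a score table; summarise state counts and
    cross-tabulations by protected status and morphologic unit."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    # keep any printed reference columns, renamed out of the result's way
    clashes = {c: c + "_ref" for c in ("wrastic", "hi_sum", "hi_type", "state")
               if c in table.columns}
    table = table.rename(columns=clashes)

    records = []
    for _, row in table.iterrows():
        scores, hazards = _row_scores(row)
        res = evaluate_lake(scores, hazards, weights, rule, thresholds)
        records.append(res.to_record())
    out = pd.concat(
        [table.reset_index(drop=True), pd.DataFrame.from_records(records)], axis=1
    ) if records else table.assign(wrastic=[], hi_sum=[], hi_type=[], state=[])

    counts = {s.value: 0 for s in State}
    if records:
        counts.update(out["state"].value_counts().to_dict())

    def crosstab(col: str) -> pd.DataFrame | None:
        if col not in out.columns or not len(out):
            return None
        ct = pd.crosstab(out[col], out["state"])
        for s in State:
            if s.value not in ct.columns:
                ct[s.value] = 0
        return ct[[s.value for s in State]]

    return BatchResult(
        table=out,
        counts={s.value: int(counts[s.value]) for s in State},
        by_protected=crosstab("protected"),
        by_morphologic_unit=crosstab("morphologic_unit"),
    )


# -- calibration of the under-specified rules ---------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    feasible: list[tuple[WeightScheme, TypeRule]]
    default_feasible: bool
    n_candidates: int

    def schemes(self) -> list[dict]:
        return [
            {"weights": w.to_dict(), "type_rule": {"t1": r.t1, "t2": r.t2}}
            for w, r in self.feasible
        ]


def _mismatches(
    reference: pd.DataFrame,
    weights: WeightScheme,
    rule: TypeRule,
    thresholds: ClassThresholds,
) -> list[str]:
    bad = []
    for _, row in reference.iterrows():
        scores, hazards = _row_scores(row)
        res = evaluate_lake(scores, hazards, weights, rule, thresholds)
        if res.state.value != str(row["state"]):
            bad.append(str(row.get("name", row.name)))
    return bad


def calibrate(
    reference: pd.DataFrame,
    weight_candidates: Sequence[WeightScheme] | None = None,
    type_rules: Iterable[TypeRule] | None = None,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> CalibrationResult:
    """Exhaustive search for (weight scheme, HI-type rule) combinations that
    reproduce every printed state of the reference table.

    The default candidate weights are the two assignments of the printed
    agricultural sub-weights {3, 5} over land-use/irrigation (other weights
    as printed); the default rule space is every monotone sum-threshold pair
    3 <= t1 < t2 <= 15.  Raises if no candidate is feasible, reporting the
    closest scheme and its mismatched lakes.
    """
    if "state" not in reference.columns:
        raise ValueError("reference table must carry the printed 'state' column")
    if weight_candidates is None:
        weight_candidates = [DEFAULT_WEIGHTS, LITERAL_WEIGHTS]
    if type_rules is None:
        type_rules = [
            TypeRule(t1, t2)
            for t1, t2 in itertools.combinations(range(3, 16), 2)
        ]
    type_rules = list(type_rules)

    feasible: list[tuple[WeightScheme, TypeRule]] = []
    closest: tuple[int, WeightScheme, TypeRule, list[str]] | None = None
    for w in weight_candidates:
        for r in type_rules:
            bad = _mismatches(reference, w, r, thresholds)
            if not bad:
                feasible.append((w, r))
            elif closest is None or len(bad) < closest[0]:
                closest = (len(bad), w, r, bad)

    n_cand = len(weight_candidates) * len(type_rules)
    if not feasible:
        assert closest is not None
        raise ValueError(
            "no candidate scheme reproduces the reference states; closest "
            f"(weights={closest[1].to_dict()}, rule=({closest[2].t1},{closest[2].t2})) "
            f"misclassifies: {', '.join(closest[3])}"
        )
    # deterministic order independent of search-space ordering
    feasible.sort(key=lambda wr: (tuple(sorted(wr[0].to_dict().items())), wr[1].t1, wr[1].t2))
    default_ok = any(
        w == DEFAULT_WEIGHTS and r == DEFAULT_TYPE_RULE for w, r in feasible
    )
    return CalibrationResult(feasible, default_ok, n_cand)
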