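"""Reference-standard nutrition assessment and its risk-rating classification.

The reference standard against which the screening tool is validated is a
full nutrition assessment.  Six components are each rated low / moderate /
high: the two anthropometric indicators (BMI-for-age and MUAC-for-age
z-scores, one point each), medical history, 24-h dietary recall, behavior,
and food security (one point each), for six points total.  The overall
classification rule is: 3 or more points rated high -> high; otherwise 3
or more rated moderate -> moderate; otherwise low.

Anthropometric z-scores use the LMS (lambda-mu-sigma) growth-reference
parameterization.  The component rating rules for medical history, recall
and behavior are not published in full, so they are configurable rule
tables with documented defaults, and every component supports a
pass-through mode that accepts a pre-assigned rating — the validation
pipeline never has to depend on unpublished clinical rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CreceError, RiskCategory

__all__ = [
    "AssessmentError",
    "UnratableError",
    "COMPONENTS",
    "lms_zscore",
    "LMSReference",
    "AnthroCutoffs",
    "DEFAULT_ANTHRO_CUTOFFS",
    "anthropometric_class",
    "classify_anthropometric",
    "food_security_screen",
    "Rule",
    "RuleTable",
    "DEFAULT_RULE_TABLES",
    "rate_component",
    "AssessmentProfile",
    "AssessmentResult",
    "aggregate_assessment",
    "AGGREGATION_POLICIES",
]


class AssessmentError(CreceError):
    """Invalid assessment input."""


class UnratableError(AssessmentError):
    """No configured rule covers the observation; never silently defaulted."""


#: The six rated points, in canonical order.  Anthropometrics contribute two
#: of the six points (BMI and MUAC rated separately); the other four
#: components one point each.
COMPONENTS = (
    "anthro_bmi",
    "anthro_muac",
    "medical_history",
    "recall_24h",
    "behavior",
    "food_security",
)

# ---------------------------------------------------------------------------
# LMS z-scores
# ---------------------------------------------------------------------------

_L_EPS = 1e-12


def lms_zscore(value: float, L: float, M: float, S: float) -> float:
    """z-score of a measurement under an LMS growth reference.

    z = ((X/M)^L - 1) / (L*S) for L != 0, and the limiting form
    z = ln(X/M) / S at L = 0 (the implementation switches to the log form
    for |L| below 1e-12, where the two agree to floating-point precision).
    """
    if not (value > 0):
        raise AssessmentError(f"measurement must be positive, got {value}")
    if not (M > 0 and S > 0):
        raise AssessmentError(f"invalid LMS row: M={M}, S={S}")
    ratio = value / M
    if abs(L) < _L_EPS:
        return math.log(ratio) / S
    # expm1(L*log(r)) == r^L - 1 without cancellation for small L
    return math.expm1(L * math.log(ratio)) / (L * S)


class LMSReference:
    """Age- and sex-specific (L, M, S) lookup table.

    Backed by a frame with columns ``metric, sex, age_months, L, M, S``.
    Age lookup defaults to the nearest tabulated month (ties toward the
    younger age) to keep results bit-reproducible; linear interpolation of
    L, M and S is available via ``interpolate=True``.  Ages outside the
    tabulated range for a metric x sex stratum are an error.
    """

    REQUIRED = ("metric", "sex", "age_months", "L", "M", "S")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.REQUIRED) - set(table.columns)
        if missing:
            raise AssessmentError(f"LMS table missing columns: {sorted(missing)}")
        tab = table.loc[:, list(self.REQUIRED)].copy()
        tab["age_months"] = tab["age_months"].astype(float)
        for stratum, grp in tab.groupby(["metric", "sex"]):
            ages = grp["age_months"].to_numpy()
            if not np.all(np.diff(np.sort(ages)) > 0):
                raise AssessmentError(f"duplicate ages in stratum {stratum}")
            if (grp["M"] <= 0).any() or (grp["S"] <= 0).any():
                raise AssessmentError(f"non-positive M or S in stratum {stratum}")
        self.table = tab.sort_values(["metric", "sex", "age_months"]).reset_index(
            drop=True
        )

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def bundled_synthetic(cls) -> "LMSReference":
        """The bundled SYNTHETIC reference (LMS-shaped, not a real standard)."""
        ref = resources.files("crece.data").joinpath("synthetic_lms_reference.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def lookup(
        self, metric: str, sex: str, age_months: float, *, interpolate: bool = False
    ) -> tuple[float, float, float]:
        grp = self.table[
            (self.table["metric"] == metric) & (self.table["sex"] == sex)
        ]
        if grp.empty:
            raise AssessmentError(f"no LMS rows for metric={metric!r}, sex={sex!r}")
        ages = grp["age_months"].to_numpy()
        if not (ages.min() <= age_months <= ages.max()):
            raise AssessmentError(
                f"age {age_months} months outside reference range "
                f"[{ages.min()}, {ages.max()}] for {metric}/{sex}"
            )
        if interpolate:
            return tuple(
                float(np.interp(age_months, ages, grp[c].to_numpy()))
                for c in ("L", "M", "S")
            )
        dist = np.abs(ages - age_months)
        idx = int(np.argmin(dist))  # argmin takes the first = younger age on ties
        row = grp.iloc[idx]
        return (float(row["L"]), float(row["M"]), float(row["S"]))

    def zscore(
        self,
        value: float,
        metric: str,
        sex: str,
        age_months: float,
        *,
        interpolate: bool = False,
    ) -> float:
        L, M, S = self.lookup(metric, sex, age_months, interpolate=interpolate)
        return lms_zscore(value, L, M, S)


# ---------------------------------------------------------------------------
# Anthropometric classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnthroCutoffs:
    """z-score thresholds for anthropometric classes and their risk mapping.

    Defaults: overweight at the 85th percentile (z >= 1.036) and obesity at
    the 95th (z >= 1.645), per the CDC percentile definitions; malnutrition
    bands at z <= -1 (mild), z <= -2 (moderate), z <= -3 (severe), per the
    pediatric consensus indicators.  The class -> risk mapping preserves
    ordinal severity: normal -> low; mild malnutrition or overweight ->
    moderate; moderate/severe malnutrition or obesity -> high.
    """

    obesity_z: float = 1.645
    overweight_z: float = 1.036
    mild_malnutrition_z: float = -1.0
    moderate_malnutrition_z: float = -2.0
    severe_malnutrition_z: float = -3.0
    mapping: Mapping[str, RiskCategory] = field(
        default_factory=lambda: {
            "normal": RiskCategory.LOW,
            "overweight": RiskCategory.MODERATE,
            "obesity": RiskCategory.HIGH,
            "mild_malnutrition": RiskCategory.MODERATE,
            "moderate_malnutrition": RiskCategory.HIGH,
            "severe_malnutrition": RiskCategory.HIGH,
        }
    )

    _CLASSES = (
        "severe_malnutrition",
        "moderate_malnutrition",
        "mild_malnutrition",
        "normal",
        "overweight",
        "obesity",
    )

    def __post_init__(self) -> None:
        if not (
            self.severe_malnutrition_z
            < self.moderate_malnutrition_z
            < self.mild_malnutrition_z
            < 0
            < self.overweight_z
            < self.obesity_z
        ):
            raise AssessmentError("anthropometric thresholds out of order")
        if set(self.mapping) != set(self._CLASSES):
            raise AssessmentError(
                "class->risk mapping must cover exactly the six anthropometric classes"
            )


DEFAULT_ANTHRO_CUTOFFS = AnthroCutoffs()


def anthropometric_class(z: float, cutoffs: AnthroCutoffs = DEFAULT_ANTHRO_CUTOFFS) -> str:
    """Name the anthropometric class of a z-score (thresholds inclusive)."""
    if not math.isfinite(z):
        raise AssessmentError(f"non-finite z-score: {z}")
    if z >= cutoffs.obesity_z:
        return "obesity"
    if z >= cutoffs.overweight_z:
        return "overweight"
    if z <= cutoffs.severe_malnutrition_z:
        return "severe_malnutrition"
    if z <= cutoffs.moderate_malnutrition_z:
        return "moderate_malnutrition"
    if z <= cutoffs.mild_malnutrition_z:
        return "mild_malnutrition"
    return "normal"


def classify_anthropometric(
    z: float, cutoffs: AnthroCutoffs = DEFAULT_ANTHRO_CUTOFFS
) -> RiskCategory:
    """Risk category of an anthropometric z-score (class, then mapping)."""
    return cutoffs.mapping[anthropometric_class(z, cutoffs)]


# ---------------------------------------------------------------------------
# Food-security screen
# ---------------------------------------------------------------------------

_FS_AFFIRMATIVE = frozenset({"often true", "sometimes true"})
_FS_NEGATIVE = frozenset({"never true"})


def food_security_screen(
    q1: str, q2: str, *, both_affirmative_high: bool = False
) -> RiskCategory:
    """Rate the two-statement household food-insecurity screen.

    An affirmative ("often true" or "sometimes true") on either statement
    flags food-insecurity risk (moderate by default); both statements
    "never true" is low.  With ``both_affirmative_high`` set, affirmatives
    on both statements escalate to high.
    """
    answers = []
    for q in (q1, q2):
        label = str(q).strip().lower()
        if label not in _FS_AFFIRMATIVE | _FS_NEGATIVE:
            raise AssessmentError(f"unknown food-security response: {q!r}")
        answers.append(label in _FS_AFFIRMATIVE)
    n_affirm = sum(answers)
    if n_affirm == 0:
        return RiskCategory.LOW
    if n_affirm == 2 and both_affirmative_high:
        return RiskCategory.HIGH
    return RiskCategory.MODERATE


# ---------------------------------------------------------------------------
# Rule-table component rating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    """One row of a component rating guide.

    ``when`` maps an observation field to a condition: ``{"equals": v}``,
    ``{"min": x}`` (>=), ``{"max": x}`` (<=), or ``{"isin": [...]}``.  A
    rule matches when every condition holds; a field absent from the
    observation fails the rule.
    """

    rule_id: str
    rating: RiskCategory
    when: Mapping[str, Mapping[str, object]]

    def matches(self, observations: Mapping[str, object]) -> bool:
        for fld, cond in self.when.items():
            if fld not in observations:
                return False
            val = observations[fld]
            if "equals" in cond and val != cond["equals"]:
                return False
            if "min" in cond and not (val >= cond["min"]):  # type: ignore[operator]
                return False
            if "max" in cond and not (val <= cond["max"]):  # type: ignore[operator]
                return False
            if "isin" in cond and val not in cond["isin"]:  # type: ignore[operator]
                return False
        return True


@dataclass(frozen=True)
class RuleTable:
    """All rules for one component.  When several rules of different
    severity match an observation, the most severe fires (documented tie
    policy: a rating guide must never understate risk)."""

    component: str
    rules: tuple[Rule, ...]

    def rate(self, observations: Mapping[str, object]) -> tuple[RiskCategory, str]:
        matched = [r for r in self.rules if r.matches(observations)]
        if not matched:
            raise UnratableError(
                f"no {self.component!r} rule covers observation {dict(observations)!r}"
            )
        winner = max(matched, key=lambda r: r.rating.rank)
        return winner.rating, winner.rule_id


def _count_rules(component: str, fld: str, mod_at: int, high_at: int) -> RuleTable:
    return RuleTable(
        component,
        (
            Rule(f"{component}:none", RiskCategory.LOW, {fld: {"max": mod_at - 1}}),
            Rule(f"{component}:some", RiskCategory.MODERATE, {fld: {"min": mod_at}}),
            Rule(f"{component}:many", RiskCategory.HIGH, {fld: {"min": high_at}}),
        ),
    )


#: Default rating guides.  Medical history counts current conditions and
#: hospitalizations/surgeries/severe accidents; the 24-h recall and behavior
#: guides count red flags (recall: sodium / added sugar / saturated fat
#: excess and food-group shortfalls; behavior: screen time, short sleep,
#: pickiness, mealtime battles, low physical activity).  These defaults are
#: the package's own reconstruction — the published rating guide is an
#: unreproduced figure — and any component accepts a pre-assigned
#: ``rating`` field instead (pass-through).
DEFAULT_RULE_TABLES: Mapping[str, RuleTable] = {
    "medical_history": RuleTable(
        "medical_history",
        (
            Rule(
                "medical_history:clear",
                RiskCategory.LOW,
                {"conditions": {"max": 0}, "hospitalizations": {"max": 0}},
            ),
            Rule(
                "medical_history:condition",
                RiskCategory.MODERATE,
                {"conditions": {"min": 1}},
            ),
            Rule(
                "medical_history:hospitalized",
                RiskCategory.MODERATE,
                {"hospitalizations": {"min": 1}},
            ),
            Rule(
                "medical_history:multiple",
                RiskCategory.HIGH,
                {"conditions": {"min": 2}},
            ),
            Rule(
                "medical_history:repeat-hospitalized",
                RiskCategory.HIGH,
                {"hospitalizations": {"min": 2}},
            ),
        ),
    ),
    "recall_24h": _count_rules("recall_24h", "flags", mod_at=1, high_at=3),
    "behavior": _count_rules("behavior", "flags", mod_at=1, high_at=3),
}

_PASS_THROUGH = {
    comp: RuleTable(
        comp,
        tuple(
            Rule(f"{comp}:pass-through-{cat.value}", cat, {"rating": {"equals": cat.value}})
            for cat in RiskCategory
        ),
    )
    for comp in COMPONENTS
}


def rate_component(
    component: str,
    observations: Mapping[str, object],
    rules: Mapping[str, RuleTable] | None = None,
) -> tuple[RiskCategory, str]:
    """Rate one assessment component; returns (category, fired rule id).

    A ``rating`` field in the observations selects pass-through mode (the
    pre-assigned category is validated and returned); otherwise the
    component's rule table is consulted.  An observation covered by no rule
    raises :class:`UnratableError` rather than defaulting.
    """
    if component not in COMPONENTS:
        raise AssessmentError(f"unknown component {component!r}")
    if "rating" in observations:
        obs = {"rating": RiskCategory.from_label(str(observations["rating"])).value}
        return _PASS_THROUGH[component].rate(obs)
    tables = DEFAULT_RULE_TABLES if rules is None else rules
    if component not in tables:
        raise UnratableError(
            f"component {component!r} has no rule table and no pre-assigned rating"
        )
    return tables[component].rate(observations)


# ---------------------------------------------------------------------------
# Six-point aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssessmentProfile:
    """The six rated points for one child, in canonical component order."""

    child_id: str
    point_ratings: tuple[tuple[str, RiskCategory], ...]

    def __post_init__(self) -> None:
        names = tuple(name for name, _ in self.point_ratings)
        if names != COMPONENTS:
            raise AssessmentError(
                f"profile must rate exactly the six points {COMPONENTS}, got {names}"
            )

    @classmethod
    def from_ratings(
        cls, child_id: str, ratings: Sequence[RiskCategory] | Mapping[str, RiskCategory]
    ) -> "AssessmentProfile":
        if isinstance(ratings, Mapping):
            ordered = tuple((c, ratings[c]) for c in COMPONENTS)
        else:
            if len(ratings) != len(COMPONENTS):
                raise AssessmentError(
                    f"expected {len(COMPONENTS)} ratings, got {len(ratings)}"
                )
            ordered = tuple(zip(COMPONENTS, ratings))
        return cls(child_id=child_id, point_ratings=ordered)

    @property
    def ratings(self) -> tuple[RiskCategory, ...]:
        return tuple(cat for _, cat in self.point_ratings)


@dataclass(frozen=True)
class AssessmentResult:
    child_id: str
    overall: RiskCategory
    n_high: int
    n_moderate: int
    n_low: int

    def __post_init__(self) -> None:
        if self.n_high + self.n_moderate + self.n_low != len(COMPONENTS):
            raise AssessmentError("rating counts must sum to 6")


#: ``literal``: the classification rule read literally — only moderate-rated
#: points count toward the moderate threshold.  ``high_counts_as_moderate``:
#: a documented alternative in which high-rated points also count toward it
#: (a child with e.g. 2 high + 2 moderate is moderate instead of low).
AGGREGATION_POLICIES = ("literal", "high_counts_as_moderate")


def aggregate_assessment(
    profile: AssessmentProfile, policy: str = "literal"
) -> AssessmentResult:
    """Overall risk from the six point ratings.

    High if 3 or more points are rated high; otherwise moderate if 3 or
    more are rated moderate (under ``high_counts_as_moderate``, high points
    count toward that threshold too); otherwise low.
    """
    if policy not in AGGREGATION_POLICIES:
        raise AssessmentError(f"unknown aggregation policy {policy!r}")
    cats = profile.ratings
    n_high = sum(c is RiskCategory.HIGH for c in cats)
    n_mod = sum(c is RiskCategory.MODERATE for c in cats)
    n_low = len(cats) - n_high - n_mod
    if n_high >= 3:
        overall = RiskCategory.HIGH
    elif (n_mod if policy == "literal" else n_mod + n_high) >= 3:
        overall = RiskCategory.MODERATE
    else:
        overall = RiskCategory.LOW
    return AssessmentResult(
        child_id=profile.child_id,
        overall=overall,
        n_high=n_high,
        n_moderate=n_mod,
        n_low=n_low,
    )
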