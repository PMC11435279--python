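"""Synthetic parent-child dyad cohorts with controlled misclassification.

The validation study's raw data are not shareable, so this module generates
cohorts that stand in for them: each child carries a latent at-risk state;
the screening arm draws a target risk category from the configured
sensitivity/specificity and then realizes it as a concrete item-response
vector whose total score lands in that category's band; the assessment arm
draws its target category the same way and realizes it as six component
ratings that aggregate to the target under the classification rule.
Misclassification is thus modeled at the category level but materialized as
real pipeline inputs, so generated files exercise scoring and aggregation
end to end rather than bypassing them.

Default parameters are the study's own margins: 39 dyads, 12/39 at risk by
the reference assessment, screening sensitivity 91.67% and specificity
81.48%, a perfect reference arm, and no high-risk children (the cohort
contained only low- and moderate-risk ratings).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assessment import (
    AGGREGATION_POLICIES,
    COMPONENTS,
    AssessmentProfile,
    aggregate_assessment,
)
from .core import CreceError, RiskCategory
from .instrument import InstrumentDefinition, default_instrument, score_screening
from .validity import ContingencyTable, diagnostic_accuracy

__all__ = [
    "SimulationError",
    "SimulationParams",
    "DyadCohort",
    "simulate_cohort",
    "sweep_small_sample",
]


class SimulationError(CreceError):
    """Invalid or unsatisfiable simulation parameters."""


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-generation parameters.

    prevalence is the probability a child's latent state is at-risk;
    screen_* and assessment_* are the probabilities that the corresponding
    arm calls an at-risk child positive (sensitivity) or a not-at-risk
    child negative (specificity); high_risk_fraction is the probability a
    positive call lands in the high (vs moderate) category.
    """

    n_dyads: int = 39
    prevalence: float = 12 / 39
    screen_sensitivity: float = 11 / 12
    screen_specificity: float = 22 / 27
    assessment_sensitivity: float = 1.0
    assessment_specificity: float = 1.0
    high_risk_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise SimulationError("n_dyads must be >= 1")
        for name in (
            "prevalence",
            "screen_sensitivity",
            "screen_specificity",
            "assessment_sensitivity",
            "assessment_specificity",
            "high_risk_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1], got {v}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationParams":
        return cls(**json.loads(text))


def _draw_category(
    rng: np.random.Generator, at_risk: bool, sens: float, spec: float, high_frac: float
) -> RiskCategory:
    positive = rng.random() < (sens if at_risk else 1.0 - spec)
    if not positive:
        return RiskCategory.LOW
    return RiskCategory.HIGH if rng.random() < high_frac else RiskCategory.MODERATE


def _sample_responses_in_band(
    rng: np.random.Generator,
    instrument: InstrumentDefinition,
    category: RiskCategory,
) -> dict[str, str]:
    """A response vector whose total score falls in the category's band.

    Draws a target total uniformly from the band, then walks the items
    assigning each a score drawn uniformly from the range that keeps the
    remaining total reachable (a random composition of the target)."""
    lo, hi = instrument.cutoffs.band(category)
    hi = min(hi, instrument.max_score)
    if lo > hi:
        raise SimulationError(
            f"score band for {category.value!r} is empty under this instrument"
        )
    target = int(rng.integers(lo, hi + 1))
    suffix_max = np.cumsum([it.max_score for it in instrument.items][::-1])[::-1]
    responses: dict[str, str] = {}
    remaining = target
    for i, item in enumerate(instrument.items):
        after = int(suffix_max[i]) - item.max_score
        s_min = max(0, remaining - after)
        s_max = min(item.max_score, remaining)
        score = int(rng.integers(s_min, s_max + 1))
        by_score = {v: k for k, v in item.score_map.items()}
        responses[item.item_id] = by_score[score]
        remaining -= score
    assert remaining == 0
    return responses


# Valid (n_high, n_moderate) count pairs for each overall category, per
# aggregation policy; the sampled profile is a uniform draw over these
# pairs followed by a random assignment of counts to components.
def _valid_count_pairs(policy: str) -> dict[RiskCategory, list[tuple[int, int]]]:
    out: dict[RiskCategory, list[tuple[int, int]]] = {c: [] for c in RiskCategory}
    for nh in range(7):
        for nm in range(7 - nh):
            if nh >= 3:
                cat = RiskCategory.HIGH
            elif (nm if policy == "literal" else nm + nh) >= 3:
                cat = RiskCategory.MODERATE
            else:
                cat = RiskCategory.LOW
            out[cat].append((nh, nm))
    return out


def _sample_ratings_for_category(
    rng: np.random.Generator,
    category: RiskCategory,
    pairs: dict[RiskCategory, list[tuple[int, int]]],
) -> tuple[RiskCategory, ...]:
    options = pairs[category]
    nh, nm = options[int(rng.integers(len(options)))]
    cats = (
        [RiskCategory.HIGH] * nh
        + [RiskCategory.MODERATE] * nm
        + [RiskCategory.LOW] * (6 - nh - nm)
    )
    perm = rng.permutation(6)
    return tuple(cats[perm[i]] for i in range(6))


@dataclass(frozen=True)
class DyadCohort:
    """A generated cohort: one row per dyad, plus its parameters.

    ``data`` columns: child_id, latent_state, one column per instrument
    item, screening_total, screening_category, one ``rating_<component>``
    column per assessment point, assessment_category.
    """

    data: pd.DataFrame
    params: SimulationParams
    instrument_name: str
    policy: str

    def responses_frame(self) -> pd.DataFrame:
        """The screening-arm CSV payload (respondent_id + item columns)."""
        item_cols = [
            c
            for c in self.data.columns
            if c
            not in {"child_id", "latent_state", "screening_total", "screening_category", "assessment_category"}
            and not c.startswith("rating_")
        ]
        out = self.data[["child_id"] + item_cols].rename(
            columns={"child_id": "respondent_id"}
        )
        return out

    def assessment_frame(self) -> pd.DataFrame:
        """The assessment-arm CSV payload (child_id + pre-rated components)."""
        cols = ["child_id"] + [f"rating_{c}" for c in COMPONENTS]
        return self.data[cols].copy()

    def pairs(self) -> list[tuple[RiskCategory, RiskCategory]]:
        return [
            (RiskCategory(s), RiskCategory(r))
            for s, r in zip(
                self.data["screening_category"], self.data["assessment_category"]
            )
        ]

    def to_files(self, outdir) -> dict[str, Path]:
        """Write screening responses, assessment components and the params
        sidecar (seed included) as plain CSV/JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "responses": outdir / "screening_responses.csv",
            "assessment": outdir / "assessment_components.csv",
            "params": outdir / "simulation_params.json",
        }
        self.responses_frame().to_csv(paths["responses"], index=False)
        self.assessment_frame().to_csv(paths["assessment"], index=False)
        paths["params"].write_text(
            json.dumps(
                {
                    "params": dataclasses.asdict(self.params),
                    "instrument": self.instrument_name,
                    "policy": self.policy,
                },
                indent=2,
            )
        )
        return paths


def simulate_cohort(
    params: SimulationParams,
    instrument: InstrumentDefinition | None = None,
    policy: str = "literal",
) -> DyadCohort:
    """Generate a dyad cohort under the given misclassification parameters.

    Every record satisfies the pipeline's own invariants by construction
    and by re-validation: the screening category equals the instrument's
    scoring of the generated responses, and the assessment category equals
    the aggregation of the generated component ratings.  Regeneration with
    the same seed is bit-identical.
    """
    if policy not in AGGREGATION_POLICIES:
        raise SimulationError(f"unknown aggregation policy {policy!r}")
    inst = instrument if instrument is not None else default_instrument()
    rng = np.random.default_rng(params.seed)
    pairs = _valid_count_pairs(policy)
    width = len(str(params.n_dyads))
    rows = []
    for i in range(params.n_dyads):
        at_risk = bool(rng.random() < params.prevalence)
        screen_cat = _draw_category(
            rng,
            at_risk,
            params.screen_sensitivity,
            params.screen_specificity,
            params.high_risk_fraction,
        )
        responses = _sample_responses_in_band(rng, inst, screen_cat)
        scored = score_screening(responses, inst, f"d{i:0{width}d}")
        if scored.category is not screen_cat:  # pragma: no cover - construction guarantee
            raise SimulationError("generated responses missed the target band")
        assess_cat = _draw_category(
            rng,
            at_risk,
            params.assessment_sensitivity,
            params.assessment_specificity,
            params.high_risk_fraction,
        )
        ratings = _sample_ratings_for_category(rng, assess_cat, pairs)
        profile = AssessmentProfile.from_ratings(f"d{i:0{width}d}", ratings)
        agg = aggregate_assessment(profile, policy)
        if agg.overall is not assess_cat:  # pragma: no cover - construction guarantee
            raise SimulationError("generated ratings missed the target category")
        row: dict[str, object] = {
            "child_id": f"d{i:0{width}d}",
            "latent_state": "at_risk" if at_risk else "not_at_risk",
        }
        row.update(responses)
        row["screening_total"] = scored.total_score
        row["screening_category"] = screen_cat.value
        row.update({f"rating_{c}": r.value for c, r in zip(COMPONENTS, ratings)})
        row["assessment_category"] = assess_cat.value
        rows.append(row)
    return DyadCohort(
        data=pd.DataFrame(rows),
        params=params,
        instrument_name=inst.name,
        policy=policy,
    )


def sweep_small_sample(
    cells: Sequence[tuple[int, int]],
    *,
    true_sensitivity: float = 11 / 12,
    true_specificity: float = 22 / 27,
    n_replicates: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sampling distribution of estimated sensitivity/specificity at fixed
    reference margins — the small-sample caution quantified.

    ``cells`` is a sequence of (n_total, n_reference_positive); for each
    cell, each replicate draws TP ~ Binomial(n_positive, sensitivity) and
    TN ~ Binomial(n_negative, specificity), builds the 2x2 table, and runs
    it through the accuracy computation.  Returns one row per cell with the
    mean and 2.5/97.5 percentiles of the estimates in percent.
    """
    if len(cells) == 0:
        raise SimulationError("empty sweep grid")
    rng = np.random.default_rng(seed)
    rows = []
    for n_total, n_pos in cells:
        if not (0 < n_pos < n_total):
            raise SimulationError(
                f"cell ({n_total}, {n_pos}) needs 0 < n_positive < n_total"
            )
        n_neg = n_total - n_pos
        tps = rng.binomial(n_pos, true_sensitivity, size=n_replicates)
        tns = rng.binomial(n_neg, true_specificity, size=n_replicates)
        sens = np.empty(n_replicates)
        spec = np.empty(n_replicates)
        for j in range(n_replicates):
            table = ContingencyTable.from_cells(
                tp=int(tps[j]), fn=n_pos - int(tps[j]), tn=int(tns[j]), fp=n_neg - int(tns[j])
            )
            rep = diagnostic_accuracy(table)
            sens[j] = rep.sensitivity.value
            spec[j] = rep.specificity.value
        rows.append(
            {
                "n_total": n_total,
                "n_positive": n_pos,
                "n_replicates": n_replicates,
                "sensitivity_mean": float(sens.mean()),
                "sensitivity_p2.5": float(np.percentile(sens, 2.5)),
                "sensitivity_p97.5": float(np.percentile(sens, 97.5)),
                "specificity_mean": float(spec.mean()),
                "specificity_p2.5": float(np.percentile(spec, 2.5)),
                "specificity_p97.5": float(np.percentile(spec, 97.5)),
            }
        )
    return pd.DataFrame(rows)
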