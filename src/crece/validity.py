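"""Content validity (CVI) and criterion validity (diagnostic accuracy).

Content validity: each instrument item is rated 1-4 by an expert panel on
relevancy, clarity and simplicity; the item CVI per dimension is the
proportion of experts rating 3 or 4, the combined CVI is the mean across
the three dimensions, and items are accepted (combined >= 0.80), revised
(0.70-0.79) or eliminated (< 0.70).

Criterion validity: paired screening and reference-assessment risk
categories are cross-classified (up to 3x3), collapsed to a binary
positive/negative axis (default: low -> negative, moderate or high ->
positive), and summarized as sensitivity, specificity, PPV and NPV with
Wald standard errors, Clopper-Pearson and Wald confidence intervals, and a
chi-square test of independence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .core import CATEGORY_ORDER, CreceError, RiskCategory

__all__ = [
    "ValidityError",
    "CVIThresholds",
    "compute_cvi",
    "DEFAULT_COLLAPSE",
    "ContingencyTable",
    "build_contingency",
    "MetricEstimate",
    "AccuracyReport",
    "diagnostic_accuracy",
    "chi_square_independence",
]


class ValidityError(CreceError):
    """Invalid validity-analysis input."""


# ---------------------------------------------------------------------------
# Content validity index
# ---------------------------------------------------------------------------

DIMENSIONS = ("relevancy", "clarity", "simplicity")


@dataclass(frozen=True)
class CVIThresholds:
    """Accept/revise/eliminate bands on the combined CVI.

    Accept at >= ``accept_min``; revise at >= ``revise_min`` but below
    ``accept_min``; eliminate below ``revise_min``.  The published bands
    (accept >= 0.8, revise 0.7-0.79, eliminate < 0.69) leave (0.69, 0.70)
    unaddressed; the default closes the gap downward (eliminate iff
    combined < 0.70).
    """

    accept_min: float = 0.80
    revise_min: float = 0.70

    def decide(self, combined: float) -> str:
        if combined >= self.accept_min:
            return "accept"
        if combined >= self.revise_min:
            return "revise"
        return "eliminate"


def compute_cvi(
    ratings: pd.DataFrame,
    thresholds: CVIThresholds = CVIThresholds(),
) -> pd.DataFrame:
    """Item-level CVI report from a long-form expert rating table.

    ``ratings`` needs columns ``item_id, expert_id, dimension, rating``
    with ratings on the 1-4 ordinal scale and dimensions among relevancy /
    clarity / simplicity.  Returns one row per item: ``cvi_<dimension>``
    columns, ``combined_cvi`` (mean of the three dimension CVIs) and
    ``decision``.

    Requires at least 2 experts overall and at least one rating per item
    per dimension; explicitly-missing cells (NaN rating) are dropped before
    the proportion is formed.
    """
    required = {"item_id", "expert_id", "dimension", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValidityError(f"rating table missing columns: {sorted(missing)}")
    tab = ratings.dropna(subset=["rating"]).copy()
    if tab.empty:
        raise ValidityError("empty expert panel")
    if tab["expert_id"].nunique() < 2:
        raise ValidityError("CVI needs at least 2 experts")
    bad_dim = set(tab["dimension"]) - set(DIMENSIONS)
    if bad_dim:
        raise ValidityError(f"unknown dimensions: {sorted(bad_dim)}")
    vals = tab["rating"].astype(float)
    if not ((vals >= 1) & (vals <= 4) & (vals == vals.round())).all():
        raise ValidityError("ratings must be integers in 1..4")
    tab["relevant"] = vals >= 3

    rows = []
    for item_id, grp in tab.groupby("item_id", sort=False):
        row: dict[str, object] = {"item_id": item_id}
        per_dim = []
        for dim in DIMENSIONS:
            sub = grp[grp["dimension"] == dim]
            if sub.empty:
                raise ValidityError(f"item {item_id!r} has no {dim} ratings")
            cvi = float(sub["relevant"].mean())
            row[f"cvi_{dim}"] = cvi
            per_dim.append(cvi)
        combined = float(np.mean(per_dim))
        row["combined_cvi"] = combined
        row["decision"] = thresholds.decide(combined)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contingency table
# ---------------------------------------------------------------------------

#: Default collapse of the three-level categories to the binary screen axis:
#: low is the negative screen, moderate and high are "at risk" (positive).
DEFAULT_COLLAPSE: Mapping[RiskCategory, str] = {
    RiskCategory.LOW: "negative",
    RiskCategory.MODERATE: "positive",
    RiskCategory.HIGH: "positive",
}


@dataclass(frozen=True)
class ContingencyTable:
    """Screening x reference cross-classification with its binary collapse.

    ``counts`` is the full 3x3 table (rows: screening category, columns:
    reference category, both in low/moderate/high order); the reference is
    the truth axis, so TP/FN are defined by reference-positive children.
    """

    counts: pd.DataFrame
    collapse_rule: Mapping[RiskCategory, str] = field(
        default_factory=lambda: dict(DEFAULT_COLLAPSE)
    )

    def __post_init__(self) -> None:
        labels = [c.value for c in CATEGORY_ORDER]
        if list(self.counts.index) != labels or list(self.counts.columns) != labels:
            raise ValidityError("counts must be a 3x3 frame in low/moderate/high order")
        if (self.counts.to_numpy() < 0).any():
            raise ValidityError("negative cell count")
        if set(self.collapse_rule) != set(CATEGORY_ORDER) or not set(
            self.collapse_rule.values()
        ) <= {"negative", "positive"}:
            raise ValidityError("collapse rule must map all three categories to negative/positive")

    def _cell(self, screen_sign: str, ref_sign: str) -> int:
        total = 0
        for s_cat in CATEGORY_ORDER:
            for r_cat in CATEGORY_ORDER:
                if (
                    self.collapse_rule[s_cat] == screen_sign
                    and self.collapse_rule[r_cat] == ref_sign
                ):
                    total += int(self.counts.loc[s_cat.value, r_cat.value])
        return total

    @property
    def tp(self) -> int:
        return self._cell("positive", "positive")

    @property
    def fp(self) -> int:
        return self._cell("positive", "negative")

    @property
    def fn(self) -> int:
        return self._cell("negative", "positive")

    @property
    def tn(self) -> int:
        return self._cell("negative", "negative")

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def collapsed(self) -> pd.DataFrame:
        """2x2 frame: rows screen positive/negative, columns reference."""
        return pd.DataFrame(
            [[self.tp, self.fp], [self.fn, self.tn]],
            index=pd.Index(["positive", "negative"], name="screening"),
            columns=pd.Index(["positive", "negative"], name="reference"),
        )

    @classmethod
    def from_cells(
        cls,
        *,
        tp: int,
        fp: int,
        fn: int,
        tn: int,
        collapse_rule: Mapping[RiskCategory, str] | None = None,
    ) -> "ContingencyTable":
        """Build a table directly from collapsed 2x2 cells (positives are
        placed in the moderate row/column, negatives in low)."""
        labels = [c.value for c in CATEGORY_ORDER]
        counts = pd.DataFrame(0, index=labels, columns=labels)
        counts.loc["low", "low"] = tn
        counts.loc["low", "moderate"] = fn
        counts.loc["moderate", "low"] = fp
        counts.loc["moderate", "moderate"] = tp
        return cls(counts, dict(collapse_rule or DEFAULT_COLLAPSE))


def build_contingency(
    pairs: Iterable[tuple[RiskCategory | str, RiskCategory | str]],
    collapse_rule: Mapping[RiskCategory, str] | None = None,
) -> ContingencyTable:
    """Cross-classify (screening, reference) category pairs.

    The first element of each pair is the screening category, the second
    the reference-standard category.
    """
    labels = [c.value for c in CATEGORY_ORDER]
    counts = pd.DataFrame(0, index=labels, columns=labels)
    n = 0
    for screen, ref in pairs:
        s = screen if isinstance(screen, RiskCategory) else RiskCategory.from_label(screen)
        r = ref if isinstance(ref, RiskCategory) else RiskCategory.from_label(ref)
        counts.loc[s.value, r.value] += 1
        n += 1
    if n == 0:
        raise ValidityError("no category pairs")
    return ContingencyTable(counts, dict(collapse_rule or DEFAULT_COLLAPSE))


# ---------------------------------------------------------------------------
# Diagnostic accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricEstimate:
    """One proportion-based accuracy metric, on the percentage scale.

    ``value`` is NaN (and ``defined`` False) when the denominator is zero —
    an undefined metric is reported as undefined, never as 0.
    """

    name: str
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float:
        if not self.defined:
            return math.nan
        return 100.0 * self.numerator / self.denominator

    @property
    def rounded(self) -> float:
        """Integer-rounded companion (half away from zero is irrelevant for
        the values produced here; banker's rounding of `round` avoided)."""
        return math.floor(self.value + 0.5) if self.defined else math.nan

    @property
    def se(self) -> float:
        """Wald standard error in percentage points."""
        if not self.defined:
            return math.nan
        p = self.numerator / self.denominator
        return 100.0 * math.sqrt(p * (1 - p) / self.denominator)

    def interval(self, method: str = "wald", alpha: float = 0.05) -> tuple[float, float]:
        """Confidence interval in percent: Wald or exact Clopper-Pearson."""
        if not self.defined:
            return (math.nan, math.nan)
        sm_method = {"wald": "normal", "clopper-pearson": "beta"}[method]
        lo, hi = proportion_confint(
            self.numerator, self.denominator, alpha=alpha, method=sm_method
        )
        return (100.0 * float(lo), 100.0 * float(hi))


@dataclass(frozen=True)
class AccuracyReport:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    table: ContingencyTable

    @property
    def metrics(self) -> tuple[MetricEstimate, ...]:
        return (self.sensitivity, self.specificity, self.ppv, self.npv)

    def to_dict(self) -> dict:
        out: dict[str, object] = {
            "cells": {
                "tp": self.table.tp,
                "fp": self.table.fp,
                "fn": self.table.fn,
                "tn": self.table.tn,
            },
            "n": self.table.n,
        }
        for m in self.metrics:
            cp = m.interval("clopper-pearson")
            wald = m.interval("wald")
            out[m.name] = {
                "percent": None if not m.defined else m.value,
                "rounded_percent": None if not m.defined else m.rounded,
                "se_percent": None if not m.defined else m.se,
                "wald_ci": None if not m.defined else list(wald),
                "clopper_pearson_ci": None if not m.defined else list(cp),
                "numerator": m.numerator,
                "denominator": m.denominator,
            }
        return out


def diagnostic_accuracy(table: ContingencyTable) -> AccuracyReport:
    """Sensitivity, specificity, PPV and NPV of the collapsed 2x2 table.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), each reported in percent with a Wald SE and both Wald
    and Clopper-Pearson intervals.  A metric with a zero denominator is
    flagged undefined.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    return AccuracyReport(
        sensitivity=MetricEstimate("sensitivity", tp, tp + fn),
        specificity=MetricEstimate("specificity", tn, tn + fp),
        ppv=MetricEstimate("ppv", tp, tp + fp),
        npv=MetricEstimate("npv", tn, tn + fn),
        table=table,
    )


def chi_square_independence(
    table: ContingencyTable, correction: str = "none"
) -> tuple[float, float]:
    """Chi-square test of independence on the collapsed 2x2 table (1 df).

    ``correction`` is ``"none"`` (default) or ``"yates"`` for the
    continuity correction.  A warning is emitted when any expected cell
    count is below 5 (the usual small-sample caveat for the chi-square
    approximation); degenerate margins are an error.
    """
    if correction not in ("none", "yates"):
        raise ValidityError(f"unknown correction {correction!r}")
    obs = np.array([[table.tp, table.fp], [table.fn, table.tn]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidityError("degenerate margin: a row or column of the 2x2 table is empty")
    stat, p, _, expected = stats.chi2_contingency(obs, correction=(correction == "yates"))
    if (expected < 5).any():
        warnings.warn(
            "expected cell count below 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    return float(stat), float(p)
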