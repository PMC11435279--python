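"""Screening-instrument definition, scoring, and risk-category banding.

The screening tool is a parent-completed questionnaire: 22 items in four
sections (food security, food habits, food intake, food behavior), each
item mapping an ordinal response to a non-negative point value with higher
points meaning higher malnutrition risk.  Total scores 0-48 are banded into
low (0-15), moderate (16-29) and high (30-48) risk.  Because the original
per-item point values are unpublished, scoring is fully config-driven and
the bundled default configuration is an explicit reconstruction of the
instrument's shape.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .core import CreceError, RiskCategory

__all__ = [
    "InstrumentError",
    "ScoringError",
    "ItemDefinition",
    "ScoreCutoffs",
    "InstrumentDefinition",
    "ScreeningResult",
    "load_instrument",
    "default_instrument",
    "categorize_score",
    "score_screening",
    "score_responses_table",
]


class InstrumentError(CreceError):
    """Structurally invalid instrument configuration."""


class ScoringError(CreceError):
    """A response vector that cannot be scored under the instrument."""


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item: ordered response levels and their point map."""

    item_id: str
    section: str
    response_levels: tuple[str, ...]
    score_map: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.response_levels) < 2:
            raise InstrumentError(
                f"item {self.item_id!r}: needs at least 2 response levels"
            )
        if set(self.score_map) != set(self.response_levels):
            raise InstrumentError(
                f"item {self.item_id!r}: score map does not cover response levels"
            )
        scores = [self.score_map[lvl] for lvl in self.response_levels]
        if any((not isinstance(s, int)) or s < 0 for s in scores):
            raise InstrumentError(
                f"item {self.item_id!r}: scores must be integers >= 0"
            )
        if min(scores) != 0:
            raise InstrumentError(
                f"item {self.item_id!r}: minimum mapped score must be 0"
            )

    @property
    def max_score(self) -> int:
        return max(self.score_map.values())


@dataclass(frozen=True)
class ScoreCutoffs:
    """Closed upper bounds of the low and moderate score bands.

    low: 0..low_max, moderate: low_max+1..moderate_max,
    high: moderate_max+1..instrument_max.
    """

    low_max: int
    moderate_max: int
    instrument_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.low_max < self.moderate_max < self.instrument_max):
            raise InstrumentError(
                "cutoffs must satisfy 0 <= low_max < moderate_max < instrument_max, "
                f"got ({self.low_max}, {self.moderate_max}, {self.instrument_max})"
            )

    def band(self, category: RiskCategory) -> tuple[int, int]:
        """Inclusive (lo, hi) total-score range of a category."""
        if category is RiskCategory.LOW:
            return (0, self.low_max)
        if category is RiskCategory.MODERATE:
            return (self.low_max + 1, self.moderate_max)
        return (self.moderate_max + 1, self.instrument_max)


@dataclass(frozen=True)
class InstrumentDefinition:
    """A validated instrument: ordered items, section layout, cutoffs."""

    items: tuple[ItemDefinition, ...]
    sections: tuple[tuple[str, int], ...]
    cutoffs: ScoreCutoffs
    name: str = "unnamed"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InstrumentError(f"duplicate item ids: {dupes}")
        declared = {name: count for name, count in self.sections}
        if len(declared) != len(self.sections):
            raise InstrumentError("duplicate section names")
        actual: dict[str, int] = {}
        for it in self.items:
            if it.section not in declared:
                raise InstrumentError(
                    f"item {it.item_id!r} references undeclared section {it.section!r}"
                )
            actual[it.section] = actual.get(it.section, 0) + 1
        if actual != declared:
            raise InstrumentError(
                f"section item counts {actual} do not match declared {declared}"
            )
        if len(self.items) != sum(declared.values()):
            raise InstrumentError("item count does not equal sum of section counts")
        if self.max_score != self.cutoffs.instrument_max:
            raise InstrumentError(
                f"sum of item maxima ({self.max_score}) does not equal "
                f"cutoffs.instrument_max ({self.cutoffs.instrument_max})"
            )

    @property
    def max_score(self) -> int:
        return sum(it.max_score for it in self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise InstrumentError(f"no item {item_id!r} in instrument {self.name!r}")


@dataclass(frozen=True)
class ScreeningResult:
    """Scored questionnaire for one respondent."""

    respondent_id: str
    total_score: int
    section_scores: Mapping[str, int]
    category: RiskCategory
    imputed_items: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.total_score != sum(self.section_scores.values()):
            raise CreceError("section scores do not sum to the total score")


def _read_config(source) -> Mapping:
    if isinstance(source, Mapping):
        return source
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_instrument(source) -> InstrumentDefinition:
    """Build a validated :class:`InstrumentDefinition` from a config.

    ``source`` may be a mapping, or a path to a YAML/JSON file with keys
    ``sections`` (list of ``{name, items}``), ``items`` (list of
    ``{id, section, scores}``), and ``cutoffs``
    (``low_max``/``moderate_max``/``instrument_max``).

    Raises
    ------
    InstrumentError
        On any structural inconsistency: missing keys, duplicate item ids,
        section counts that do not match the item list, or cutoffs whose
        ``instrument_max`` differs from the sum of per-item maxima.
    """
    cfg = _read_config(source)
    try:
        sections = tuple(
            (str(s["name"]), int(s["items"])) for s in cfg["sections"]
        )
        cut = cfg["cutoffs"]
        cutoffs = ScoreCutoffs(
            low_max=int(cut["low_max"]),
            moderate_max=int(cut["moderate_max"]),
            instrument_max=int(cut["instrument_max"]),
        )
        raw_items = cfg["items"]
    except (KeyError, TypeError) as exc:
        raise InstrumentError(f"malformed instrument config: {exc!r}") from exc
    items = []
    for raw in raw_items:
        try:
            scores = raw["scores"]
            item = ItemDefinition(
                item_id=str(raw["id"]),
                section=str(raw["section"]),
                response_levels=tuple(str(k) for k in scores),
                score_map={str(k): int(v) for k, v in scores.items()},
            )
        except (KeyError, TypeError) as exc:
            raise InstrumentError(f"malformed item entry {raw!r}") from exc
        items.append(item)
    return InstrumentDefinition(
        items=tuple(items),
        sections=sections,
        cutoffs=cutoffs,
        name=str(cfg.get("name", "unnamed")),
    )


def default_instrument() -> InstrumentDefinition:
    """The bundled 22-item reconstruction (max score 48, cutoffs 15/29/48)."""
    ref = resources.files("crece.data").joinpath("default_instrument.yaml")
    return load_instrument(yaml.safe_load(ref.read_text()))


def categorize_score(total_score: int, cutoffs: ScoreCutoffs) -> RiskCategory:
    """Band a total score: low iff <= low_max, moderate iff <= moderate_max,
    else high.  Scores outside [0, instrument_max] are rejected."""
    if not (0 <= total_score <= cutoffs.instrument_max):
        raise ScoringError(
            f"total score {total_score} outside [0, {cutoffs.instrument_max}]"
        )
    if total_score <= cutoffs.low_max:
        return RiskCategory.LOW
    if total_score <= cutoffs.moderate_max:
        return RiskCategory.MODERATE
    return RiskCategory.HIGH


def score_screening(
    responses: Mapping[str, str],
    instrument: InstrumentDefinition,
    respondent_id: str = "",
    *,
    allow_missing: bool = False,
) -> ScreeningResult:
    """Score one respondent's answers.

    ``responses`` maps item_id -> response label.  Every instrument item
    must be answered; a missing answer is a :class:`ScoringError` unless
    ``allow_missing`` is set, in which case it scores 0 and the item is
    flagged in ``imputed_items`` (with a warning).  Unknown item ids and
    unknown response labels are always errors.
    """
    unknown = set(responses) - set(instrument.item_ids)
    if unknown:
        raise ScoringError(f"responses for unknown items: {sorted(unknown)}")
    section_scores = {name: 0 for name, _ in instrument.sections}
    imputed: list[str] = []
    for item in instrument.items:
        if item.item_id not in responses or pd.isna(responses[item.item_id]):
            if not allow_missing:
                raise ScoringError(
                    f"missing response for item {item.item_id!r}"
                    + (f" (respondent {respondent_id!r})" if respondent_id else "")
                )
            imputed.append(item.item_id)
            continue
        label = str(responses[item.item_id])
        if label not in item.score_map:
            raise ScoringError(
                f"unknown response label {label!r} for item {item.item_id!r}"
            )
        section_scores[item.section] += item.score_map[label]
    if imputed:
        warnings.warn(
            f"respondent {respondent_id!r}: scored {len(imputed)} missing "
            f"item(s) as 0: {imputed}",
            stacklevel=2,
        )
    total = sum(section_scores.values())
    return ScreeningResult(
        respondent_id=respondent_id,
        total_score=total,
        section_scores=section_scores,
        category=categorize_score(total, instrument.cutoffs),
        imputed_items=tuple(imputed),
    )


def score_responses_table(
    responses: pd.DataFrame,
    instrument: InstrumentDefinition,
    *,
    id_column: str = "respondent_id",
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Score a table with one row per respondent and one column per item.

    Returns a frame with the id, per-section scores, the total, and the
    risk category.  Scoring errors are re-raised with the offending row
    number (1-based, excluding the header) attached.
    """
    if responses.empty:
        raise ScoringError("no records to score")
    if id_column not in responses.columns:
        raise ScoringError(f"missing id column {id_column!r}")
    rows = []
    for pos, (_, row) in enumerate(responses.iterrows(), start=1):
        rid = str(row[id_column])
        answer_map = {
            c: row[c] for c in responses.columns
            if c != id_column and c in instrument.item_ids
        }
        try:
            res = score_screening(
                answer_map, instrument, rid, allow_missing=allow_missing
            )
        except ScoringError as exc:
            raise ScoringError(f"row {pos} (id {rid!r}): {exc}") from exc
        out = {id_column: rid}
        out.update({f"score_{k}": v for k, v in res.section_scores.items()})
        out["total_score"] = res.total_score
        out["category"] = res.category.value
        rows.append(out)
    return pd.DataFrame(rows)
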