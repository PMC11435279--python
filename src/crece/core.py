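"""Shared core types for the screening and assessment pipelines.

The screening instrument and the reference-standard assessment both report
malnutrition risk on the same ordered three-level scale, so the category
type lives here rather than in either module.
"""

from __future__ import annotations

import enum
import functools


class CreceError(Exception):
    """Base class for all package errors."""


@functools.total_ordering
class RiskCategory(enum.Enum):
    """Ordered malnutrition-risk category: low < moderate < high."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return _RANK[self]

    def __lt__(self, other: object) -> bool:
        if not isinstance(other, RiskCategory):
            return NotImplemented
        return self.rank < other.rank

    @classmethod
    def from_label(cls, label: str) -> "RiskCategory":
        """Parse a category label case-insensitively.

        Accepts the canonical names plus common file spellings
        (``"Low risk"`` etc.).
        """
        key = str(label).strip().lower()
        key = key.removesuffix(" risk")
        try:
            return cls(key)
        except ValueError:
            raise CreceError(f"unknown risk category label: {label!r}") from None


_RANK = {RiskCategory.LOW: 0, RiskCategory.MODERATE: 1, RiskCategory.HIGH: 2}

#: Categories in ascending risk order.
CATEGORY_ORDER = (RiskCategory.LOW, RiskCategory.MODERATE, RiskCategory.HIGH)
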