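"""Parsing legacy full-study XML records into structured outcome entries.

A registry full-study record is an XML document whose ``primary_outcome``,
``secondary_outcome`` and ``other_outcome`` elements each carry ``measure``,
``description`` and ``time_frame`` children. Parsing extracts one entry per
outcome element, preserving document order; all text normalization happens
downstream — the raw measure text is kept verbatim apart from trimming the
ends.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional

logger = logging.getLogger(__name__)

NCT_PATTERN = re.compile(r"^NCT\d{8}$")

#: XML element name → outcome category.
_CATEGORY_ELEMENTS = {
    "primary_outcome": "primary",
    "secondary_outcome": "secondary",
    "other_outcome": "other",
}

CATEGORIES = ("primary", "secondary", "other")


class RecordParseError(ValueError):
    """Raised when a trial's XML payload cannot be parsed."""

    def __init__(self, nct_id: str, cause: Exception):
        super().__init__(f"malformed XML for {nct_id}: {cause}")
        self.nct_id = nct_id


def validate_nct(nct_id: str, *, lenient: bool = False) -> bool:
    """True iff ``nct_id`` is 'NCT' followed by exactly eight digits.

    Lenient mode uppercases first, accepting e.g. ``nct01234567``.
    """
    if lenient:
        nct_id = nct_id.upper()
    return bool(NCT_PATTERN.match(nct_id))


@dataclass(frozen=True)
class OutcomeEntry:
    """One outcome measure as registered for one trial."""

    nct_id: str
    category: str  # primary | secondary | other
    measure: str  # raw text, end-trimmed only
    description: Optional[str] = None
    time_frame: Optional[str] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown outcome category: {self.category!r}")
        if not self.measure.strip():
            raise ValueError("measure must be non-empty")


@dataclass
class TrialRecord:
    """One registered study: identifier plus its parsed outcome entries."""

    nct_id: str
    outcomes: list[OutcomeEntry] = field(default_factory=list)

    @property
    def has_outcomes(self) -> bool:
        return bool(self.outcomes)


def _local_name(tag: str) -> str:
    # legacy records are namespace-free, but tolerate {ns}tag forms
    return tag.rsplit("}", 1)[-1]


def _child_text(element: ET.Element, name: str) -> Optional[str]:
    for child in element:
        if _local_name(child.tag) == name:
            text = (child.text or "").strip()
            return text or None
    return None


def parse_trial_xml(xml_text: str, nct_id: str) -> TrialRecord:
    """Extract outcome entries from a full-study XML document.

    One entry is produced per outcome element found anywhere in the document,
    in document order; the element name alone determines the category.
    Outcome elements with an empty or missing ``measure`` child are dropped
    and logged. Malformed XML raises :class:`RecordParseError`.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise RecordParseError(nct_id, exc) from exc

    outcomes: list[OutcomeEntry] = []
    for element in root.iter():
        category = _CATEGORY_ELEMENTS.get(_local_name(element.tag))
        if category is None:
            continue
        measure = _child_text(element, "measure")
        if measure is None:
            logger.warning(
                "dropping %s outcome with empty measure in %s", category, nct_id
            )
            continue
        outcomes.append(
            OutcomeEntry(
                nct_id=nct_id,
                category=category,
                measure=measure,
                description=_child_text(element, "description"),
                time_frame=_child_text(element, "time_frame"),
            )
        )
    return TrialRecord(nct_id=nct_id, outcomes=outcomes)
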