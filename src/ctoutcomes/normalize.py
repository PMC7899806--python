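"""Canonicalization of free-text outcome names and frequency ranking.

Outcome measures in trial registries are free text, so the same concept is
registered under many surface forms ("Quality of Life", "quality of life
(QoL)", "QUALITY-OF-LIFE"). This module collapses surface variation with four
ordered transformations:

1. strip a trailing parenthesized initialism whose letters match the initials
   of the preceding words,
2. lowercase,
3. replace every punctuation character with a space,
4. collapse runs of spaces and trim the ends.

Grouping by the canonical form then yields a frequency table mapping each
canonical outcome to the set of distinct trials that registered it.
"""

from __future__ import annotations

import re
import string
import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .records import OutcomeEntry

Scope = Literal["primary", "secondary_other", "combined"]

#: Categories contributing to each frequency-table scope.
SCOPE_CATEGORIES: dict[str, frozenset[str]] = {
    "primary": frozenset({"primary"}),
    "secondary_other": frozenset({"secondary", "other"}),
    "combined": frozenset({"primary", "secondary", "other"}),
}

_ASCII_PUNCT = frozenset(string.punctuation)

# A trailing bracketed token: captures everything inside the final () or []
# pair when that pair closes the string (brackets must match).
_TRAILING_PAREN = re.compile(
    r"^(.*?)[ \t]*(?:\(([^()\[\]]*)\)|\[([^()\[\]]*)\])$", re.DOTALL
)


def _is_punct(ch: str, unicode_punct: bool = True) -> bool:
    if ch in _ASCII_PUNCT:
        return True
    return unicode_punct and unicodedata.category(ch).startswith("P")


def _word_initials(text: str, unicode_punct: bool = True) -> list[str]:
    """First character of each word; words are maximal runs of
    non-space, non-punctuation characters."""
    initials: list[str] = []
    in_word = False
    for ch in text:
        if ch.isspace() or _is_punct(ch, unicode_punct):
            in_word = False
        elif not in_word:
            initials.append(ch)
            in_word = True
    return initials


def strip_trailing_abbreviation(text: str, *, unicode_punct: bool = True) -> str:
    """Remove a trailing parenthesized initialism, if present.

    The token inside the final ``(...)`` or ``[...]`` pair is removed when all
    of the following hold; otherwise the input is returned unchanged:

    * the pair closes the string (ignoring trailing whitespace);
    * the token contains no internal whitespace (so multi-word parentheticals
      such as ``(left arm)`` are never treated as abbreviations);
    * the token has at least two alphanumeric characters;
    * those characters, compared case-insensitively, form an in-order
      subsequence of the initial characters of the preceding words.

    The subsequence rule accepts ``QoL`` after "Quality of life" and ``SGRQ``
    after "St. George's Respiratory Questionnaire" while rejecting tokens
    unrelated to the preceding words.
    """
    trimmed = text.rstrip()
    m = _TRAILING_PAREN.match(trimmed)
    if m is None:
        return text
    head = m.group(1)
    token = m.group(2) if m.group(2) is not None else m.group(3)
    if any(ch.isspace() for ch in token):
        return text
    token_chars = [ch.lower() for ch in token if ch.isalnum()]
    if len(token_chars) < 2:
        return text
    initials = [ch.lower() for ch in _word_initials(head, unicode_punct)]
    # in-order subsequence test
    pos = 0
    for ch in token_chars:
        while pos < len(initials) and initials[pos] != ch:
            pos += 1
        if pos == len(initials):
            return text
        pos += 1
    return head.rstrip()


def normalize_outcome(text: str, *, unicode_punct: bool = True) -> str:
    """Canonical form of a raw outcome string (the four ordered rules).

    Returns the empty string for inputs that contain no word characters;
    callers drop such entries.
    """
    out = strip_trailing_abbreviation(text, unicode_punct=unicode_punct)
    out = out.lower()
    out = "".join(" " if _is_punct(ch, unicode_punct) else ch for ch in out)
    return " ".join(out.split())


@dataclass
class NormalizedOutcome:
    """One canonical outcome with its observed surface forms and trial sets."""

    canonical_text: str
    variants: set[str] = field(default_factory=set)
    trials_by_category: dict[str, set[str]] = field(
        default_factory=lambda: defaultdict(set)
    )

    @property
    def trials(self) -> set[str]:
        """Union of the per-category trial sets."""
        combined: set[str] = set()
        for nct_ids in self.trials_by_category.values():
            combined |= nct_ids
        return combined


@dataclass(frozen=True)
class FrequencyRow:
    canonical_text: str
    trial_count: int
    nct_ids: tuple[str, ...]  # sorted ascending


@dataclass(frozen=True)
class FrequencyTable:
    """Canonical outcomes ranked by the number of distinct trials using them.

    Rows are strictly ordered by (trial_count descending, canonical_text
    ascending); a trial registering the same canonical outcome several times
    counts once.
    """

    scope: str
    rows: tuple[FrequencyRow, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def counts(self) -> dict[str, int]:
        return {row.canonical_text: row.trial_count for row in self.rows}

    def top(self, n: int) -> tuple[FrequencyRow, ...]:
        return self.rows[:n]


def group_outcomes(
    entries: Iterable[OutcomeEntry], *, unicode_punct: bool = True
) -> dict[str, NormalizedOutcome]:
    """Group entries by their canonical text (empty canonicals dropped)."""
    groups: dict[str, NormalizedOutcome] = {}
    for entry in entries:
        canonical = normalize_outcome(entry.measure, unicode_punct=unicode_punct)
        if not canonical:
            continue
        group = groups.get(canonical)
        if group is None:
            group = groups[canonical] = NormalizedOutcome(canonical)
        group.variants.add(entry.measure)
        group.trials_by_category[entry.category].add(entry.nct_id)
    return groups


def build_frequency_table(
    entries: Sequence[OutcomeEntry],
    scope: Scope,
    *,
    unicode_punct: bool = True,
) -> FrequencyTable:
    """Rank canonical outcomes by distinct-trial count within a scope.

    ``scope`` selects which outcome categories contribute: ``primary``,
    ``secondary_other`` (the registry's secondary and other categories
    pooled), or ``combined``.
    """
    categories = SCOPE_CATEGORIES[scope]
    selected = [e for e in entries if e.category in categories]
    groups = group_outcomes(selected, unicode_punct=unicode_punct)
    rows = [
        FrequencyRow(text, len(group.trials), tuple(sorted(group.trials)))
        for text, group in groups.items()
    ]
    rows.sort(key=lambda r: (-r.trial_count, r.canonical_text))
    return FrequencyTable(scope=scope, rows=tuple(rows))


def exclude_top_primary(
    secondary_table: FrequencyTable,
    primary_table: FrequencyTable,
    top_n: int,
) -> FrequencyTable:
    """Drop from ``secondary_table`` any outcome among the ``top_n``
    most frequent primary outcomes (used to surface outcomes that are
    distinctively secondary)."""
    excluded = {row.canonical_text for row in primary_table.top(top_n)}
    rows = tuple(r for r in secondary_table.rows if r.canonical_text not in excluded)
    return FrequencyTable(scope=secondary_table.scope, rows=rows)
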