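"""Merging per-term search results into one deduplicated trial list.

Related query terms (e.g. "emphysema" and "COPD") match overlapping trial
sets, so the per-term result tables are unioned on the trial identifier. The
union keeps first-seen order and records, for every identifier, the set of
terms under which it appeared (provenance, exportable for audit).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .records import validate_nct
from .sources import SearchPage

logger = logging.getLogger(__name__)


@dataclass
class TrialIdSet:
    """Ordered unique trial identifiers with per-identifier provenance."""

    nct_ids: list[str] = field(default_factory=list)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.nct_ids)

    def __contains__(self, nct_id: str) -> bool:
        return nct_id in self.provenance

    def __iter__(self):
        return iter(self.nct_ids)

    def add(self, nct_id: str, term: str) -> None:
        if nct_id not in self.provenance:
            self.nct_ids.append(nct_id)
            self.provenance[nct_id] = set()
        self.provenance[nct_id].add(term)

    def export_provenance_csv(self, path: str | Path) -> None:
        """Two-column audit file: nct_id, semicolon-joined matching terms."""
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(["nct_id", "terms"])
            for nct_id in self.nct_ids:
                writer.writerow([nct_id, ";".join(sorted(self.provenance[nct_id]))])


def collect_nct_ids(
    pages_by_term: Mapping[str, Sequence[SearchPage]]
) -> TrialIdSet:
    """Union all search rows into a deduplicated identifier list.

    Terms are processed in input order, pages in chunk order, rows in row
    order, so the output order is first-seen and reproducible. Rows whose
    identifier fails validation are skipped and logged rather than aborting
    the run.
    """
    id_set = TrialIdSet()
    for term, pages in pages_by_term.items():
        for page in pages:
            for row_index, (nct_id, _meta) in enumerate(page.rows):
                if not validate_nct(nct_id):
                    logger.warning(
                        "skipping invalid NCT id %r (term=%r chunk=%d row=%d)",
                        nct_id, term, page.chunk_index, row_index,
                    )
                    continue
                id_set.add(nct_id, term)
    return id_set
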