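"""Output spreadsheet and run-level summary statistics.

The ranked outcome table is emitted as a strict three-column CSV (outcome
name, distinct-trial count, pipe-separated trial identifiers) so a clinician
can explore the trials behind each outcome. The run summary mirrors the
bookkeeping a registry-mining run reports: per-term hit counts, unique trials
after deduplication, how many listed outcomes, and how many outcome entries
of each category were parsed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

from .aggregation import TrialIdSet
from .normalize import FrequencyRow, FrequencyTable
from .records import TrialRecord

CSV_HEADER = ("outcome", "trial_count", "nct_ids")
NCT_DELIMITER = "|"  # keeps the file strictly three-column


def write_outcome_csv(table: FrequencyTable, path: str | Path) -> int:
    """Write the ranked table as UTF-8, LF-terminated, RFC-4180 CSV.

    Rows appear in table order; the third cell joins the sorted trial
    identifiers with ``|``. Returns the number of data rows written.
    """
    count = 0
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        for row in table.rows:
            writer.writerow(
                [row.canonical_text, row.trial_count,
                 NCT_DELIMITER.join(row.nct_ids)]
            )
            count += 1
    return count


def read_outcome_csv(path: str | Path, scope: str = "combined") -> FrequencyTable:
    """Inverse of :func:`write_outcome_csv` (used for audits and round-trips)."""
    rows: list[FrequencyRow] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = tuple(next(reader))
        if header != CSV_HEADER:
            raise ValueError(f"unexpected header {header!r}")
        for text, count, ncts in reader:
            nct_ids = tuple(ncts.split(NCT_DELIMITER)) if ncts else ()
            rows.append(FrequencyRow(text, int(count), nct_ids))
    return FrequencyTable(scope=scope, rows=tuple(rows))


def percent_one_decimal(numerator: int, denominator: int) -> Optional[float]:
    """100·numerator/denominator to one decimal, half away from zero;
    None when the denominator is zero."""
    if denominator == 0:
        return None
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RunSummary:
    """Run-level statistics, pure functions of the in-memory run state."""

    per_term_trial_counts: dict[str, int] = field(default_factory=dict)
    unique_trials: int = 0
    trials_with_outcomes: int = 0
    pct_trials_with_outcomes: Optional[float] = None  # one decimal, or None
    primary_outcomes: int = 0
    secondary_other_outcomes: int = 0
    elapsed_seconds: Optional[float] = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8"
        )


def summarize_run(
    id_set: TrialIdSet,
    records: Sequence[TrialRecord],
    *,
    elapsed_seconds: Optional[float] = None,
) -> RunSummary:
    per_term: dict[str, int] = {}
    for terms in id_set.provenance.values():
        for term in terms:
            per_term[term] = per_term.get(term, 0) + 1
    with_outcomes = sum(1 for r in records if r.has_outcomes)
    primary = sum(
        1 for r in records for e in r.outcomes if e.category == "primary"
    )
    secondary_other = sum(
        1 for r in records for e in r.outcomes if e.category != "primary"
    )
    return RunSummary(
        per_term_trial_counts=per_term,
        unique_trials=len(id_set),
        trials_with_outcomes=with_outcomes,
        pct_trials_with_outcomes=percent_one_decimal(with_outcomes, len(id_set)),
        primary_outcomes=primary,
        secondary_other_outcomes=secondary_other,
        elapsed_seconds=elapsed_seconds,
    )
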