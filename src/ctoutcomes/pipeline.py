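"""End-to-end orchestration: query → download → parse → rank.

Runs the whole mining sequence against any registry backend: fetch paginated
search results for every query term, union the trial identifiers, download
and parse each full-study record, and build the ranked per-scope frequency
tables plus a run summary. Individual record failures (missing or malformed
records) are skipped and counted rather than aborting a multi-thousand-trial
run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

from .aggregation import TrialIdSet, collect_nct_ids
from .normalize import FrequencyTable, build_frequency_table
from .records import OutcomeEntry, RecordParseError, TrialRecord, parse_trial_xml
from .report import RunSummary, summarize_run
from .sources import (
    QuerySpec,
    RecordNotFoundError,
    RegistrySource,
    fetch_search_pages,
    fetch_trial_record,
)

logger = logging.getLogger(__name__)

SCOPES = ("primary", "secondary_other", "combined")


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    id_set: TrialIdSet
    records: list[TrialRecord]
    tables: dict[str, FrequencyTable]
    summary: RunSummary
    skipped_records: list[str] = field(default_factory=list)

    @property
    def entries(self) -> list[OutcomeEntry]:
        return [e for record in self.records for e in record.outcomes]


def run_pipeline(
    source: RegistrySource,
    terms: Sequence[str],
    *,
    field_mode: str = "condition",
    page_size: int = 10_000,
    max_chunks: int = 100,
) -> PipelineResult:
    """Mine a registry backend for the outcomes registered under ``terms``."""
    started = time.monotonic()
    query = QuerySpec(terms=tuple(terms), field_mode=field_mode,
                      page_size=page_size)

    pages_by_term = {
        term: fetch_search_pages(source, query, term, max_chunks=max_chunks)
        for term in query.terms
    }
    id_set = collect_nct_ids(pages_by_term)
    logger.info("aggregated %d unique trials from %d terms",
                len(id_set), len(query.terms))

    records: list[TrialRecord] = []
    skipped: list[str] = []
    for nct_id in id_set:
        try:
            xml_text = fetch_trial_record(source, nct_id)
            records.append(parse_trial_xml(xml_text, nct_id))
        except (RecordNotFoundError, RecordParseError) as exc:
            logger.warning("skipping %s: %s", nct_id, exc)
            skipped.append(nct_id)

    entries = [e for record in records for e in record.outcomes]
    tables = {
        scope: build_frequency_table(entries, scope) for scope in SCOPES
    }
    summary = summarize_run(
        id_set, records, elapsed_seconds=time.monotonic() - started
    )
    return PipelineResult(
        id_set=id_set,
        records=records,
        tables=tables,
        summary=summary,
        skipped_records=skipped,
    )
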