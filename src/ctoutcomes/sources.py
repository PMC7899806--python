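"""Registry query construction and search/record retrieval backends.

The legacy registry dialect exposes two endpoints:

* a search endpoint returning CSV tables of matching trials, paginated by a
  chunk number (``download_fields?cond=<term>&down_chunk=<k>&...``) — the
  ``cond`` parameter restricts the search to the trial's condition field,
  while substituting ``term`` searches additional fields;
* a per-trial full-record endpoint returning XML
  (``show/<NCT>?displayxml=true``).

Both a live HTTP backend and an offline fixture backend (reading a generated
corpus directory) implement the same :class:`RegistrySource` contract, so the
rest of the pipeline is backend-agnostic.
"""

from __future__ import annotations

import io
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import validate_nct

logger = logging.getLogger(__name__)

PAGE_SIZE_CAP = 10_000  # registry maximum for down_count
DEFAULT_MAX_CHUNKS = 100

SEARCH_BASE_URL = "https://clinicaltrials.gov/ct2/results/download_fields"
RECORD_BASE_URL = "https://clinicaltrials.gov/ct2/show"

FIELD_MODES = ("condition", "other_terms")
_FIELD_PARAM = {"condition": "cond", "other_terms": "term"}

#: Candidate header names for the trial-identifier column, case-insensitive.
DEFAULT_NCT_COLUMNS = ("NCT Number", "nct_id")


class SourceError(RuntimeError):
    """Retrieval or decoding failure, annotated with term and chunk."""

    def __init__(self, message: str, *, term: str | None = None,
                 chunk_index: int | None = None):
        super().__init__(message)
        self.term = term
        self.chunk_index = chunk_index


class RecordNotFoundError(SourceError):
    """The backend holds no record for the requested trial identifier."""


@dataclass(frozen=True)
class QuerySpec:
    """A registry search: query terms, field mode, and pagination size."""

    terms: tuple[str, ...]
    field_mode: str = "condition"
    page_size: int = PAGE_SIZE_CAP

    def __post_init__(self):
        terms = tuple(t.strip() for t in self.terms)
        if not terms or any(not t for t in terms):
            raise ValueError("terms must be non-empty strings")
        object.__setattr__(self, "terms", terms)
        if self.field_mode not in FIELD_MODES:
            raise ValueError(f"field_mode must be one of {FIELD_MODES}")
        if not 1 <= self.page_size <= PAGE_SIZE_CAP:
            raise ValueError(f"page_size must be in [1, {PAGE_SIZE_CAP}]")


@dataclass(frozen=True)
class SearchPage:
    """One chunk of search results: (nct_id, metadata) rows."""

    term: str
    chunk_index: int  # 1-based
    rows: tuple[tuple[str, dict], ...]

    def nct_ids(self) -> tuple[str, ...]:
        return tuple(nct for nct, _ in self.rows)


def build_search_url(
    term: str,
    field_mode: str = "condition",
    chunk_index: int = 1,
    page_size: int = PAGE_SIZE_CAP,
) -> str:
    """Legacy search-endpoint URL for one term and result chunk.

    Pure function: identical arguments always yield the identical string.
    The term is percent-encoded; results format is fixed to CSV.
    """
    term = term.strip()
    if not term:
        raise ValueError("term must be non-empty")
    if field_mode not in FIELD_MODES:
        raise ValueError(f"field_mode must be one of {FIELD_MODES}")
    if not 1 <= page_size <= PAGE_SIZE_CAP:
        raise ValueError(f"page_size must be in [1, {PAGE_SIZE_CAP}]")
    if chunk_index < 1:
        raise ValueError("chunk_index starts at 1")
    params = [
        (_FIELD_PARAM[field_mode], term),
        ("down_count", str(page_size)),
        ("down_chunk", str(chunk_index)),
        ("down_fmt", "csv"),
    ]
    return f"{SEARCH_BASE_URL}?{urllib.parse.urlencode(params)}"


def build_record_url(nct_id: str) -> str:
    """Legacy full-record endpoint URL for one trial."""
    return f"{RECORD_BASE_URL}/{nct_id}?displayxml=true"


def _parse_search_csv(
    csv_text: str,
    term: str,
    chunk_index: int,
    nct_columns: Sequence[str] = DEFAULT_NCT_COLUMNS,
) -> SearchPage:
    """Parse one CSV chunk into a SearchPage, locating the NCT column by
    header name (case-insensitive)."""
    try:
        frame = pd.read_csv(io.StringIO(csv_text), dtype=str).fillna("")
    except Exception as exc:  # pragma: no cover - pandas raises many types
        raise SourceError(
            f"malformed CSV for term {term!r} chunk {chunk_index}: {exc}",
            term=term, chunk_index=chunk_index,
        ) from exc
    wanted = {c.lower() for c in nct_columns}
    nct_col = next((c for c in frame.columns if c.lower() in wanted), None)
    if nct_col is None:
        raise SourceError(
            f"no NCT-identifier column among {list(frame.columns)!r} "
            f"for term {term!r} chunk {chunk_index}",
            term=term, chunk_index=chunk_index,
        )
    rows = tuple(
        (record[nct_col], {k: v for k, v in record.items() if k != nct_col})
        for record in frame.to_dict(orient="records")
    )
    return SearchPage(term=term, chunk_index=chunk_index, rows=rows)


class RegistrySource:
    """Backend contract: fetch one search chunk and one trial record."""

    def fetch_search_chunk(
        self, term: str, field_mode: str, chunk_index: int, page_size: int
    ) -> SearchPage:
        raise NotImplementedError

    def fetch_record(self, nct_id: str) -> str:
        raise NotImplementedError


def fetch_search_pages(
    source: RegistrySource,
    query: QuerySpec,
    term: str,
    *,
    max_chunks: int = DEFAULT_MAX_CHUNKS,
) -> list[SearchPage]:
    """Fetch consecutive result chunks for one term until exhausted.

    Chunks are requested starting at 1; iteration stops after the first chunk
    holding fewer rows than ``page_size`` (an empty first chunk yields an
    empty list). ``max_chunks`` caps the loop against a misbehaving source.
    """
    pages: list[SearchPage] = []
    for chunk_index in range(1, max_chunks + 1):
        page = source.fetch_search_chunk(
            term, query.field_mode, chunk_index, query.page_size
        )
        if page.rows:
            pages.append(page)
        if len(page.rows) < query.page_size:
            return pages
    raise SourceError(
        f"term {term!r} still returning full chunks after {max_chunks} chunks",
        term=term, chunk_index=max_chunks,
    )


def fetch_trial_record(source: RegistrySource, nct_id: str) -> str:
    """Fetch one trial's full-study XML, gating on identifier validity."""
    if not validate_nct(nct_id):
        raise ValueError(f"invalid NCT identifier: {nct_id!r}")
    return source.fetch_record(nct_id)


class FixtureSource(RegistrySource):
    """Offline backend over a generated corpus directory.

    Layout: ``search/<term>.chunk<k>.csv`` and ``records/<NCT>.xml``. All
    chunks for a term are concatenated on load, then re-sliced to the
    requested page size, so pagination behaviour is exercised regardless of
    how the corpus was chunked on disk.
    """

    def __init__(self, corpus_dir: str | Path,
                 nct_columns: Sequence[str] = DEFAULT_NCT_COLUMNS):
        self.corpus_dir = Path(corpus_dir)
        self.nct_columns = tuple(nct_columns)
        self._rows_cache: dict[str, tuple[tuple[str, dict], ...]] = {}

    def _term_rows(self, term: str) -> tuple[tuple[str, dict], ...]:
        if term in self._rows_cache:
            return self._rows_cache[term]
        search_dir = self.corpus_dir / "search"
        safe = _term_filename(term)
        chunk_files = sorted(
            search_dir.glob(f"{safe}.chunk*.csv"),
            key=lambda p: int(p.stem.rsplit("chunk", 1)[1]),
        )
        rows: list[tuple[str, dict]] = []
        for k, path in enumerate(chunk_files, start=1):
            page = _parse_search_csv(
                path.read_text(encoding="utf-8"), term, k, self.nct_columns
            )
            rows.extend(page.rows)
        self._rows_cache[term] = tuple(rows)
        return self._rows_cache[term]

    def fetch_search_chunk(
        self, term: str, field_mode: str, chunk_index: int, page_size: int
    ) -> SearchPage:
        rows = self._term_rows(term)
        start = (chunk_index - 1) * page_size
        return SearchPage(
            term=term,
            chunk_index=chunk_index,
            rows=rows[start:start + page_size],
        )

    def fetch_record(self, nct_id: str) -> str:
        path = self.corpus_dir / "records" / f"{nct_id}.xml"
        if not path.exists():
            raise RecordNotFoundError(f"no record for {nct_id}")
        return path.read_text(encoding="utf-8")


def _term_filename(term: str) -> str:
    """Filesystem-safe name for a query term."""
    return "".join(c if c.isalnum() else "_" for c in term.strip().lower())


@dataclass
class LiveSource(RegistrySource):
    """HTTP backend against the legacy endpoints, with bounded retries.

    Transient failures are retried ``retries`` times with exponential backoff
    before the call fails; ``delay_seconds`` inserts a politeness pause
    before each request (default 0).
    """

    retries: int = 3
    backoff_seconds: float = 1.0
    delay_seconds: float = 0.0
    timeout: float = 60.0
    nct_columns: tuple[str, ...] = DEFAULT_NCT_COLUMNS

    def _get(self, url: str, *, term: str | None = None,
             chunk_index: int | None = None) -> str:
        last_error: Exception | None = None
        for attempt in range(self.retries + 1):
            if self.delay_seconds:
                time.sleep(self.delay_seconds)
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read().decode("utf-8", errors="replace")
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    raise RecordNotFoundError(
                        f"HTTP 404 for {url}", term=term, chunk_index=chunk_index
                    ) from exc
                last_error = exc
            except (urllib.error.URLError, TimeoutError, OSError) as exc:
                last_error = exc
            if attempt < self.retries:
                wait = self.backoff_seconds * (2 ** attempt)
                logger.warning("retrying %s in %.1fs after %s", url, wait,
                               last_error)
                time.sleep(wait)
        raise SourceError(
            f"failed to fetch {url}: {last_error}",
            term=term, chunk_index=chunk_index,
        )

    def fetch_search_chunk(
        self, term: str, field_mode: str, chunk_index: int, page_size: int
    ) -> SearchPage:
        url = build_search_url(term, field_mode, chunk_index, page_size)
        csv_text = self._get(url, term=term, chunk_index=chunk_index)
        return _parse_search_csv(csv_text, term, chunk_index, self.nct_columns)

    def fetch_record(self, nct_id: str) -> str:
        return self._get(build_record_url(nct_id))
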