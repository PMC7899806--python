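# Methods

## Overview

`ctoutcomes` treats a trial registry as an evidence base for which clinical
outcomes a field actually measures. The unit of evidence is the *distinct
trial*: an outcome's rank is the number of different registered studies that
list it (in any phrasing), never the number of times a phrasing occurs. All
downstream statistics — ranked tables, the ≥ 4-trial grouping threshold,
recall/precision against a gold standard — are functions of the mapping
*canonical outcome text → set of NCT identifiers*.

## Registry dialect and retrieval

The reference dialect is the legacy self-service interface: a search
endpoint returning CSV chunks keyed by NCT number, and a full-record
endpoint returning one XML document per trial. The source contract
(`RegistrySource`) is dialect-agnostic — a backend only has to produce
search rows and record text — so newer registry APIs can be added without
touching aggregation, parsing or ranking. Retrieval policy for the live
backend: bounded retries (default 3) with exponential backoff (base 1 s) on
transient HTTP errors, failing the term rather than the whole run; an
optional politeness delay between calls (default 0 s, which is also what
the offline fixture backend uses); a page size of 10,000 rows (the
registry's cap) and a safety cap of 100 chunks per term to bound the
pagination loop on a misbehaving source. Pagination stops at the first
chunk shorter than the page size; an empty first chunk means zero matches.

## Aggregation

Per-term result tables are unioned on the NCT identifier in first-seen
order (terms in input order, chunks in order, rows in order), which makes
the output reproducible; ranking does not depend on this order. Every
identifier records the set of terms that matched it, exportable as a
two-column audit CSV. A row with a malformed identifier is skipped and
logged with its term/chunk/row position — one bad row must not abort a
multi-thousand-trial run. Identifier validity is `NCT` + exactly 8 digits;
a lenient mode uppercasing first is available but off by default.

## Parsing

Outcome entries are read from `primary_outcome`, `secondary_outcome` and
`other_outcome` elements found anywhere in the record, in document order;
the element name alone fixes the category. Element matching ignores XML
namespaces (legacy records carry none). The `measure` child is kept
verbatim apart from end-trimming — all normalization is downstream, so the
parse stage is auditable against the registry page. Entries with an empty
measure are dropped and logged. Duplicate identical outcome elements within
one trial are kept at parse time; distinct-trial counting makes them
harmless. Malformed records raise a parse error carried per-NCT and are
skipped and counted at pipeline level.

## Normalization

Four ordered transformations:

1. **Trailing-initialism strip.** If the string ends with a `(…)` or `[…]`
   group (brackets must match) whose token contains no whitespace and has at
   least two alphanumeric characters, and those characters — case-
   insensitively — form an in-order subsequence of the initials of the
   preceding words, the group is removed. Words are maximal runs of
   non-space, non-punctuation characters; a word's initial is its first
   character, letter or digit. The subsequence rule (rather than exact
   initial-by-initial equality) accepts `QoL`, `FEV1` (the digit `1` is the
   initial of the word "1") and `SGRQ` (skipping the possessive "s"), while
   the no-whitespace guard keeps `(left arm)`-style parentheticals, and the
   two-character minimum keeps unit annotations like `(L)`. Only the final
   group is ever considered.
2. **Lowercase.**
3. **Punctuation → space.** The 32 ASCII punctuation characters always;
   other Unicode punctuation (category `P*`) by default, switchable off via
   `unicode_punct=False`.
4. **Whitespace collapse and trim.**

Whether the initialism strip runs before or after lowercasing is
unobservable because the match is case-insensitive; the order above is
fixed. The composition is idempotent, and its output alphabet (lowercase,
punctuation-free, single-spaced, trimmed) is property-tested. A second,
independently written character-by-character implementation of the same
rules lives in `tests/oracle_normalize.py`; a differential test keeps the
two in agreement, and the curated 30-string corpus in `tests/test_normalize.py`
freezes outputs computed with that oracle.

Strings that normalize to empty (e.g. `(!)`) are dropped from tables with a
logged count.

## Ranking and scopes

Tables are built per scope: `primary`, `secondary_other` (the registry's
secondary and other categories pooled, as summary statistics convention
pools them), and `combined`. Rows are ordered by distinct-trial count
descending with canonical text ascending as the tie-break, so output files
are byte-reproducible. `exclude_top_primary(secondary, primary, top_n)`
removes from a secondary table any outcome among the top `top_n` primary
outcomes; `top_n` defaults to 15 (the length of a conventional top-outcomes
table) and is a parameter because no principled threshold exists.

## Evaluation

The pipeline side is the set of canonical outcomes used in at least
`min_trials` trials (default 4 — the grouping threshold under which manual
review of mined outcomes stays tractable). The equivalence relation between
gold and pipeline outcomes is explicitly many-to-many: automatic pairs from
normalized-equality plus a curator-supplied two-column CSV. Scoring counts a
gold outcome as matched if it has ≥ 1 mapped pipeline partner (unmatched
gold = false negatives) and a pipeline outcome as matched if it has ≥ 1
mapped gold partner (unmatched pipeline = false positives); the two matched
counts can differ, which is why recall and precision numerators differ.
Metrics are reported as raw fractions to 4 decimals and as **truncated**
integer percentages (74/80 = 0.925 → 92 %), the display convention
consistent with published figures of this protocol. Precision over an empty
pipeline set is reported as undefined, never a division error. Adding
mapping pairs can only grow the matched sets, so both metrics are monotone
in the mapping; raising `min_trials` shrinks the pipeline set and cannot
increase recall (both property-tested).

## Summary statistics

Percentages of trials listing outcomes are rounded to one decimal,
half-away-from-zero (3734/3876 → 96.3, 4299/4450 → 96.6); a zero-trial run
reports the percentage as undefined. Summaries are pure functions of the
in-memory run state.

## Synthetic registry generator

The generator emulates the structural dialect, not real vocabularies: it
plants each specified canonical outcome in a chosen number of eligible
trials, renders every occurrence as a surface variant (case shuffle,
appended word-initial initialism, punctuation inserted at token boundaries,
whitespace padding) and verifies by construction that each variant
round-trips through the normalizer to its canonical (failed candidates are
retried with a perturbed seed, then fall back to the canonical unchanged).
Canonicals must be distinct and already normalized, so ground truth is
unambiguous: no variant of one canonical can collapse onto another.
Eligible trials not reached by any planted outcome receive a unique filler
outcome, making the fraction of trials without outcomes exact (default
3.7 %, a realistic share for a mature registry). NCT identifiers are
sequential 8-digit numbers from a seeded offset; corpora are byte-identical
given the same spec. Default problem sizes in the tests are 40–200 trials
per corpus across 20 seeds — large enough to exercise multi-chunk
pagination, overlapping-term dedup and all variant styles, while keeping
the whole suite fast.

What passing the end-to-end oracle shows: the pipeline inverts every
surface perturbation the generator emits and counts distinct trials
correctly. What it does not show: robustness to real-world variation the
normalizer intentionally does not model — synonyms, misspellings,
ontological relatedness (e.g. "spirometry" vs "FEV1") — which is exactly
the residue the manual equivalence mapping covers in evaluation.

## Known limitations

- The legacy endpoints are a reference dialect; the live registry has moved
  to newer APIs, so live-mode use requires a backend for the current API.
- No semantic grouping (UMLS/MeSH/ontologies), stemming or spelling
  correction; near-duplicate canonical outcomes remain separate rows.
- Time frames are parsed and exported but not aggregated.
- Other-terms queries return a superset of condition-field results; no
  relevance filtering is applied.
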