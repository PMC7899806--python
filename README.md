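# ctoutcomes

Automated identification of disease-specific clinical-trial outcome
measures from a trial registry.

## The problem

Choosing which outcomes a new clinical trial should measure — and making
those outcomes comparable across trials — is traditionally done by expert
panels abstracting common data elements from the literature. Trial
registries such as ClinicalTrials.gov already hold, for every registered
study, the primary, secondary and other outcome measures its investigators
chose. `ctoutcomes` mines that evidence directly: given a condition query it
retrieves the matching trials, parses their registered outcome measures,
collapses the heterogeneous free-text phrasings of the same outcome onto one
canonical form, and ranks the canonical outcomes by how many distinct trials
use them. The ranked list can then be scored against an expert-abstracted
gold standard with recall and precision.

The package is aimed at clinical-research informaticians building
disease-specific outcome sets (common data elements) and at methodologists
studying outcome heterogeneity in trial registries.

## Method

1. **Search** — for each query term, the legacy registry search endpoint is
   paged through in CSV chunks (`cond=<term>` for the condition field,
   `term=<term>` for the other-terms field; up to 10,000 rows per chunk)
   until results are exhausted.
2. **Aggregate** — rows from all terms are unioned on the NCT identifier
   (`NCT` + 8 digits), keeping first-seen order and per-identifier term
   provenance.
3. **Download & parse** — each trial's full-study XML is fetched and its
   `primary_outcome` / `secondary_outcome` / `other_outcome` elements are
   read into structured entries (measure, description, time frame).
4. **Normalize** — each raw measure text is canonicalized by four ordered
   rules: strip a trailing parenthesized initialism whose letters form an
   in-order subsequence of the preceding word initials (`Quality of life
   (QoL)` → `Quality of life`); lowercase; replace punctuation with spaces;
   collapse and trim whitespace.
5. **Rank** — canonical outcomes are grouped and ranked by the number of
   *distinct* trials using them, per scope (primary, secondary+other,
   combined).
6. **Evaluate** — the table is thresholded (outcomes in ≥ 4 trials by
   default), related to a gold-standard list through a many-to-many
   equivalence map (automatic normalized-equality pairs ∪ a curator mapping
   file), and scored:

   recall = |matched gold| / |gold|,  precision = |matched pipeline| / |pipeline|.

Because real registry contents drift over time, correctness is established
against a synthetic offline registry (`ctoutcomes.fixtures`) whose
ground-truth frequency tables are known by construction: the generator
plants canonical outcomes at chosen frequencies and emits surface variants
(case shuffling, appended initialisms, punctuation, padding) that are
guaranteed to normalize back to their canonical form.

## Worked example

`examples/02_mine_fixture_registry.py` generates a 150-trial synthetic
registry (two overlapping query terms, 4 % of trials listing no outcomes)
and runs the full pipeline over it:

```
per-term hits : {'alpha': 150, 'beta': 60}
unique trials : 150
with outcomes : 144 (96.0%)
primary outcome entries parsed        : 86
secondary/other outcome entries parsed: 86

top combined outcomes (distinct-trial counts):
   40  quality of life
   25  forced expiratory volume in 1 second
   18  six minute walk test
   12  exacerbation rate
    6  dyspnea score

ranked tables equal generator ground truth: True
wrote 76 rows to outcomes_combined.csv
```

The top counts are exactly the planted frequencies, and the ranked tables
match the generator's ground truth row for row — the end-to-end guarantee
the test suite checks across many seeds. `examples/01_normalize_outcomes.py`
shows the canonicalization rules on tricky strings, and
`examples/03_benchmark_against_gold.py` walks through a small
recall/precision benchmark (its output distinguishes false negatives —
gold outcomes the pipeline missed — from false positives — mined outcomes
absent from the gold list, which are often genuinely relevant outcomes the
literature reviews did not cover).

A thin CLI wraps the same functions:

```sh
ct-outcomes generate-fixtures --spec spec.yaml --out corpus/
ct-outcomes run copd emphysema --backend fixture --fixture-dir corpus/ --out tables/
ct-outcomes evaluate --gold gold.txt --table tables/outcomes_combined.csv --min-trials 4
```

## Layout

- `src/ctoutcomes/` — the library: `sources` (query URLs, pagination, live
  and fixture backends), `aggregation` (NCT dedup + provenance), `records`
  (XML parsing), `normalize` (canonicalization and frequency tables),
  `report` (CSV output, run summaries), `evaluation` (gold-standard
  scoring), `fixtures` (synthetic registry generator), `pipeline`
  (orchestration), `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model, parameters, numerical choices, limitations.
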