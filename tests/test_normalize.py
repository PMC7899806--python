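"""Normalization rules, frequency tables, and their invariants."""

import random
import string

import pytest
from hypothesis import given, settings, strategies as st

from ctoutcomes import (
    OutcomeEntry,
    build_frequency_table,
    exclude_top_primary,
    normalize_outcome,
    strip_trailing_abbreviation,
)
from oracle_normalize import oracle_normalize, oracle_strip_abbreviation

# Expected outputs computed with the independent hand-written oracle
# (tests/oracle_normalize.py) and frozen here.
CURATED_CORPUS = [
    ("Quality of life (QoL)", "quality of life"),
    ("Quality of life [QoL]", "quality of life"),
    ("Heart rate", "heart rate"),
    ("Forced expiratory volume in 1 second (FEV1)",
     "forced expiratory volume in 1 second"),
    ("Pain score (left arm)", "pain score left arm"),
    ("St. George's Respiratory Questionnaire (SGRQ)",
     "st george s respiratory questionnaire"),
    ("FEV1/FVC", "fev1 fvc"),
    ("Six-Minute Walk Distance (6MWD)", "six minute walk distance 6mwd"),
    ("Number of Participants With Adverse Events",
     "number of participants with adverse events"),
    ("Change From Baseline in FEV1 (L)", "change from baseline in fev1 l"),
    ("COPD Assessment Test (CAT)", "copd assessment test"),
    ("Body-Mass Index (BMI)", "body mass index"),
    ("Exacerbation rate", "exacerbation rate"),
    ("Time to First Exacerbation (TTFE)", "time to first exacerbation"),
    ("Modified Medical Research Council (mMRC) Dyspnea Scale",
     "modified medical research council mmrc dyspnea scale"),
    ("Borg Dyspnea Score", "borg dyspnea score"),
    ("  Padded   whitespace   ", "padded whitespace"),
    ("ALL UPPERCASE OUTCOME", "all uppercase outcome"),
    ("Transition Dyspnoea Index (TDI)", "transition dyspnoea index"),
    ("Oxygen saturation (SpO2)", "oxygen saturation spo2"),
    ("Residual Volume/Total Lung Capacity (RV/TLC)",
     "residual volume total lung capacity"),
    ("Hospital Anxiety and Depression Scale (HADS)",
     "hospital anxiety and depression scale"),
    ("a (b) (QoL)", "a b qol"),
    ("(!)", ""),
    ("", ""),
    ("Mortality — all causes", "mortality all causes"),
    ("Peak VO2 (mL/kg/min)", "peak vo2 ml kg min"),
    ("Use of rescue medication (puffs/day)",
     "use of rescue medication puffs day"),
    ("Inspiratory Capacity (IC)", "inspiratory capacity"),
    ("Systolic blood pressure (SBP), mmHg",
     "systolic blood pressure sbp mmhg"),
]


@pytest.mark.parametrize("raw,expected", CURATED_CORPUS,
                         ids=[r[:30] or "<empty>" for r, _ in CURATED_CORPUS])
def test_curated_corpus(raw, expected):
    """The four canonicalization rules on a curated 30-string corpus."""
    assert normalize_outcome(raw) == expected
    # dual route: the independent oracle must agree
    assert oracle_normalize(raw) == expected


class TestStripTrailingAbbreviation:
    @pytest.mark.parametrize("raw,expected", [
        ("Quality of life (QoL)", "Quality of life"),
        ("Quality of life [QoL]", "Quality of life"),
        ("Heart rate", "Heart rate"),                      # no parenthetical
        ("Pain score (left arm)", "Pain score (left arm)"),  # internal space
        ("Change in FEV1 (L)", "Change in FEV1 (L)"),      # < 2 alnum chars
        ("Oxygen saturation (SpO2)", "Oxygen saturation (SpO2)"),  # not a subsequence
        ("Quality of life (QoL]", "Quality of life (QoL]"),  # mismatched pair
    ])
    def test_rule(self, raw, expected):
        assert strip_trailing_abbreviation(raw) == expected
        assert oracle_strip_abbreviation(raw) == expected

    def test_only_final_group_considered(self):
        # earlier parentheticals are part of the text, never stripped
        assert strip_trailing_abbreviation("Score (raw) over time") == \
            "Score (raw) over time"


def _random_strings(n, seed):
    rng = random.Random(seed)
    alphabet = (string.ascii_letters + string.digits + string.punctuation
                + "     ()[]éµαΣ—")
    return [
        "".join(rng.choice(alphabet) for _ in range(rng.randrange(0, 60)))
        for _ in range(n)
    ]


def test_idempotence_and_alphabet_bulk():
    """Idempotence and the output-alphabet invariant on 10,000 seeded
    random strings."""
    for text in _random_strings(10_000, seed=20260101):
        once = normalize_outcome(text)
        assert normalize_outcome(once) == once
        assert once == once.strip()
        assert "  " not in once
        assert not any(c.isupper() for c in once)
        assert not any(c in string.punctuation for c in once)


@settings(max_examples=300, derandomize=True)
@given(st.text(max_size=80))
def test_idempotence_property(text):
    once = normalize_outcome(text)
    assert normalize_outcome(once) == once


@settings(max_examples=300, derandomize=True)
@given(st.text(max_size=80))
def test_matches_independent_oracle(text):
    """Differential test: implementation vs the hand-written oracle."""
    assert normalize_outcome(text) == oracle_normalize(text)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.sampled_from([" ", ", ", " - ", ": ", "/", "  ", " . "]),
                min_size=3, max_size=3),
       st.booleans())
def test_case_punct_whitespace_insensitivity(separators, upper):
    """Variants differing only in case and in the separators between words
    normalize identically."""
    words = ["six", "minute", "walk", "test"]
    mangled = ""
    for i, word in enumerate(words):
        mangled += word.upper() if upper else word
        if i < len(separators):
            mangled += separators[i]
    assert normalize_outcome(mangled) == "six minute walk test"


def _entries(*triples):
    return [OutcomeEntry(nct_id=n, category=c, measure=m)
            for n, c, m in triples]


class TestFrequencyTable:
    def test_groups_variants_and_counts_distinct_trials(self):
        entries = _entries(
            ("NCT00000001", "primary", "Quality of Life"),
            ("NCT00000002", "primary", "quality of life (QoL)"),
            ("NCT00000002", "primary", "QUALITY OF LIFE"),  # same trial twice
        )
        table = build_frequency_table(entries, "primary")
        assert len(table) == 1
        row = table.rows[0]
        assert row.canonical_text == "quality of life"
        assert row.trial_count == 2
        assert row.nct_ids == ("NCT00000001", "NCT00000002")

    def test_empty_input_and_empty_canonicals_dropped(self):
        assert len(build_frequency_table([], "combined")) == 0
        table = build_frequency_table(
            _entries(("NCT00000001", "primary", "(!)")), "combined"
        )
        assert len(table) == 0

    def test_scope_selects_categories(self):
        entries = _entries(
            ("NCT00000001", "primary", "fev1"),
            ("NCT00000002", "secondary", "fev1"),
            ("NCT00000003", "other", "fev1"),
        )
        assert build_frequency_table(entries, "primary").counts() == {"fev1": 1}
        assert build_frequency_table(entries, "secondary_other").counts() == \
            {"fev1": 2}
        assert build_frequency_table(entries, "combined").counts() == {"fev1": 3}

    def test_ordering_count_desc_then_text_asc(self):
        entries = _entries(
            ("NCT00000001", "primary", "beta"),
            ("NCT00000002", "primary", "beta"),
            ("NCT00000003", "primary", "alpha"),
            ("NCT00000004", "primary", "gamma"),
        )
        table = build_frequency_table(entries, "primary")
        assert [r.canonical_text for r in table.rows] == \
            ["beta", "alpha", "gamma"]

    def test_count_conservation_against_raw_entries(self, small_corpus):
        """Every trial listed for a row really registered an entry
        normalizing to that row's canonical text."""
        from ctoutcomes import run_pipeline
        source, _truth, spec = small_corpus
        result = run_pipeline(source, ["copd"], page_size=spec.page_size)
        by_trial = {}
        for e in result.entries:
            by_trial.setdefault(e.nct_id, set()).add(
                normalize_outcome(e.measure))
        for row in result.tables["combined"].rows:
            for nct in row.nct_ids:
                assert row.canonical_text in by_trial[nct]


class TestExcludeTopPrimary:
    def _table(self, scope, *pairs):
        entries = []
        nct = 1
        for text, count in pairs:
            for _ in range(count):
                entries.append(OutcomeEntry(f"NCT{nct:08d}", "primary", text))
                nct += 1
        return build_frequency_table(entries, "primary")

    def test_top_n_zero_is_identity(self):
        sec = self._table("primary", ("a", 5), ("b", 4))
        assert exclude_top_primary(sec, sec, 0).rows == sec.rows

    def test_removes_top_primary_outcomes(self):
        sec = self._table("primary", ("a", 5), ("b", 4))
        pri = self._table("primary", ("a", 9))
        result = exclude_top_primary(sec, pri, 1)
        assert result.counts() == {"b": 4}

    def test_matches_brute_force_on_fixture(self, small_corpus):
        from ctoutcomes import run_pipeline
        source, truth, spec = small_corpus
        result = run_pipeline(source, ["copd"], page_size=spec.page_size)
        pri = result.tables["primary"]
        sec = result.tables["secondary_other"]
        for top_n in (0, 1, 2, 5):
            excluded = {r.canonical_text for r in pri.rows[:top_n]}
            expect = [r for r in sec.rows if r.canonical_text not in excluded]
            assert list(exclude_top_primary(sec, pri, top_n).rows) == expect
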