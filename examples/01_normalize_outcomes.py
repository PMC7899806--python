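"""Canonicalize heterogeneous outcome phrasings.

Registered trial outcomes are free text, so one concept appears under many
surface forms. The normalizer strips a trailing initialism whose letters
match the word initials, lowercases, folds punctuation to spaces, and
collapses whitespace — variants of one concept land on one canonical string.
"""

from ctoutcomes import normalize_outcome, strip_trailing_abbreviation

RAW = [
    "Quality of life (QoL)",
    "QUALITY-OF-LIFE",
    "quality   of life",
    "St. George's Respiratory Questionnaire (SGRQ)",
    "Forced expiratory volume in 1 second (FEV1)",
    "Pain score (left arm)",          # not an initialism: kept
    "Oxygen saturation (SpO2)",       # letters don't match initials: kept
]

for raw in RAW:
    print(f"{raw!r:55} -> {normalize_outcome(raw)!r}")

print()
print("abbreviation rule only:",
      strip_trailing_abbreviation("Time to First Exacerbation (TTFE)"))
# The first three inputs all map to 'quality of life', so a frequency table
# counts them as one outcome; the last two parentheticals are kept because
# they fail the initials-subsequence test.
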