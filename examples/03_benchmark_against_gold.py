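"""Score a mined outcome table against an expert gold standard.

Thresholds a frequency table at ≥4 trials, builds the equivalence mapping
(automatic normalized-equality pairs plus one curator-supplied pair), and
reports recall (gold coverage) and precision (share of mined outcomes with a
gold equivalent). Percentages are displayed truncated, alongside the raw
fractions.
"""

from ctoutcomes import (
    EquivalenceMap,
    GoldStandard,
    auto_map,
    evaluate,
    threshold_pipeline,
)
from ctoutcomes.normalize import FrequencyRow, FrequencyTable

gold = GoldStandard((
    "Quality of life",
    "FEV1",
    "Six-minute walk test",
    "Exacerbation rate",
    "Mortality",
))

table = FrequencyTable(scope="combined", rows=(
    FrequencyRow("quality of life", 40, ()),
    FrequencyRow("fev1", 25, ()),
    FrequencyRow("6 minute walking distance", 18, ()),
    FrequencyRow("exacerbation rate", 12, ()),
    FrequencyRow("adverse events", 9, ()),
    FrequencyRow("mortality", 2, ()),          # below threshold
))

pipeline_set = threshold_pipeline(table, min_trials=4)
print(f"outcomes used in >=4 trials: {sorted(pipeline_set)}")

mapping = auto_map(gold, pipeline_set)
manual = EquivalenceMap()
manual.add("Six-minute walk test", "6 minute walking distance")
mapping = mapping.union(manual)

result = evaluate(gold, pipeline_set, mapping, min_trials_threshold=4)
print()
print(result.report_text())
# 'Mortality' is a false negative (only 2 trials, below the threshold);
# 'adverse events' is a false positive — mined, relevant, but absent from
# the gold list. Recall 4/5, precision 4/5.
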