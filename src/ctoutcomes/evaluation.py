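"""Scoring a mined outcome list against an expert gold standard.

The benchmark protocol: threshold the pipeline's frequency table to outcomes
used by at least ``min_trials`` trials (default 4), relate the thresholded
outcomes to an expert-abstracted gold list through an explicit many-to-many
equivalence mapping, and report

* recall — the fraction of gold outcomes with at least one mapped pipeline
  equivalent (unmatched gold outcomes are the false negatives), and
* precision — the fraction of thresholded pipeline outcomes with at least
  one mapped gold equivalent (unmatched pipeline outcomes are the false
  positives).

Because the mapping is many-to-many, the matched counts on the two sides may
differ. The mapping itself is the union of automatic normalized-equality
pairs and a curator-supplied mapping file, making the scoring deterministic
and auditable.

Percentages are reported both as raw fractions (4 decimals) and as truncated
integer percents: 74/80 → 0.925 → 92, 76/96 → 0.7917 → 79.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .normalize import FrequencyTable, normalize_outcome

DEFAULT_MIN_TRIALS = 4


@dataclass(frozen=True)
class GoldStandard:
    """Expert-abstracted outcome names (unique after normalization)."""

    outcomes: tuple[str, ...]

    def __post_init__(self):
        if not self.outcomes:
            raise ValueError("gold standard must be non-empty")
        normalized = [normalize_outcome(o) for o in self.outcomes]
        dupes = {n for n in normalized if normalized.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gold outcomes after normalization: {dupes}")

    def __len__(self) -> int:
        return len(self.outcomes)

    def __iter__(self):
        return iter(self.outcomes)


def load_gold_standard(path: str | Path) -> GoldStandard:
    """Plain-text gold list: one outcome per line, '#' comments allowed."""
    outcomes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            outcomes.append(line)
    return GoldStandard(tuple(outcomes))


@dataclass
class EquivalenceMap:
    """Many-to-many (gold outcome, pipeline outcome) match relation."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, gold: str, pipeline: str, provenance: str = "manual") -> None:
        self.pairs.add((gold, pipeline))
        self.provenance[(gold, pipeline)] = provenance

    def union(self, other: "EquivalenceMap") -> "EquivalenceMap":
        merged = EquivalenceMap(set(self.pairs), dict(self.provenance))
        for pair in other.pairs:
            merged.pairs.add(pair)
            merged.provenance.setdefault(pair, other.provenance.get(pair, "manual"))
        return merged

    def matched_gold(self) -> set[str]:
        return {g for g, _ in self.pairs}

    def matched_pipeline(self) -> set[str]:
        return {p for _, p in self.pairs}


def load_equivalence_csv(path: str | Path) -> EquivalenceMap:
    """Curator mapping file: two-column CSV (gold_outcome, pipeline_outcome)."""
    mapping = EquivalenceMap()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        for row in reader:
            if not row or row[0].lstrip().startswith("#"):
                continue
            if row[0].strip().lower() == "gold_outcome":
                continue  # optional header
            gold, pipeline = row[0].strip(), row[1].strip()
            mapping.add(gold, pipeline, "manual")
    return mapping


def auto_map(gold: GoldStandard, pipeline_set: Iterable[str]) -> EquivalenceMap:
    """Pair every gold outcome with every pipeline outcome whose normalized
    forms are equal; intended to be unioned with a curator mapping."""
    by_canonical: dict[str, list[str]] = {}
    for p in pipeline_set:
        by_canonical.setdefault(normalize_outcome(p), []).append(p)
    mapping = EquivalenceMap()
    for g in gold:
        for p in by_canonical.get(normalize_outcome(g), []):
            mapping.add(g, p, "auto")
    return mapping


def threshold_pipeline(table: FrequencyTable, min_trials: int = DEFAULT_MIN_TRIALS) -> set[str]:
    """Canonical outcomes used in at least ``min_trials`` distinct trials."""
    if min_trials < 1:
        raise ValueError("min_trials must be >= 1")
    return {r.canonical_text for r in table.rows if r.trial_count >= min_trials}


def truncated_percent(fraction: float) -> int:
    """Integer percent by truncation: 0.925 → 92, 0.7917 → 79."""
    return math.floor(fraction * 100)


@dataclass
class EvalResult:
    """Matched/unmatched outcome sets on both sides, with the two metrics."""

    matched_gold: set[str]
    unmatched_gold: set[str]  # false negatives
    matched_pipeline: set[str]
    unmatched_pipeline: set[str]  # false positives
    recall: float
    precision: Optional[float]  # None when the pipeline set is empty
    min_trials_threshold: Optional[int] = None

    @property
    def recall_percent(self) -> int:
        return truncated_percent(self.recall)

    @property
    def precision_percent(self) -> Optional[int]:
        return None if self.precision is None else truncated_percent(self.precision)

    def to_dict(self) -> dict:
        return {
            "recall": round(self.recall, 4),
            "recall_percent": self.recall_percent,
            "precision": None if self.precision is None else round(self.precision, 4),
            "precision_percent": self.precision_percent,
            "matched_gold": sorted(self.matched_gold),
            "unmatched_gold": sorted(self.unmatched_gold),
            "matched_pipeline": sorted(self.matched_pipeline),
            "unmatched_pipeline": sorted(self.unmatched_pipeline),
            "min_trials_threshold": self.min_trials_threshold,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8"
        )

    def report_text(self) -> str:
        """Human-readable false-negative / false-positive listing."""
        lines = [
            f"recall    = {len(self.matched_gold)}/"
            f"{len(self.matched_gold) + len(self.unmatched_gold)}"
            f" = {self.recall:.4f} ({self.recall_percent}%)",
        ]
        n_pipe = len(self.matched_pipeline) + len(self.unmatched_pipeline)
        if self.precision is None:
            lines.append("precision = undefined (empty pipeline set)")
        else:
            lines.append(
                f"precision = {len(self.matched_pipeline)}/{n_pipe}"
                f" = {self.precision:.4f} ({self.precision_percent}%)"
            )
        lines.append("")
        lines.append("Gold outcomes without a pipeline equivalent (FN):")
        lines.extend(f"  - {o}" for o in sorted(self.unmatched_gold))
        lines.append("Pipeline outcomes without a gold equivalent (FP):")
        lines.extend(f"  - {o}" for o in sorted(self.unmatched_pipeline))
        return "\n".join(lines) + "\n"


def evaluate(
    gold: GoldStandard,
    pipeline_set: set[str],
    mapping: EquivalenceMap,
    *,
    min_trials_threshold: Optional[int] = None,
) -> EvalResult:
    """Score the thresholded pipeline set against the gold standard.

    Only mapping pairs whose members exist in the respective lists count.
    Precision is undefined (None) for an empty pipeline set.
    """
    gold_set = set(gold.outcomes)
    active = {(g, p) for g, p in mapping.pairs
              if g in gold_set and p in pipeline_set}
    matched_gold = {g for g, _ in active}
    matched_pipeline = {p for _, p in active}
    recall = len(matched_gold) / len(gold_set)
    precision = (
        len(matched_pipeline) / len(pipeline_set) if pipeline_set else None
    )
    return EvalResult(
        matched_gold=matched_gold,
        unmatched_gold=gold_set - matched_gold,
        matched_pipeline=matched_pipeline,
        unmatched_pipeline=set(pipeline_set) - matched_pipeline,
        recall=recall,
        precision=precision,
        min_trials_threshold=min_trials_threshold,
    )
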