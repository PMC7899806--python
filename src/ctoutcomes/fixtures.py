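"""Synthetic offline registry with a known ground-truth outcome distribution.

Real registry numbers drift as new trials are registered, so correctness is
checked against a generated corpus instead: a directory of per-term search
CSVs and per-trial XML records in the legacy dialect, built from an explicit
specification of which canonical outcome appears in how many trials. The
generator perturbs each planted outcome into a surface variant (case
shuffling, an appended initialism, inserted punctuation, padded whitespace)
that is guaranteed — by a round-trip check through the normalizer — to map
back to its canonical form, so the ground-truth frequency tables the
pipeline must recover are known exactly and unambiguously.

Realism is limited to structural dialect fidelity; no attempt is made to
mimic real disease-specific outcome vocabularies.
"""

from __future__ import annotations

import json
import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .normalize import (
    FrequencyRow,
    FrequencyTable,
    SCOPE_CATEGORIES,
    normalize_outcome,
)
from .records import CATEGORIES
from .sources import PAGE_SIZE_CAP, _term_filename

VARIANT_STYLES = (
    "case_shuffle",
    "add_abbreviation",
    "add_punctuation",
    "pad_whitespace",
)

#: Fraction of trials listing no outcomes; real registries sit near 3-4%.
DEFAULT_FRACTION_WITHOUT_OUTCOMES = 0.037

_MAX_VARIANT_RETRIES = 5


@dataclass(frozen=True)
class OutcomeSpec:
    """One planted canonical outcome: text, category, target trial count."""

    canonical: str
    category: str
    frequency: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")
        if normalize_outcome(self.canonical) != self.canonical:
            raise ValueError(
                f"canonical text must be in normalized form: {self.canonical!r}"
            )


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of a synthetic registry corpus.

    ``term_membership`` maps each query term either to an explicit list of
    trial indices (0-based) or to a coverage fraction in (0, 1]; the union
    of all term subsets must cover every trial, or some trials would be
    unreachable by any search.
    """

    seed: int
    n_trials: int
    outcomes: tuple[OutcomeSpec, ...]
    term_membership: Mapping[str, object] = field(
        default_factory=lambda: {"condition": 1.0}
    )
    variant_styles: tuple[str, ...] = VARIANT_STYLES
    fraction_without_outcomes: float = DEFAULT_FRACTION_WITHOUT_OUTCOMES
    page_size: int = PAGE_SIZE_CAP

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.fraction_without_outcomes < 1.0:
            raise ValueError("fraction_without_outcomes must be in [0, 1)")
        if not 1 <= self.page_size <= PAGE_SIZE_CAP:
            raise ValueError(f"page_size must be in [1, {PAGE_SIZE_CAP}]")
        unknown = set(self.variant_styles) - set(VARIANT_STYLES)
        if unknown:
            raise ValueError(f"unknown variant styles: {unknown}")
        canonicals = [o.canonical for o in self.outcomes]
        if len(set(canonicals)) != len(canonicals):
            raise ValueError("canonical outcome texts must be distinct")
        n_without = round(self.n_trials * self.fraction_without_outcomes)
        eligible = self.n_trials - n_without
        for o in self.outcomes:
            if o.frequency > eligible:
                raise ValueError(
                    f"{o.canonical!r} frequency {o.frequency} exceeds the "
                    f"{eligible} trials eligible to carry outcomes"
                )


def load_fixture_spec(path: str | Path) -> FixtureSpec:
    """Read a fixture specification from YAML."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    outcomes = tuple(
        OutcomeSpec(o["canonical"], o["category"], int(o["frequency"]))
        for o in data["outcomes"]
    )
    return FixtureSpec(
        seed=int(data["seed"]),
        n_trials=int(data["n_trials"]),
        outcomes=outcomes,
        term_membership=data.get("term_membership", {"condition": 1.0}),
        variant_styles=tuple(data.get("variant_styles", VARIANT_STYLES)),
        fraction_without_outcomes=float(
            data.get("fraction_without_outcomes", DEFAULT_FRACTION_WITHOUT_OUTCOMES)
        ),
        page_size=int(data.get("page_size", PAGE_SIZE_CAP)),
    )


def _case_shuffle(canonical: str, rng: random.Random) -> str:
    return "".join(
        ch.upper() if rng.random() < 0.5 else ch for ch in canonical
    )


def _initialism(canonical: str) -> Optional[str]:
    initials = [w[0] for w in canonical.split()]
    if len(initials) < 2:
        return None
    return "".join(initials).upper()


def _add_abbreviation(canonical: str, rng: random.Random) -> str:
    abbr = _initialism(canonical)
    if abbr is None:
        return canonical
    open_b, close_b = rng.choice(["()", "[]"])
    return f"{canonical} {open_b}{abbr}{close_b}"


def _add_punctuation(canonical: str, rng: random.Random) -> str:
    words = canonical.split()
    text = canonical
    if len(words) > 1 and rng.random() < 0.7:
        i = rng.randrange(len(words) - 1)
        sep = rng.choice([", ", " - ", ": ", "/"])
        text = " ".join(words[: i + 1]) + sep + " ".join(words[i + 1:])
    if rng.random() < 0.5:
        text = text + "."
    return text


def _pad_whitespace(canonical: str, rng: random.Random) -> str:
    text = canonical
    if " " in text and rng.random() < 0.7:
        i = rng.randrange(text.count(" ")) + 1
        parts = text.split(" ")
        text = " ".join(parts[:i]) + "  " + " ".join(parts[i:])
    return " " * rng.randint(0, 2) + text + " " * rng.randint(0, 2)


_STYLE_FUNCS = {
    "case_shuffle": _case_shuffle,
    "add_abbreviation": _add_abbreviation,
    "add_punctuation": _add_punctuation,
    "pad_whitespace": _pad_whitespace,
}


def make_variants(canonical: str, style: str, seed: int) -> str:
    """A surface variant of ``canonical`` guaranteed to normalize back to it.

    Each generated candidate is round-tripped through the normalizer; on
    failure generation retries with a perturbed seed, and after a bounded
    number of failures the canonical itself is returned unchanged.
    """
    func = _STYLE_FUNCS[style]
    for attempt in range(_MAX_VARIANT_RETRIES):
        rng = random.Random(f"{seed}:{attempt}")
        candidate = func(canonical, rng)
        if normalize_outcome(candidate) == canonical:
            return candidate
    return canonical


@dataclass
class GroundTruth:
    """Exactly what the pipeline must recover from a generated corpus."""

    n_trials: int
    nct_ids: tuple[str, ...]
    per_term: dict[str, tuple[str, ...]]  # term → ordered matching NCTs
    #: scope → canonical text → sorted tuple of NCTs carrying it
    tables: dict[str, dict[str, tuple[str, ...]]]
    trials_with_outcomes: tuple[str, ...]

    def expected_table(self, scope: str) -> FrequencyTable:
        rows = [
            FrequencyRow(text, len(ncts), tuple(ncts))
            for text, ncts in self.tables[scope].items()
        ]
        rows.sort(key=lambda r: (-r.trial_count, r.canonical_text))
        return FrequencyTable(scope=scope, rows=tuple(rows))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_trials": self.n_trials,
            "nct_ids": list(self.nct_ids),
            "per_term": {t: list(v) for t, v in self.per_term.items()},
            "tables": {
                scope: {text: list(ncts) for text, ncts in table.items()}
                for scope, table in self.tables.items()
            },
            "trials_with_outcomes": list(self.trials_with_outcomes),
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def _resolve_membership(
    spec: FixtureSpec, rng: random.Random
) -> dict[str, list[int]]:
    membership: dict[str, list[int]] = {}
    for term, value in spec.term_membership.items():
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            if not 0.0 < float(value) <= 1.0:
                raise ValueError(f"coverage fraction for {term!r} not in (0, 1]")
            k = max(1, round(spec.n_trials * float(value)))
            indices = sorted(rng.sample(range(spec.n_trials), k))
        else:
            indices = sorted(int(i) for i in value)  # type: ignore[union-attr]
            if indices and (indices[0] < 0 or indices[-1] >= spec.n_trials):
                raise ValueError(f"trial index out of range for term {term!r}")
        membership[term] = indices
    covered = set().union(*membership.values()) if membership else set()
    if covered != set(range(spec.n_trials)):
        missing = sorted(set(range(spec.n_trials)) - covered)[:5]
        raise ValueError(
            f"term membership leaves trials unreachable (e.g. {missing})"
        )
    return membership


def _trial_xml(nct_id: str, planted: Sequence[tuple[str, str]],
               rng: random.Random) -> str:
    root = ET.Element("clinical_study")
    id_info = ET.SubElement(root, "id_info")
    ET.SubElement(id_info, "nct_id").text = nct_id
    ET.SubElement(root, "brief_title").text = f"Synthetic study {nct_id}"
    ET.SubElement(root, "overall_status").text = "Completed"
    for category, surface in planted:
        node = ET.SubElement(root, f"{category}_outcome")
        ET.SubElement(node, "measure").text = surface
        if rng.random() < 0.7:
            ET.SubElement(node, "time_frame").text = (
                f"{rng.choice([4, 8, 12, 24, 52])} weeks"
            )
        if rng.random() < 0.4:
            ET.SubElement(node, "description").text = (
                f"Assessment of {normalize_outcome(surface)}."
            )
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def generate_registry(
    spec: FixtureSpec, out_dir: str | Path
) -> GroundTruth:
    """Write a corpus directory and return its ground truth.

    Layout: ``search/<term>.chunk<k>.csv``, ``records/<NCT>.xml`` and
    ``ground_truth.json``. Fully deterministic given ``spec.seed`` — the same
    spec writes byte-identical corpora. The spec is validated (and the
    membership resolved) before any file is written.
    """
    rng = random.Random(spec.seed)
    membership = _resolve_membership(spec, rng)

    start = rng.randrange(1, 99_000_000 - spec.n_trials)
    nct_ids = tuple(f"NCT{start + i:08d}" for i in range(spec.n_trials))

    n_without = round(spec.n_trials * spec.fraction_without_outcomes)
    without_outcomes = set(rng.sample(range(spec.n_trials), n_without))
    eligible = [i for i in range(spec.n_trials) if i not in without_outcomes]

    # plant each outcome in `frequency` distinct eligible trials
    planted: dict[int, list[tuple[str, str, str]]] = {i: [] for i in range(spec.n_trials)}
    assignment: dict[str, tuple[str, list[int]]] = {}
    for outcome in spec.outcomes:
        chosen = sorted(rng.sample(eligible, outcome.frequency))
        assignment[outcome.canonical] = (outcome.category, chosen)
        for trial_index in chosen:
            style = rng.choice(spec.variant_styles)
            surface = make_variants(
                outcome.canonical, style, rng.randrange(2**31)
            )
            planted[trial_index].append(
                (outcome.category, surface, outcome.canonical)
            )

    # every eligible trial must list at least one outcome, so the share of
    # trials without outcomes equals fraction_without_outcomes exactly: give
    # unreached eligible trials a unique filler outcome, recorded in the
    # ground truth like any planted one
    spec_canonicals = {o.canonical for o in spec.outcomes}
    for trial_index in eligible:
        if planted[trial_index]:
            continue
        canonical = f"study specific measure {trial_index:04d}"
        if canonical in spec_canonicals:  # pragma: no cover - defensive
            raise ValueError(f"spec'd canonical collides with filler {canonical!r}")
        category = rng.choice(CATEGORIES)
        assignment[canonical] = (category, [trial_index])
        style = rng.choice(spec.variant_styles)
        surface = make_variants(canonical, style, rng.randrange(2**31))
        planted[trial_index].append((category, surface, canonical))

    # cross-canonical collision guard: every surface form must normalize to
    # its own canonical and to no other spec'd canonical
    for trial_outcomes in planted.values():
        for _cat, surface, canonical in trial_outcomes:
            got = normalize_outcome(surface)
            if got != canonical:
                raise AssertionError(
                    f"variant {surface!r} normalizes to {got!r}, "
                    f"expected {canonical!r}"
                )

    out_dir = Path(out_dir)
    records_dir = out_dir / "records"
    search_dir = out_dir / "search"
    records_dir.mkdir(parents=True, exist_ok=True)
    search_dir.mkdir(parents=True, exist_ok=True)

    for i, nct_id in enumerate(nct_ids):
        xml_rng = random.Random(f"{spec.seed}:xml:{i}")
        entries = [(cat, surface) for cat, surface, _ in planted[i]]
        (records_dir / f"{nct_id}.xml").write_text(
            _trial_xml(nct_id, entries, xml_rng), encoding="utf-8"
        )

    for term, indices in membership.items():
        safe = _term_filename(term)
        for k in range(0, len(indices), spec.page_size):
            chunk = indices[k:k + spec.page_size]
            lines = ["Rank,NCT Number,Title,Status"]
            for rank, idx in enumerate(chunk, start=k + 1):
                lines.append(
                    f"{rank},{nct_ids[idx]},Synthetic study {nct_ids[idx]},"
                    "Completed"
                )
            chunk_no = k // spec.page_size + 1
            (search_dir / f"{safe}.chunk{chunk_no}.csv").write_text(
                "\n".join(lines) + "\n", encoding="utf-8"
            )

    tables: dict[str, dict[str, tuple[str, ...]]] = {}
    for scope, categories in SCOPE_CATEGORIES.items():
        table: dict[str, tuple[str, ...]] = {}
        for canonical, (category, chosen) in assignment.items():
            if category in categories:
                table[canonical] = tuple(nct_ids[i] for i in chosen)
        tables[scope] = table

    truth = GroundTruth(
        n_trials=spec.n_trials,
        nct_ids=nct_ids,
        per_term={
            term: tuple(nct_ids[i] for i in indices)
            for term, indices in membership.items()
        },
        tables=tables,
        trials_with_outcomes=tuple(
            nct_ids[i] for i in range(spec.n_trials)
            if planted[i]
        ),
    )
    truth.to_json(out_dir / "ground_truth.json")
    return truth
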