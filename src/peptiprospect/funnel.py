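"""Sequential exclusion screening of candidate peptides.

Digestion products are screened through an ordered funnel of threshold
filters on ingested predictor scores — cytotoxicity (SVM score, toxic above
0.0), bitterness (scoring-card score, bitter above 333), plasma stability
(predicted half-life, kept at or above 800 s) and intestinal stability
(half-life, kept above 1.0 s) — followed by allergen-motif and novelty
screens.  The funnel never computes predictor scores itself; it ingests
them as data.  Records missing a referenced score are quarantined rather
than silently passed: failing safe matters more than coverage here.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CandidateRecord",
    "FilterSpec",
    "FunnelStage",
    "FunnelReport",
    "apply_filter",
    "run_funnel",
    "default_filters",
    "novelty_screen",
    "allergen_screen",
    "load_sequence_set",
]

_COMPARATORS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
}


@dataclass(frozen=True)
class CandidateRecord:
    """A peptide with its ingested screening scores."""

    peptide_id: str
    sequence: str
    source_accession: str = ""
    toxicity_score: float | None = None
    bitterness_score: float | None = None
    plasma_half_life_s: float | None = None
    intestinal_half_life_s: float | None = None
    stability_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"candidate {self.peptide_id!r} has an empty sequence")
        for name in ("plasma_half_life_s", "intestinal_half_life_s"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} of {self.peptide_id!r} is negative")


@dataclass(frozen=True)
class FilterSpec:
    """One threshold filter.

    ``action`` is ``"keep"`` (retain records where the comparison is true)
    or ``"exclude"`` (drop them).  Strictness of the comparator matters at
    the boundaries: a bitterness score of exactly 333 is non-bitter, a
    plasma half-life of exactly 800 s is kept.
    """

    name: str
    field: str
    comparator: str
    threshold: float
    action: str = "keep"

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.action not in ("keep", "exclude"):
            raise ValueError(f"action must be 'keep' or 'exclude', got {self.action!r}")
        if self.field not in CandidateRecord.__dataclass_fields__:
            raise ValueError(f"unknown candidate field {self.field!r}")


@dataclass(frozen=True)
class FunnelStage:
    name: str
    n_in: int
    n_kept: int
    excluded_ids: tuple[str, ...]
    quarantined_ids: tuple[str, ...] = ()


@dataclass
class FunnelReport:
    """Stage-by-stage accounting; the narrative of a screen is these counts."""

    stages: list[FunnelStage] = field(default_factory=list)

    @property
    def survivor_count(self) -> int:
        return self.stages[-1].n_kept if self.stages else 0

    def as_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "input": s.n_in,
                    "kept": s.n_kept,
                    "excluded": list(s.excluded_ids),
                    "quarantined": list(s.quarantined_ids),
                }
                for s in self.stages
            ],
            "survivors": self.survivor_count,
        }


def apply_filter(
    records: Sequence[CandidateRecord], spec: FilterSpec
) -> tuple[list[CandidateRecord], list[CandidateRecord], list[CandidateRecord]]:
    """Partition records into (kept, removed, quarantined), order-preserving.

    Records whose referenced score is missing (None) are quarantined: a
    screen must never pass a peptide it could not actually evaluate.
    """
    compare = _COMPARATORS[spec.comparator]
    kept: list[CandidateRecord] = []
    removed: list[CandidateRecord] = []
    quarantined: list[CandidateRecord] = []
    for record in records:
        value = getattr(record, spec.field)
        if value is None:
            quarantined.append(record)
            continue
        hit = compare(value, spec.threshold)
        retain = hit if spec.action == "keep" else not hit
        (kept if retain else removed).append(record)
    return kept, removed, quarantined


def run_funnel(
    records: Sequence[CandidateRecord], filters: Sequence[FilterSpec]
) -> tuple[list[CandidateRecord], FunnelReport]:
    """Apply filters sequentially, recording per-stage accounting.

    The filters are conjunctive, so the survivor *set* is invariant to their
    order; the order only attributes exclusions to stages.
    """
    if not filters:
        raise ValueError("at least one filter is required")
    report = FunnelReport()
    current = list(records)
    for spec in filters:
        kept, removed, quarantined = apply_filter(current, spec)
        report.stages.append(
            FunnelStage(
                name=spec.name,
                n_in=len(current),
                n_kept=len(kept),
                excluded_ids=tuple(r.peptide_id for r in removed),
                quarantined_ids=tuple(r.peptide_id for r in quarantined),
            )
        )
        current = kept
    return current, report


def default_filters() -> list[FilterSpec]:
    """The four stated screening thresholds, in funnel order."""
    return [
        FilterSpec("toxicity", "toxicity_score", ">", 0.0, action="exclude"),
        FilterSpec("bitterness", "bitterness_score", ">", 333.0, action="exclude"),
        FilterSpec("plasma_stability", "plasma_half_life_s", ">=", 800.0, action="keep"),
        FilterSpec(
            "intestinal_stability", "intestinal_half_life_s", ">", 1.0, action="keep"
        ),
    ]


def load_sequence_set(path: str | Path) -> set[str]:
    """Read a plain-text sequence set (one per line, '#' comments)."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read sequence set {path}: {exc}") from exc
    return {
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    }


def novelty_screen(
    peptides: Iterable[str], known_sets: Mapping[str, Iterable[str]]
) -> tuple[list[str], dict[str, list[str]]]:
    """Exact-sequence lookup against named known-peptide collections.

    Returns the novel peptides (input order preserved) and, for each known
    hit, the names of the collections that already record it.
    """
    sets = {name: {s.upper() for s in seqs} for name, seqs in known_sets.items()}
    novel: list[str] = []
    hits: dict[str, list[str]] = {}
    for peptide in peptides:
        matched = [name for name, seqs in sets.items() if peptide.upper() in seqs]
        if matched:
            hits[peptide] = matched
        else:
            novel.append(peptide)
    return novel, hits


def allergen_screen(
    peptides: Iterable[str], epitope_motifs: Sequence[str]
) -> dict[str, dict[str, list[str]]]:
    """Substring screen against allergenic epitope motifs.

    A peptide hits when it contains a motif, or is itself contained in one
    (a short digestion product inside a longer epitope is still a liability);
    the two directions are reported separately.
    """
    motifs = [m.upper() for m in epitope_motifs]
    if any(not m for m in motifs):
        raise ValueError("empty motif string in epitope list")
    hits: dict[str, dict[str, list[str]]] = {}
    for peptide in peptides:
        pep = peptide.upper()
        contains = [m for m in motifs if m in pep]
        within = [m for m in motifs if pep in m]
        if contains or within:
            hits[peptide] = {"contains_motif": contains, "within_motif": within}
    return hits
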