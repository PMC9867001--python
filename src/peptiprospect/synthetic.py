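"""Seeded synthetic data so every pipeline stage runs without downloads.

``random_proteome`` emulates input proteins (residue frequencies uniform by
default, lengths configurable); ``synth_scores`` attaches predictor scores
drawn around the value ranges seen in real candidate tables (toxicity SVM
scores near -0.8, bitterness near 300, plasma half-life near 835 s,
intestinal half-life near 1.5 s) and can deliberately plant records that
fail a given filter, so funnel tests have exactly known expected outcomes.
What the generator does *not* emulate: real residue usage biases, score
correlations between predictors, or any relationship between a sequence and
its scores — passing tests therefore exercise the machinery, not predictor
realism.

``oracle_digest`` is an independent naive re-implementation of the two
cleavage dialects — literal per-position rule tables, no code shared with
the digestion engine — used as the equivalence oracle in property tests.

All randomness flows through one explicitly seeded generator; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .digestion import AMINO_ACIDS, EnzymeSpec, PeptideFragment, ProteinRecord
from .funnel import CandidateRecord

__all__ = ["SyntheticSpec", "random_proteome", "synth_scores", "oracle_digest"]

_ALPHABET = sorted(AMINO_ACIDS)

#: (mean, sd) anchors spanning realistic candidate-table score ranges
_SCORE_ANCHORS = {
    "toxicity_score": (-0.8, 0.25),
    "bitterness_score": (300.0, 25.0),
    "plasma_half_life_s": (835.0, 25.0),
    "intestinal_half_life_s": (1.5, 0.3),
}

# value planted on the failing side of each default filter threshold
_FAILING_VALUES = {
    "toxicity_score": 0.5,
    "bitterness_score": 400.0,
    "plasma_half_life_s": 700.0,
    "intestinal_half_life_s": 0.5,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic proteome / score-table generators."""

    seed: int = 0
    n_proteins: int = 5
    mean_length: int = 200
    length_sd: float = 0.0
    residue_frequencies: Mapping[str, float] | None = None
    score_anchors: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_SCORE_ANCHORS)
    )
    #: per-filter fraction of records planted to fail that filter
    failing_fractions: Mapping[str, float] = field(default_factory=dict)

    def frequency_vector(self) -> np.ndarray:
        if self.residue_frequencies is None:
            return np.full(len(_ALPHABET), 1.0 / len(_ALPHABET))
        unknown = set(self.residue_frequencies) - set(_ALPHABET)
        if unknown:
            raise ValueError(f"non-canonical residue(s) in frequency table: {unknown}")
        vec = np.array([self.residue_frequencies.get(a, 0.0) for a in _ALPHABET])
        if (vec < 0).any() or not np.isclose(vec.sum(), 1.0):
            raise ValueError("residue frequencies must be non-negative and sum to 1")
        return vec / vec.sum()


def random_proteome(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Deterministic (per seed) random proteins."""
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequency_vector()
    records = []
    for i in range(spec.n_proteins):
        length = max(2, int(round(rng.normal(spec.mean_length, spec.length_sd))))
        seq = "".join(rng.choice(_ALPHABET, size=length, p=freqs))
        records.append(
            ProteinRecord(accession=f"SYN{i + 1:03d}", name="synthetic protein", sequence=seq)
        )
    return records


def synth_scores(
    peptides: Sequence[str], spec: SyntheticSpec
) -> tuple[list[CandidateRecord], dict[str, set[str]]]:
    """Score each peptide; plant known failures per filter.

    Returns the candidate records and the planting record: for each score
    field, the set of peptide_ids deliberately placed on the failing side
    of the corresponding default threshold.  Scores are truncated to
    plausible ranges (half-lives positive, bitterness non-negative).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[CandidateRecord] = []
    planted: dict[str, set[str]] = {name: set() for name in _SCORE_ANCHORS}
    n = len(peptides)
    fail_ids: dict[str, np.ndarray] = {}
    for name, fraction in spec.failing_fractions.items():
        if name not in _SCORE_ANCHORS:
            raise ValueError(f"unknown score field {name!r}")
        k = int(round(fraction * n))
        fail_ids[name] = rng.choice(n, size=k, replace=False)
    for i, sequence in enumerate(peptides):
        peptide_id = f"S{i + 1}"
        values: dict[str, float] = {}
        for name, (mean, sd) in spec.score_anchors.items():
            value = float(rng.normal(mean, sd))
            # clamp non-planted draws to the passing side of the default
            # thresholds so the planting record is the exact expected outcome
            if name == "toxicity_score":
                value = min(value, 0.0)
            elif name == "bitterness_score":
                value = min(max(value, 0.0), 333.0)
            elif name == "plasma_half_life_s":
                value = max(value, 800.0)
            elif name == "intestinal_half_life_s":
                value = max(value, 1.01)
            if name in fail_ids and i in fail_ids[name]:
                value = _FAILING_VALUES[name]
                planted[name].add(peptide_id)
            values[name] = value
        records.append(
            CandidateRecord(
                peptide_id=peptide_id,
                sequence=sequence,
                source_accession="SYN",
                stability_label="synthetic",
                **values,
            )
        )
    return records, planted


# --------------------------------------------------------------------------
# Independent digestion oracle: literal rule tables, windows checked by hand.
# Deliberately not built on SiteRule/EnzymeSpec matching.
# --------------------------------------------------------------------------


def _res(seq: str, idx: int) -> str | None:
    return seq[idx] if 0 <= idx < len(seq) else None


def _oracle_cuts_biopep(seq: str, enzyme: str) -> set[int]:
    cuts: set[int] = set()
    for i in range(1, len(seq)):
        p1, p1p = seq[i - 1], seq[i]
        if enzyme == "pepsin_ph_gt2":
            if p1 in "FLGYAEQTNKDM" or p1p in "VI":
                cuts.add(i)
        elif enzyme == "trypsin":
            if p1 in "KR" and not (p1 == "K" and p1p == "P"):
                cuts.add(i)
        elif enzyme == "chymotrypsin_A":
            if p1 in "FYWLNHM":
                if p1 in "YFLW" and p1p == "P":
                    continue
                if p1 == "W" and p1p == "M":
                    continue
                cuts.add(i)
        else:
            raise ValueError(enzyme)
    return cuts


def _oracle_cuts_expasy(seq: str, enzyme: str) -> set[int]:
    cuts: set[int] = set()
    for i in range(1, len(seq)):
        p4, p3, p2 = _res(seq, i - 4), _res(seq, i - 3), _res(seq, i - 2)
        p1, p1p, p2p = seq[i - 1], seq[i], _res(seq, i + 1)
        if enzyme == "trypsin":
            if p1 not in "RK":
                continue
            blocked = False
            if p1p == "P":
                blocked = True
                if (p1 == "K" and p2 == "W") or (p1 == "R" and p2 == "M"):
                    blocked = False
            if p1 == "K" and (p2, p1p) in {("D", "D"), ("C", "D"), ("C", "H"), ("C", "Y")}:
                blocked = True
            if p1 == "R" and (p2, p1p) in {("R", "H"), ("C", "K"), ("R", "R")}:
                blocked = True
            if not blocked:
                cuts.add(i)
        elif enzyme == "chymotrypsin_A":
            if p1 not in "FYWLMH":
                continue
            if p1p == "P":
                continue
            if p1 == "W" and p1p == "M":
                continue
            if p1 == "M" and p1p == "Y":
                continue
            if p1 == "H" and p1p in "DMW":
                continue
            cuts.add(i)
        elif enzyme == "pepsin_ph_gt2":
            # driver at P1'
            if p1p in "FLWY" and p1 not in "HKR" and p2 != "P" and p2p != "P":
                cuts.add(i)
            # driver at P1
            elif p1 in "FLWY" and p1p != "P" and p2 != "P" and p3 != "R":
                cuts.add(i)
        else:
            raise ValueError(enzyme)
    return cuts


def oracle_digest(
    sequence: str, specs: Sequence[EnzymeSpec]
) -> list[PeptideFragment]:
    """Naive reference digestion used only to cross-check the engine."""
    cuts: set[int] = set()
    dialect = specs[0].dialect if specs else ""
    for spec in specs:
        if spec.dialect == "BIOPEP":
            cuts |= _oracle_cuts_biopep(sequence, spec.enzyme_id)
        elif spec.dialect == "EXPASY":
            cuts |= _oracle_cuts_expasy(sequence, spec.enzyme_id)
        else:
            raise ValueError(spec.dialect)
    bounds = [0, *sorted(cuts), len(sequence)]
    return [
        PeptideFragment(
            parent_accession="",
            start=a,
            end=b,
            sequence=sequence[a:b],
            dialect=dialect,
        )
        for a, b in zip(bounds, bounds[1:])
    ]
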