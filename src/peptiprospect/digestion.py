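"""Rule-based simulation of gastrointestinal proteolysis.

Two public web platforms encode the specificity of the same digestive
proteases (pepsin pH > 2, trypsin, chymotrypsin A) differently; each encoding
is treated here as a *dialect* of cleavage rules.  A compiled
:class:`EnzymeSpec` carries positional rules in Schechter–Berger notation:
a cut between residues P1 and P1' happens when the P1 (or P1') residue is in
the enzyme's cleavable set, unless a blocking context pattern over the
P4..P2' window matches (and is not re-enabled by an override pattern).

Digestion is simultaneous and exhaustive: the cut-site sets of all enzymes
of one dialect are unioned and the sequence split at every site, which is how
both source platforms behave in a single multi-enzyme run.  Partial digests
and missed cleavages are out of scope, as is any conformational shielding of
cleavage sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "AMINO_ACIDS",
    "DIALECTS",
    "ENZYME_IDS",
    "ProteinRecord",
    "SiteRule",
    "EnzymeSpec",
    "PeptideFragment",
    "PooledDigest",
    "UnknownTagError",
    "NonCanonicalResidueError",
    "DialectMismatchError",
    "compile_ruleset",
    "find_cut_sites",
    "codigest",
    "digest_proteome",
    "length_filter",
    "fragment_consistency",
]

#: the 20 canonical one-letter amino-acid codes
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

DIALECTS = ("BIOPEP", "EXPASY")
ENZYME_IDS = ("pepsin_ph_gt2", "trypsin", "chymotrypsin_A")

# window position -> index offset relative to a cut at position i
# (the cut lies between sequence indices i-1 and i)
_WINDOW_OFFSETS: Mapping[str, int] = {
    "P4": -4,
    "P3": -3,
    "P2": -2,
    "P1": -1,
    "P1prime": 0,
    "P2prime": 1,
}

_RULE_FILES = {
    "BIOPEP": "rules_biopep.yaml",
    "EXPASY": "rules_expasy.yaml",
}


class UnknownTagError(ValueError):
    """An unrecognized dialect or enzyme tag was requested."""


class NonCanonicalResidueError(ValueError):
    """A sequence contains a residue outside the 20-letter alphabet."""


class DialectMismatchError(ValueError):
    """Enzyme specs from different dialects were mixed in one digestion."""


def _check_sequence(sequence: str, permissive: bool, context: str = "sequence") -> None:
    bad = sorted(set(sequence) - AMINO_ACIDS)
    if bad and not permissive:
        raise NonCanonicalResidueError(
            f"{context} contains non-canonical residue(s) {''.join(bad)!r}; "
            "pass permissive=True to treat them as matching no rule"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein to digest, identified by its database accession."""

    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class SiteRule:
    """One positional cleavage rule.

    The rule fires at a candidate cut when the P1 residue is in
    ``p1_residues`` or the P1' residue is in ``p1prime_residues``.  Each
    exception is a mapping of window positions to residue sets that blocks
    the cut when *all* listed positions match; an override re-enables a
    blocked cut the same way.  Window positions outside the sequence never
    match (so an out-of-range blocker cannot block).
    """

    p1_residues: frozenset[str] = frozenset()
    p1prime_residues: frozenset[str] = frozenset()
    exceptions: tuple[Mapping[str, frozenset[str]], ...] = ()
    exception_overrides: tuple[Mapping[str, frozenset[str]], ...] = ()

    def __post_init__(self) -> None:
        for pattern in (*self.exceptions, *self.exception_overrides):
            unknown = set(pattern) - set(_WINDOW_OFFSETS)
            if unknown:
                raise ValueError(f"unknown window position(s) {sorted(unknown)}")

    def matches(self, sequence: str, i: int) -> bool:
        """True iff this rule produces a cut between indices i-1 and i."""
        if not (
            sequence[i - 1] in self.p1_residues
            or sequence[i] in self.p1prime_residues
        ):
            return False
        blocked = any(
            _pattern_matches(sequence, i, pattern) for pattern in self.exceptions
        )
        if blocked and any(
            _pattern_matches(sequence, i, pattern)
            for pattern in self.exception_overrides
        ):
            blocked = False
        return not blocked


def _pattern_matches(
    sequence: str, i: int, pattern: Mapping[str, frozenset[str]]
) -> bool:
    for position, residues in pattern.items():
        idx = i + _WINDOW_OFFSETS[position]
        if idx < 0 or idx >= len(sequence) or sequence[idx] not in residues:
            return False
    return True


@dataclass(frozen=True)
class EnzymeSpec:
    """A compiled cleavage-rule grammar for one protease under one dialect."""

    enzyme_id: str
    ec_number: str
    dialect: str
    rules: tuple[SiteRule, ...]
    name: str = ""


@dataclass(frozen=True)
class PeptideFragment:
    """A digestion product with parent coordinates (0-based, half-open)."""

    parent_accession: str
    start: int
    end: int
    sequence: str
    dialect: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid fragment coordinates [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("fragment sequence length does not match coordinates")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PooledDigest:
    """Fragments pooled across proteins and dialects, with summary counts.

    ``total_fragments`` counts fragment occurrences of length >= 2 across all
    proteins and dialects, before deduplication (the headline number both
    source platforms report); ``length_histogram`` includes single residues
    so either counting convention can be reconstructed.
    """

    fragments: list[PeptideFragment]
    unique_sequences: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.unique_sequences:
            for frag in self.fragments:
                self.unique_sequences.setdefault(frag.sequence, set()).add(
                    (frag.parent_accession, frag.dialect)
                )

    @property
    def total_fragments(self) -> int:
        return sum(1 for f in self.fragments if len(f) >= 2)

    @property
    def unique_sequence_count(self) -> int:
        return len(self.unique_sequences)

    @property
    def length_histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(len(f) for f in self.fragments).items()))

    @property
    def max_fragment_length(self) -> int:
        return max((len(f) for f in self.fragments), default=0)


def _load_dialect_rules(dialect: str, rules_path: str | Path | None = None) -> dict:
    if rules_path is not None:
        raw = yaml.safe_load(Path(rules_path).read_text())
    else:
        if dialect not in _RULE_FILES:
            raise UnknownTagError(
                f"unknown dialect {dialect!r}; expected one of {DIALECTS}"
            )
        from importlib.resources import files

        raw = yaml.safe_load(
            (files("peptiprospect.data") / _RULE_FILES[dialect]).read_text()
        )
    return raw


def _as_pattern(mapping: Mapping[str, Sequence[str]]) -> dict[str, frozenset[str]]:
    return {pos: frozenset(res) for pos, res in mapping.items()}


def compile_ruleset(
    dialect: str,
    enzyme_ids: Sequence[str] | None = None,
    *,
    chymotrypsin_h_at_p1: bool = True,
    rules_path: str | Path | None = None,
) -> list[EnzymeSpec]:
    """Compile the built-in (or user-supplied) rule file into enzyme specs.

    Parameters
    ----------
    dialect:
        ``"BIOPEP"`` or ``"EXPASY"`` (case-insensitive).
    enzyme_ids:
        Enzymes to compile, default all three digestive enzymes.
    chymotrypsin_h_at_p1:
        The ExPASy chymotrypsin entry states blocking contexts for histidine
        at P1, implying H is cleavable; set False to restrict the P1 set to
        the five-residue {F, Y, W, L, M} reading.
    rules_path:
        Optional path to a rule file in the packaged YAML schema.
    """
    dialect = dialect.upper()
    raw = _load_dialect_rules(dialect, rules_path)
    if raw.get("dialect", dialect).upper() != dialect:
        raise DialectMismatchError(
            f"rule file declares dialect {raw.get('dialect')!r}, not {dialect!r}"
        )
    available = raw["enzymes"]
    if enzyme_ids is None:
        enzyme_ids = list(available)
    specs = []
    for enzyme_id in enzyme_ids:
        if enzyme_id not in available:
            raise UnknownTagError(
                f"unknown enzyme {enzyme_id!r} for dialect {dialect}; "
                f"available: {sorted(available)}"
            )
        entry = available[enzyme_id]
        rules = []
        for rule in entry.get("rules", []):
            p1 = set(rule.get("p1", []))
            if (
                enzyme_id == "chymotrypsin_A"
                and dialect == "EXPASY"
                and not chymotrypsin_h_at_p1
            ):
                p1.discard("H")
            rules.append(
                SiteRule(
                    p1_residues=frozenset(p1),
                    p1prime_residues=frozenset(rule.get("p1_prime", [])),
                    exceptions=tuple(
                        _as_pattern(p) for p in rule.get("exceptions", [])
                    ),
                    exception_overrides=tuple(
                        _as_pattern(p) for p in rule.get("overrides", [])
                    ),
                )
            )
        specs.append(
            EnzymeSpec(
                enzyme_id=enzyme_id,
                ec_number=str(entry["ec_number"]),
                dialect=dialect,
                rules=tuple(rules),
                name=entry.get("name", enzyme_id),
            )
        )
    return specs


def find_cut_sites(
    sequence: str, spec: EnzymeSpec, *, permissive: bool = False
) -> list[int]:
    """Cut positions of one enzyme on ``sequence``, sorted ascending.

    A cut at position ``i`` separates residues ``i-1`` and ``i``
    (``1 <= i <= len(sequence) - 1``).  Sequences shorter than two residues
    have no internal bond and yield an empty list.
    """
    _check_sequence(sequence, permissive)
    if len(sequence) < 2:
        return []
    return [
        i
        for i in range(1, len(sequence))
        if any(rule.matches(sequence, i) for rule in spec.rules)
    ]


def _union_cut_sites(
    sequence: str, specs: Sequence[EnzymeSpec], permissive: bool
) -> list[int]:
    sites: set[int] = set()
    for spec in specs:
        sites.update(find_cut_sites(sequence, spec, permissive=permissive))
    return sorted(sites)


def codigest(
    sequence: str,
    specs: Sequence[EnzymeSpec],
    *,
    parent_accession: str = "",
    permissive: bool = False,
) -> list[PeptideFragment]:
    """Simultaneous exhaustive digestion by all enzymes of one dialect.

    The cut-site set is the union over enzymes; fragments are the maximal
    substrings between consecutive cuts, reported N- to C-terminally.  The
    concatenation of the fragment sequences always reproduces the input.
    """
    if not specs:
        raise ValueError("at least one enzyme spec is required")
    dialects = {spec.dialect for spec in specs}
    if len(dialects) > 1:
        raise DialectMismatchError(
            f"specs mix dialects {sorted(dialects)}; digest per dialect and pool"
        )
    dialect = specs[0].dialect
    cuts = _union_cut_sites(sequence, specs, permissive)
    bounds = [0, *cuts, len(sequence)]
    return [
        PeptideFragment(
            parent_accession=parent_accession,
            start=start,
            end=end,
            sequence=sequence[start:end],
            dialect=dialect,
        )
        for start, end in zip(bounds, bounds[1:])
    ]


def digest_proteome(
    records: Sequence[ProteinRecord],
    dialects: Sequence[str] = DIALECTS,
    *,
    enzyme_ids: Sequence[str] | None = None,
    permissive: bool = False,
    **compile_kwargs,
) -> PooledDigest:
    """Digest every protein under every requested dialect and pool the output."""
    if not records:
        raise ValueError("no protein records supplied")
    seen: Counter[str] = Counter(r.accession for r in records)
    duplicates = sorted(acc for acc, n in seen.items() if n > 1)
    if duplicates:
        raise ValueError(f"duplicate accession(s): {duplicates}")
    fragments: list[PeptideFragment] = []
    for dialect in dialects:
        specs = compile_ruleset(dialect, enzyme_ids, **compile_kwargs)
        for record in records:
            fragments.extend(
                codigest(
                    record.sequence,
                    specs,
                    parent_accession=record.accession,
                    permissive=permissive,
                )
            )
    return PooledDigest(fragments=fragments)


def length_filter(
    digest: PooledDigest, min_len: int, max_len: int
) -> dict[str, set[tuple[str, str]]]:
    """Unique sequences with length in [min_len, max_len], with provenance."""
    if not 1 <= min_len <= max_len:
        raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
    return {
        seq: set(prov)
        for seq, prov in digest.unique_sequences.items()
        if min_len <= len(seq) <= max_len
    }


def fragment_consistency(
    peptide: str, specs: Sequence[EnzymeSpec], *, permissive: bool = False
) -> bool:
    """Whether ``peptide`` is a plausible exhaustive-digestion product.

    True iff no internal position is an unambiguous cut site under the union
    of ``specs``.  Because the parent context of a free peptide is unknown,
    only constraints whose window lies inside the fragment are judged:
    blocking patterns reaching outside the fragment are treated as unknown
    and do not block (this is exactly how the rule engine treats
    out-of-range window positions).
    """
    if not peptide:
        raise ValueError("empty peptide")
    return not _union_cut_sites(peptide, specs, permissive)
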