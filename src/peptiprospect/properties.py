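"""Sequence-derived physicochemical descriptors of peptides.

Used to examine composition and property trends of shortlisted peptides:
ACE-inhibitory peptides tend to carry C-terminal proline / hydrophobic /
aromatic / branched / positively charged residues; antimicrobial and
anticancer peptides tend to be cationic and hydrophobic, the latter often
cysteine-rich.  The descriptors are deliberately simple and integer-valued
where possible: net charge is +1 per K/R and -1 per D/E (histidine neutral),
hydrophobicity is the fraction of residues in a configurable hydrophobic
set (default: the Kyte–Doolittle-positive residues A, V, I, L, M, F, W, C).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digestion import AMINO_ACIDS, NonCanonicalResidueError

__all__ = [
    "HYDROPHOBIC_DEFAULT",
    "RESIDUE_CLASSES",
    "DescriptorSet",
    "descriptors",
    "trend_summary",
]

HYDROPHOBIC_DEFAULT = frozenset("AVILMFWC")

#: residue class taxonomy used to tag terminal residues
RESIDUE_CLASSES: Mapping[str, frozenset[str]] = {
    "hydrophobic": HYDROPHOBIC_DEFAULT,
    "aromatic": frozenset("FWY"),
    "branched": frozenset("VLI"),
    "positively_charged": frozenset("KRH"),
    "proline": frozenset("P"),
}

_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")


def _residue_classes(residue: str) -> tuple[str, ...]:
    return tuple(name for name, members in RESIDUE_CLASSES.items() if residue in members)


@dataclass(frozen=True)
class DescriptorSet:
    sequence: str
    length: int
    aa_composition: Mapping[str, float]
    dipeptide_composition: Mapping[str, float]
    net_charge: int
    hydrophobic_fraction: float
    n_terminal_residue: str
    n_terminal_classes: tuple[str, ...]
    c_terminal_residue: str
    c_terminal_classes: tuple[str, ...]
    proline_count: int
    cysteine_count: int


def descriptors(
    sequence: str, *, hydrophobic_set: frozenset[str] = HYDROPHOBIC_DEFAULT
) -> DescriptorSet:
    """Compute the full descriptor set for one peptide."""
    sequence = sequence.upper()
    bad = sorted(set(sequence) - AMINO_ACIDS)
    if not sequence:
        raise ValueError("empty sequence")
    if bad:
        raise NonCanonicalResidueError(f"non-canonical residue(s) {''.join(bad)!r}")
    n = len(sequence)
    aa_counts = Counter(sequence)
    dipeptides = Counter(sequence[i : i + 2] for i in range(n - 1))
    n_dip = max(n - 1, 1)
    return DescriptorSet(
        sequence=sequence,
        length=n,
        aa_composition={aa: aa_counts.get(aa, 0) / n for aa in sorted(AMINO_ACIDS)},
        dipeptide_composition={dp: c / n_dip for dp, c in sorted(dipeptides.items())},
        net_charge=sum(+1 for r in sequence if r in _POSITIVE)
        + sum(-1 for r in sequence if r in _NEGATIVE),
        hydrophobic_fraction=sum(1 for r in sequence if r in hydrophobic_set) / n,
        n_terminal_residue=sequence[0],
        n_terminal_classes=_residue_classes(sequence[0]),
        c_terminal_residue=sequence[-1],
        c_terminal_classes=_residue_classes(sequence[-1]),
        proline_count=aa_counts.get("P", 0),
        cysteine_count=aa_counts.get("C", 0),
    )


def trend_summary(
    classes: Mapping[str, Sequence[str]],
    *,
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_DEFAULT,
) -> pd.DataFrame:
    """Aggregate composition/property trends per labelled peptide class.

    One row per class (classes sorted by name): mean net charge, mean
    hydrophobic fraction, terminal-class frequencies, proline/cysteine
    prevalence.  Empty classes are reported with null statistics rather
    than dropped.
    """
    if not classes:
        raise ValueError("at least one class is required")
    rows = []
    for name in sorted(classes):
        peptides = list(classes[name])
        if not peptides:
            rows.append({"class": name, "n_peptides": 0})
            continue
        desc = [descriptors(p, hydrophobic_set=hydrophobic_set) for p in peptides]
        n = len(desc)
        row: dict[str, object] = {
            "class": name,
            "n_peptides": n,
            "mean_net_charge": sum(d.net_charge for d in desc) / n,
            "mean_hydrophobic_fraction": sum(d.hydrophobic_fraction for d in desc) / n,
            "proline_prevalence": sum(d.proline_count > 0 for d in desc) / n,
            "cysteine_prevalence": sum(d.cysteine_count > 0 for d in desc) / n,
        }
        for cls in RESIDUE_CLASSES:
            row[f"c_term_{cls}_freq"] = sum(cls in d.c_terminal_classes for d in desc) / n
            row[f"n_term_{cls}_freq"] = sum(cls in d.n_terminal_classes for d in desc) / n
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
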