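"""Per-bioactivity consensus shortlisting.

Five peptide bioactivity classes are shortlisted from ingested predictor
scores and peptide–receptor binding predictions:

* AHP (antihypertensive): SVM score > 1.0 plus predicted contact with *all*
  zinc-site residues of angiotensin-converting enzyme (H383, H387, E411 of
  PDB 1O86); optional bioavailability bounds when such scores are supplied.
* ADP (antidiabetic): scoring-card score >= 350 plus contact with at least
  two of the DPP-IV catalytic triad (S630, D708, H740 of PDB 2ONC).
* AIP (anti-inflammatory): positive by two independent predictors, ranked,
  top four.
* AMP (antimicrobial): a conjunction of three predictor cutoffs, with
  positives from a fourth platform appended.
* ACP (anticancer): positive cross-hits of three predictors, top three.

Binding predictions are ingested (e.g. from a peptide–protein docking or
surface-patch server); nothing here estimates binding energies.
"""

from __future__ import annotations

import math
import operator
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PREDICTOR_REGISTRY",
    "ACE_ACTIVE_SITE",
    "DPP4_CATALYTIC_TRIAD",
    "ScoreTable",
    "BindingPrediction",
    "ActiveSiteSpec",
    "ScorePredicate",
    "BindingPredicate",
    "ClassRule",
    "ShortlistReport",
    "binding_overlap",
    "select_class",
    "default_rules",
    "compile_shortlist",
]

#: predictors whose scores may appear in a ScoreTable
PREDICTOR_REGISTRY = (
    "AHTpin",
    "iDPPIV-SCM",
    "PreAIP",
    "AIPpred",
    "Antiinflam",
    "CAMP-SVM",
    "CAMP-RF",
    "ADAM",
    "DBAASP",
    "ACPred",
    "iDACP",
    "mACPpred",
    "HIA",
    "bioavailability",
)

_COMPARATORS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
    "==": operator.eq,
}


@dataclass(frozen=True)
class ActiveSiteSpec:
    """Residues an inhibitory peptide should contact on the receptor."""

    receptor_id: str
    required_residues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_residues:
            raise ValueError("active-site residue set must be non-empty")


#: zinc-ligand residues of human ACE (PDB 1O86)
ACE_ACTIVE_SITE = ActiveSiteSpec("1O86", frozenset({"H383", "H387", "E411"}))
#: catalytic triad of human DPP-IV (PDB 2ONC)
DPP4_CATALYTIC_TRIAD = ActiveSiteSpec("2ONC", frozenset({"S630", "D708", "H740"}))


@dataclass(frozen=True)
class BindingPrediction:
    """A receptor–peptide binding report with bound-residue sets."""

    sequence: str
    receptor_id: str
    p_value: float
    receptor_residues: frozenset[str]
    peptide_residues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        import re

        for label in self.receptor_residues | self.peptide_residues:
            if not re.fullmatch(r"[A-Z]\d+", label):
                raise ValueError(f"malformed residue label {label!r}")


def binding_overlap(
    prediction: BindingPrediction, site: ActiveSiteSpec
) -> tuple[int, bool]:
    """(number of required residues contacted, whether all are contacted)."""
    if prediction.receptor_id != site.receptor_id:
        raise ValueError(
            f"receptor mismatch: prediction is for {prediction.receptor_id!r}, "
            f"active site for {site.receptor_id!r}"
        )
    count = len(prediction.receptor_residues & site.required_residues)
    return count, count == len(site.required_residues)


class ScoreTable:
    """Peptide-by-predictor score matrix with optional positivity flags.

    Backed by a DataFrame indexed by sequence.  A column ``"<predictor>"``
    holds numeric scores (NaN = not evaluated); an optional column
    ``"<predictor>_positive"`` holds explicit binary calls.  Explicit flags
    take precedence over the generic score-above-0.5 positivity reading.
    """

    POSITIVITY_CUTOFF = 0.5

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValueError("duplicate peptide sequences in score table")
        base_cols = {c.removesuffix("_positive") for c in frame.columns}
        unknown = base_cols - set(PREDICTOR_REGISTRY)
        if unknown:
            raise ValueError(
                f"unknown predictor column(s) {sorted(unknown)}; "
                f"registry: {PREDICTOR_REGISTRY}"
            )
        self.frame = frame

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.frame.index

    @property
    def peptides(self) -> list[str]:
        return list(self.frame.index)

    def has_predictor(self, predictor: str) -> bool:
        return predictor in self.frame.columns

    def score(self, sequence: str, predictor: str) -> float | None:
        if predictor not in self.frame.columns:
            raise KeyError(f"predictor {predictor!r} not in score table")
        if sequence not in self.frame.index:
            return None
        value = self.frame.at[sequence, predictor]
        return None if pd.isna(value) else float(value)

    def is_positive(self, sequence: str, predictor: str) -> bool | None:
        """Explicit flag if present, else score > 0.5; None if unevaluated."""
        flag_col = f"{predictor}_positive"
        if flag_col not in self.frame.columns and not self.has_predictor(predictor):
            raise KeyError(f"predictor {predictor!r} not in score table")
        if flag_col in self.frame.columns and sequence in self.frame.index:
            flag = self.frame.at[sequence, flag_col]
            if not pd.isna(flag):
                return bool(int(flag))
        if not self.has_predictor(predictor):
            return None
        score = self.score(sequence, predictor)
        if score is None:
            return None
        return score > self.POSITIVITY_CUTOFF


@dataclass(frozen=True)
class ScorePredicate:
    predictor: str
    comparator: str
    threshold: float
    #: "strict" fails peptides with no score; "ignore" skips the predicate
    missing_policy: str = "strict"

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.missing_policy not in ("strict", "ignore"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")

    def holds(self, sequence: str, scores: ScoreTable) -> bool:
        if not scores.has_predictor(self.predictor):
            raise KeyError(f"predictor {self.predictor!r} not in score table")
        value = scores.score(sequence, self.predictor)
        if value is None:
            return self.missing_policy == "ignore"
        return _COMPARATORS[self.comparator](value, self.threshold)


@dataclass(frozen=True)
class BindingPredicate:
    site: ActiveSiteSpec
    min_overlap: int = 0
    require_full: bool = False

    def holds(self, sequence: str, bindings: Mapping[str, BindingPrediction]) -> bool:
        prediction = bindings.get(sequence)
        if prediction is None:
            return False
        count, full = binding_overlap(prediction, self.site)
        if self.require_full:
            return full
        return count >= self.min_overlap


@dataclass(frozen=True)
class ClassRule:
    """A per-bioactivity selection rule: predicates + ranking + top-k."""

    name: str
    score_predicates: tuple[ScorePredicate, ...] = ()
    positive_predictors: tuple[str, ...] = ()
    binding_predicate: BindingPredicate | None = None
    #: predicates applied only when their score column is supplied
    optional_score_predicates: tuple[ScorePredicate, ...] = ()
    #: peptides flagged positive by this predictor are appended regardless
    union_positive_predictor: str | None = None
    rank_by: str = ""
    top_k: int | None = None

    def __post_init__(self) -> None:
        if not (
            self.score_predicates
            or self.positive_predictors
            or self.binding_predicate
            or self.union_positive_predictor
        ):
            raise ValueError(f"class rule {self.name!r} has no predicate")


def _rank_key(sequence: str, scores: ScoreTable, rank_by: str) -> tuple:
    value = (
        scores.score(sequence, rank_by)
        if rank_by and scores.has_predictor(rank_by)
        else None
    )
    if value is None:
        value = -math.inf
    return (-value, sequence)  # descending score, lexicographic tie-break


def select_class(
    pool: Iterable[str],
    scores: ScoreTable,
    bindings: Sequence[BindingPrediction],
    rule: ClassRule,
) -> list[str]:
    """Peptides of ``pool`` satisfying every predicate of ``rule``, ranked.

    Ranking is descending by the rule's ranking predictor with lexicographic
    tie-break, truncated to ``top_k`` when set; the result is therefore
    invariant to the input ordering of the pool.
    """
    binding_by_seq = {}
    if rule.binding_predicate is not None:
        binding_by_seq = {
            b.sequence: b
            for b in bindings
            if b.receptor_id == rule.binding_predicate.site.receptor_id
        }

    applicable_optional = []
    for predicate in rule.optional_score_predicates:
        if scores.has_predictor(predicate.predictor):
            applicable_optional.append(predicate)
        else:
            warnings.warn(
                f"{rule.name}: score column {predicate.predictor!r} absent; "
                "skipping that predicate",
                stacklevel=2,
            )

    selected: list[str] = []
    for sequence in dict.fromkeys(pool):  # de-dupe, keep order until ranking
        ok = all(p.holds(sequence, scores) for p in rule.score_predicates)
        for predicate in applicable_optional:
            ok = ok and predicate.holds(sequence, scores)
        for predictor in rule.positive_predictors:
            ok = ok and bool(scores.is_positive(sequence, predictor))
        if ok and rule.binding_predicate is not None:
            ok = rule.binding_predicate.holds(sequence, binding_by_seq)
        if ok:
            selected.append(sequence)

    if rule.union_positive_predictor is not None:
        for sequence in dict.fromkeys(pool):
            if sequence not in selected and scores.is_positive(
                sequence, rule.union_positive_predictor
            ):
                selected.append(sequence)

    selected.sort(key=lambda s: _rank_key(s, scores, rule.rank_by))
    if rule.top_k is not None:
        selected = selected[: rule.top_k]
    return selected


def default_rules(
    *,
    adam_missing_policy: str = "ignore",
    ace_site: ActiveSiteSpec = ACE_ACTIVE_SITE,
    dpp4_site: ActiveSiteSpec = DPP4_CATALYTIC_TRIAD,
) -> list[ClassRule]:
    """The five built-in class rules.

    ``adam_missing_policy`` controls the AMP conjunction when no ADAM score
    is supplied ("ignore" reproduces published shortlists where the column
    is blank; "strict" demands the score).
    """
    return [
        ClassRule(
            name="AHP",
            score_predicates=(ScorePredicate("AHTpin", ">", 1.0),),
            binding_predicate=BindingPredicate(ace_site, require_full=True),
            optional_score_predicates=(
                ScorePredicate("HIA", "<", 30.0),
                ScorePredicate("bioavailability", "<", 20.0),
            ),
            rank_by="AHTpin",
        ),
        ClassRule(
            name="ADP",
            score_predicates=(ScorePredicate("iDPPIV-SCM", ">=", 350.0),),
            binding_predicate=BindingPredicate(dpp4_site, min_overlap=2),
            rank_by="iDPPIV-SCM",
        ),
        ClassRule(
            name="AIP",
            positive_predictors=("PreAIP", "Antiinflam"),
            rank_by="PreAIP",
            top_k=4,
        ),
        ClassRule(
            name="AMP",
            score_predicates=(
                ScorePredicate("CAMP-SVM", "==", 1.0),
                ScorePredicate("CAMP-RF", ">", 0.54),
                ScorePredicate("ADAM", ">", 2.0, missing_policy=adam_missing_policy),
            ),
            union_positive_predictor="DBAASP",
            rank_by="CAMP-RF",
        ),
        ClassRule(
            name="ACP",
            positive_predictors=("ACPred", "iDACP", "mACPpred"),
            rank_by="mACPpred",
            top_k=3,
        ),
    ]


@dataclass
class ShortlistReport:
    """Union of per-class selections with provenance and both totals."""

    selections: dict[str, list[str]] = field(default_factory=dict)

    @property
    def with_multiplicity(self) -> int:
        return sum(len(s) for s in self.selections.values())

    @property
    def distinct_peptides(self) -> list[str]:
        seen: dict[str, None] = {}
        for selection in self.selections.values():
            for sequence in selection:
                seen.setdefault(sequence)
        return list(seen)

    @property
    def classes_by_peptide(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cls, selection in self.selections.items():
            for sequence in selection:
                out.setdefault(sequence, []).append(cls)
        return out

    def as_dict(self) -> dict:
        return {
            "per_class": {k: list(v) for k, v in self.selections.items()},
            "distinct": self.distinct_peptides,
            "total_with_multiplicity": self.with_multiplicity,
            "total_distinct": len(self.distinct_peptides),
        }


def compile_shortlist(selections: Mapping[str, Sequence[str]]) -> ShortlistReport:
    """Assemble per-class selections into one report."""
    return ShortlistReport({cls: list(sel) for cls, sel in selections.items()})
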