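"""Readers and writers for the pipeline's interchange formats.

FASTA goes through Biopython; tabular interchange is tab-separated UTF-8
text with a mandatory header row and '.' decimal point, so that writing and
re-reading any table reproduces the in-memory data exactly.  A structured
JSON summary accompanies the delimited funnel report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .digestion import PeptideFragment, PooledDigest, ProteinRecord
from .funnel import CandidateRecord, FunnelReport

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_candidates",
    "write_candidates",
    "write_fragments",
    "read_fragments",
    "write_histogram",
    "write_funnel_report",
    "PipelineConfig",
    "load_config",
    "fetch_reference_proteome",
]

log = logging.getLogger("peptiprospect")

_CANDIDATE_COLUMNS = [f.name for f in dataclass_fields(CandidateRecord)]
_FRAGMENT_COLUMNS = ["accession", "start", "end", "length", "sequence", "dialect"]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA; the description line is "accession name"."""
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sequence = str(rec.seq).upper()
        if not sequence:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate accession {rec.id!r} in {path}")
        seen.add(rec.id)
        name = rec.description[len(rec.id) :].strip()
        records.append(ProteinRecord(accession=rec.id, name=name, sequence=sequence))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord] | Sequence[str], path: str | Path) -> None:
    """Write proteins, or bare peptide sequences, as FASTA."""
    path = Path(path)
    with path.open("w") as handle:
        for i, rec in enumerate(records, start=1):
            if isinstance(rec, ProteinRecord):
                header = f"{rec.accession} {rec.name}".strip()
                handle.write(f">{header}\n{rec.sequence}\n")
            else:
                handle.write(f">pep{i}\n{rec}\n")


def write_candidates(records: Sequence[CandidateRecord], path: str | Path) -> None:
    frame = pd.DataFrame([asdict(r) for r in records], columns=_CANDIDATE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[CandidateRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"peptide_id": str})
    missing = set(_CANDIDATE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"candidate table {path} lacks column(s) {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        kwargs = {}
        for name in _CANDIDATE_COLUMNS:
            value = getattr(row, name)
            if pd.isna(value):
                value = None if name.endswith(("_score", "_s")) else ""
            kwargs[name] = value
        records.append(CandidateRecord(**kwargs))
    return records


def write_fragments(fragments: Sequence[PeptideFragment], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "accession": f.parent_accession,
                "start": f.start,
                "end": f.end,
                "length": len(f),
                "sequence": f.sequence,
                "dialect": f.dialect,
            }
            for f in fragments
        ],
        columns=_FRAGMENT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_fragments(path: str | Path) -> list[PeptideFragment]:
    frame = pd.read_csv(path, sep="\t")
    return [
        PeptideFragment(
            parent_accession=str(row.accession),
            start=int(row.start),
            end=int(row.end),
            sequence=str(row.sequence),
            dialect=str(row.dialect),
        )
        for row in frame.itertuples(index=False)
    ]


def write_histogram(digest: PooledDigest, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(digest.length_histogram.items()), columns=["length", "n_fragments"]
    )
    frame.to_csv(path, sep="\t", index=False)


def write_funnel_report(report: FunnelReport, tsv_path: str | Path, json_path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "stage": s.name,
                "input": s.n_in,
                "kept": s.n_kept,
                "excluded": len(s.excluded_ids),
                "quarantined": len(s.quarantined_ids),
            }
            for s in report.stages
        ]
    )
    frame.to_csv(tsv_path, sep="\t", index=False)
    Path(json_path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")


@dataclass
class PipelineConfig:
    """Validated end-to-end run configuration."""

    dialects: list[str]
    enzymes: list[str]
    min_len: int = 5
    max_len: int = 10
    seed: int = 0
    funnel: dict | None = None
    paths: dict | None = None

    def __post_init__(self) -> None:
        from .digestion import DIALECTS, ENZYME_IDS

        for dialect in self.dialects:
            if dialect.upper() not in DIALECTS:
                raise ValueError(f"unknown dialect {dialect!r}")
        for enzyme in self.enzymes:
            if enzyme not in ENZYME_IDS:
                raise ValueError(f"unknown enzyme {enzyme!r}")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError(f"invalid length bounds [{self.min_len}, {self.max_len}]")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    return PipelineConfig(**raw)


_UNIPROT_FASTA = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"
_NCBI_FASTA = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&id={accession}&rettype=fasta&retmode=text"
)


def fetch_reference_proteome(
    accessions: Sequence[str], cache_dir: str | Path, *, timeout: float = 10.0
) -> list[ProteinRecord]:
    """Download protein sequences by accession (network required).

    UniProt accessions go to the UniProt REST API, RefSeq-style accessions
    (containing '_') to NCBI efetch.  Downloads are cached as FASTA in
    ``cache_dir`` so a run is repeatable offline afterwards.  Sequences are
    deliberately not bundled with the package; this helper exists for the
    optional full-proteome reproduction.
    """
    from urllib.request import urlopen

    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for accession in accessions:
        cached = cache_dir / f"{accession}.fasta"
        if not cached.exists():
            url = (
                _NCBI_FASTA if "_" in accession else _UNIPROT_FASTA
            ).format(accession=accession)
            log.info("fetching %s", url)
            with urlopen(url, timeout=timeout) as response:
                cached.write_bytes(response.read())
        rec = next(SeqIO.parse(str(cached), "fasta"))
        records.append(
            ProteinRecord(
                accession=accession,
                name=rec.description,
                sequence=str(rec.seq).upper(),
            )
        )
    return records
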