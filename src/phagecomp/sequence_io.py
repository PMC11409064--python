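"""Reading, labelling and filtering of genome sequences and taxonomy metadata.

Sequences are treated as linear, single-stranded, 5'->3' as given; no
reverse-complement canonicalization is performed. On read, sequences are
uppercased, U is converted to T, and every other non-ACGT character
collapses to N (ambiguity codes are not rejected; windows containing N are
skipped by downstream metrics).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

NATURAL = "natural"
GENERATED = "generated"
PROVENANCES = (NATURAL, GENERATED)

_VALID = set("ACGTN")
# str.translate table: uppercase, U->T, anything else handled afterwards
_UPPER_U2T = str.maketrans("acgtun", "ACGTTN", "")


def normalize_sequence(raw: str) -> str:
    """Uppercase, map U/u to T, collapse any other character to N."""
    s = raw.upper().replace("U", "T")
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass
class SequenceRecord:
    """One genome with provenance and optional taxonomy labels."""

    id: str
    seq: str
    provenance: str
    family: str | None = None
    virus_score: float | None = None

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}, got {self.provenance!r}")
        if self.virus_score is not None and not 0.0 <= self.virus_score <= 1.0:
            raise ValueError(f"virus_score must lie in [0, 1], got {self.virus_score}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Cohort:
    """An ordered collection of records sharing a label (e.g. 'natural')."""

    records: list[SequenceRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in cohort {self.label!r}: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def lengths(self) -> list[int]:
        return [r.length for r in self.records]


def read_fasta(path: str | Path, provenance: str, label: str | None = None) -> Cohort:
    """Read a (multi-)FASTA file into a Cohort with the given provenance.

    Raises ``ValueError("no records")`` on an empty file.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=normalize_sequence(str(rec.seq)), provenance=provenance))
    if not records:
        raise ValueError(f"no records in {path}")
    return Cohort(records=records, label=label if label is not None else provenance)


def write_fasta(cohort: Cohort, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in cohort:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


def _family_from_taxonomy(taxonomy: Iterable[str]) -> str | None:
    for rank in taxonomy:
        if rank.endswith("viridae"):
            return rank
    return None


def _looks_like_genbank(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith("LOCUS")
    return False


def read_family_metadata(*paths: str | Path) -> dict[str, str]:
    """Map record id -> viral family from GenBank flat files or 2-column TSVs.

    Family is the taxonomy rank ending in "viridae"; ids without such a rank
    are omitted. Multiple files are merged; conflicting assignments keep the
    first value with a warning.
    """
    mapping: dict[str, str] = {}

    def _put(key: str, fam: str) -> None:
        if key in mapping and mapping[key] != fam:
            logger.warning("conflicting family for %s: keeping %s, ignoring %s", key, mapping[key], fam)
            return
        mapping[key] = fam

    for p in paths:
        p = Path(p)
        if _looks_like_genbank(p):
            try:
                for rec in SeqIO.parse(str(p), "genbank"):
                    fam = _family_from_taxonomy(rec.annotations.get("taxonomy", []))
                    if fam is not None:
                        _put(rec.id.split(".")[0], fam)
                        _put(rec.id, fam)
            except ValueError as exc:  # malformed record
                logger.warning("skipping malformed GenBank content in %s: %s", p, exc)
        else:
            with open(p) as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if len(row) >= 2 and row[0] and row[1]:
                        _put(row[0], row[1])
    return mapping


def read_virus_scores(path: str | Path, id_col: str = "id", score_col: str = "virus_score") -> dict[str, float]:
    """Read an external per-sequence virus-score table (TSV, with header)."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = reader.fieldnames or []
        if id_col not in fields or score_col not in fields:
            # fall back to first two columns, headerless convention
            fh.seek(0)
            for row in csv.reader(fh, delimiter="\t"):
                if len(row) >= 2:
                    scores[row[0]] = float(row[1])
            return scores
        for row in reader:
            scores[row[id_col]] = float(row[score_col])
    return scores


def attach_families(cohort: Cohort, families: dict[str, str]) -> Cohort:
    for rec in cohort:
        fam = families.get(rec.id)
        if fam is not None:
            rec.family = fam
    return cohort


def filter_by_length(cohort: Cohort, min_bp: int = 1000, max_bp: int | None = None) -> Cohort:
    """Keep records with min_bp <= length (<= max_bp if set); order preserved.

    The 1 kb analysis cut-off is inclusive (length >= 1000 is kept).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if max_bp is not None and max_bp < min_bp:
        raise ValueError("max_bp must be >= min_bp")
    kept = [r for r in cohort if r.length >= min_bp and (max_bp is None or r.length <= max_bp)]
    return Cohort(records=kept, label=cohort.label)
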