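"""Readers and writers for the standard formats the pipeline touches.

FASTA, FASTQ (Phred+33 only) and a read-only subset of the GenBank flat-file
format. Parsing is delegated to Biopython; records are converted into the
package's lightweight domain types so the rest of the pipeline never touches
Biopython objects directly.

Coordinates are 1-based inclusive everywhere at module interfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

log = logging.getLogger(__name__)

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "tmRNA", "misc")
_RNA_ALIASES = {"ncRNA": "misc", "misc_RNA": "misc"}

IUPAC_DNA = set("ACGTNRYSWKMBDHV")


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class SeqRecordLite:
    """A bare sequence record: id, uppercase DNA sequence, free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("record id must be non-empty")
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )


@dataclass
class Feature:
    """One annotated feature with 1-based inclusive location segments."""

    type: str  # one of FEATURE_TYPES
    strand: str  # "+" or "-"
    segments: list[tuple[int, int]]  # [(start, end), ...] 1-based inclusive
    qualifiers: dict[str, str] = field(default_factory=dict)
    pseudo: bool = False


@dataclass
class AnnotatedRecord:
    """A genome sequence plus its feature table (GenBank subset)."""

    id: str
    length: int
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            for s, e in f.segments:
                if not (1 <= s <= e <= self.length):
                    raise ParseError(
                        f"feature {f.type} segment ({s},{e}) outside [1,{self.length}]"
                    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecordLite]:
    """Parse a FASTA file into SeqRecordLite records, in file order.

    Sequences are uppercased and whitespace-stripped. Malformed records raise
    :class:`ParseError`.
    """
    path = Path(path)
    records: list[SeqRecordLite] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper().replace(" ", "")
            if not seq:
                raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
            records.append(SeqRecordLite(rec.id, seq, rec.description))
    except ParseError:
        raise
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise ParseError(f"{path}: {exc}") from exc
    if not records and path.stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records found (malformed header?)")
    return records


def write_fasta(records: Iterable[SeqRecordLite], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path):
    """Parse 4-line FASTQ (Phred+33) into a list of :class:`~diffpick.simdata.Read`."""
    from .simdata import Read  # local import to avoid a cycle

    path = Path(path)
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            seq = str(rec.seq).upper()
            if len(seq) != len(quals):
                raise ParseError(f"{path}: {rec.id}: sequence/quality length mismatch")
            reads.append(Read(id=rec.id, platform=None, sequence=seq, qualities=list(quals)))
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GenBank (read-only subset)


def _segments_of(location) -> list[tuple[int, int]]:
    parts = location.parts if isinstance(location, CompoundLocation) else [location]
    segs = []
    for p in parts:
        # Biopython positions are 0-based half-open; report 1-based inclusive.
        segs.append((int(p.start) + 1, int(p.end)))
    segs.sort()
    return segs


def read_genbank_lite(path: str | Path) -> AnnotatedRecord:
    """Parse a GenBank flat file into an :class:`AnnotatedRecord`.

    Only CDS / tRNA / rRNA / tmRNA (plus ncRNA-like features mapped to
    ``misc``) are retained. ``complement(...)`` and ``join(...)`` locations are
    resolved into strand plus 1-based inclusive segments. Partial-location
    markers (``<`` / ``>``) are treated as exact with a logged warning. A
    ``/pseudo`` qualifier sets ``pseudo=True``.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
        seq = str(rec.seq).upper()  # undefined when ORIGIN is absent
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not seq:
        raise ParseError(f"{path}: missing ORIGIN sequence")
    features: list[Feature] = []
    for f in rec.features:
        ftype = _RNA_ALIASES.get(f.type, f.type)
        if ftype not in FEATURE_TYPES:
            continue
        if f.location is None:
            log.warning("skipping %s feature with unparseable location", f.type)
            continue
        if "<" in str(f.location) or ">" in str(f.location):
            log.warning("partial location %s treated as exact", f.location)
        strand = "-" if f.location.strand == -1 else "+"
        quals = {k: v[0] if isinstance(v, list) and v else "" for k, v in f.qualifiers.items()}
        features.append(
            Feature(
                type=ftype,
                strand=strand,
                segments=_segments_of(f.location),
                qualifiers=quals,
                pseudo="pseudo" in f.qualifiers or "pseudogene" in f.qualifiers,
            )
        )
    return AnnotatedRecord(id=rec.id, length=len(seq), sequence=seq, features=features)
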