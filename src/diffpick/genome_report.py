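"""Genome statistics from an annotated record.

Computes the classic genome-table rows that depend only on the record
itself: genome size, G+C base count and percentage, coding base pairs
(strand-agnostic union of CDS segments), and feature counts (CDS, RNA
genes, pseudogenes).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .io_formats import AnnotatedRecord

_RNA_TYPES = {"tRNA", "rRNA", "tmRNA"}


@dataclass
class GenomeStats:
    size: int
    gc_bp: int
    gc_pct: float
    coding_bp: int
    coding_pct: float
    n_total_genes: int
    n_cds: int
    n_rna: int
    n_pseudo: int
    n_scaffolds: int = 1


def _pct(numer: int, denom: int) -> float:
    """Percentage rounded half-up to 2 decimals (table formatting convention)."""
    if denom == 0:
        return 0.0
    return float(
        (Decimal(100 * numer) / Decimal(denom)).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


def gc_content(sequence: str) -> tuple[int, float]:
    """(G+C base count, percentage of total length incl. ambiguity codes)."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    return gc, _pct(gc, len(s))


def coding_bp(record: AnnotatedRecord) -> int:
    """Bases covered by at least one CDS segment (overlaps merged, strand-agnostic)."""
    segs = sorted(
        seg for f in record.features if f.type == "CDS" for seg in f.segments
    )
    total = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def coding_bp_summed(record: AnnotatedRecord) -> int:
    """Alternative convention: CDS segment lengths summed without merging."""
    return sum(e - s + 1 for f in record.features if f.type == "CDS" for s, e in f.segments)


def genome_stats(record: AnnotatedRecord) -> GenomeStats:
    """All computable genome-table rows for one annotated record."""
    gc_bp_, gc_pct_ = gc_content(record.sequence)
    cod = coding_bp(record)
    n_cds = sum(1 for f in record.features if f.type == "CDS")
    n_rna = sum(1 for f in record.features if f.type in _RNA_TYPES)
    n_pseudo = sum(1 for f in record.features if f.pseudo)
    return GenomeStats(
        size=record.length,
        gc_bp=gc_bp_,
        gc_pct=gc_pct_,
        coding_bp=cod,
        coding_pct=_pct(cod, record.length),
        n_total_genes=n_cds + n_rna,
        n_cds=n_cds,
        n_rna=n_rna,
        n_pseudo=n_pseudo,
    )
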