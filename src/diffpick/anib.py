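"""ANIb: average nucleotide identity by genome fragmentation and alignment.

The query genome is cut into consecutive non-overlapping 1020 bp fragments;
each fragment is aligned to the reference (both strands) and the best hit
kept. Hits with identity >= 30% over an alignment covering >= 70% of the
fragment are retained, and the ANI is the mean identity of the retained
best hits. A 95-96% ANI approximates the bacterial species boundary.

The alignment engine is a contract, not a tool: the default engine aligns
each fragment end-to-end against the best-matching stretch of the reference
(semi-global edit-distance alignment via edlib) and derives identity from
the extended CIGAR. Under this engine the whole fragment is always part of
the alignment, so filtering is effectively driven by the identity cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import edlib

from .kmers import revcomp

DEFAULT_FRAGMENT_LEN = 1020
DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 70.0
MIN_TAIL_FRAGMENT = 100


@dataclass
class FragmentHit:
    fragment_index: int
    identity_pct: float
    aligned_fraction: float
    strand: str


@dataclass
class AniResult:
    ani_pct: Optional[float]
    n_fragments_total: int
    n_fragments_aligned: int
    fragments: list[FragmentHit] = field(default_factory=list)


def fragment_genome(sequence: str, fragment_len: int = DEFAULT_FRAGMENT_LEN) -> list[str]:
    """Consecutive non-overlapping windows; a final fragment < 100 bp is dropped."""
    if fragment_len <= 0:
        raise ValueError("fragment_len must be positive")
    frags = [sequence[i : i + fragment_len] for i in range(0, len(sequence), fragment_len)]
    if frags and len(frags[-1]) < MIN_TAIL_FRAGMENT:
        frags.pop()
    return frags


def _edlib_engine(fragment: str, reference: str) -> tuple[float, float]:
    """Best semi-global alignment of the fragment within the reference.

    Returns (identity %, aligned fragment fraction). Identity is matches
    over alignment columns from the extended CIGAR.
    """
    res = edlib.align(fragment, reference, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return 0.0, 0.0
    matches = 0
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    identity = 100.0 * matches / columns if columns else 0.0
    return identity, 100.0 * min(1.0, columns / len(fragment))


def anib(
    query_genome: str,
    reference_genome: str,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    engine: Optional[Callable[[str, str], tuple[float, float]]] = None,
) -> AniResult:
    """ANIb of ``query_genome`` against ``reference_genome``.

    ``engine(fragment, reference) -> (identity_pct, aligned_fraction_pct)``
    may be swapped in; the default is the internal edlib-based aligner.
    Reverse-strand hits are allowed; only the best hit per fragment counts.
    """
    if not query_genome or not reference_genome:
        raise ValueError("both genomes must be non-empty")
    align = engine or _edlib_engine
    rc_ref = revcomp(reference_genome)
    fragments = fragment_genome(query_genome, fragment_len)
    hits: list[FragmentHit] = []
    for i, frag in enumerate(fragments):
        fwd = align(frag, reference_genome)
        rev = align(frag, rc_ref)
        (ident, cov), strand = max(((fwd, "+"), (rev, "-")), key=lambda t: t[0][0])
        if ident >= min_identity and cov >= min_coverage:
            hits.append(FragmentHit(i, ident, cov, strand))
    if not hits:
        return AniResult(None, len(fragments), 0)
    ani = sum(h.identity_pct for h in hits) / len(hits)
    return AniResult(ani, len(fragments), len(hits), hits)
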