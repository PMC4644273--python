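"""Packed-integer k-mer primitives shared by the assembler, mapper and evaluator.

k-mers with k <= 31 are packed 2 bits/base into uint64 (A=0, C=1, G=2, T=3).
All hot paths are vectorised with numpy; reads and contigs at desk scale
(tens of megabases) stay well under a few hundred MB this way.

The canonical form of a k-mer is the lexicographic minimum of the k-mer and
its reverse complement; with k odd a k-mer is never its own reverse
complement, so every k-mer has a well-defined orientation.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

_DECODE = np.array(list("ACGT"))

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to base codes (uint8); non-ACGT bases become 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_kmer(km: int, k: int) -> str:
    out = []
    for i in range(k - 1, -1, -1):
        out.append("ACGT"[(int(km) >> (2 * i)) & 3])
    return "".join(out)


def forward_kmers(seq: str, k: int) -> np.ndarray:
    """All forward-strand k-mers of ``seq`` as packed uint64.

    Windows containing a non-ACGT base are dropped. Returns an empty array
    when the sequence is shorter than k.
    """
    codes = encode(seq)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    km = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        km = (km << np.uint64(2)) | codes[i : i + m].astype(np.uint64)
    bad = codes >= 4
    if bad.any():
        cum = np.concatenate(([0], np.cumsum(bad)))
        km = km[(cum[k:] - cum[:m]) == 0]
    return km


def forward_kmers_with_pos(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mers plus their 0-based start offsets (invalid windows dropped)."""
    codes = encode(seq)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    km = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        km = (km << np.uint64(2)) | codes[i : i + m].astype(np.uint64)
    pos = np.arange(m, dtype=np.int64)
    bad = codes >= 4
    if bad.any():
        cum = np.concatenate(([0], np.cumsum(bad)))
        keep = (cum[k:] - cum[:m]) == 0
        km, pos = km[keep], pos[keep]
    return km, pos


def revcomp_kmers(km: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of packed k-mers, vectorised."""
    mask = np.uint64((1 << (2 * k)) - 1)
    t = km ^ mask  # complement: A<->T, C<->G is bitwise NOT within 2 bits
    rc = np.zeros_like(km)
    two = np.uint64(2)
    three = np.uint64(3)
    for _ in range(k):
        rc = (rc << two) | (t & three)
        t = t >> two
    return rc


def canonical_kmers(km: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical form and orientation flag (True where forward == canonical)."""
    rc = revcomp_kmers(km, k)
    fwd_is_canon = km <= rc
    return np.where(fwd_is_canon, km, rc), fwd_is_canon


def canonical_kmer_set(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mers of a sequence."""
    km = forward_kmers(seq, k)
    canon, _ = canonical_kmers(km, k)
    return np.unique(canon)


def count_canonical(seqs, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Count canonical k-mers over an iterable of sequences.

    Returns (sorted unique canonical k-mers, counts). Sequences are joined
    with an ``N`` separator so the whole batch is processed in one
    vectorised pass; windows spanning the separator are dropped anyway.
    """
    joined = "N".join(seqs)
    if not joined:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    km = forward_kmers(joined, k)
    if km.size == 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    canon, _ = canonical_kmers(km, k)
    return np.unique(canon, return_counts=True)
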