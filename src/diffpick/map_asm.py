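"""Minimal de Bruijn assembler and k-mer voting read-to-contig assigner.

These stand in for the proprietary assembler/mapper pipeline that originally
produced and mapped contigs: the goal is faithful read *binning*, not
polished assembly. The assembler builds a bidirected de Bruijn graph on
canonical k-mers (count >= ``min_kmer_count``), clips short tips, and emits
maximal non-branching paths (unitigs) of length >= 2k as contigs. Every
input read is then placed on the contigs by canonical k-mer voting.

The mapper tolerates chimeric bait reads by design: a chimera matches a
contig over only part of its length, so bait assignment uses a lower
matched-k-mer-fraction threshold (default 0.3) than direct-shotgun
placement (default 0.5). Ambiguous equal-vote assignments are left
unassigned — a conservative tie-break that protects picking precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .kmers import (
    canonical_kmers,
    count_canonical,
    decode_kmer,
    forward_kmers,
    forward_kmers_with_pos,
    revcomp,
    revcomp_kmers,
)
from .simdata import Read

log = logging.getLogger(__name__)

DEFAULT_ASSEMBLY_K = 31
DEFAULT_MAP_K = 21
DEFAULT_MIN_KMER_COUNT = 2
DEFAULT_MIN_FRAC_DS = 0.5
DEFAULT_MIN_FRAC_BAIT = 0.3


@dataclass
class Contig:
    id: str
    sequence: str
    mean_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Placement:
    """One read placement: contig, 1-based start estimate, strand, k-mer support."""

    contig_id: str
    start: int
    strand: str
    matched_kmer_fraction: float


@dataclass
class Assembly:
    contigs: list[Contig] = field(default_factory=list)
    placements: dict[str, list[Placement]] = field(default_factory=dict)

    def contig_ids(self) -> set[str]:
        return {c.id for c in self.contigs}


@dataclass
class KmerIndex:
    """Canonical k-mer -> contig position index, stored as parallel sorted arrays."""

    k: int
    kmers: np.ndarray  # sorted canonical k-mers (uint64), duplicates allowed
    contig_idx: np.ndarray  # int32 index into contig_ids
    offsets: np.ndarray  # int64 0-based offset of the k-mer in its contig
    fwd_is_canon: np.ndarray  # bool: contig occurrence orientation vs canonical
    contig_ids: list[str]

    def lookup(self, kmer: int) -> list[tuple[str, int, str]]:
        """All occurrences of a canonical k-mer as (contig_id, 1-based offset, strand)."""
        lo = int(np.searchsorted(self.kmers, np.uint64(kmer), side="left"))
        hi = int(np.searchsorted(self.kmers, np.uint64(kmer), side="right"))
        return [
            (
                self.contig_ids[self.contig_idx[i]],
                int(self.offsets[i]) + 1,
                "+" if self.fwd_is_canon[i] else "-",
            )
            for i in range(lo, hi)
        ]


def build_index(contigs: Sequence[Contig], k: int = DEFAULT_MAP_K) -> KmerIndex:
    """Index every k-mer occurrence of every contig under its canonical form."""
    if not contigs:
        raise ValueError("cannot index an empty contig set")
    if not (15 <= k <= 63) or k % 2 == 0:
        raise ValueError("k must be odd and in [15, 63]")
    if k > 31:
        raise ValueError("packed k-mers support k <= 31")
    km_all, cidx_all, off_all, ori_all = [], [], [], []
    ids = [c.id for c in contigs]
    for ci, c in enumerate(contigs):
        km, pos = forward_kmers_with_pos(c.sequence, k)
        canon, fwd = canonical_kmers(km, k)
        km_all.append(canon)
        cidx_all.append(np.full(canon.size, ci, dtype=np.int32))
        off_all.append(pos)
        ori_all.append(fwd)
    km = np.concatenate(km_all)
    order = np.argsort(km, kind="stable")
    return KmerIndex(
        k=k,
        kmers=km[order],
        contig_idx=np.concatenate(cidx_all)[order],
        offsets=np.concatenate(off_all)[order],
        fwd_is_canon=np.concatenate(ori_all)[order],
        contig_ids=ids,
    )


# ---------------------------------------------------------------------------
# read assignment


def _assign_batch(
    reads: Sequence[Read], index: KmerIndex, min_frac: float
) -> dict[str, list[Placement]]:
    """Vectorised k-mer voting for a batch of reads.

    Returns, per read that clears ``min_frac``, the top-scoring placements
    (more than one only on an exact tie between contigs).
    """
    k = index.k
    out: dict[str, list[Placement]] = {}
    if not reads:
        return out
    # one vectorised k-mer pass over all reads, joined with an N separator
    lengths = np.array([len(r.sequence) for r in reads], dtype=np.int64)
    n_kmers = np.maximum(lengths - k + 1, 0)
    read_start = np.concatenate(([0], np.cumsum(lengths + 1)))[:-1]
    joined = "N".join(r.sequence for r in reads)
    km, gpos = forward_kmers_with_pos(joined, k)
    if km.size == 0:
        return out
    canon, ori = canonical_kmers(km, k)
    rid = np.searchsorted(read_start, gpos, side="right") - 1
    pos = gpos - read_start[rid]

    lo = np.searchsorted(index.kmers, canon, side="left")
    hi = np.searchsorted(index.kmers, canon, side="right")
    counts = hi - lo
    has = counts > 0
    if not has.any():
        return out
    # expand matches: one row per (read k-mer, index occurrence)
    reps = counts[has]
    total = int(reps.sum())
    src = np.repeat(np.nonzero(has)[0], reps)
    flat = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps) + np.repeat(lo[has], reps)
    m_rid = rid[src]
    m_pos = pos[src]
    m_contig = index.contig_idx[flat].astype(np.int64)
    m_off = index.offsets[flat]
    # strand of the read k-mer on the contig: same iff orientations agree
    m_same = (ori[src] == index.fwd_is_canon[flat]).astype(np.int64)

    # vote per (read, contig, strand), counting each read k-mer position once
    n_c = np.int64(len(index.contig_ids))
    max_pos = np.int64(int(pos.max()) + 1)
    key = (m_rid * n_c + m_contig) * np.int64(2) + m_same
    pair = key * max_pos + m_pos
    order = np.lexsort((m_off, pair))
    pair_s, key_s, pos_s, off_s = pair[order], key[order], m_pos[order], m_off[order]
    keep = np.concatenate(([True], pair_s[1:] != pair_s[:-1]))
    key_u, pos_u, off_u = key_s[keep], pos_s[keep], off_s[keep]
    votes_key, grp_start, votes = np.unique(key_u, return_index=True, return_counts=True)
    # pos_u is sorted within each key group, so the group head is the min-offset hit
    rep_pos, rep_off = pos_u[grp_start], off_u[grp_start]
    v_rid = votes_key // (2 * n_c)
    v_contig = (votes_key // 2) % n_c
    v_same = (votes_key % 2).astype(bool)

    r_start = np.searchsorted(v_rid, np.arange(len(reads)))
    r_end = np.searchsorted(v_rid, np.arange(len(reads)), side="right")

    for ri, r in enumerate(reads):
        s, e = int(r_start[ri]), int(r_end[ri])
        if s == e or n_kmers[ri] == 0:
            continue
        best_per_contig: dict[int, tuple[int, bool, int]] = {}
        for j in range(s, e):
            c = int(v_contig[j])
            v = int(votes[j])
            if c not in best_per_contig or v > best_per_contig[c][0]:
                best_per_contig[c] = (v, bool(v_same[j]), j)
        top = max(v for v, _, _ in best_per_contig.values())
        frac = top / int(n_kmers[ri])
        if frac < min_frac:
            continue
        winners = [c for c, (v, _, _) in best_per_contig.items() if v == top]
        if len(winners) > 1:
            continue  # tie between contigs -> unassigned
        c = winners[0]
        _, same, j = best_per_contig[c]
        p, o = int(rep_pos[j]), int(rep_off[j])
        if same:
            start = o - p + 1
        else:
            start = o - (len(r.sequence) - k - p) + 1
        out[r.id] = [Placement(index.contig_ids[c], start, "+" if same else "-", frac)]
    return out


def assign_read(read: Read, index: KmerIndex, min_frac: float = DEFAULT_MIN_FRAC_DS) -> Optional[Placement]:
    """Place one read by canonical k-mer voting; None when below ``min_frac`` or tied.

    Votes are counted per contig on the consistent strand; the read is
    assigned to the contig with the highest matched-k-mer fraction when that
    fraction reaches ``min_frac``. An exact tie between two contigs leaves
    the read unassigned.
    """
    if len(read.sequence) < index.k:
        raise ValueError(f"read {read.id} shorter than k={index.k}")
    got = _assign_batch([read], index, min_frac)
    pl = got.get(read.id)
    return pl[0] if pl else None


def assign_reads(
    reads: Sequence[Read], index: KmerIndex, min_frac: float = DEFAULT_MIN_FRAC_DS
) -> dict[str, list[Placement]]:
    """Batch version of :func:`assign_read`; reads shorter than k are skipped."""
    usable = [r for r in reads if len(r.sequence) >= index.k]
    return _assign_batch(usable, index, min_frac)


# ---------------------------------------------------------------------------
# de Bruijn assembly


def _successor_tables(solid: np.ndarray, k: int):
    """For each solid canonical k-mer and orientation, the unique successor.

    Returns (out_n, succ_idx, succ_ori, succ_base):
      out_n[o][i]    — number of solid successors of node i read in orientation o
                       (o=0 forward/canonical, o=1 reverse complement)
      succ_idx[o][i] — index of the unique successor when out_n == 1
      succ_ori[o][i] — orientation of that successor
      succ_base[o][i]— appended base code (0..3)
    """
    n = solid.size
    mask = np.uint64((1 << (2 * k)) - 1)
    oriented = [solid, revcomp_kmers(solid, k)]
    out_n = [np.zeros(n, np.int8), np.zeros(n, np.int8)]
    succ_idx = [np.full(n, -1, np.int64), np.full(n, -1, np.int64)]
    succ_ori = [np.zeros(n, np.int8), np.zeros(n, np.int8)]
    succ_base = [np.zeros(n, np.int8), np.zeros(n, np.int8)]
    two = np.uint64(2)
    for o in (0, 1):
        v = oriented[o]
        for b in range(4):
            cand = ((v << two) | np.uint64(b)) & mask
            canon, fwd = canonical_kmers(cand, k)
            idx = np.searchsorted(solid, canon)
            idx_c = np.clip(idx, 0, max(n - 1, 0))
            hit = (idx < n) & (solid[idx_c] == canon)
            out_n[o] += hit
            sel = hit
            succ_idx[o][sel] = idx_c[sel]
            succ_ori[o][sel] = (~fwd[sel]).astype(np.int8)  # successor read fwd iff cand is canonical
            succ_base[o][sel] = b
    return out_n, succ_idx, succ_ori, succ_base


def _walk_unitigs(solid: np.ndarray, k: int):
    """Emit maximal non-branching paths as (node index list, orientation list)."""
    n = solid.size
    out_n, succ_idx, succ_ori, succ_base = _successor_tables(solid, k)

    def outdeg(i, o):
        return int(out_n[o][i])

    def indeg(i, o):
        return int(out_n[1 - o][i])

    def step(i, o):
        return int(succ_idx[o][i]), int(succ_ori[o][i])

    visited = np.zeros(n, dtype=bool)
    unitigs = []

    def walk(i, o):
        path = [(i, o)]
        visited[i] = True
        while outdeg(i, o) == 1:
            j, oj = step(i, o)
            if indeg(j, oj) != 1 or visited[j]:
                break
            path.append((j, oj))
            visited[j] = True
            i, o = j, oj
        unitigs.append(path)

    for i in range(n):
        if visited[i]:
            continue
        for o in (0, 1):
            if indeg(i, o) != 1:
                walk(i, o)
                break
            p, po = step(i, 1 - o)  # predecessor of (i,o) is rc of successor of (i,1-o)
            if outdeg(p, 1 - po) != 1:
                walk(i, o)
                break
    # leftover nodes belong to perfect cycles; walk each from an arbitrary entry
    for i in range(n):
        if not visited[i]:
            walk(i, 0)
    return unitigs, out_n


def _unitig_seq(path, solid: np.ndarray, k: int) -> str:
    i0, o0 = path[0]
    first = decode_kmer(int(solid[i0]), k)
    if o0 == 1:
        first = revcomp(first)
    chars = [first]
    for i, o in path[1:]:
        km = decode_kmer(int(solid[i]), k)
        if o == 1:
            km = revcomp(km)
        chars.append(km[-1])
    return "".join(chars)


def assemble(
    reads: Sequence[Read],
    k: int = DEFAULT_ASSEMBLY_K,
    min_kmer_count: int = DEFAULT_MIN_KMER_COUNT,
    tip_max_len: Optional[int] = None,
    *,
    place_reads: bool = True,
    min_frac: float = DEFAULT_MIN_FRAC_DS,
    tip_rounds: int = 3,
) -> Assembly:
    """Assemble reads into unitig contigs and place every input read on them.

    Contigs are maximal non-branching de Bruijn paths of length >= 2k over
    canonical k-mers seen at least ``min_kmer_count`` times. Tips (dead-end
    unitigs shorter than ``tip_max_len``, default 2k) are clipped for up to
    ``tip_rounds`` rounds. Contig order and ids are deterministic: sorted by
    length descending, then by canonical sequence.
    """
    if k % 2 == 0 or k < 15:
        raise ValueError("k must be odd and >= 15")
    if k > 31:
        raise ValueError("packed k-mers support k <= 31")
    usable = [r for r in reads if len(r.sequence) >= k]
    if reads and not usable:
        raise ValueError(f"k={k} is not smaller than every read length")
    if not usable:
        return Assembly()
    tip_max = tip_max_len if tip_max_len is not None else 2 * k

    solid, counts = count_canonical((r.sequence for r in usable), k)
    keep = counts >= min_kmer_count
    solid, counts = solid[keep], counts[keep]
    if solid.size == 0:
        return Assembly()

    for _ in range(tip_rounds):
        unitigs, out_n = _walk_unitigs(solid, k)
        tip_nodes = []
        for path in unitigs:
            length = k + len(path) - 1
            if length >= tip_max:
                continue
            i0, o0 = path[0]
            iL, oL = path[-1]
            dead_start = out_n[1 - o0][i0] == 0
            dead_end = out_n[oL][iL] == 0
            if (dead_start != dead_end):  # a tip hangs off the graph at one end only
                tip_nodes.extend(i for i, _ in path)
        if not tip_nodes:
            break
        mask = np.ones(solid.size, dtype=bool)
        mask[tip_nodes] = False
        solid, counts = solid[mask], counts[mask]
        if solid.size == 0:
            return Assembly()

    unitigs, _ = _walk_unitigs(solid, k)
    seqs = []
    for path in unitigs:
        s = _unitig_seq(path, solid, k)
        if len(s) < 2 * k:
            continue
        cov = float(np.mean(counts[[i for i, _ in path]]))
        seqs.append((s, cov))
    # deterministic ordering: length desc, then canonical sequence
    seqs.sort(key=lambda t: (-len(t[0]), min(t[0], revcomp(t[0]))))
    contigs = [
        Contig(id=f"c{i + 1:04d}", sequence=s, mean_coverage=cov)
        for i, (s, cov) in enumerate(seqs)
    ]
    asm = Assembly(contigs=contigs)
    if place_reads and contigs:
        index = build_index(contigs, k)
        asm.placements = assign_reads(usable, index, min_frac)
    n_bases = sum(len(r.sequence) for r in usable)
    log.info(
        "assembled %d reads (%d bp) -> %d contigs (%d bp), placed %d reads",
        len(usable), n_bases, len(contigs), sum(len(c) for c in contigs), len(asm.placements),
    )
    return asm
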