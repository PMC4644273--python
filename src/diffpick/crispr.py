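"""CRISPR direct-repeat/spacer array detection.

An array is a run of >= 3 copies of a direct repeat (23-55 bp) separated by
spacers of 0.6-2.5x the repeat length that are mutually dissimilar (< 60%
pairwise identity). Copies may diverge from the running consensus by at
most 20% of positions (degenerate terminal copies up to 33%). Candidate
arrays are seeded by exact 23-mer triples with compliant spacing, extended
into full repeats column-by-column, then extended outward with degenerate
terminal copies; overlapping candidates are resolved by repeat count, then
span. Coordinates are 1-based; the array span runs from the first repeat
start to the last repeat end, reported on the forward strand as written.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib

IUPAC_FROM_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class CrisprParams:
    repeat_min: int = 23
    repeat_max: int = 55
    min_copies: int = 3
    max_divergence: float = 0.20  # internal copies vs running consensus
    max_terminal_divergence: float = 0.33
    spacer_min_ratio: float = 0.6
    spacer_max_ratio: float = 2.5
    spacer_max_identity: float = 0.60
    seed_k: int = 23


@dataclass
class CrisprArray:
    """One detected array; repeats and spacers alternate, 1-based coordinates."""

    start: int
    end: int
    repeats: list[tuple[int, str]]
    spacers: list[tuple[int, str]]
    consensus_repeat: str
    conservation: list[float] = field(default_factory=list)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _consensus_of(seqs: list[str]) -> tuple[str, list[float]]:
    """Per-column majority consensus, 5'-aligned; ties become IUPAC codes.

    Trailing columns (beyond the shortest copy) require >= 50% occupancy.
    """
    n = len(seqs)
    width = max(len(s) for s in seqs)
    cons, conserv = [], []
    for col in range(width):
        bases = [s[col] for s in seqs if col < len(s)]
        if len(bases) < n / 2:
            break
        counts = defaultdict(int)
        for b in bases:
            counts[b] += 1
        top = max(counts.values())
        winners = frozenset(b for b, c in counts.items() if c == top)
        cons.append(IUPAC_FROM_SET.get(winners, "N") if len(winners) > 1 else next(iter(winners)))
        conserv.append(top / len(bases))
    return "".join(cons), conserv


def consensus_repeat(array_or_repeats) -> str:
    """Majority consensus of an array's repeat copies (>= 3 required)."""
    seqs = (
        [s for _, s in array_or_repeats.repeats]
        if isinstance(array_or_repeats, CrisprArray)
        else list(array_or_repeats)
    )
    if len(seqs) < 3:
        raise ValueError("consensus requires at least 3 repeat copies")
    return _consensus_of(seqs)[0]


def _divergence(copy: str, consensus: str) -> float:
    n = max(len(copy), len(consensus))
    mism = sum(1 for a, b in zip(copy, consensus) if a != b) + abs(len(copy) - len(consensus))
    return mism / n


@dataclass
class _Candidate:
    positions: list[int]  # 0-based starts of repeat copies
    rep_len: int

    @property
    def span(self) -> tuple[int, int]:
        return self.positions[0], self.positions[-1] + self.rep_len


def _seed_runs(seq: str, p: CrisprParams) -> list[list[int]]:
    """Maximal runs of >= min_copies exact seed-k-mer occurrences with compliant gaps."""
    k = p.seed_k
    min_gap = int(p.repeat_min * (1 + p.spacer_min_ratio))
    max_gap = int(p.repeat_max * (1 + p.spacer_max_ratio)) + 1
    occ: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        occ[seq[i : i + k]].append(i)
    runs = []
    for positions in occ.values():
        if len(positions) < p.min_copies:
            continue
        run = [positions[0]]
        for q in positions[1:]:
            if min_gap <= q - run[-1] <= max_gap:
                run.append(q)
            else:
                if len(run) >= p.min_copies:
                    runs.append(run)
                run = [q]
        if len(run) >= p.min_copies:
            runs.append(run)
    return runs


def _extend_columns(seq: str, run: list[int], p: CrisprParams) -> _Candidate | None:
    """Grow the seed k-mer into the full repeat, column by column on each side."""
    k = p.seed_k
    left, right = 0, 0

    def ok(ext_left: int, ext_right: int) -> bool:
        length = ext_left + k + ext_right
        if length > p.repeat_max:
            return False
        starts = [q - ext_left for q in run]
        if starts[0] < 0 or run[-1] + k + ext_right > len(seq):
            return False
        # spacers must stay above the lower bound as the repeat grows
        for a, b in zip(starts, starts[1:]):
            spacer = (b - a) - length
            if spacer < p.spacer_min_ratio * length:
                return False
        return True

    def column_agrees(col_positions: list[int]) -> bool:
        bases = [seq[i] for i in col_positions]
        counts = defaultdict(int)
        for b in bases:
            counts[b] += 1
        return max(counts.values()) / len(bases) >= 0.8

    while ok(left + 1, right) and column_agrees([q - left - 1 for q in run]):
        left += 1
    while ok(left, right + 1) and column_agrees([q + k + right for q in run]):
        right += 1
    if k + left + right < p.repeat_min:
        return None
    return _Candidate([q - left for q in run], k + left + right)


def _extend_terminal(seq: str, cand: _Candidate, p: CrisprParams) -> _Candidate:
    """Add degenerate terminal copies (<= max_terminal_divergence) on both sides."""
    L = cand.rep_len
    cons = _consensus_of([seq[q : q + L] for q in cand.positions])[0]
    max_d = int(p.max_terminal_divergence * L)

    def search(window_start: int, window_end: int) -> int | None:
        window_start = max(0, window_start)
        window_end = min(len(seq), window_end)
        if window_end - window_start < L:
            return None
        res = edlib.align(cons, seq[window_start:window_end], mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > max_d:
            return None
        loc = res["locations"][0]
        return window_start + loc[0]

    changed = True
    while changed:
        changed = False
        first = cand.positions[0]
        lo = first - int(p.spacer_max_ratio * L) - 2 * L
        hit = search(lo, first - int(p.spacer_min_ratio * L))
        if hit is not None and hit + L <= first - int(p.spacer_min_ratio * L):
            cand.positions.insert(0, hit)
            changed = True
        last_end = cand.positions[-1] + L
        hi = last_end + int(p.spacer_max_ratio * L) + 2 * L
        hit = search(last_end + int(p.spacer_min_ratio * L), hi)
        if hit is not None:
            cand.positions.append(hit)
            changed = True
    return cand


def _validate(seq: str, cand: _Candidate, p: CrisprParams) -> CrisprArray | None:
    L = cand.rep_len
    copies = [seq[q : q + L] for q in cand.positions]
    cons, conserv = _consensus_of(copies)
    # trim terminal copies that diverge too far; internal copies are stricter
    while copies and _divergence(copies[0], cons) > p.max_terminal_divergence:
        copies.pop(0)
        cand.positions.pop(0)
    while copies and _divergence(copies[-1], cons) > p.max_terminal_divergence:
        copies.pop()
        cand.positions.pop()
    if len(copies) < p.min_copies:
        return None
    if any(_divergence(c, cons) > p.max_divergence for c in copies[1:-1]):
        return None

    def spacer_ok(a: int, b: int) -> bool:
        return p.spacer_min_ratio * L <= (b - (a + L)) <= p.spacer_max_ratio * L

    # terminal copies whose spacer is out of range are dropped, not fatal
    while len(cand.positions) >= 2 and not spacer_ok(cand.positions[0], cand.positions[1]):
        cand.positions.pop(0)
        copies.pop(0)
    while len(cand.positions) >= 2 and not spacer_ok(cand.positions[-2], cand.positions[-1]):
        cand.positions.pop()
        copies.pop()
    if len(copies) < p.min_copies:
        return None
    spacers = []
    for a, b in zip(cand.positions, cand.positions[1:]):
        if not spacer_ok(a, b):
            return None  # an internal spacer out of range: not a compliant array
        s_start = a + L
        spacers.append((s_start + 1, seq[s_start:b]))
    for i in range(len(spacers)):
        for j in range(i + 1, len(spacers)):
            if _identity(spacers[i][1], spacers[j][1]) >= p.spacer_max_identity:
                return None
    cons, conserv = _consensus_of(copies)
    return CrisprArray(
        start=cand.positions[0] + 1,
        end=cand.positions[-1] + L,
        repeats=[(q + 1, seq[q : q + L]) for q in cand.positions],
        spacers=spacers,
        consensus_repeat=cons,
        conservation=conserv,
    )


def find_arrays(genome: str, params: CrisprParams | None = None) -> list[CrisprArray]:
    """Detect CRISPR arrays in a genome sequence (forward strand as written)."""
    if not genome:
        raise ValueError("genome is empty")
    p = params or CrisprParams()
    seq = genome.upper()
    arrays: list[CrisprArray] = []
    for run in _seed_runs(seq, p):
        cand = _extend_columns(seq, run, p)
        if cand is None:
            continue
        cand = _extend_terminal(seq, cand, p)
        arr = _validate(seq, cand, p)
        if arr is not None:
            arrays.append(arr)
    # resolve overlaps: more repeats wins, then longer span
    arrays.sort(key=lambda a: (-len(a.repeats), -(a.end - a.start), a.start))
    accepted: list[CrisprArray] = []
    for arr in arrays:
        if all(arr.end < other.start or arr.start > other.end for other in accepted):
            accepted.append(arr)
    accepted.sort(key=lambda a: a.start)
    return accepted
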