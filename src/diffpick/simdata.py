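"""Truth-labelled synthetic co-culture sequencing data.

Emulates the experimental inputs of bait-guided genome recovery from a
two-organism co-culture:

* direct-shotgun (DS) reads of the mixed DNA on two platforms — platform A,
  long single-end reads (~400 bp, pyrosequencer-like) and platform B, 251 bp
  paired-end reads (MiSeq-like);
* a whole-genome-amplification (WGA) bait library sequenced from a pure
  culture of the target organism. Multiple-displacement WGA produces chimeric
  reads (junctions of two non-adjacent loci) and strongly uneven coverage;
  both artifacts are modelled, because tolerating them is the whole point of
  using WGA reads only as bait.

Every simulated read carries a truth label (origin genome, 1-based interval,
strand, chimera flag) used downstream to score picking precision and recall.
Truth labels live in a sidecar TSV, never in FASTQ headers by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .kmers import revcomp

PLATFORM_A = "A_long_single"
PLATFORM_B = "B_short_paired"

_BASES = np.array(list("ACGT"))


@dataclass
class SynGenome:
    """A synthetic genome: id, pure-ACGT sequence, circular flag."""

    id: str
    sequence: str
    circular: bool = True

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TruthEntry:
    """Ground-truth origin of one read.

    ``intervals`` are 1-based inclusive on the origin genome; for fragments
    that wrap the origin of a circular genome the end may exceed the genome
    length (coordinates continue past the origin). Chimeric reads have
    exactly two intervals, one per joined locus.
    """

    genome_id: str
    intervals: list[tuple[int, int]]
    strands: list[str]
    is_chimera: bool = False


@dataclass
class Read:
    """A sequenced fragment. ``qualities`` are Phred scores, same length as sequence."""

    id: str
    platform: Optional[str]
    sequence: str
    qualities: list[int]
    mate_id: Optional[str] = None
    truth: Optional[TruthEntry] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimProfile:
    """Sequencing-run parameters for the synthetic platforms.

    Defaults mirror the study conditions: ~400 bp single-end long reads,
    fixed 251 bp paired-end short reads, a 0.2% per-base substitution rate,
    and a WGA bait library with 10% chimeric reads and lognormal (sigma=1)
    window-level amplification bias over 5 kb windows.
    """

    read_len_a_mean: float = 400.0
    read_len_a_sd: float = 80.0
    read_len_a_min: int = 100
    read_len_b: int = 251
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    error_rate: float = 0.002
    qual_mean: float = 35.0
    qual_decay: float = 8.0
    coverage_a: float = 40.0
    coverage_b: float = 200.0
    coverage_bait: float = 10.0
    wga_chimera_rate: float = 0.1
    wga_bias_sigma: float = 1.0
    wga_window: int = 5000

    def __post_init__(self) -> None:
        for name in ("error_rate", "wga_chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for name in ("coverage_a", "coverage_b", "coverage_bait"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_genome(length: int, gc: float, seed: int, *, genome_id: str = "g", circular: bool = True) -> SynGenome:
    """I.i.d. random genome with P(G)+P(C) = ``gc``; deterministic under seed."""
    if length < 1000:
        raise ValueError("simulation genomes must be >= 1 kb")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must lie in (0,1), got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return SynGenome(genome_id, seq, circular)


# ---------------------------------------------------------------------------
# helpers


def _fragment(genome: SynGenome, start: int, length: int) -> str:
    """Extract a fragment at 0-based ``start``; wraps the origin when circular."""
    s = genome.sequence
    if start + length <= len(s):
        return s[start : start + length]
    if genome.circular:
        return s[start:] + s[: start + length - len(s)]
    return s[start:]


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size == 0:
        return seq
    lut = {ord(b): [ord(c) for c in "ACGT" if c != b] for b in "ACGT"}
    choices = rng.integers(0, 3, size=hit.size)
    for i, c in zip(hit, choices):
        arr[i] = lut[arr[i]][c]
    return arr.tobytes().decode("ascii")


def _qualities(length: int, profile: SimProfile, rng: np.random.Generator) -> list[int]:
    pos = np.arange(length) / max(length - 1, 1)
    q = profile.qual_mean - profile.qual_decay * pos + rng.normal(0, 2, size=length)
    return np.clip(np.rint(q), 2, 41).astype(int).tolist()


def _draw_start(glen: int, flen: int, circular: bool, rng: np.random.Generator) -> int:
    if circular:
        return int(rng.integers(0, glen))
    return int(rng.integers(0, max(glen - flen, 0) + 1))


# ---------------------------------------------------------------------------
# shotgun simulation


def simulate_shotgun(
    genomes: Sequence[SynGenome],
    abundances: Sequence[float],
    profile: SimProfile,
    platform: str,
    seed: int,
    *,
    coverage: Optional[float] = None,
    n_reads: Optional[int] = None,
) -> list[Read]:
    """Simulate direct-shotgun reads of a mixture of genomes.

    ``abundances`` must sum to 1; genome ``g`` receives an expected coverage
    of ``coverage * abundance_g``. With ``n_reads`` given instead, reads are
    allotted to genomes i.i.d. with probability proportional to
    ``abundance * genome length``. Platform B emits proper innie mate pairs
    (ids ``<base>/1`` and ``<base>/2``) with insert sizes from the profile.
    """
    if abs(sum(abundances) - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    if platform not in (PLATFORM_A, PLATFORM_B):
        raise ValueError(f"unknown platform {platform!r}")
    rng = np.random.default_rng(seed)
    if platform == PLATFORM_A:
        unit = profile.read_len_a_mean
        cov = profile.coverage_a if coverage is None else coverage
        if profile.read_len_a_min > min(len(g) for g in genomes):
            raise ValueError("read length exceeds genome length")
    else:
        unit = 2 * profile.read_len_b
        cov = profile.coverage_b if coverage is None else coverage
        if profile.read_len_b > min(len(g) for g in genomes):
            raise ValueError("read length exceeds genome length")

    if n_reads is not None:
        w = np.array([a * len(g) for a, g in zip(abundances, genomes)], dtype=float)
        counts = rng.multinomial(n_reads, w / w.sum())
    else:
        counts = [rng.poisson(cov * a * len(g) / unit) for a, g in zip(abundances, genomes)]

    reads: list[Read] = []
    serial = 0
    for genome, n in zip(genomes, counts):
        for _ in range(int(n)):
            serial += 1
            if platform == PLATFORM_A:
                flen = int(np.clip(rng.normal(profile.read_len_a_mean, profile.read_len_a_sd),
                                   profile.read_len_a_min, len(genome)))
                start = _draw_start(len(genome), flen, genome.circular, rng)
                frag = _fragment(genome, start, flen)
                strand = "+" if rng.random() < 0.5 else "-"
                seq = frag if strand == "+" else revcomp(frag)
                rid = f"A_{serial:07d}"
                reads.append(
                    Read(
                        id=rid,
                        platform=platform,
                        sequence=_apply_errors(seq, profile.error_rate, rng),
                        qualities=_qualities(len(seq), profile, rng),
                        truth=TruthEntry(genome.id, [(start + 1, start + flen)], [strand]),
                    )
                )
            else:
                rl = profile.read_len_b
                ins = int(np.clip(rng.normal(profile.insert_mean, profile.insert_sd), rl, len(genome)))
                start = _draw_start(len(genome), ins, genome.circular, rng)
                frag = _fragment(genome, start, ins)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    frag = revcomp(frag)
                base = f"B_{serial:07d}"
                r1_seq, r2_seq = frag[:rl], revcomp(frag[-rl:])
                if strand == "+":
                    iv1, iv2 = (start + 1, start + rl), (start + ins - rl + 1, start + ins)
                    s1, s2 = "+", "-"
                else:
                    iv1, iv2 = (start + ins - rl + 1, start + ins), (start + 1, start + rl)
                    s1, s2 = "-", "+"
                r1 = Read(
                    id=f"{base}/1", platform=platform,
                    sequence=_apply_errors(r1_seq, profile.error_rate, rng),
                    qualities=_qualities(rl, profile, rng), mate_id=f"{base}/2",
                    truth=TruthEntry(genome.id, [iv1], [s1]),
                )
                r2 = Read(
                    id=f"{base}/2", platform=platform,
                    sequence=_apply_errors(r2_seq, profile.error_rate, rng),
                    qualities=_qualities(rl, profile, rng), mate_id=f"{base}/1",
                    truth=TruthEntry(genome.id, [iv2], [s2]),
                )
                reads.extend((r1, r2))
    return reads


# ---------------------------------------------------------------------------
# WGA bait simulation


def simulate_wga(
    genome: SynGenome,
    profile: SimProfile,
    seed: int,
    *,
    coverage: Optional[float] = None,
    n_reads: Optional[int] = None,
) -> list[Read]:
    """Simulate a WGA bait library from a single (pure-culture) genome.

    Each read is chimeric with probability ``wga_chimera_rate``: a junction
    of two independently drawn loci (uniform junction point along the read,
    independent strands). Sampling intensity is modulated per 5 kb window by
    a lognormal(0, ``wga_bias_sigma``) amplification factor, mimicking the
    unevenness of multiple-displacement amplification.
    """
    if not genome.sequence:
        raise ValueError("genome is empty")
    rng = np.random.default_rng(seed)
    cov = profile.coverage_bait if coverage is None else coverage
    n = int(n_reads) if n_reads is not None else int(rng.poisson(cov * len(genome) / profile.read_len_a_mean))

    win = profile.wga_window
    n_win = max(1, -(-len(genome) // win))
    weights = rng.lognormal(0.0, profile.wga_bias_sigma, size=n_win)
    weights /= weights.sum()
    win_sizes = np.minimum(np.arange(1, n_win + 1) * win, len(genome)) - np.arange(n_win) * win

    def biased_start(flen: int) -> int:
        w = int(rng.choice(n_win, p=weights))
        off = int(rng.integers(0, win_sizes[w]))
        start = w * win + off
        if not genome.circular:
            start = min(start, max(len(genome) - flen, 0))
        return start

    reads: list[Read] = []
    for i in range(n):
        flen = int(np.clip(rng.normal(profile.read_len_a_mean, profile.read_len_a_sd),
                           profile.read_len_a_min, len(genome)))
        rid = f"W_{i + 1:07d}"
        if rng.random() < profile.wga_chimera_rate:
            j = int(rng.integers(1, flen))  # junction point: [1, flen-1]
            parts, ivs, strands = [], [], []
            for seg_len in (j, flen - j):
                start = biased_start(seg_len)
                frag = _fragment(genome, start, seg_len)
                strand = "+" if rng.random() < 0.5 else "-"
                parts.append(frag if strand == "+" else revcomp(frag))
                ivs.append((start + 1, start + seg_len))
                strands.append(strand)
            seq = "".join(parts)
            truth = TruthEntry(genome.id, ivs, strands, is_chimera=True)
        else:
            start = biased_start(flen)
            frag = _fragment(genome, start, flen)
            strand = "+" if rng.random() < 0.5 else "-"
            seq = frag if strand == "+" else revcomp(frag)
            truth = TruthEntry(genome.id, [(start + 1, start + flen)], [strand])
        reads.append(
            Read(
                id=rid, platform=PLATFORM_A,
                sequence=_apply_errors(seq, profile.error_rate, rng),
                qualities=_qualities(len(seq), profile, rng),
                truth=truth,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# truth sidecar


def write_truth_tsv(reads: Sequence[Read], path: str | Path) -> None:
    """Write the truth sidecar: one row per read, chimeras carry a second interval."""
    with open(path, "w") as fh:
        fh.write("read_id\tgenome_id\tstart\tend\tstrand\tis_chimera\tstart2\tend2\tstrand2\n")
        for r in reads:
            t = r.truth
            if t is None:
                continue
            (s1, e1), st1 = t.intervals[0], t.strands[0]
            if t.is_chimera:
                (s2, e2), st2 = t.intervals[1], t.strands[1]
                extra = f"{s2}\t{e2}\t{st2}"
            else:
                extra = "\t\t"
            fh.write(f"{r.id}\t{t.genome_id}\t{s1}\t{e1}\t{st1}\t{int(t.is_chimera)}\t{extra}\n")


def read_truth_tsv(path: str | Path) -> dict[str, TruthEntry]:
    truth: dict[str, TruthEntry] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rid, gid, s1, e1, st1, chim = f[0], f[1], int(f[2]), int(f[3]), f[4], bool(int(f[5]))
            if chim:
                truth[rid] = TruthEntry(gid, [(s1, e1), (int(f[6]), int(f[7]))], [st1, f[8]], True)
            else:
                truth[rid] = TruthEntry(gid, [(s1, e1)], [st1], False)
    return truth


# ---------------------------------------------------------------------------
# study-condition scenario


@dataclass
class Scenario:
    """One complete synthetic co-culture experiment with truth labels."""

    target: SynGenome
    contaminant: SynGenome
    bait_reads: list[Read]
    a_reads: list[Read]
    b_pairs: list[tuple[Read, Read]]
    profile: SimProfile

    @property
    def truth(self) -> dict[str, TruthEntry]:
        t = {r.id: r.truth for r in self.bait_reads + self.a_reads}
        for r1, r2 in self.b_pairs:
            t[r1.id], t[r2.id] = r1.truth, r2.truth
        return t


def standard_scenario(
    seed: int,
    *,
    genome_len: int = 100_000,
    gc: float = 0.47,
    shared_frac: float = 0.0,
    cov_a: float = 20.0,
    cov_b: float = 100.0,
    cov_bait: float = 10.0,
    chimera_rate: float = 0.1,
    profile: Optional[SimProfile] = None,
) -> Scenario:
    """Build the reference two-organism co-culture experiment.

    Two circular genomes of ``genome_len`` bp at equal abundance; DS reads at
    ``cov_a`` (platform A) and ``cov_b`` (platform B) per genome; WGA baits
    from the target at ``cov_bait`` with the given chimera rate.
    ``shared_frac`` implants a copy of that fraction of the target genome
    into the contaminant, for studying the method's failure mode as sequence
    sharing rises.
    """
    prof = profile or SimProfile()
    prof = replace(prof, wga_chimera_rate=chimera_rate,
                   coverage_a=2 * cov_a, coverage_b=2 * cov_b, coverage_bait=cov_bait)
    target = generate_genome(genome_len, gc, seed * 10 + 1, genome_id="target")
    contaminant = generate_genome(genome_len, gc, seed * 10 + 2, genome_id="contaminant")
    if shared_frac > 0:
        n = int(round(shared_frac * genome_len))
        contaminant = SynGenome(
            "contaminant",
            target.sequence[:n] + contaminant.sequence[n:],
            contaminant.circular,
        )
    genomes, ab = [target, contaminant], [0.5, 0.5]
    a_reads = simulate_shotgun(genomes, ab, prof, PLATFORM_A, seed * 10 + 3)
    b_reads = simulate_shotgun(genomes, ab, prof, PLATFORM_B, seed * 10 + 4)
    b_pairs = [(b_reads[i], b_reads[i + 1]) for i in range(0, len(b_reads), 2)]
    bait_reads = simulate_wga(target, prof, seed * 10 + 5)
    return Scenario(target, contaminant, bait_reads, a_reads, b_pairs, prof)
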