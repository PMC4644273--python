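import numpy as np
import pytest

from diffpick.kmers import canonical_kmer_set, revcomp
from diffpick.map_asm import Contig, assemble, assign_read, build_index
from diffpick.simdata import generate_genome

from .conftest import make_read, tiling_reads


def brute_force_kmers(seq, k):
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def has_duplicate_kmers(seq, k):
    seen = set()
    for i in range(len(seq) - k + 1):
        km = min(seq[i : i + k], revcomp(seq[i : i + k]))
        if km in seen:
            return True
        seen.add(km)
    return False


class TestAssemble:
    def test_reconstructs_repeat_free_genome(self):
        g = generate_genome(5000, 0.5, seed=21, circular=False)
        assert not has_duplicate_kmers(g.sequence, 31)
        reads = tiling_reads(g.sequence, read_len=200, step=50)
        asm = assemble(reads, k=31, min_kmer_count=1)
        assert len(asm.contigs) == 1
        seq = asm.contigs[0].sequence
        covered = g.sequence[: len(seq)]
        assert seq == covered or seq == revcomp(covered)

    def test_disjoint_genomes_never_mix(self):
        g1 = generate_genome(3000, 0.5, seed=22, circular=False)
        g2 = generate_genome(3000, 0.5, seed=23, circular=False)
        reads = tiling_reads(g1.sequence) + [
            make_read(r.sequence, rid=f"b{i}")
            for i, r in enumerate(tiling_reads(g2.sequence))
        ]
        asm = assemble(reads, k=31, min_kmer_count=1)
        k1 = canonical_kmer_set(g1.sequence, 31)
        k2 = canonical_kmer_set(g2.sequence, 31)
        for c in asm.contigs:
            ck = canonical_kmer_set(c.sequence, 31)
            from1 = np.isin(ck, k1).any()
            from2 = np.isin(ck, k2).any()
            assert not (from1 and from2)

    def test_k_not_below_read_length_raises(self):
        reads = [make_read("ACGTACGTACGTACGTACGTACGTACGTAC")]  # 30 bp
        with pytest.raises(ValueError):
            assemble(reads, k=31)

    def test_determinism(self):
        g = generate_genome(4000, 0.5, seed=24, circular=False)
        reads = tiling_reads(g.sequence, read_len=150, step=40)
        a1 = assemble(reads, k=31, min_kmer_count=1)
        a2 = assemble(list(reversed(reads)), k=31, min_kmer_count=1)
        canon = lambda s: min(s, revcomp(s))
        assert [canon(c.sequence) for c in a1.contigs] == [canon(c.sequence) for c in a2.contigs]

    def test_min_kmer_count_filters_singletons(self):
        g = generate_genome(2000, 0.5, seed=25, circular=False)
        reads = tiling_reads(g.sequence, read_len=150, step=75)
        # a one-off read full of private k-mers
        junk = generate_genome(1000, 0.5, seed=26, circular=False)
        reads.append(make_read(junk.sequence[:200], rid="junk"))
        asm = assemble(reads, k=31, min_kmer_count=2)
        jk = canonical_kmer_set(junk.sequence[:200], 31)
        for c in asm.contigs:
            assert not np.isin(canonical_kmer_set(c.sequence, 31), jk).any()


class TestIndexAndAssign:
    def test_index_position_count(self):
        idx = build_index([Contig("c1", "ACGTACGTACGTACGTACGT", 1.0)], k=17)
        assert idx.kmers.size == 4  # L - k + 1

    def test_lookup_own_kmer(self):
        g = generate_genome(2000, 0.5, seed=27, circular=False)
        idx = build_index([Contig("c1", g.sequence, 1.0)], k=21)
        km = canonical_kmer_set(g.sequence[100:121], 21)
        hits = idx.lookup(int(km[0]))
        assert ("c1", 101, "+") in hits or ("c1", 101, "-") in hits

    def test_lookup_absent_kmer_empty(self):
        idx = build_index([Contig("c1", "A" * 100, 1.0)], k=21)
        missing = canonical_kmer_set("ACGT" * 10, 21)
        assert idx.lookup(int(missing[0])) == []

    def test_exact_substring_full_fraction(self):
        g = generate_genome(3000, 0.5, seed=28, circular=False)
        idx = build_index([Contig("c1", g.sequence, 1.0)], k=21)
        read = make_read(g.sequence[500:900])
        pl = assign_read(read, idx, min_frac=0.5)
        assert pl is not None
        assert pl.contig_id == "c1" and pl.matched_kmer_fraction == 1.0
        assert pl.strand == "+" and pl.start == 501

    def test_reverse_complement_maps_minus_strand(self):
        g = generate_genome(3000, 0.5, seed=29, circular=False)
        idx = build_index([Contig("c1", g.sequence, 1.0)], k=21)
        pl = assign_read(make_read(revcomp(g.sequence[500:900])), idx, min_frac=0.5)
        assert pl is not None and pl.strand == "-" and pl.matched_kmer_fraction == 1.0
        assert pl.start == 501

    def test_unrelated_read_unassigned(self):
        g = generate_genome(100_000, 0.5, seed=30, circular=False)
        idx = build_index([Contig("c1", g.sequence, 1.0)], k=21)
        read_seq = generate_genome(1000, 0.5, seed=31, circular=False).sequence[:400]
        # oracle: count chance 21-mer hits directly
        ref = brute_force_kmers(g.sequence, 21) | brute_force_kmers(revcomp(g.sequence), 21)
        hits = sum(1 for i in range(400 - 21 + 1) if read_seq[i : i + 21] in ref)
        assert hits / (400 - 21 + 1) < 0.3
        assert assign_read(make_read(read_seq), idx, min_frac=0.3) is None

    def test_tie_between_contigs_unassigned(self):
        g = generate_genome(2000, 0.5, seed=32, circular=False)
        contigs = [Contig("c1", g.sequence, 1.0), Contig("c2", g.sequence, 1.0)]
        idx = build_index(contigs, k=21)
        assert assign_read(make_read(g.sequence[100:400]), idx, min_frac=0.5) is None

    def test_short_read_raises(self):
        idx = build_index([Contig("c1", "ACGT" * 30, 1.0)], k=21)
        with pytest.raises(ValueError):
            assign_read(make_read("ACGTACGT"), idx)

    def test_assembly_places_error_free_reads(self):
        g = generate_genome(4000, 0.5, seed=33, circular=False)
        reads = tiling_reads(g.sequence, read_len=200, step=100)
        asm = assemble(reads, k=31, min_kmer_count=1)
        assert set(asm.placements) == {r.id for r in reads}
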