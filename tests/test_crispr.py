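import numpy as np
import pytest

from diffpick.crispr import CrisprParams, consensus_repeat, find_arrays
from diffpick.simdata import generate_genome

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, size=n)])


def dissimilar_spacers(rng, n, length, max_identity=0.5):
    """Random spacers kept pairwise below the dissimilarity threshold."""
    from diffpick.crispr import _identity

    spacers = []
    while len(spacers) < n:
        cand = random_seq(rng, length)
        if all(_identity(cand, s) < max_identity for s in spacers):
            spacers.append(cand)
    return spacers


def plant_array(rng, repeat_len=29, n_spacers=3, spacer_len=35, flank=5000, repeat=None):
    """Random genome with one planted repeat/spacer array; returns (seq, start, end, repeat)."""
    rep = repeat or random_seq(rng, repeat_len)
    spacers = dissimilar_spacers(rng, n_spacers, spacer_len)
    array = rep + "".join(s + rep for s in spacers)
    left = random_seq(rng, flank)
    right = random_seq(rng, flank)
    start = flank + 1
    return left + array + right, start, flank + len(array), rep


class TestPlantedArray:
    def test_single_array_recovered_exactly(self):
        rng = np.random.default_rng(71)
        seq, start, end, rep = plant_array(rng)
        arrays = find_arrays(seq)
        assert len(arrays) == 1
        arr = arrays[0]
        assert arr.n_spacers == 3 and len(arr.repeats) == 4
        assert arr.consensus_repeat == rep
        assert (arr.start, arr.end) == (start, end)

    def test_coordinates_are_one_based_span(self):
        rng = np.random.default_rng(72)
        seq, start, end, _ = plant_array(rng, n_spacers=5)
        (arr,) = find_arrays(seq)
        span = sum(len(r) for _, r in arr.repeats) + sum(len(s) for _, s in arr.spacers)
        assert arr.end - arr.start + 1 == span
        assert arr.repeats[0][0] == arr.start
        assert arr.repeats[-1][0] + len(arr.repeats[-1][1]) - 1 == arr.end

    def test_alternation_invariant(self):
        rng = np.random.default_rng(73)
        seq, *_ = plant_array(rng, n_spacers=6)
        (arr,) = find_arrays(seq)
        assert len(arr.repeats) == len(arr.spacers) + 1
        marks = sorted(
            [(p, "r") for p, _ in arr.repeats] + [(p, "s") for p, _ in arr.spacers]
        )
        assert [m for _, m in marks] == ["r", "s"] * arr.n_spacers + ["r"]

    def test_degenerate_terminal_copy_included(self):
        rng = np.random.default_rng(74)
        rep = random_seq(rng, 30)
        spacers = dissimilar_spacers(rng, 4, 36)
        # last copy carries 6/30 = 20%...33% substitutions
        bad = list(rep)
        for i in rng.choice(30, size=7, replace=False):
            bad[i] = "ACGT"[(("ACGT".index(bad[i])) + 1) % 4]
        array = rep + spacers[0] + rep + spacers[1] + rep + spacers[2] + rep + spacers[3] + "".join(bad)
        seq = random_seq(rng, 3000) + array + random_seq(rng, 3000)
        (arr,) = find_arrays(seq)
        assert len(arr.repeats) == 5 and arr.n_spacers == 4

    def test_random_sequence_has_no_arrays(self):
        g = generate_genome(100_000, 0.5, seed=75).sequence
        # brute-force confirmation: no 23-mer occurs 3+ times with compliant gaps
        occ = {}
        for i in range(len(g) - 22):
            occ.setdefault(g[i : i + 23], []).append(i)
        p = CrisprParams()
        min_gap = int(p.repeat_min * (1 + p.spacer_min_ratio))
        max_gap = int(p.repeat_max * (1 + p.spacer_max_ratio)) + 1
        for positions in occ.values():
            run = 1
            best = 1
            for a, b in zip(positions, positions[1:]):
                run = run + 1 if min_gap <= b - a <= max_gap else 1
                best = max(best, run)
            assert best < 3
        assert find_arrays(g) == []

    def test_planted_recovery_property(self):
        # many random geometries: repeat length, spacer count and spacer
        # length all drawn from the compliant ranges
        rng = np.random.default_rng(76)
        for trial in range(100):
            rep_len = int(rng.integers(23, 56))
            n_spacers = int(rng.integers(3, 21))
            spacer_len = int(rng.integers(int(np.ceil(0.6 * rep_len)), int(2.5 * rep_len)))
            seq, start, end, rep = plant_array(
                rng, repeat_len=rep_len, n_spacers=n_spacers, spacer_len=spacer_len, flank=1500
            )
            arrays = find_arrays(seq)
            assert len(arrays) == 1, f"trial {trial}: {len(arrays)} arrays"
            arr = arrays[0]
            assert arr.n_spacers == n_spacers, f"trial {trial}"
            assert len(arr.repeats) == n_spacers + 1


class TestConsensus:
    def test_identical_copies(self):
        assert consensus_repeat(["ACGTACG"] * 4) == "ACGTACG"

    def test_majority_overrides_single_substitution(self):
        assert consensus_repeat(["ACGTACG", "ACGTACG", "ACGTACG", "ACTTACG"]) == "ACGTACG"

    def test_tie_becomes_iupac(self):
        assert consensus_repeat(["AC", "AC", "AG", "AG"]) == "AS"

    def test_requires_three_copies(self):
        with pytest.raises(ValueError):
            consensus_repeat(["AC", "AC"])

    def test_unequal_lengths_aligned_5prime(self):
        # trailing column present in 2/4 copies (50% occupancy) is kept
        assert consensus_repeat(["ACGT", "ACGT", "ACG", "ACG"]) == "ACGT"
        # present in only 1/4: dropped
        assert consensus_repeat(["ACGT", "ACG", "ACG", "ACG"]) == "ACG"
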