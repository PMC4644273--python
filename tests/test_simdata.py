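import numpy as np
import pytest

from diffpick.kmers import revcomp
from diffpick.simdata import (
    PLATFORM_A,
    PLATFORM_B,
    SimProfile,
    generate_genome,
    simulate_shotgun,
    simulate_wga,
    standard_scenario,
)


class TestGenerateGenome:
    def test_length_contract(self):
        g = generate_genome(10_000, 0.47, seed=1)
        assert len(g.sequence) == 10_000

    def test_determinism(self):
        a = generate_genome(5_000, 0.5, seed=7)
        b = generate_genome(5_000, 0.5, seed=7)
        assert a.sequence == b.sequence

    def test_gc_fraction(self):
        # binomial SE at n=1e5 is ~0.0016, so +-0.01 is a >6 sigma band
        g = generate_genome(100_000, 0.47, seed=2)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / len(g.sequence)
        assert abs(gc - 0.47) < 0.01

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1, 1.5])
    def test_gc_out_of_range(self, gc):
        with pytest.raises(ValueError):
            generate_genome(2000, gc, seed=1)


class TestShotgun:
    def test_total_bases_near_coverage_target(self):
        # the fragment count is Poisson(2500) per run (sigma ~2%), so check
        # the mean of 5 independent runs against the 10^6 bp target
        g = generate_genome(50_000, 0.47, seed=3)
        prof = SimProfile(error_rate=0.0)
        totals = []
        for seed in range(4, 9):
            reads = simulate_shotgun([g], [1.0], prof, PLATFORM_A, seed=seed, coverage=20)
            totals.append(sum(len(r.sequence) for r in reads))
        mean = sum(totals) / len(totals)
        assert abs(mean - 1_000_000) / 1_000_000 < 0.02

    def test_abundance_proportions(self):
        g1 = generate_genome(20_000, 0.47, seed=5, genome_id="g1")
        g2 = generate_genome(20_000, 0.47, seed=6, genome_id="g2")
        prof = SimProfile()
        reads = simulate_shotgun([g1, g2], [0.8, 0.2], prof, PLATFORM_A, seed=7, n_reads=10_000)
        frac = sum(1 for r in reads if r.truth.genome_id == "g1") / len(reads)
        assert abs(frac - 0.8) < 0.02

    def test_error_free_reads_are_substrings(self, genome_20kb, noiseless_profile):
        reads = simulate_shotgun([genome_20kb], [1.0], noiseless_profile, PLATFORM_A, seed=8, n_reads=200)
        doubled = genome_20kb.sequence * 2  # circular genome: fragments may wrap
        for r in reads:
            assert r.sequence in doubled or revcomp(r.sequence) in doubled

    def test_paired_reads_are_proper_mates(self, genome_20kb, noiseless_profile):
        reads = simulate_shotgun([genome_20kb], [1.0], noiseless_profile, PLATFORM_B, seed=9, n_reads=100)
        assert len(reads) == 200
        by_id = {r.id: r for r in reads}
        doubled = genome_20kb.sequence * 2
        for r in reads:
            assert len(r.sequence) == 251 == len(r.qualities)
            assert by_id[r.mate_id].mate_id == r.id  # symmetric mate link
            assert r.sequence in doubled or revcomp(r.sequence) in doubled

    def test_truth_partition(self, genome_20kb):
        prof = SimProfile()
        reads = simulate_shotgun([genome_20kb], [1.0], prof, PLATFORM_B, seed=10, n_reads=50)
        assert all(r.truth is not None for r in reads)
        assert len({r.id for r in reads}) == len(reads)

    def test_determinism(self, genome_20kb):
        prof = SimProfile()
        a = simulate_shotgun([genome_20kb], [1.0], prof, PLATFORM_A, seed=12, n_reads=100)
        b = simulate_shotgun([genome_20kb], [1.0], prof, PLATFORM_A, seed=12, n_reads=100)
        assert [(r.id, r.sequence, r.qualities) for r in a] == [
            (r.id, r.sequence, r.qualities) for r in b
        ]

    def test_abundances_must_sum_to_one(self, genome_20kb):
        with pytest.raises(ValueError):
            simulate_shotgun([genome_20kb], [0.5], SimProfile(), PLATFORM_A, seed=1)

    def test_read_longer_than_genome_raises(self):
        g = generate_genome(1000, 0.5, seed=1)
        prof = SimProfile(read_len_a_min=2000)
        with pytest.raises(ValueError):
            simulate_shotgun([g], [1.0], prof, PLATFORM_A, seed=1)


class TestWga:
    def test_zero_chimera_rate_gives_substrings(self, genome_20kb):
        prof = SimProfile(error_rate=0.0, wga_chimera_rate=0.0)
        reads = simulate_wga(genome_20kb, prof, seed=13, n_reads=300)
        doubled = genome_20kb.sequence * 2
        for r in reads:
            assert not r.truth.is_chimera
            assert r.sequence in doubled or revcomp(r.sequence) in doubled

    def test_full_chimera_rate_gives_two_intervals(self, genome_20kb):
        prof = SimProfile(wga_chimera_rate=1.0)
        reads = simulate_wga(genome_20kb, prof, seed=14, n_reads=100)
        for r in reads:
            assert r.truth.is_chimera and len(r.truth.intervals) == 2

    def test_chimera_fraction_matches_rate(self, genome_20kb):
        prof = SimProfile(wga_chimera_rate=0.3)
        reads = simulate_wga(genome_20kb, prof, seed=15, n_reads=10_000)
        frac = sum(r.truth.is_chimera for r in reads) / len(reads)
        assert abs(frac - 0.3) < 0.015

    def test_coverage_bias_is_uneven(self, genome_20kb):
        # with sigma=1 the per-window read-start counts should spread far
        # beyond Poisson noise around the mean
        prof = SimProfile(wga_chimera_rate=0.0, wga_bias_sigma=1.0)
        reads = simulate_wga(genome_20kb, prof, seed=16, n_reads=4000)
        starts = np.array([r.truth.intervals[0][0] - 1 for r in reads])
        counts = np.bincount(starts // 5000, minlength=4)
        assert counts.max() > 2 * counts.min() + 10

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            SimProfile(wga_chimera_rate=1.5)


class TestScenario:
    def test_scenario_labels_cover_all_reads(self):
        sc = standard_scenario(3, genome_len=5_000, cov_a=5, cov_b=10, cov_bait=3)
        truth = sc.truth
        ids = [r.id for r in sc.a_reads + sc.bait_reads] + [
            r.id for p in sc.b_pairs for r in p
        ]
        assert set(ids) <= set(truth)
        assert len(set(ids)) == len(ids)

    def test_shared_fraction_implants_target_sequence(self):
        sc = standard_scenario(4, genome_len=5_000, shared_frac=0.1, cov_a=5, cov_b=10, cov_bait=3)
        assert sc.contaminant.sequence[:500] == sc.target.sequence[:500]
        assert sc.contaminant.sequence[500:] != sc.target.sequence[500:]
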