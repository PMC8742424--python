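import math

import edlib
import numpy as np
import pytest

from mitomix.simdata import (
    SimConfig,
    SpikeDesign,
    add_offtarget_reads,
    build_mixture,
    build_spike_series,
    divergence_to_mutation,
    simulate_panel,
    simulate_reads,
)
from mitomix.refdb import p_distance

from _oracles import revcomp


class TestSimulatePanel:
    def test_zero_mutation_identical_genomes(self):
        panel = simulate_panel(3, 500, 0.0, seed=1)
        assert len({g.sequence for g in panel}) == 1

    def test_pairwise_distance_matches_closed_form(self):
        m, L = 0.1, 10000
        panel = simulate_panel(2, L, m, seed=2)
        expected = 2 * m * (1 - m) + (2 / 3) * m * m  # = 0.186667
        sd = math.sqrt(expected * (1 - expected) / L)
        observed = p_distance(panel[0].sequence, panel[1].sequence)
        assert abs(observed - expected) < 3 * sd

    def test_exact_substitution_count_per_species(self):
        panel = simulate_panel(2, 1000, 0.1, seed=3)
        # each species differs from the common ancestor at exactly 100 sites;
        # regenerate with m=0 and the same seed to recover the ancestor
        ancestor = simulate_panel(1, 1000, 0.0, seed=3)[0].sequence
        diffs = sum(a != b for a, b in zip(ancestor, panel[0].sequence))
        assert diffs == 100

    def test_deterministic(self):
        a = simulate_panel(4, 800, 0.05, seed=9)
        b = simulate_panel(4, 800, 0.05, seed=9)
        assert [g.sequence for g in a] == [g.sequence for g in b]

    def test_bad_args(self):
        with pytest.raises(ValueError):
            simulate_panel(0, 100, 0.1, seed=1)
        with pytest.raises(ValueError):
            simulate_panel(2, 100, 0.5, seed=1)


def test_divergence_to_mutation_inverts_expectation():
    for p in (0.05, 0.2, 0.4):
        m = divergence_to_mutation(p)
        assert 2 * m * (1 - m) + (2 / 3) * m * m == pytest.approx(p)


class TestSimulateReads:
    def test_zero_reads(self):
        genome = simulate_panel(1, 400, 0.0, seed=4)[0]
        assert simulate_reads(genome, 0, SimConfig()) == []

    def test_error_free_reads_are_substrings(self):
        genome = simulate_panel(1, 400, 0.0, seed=5)[0]
        doubled = genome.sequence * 2
        reads = simulate_reads(genome, 200, SimConfig(read_length=100, error_rate=0.0, seed=6))
        spanning = 0
        for read in reads:
            assert read.sequence in doubled or revcomp(read.sequence) in doubled
            fwd = read.sequence if read.sequence in doubled else revcomp(read.sequence)
            if fwd not in genome.sequence:
                spanning += 1
            assert read.truth_species == genome.species_id
            assert read.qualities == (30,) * 100
        assert spanning > 0  # some reads cross the origin of the circle

    def test_substitution_count_matches_binomial(self):
        genome = simulate_panel(1, 2000, 0.0, seed=7)[0]
        n, rl, e = 2000, 150, 0.01
        reads = simulate_reads(genome, n, SimConfig(read_length=rl, error_rate=e, seed=8))
        doubled = genome.sequence * 2
        total_edits = sum(
            min(
                edlib.align(r.sequence, doubled, mode="HW")["editDistance"],
                edlib.align(revcomp(r.sequence), doubled, mode="HW")["editDistance"],
            )
            for r in reads
        )
        expected = n * rl * e
        sd = math.sqrt(n * rl * e * (1 - e))
        assert abs(total_edits - expected) < 3 * sd

    def test_read_longer_than_genome_error(self):
        genome = simulate_panel(1, 100, 0.0, seed=9)[0]
        with pytest.raises(ValueError):
            simulate_reads(genome, 1, SimConfig(read_length=150))

    def test_deterministic(self):
        genome = simulate_panel(1, 500, 0.0, seed=10)[0]
        a = simulate_reads(genome, 50, SimConfig(seed=11))
        b = simulate_reads(genome, 50, SimConfig(seed=11))
        assert a == b


class TestBuildMixture:
    @pytest.fixture()
    def pools(self):
        panel = simulate_panel(2, 500, 0.1, seed=12, species_ids=["A", "B"])
        return {
            "A": simulate_reads(panel[0], 40000, SimConfig(read_length=60, seed=13)),
            "B": simulate_reads(panel[1], 40000, SimConfig(read_length=60, seed=14)),
        }

    def test_counts_and_labels(self, pools):
        mix = build_mixture(pools, {"A": 3, "B": 0}, seed=1)
        assert len(mix) == 3
        assert all(r.truth_species == "A" for r in mix)

    def test_two_percent_spike_count(self, pools):
        mix = build_mixture(pools, {"A": 29400, "B": 600}, seed=2)
        labels = [r.truth_species for r in mix]
        assert labels.count("B") == 600
        assert len(mix) == 30000

    def test_deterministic_order(self, pools):
        a = build_mixture(pools, {"A": 100, "B": 50}, seed=3)
        b = build_mixture(pools, {"A": 100, "B": 50}, seed=3)
        assert [r.read_id for r in a] == [r.read_id for r in b]

    def test_insufficient_reads_names_species(self, pools):
        with pytest.raises(ValueError, match="B"):
            build_mixture(pools, {"A": 10, "B": 50000}, seed=4)


class TestSpikeSeries:
    def test_level_rounding(self):
        design = SpikeDesign("pig", "chicken")
        assert design.minor_count(0.01) == 3
        assert design.minor_count(2) == 600

    def test_full_design_product(self):
        panel = simulate_panel(2, 300, 0.1, seed=15, species_ids=["pig", "chicken"])
        pools = {
            g.species_id: simulate_reads(g, 600, SimConfig(read_length=60, seed=16 + i))
            for i, g in enumerate(panel)
        }
        design = SpikeDesign(
            "pig", "chicken", total_reads=500,
            levels=(0.01, 1, 50, 100), replicates=5,
        )
        datasets = build_spike_series(design, pools["pig"], pools["chicken"], seed=5)
        assert len(datasets) == 4 * 5
        full = [d for d in datasets if d.level == 100]
        assert all(
            all(r.truth_species == "chicken" for r in d.reads) for d in full
        )
        for d in datasets:
            labels = [r.truth_species for r in d.reads]
            assert labels.count("chicken") == d.minor_count
            assert len(d.reads) == design.total_reads

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            SpikeDesign("a", "b", levels=(0.0,))


class TestOfftarget:
    def test_zero_noise_unchanged(self):
        reads = []
        assert add_offtarget_reads(reads, 0, 100, seed=1) == []

    def test_deterministic_and_labelled(self):
        a = add_offtarget_reads([], 20, 100, seed=2)
        b = add_offtarget_reads([], 20, 100, seed=2)
        assert a == b
        assert all(r.truth_species == "offtarget" for r in a)

    def test_noise_rarely_shares_21mer_with_genome(self):
        genome = simulate_panel(1, 16000, 0.0, seed=17)[0]
        kmers = {genome.sequence[i : i + 21] for i in range(len(genome) - 20)}
        noise = add_offtarget_reads([], 100, 150, seed=18)
        colliding = sum(
            any(r.sequence[i : i + 21] in kmers for i in range(len(r.sequence) - 20))
            for r in noise
        )
        assert colliding <= 1  # >=99% clean
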