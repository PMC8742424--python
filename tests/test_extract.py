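import numpy as np
import pytest

from mitomix.extract import ClassifierParams, classify_read, extract_mito
from mitomix.seqio import ReadRecord
from mitomix.simdata import SimConfig, add_offtarget_reads, build_mixture, simulate_reads

from _oracles import exhaustive_ungapped_hit, revcomp
from conftest import mutate_sites


def _record(seq, rid="r"):
    return ReadRecord(rid, seq)


class TestClassifyRead:
    def test_exact_substring_hits_with_full_identity(self, panel3, db3):
        seq = panel3[0].sequence[100:250]
        hit = classify_read(_record(seq), db3)
        assert hit is not None
        assert hit.species_id == "alpha"
        assert hit.identity == 1.0
        assert hit.span == 150

    def test_reverse_complement_hits(self, panel3, db3):
        seq = revcomp(panel3[1].sequence[500:650])
        hit = classify_read(_record(seq), db3)
        assert hit is not None
        assert hit.species_id == "beta"
        assert hit.strand == "-"

    def test_origin_spanning_read_hits(self, panel3, db3):
        g = panel3[2].sequence
        seq = g[-70:] + g[:80]
        hit = classify_read(_record(seq), db3)
        assert hit is not None and hit.species_id == "gamma"

    def test_random_read_misses(self, db3):
        rng = np.random.default_rng(77)
        seq = "".join(rng.choice(list("ACGT"), size=150))
        assert classify_read(_record(seq), db3) is None

    def test_short_read_returns_none(self, db3):
        assert classify_read(_record("ACGTACGTACGT"), db3) is None

    def test_mismatched_k_rejected(self, db3):
        with pytest.raises(ValueError, match="k"):
            classify_read(_record("A" * 150), db3, ClassifierParams(k=15))

    def test_noisy_reads_recovered_by_alignment(self, panel3, db3):
        """10%-substituted reference substrings are recoverable: exhaustive
        ungapped alignment finds a hit with identity >= 0.85 in at least 95%
        of trials, and every hit the seeded classifier reports matches the
        oracle's species and passes the same thresholds."""
        rng = np.random.default_rng(88)
        genomes = {g.species_id: g.sequence for g in panel3}
        params = ClassifierParams()
        n_trials, oracle_hits = 300, 0
        for _ in range(n_trials):
            src = panel3[rng.integers(0, 3)]
            start = rng.integers(0, len(src) - 150)
            seq = mutate_sites(src.sequence[start : start + 150], 15, seed=int(rng.integers(2**31)))
            oracle = exhaustive_ungapped_hit(
                seq, genomes, circular=True,
                min_identity=params.min_identity, min_span=params.min_span,
            )
            if oracle is not None and oracle[1] >= 0.85:
                oracle_hits += 1
            hit = classify_read(_record(seq), db3, params)
            if hit is not None:
                assert oracle is not None
                assert hit.species_id == oracle[0]
                assert hit.identity >= params.min_identity
                assert hit.span >= params.min_span
        assert oracle_hits >= 0.95 * n_trials

    def test_classifier_agrees_with_oracle_at_default_conditions(
        self, panel3, db3, reads_by_species
    ):
        """At the generator's default error rate the seeded classifier and
        the exhaustive all-diagonal oracle agree on >= 99.5% of reads."""
        mixed = build_mixture(
            reads_by_species, {"alpha": 70, "beta": 70, "gamma": 70}, seed=14
        )
        mixed = add_offtarget_reads(mixed, 40, 150, seed=15)
        genomes = {g.species_id: g.sequence for g in panel3}
        params = ClassifierParams()
        agree = 0
        for read in mixed:
            hit = classify_read(read, db3, params)
            oracle = exhaustive_ungapped_hit(
                read.sequence, genomes, circular=True,
                min_identity=params.min_identity, min_span=params.min_span,
            )
            if (hit is None) == (oracle is None):
                agree += 1
        assert agree >= 0.995 * len(mixed)


class TestExtractMito:
    def test_truth_label_split_error_free(self, panel3, db3):
        reads = simulate_reads(panel3[0], 500, SimConfig(error_rate=0.0, seed=5))
        mixed = add_offtarget_reads(reads, 500, 150, seed=6)
        result = extract_mito(mixed, db3)
        assert len(result.mito_reads) == 500
        assert len(result.unmapped_reads) == 500
        assert all(r.truth_species == "alpha" for r in result.mito_reads)
        assert all(r.truth_species == "offtarget" for r in result.unmapped_reads)
        assert result.mito_fraction == 0.5

    def test_partition_preserves_order_and_ids(self, reads_by_species, db3):
        mixed = build_mixture(reads_by_species, {"alpha": 100, "beta": 100, "gamma": 100}, seed=9)
        mixed = add_offtarget_reads(mixed, 30, 150, seed=10)
        result = extract_mito(mixed, db3)
        assert result.n_input == len(mixed)
        out_ids = {r.read_id for r in result.mito_reads} | {
            r.read_id for r in result.unmapped_reads
        }
        assert out_ids == {r.read_id for r in mixed}
        mito_ids = [r.read_id for r in result.mito_reads]
        input_order = {r.read_id: i for i, r in enumerate(mixed)}
        assert mito_ids == sorted(mito_ids, key=input_order.get)

    def test_recall_on_noisy_reads(self, reads_by_species, db3):
        mixed = build_mixture(reads_by_species, {"alpha": 300, "beta": 300, "gamma": 300}, seed=11)
        result = extract_mito(mixed, db3)
        assert len(result.mito_reads) >= 0.99 * 900

    def test_all_offtarget_zero_fraction(self, db3):
        noise = add_offtarget_reads([], 200, 150, seed=12)
        result = extract_mito(noise, db3)
        assert result.mito_fraction == 0.0

    def test_empty_input(self, db3):
        result = extract_mito([], db3)
        assert result.mito_fraction is None
        assert result.n_input == 0

    def test_short_reads_counted(self, db3):
        result = extract_mito([_record("ACGT")], db3)
        assert result.n_too_short == 1
        assert len(result.unmapped_reads) == 1

    def test_min_identity_monotonicity(self, panel3, db3):
        rng = np.random.default_rng(13)
        reads = []
        for i in range(200):
            start = rng.integers(0, len(panel3[0]) - 150)
            n_mut = int(rng.integers(0, 40))
            reads.append(
                _record(
                    mutate_sites(
                        panel3[0].sequence[start : start + 150], n_mut, seed=i
                    ),
                    rid=f"n{i}",
                )
            )
        counts = [
            len(extract_mito(reads, db3, ClassifierParams(min_identity=mi)).mito_reads)
            for mi in (0.95, 0.85, 0.75, 0.65)
        ]
        assert counts == sorted(counts)
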