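import numpy as np
import pytest

import porebias as pb
from porebias.io_formats import ReadClass
from porebias.read_metrics import percent_identity
from porebias.synthetic_data import (
    SimulationConfig,
    default_transition_matrix,
    generate_reference,
    make_replicates,
    sample_markov_chains,
    simulate_reads,
    stationary_distribution,
)

from conftest import reconstruct_alignment_columns


class TestReference:
    def test_realized_gc_within_binomial_error(self):
        length = 200_000
        for gc in (0.28, 0.5, 0.68):
            ref = generate_reference(length, gc, seed=3)
            realized = (ref.sequence.count("G") + ref.sequence.count("C")) / length
            se = np.sqrt(gc * (1 - gc) / length)
            assert abs(realized - gc) < 3 * se

    def test_determinism(self):
        a = generate_reference(5000, 0.5, seed=9)
        b = generate_reference(5000, 0.5, seed=9)
        assert a.sequence == b.sequence

    def test_extreme_gc_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(5000, 1.0, seed=0)
        with pytest.raises(ValueError):
            generate_reference(5000, 0.0, seed=0)


class TestMarkovSampler:
    def test_chain_lengths_and_range(self, rng):
        T = default_transition_matrix(10)
        chains = sample_markov_chains([5, 50, 500], T, rng)
        assert [len(c) for c in chains] == [5, 50, 500]
        assert all(c.min() >= 0 and c.max() <= 9 for c in chains)

    def test_default_matrix_is_doubly_stochastic(self):
        T = default_transition_matrix(10)
        assert np.allclose(T.sum(axis=1), 1.0)
        assert np.allclose(stationary_distribution(T), 0.1)

    def test_deterministic_given_seed(self):
        T = default_transition_matrix(5)
        a = sample_markov_chains([100, 20], T, np.random.default_rng(7))
        b = sample_markov_chains([100, 20], T, np.random.default_rng(7))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestSimulateReads:
    def test_null_config_yields_exact_substrings(self):
        cfg = SimulationConfig(
            seed=2,
            genome_length=20_000,
            n_reads=50,
            length_median=300,
            length_sigma=0.3,
            length_max=2000,
            q_levels=np.array([12.0]),
            q_transition_matrix=np.array([[1.0]]),
            base_q_offsets={},
            end_dip_delta=0.0,
            short_read_penalty=0.0,
            complement_q_offset=0.0,
            consensus_q_boost=0.0,
            substitution_rate=0.0,
            insertion_rate=0.0,
            deletion_rate=0.0,
        )
        ref = generate_reference(cfg.genome_length, cfg.genome_gc, cfg.seed)
        ds = simulate_reads(cfg, ref)
        from porebias.kmer_bias import aligned_read_portion

        for read, aln in zip(ds.reads, ds.alignments):
            assert set(read.qualities) == {12}
            assert aln.cigar == [("M", len(read))]
            assert percent_identity(aln) == 100.0
            assert (
                aligned_read_portion(read, aln)
                == ref.sequence[aln.ref_start : aln.ref_end]
            )

    def test_substitution_rate_sets_identity(self):
        cfg = SimulationConfig(
            seed=4,
            genome_length=100_000,
            n_reads=1000,
            length_median=500,
            length_sigma=0.2,
            fraction_2d=0.0,
            substitution_rate=0.05,
            insertion_rate=0.0,
            deletion_rate=0.0,
        )
        ref = generate_reference(cfg.genome_length, cfg.genome_gc, cfg.seed)
        ds = simulate_reads(cfg, ref)
        pid = np.mean([percent_identity(a) for a in ds.alignments])
        assert pid == pytest.approx(95.0, abs=0.5)

    def test_truth_cigar_consistent_with_planted_errors(self, small_dataset):
        """Reconstructed alignments have exactly the planted mismatch,
        insertion, and deletion counts."""
        ref_seq = small_dataset.reference.sequence
        for read, aln, truth in zip(
            small_dataset.reads, small_dataset.alignments, small_dataset.truth
        ):
            m, mm, cols = reconstruct_alignment_columns(read.sequence, ref_seq, aln)
            assert mm == truth.n_sub
            assert aln.nm == truth.n_sub + truth.n_ins + truth.n_del
            assert cols == sum(n for op, n in aln.cigar if op in "MID")
            assert aln.ref_end - aln.ref_start == truth.ref_interval[1] - truth.ref_interval[0]

    def test_2d_molecules_emit_three_read_classes(self, small_dataset):
        classes = {}
        for read in small_dataset.reads:
            classes.setdefault(read.id, set()).add(read.read_class)
        for cls_set in classes.values():
            assert cls_set == {ReadClass.RAW_1D} or cls_set == {
                ReadClass.TEMPLATE,
                ReadClass.COMPLEMENT,
                ReadClass.CONSENSUS_2D,
            }

    def test_short_reads_scored_low(self):
        cfg = SimulationConfig(
            seed=6,
            genome_length=50_000,
            n_reads=400,
            length_median=220,
            length_sigma=0.5,
            length_max=2000,
            fraction_2d=0.0,
            short_read_cutoff=200,
            short_read_penalty=4.0,
        )
        ref = generate_reference(cfg.genome_length, cfg.genome_gc, cfg.seed)
        ds = simulate_reads(cfg, ref)
        short = [np.mean(r.qualities) for r in ds.reads if len(r) <= 200]
        longer = [np.mean(r.qualities) for r in ds.reads if len(r) > 300]
        assert np.mean(short) < np.mean(longer) - 3

    def test_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=8, genome_length=10_000, n_reads=30, length_median=300)
        ref = generate_reference(cfg.genome_length, cfg.genome_gc, cfg.seed)
        paths1 = simulate_reads(cfg, ref).write(tmp_path / "a_")
        paths2 = simulate_reads(cfg, ref).write(tmp_path / "b_")
        for key in ("fastq", "sam", "fasta"):
            assert paths1[key].read_bytes() == paths2[key].read_bytes()

    def test_coupled_errors_prefer_low_q_positions(self):
        common = dict(
            genome_length=80_000,
            n_reads=600,
            length_median=600,
            length_sigma=0.2,
            fraction_2d=0.0,
            base_q_offsets={},
            end_dip_delta=0.0,
            short_read_penalty=0.0,
            substitution_rate=0.08,
            insertion_rate=0.0,
            deletion_rate=0.0,
        )
        ref = generate_reference(80_000, 0.5, seed=11)

        def mean_q_at_mismatches(coupled):
            cfg = SimulationConfig(seed=11, couple_errors_to_q=coupled, **common)
            ds = simulate_reads(cfg, ref)
            qs, all_q = [], []
            for read, aln in zip(ds.reads, ds.alignments):
                if aln.strand != "+" or aln.cigar != [("M", len(read))]:
                    continue
                seg = ref.sequence[aln.ref_start : aln.ref_end]
                q = np.asarray(read.qualities)
                mism = np.frombuffer(read.sequence.encode(), np.uint8) != np.frombuffer(
                    seg.encode(), np.uint8
                )
                qs.extend(q[mism])
                all_q.extend(q)
            return np.mean(qs), np.mean(all_q)

        q_mm_coupled, q_all = mean_q_at_mismatches(True)
        q_mm_uncoupled, _ = mean_q_at_mismatches(False)
        assert q_mm_coupled < q_all - 1  # errors sit at low-Q positions
        assert abs(q_mm_uncoupled - q_all) < 0.5


class TestReplicates:
    def test_three_distinct_deterministic_replicates(self):
        cfg = SimulationConfig(seed=13, genome_length=20_000, n_reads=40, length_median=300)
        ref1, reps1 = make_replicates(cfg, 3)
        ref2, reps2 = make_replicates(cfg, 3)
        assert ref1.sequence == ref2.sequence
        assert len(reps1) == 3
        seqs = ["".join(r.sequence for r in ds.reads) for ds in reps1]
        assert len(set(seqs)) == 3  # replicates differ
        for a, b in zip(reps1, reps2):
            assert all(x.sequence == y.sequence for x, y in zip(a.reads, b.reads))

    def test_minimum_replicates(self):
        with pytest.raises(ValueError):
            make_replicates(SimulationConfig(), 1)


class TestConfigValidation:
    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(substitution_rate=0.7, deletion_rate=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(genome_gc=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(kmer_bias_spikes={"ACG": 2.0})

    def test_transition_rows_must_normalize(self):
        T = default_transition_matrix(10)
        T[0, 0] += 0.2
        with pytest.raises(ValueError):
            SimulationConfig(q_transition_matrix=T)
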