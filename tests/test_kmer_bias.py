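import numpy as np
import pytest

import porebias as pb
from porebias.io_formats import AlignmentRecord, ReadClass, ReadRecord, reverse_complement
from porebias.kmer_bias import (
    KmerTable,
    aligned_read_portion,
    annotate_volcano,
    bh_adjust,
    count_kmers,
    kmer_bias_analysis,
    kmer_strings,
    mapped_kmer_tables,
    nb_regression,
    normalized_ratio,
    replicate_concordance,
    zscore_outliers,
)
from porebias.synthetic_data import simulate_read_kmer_tables

from conftest import random_sequence


@pytest.fixture(scope="module")
def ref_table():
    ref = pb.generate_reference(200_000, 0.4, seed=21)
    return count_kmers([ref], 5, source_label="reference")


class TestCountKmers:
    def test_enumeration_example(self):
        t = count_kmers(["ACGTACGT"], 5)
        nonzero = {k: int(v) for k, v in t.as_series().items() if v}
        assert nonzero == {"ACGTA": 1, "CGTAC": 1, "GTACG": 1, "TACGT": 1}

    def test_key_space_is_complete(self):
        t = count_kmers(["ACGT"], 5)
        assert len(t.counts) == 1024 == len(kmer_strings(5))
        assert len(set(kmer_strings(5))) == 1024

    def test_homopolymer_overlap(self):
        assert count_kmers(["AAAAAA"], 5).as_series()["AAAAA"] == 2

    def test_n_windows_skipped(self):
        t = count_kmers(["ACGTNACGTA"], 5)
        # windows 0-4 contain the N except the last window ACGTA
        assert t.total == 1 and t.as_series()["ACGTA"] == 1

    def test_short_sequences_contribute_nothing(self):
        assert count_kmers(["ACG", "", "ACGTA"], 5).total == 1

    def test_permutation_invariance(self, rng):
        seqs = [random_sequence(rng, 200) for _ in range(10)]
        a = count_kmers(seqs, 4)
        b = count_kmers(seqs[::-1], 4)
        assert np.array_equal(a.counts, b.counts)

    def test_total_matches_window_count(self, rng):
        seqs = [random_sequence(rng, n) for n in (5, 50, 499)]
        assert count_kmers(seqs, 5).total == sum(len(s) - 4 for s in seqs)


class TestNormalizedRatio:
    def test_identity(self, ref_table):
        r = normalized_ratio(ref_table, ref_table)
        assert np.allclose(r, 1.0)

    def test_doubled_kmer(self, ref_table):
        c = ref_table.counts.copy()
        c[100] *= 2
        r = normalized_ratio(KmerTable(5, c), ref_table)
        assert r.iloc[100] == pytest.approx(2.0, rel=0.01)
        others = np.delete(np.asarray(r), 100)
        assert np.allclose(others, 1.0, atol=0.01)

    def test_pseudocount_keeps_zero_ref_finite(self):
        ref = KmerTable(2, np.full(16, 100))
        reads = KmerTable(2, np.full(16, 100))
        ref.counts[3] = 0
        reads.counts[3] = 10
        r = normalized_ratio(reads, ref, pseudocount=0.5)
        assert np.isfinite(r.iloc[3]) and r.iloc[3] > 1


class TestZscores:
    def test_all_equal(self):
        import pandas as pd

        r = pd.Series(np.ones(10), index=[f"k{i}" for i in range(10)])
        z = zscore_outliers(r)
        assert (z.zscore == 0).all() and not z.outlier.any()

    def test_single_extreme_ratio_flagged(self):
        import pandas as pd

        vals = np.ones(1024)
        vals[7] = 8.0
        r = pd.Series(vals, index=list(kmer_strings(5)))
        z = zscore_outliers(r)
        assert z.outlier.iloc[7] and z.zscore.iloc[7] > 3
        assert z.outlier.sum() == 1

    def test_log_symmetry(self):
        import pandas as pd

        r = pd.Series([2.0, 0.5, 1.0], index=["AA", "AC", "AG"])
        z = zscore_outliers(r)["zscore"]
        assert z.iloc[0] == pytest.approx(-z.iloc[1])


class TestBH:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_trivial_cases(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_elementwise_monotone(self, rng):
        p = rng.uniform(1e-6, 1, 500)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNBRegression:
    def test_matches_statsmodels_mle(self, ref_table):
        """Our vectorized two-group NB fit agrees with statsmodels' joint
        NB MLE (coefficient and dispersion) on individual k-mers."""
        from statsmodels.discrete.discrete_model import NegativeBinomial

        tables = simulate_read_kmer_tables(
            ref_table, 500_000, 3, spikes={"CTAGA": 3.0}, seed=5
        )
        res = nb_regression(tables, ref_table)
        Y = np.stack([t.counts for t in tables], axis=1)
        T = np.array([t.total for t in tables], float)
        for kmer in ["AAAAA", "GCGCG", "CTAGA", "TTTTT"]:
            idx = list(res.index).index(kmer)
            y = np.concatenate([[ref_table.counts[idx]], Y[idx]])
            X = np.column_stack([np.ones(4), [0, 1, 1, 1]])
            off = np.log(np.concatenate([[ref_table.total], T]))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = NegativeBinomial(y, X, offset=off).fit(disp=0, maxiter=300)
            assert res.log2_fold_change.loc[kmer] * np.log(2) == pytest.approx(
                fit.params[1], abs=2e-3
            )
            assert res.dispersion.loc[kmer] == pytest.approx(
                max(fit.params[2], 1e-8), abs=2e-4
            )

    def test_identical_replicates_vs_self_reference(self, ref_table):
        res = nb_regression([ref_table, ref_table], ref_table)
        assert np.allclose(res.log2_fold_change, 0.0, atol=1e-8)
        assert not res.significant.any()

    def test_spike_recovered(self, ref_table):
        tables = simulate_read_kmer_tables(
            ref_table, 1_000_000, 3, spikes={"CTAGA": 3.0}, seed=17
        )
        res = annotate_volcano(nb_regression(tables, ref_table), fc_threshold=2.0)
        assert res.loc["CTAGA", "significant"]
        assert res.loc["CTAGA", "log2_fold_change"] == pytest.approx(np.log2(3), abs=0.15)
        assert list(res[res.annotated].index) == ["CTAGA"]

    def test_all_zero_kmer_p_is_one(self):
        ref = KmerTable(2, np.full(16, 50))
        reads = [KmerTable(2, np.full(16, 50)) for _ in range(2)]
        ref.counts[0] = 0
        for t in reads:
            t.counts[0] = 0
        res = nb_regression(reads, ref)
        assert res.p_value.iloc[0] == 1.0 and res.all_zero.iloc[0]

    def test_needs_two_replicates(self, ref_table):
        with pytest.raises(ValueError):
            nb_regression([ref_table], ref_table)

    def test_zscore_and_regression_agree_on_direction(self, ref_table):
        tables = simulate_read_kmer_tables(
            ref_table, 1_000_000, 3, spikes={"AACCG": 3.0, "TTGGC": 0.3}, seed=8
        )
        full = kmer_bias_analysis(tables, ref_table)
        sig = full[full.significant]
        assert len(sig) >= 2
        assert np.all(np.sign(sig.zscore) == np.sign(sig.log2_fold_change))


class TestMappedTables:
    def test_minus_strand_reads_counted_in_reference_frame(self):
        ref_seq = "ACGTACGGTACCTTGACGTACGAT" * 4
        ref = pb.SequenceRecord(id="c", sequence=ref_seq)
        fragment = ref_seq[10:40]
        read = ReadRecord(
            id="r1",
            read_class=ReadClass.RAW_1D,
            sequence=reverse_complement(fragment),
            qualities=[10] * 30,
        )
        aln = AlignmentRecord(
            read_id="r1", cigar=[("M", 30)], nm=0, ref_name="c", ref_start=10, strand="-"
        )
        assert aligned_read_portion(read, aln) == fragment
        (read_tab,), ref_tab = mapped_kmer_tables([([read], [aln])], [ref], k=5)
        assert np.array_equal(read_tab.counts, count_kmers([fragment], 5).counts)
        assert np.array_equal(ref_tab.counts, count_kmers([fragment], 5).counts)

    def test_error_free_simulation_gives_unit_ratios(self):
        cfg = pb.SimulationConfig(
            seed=31,
            genome_length=100_000,
            genome_gc=0.35,
            n_reads=400,
            length_median=800,
            length_sigma=0.3,
            fraction_2d=0.0,
            substitution_rate=0.0,
            insertion_rate=0.0,
            deletion_rate=0.0,
        )
        ref = pb.generate_reference(cfg.genome_length, cfg.genome_gc, cfg.seed)
        ds = pb.simulate_reads(cfg, ref)
        (read_tab,), ref_tab = mapped_kmer_tables(
            [(ds.reads, ds.alignments)], [ref], k=5
        )
        r = normalized_ratio(read_tab, ref_tab)
        # reads re-sample covered regions (possibly multiple coverage), so
        # ratios concentrate near 1 without bias
        assert abs(np.log2(r).mean()) < 0.05


class TestConcordance:
    def test_identical_tables(self, ref_table):
        assert replicate_concordance([ref_table, ref_table]) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        a = KmerTable(5, np.arange(1024))
        b = KmerTable(5, np.arange(1024)[::-1])
        assert replicate_concordance([a, b]) == pytest.approx(-1.0)

    def test_constant_counts_undefined(self):
        a = KmerTable(2, np.full(16, 5))
        b = KmerTable(2, np.arange(16))
        assert np.isnan(replicate_concordance([a, b]))


class TestVolcano:
    def test_annotation_threshold(self, ref_table):
        tables = simulate_read_kmer_tables(ref_table, 500_000, 2, seed=4)
        res = nb_regression(tables, ref_table)
        res.loc["AAAAA", "significant"] = True
        res.loc["AAAAA", "log2_fold_change"] = np.log2(1.9)
        out = annotate_volcano(res, fc_threshold=2.0)
        assert not out.loc["AAAAA", "annotated"]  # below fold-change bar
        assert out.loc["CACGG", "gc_fraction"] == pytest.approx(4 / 5)
        assert out.loc["CACGA", "gc_fraction"] == pytest.approx(3 / 5)
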