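"""Acceptor windows, composition, Fisher, A-run and k-mer statistics."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import reverse_complement

from crypticsplice import sequence_features as seqf
from crypticsplice.junction_io import GenomeSequence

from helpers import fisher_two_sided_enum, signed_rank_two_sided_enum


def window_from_string(seq, site_id="w", site_class="cryptic", up=100, down=10):
    return seqf.SeqWindow(site_id, site_class, seq, up, down)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestExtractWindows:
    def test_plus_strand_verbatim(self):
        rng = np.random.default_rng(0)
        known = random_seq(rng, 110)
        chrom = random_seq(rng, 40) + known + random_seq(rng, 40)
        genome = GenomeSequence({"c": chrom})
        # acceptor base is the 100th base of the 110-mer: 0-based 40 + 99
        pos = 40 + 99
        wins = seqf.extract_windows([("s", "cryptic", "c", "+", pos)], genome)
        assert len(wins) == 1 and wins[0].seq == known

    def test_minus_strand_mirrors_to_same_window(self):
        rng = np.random.default_rng(1)
        known = random_seq(rng, 110)
        chrom_fwd = random_seq(rng, 40) + known + random_seq(rng, 40)
        chrom_rev = reverse_complement(chrom_fwd)
        genome = GenomeSequence({"c": chrom_rev})
        # the + strand acceptor at 0-based 139 maps to 190 - 139 - 1 = 50
        wins = seqf.extract_windows([("s", "cryptic", "c", "-", 50)], genome)
        assert len(wins) == 1 and wins[0].seq == known

    def test_off_chromosome_window_dropped(self):
        genome = GenomeSequence({"c": "ACGT" * 40})
        wins = seqf.extract_windows([("s", "cryptic", "c", "+", 49)], genome)
        assert wins == []

    def test_window_with_n_dropped(self):
        genome = GenomeSequence({"c": "A" * 120 + "N" + "A" * 120})
        wins = seqf.extract_windows([("s", "cryptic", "c", "+", 150)], genome)
        assert wins == []

    def test_position_labels(self):
        w = window_from_string("A" * 110)
        assert w.index_of(-100) == 0
        assert w.index_of(-1) == 99
        assert w.index_of(1) == 100
        assert w.index_of(10) == 109
        with pytest.raises(IndexError):
            w.index_of(0)


class TestCompositionProfile:
    def test_single_window_is_indicator(self):
        prof = seqf.composition_profile([window_from_string("ACGT" * 27 + "AC")])
        freq = prof.frequencies
        assert set(np.unique(freq.to_numpy())) == {0.0, 1.0}
        assert freq.loc["A", -100] == 1.0

    def test_two_windows_half_half(self):
        prof = seqf.composition_profile(
            [window_from_string("A" * 110), window_from_string("T" * 110)]
        )
        np.testing.assert_allclose(prof.frequencies.loc["A"], 0.5)
        np.testing.assert_allclose(prof.frequencies.loc["T"], 0.5)

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        wins = [window_from_string(random_seq(rng, 110), f"w{i}") for i in range(100)]
        prof = seqf.composition_profile(wins)
        np.testing.assert_array_equal(prof.counts.sum(axis=0), 100)

    def test_logo_matrix_columns_sum_to_one(self):
        rng = np.random.default_rng(3)
        wins = [window_from_string(random_seq(rng, 110), f"w{i}") for i in range(10)]
        logo = seqf.logo_matrix(seqf.composition_profile(wins))
        np.testing.assert_allclose(logo.sum(axis=1), 1.0, atol=1e-12)


class TestFisherPositionEnrichment:
    def test_identical_profiles_give_p_one(self):
        rng = np.random.default_rng(4)
        wins = [window_from_string(random_seq(rng, 110), f"w{i}") for i in range(20)]
        prof = seqf.composition_profile(wins)
        p = seqf.fisher_position_enrichment(prof, prof)
        np.testing.assert_allclose(p.to_numpy(), 1.0)

    def test_extreme_table_exact_value(self):
        target = seqf.composition_profile(
            [window_from_string("A" * 110, f"a{i}") for i in range(10)]
        )
        control = seqf.composition_profile(
            [window_from_string("T" * 110, f"t{i}") for i in range(10)]
        )
        p = seqf.fisher_position_enrichment(target, control)
        from math import comb
        expected = 2 / comb(20, 10)
        np.testing.assert_allclose(p.loc["A"], expected, rtol=1e-9)

    def test_symmetric_in_target_and_control(self):
        rng = np.random.default_rng(5)
        wa = [window_from_string(random_seq(rng, 110), f"a{i}") for i in range(15)]
        wb = [window_from_string(random_seq(rng, 110), f"b{i}") for i in range(9)]
        pa = seqf.composition_profile(wa)
        pb = seqf.composition_profile(wb)
        np.testing.assert_allclose(
            seqf.fisher_position_enrichment(pa, pb).to_numpy(),
            seqf.fisher_position_enrichment(pb, pa).to_numpy(),
            rtol=1e-9,
        )

    def test_matches_enumeration_on_random_tables(self):
        from scipy import stats
        rng = np.random.default_rng(6)
        for _ in range(300):
            r1, r2 = rng.integers(1, 31, size=2)
            a = int(rng.integers(0, r1 + 1))
            c = int(rng.integers(0, r2 + 1))
            table = [[a, int(r1) - a], [c, int(r2) - c]]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            assert p == pytest.approx(fisher_two_sided_enum(a, int(r1) - a, c,
                                                            int(r2) - c), rel=1e-8)


class TestPolyARunFeatures:
    def region_features(self, region_seq):
        # embed the 50-nt region at window positions -50..-1
        seq = "C" * 50 + region_seq.ljust(50, "C") + "G" * 10
        rf = seqf.polyA_run_features([window_from_string(seq)])
        return rf.counts.iloc[0].to_dict()

    def test_maximal_run_of_three(self):
        assert self.region_features("CAAAT") == {"A": 0, "AA": 0, "AAA": 1, "AAAA": 0}

    def test_all_pyrimidine_region_is_zero(self):
        assert self.region_features("T" * 50) == {"A": 0, "AA": 0, "AAA": 0, "AAAA": 0}

    def test_long_run_counts_as_aaaa(self):
        assert self.region_features("TTAAAAAATT") == {"A": 0, "AA": 0, "AAA": 0,
                                                      "AAAA": 1}

    def test_mixture(self):
        assert self.region_features("ATTAATTAAATTAAAAT") == {
            "A": 1, "AA": 1, "AAA": 1, "AAAA": 1}

    def test_invariant_to_sequence_outside_region(self):
        rng = np.random.default_rng(7)
        region = random_seq(rng, 50)
        seq1 = "C" * 50 + region + "G" * 10
        seq2 = random_seq(rng, 50) + region + random_seq(rng, 10)
        rf1 = seqf.polyA_run_features([window_from_string(seq1)])
        rf2 = seqf.polyA_run_features([window_from_string(seq2)])
        pd.testing.assert_frame_equal(rf1.counts, rf2.counts)

    def test_runs_clipped_at_region_boundary(self):
        # run straddling -51/-50: only the in-region part is scanned
        seq = "C" * 48 + "AA" + "A" + "C" * 49 + "G" * 10
        rf = seqf.polyA_run_features([window_from_string(seq)])
        assert rf.counts.iloc[0]["A"] == 1

    def test_track_marks_run_starts(self):
        seq = "C" * 50 + "TTAAA" + "C" * 45 + "G" * 10
        rf = seqf.polyA_run_features([window_from_string(seq)])
        track = rf.tracks["AAA"].iloc[0]
        assert track[-48] == 1 and track.sum() == 1

    def test_overlapping_mode_counts_kmers(self):
        seq = "C" * 50 + "AAAA" + "C" * 46 + "G" * 10
        rf = seqf.polyA_run_features([window_from_string(seq)], overlapping=True)
        counts = rf.counts.iloc[0]
        assert counts["A"] == 4 and counts["AA"] == 3 and counts["AAA"] == 2
        assert counts["AAAA"] == 1

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            seqf.polyA_run_features([window_from_string("A" * 110)], region=(-200, -1))


class TestCompareRunFrequencies:
    def test_identical_tracks_give_p_one(self):
        t = pd.Series([0.1, 0.2, 0.3], index=[-3, -2, -1])
        w, p = seqf.compare_run_frequencies(t, t.copy(), "AA")
        assert p == 1.0 and w == 0.0

    def test_three_positive_pairs(self):
        a = pd.Series([0.3, 0.5, 0.4], index=[-3, -2, -1])
        b = pd.Series([0.1, 0.2, 0.25], index=[-3, -2, -1])
        _, p = seqf.compare_run_frequencies(a, b, "AA")
        assert p == pytest.approx(0.25)  # 2 * P(all three positive) = 2/8

    def test_exact_matches_sign_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(1, 13))
            d = np.round(rng.normal(0.02, 0.05, size=n), 3)
            a = pd.Series(np.abs(rng.normal(0.2, 0.05, size=n)),
                          index=range(-n, 0))
            b = a - d
            actual_diffs = a.to_numpy() - b.to_numpy()
            _, p = seqf.compare_run_frequencies(a, b, "AA")
            assert p == pytest.approx(signed_rank_two_sided_enum(actual_diffs),
                                      abs=1e-12)

    def test_approx_branch_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(9)
        d = rng.normal(0.01, 0.05, size=40)
        a = pd.Series(rng.uniform(0.1, 0.5, size=40), index=range(-40, 0))
        b = a - d
        _, p = seqf.compare_run_frequencies(a, b, "AA")
        expected = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                                  method="approx").pvalue
        assert p == pytest.approx(expected, rel=1e-10)

    def test_mismatched_positions_rejected(self):
        a = pd.Series([0.1], index=[-2])
        b = pd.Series([0.1], index=[-1])
        with pytest.raises(ValueError):
            seqf.compare_run_frequencies(a, b, "AA")


class TestKmerEnrichment:
    def test_all_t_windows(self):
        wins = [window_from_string("T" * 110, f"w{i}") for i in range(5)]
        ctrl = [window_from_string("C" * 110, f"c{i}") for i in range(5)]
        df = seqf.kmer_enrichment(wins, ctrl)
        assert df.index[0] == "TTTTTT"
        assert df.iloc[0]["target_freq"] == 1.0
        assert df.iloc[0]["rank"] == 1

    def test_ranks_unique(self):
        rng = np.random.default_rng(10)
        wins = [window_from_string(random_seq(rng, 110), f"w{i}") for i in range(30)]
        ctrl = [window_from_string(random_seq(rng, 110), f"c{i}") for i in range(30)]
        df = seqf.kmer_enrichment(wins, ctrl)
        assert df["rank"].is_unique

    def test_region_shorter_than_k_rejected(self):
        wins = [window_from_string("T" * 110)]
        with pytest.raises(ValueError):
            seqf.kmer_enrichment(wins, wins, k=6, region=(-4, -1))

    def test_planted_polya_kmer_enriched(self):
        rng = np.random.default_rng(11)
        target = [
            window_from_string(random_seq(rng, 70) + "AAAAAA" + random_seq(rng, 34),
                               f"t{i}")
            for i in range(50)
        ]
        ctrl = [
            window_from_string(random_seq(rng, 70) + "TTTCCC" + random_seq(rng, 34),
                               f"c{i}")
            for i in range(50)
        ]
        df = seqf.kmer_enrichment(target, ctrl)
        row = df.loc["AAAAAA"]
        assert row["target_freq"] > row["control_freq"]
        assert row["fisher_p"] < 0.05


class TestWindowsFasta:
    def test_round_trip_via_fasta_parser(self, tmp_path):
        from Bio import SeqIO
        rng = np.random.default_rng(12)
        wins = [window_from_string(random_seq(rng, 110), f"w{i}", "control")
                for i in range(5)]
        path = tmp_path / "wins.fa"
        seqf.windows_to_fasta(wins, path)
        records = list(SeqIO.parse(str(path), "fasta"))
        assert [r.id for r in records] == [w.site_id for w in wins]
        assert [str(r.seq) for r in records] == [w.seq for w in wins]


class TestMaximalARuns:
    def test_examples(self):
        assert seqf.maximal_a_runs("CAAAT") == [(1, 3)]
        assert seqf.maximal_a_runs("AAXAA") == [(0, 2), (3, 2)]
        assert seqf.maximal_a_runs("TTT") == []
        assert seqf.maximal_a_runs("A") == [(0, 1)]
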