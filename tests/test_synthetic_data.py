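"""Ground-truth simulator: determinism, sequence layout, count models."""

import filecmp
import os

import numpy as np
import pytest

from crypticsplice import synthetic_data as sd
from crypticsplice.junction_io import extract_sequence

TINY = dict(seed=3, n_genes=40, n_r_preferred=6, n_k_preferred=6, n_shared=2,
            n_null=4, genes_per_chrom=20)


@pytest.fixture(scope="module")
def tiny():
    cfg = sd.SimulationConfig(**TINY)
    genome, ann, truth = sd.simulate_genome(cfg)
    return cfg, genome, ann, truth


class TestConfigValidation:
    def test_too_many_events_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            sd.SimulationConfig(n_genes=10, n_r_preferred=20)

    def test_short_intron_names_field(self):
        with pytest.raises(ValueError, match="intron_length_range"):
            sd.SimulationConfig(intron_length_range=(40, 60))

    def test_psi_bounds_checked(self):
        bad = {
            "r_preferred": {"WT": 0.02, "K700E": 0.15, "R625H": 1.4},
            "k_preferred": {"WT": 0.02, "K700E": 0.40, "R625H": 0.15},
            "shared": {"WT": 0.02, "K700E": 0.30, "R625H": 0.30},
            "null": {"WT": 0.02, "K700E": 0.02, "R625H": 0.02},
        }
        with pytest.raises(ValueError, match="psi_by_class"):
            sd.SimulationConfig(psi_by_class=bad)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = sd.SimulationConfig(**TINY)
        sd.simulate_all(cfg, tmp_path / "a")
        sd.simulate_all(sd.SimulationConfig(**TINY), tmp_path / "b")
        for rel in ("genome.fa", "annotation.gtf", "counts.tsv", "groups.tsv",
                    "truth_events.tsv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel,
                               shallow=False), rel
        sj_a = sorted(os.listdir(tmp_path / "a" / "sj"))
        sj_b = sorted(os.listdir(tmp_path / "b" / "sj"))
        assert sj_a == sj_b
        for name in sj_a:
            assert filecmp.cmp(tmp_path / "a" / "sj" / name,
                               tmp_path / "b" / "sj" / name, shallow=False)

    def test_different_seed_differs(self, tmp_path):
        cfg1 = sd.SimulationConfig(**TINY)
        cfg2 = sd.SimulationConfig(**{**TINY, "seed": 4})
        sd.simulate_all(cfg1, tmp_path / "a")
        sd.simulate_all(cfg2, tmp_path / "b")
        assert not filecmp.cmp(tmp_path / "a" / "genome.fa",
                               tmp_path / "b" / "genome.fa", shallow=False)


class TestPlantedSequenceLayout:
    def test_distances_within_configured_range(self, tiny):
        _, _, _, truth = tiny
        assert truth.events["distance"].between(10, 24).all()

    def test_event_counts_by_class(self, tiny):
        _, _, _, truth = tiny
        counts = truth.events["event_class"].value_counts()
        assert counts["r_preferred"] == 6 and counts["k_preferred"] == 6
        assert counts["shared"] == 2 and counts["null"] == 4

    def acceptor_context(self, genome, ev, n_up=60):
        """Transcript-oriented sequence ending at the cryptic acceptor G."""
        if ev.strand == "+":
            return extract_sequence(genome, ev.chrom, ev.cryptic_pos + 1 - n_up + 1,
                                    ev.cryptic_pos + 1, "+")
        return extract_sequence(genome, ev.chrom, ev.cryptic_pos + 1,
                                ev.cryptic_pos + 1 + n_up - 1, "-")

    def test_cryptic_windows_end_in_ag(self, tiny):
        _, genome, _, truth = tiny
        for ev in truth.events.itertuples(index=False):
            ctx = self.acceptor_context(genome, ev)
            assert ctx[-2:] == "AG", ev.event_id

    def test_canonical_acceptors_end_in_ag_with_pyrimidine_tract(self, tiny):
        cfg, genome, ann, truth = tiny
        for chrom, strand, start, end in list(ann.introns)[:40]:
            if strand == "+":
                ctx = extract_sequence(genome, chrom, end - 30 + 1, end, "+")
            else:
                ctx = extract_sequence(genome, chrom, start + 1, start + 30, "-")
            assert ctx[-2:] == "AG"
            tract = ctx[:-2]
            py = sum(b in "CT" for b in tract) / len(tract)
            assert py > 0.5  # T/C-biased polypyrimidine tract

    def test_no_competing_ag_near_cryptic_acceptor(self, tiny):
        _, genome, _, truth = tiny
        for ev in truth.events.itertuples(index=False):
            ctx = self.acceptor_context(genome, ev)
            # 8 nt immediately upstream of the cryptic AG hold no other AG
            guard = ctx[-12:-2]
            assert "AG" not in guard[2:], ev.event_id

    def test_no_ag_between_cryptic_and_canonical(self, tiny):
        _, genome, _, truth = tiny
        for ev in truth.events.itertuples(index=False):
            d = ev.distance
            if ev.strand == "+":
                between = extract_sequence(genome, ev.chrom, ev.cryptic_pos + 2,
                                           ev.canonical_pos + 1, "+")
            else:
                between = extract_sequence(genome, ev.chrom, ev.canonical_pos + 1,
                                           ev.cryptic_pos, "-")
            # the only AG ending this stretch is the canonical acceptor itself
            assert between[-2:] == "AG"
            assert "AG" not in between[:-2], ev.event_id

    def test_cryptic_acceptor_strictly_inside_intron(self, tiny):
        _, _, _, truth = tiny
        for ev in truth.events.itertuples(index=False):
            assert ev.intron_start < ev.cryptic_pos < ev.intron_end - 1 or (
                ev.strand == "-" and ev.intron_start < ev.cryptic_pos < ev.intron_end
            )


class TestJunctionSimulation:
    def test_zero_psi_emits_no_cryptic_rows(self):
        cfg = sd.SimulationConfig(**{
            **TINY,
            "psi_by_class": {
                "r_preferred": {"WT": 0.0, "K700E": 0.0, "R625H": 0.0},
                "k_preferred": {"WT": 0.0, "K700E": 0.0, "R625H": 0.0},
                "shared": {"WT": 0.0, "K700E": 0.0, "R625H": 0.0},
                "null": {"WT": 0.0, "K700E": 0.0, "R625H": 0.0},
            },
        })
        _, _, truth = sd.simulate_genome(cfg)
        tables = sd.simulate_junction_tables(truth, cfg)
        for df in tables.values():
            assert (df["annotated_flag"] == 1).all()

    def test_psi_one_gives_zero_canonical_for_event_introns(self):
        cfg = sd.SimulationConfig(**{
            **TINY,
            "psi_by_class": {
                "r_preferred": {"WT": 1.0, "K700E": 1.0, "R625H": 1.0},
                "k_preferred": {"WT": 1.0, "K700E": 1.0, "R625H": 1.0},
                "shared": {"WT": 1.0, "K700E": 1.0, "R625H": 1.0},
                "null": {"WT": 1.0, "K700E": 1.0, "R625H": 1.0},
            },
        })
        _, _, truth = sd.simulate_genome(cfg)
        tables = sd.simulate_junction_tables(truth, cfg)
        event_keys = {
            (r.chrom, r.intron_start + 1, r.intron_end)
            for r in truth.events.itertuples(index=False)
        }
        for df in tables.values():
            canon = df[df["annotated_flag"] == 1]
            keys = set(zip(canon["chrom"], canon["intron_first"], canon["intron_last"]))
            assert keys.isdisjoint(event_keys)

    def test_binomial_mean_recovered(self):
        cfg = sd.SimulationConfig(**TINY)
        rng = np.random.default_rng(0)
        psi = 0.3
        n = 10_000
        depth = 100
        draws = rng.binomial(depth, psi, size=n) / depth
        se = np.sqrt(psi * (1 - psi) / depth / n)
        assert abs(draws.mean() - psi) < 3 * se

    def test_event_psi_reflected_in_counts(self, tiny):
        cfg, _, _, truth = tiny
        tables = sd.simulate_junction_tables(truth, cfg)
        ev = truth.events[truth.events.event_class == "r_preferred"].iloc[0]
        cryp_key = (ev.chrom, ev.cryptic_start + 1, ev.cryptic_end)
        r_counts = wt_counts = 0
        r_depth = wt_depth = 0
        for sample, df in tables.items():
            row = df[(df.chrom == cryp_key[0]) & (df.intron_first == cryp_key[1])
                     & (df.intron_last == cryp_key[2])]
            canon = df[(df.chrom == ev.chrom) & (df.intron_first == ev.intron_start + 1)
                       & (df.intron_last == ev.intron_end)]
            cryp = int(row["unique_reads"].sum())
            dep = cryp + int(canon["unique_reads"].sum())
            if sample.startswith("R625H"):
                r_counts += cryp
                r_depth += dep
            elif sample.startswith("WT"):
                wt_counts += cryp
                wt_depth += dep
        assert r_counts / r_depth > wt_counts / max(wt_depth, 1) + 0.2


class TestExpressionSimulation:
    def test_zero_nmd_efficiency_keeps_baseline(self):
        cfg = sd.SimulationConfig(**{**TINY, "nmd_efficiency": 0.0,
                                     "expression_dispersion": 1e6})
        _, _, truth = sd.simulate_genome(cfg)
        counts = sd.simulate_expression(truth, cfg)
        event_genes = truth.events["gene_id"]
        baselines = truth.genes.set_index("gene_id")["baseline"]
        for g in event_genes:
            np.testing.assert_allclose(counts.loc[g].mean(), baselines[g],
                                       rtol=0.05)

    def test_nmd_multiplier(self):
        # efficiency 0.8 at PSI 0.5 scales the mean by 0.6
        psis = {"WT": 0.5, "K700E": 0.5, "R625H": 0.5}
        cfg = sd.SimulationConfig(**{
            **TINY, "nmd_efficiency": 0.8, "expression_dispersion": 1e6,
            "psi_by_class": {c: psis for c in sd.EVENT_CLASSES},
        })
        _, _, truth = sd.simulate_genome(cfg)
        counts = sd.simulate_expression(truth, cfg)
        baselines = truth.genes.set_index("gene_id")["baseline"]
        for g in truth.events["gene_id"][:5]:
            np.testing.assert_allclose(counts.loc[g].mean(), 0.6 * baselines[g],
                                       rtol=0.1)

    def test_event_free_genes_equal_group_means(self, tiny):
        cfg, _, _, truth = tiny
        counts = sd.simulate_expression(truth, cfg)
        free = truth.genes[truth.genes.event_class == "none"]["gene_id"]
        samples = counts.columns
        wt = [s for s in samples if s.startswith("WT")]
        mut = [s for s in samples if not s.startswith("WT")]
        # no systematic shift: across event-free genes the WT/MUT log-ratio
        # is centred on zero
        ratios = np.log((counts.loc[free, wt].mean(axis=1) + 1)
                        / (counts.loc[free, mut].mean(axis=1) + 1))
        assert abs(ratios.mean()) < 0.1


class TestSimulatedAcceptorWindows:
    def test_cryptic_windows_end_at_acceptor(self):
        cfg = sd.SimulationConfig()
        rng = np.random.default_rng(1)
        wins = sd.simulate_acceptor_windows(cfg, "r_preferred", 10, rng)
        for w in wins:
            assert len(w.seq) == 110
            assert w.region(-2, -1) == "AG"

    def test_control_windows_are_canonical_acceptors(self):
        cfg = sd.SimulationConfig()
        rng = np.random.default_rng(2)
        wins = sd.simulate_acceptor_windows(cfg, "control", 10, rng)
        for w in wins:
            assert w.region(-2, -1) == "AG"
            tract = w.region(-20, -3)
            assert sum(b in "CT" for b in tract) / len(tract) > 0.5

    def test_class_ordering_of_a_run_means(self):
        from crypticsplice import sequence_features as seqf
        cfg = sd.SimulationConfig()
        rng = np.random.default_rng(3)
        means = {}
        for cls in ("r_preferred", "k_preferred", "control"):
            wins = sd.simulate_acceptor_windows(cfg, cls, 150, rng)
            means[cls] = seqf.polyA_run_features(wins).feature_means()
        for feat in ("AA", "AAA", "AAAA"):
            assert means["r_preferred"][feat] > means["k_preferred"][feat]
            assert means["k_preferred"][feat] > means["control"][feat]
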