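"""Synthetic-data generator: determinism, planted structure, conservation."""

import numpy as np
import pandas as pd
import pytest

from longapa.simulate import (
    PATTERN_PROXIMAL_USAGE,
    SimConfig,
    simulate_genome,
    simulate_reads,
    true_direction,
)


class TestSimConfig:
    def test_rejects_unnormalized_distributions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(pas_per_gene={1: 0.5, 2: 0.6})

    def test_rejects_negative_jitter(self):
        with pytest.raises(ValueError, match="jitter_sd"):
            SimConfig(jitter_sd=-1)

    def test_rejects_structure_too_short_for_planted_signal(self):
        with pytest.raises(ValueError, match="too short"):
            SimConfig(first_pas_offset=10, motif_offset=21)


class TestSimulateGenome:
    def test_identical_seed_gives_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_genes=15, seed=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_genome(cfg, d1)
        simulate_genome(cfg, d2)
        for name in ("genome.fa", "annotation.gtf", "ref_pas.bed",
                     "truth_sites.tsv", "truth_genes.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_zero_artifact_rate_plants_no_artifacts(self):
        sim = simulate_genome(SimConfig(n_genes=20, seed=2, artifact_rate=0.0))
        assert not sim.truth.sites["is_artifact"].any()

    def test_usage_vectors_sum_to_one(self):
        sim = simulate_genome(SimConfig(n_genes=30, seed=3))
        usage_cols = [c for c in sim.truth.sites if c.startswith("usage_")]
        sums = sim.truth.sites.groupby("gene_id")[usage_cols].sum()
        assert np.allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_planted_motif_upstream_of_every_nonartifact_pas(self):
        cfg = SimConfig(n_genes=30, seed=4)
        sim = simulate_genome(cfg)
        from longapa.seqcontext import extract_flanks

        nonart = sim.truth.sites[~sim.truth.sites["is_artifact"]]
        sites = [(r["chrom"], r["strand"], int(r["position"]))
                 for _, r in nonart.iterrows()]
        flanks = extract_flanks(sites, sim.genome, length=50)
        start = 50 - cfg.motif_offset
        assert all(s[start:start + 6] == "AATAAA" for s in flanks.sequences)

    def test_artifact_sites_sit_in_a_run_that_fails_the_filter(self):
        from longapa.priming import classify_priming, extract_window
        from longapa.io import EndSite

        sim = simulate_genome(SimConfig(n_genes=40, seed=5, artifact_rate=0.5))
        art = sim.truth.sites[sim.truth.sites["is_artifact"]]
        assert len(art) > 0
        for _, r in art.iterrows():
            site = EndSite(r["chrom"], r["strand"], int(r["position"]), {"s": 1})
            seq, _ = extract_window(site, sim.genome)
            assert classify_priming(seq)[2]

    def test_expected_direction_from_planted_usage(self):
        """A 2-PAS gene going 0.8/0.2 to 0.2/0.8 proximal/distal is an
        expected lengthening, per the RED rule applied to true usage."""
        cfg = SimConfig(
            n_genes=4, seed=6, pas_per_gene={2: 1.0}, artifact_rate=0.0,
            pattern_fractions={"1": 1.0},
        )
        sim = simulate_genome(cfg)
        # hand-applied RED rule on the planted usage table
        prox = PATTERN_PROXIMAL_USAGE["1"]
        for s in range(2):
            du_prox = prox[s + 1] - prox[s]
            du_dist = (1 - prox[s + 1]) - (1 - prox[s])
            red = du_dist - du_prox
            assert red > 0.05
        genes = sim.truth.genes
        assert (genes["direction_NSC_vs_hESC"] == "lengthening").all()
        assert (genes["direction_NPC_vs_NSC"] == "lengthening").all()
        assert (genes["expected_pattern"] == "1").all()

    def test_pattern_quotas_are_exact(self):
        cfg = SimConfig(
            n_genes=40, seed=7, pas_per_gene={2: 1.0},
            pattern_fractions={"1": 0.25, "2": 0.25, "3": 0.25, "4": 0.25},
        )
        sim = simulate_genome(cfg)
        counts = sim.truth.genes["expected_pattern"].value_counts()
        assert all(counts[p] == 10 for p in ("1", "2", "3", "4"))

    def test_strands_are_balanced(self):
        sim = simulate_genome(SimConfig(n_genes=30, seed=8))
        counts = sim.truth.genes["strand"].value_counts()
        assert abs(counts["+"] - counts["-"]) <= 1


class TestTrueDirection:
    def test_lengthening_and_shortening_thresholds(self):
        assert true_direction([-0.3, 0.3], [0, 1]) == "lengthening"
        assert true_direction([0.2, -0.2], [0, 1]) == "shortening"
        assert true_direction([-0.02, 0.02], [0, 1]) == "unclassified"

    def test_top_two_by_absolute_shift_are_used(self):
        # middle site barely moves; outer sites dominate
        assert true_direction([-0.3, 0.01, 0.29], [0, 1, 2]) == "lengthening"


class TestSimulateReads:
    def test_zero_jitter_single_pas_gives_one_position(self):
        cfg = SimConfig(n_genes=4, seed=9, pas_per_gene={1: 1.0},
                        jitter_sd=0.0, artifact_rate=0.0,
                        pattern_fractions={"stable": 1.0})
        sim = simulate_genome(cfg)
        reads = simulate_reads(cfg, sim.truth)
        truth_pos = set(sim.truth.sites["position"])
        for df in reads.values():
            assert set(df["position"]) <= truth_pos

    def test_counts_conserved_per_sample(self):
        cfg = SimConfig(n_genes=10, seed=10)
        sim = simulate_genome(cfg)
        reads = simulate_reads(cfg, sim.truth)
        # totals across BED lines are reproducible under the same seed
        reads2 = simulate_reads(cfg, sim.truth)
        for sample in reads:
            assert reads[sample]["count"].sum() == reads2[sample]["count"].sum()
            pd.testing.assert_frame_equal(reads[sample], reads2[sample])

    def test_allocation_follows_usage_proportions(self):
        usage = {"G0001": {"hESC": [0.8, 0.2], "NSC": [0.8, 0.2], "NPC": [0.8, 0.2]}}
        cfg = SimConfig(n_genes=1, seed=12, pas_per_gene={2: 1.0},
                        usage_by_stage=usage, artifact_rate=0.0,
                        reads_per_gene=5000.0, jitter_sd=0.0,
                        pattern_fractions={"stable": 1.0})
        sim = simulate_genome(cfg)
        reads = simulate_reads(cfg, sim.truth)
        sites = sim.truth.sites.sort_values("tx_rank")
        prox_pos = int(sites.iloc[0]["position"])
        df = reads["hESC_rep1"]
        prox = df[df["position"] == prox_pos]["count"].sum()
        total = df["count"].sum()
        # binomial 99% interval at n=5000, p=0.8
        assert abs(prox / total - 0.8) < 0.02

    def test_jitter_stays_within_four_sd(self):
        cfg = SimConfig(n_genes=5, seed=13, jitter_sd=3.0, artifact_rate=0.0)
        sim = simulate_genome(cfg)
        reads = simulate_reads(cfg, sim.truth)
        truth_pos = np.sort(sim.truth.sites["position"].to_numpy())
        for df in reads.values():
            for p in df["position"]:
                nearest = truth_pos[np.argmin(np.abs(truth_pos - p))]
                assert abs(p - nearest) <= 12
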