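"""PSU/DPUI/Wald/RED statistics and four-pattern classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longapa.annotation import AnnotatedPAC
from longapa.clustering import PAC
from longapa.differential import (
    call_events,
    call_red,
    classify_patterns,
    compute_psu,
    pac_count_table,
    retain_genes,
    wald_test,
)
from longapa.io import EndSite, GeneModel

SAMPLES = ["A_rep1", "A_rep2", "B_rep1", "B_rep2"]
BY_STAGE = {"A": ["A_rep1", "A_rep2"], "B": ["B_rep1", "B_rep2"]}


def ap(gene, center, counts, region="3UTR", strand="+", chrom="chr1"):
    site = EndSite(chrom, strand, center, dict(counts))
    return AnnotatedPAC(
        pac=PAC(chrom, strand, [site]), gene_id=gene, region=region
    )


def table_for(pacs):
    return pac_count_table(pacs, SAMPLES)


def gene_model(strand="+"):
    if strand == "+":
        iv = [(0, 100, "5UTR"), (100, 500, "CDS"), (500, 900, "3UTR")]
        return GeneModel("g1", "chr1", strand, iv, (100, 900), tx_end=899,
                         coding=True, cds_anchor=499)
    iv = [(800, 900, "5UTR"), (400, 800, "CDS"), (0, 400, "3UTR")]
    return GeneModel("g1", "chr1", strand, iv, (0, 800), tx_end=0,
                     coding=True, cds_anchor=400)


class TestRetainGenes:
    def test_gene_with_two_qualifying_pacs_retained(self):
        t = table_for([
            ap("g1", 600, {"A_rep1": 3, "A_rep2": 3, "B_rep1": 6, "B_rep2": 0}),
            ap("g1", 700, {"A_rep1": 6, "A_rep2": 6, "B_rep1": 10, "B_rep2": 10}),
        ])
        kept = retain_genes(t, BY_STAGE["A"], BY_STAGE["B"])
        assert len(kept) == 2  # 3+3=6 > 5 in group A, 6 > 5 in group B

    def test_single_pac_gene_dropped(self):
        t = table_for([ap("g1", 600, {s: 100 for s in SAMPLES})])
        assert retain_genes(t, BY_STAGE["A"], BY_STAGE["B"]).empty

    def test_threshold_is_strict_inequality(self):
        t = table_for([
            ap("g1", 600, {"A_rep1": 100, "A_rep2": 0, "B_rep1": 100, "B_rep2": 0}),
            ap("g1", 700, {"A_rep1": 5, "A_rep2": 0, "B_rep1": 100, "B_rep2": 0}),
        ])
        # second PAC has exactly 5 reads in group A: 5 is not > 5 -> gene dropped
        assert retain_genes(t, BY_STAGE["A"], BY_STAGE["B"]).empty


class TestComputePsu:
    def test_psu_is_count_over_gene_total(self):
        t = table_for([
            ap("g1", 600, {"A_rep1": 30}),
            ap("g1", 700, {"A_rep1": 70}),
        ])
        psu = compute_psu(t, ["A_rep1"])
        assert np.allclose(sorted(psu["A_rep1"]), [0.3, 0.7])

    def test_rows_sum_to_one_per_gene_and_sample(self):
        rng = np.random.default_rng(0)
        pacs = []
        for g in range(5):
            for c in range(3):
                counts = {s: int(rng.integers(1, 50)) for s in SAMPLES}
                pacs.append(ap(f"g{g}", 100 * c + 100, counts))
        psu = compute_psu(table_for(pacs), SAMPLES)
        sums = psu.groupby(level="gene").sum()
        assert np.allclose(sums.to_numpy(), 1.0)

    def test_zero_gene_total_gives_missing_psu(self):
        t = table_for([
            ap("g1", 600, {"A_rep1": 10, "A_rep2": 0}),
            ap("g1", 700, {"A_rep1": 10, "A_rep2": 0}),
        ])
        psu = compute_psu(t, SAMPLES)
        assert psu["A_rep2"].isna().all()


class TestWaldTest:
    def test_identical_proportions_give_p_one(self):
        assert wald_test(50, 100, 50, 100) == pytest.approx(1.0)

    def test_closed_form_example(self):
        # z = (0.7-0.3)/sqrt(0.21/100 + 0.21/100) = 6.172
        p = wald_test(70, 100, 30, 100)
        z = 0.4 / np.sqrt(2 * 0.21 / 100)
        assert z == pytest.approx(6.1721, abs=1e-3)
        assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)
        assert p == pytest.approx(6.7e-10, rel=0.05)

    def test_degenerate_proportion_variance_floor(self):
        # k=0: variance uses 0.5/n instead of 0 -> finite p
        p = wald_test(0, 100, 10, 100)
        assert np.isfinite(p) and 0 < p < 0.05

    def test_zero_group_total_gives_missing(self):
        assert np.isnan(wald_test(0, 0, 5, 10))

    def test_null_calibration_monte_carlo(self):
        """Under equal true usage the rejection rate at p<=0.05 is near
        nominal (binomial CI at 2000 simulated genes)."""
        rng = np.random.default_rng(42)
        k1 = rng.binomial(100, 0.5, size=2000)
        k2 = rng.binomial(100, 0.5, size=2000)
        p = wald_test(k1, 100, k2, 100)
        rate = float((p <= 0.05).mean())
        assert 0.035 <= rate <= 0.065


class TestCallEvents:
    def make_table(self, kA_prox, kB_prox, n=200):
        half = {"A_rep1": 0.5, "A_rep2": 0.5, "B_rep1": 0.5, "B_rep2": 0.5}
        return table_for([
            ap("g1", 600, {"A_rep1": kA_prox // 2, "A_rep2": kA_prox - kA_prox // 2,
                           "B_rep1": kB_prox // 2, "B_rep2": kB_prox - kB_prox // 2}),
            ap("g1", 700, {"A_rep1": (n - kA_prox) // 2,
                           "A_rep2": (n - kA_prox) - (n - kA_prox) // 2,
                           "B_rep1": (n - kB_prox) // 2,
                           "B_rep2": (n - kB_prox) - (n - kB_prox) // 2}),
        ])

    def test_dpui_is_difference_of_group_mean_psus(self):
        t = self.make_table(140, 60)
        ev = call_events(t, BY_STAGE, "A", "B")
        assert ev.loc[("g1", 600), "dpui"] == pytest.approx(0.4)
        assert ev.loc[("g1", 700), "dpui"] == pytest.approx(-0.4)

    def test_small_dpui_not_significant_despite_small_p(self):
        t = self.make_table(104, 96, n=200)
        ev = call_events(t, BY_STAGE, "A", "B")
        assert abs(ev.loc[("g1", 600), "dpui"]) < 0.05
        assert not ev["significant"].any()

    def test_large_dpui_with_large_p_not_significant(self):
        t = self.make_table(12, 8, n=20)
        ev = call_events(t, BY_STAGE, "A", "B", min_reads=5)
        row = ev.loc[("g1", 600)]
        assert abs(row["dpui"]) >= 0.05 and row["p"] > 0.05
        assert not row["significant"]

    def test_clear_shift_is_significant(self):
        ev = call_events(self.make_table(140, 60), BY_STAGE, "A", "B")
        assert ev["significant"].all()

    def test_antisymmetry_under_group_swap(self):
        t = self.make_table(140, 60)
        fwd = call_events(t, BY_STAGE, "A", "B")
        rev = call_events(t, BY_STAGE, "B", "A")
        assert np.allclose(fwd["dpui"].to_numpy(), -rev["dpui"].to_numpy())
        assert np.allclose(fwd["p"].to_numpy(), rev["p"].to_numpy())


class TestCallRed:
    def events(self, dpui_prox, dpui_dist, strand="+", significant=True):
        prox, dist = (600, 800) if strand == "+" else (300, 100)
        idx = pd.MultiIndex.from_tuples(
            [("g1", prox), ("g1", dist)], names=["gene", "center"]
        )
        return pd.DataFrame(
            {"region": "3UTR", "chrom": "chr1", "strand": strand,
             "status": "novel",
             "dpui": [dpui_prox, dpui_dist], "p": 0.001,
             "q": 0.01, "significant": significant},
            index=idx,
        )

    def test_red_formula_lengthening(self):
        red = call_red(self.events(-0.3, 0.3), {"g1": gene_model()})
        assert red.loc[0, "red"] == pytest.approx(0.6)
        assert red.loc[0, "direction"] == "lengthening"
        assert red.loc[0, "proximal_center"] == 600

    def test_red_formula_shortening(self):
        red = call_red(self.events(0.2, -0.2), {"g1": gene_model()})
        assert red.loc[0, "red"] == pytest.approx(-0.4)
        assert red.loc[0, "direction"] == "shortening"

    def test_small_red_unclassified(self):
        red = call_red(self.events(-0.015, 0.015), {"g1": gene_model()})
        assert red.loc[0, "direction"] == "unclassified"

    def test_minus_strand_proximal_is_higher_coordinate(self):
        red = call_red(self.events(-0.3, 0.3, strand="-"),
                       {"g1": gene_model(strand="-")})
        assert red.loc[0, "proximal_center"] == 300
        assert red.loc[0, "direction"] == "lengthening"

    def test_requires_significant_event_and_two_utr_pacs(self):
        assert call_red(self.events(-0.3, 0.3, significant=False),
                        {"g1": gene_model()}).empty
        one = self.events(-0.3, 0.3).iloc[:1]
        assert call_red(one, {"g1": gene_model()}).empty


class TestClassifyPatterns:
    def red_df(self, directions):
        return pd.DataFrame(
            [{"gene": g, "proximal_center": 0, "distal_center": 1,
              "dpui_proximal": 0.0, "dpui_distal": 0.0, "red": 0.0,
              "direction": d} for g, d in directions.items()]
        )

    @pytest.mark.parametrize("d1,d2,expected", [
        ("lengthening", "lengthening", "1"),
        ("lengthening", "shortening", "2"),
        ("shortening", "shortening", "3"),
        ("shortening", "lengthening", "4"),
        ("lengthening", "unclassified", "none"),
    ])
    def test_pattern_mapping(self, d1, d2, expected):
        out = classify_patterns(self.red_df({"g": d1}), self.red_df({"g": d2}))
        assert out.loc[0, "pattern"] == expected

    def test_gene_in_only_one_comparison_is_none(self):
        out = classify_patterns(self.red_df({"g": "lengthening"}), self.red_df({}))
        assert out.loc[0, "pattern"] == "none"

    def test_patterns_partition_gene_universe(self):
        d1 = self.red_df({"a": "lengthening", "b": "shortening",
                          "c": "lengthening", "d": "unclassified"})
        d2 = self.red_df({"a": "lengthening", "b": "lengthening",
                          "e": "shortening"})
        out = classify_patterns(d1, d2)
        assert sorted(out["gene"]) == ["a", "b", "c", "d", "e"]
        assert set(out["pattern"]) <= {"1", "2", "3", "4", "none"}
        assert out["gene"].is_unique
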