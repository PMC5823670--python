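from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from tumoronly.panel import (
    PanelGene,
    fisher_cooccurrence,
    merge_panel,
    network_filter,
    normalize_gene_names,
    score_genes,
    select_core_panel,
    tcga_top_genes,
)


def hypergeom_tail(a, b, c, d):
    """Exhaustive upper-tail hypergeometric enumeration for a 2x2 table."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    p = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        p += Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
    return float(p)


class TestScoreGenes:
    def make_matrix(self):
        idx = ["APC", "BRAF", "KRAS", "TP53"]
        features = {f"f{i}": [0, 0, 0, 0] for i in range(9)}
        fm = pd.DataFrame(features, index=idx)
        fm.loc["TP53", ["f0", "f1", "f2"]] = 1
        fm.loc["KRAS", ["f0", "f1"]] = 1
        fm.loc["BRAF", ["f3", "f4"]] = 1
        return fm

    def test_score_is_feature_membership_sum(self):
        ranked = score_genes(self.make_matrix())
        assert ranked.set_index("gene").loc["TP53", "score"] == 3

    def test_tie_break_by_cosmic_frequency(self):
        cosmic = pd.Series({"KRAS": 5.0, "BRAF": 12.0})
        ranked = score_genes(self.make_matrix(), cosmic)
        order = list(ranked["gene"])
        assert order.index("BRAF") < order.index("KRAS")

    def test_column_order_invariance(self):
        fm = self.make_matrix()
        shuffled = fm[list(fm.columns[::-1])]
        pd.testing.assert_frame_equal(score_genes(fm), score_genes(shuffled))

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i:02d}" for i in range(20)]
        fm = pd.DataFrame(
            rng.integers(0, 2, size=(20, 9)),
            index=genes, columns=[f"f{i}" for i in range(9)],
        )
        cosmic = pd.Series(rng.uniform(0, 20, 20).round(1), index=genes)
        ranked = score_genes(fm, cosmic)
        expected = sorted(
            genes,
            key=lambda g: (-fm.loc[g].sum(), -cosmic[g], g),
        )
        assert list(ranked["gene"]) == expected

    def test_non_binary_matrix_rejected(self):
        fm = self.make_matrix()
        fm.iloc[0, 0] = 2
        with pytest.raises(ValueError):
            score_genes(fm)


class TestCorePanel:
    def test_frequency_addin_is_strict(self):
        ranked = pd.DataFrame(
            {
                "gene": ["A", "B", "C"],
                "score": [0, 0, 2],
                "cosmic_freq": [8.0, 7.0, 1.0],
            }
        )
        panel = select_core_panel(ranked)
        tags = {p.gene: p.provenance for p in panel}
        assert tags["A"] == {"freq-addin"}  # 8% > 7%
        assert "B" not in tags              # exactly 7% is excluded
        assert tags["C"] == {"core-score"}

    def test_all_zero_matrix_gives_empty_panel(self):
        ranked = pd.DataFrame(
            {"gene": ["A"], "score": [0], "cosmic_freq": [0.0]}
        )
        assert select_core_panel(ranked) == []


class TestFisher:
    def test_small_table_exact_value(self):
        # C(5,5)*C(5,0)/C(10,5) = 1/252
        p, sig = fisher_cooccurrence(5, 0, 0, 5)
        assert p == pytest.approx(1 / 252)
        assert not sig  # 0.004 is far above genome-wide threshold

    def test_zero_overlap_gives_p_one(self):
        p, _ = fisher_cooccurrence(0, 10, 10, 100)
        assert p == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        p, sig = fisher_cooccurrence(5, 0, 0, 5, bonferroni_alpha=1 / 252)
        assert not sig
        p, sig = fisher_cooccurrence(
            5, 0, 0, 5, bonferroni_alpha=1 / 252 + 1e-12
        )
        assert sig

    def test_matches_enumeration_on_sample_of_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 8, size=4)
            p, _ = fisher_cooccurrence(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(hypergeom_tail(a, b, c, d), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_cooccurrence(-1, 0, 0, 0)


class TestNetworkFilter:
    interactions = pd.DataFrame(
        {
            "gene_a": ["X"] * 10 + ["Y"] * 10 + ["Z"],
            "gene_b": [f"A{i}" for i in range(10)]
            + [f"B{i}" for i in range(10)] + ["A0"],
            "high_confidence": [True] * 21,
        }
    )

    def test_ten_percent_inclusive(self):
        anchors = {"A0"}  # X has 10 interactors, exactly 1 anchored
        kept = network_filter(["X"], self.interactions, anchors)
        assert kept == ["X"]

    def test_no_anchored_interactors_excluded(self):
        anchors = {"A0"}
        assert network_filter(["Y"], self.interactions, anchors) == []

    def test_anchor_without_interactions_retained(self):
        kept = network_filter(["LONE"], self.interactions, {"LONE"})
        assert kept == ["LONE"]

    def test_low_confidence_edges_ignored(self):
        inter = self.interactions.copy()
        inter["high_confidence"] = False
        assert network_filter(["X"], inter, {"A0"}) == []


class TestTcgaTopGenes:
    lengths = pd.Series({"SHORT": 1000, "LONG": 2000, "OTHER": 500})

    def test_rate_ordering_prefers_short_gene(self):
        table = pd.DataFrame(
            {"gene": ["SHORT"] * 10 + ["LONG"] * 10,
             "impact": ["high"] * 20}
        )
        top = tcga_top_genes(table, self.lengths, k=2)
        assert top == ["SHORT", "LONG"]

    def test_all_low_impact_discarded(self):
        table = pd.DataFrame(
            {"gene": ["SHORT"] * 5, "impact": ["low"] * 3 + ["modifier"] * 2}
        )
        assert tcga_top_genes(table, self.lengths) == []

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i:02d}" for i in range(30)]
        lengths = pd.Series(rng.integers(500, 5000, 30), index=genes, dtype=float)
        table = pd.DataFrame(
            {
                "gene": rng.choice(genes, 400),
                "impact": rng.choice(
                    ["modifier", "low", "moderate", "high"], 400
                ),
            }
        )
        top = tcga_top_genes(table, lengths, k=10)
        kept = table[table["impact"].isin(["moderate", "high"])]
        counts = kept.groupby("gene").size()
        expected = sorted(
            counts.index,
            key=lambda g: (-counts[g] / lengths[g], -counts[g], g),
        )[:10]
        assert top == expected


class TestMergePanel:
    def core(self):
        return [
            PanelGene("TP53", 5, {"core-score"}),
            PanelGene("KRAS", 3, {"core-score"}),
        ]

    def test_union_accumulates_provenance(self):
        merged = merge_panel(
            self.core(), {"textmining": ["TP53", "MLH1"]}
        )
        by_gene = {p.gene: p for p in merged}
        assert by_gene["TP53"].provenance == {"core-score", "textmining"}
        assert by_gene["MLH1"].provenance == {"textmining"}

    def test_empty_extensions_is_core(self):
        merged = merge_panel(self.core())
        assert {p.gene for p in merged} == {"TP53", "KRAS"}

    def test_handpicked_always_retained(self):
        merged = merge_panel(self.core(), handpicked=["EPCAM"])
        assert any(
            p.gene == "EPCAM" and p.provenance == {"handpicked"} for p in merged
        )

    def test_idempotent_and_order_independent(self):
        exts = {
            "pathway": ["A", "B"],
            "drugtarget": ["B", "C"],
            "tcga": ["C", "A"],
        }
        m1 = merge_panel(self.core(), exts)
        m2 = merge_panel(self.core(), dict(reversed(exts.items())))
        m3 = merge_panel(m1, exts)  # merging twice changes nothing
        assert [(p.gene, p.score, p.provenance) for p in m1] == [
            (p.gene, p.score, p.provenance) for p in m2
        ]
        assert {p.gene for p in m3} == {p.gene for p in m1}

    def test_union_size_matches_set_oracle(self):
        rng = np.random.default_rng(14)
        pool = [f"g{i}" for i in range(40)]
        exts = {
            f"src{j}": list(rng.choice(pool, size=10, replace=False))
            for j in range(5)
        }
        merged = merge_panel(self.core(), exts)
        expected = {"TP53", "KRAS"} | {
            g.upper() for genes in exts.values() for g in genes
        }
        assert {p.gene for p in merged} == expected

    def test_synonym_collision_raises(self):
        with pytest.raises(ValueError, match="normalize"):
            normalize_gene_names(["TRP53", "TP53"], {"TRP53": "TP53"})
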