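import itertools

import numpy as np
import pandas as pd
import pytest

from statefate.network import (
    build_network,
    categorize_ra_response,
    classify_rara_peaks,
    identify_direct_targets,
    mediating_distances,
    to_graph,
)

from conftest import make_genes


class TestClassifyRara:
    def counts(self, afe, pe):
        return pd.DataFrame({"afe": [afe], "pe": [pe]})

    @pytest.mark.parametrize(
        "afe,pe,expected",
        [
            (3.0, 8.2, "Enriched"),   # log2(9.2/4) ~ 1.2
            (7.0, 3.0, "Depleted"),   # log2(4/8) = -1 inclusive
            (3.0, 6.95, "Equal"),     # log2(7.95/4) ~ 0.99
            (3.0, 7.0, "Enriched"),   # log2(8/4) = 1 inclusive
            (1.0, 1.0, "Equal"),
        ],
    )
    def test_threshold_rule(self, afe, pe, expected):
        assert classify_rara_peaks(self.counts(afe, pe)).iloc[0] == expected

    def test_boundary_grid_exhaustive(self):
        # classification must match a direct restatement of the rule over a
        # grid straddling the +/-1 log2FC boundaries
        vals = [0.0, 0.5, 1.0, 3.0, 7.0, 15.0]
        for afe, pe in itertools.product(vals, vals):
            lfc = np.log2((pe + 1) / (afe + 1))
            expected = "Enriched" if lfc >= 1 else "Depleted" if lfc <= -1 else "Equal"
            assert classify_rara_peaks(self.counts(afe, pe)).iloc[0] == expected

    def test_negative_counts_floored(self):
        # input subtraction can leave negative values; floored to 0
        assert classify_rara_peaks(self.counts(-5.0, 1.0)).iloc[0] == "Enriched"


class TestDirectTargets:
    def genes(self):
        g = make_genes(
            [
                ("tf_up", "chr1", 1000, 10, 30, "up"),
                ("gene_pc", "chr1", 5000, 10, 10, "no"),
                ("tf_flat", "chr1", 9000, 10, 10, "no"),
            ]
        )
        g.loc[g.gene_id.str.startswith("tf"), "is_tf"] = True
        return g

    def peaks(self, summit):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": summit - 50, "end": summit + 51, "summit": summit}]
        )

    def test_nearest_upregulated_tf_included(self):
        assert identify_direct_targets(self.peaks(900), self.genes()) == {"tf_up"}

    def test_non_tf_nearest_contributes_nothing(self):
        # peak nearest to gene_pc even though a TF is second nearest
        assert identify_direct_targets(self.peaks(4800), self.genes()) == set()

    def test_tf_without_peak_excluded(self):
        # nearest gene is tf_flat (not upregulated)
        assert identify_direct_targets(self.peaks(8900), self.genes()) == set()


class TestMediatingDistances:
    def test_gap_and_min_over_peaks(self):
        genes = make_genes([("tf_t", "chr1", 100_000, 10, 20, "up")])
        gain = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 110_000, "end": 110_201},
                {"chrom": "chr1", "start": 130_000, "end": 130_201},
            ]
        )
        fps = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 110_050, "end": 110_070, "motif_id": "m", "tf_id": "tf_s"},
                {"chrom": "chr1", "start": 130_050, "end": 130_070, "motif_id": "m", "tf_id": "tf_s"},
            ]
        )
        out = mediating_distances(fps, gain, genes, ["tf_s"], ["tf_t"])
        assert len(out) == 1
        assert out["distance"].iloc[0] == 10_000

    def test_footprint_outside_peak_ignored(self):
        genes = make_genes([("tf_t", "chr1", 100_000, 10, 20, "up")])
        gain = pd.DataFrame([{"chrom": "chr1", "start": 110_000, "end": 110_201}])
        fps = pd.DataFrame(
            [{"chrom": "chr1", "start": 120_000, "end": 120_020, "motif_id": "m", "tf_id": "tf_s"}]
        )
        assert mediating_distances(fps, gain, genes, ["tf_s"], ["tf_t"]).empty


def hand_fixture():
    """12 candidate edges over 8 annotated TFs; exactly 5 survive.

    Hand enumeration: edges 1-5 pass every predicate (scores > 0.7, both
    TFs qualified, mediating distance < 50 kb); 6 fails the strict score
    bound (0.7), 7 low score, 8/9 unqualified endpoint, 10 low source TPM,
    11 distance 50 kb (strict <), 12 no mediating peak.
    """
    annot = pd.DataFrame(
        {
            "tpm_pe": [20.0] * 6 + [3.0, 20.0],
            "active_integrated": [True] * 5 + [False, True, True],
            "fp_gain_enriched": False,
            "influence_rank": [1, 2, 3, 4, 5, 100, 7, 8],
        },
        index=[f"T{i}" for i in range(1, 9)],
    )
    annot.loc["T6", "influence_rank"] = 100  # fails all three criteria
    edges = pd.DataFrame(
        [
            ("T1", "T2", 0.90),
            ("T2", "T3", 0.80),
            ("T3", "T4", 0.75),
            ("T4", "T5", 0.71),
            ("T5", "T1", 0.95),
            ("T1", "T3", 0.70),
            ("T2", "T4", 0.65),
            ("T1", "T6", 0.90),
            ("T6", "T2", 0.90),
            ("T7", "T2", 0.90),
            ("T1", "T5", 0.90),
            ("T4", "T2", 0.90),
        ],
        columns=["source_tf", "target_tf", "diff_score"],
    )
    mediating = pd.DataFrame(
        [
            ("T1", "T2", 10_000),
            ("T2", "T3", 30_000),
            ("T3", "T4", 24_999),
            ("T4", "T5", 49_999),
            ("T5", "T1", 0),
            ("T1", "T3", 10_000),
            ("T2", "T4", 10_000),
            ("T1", "T6", 10_000),
            ("T6", "T2", 10_000),
            ("T7", "T2", 10_000),
            ("T1", "T5", 50_000),
        ],
        columns=["source_tf", "target_tf", "distance"],
    )
    expected = {("T1", "T2"), ("T2", "T3"), ("T3", "T4"), ("T4", "T5"), ("T5", "T1")}
    return edges, annot, mediating, expected


class TestBuildNetwork:
    def test_hand_enumerated_fixture(self):
        edges, annot, mediating, expected = hand_fixture()
        kept = build_network(edges, annot, mediating)
        assert set(map(tuple, kept[["source_tf", "target_tf"]].to_numpy())) == expected

    def test_display_flag_is_strict_25kb(self):
        edges, annot, mediating, _ = hand_fixture()
        kept = build_network(edges, annot, mediating).set_index(["source_tf", "target_tf"])
        assert kept.loc[("T1", "T2"), "display"]
        assert kept.loc[("T3", "T4"), "display"]  # 24 999 < 25 000
        assert not kept.loc[("T2", "T3"), "display"]
        assert not kept.loc[("T4", "T5"), "display"]

    def test_display_subset_of_network(self):
        edges, annot, mediating, _ = hand_fixture()
        kept = build_network(edges, annot, mediating)
        assert (kept.loc[kept["display"], "distance"] < 25_000).all()
        assert (kept["distance"] < 50_000).all()

    def test_qualification_is_disjunctive(self):
        edges, annot, mediating, _ = hand_fixture()
        # T6 qualifies through influence rank alone -> edge 8 now passes
        annot.loc["T6", "influence_rank"] = 10
        kept = build_network(edges, annot, mediating)
        assert ("T1", "T6") in set(map(tuple, kept[["source_tf", "target_tf"]].to_numpy()))

    def test_unannotated_tf_rejected(self):
        edges, annot, mediating, _ = hand_fixture()
        with pytest.raises(ValueError, match="annotation"):
            build_network(edges, annot.drop(index="T3"), mediating)


class TestRaCategories:
    def test_partition_and_rules(self):
        cats = categorize_ra_response(
            ["A", "B", "C"],
            direct_targets={"A"},
            de_expanded={"A": "up", "B": "up", "C": "no"},
        )
        assert cats == {
            "A": "RARA_direct_target",
            "B": "RA_responsive",
            "C": "RA_non_responsive",
        }

    def test_direct_target_requires_upregulation(self):
        cats = categorize_ra_response(
            ["A"], direct_targets={"A"}, de_expanded={"A": "no"}
        )
        assert cats["A"] == "RA_non_responsive"

    def test_forced_node_addition(self):
        cats = categorize_ra_response(
            ["A"], set(), {"A": "no"}, forced={"GBX2": "RARA_direct_target"}
        )
        assert cats["GBX2"] == "RARA_direct_target"
        with pytest.raises(ValueError, match="category"):
            categorize_ra_response(["A"], set(), {"A": "no"}, forced={"X": "bogus"})


def test_graph_export_attributes():
    edges, annot, mediating, expected = hand_fixture()
    kept = build_network(edges, annot, mediating)
    g = to_graph(kept, categories={t: "RA_responsive" for t in annot.index})
    assert set(g.edges) == expected
    assert g.edges[("T1", "T2")]["display"] is True
    assert g.nodes["T1"]["ra_category"] == "RA_responsive"
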