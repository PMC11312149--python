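import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from statefate.association import (
    adjust_bh,
    classify_association,
    compute_ratios,
    fisher_triplet,
    tally_gene_neighbors,
    tally_peak_bins,
)

ABC = ("Tss", "EnhA", "Quies")
K = len(ABC)


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive enumeration over all tables with the same margins."""
    n = a + b + c + d
    r, col = a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r, col)
    p0 = hypergeom.pmf(a, n, r, col)
    return min(1.0, float(pmf[pmf <= p0 * (1 + 1e-7)].sum()))


class TestTallyGenes:
    def test_unique_gene_dedup(self):
        # 10 bins, 3 undergoing transition code 1; their nearest genes are
        # g1 (up) and g2 (up) twice -> UP_T counts unique genes = 2
        trans = np.array([0, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        nearest = pd.DataFrame(
            {
                "gene_id": ["g3", "g1", "g2", "g2", "g4", None, None, None, None, None],
                "distance": [0, 0, 0, 0, 0, -1, -1, -1, -1, -1],
            }
        )
        labels = pd.Series({"g1": "up", "g2": "up", "g3": "no", "g4": "down"})
        out = tally_gene_neighbors(trans, ABC, nearest, labels)
        row = out[(out.s_from == "Tss") & (out.s_to == "EnhA")].iloc[0]
        assert (row.up_t, row.down_t, row.no_t) == (2, 0, 0)
        # g3, g4 nearest only to non-t bins; g1, g2 nearest only to t bins
        assert (row.up_o, row.down_o, row.no_o) == (0, 1, 1)

    def test_gene_in_both_groups_when_shared(self):
        # g1 nearest to a t-bin and to another-transition bin: in T and in O
        trans = np.array([1, 0])
        nearest = pd.DataFrame({"gene_id": ["g1", "g1"], "distance": [0, 0]})
        labels = pd.Series({"g1": "up"})
        out = tally_gene_neighbors(trans, ABC, nearest, labels)
        t_row = out[(out.s_from == "Tss") & (out.s_to == "EnhA")].iloc[0]
        assert t_row.up_t == 1 and t_row.up_o == 1

    def test_per_bin_mode(self):
        trans = np.array([1, 1, 0])
        nearest = pd.DataFrame({"gene_id": ["g1", "g1", "g1"], "distance": [0, 0, 0]})
        labels = pd.Series({"g1": "up"})
        out = tally_gene_neighbors(trans, ABC, nearest, labels, unique_genes=False)
        t_row = out[(out.s_from == "Tss") & (out.s_to == "EnhA")].iloc[0]
        assert t_row.up_t == 2 and t_row.up_o == 1

    def test_bad_label_rejected(self):
        trans = np.array([0])
        nearest = pd.DataFrame({"gene_id": ["g1"], "distance": [0]})
        with pytest.raises(ValueError, match="labels"):
            tally_gene_neighbors(trans, ABC, nearest, pd.Series({"g1": "UP"}))


class TestTallyPeaks:
    def test_direct_count(self):
        # 4 t-bins, one carries a Gain summit, none a Lose summit
        trans = np.array([1, 1, 1, 1, 0, 0])
        out = tally_peak_bins(trans, ABC, gain_bins=np.array([0]), lose_bins=np.array([5]))
        row = out[(out.s_from == "Tss") & (out.s_to == "EnhA")].iloc[0]
        assert (row.up_t, row.down_t, row.no_t) == (1, 0, 3)
        assert (row.up_o, row.down_o, row.no_o) == (0, 1, 1)

    def test_gain_precedence_on_conflict(self):
        trans = np.array([1, 0])
        out = tally_peak_bins(trans, ABC, gain_bins=np.array([0]), lose_bins=np.array([0]))
        row = out[(out.s_from == "Tss") & (out.s_to == "EnhA")].iloc[0]
        assert (row.up_t, row.down_t) == (1, 0)
        assert out.attrs["conflict_bins"] == [0]


class TestFisherTriplet:
    def counts(self, up_t, down_t, no_t, up_o, down_o, no_o):
        return pd.Series(
            dict(up_t=up_t, down_t=down_t, no_t=no_t, up_o=up_o, down_o=down_o, no_o=no_o)
        )

    def test_balanced_table_p_one(self):
        p_ud, _, _ = fisher_triplet(self.counts(1, 1, 0, 10, 10, 0))
        assert p_ud == pytest.approx(1.0)

    def test_closed_case_5005(self):
        p_ud, _, _ = fisher_triplet(self.counts(5, 0, 0, 0, 5, 0))
        assert p_ud == pytest.approx(2 / 252, abs=1e-12)

    def test_zero_margin_convention(self):
        p_ud, p_up, p_down = fisher_triplet(self.counts(0, 0, 5, 0, 0, 50))
        assert p_ud == 1.0 and p_up == 1.0 and p_down == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 13, 4)
            if a + b + c + d == 0:
                continue
            counts = self.counts(int(a), int(b), 0, int(c), int(d), 0)
            p_ud, _, _ = fisher_triplet(counts)
            if min(a + b, c + d, a + c, b + d) == 0:
                assert p_ud == 1.0
            else:
                assert p_ud == pytest.approx(
                    fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), abs=1e-12
                )


class TestAdjustBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(100))
        q = adjust_bh(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


class TestRatios:
    def counts(self, *vals):
        return pd.Series(dict(zip(["up_t", "down_t", "no_t", "up_o", "down_o", "no_o"], vals)))

    def test_displayed_formulas(self):
        r = compute_ratios(self.counts(6, 2, 12, 15, 5, 80))
        assert r == (pytest.approx(2.0), pytest.approx(2.0), pytest.approx(2.0))

    def test_control_numerator_zero_undefined(self):
        r_ud, r_up, r_down = compute_ratios(self.counts(3, 1, 0, 5, 5, 0))
        assert np.isnan(r_ud)
        assert not np.isnan(r_up) and not np.isnan(r_down)

    def test_proportional_groups_give_unity(self):
        r = compute_ratios(self.counts(2, 4, 14, 10, 20, 70))
        assert r == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))

    def test_empty_group_all_undefined(self):
        assert all(np.isnan(v) for v in compute_ratios(self.counts(0, 0, 0, 1, 2, 3)))


class TestClassify:
    @pytest.mark.parametrize(
        "ratios,pvals,expected",
        [
            ((2.0, 2.0, 2.0), (0.01, 0.02, 0.9), "up_enriched"),
            ((0.5, 0.9, 1.5), (0.01, 0.9, 0.03), "down_enriched"),
            ((2.0, 1.1, np.nan), (0.01, 0.01, np.nan), "none"),
            ((2.0, 1.2, 2.0), (0.01, 0.01, 0.9), "none"),  # strict > 1.2
            ((1.0, 2.0, 2.0), (0.01, 0.01, 0.01), "none"),  # strict > 1
            ((2.0, 2.0, 2.0), (0.05, 0.01, 0.9), "none"),  # strict < 0.05
            ((np.nan, 2.0, 2.0), (0.01, 0.01, 0.01), "undefined"),
        ],
    )
    def test_rule(self, ratios, pvals, expected):
        assert classify_association(ratios, pvals) == expected


def test_updown_symmetry():
    """Swapping up/down everywhere mirrors the classification."""
    trans = np.tile(np.array([1, 1, 1, 0, 0, 0, 0, 0]), 10)
    rng = np.random.default_rng(3)
    gain = rng.choice(np.flatnonzero(trans == 1), 20, replace=False)
    lose = rng.choice(np.flatnonzero(trans == 0), 8, replace=False)
    a = tally_peak_bins(trans, ABC, gain, lose)
    b = tally_peak_bins(trans, ABC, lose, gain)  # labels swapped
    row_a = a[(a.s_from == "Tss") & (a.s_to == "EnhA")].iloc[0]
    row_b = b[(b.s_from == "Tss") & (b.s_to == "EnhA")].iloc[0]
    pa, pb = fisher_triplet(row_a), fisher_triplet(row_b)
    assert pa[0] == pytest.approx(pb[0], abs=1e-12)  # p_updown invariant
    assert pa[1] == pytest.approx(pb[2], abs=1e-12)
    ra, rb = compute_ratios(row_a), compute_ratios(row_b)
    la = classify_association(ra, (pa[0], pa[1], pa[2]))
    lb = classify_association(rb, (pb[0], pb[1], pb[2]))
    flip = {"up_enriched": "down_enriched", "down_enriched": "up_enriched"}
    assert lb == flip.get(la, la)
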