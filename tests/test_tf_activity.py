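import numpy as np
import pandas as pd
import pytest

from statefate.simulate import SimulationConfig, simulate_tf_inputs
from statefate.tf_activity import (
    MotifActivityInput,
    expression_zscores,
    fp_enrichment_scores,
    prepare_scaled_accessibility,
    select_active_motifs,
)

CONDS = ["DE", "AFE", "PE"]


class TestScaledAccessibility:
    def test_log2_then_center(self):
        m = pd.DataFrame([[4, 8, 16]], columns=CONDS)
        out = prepare_scaled_accessibility(m)
        np.testing.assert_allclose(out.to_numpy(), [[-1, 0, 1]])

    def test_constant_row_zero(self):
        out = prepare_scaled_accessibility(pd.DataFrame([[7, 7, 7]], columns=CONDS))
        np.testing.assert_allclose(out.to_numpy(), [[0, 0, 0]])

    def test_row_sums_zero(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.lognormal(3, 1, (50, 3)), columns=CONDS)
        out = prepare_scaled_accessibility(m)
        np.testing.assert_allclose(out.sum(axis=1), 0, atol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            prepare_scaled_accessibility(pd.DataFrame([[0.0, 1.0, 2.0]], columns=CONDS))


class TestFpScores:
    def padj(self, rows):
        return pd.DataFrame(rows, columns=["motif", "dar_set", "padj"])

    def test_floor_then_mean(self):
        fp = self.padj([("m1", "s1", 1e-3), ("m1", "s2", 0.0)])
        out = fp_enrichment_scores(fp, {"s1": "PE", "s2": "PE"})
        assert out.loc["m1", "PE"] == pytest.approx((3 + 16) / 2)

    def test_p_one_scores_zero(self):
        fp = self.padj([("m1", "s1", 1.0)])
        out = fp_enrichment_scores(fp, {"s1": "PE"})
        assert out.loc["m1", "PE"] == 0.0

    def test_single_set_is_neglog10(self):
        fp = self.padj([("m1", "s1", 0.01)])
        out = fp_enrichment_scores(fp, {"s1": "PE"})
        assert out.loc["m1", "PE"] == pytest.approx(2.0)

    def test_absent_motif_contributes_zero(self):
        fp = self.padj([("m1", "s1", 1e-4), ("m2", "s1", 1e-2), ("m2", "s2", 1e-2)])
        out = fp_enrichment_scores(fp, {"s1": "PE", "s2": "PE"})
        assert out.loc["m1", "PE"] == pytest.approx(2.0)  # (4 + 0) / 2

    def test_unmapped_set_rejected(self):
        with pytest.raises(ValueError, match="mapping"):
            fp_enrichment_scores(self.padj([("m1", "sX", 0.5)]), {"s1": "PE"})

    def test_monotone_in_p(self):
        for p_lo, p_hi in [(1e-8, 1e-4), (1e-4, 0.5), (0.5, 1.0)]:
            lo = fp_enrichment_scores(self.padj([("m", "s", p_lo)]), {"s": "PE"})
            hi = fp_enrichment_scores(self.padj([("m", "s", p_hi)]), {"s": "PE"})
            assert lo.loc["m", "PE"] > hi.loc["m", "PE"]


class TestExpressionZ:
    def test_population_sd(self):
        z = expression_zscores(pd.DataFrame([[2, 8, 32]], columns=CONDS))
        np.testing.assert_allclose(z.to_numpy(), [[-1.2247, 0, 1.2247]], atol=1e-4)

    def test_constant_row(self):
        z = expression_zscores(pd.DataFrame([[5, 5, 5]], columns=CONDS))
        np.testing.assert_allclose(z.to_numpy(), [[0, 0, 0]])

    def test_rows_centered(self):
        rng = np.random.default_rng(1)
        z = expression_zscores(pd.DataFrame(rng.lognormal(2, 1, (20, 3)), columns=CONDS))
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)


def make_input(motif_z, fp_min_padj, tpm, de=True):
    """One-motif input with an aligned or custom FP profile."""
    fp = pd.DataFrame(
        [("m1", "s_DE", 0.3), ("m1", "s_AFE", 0.3), ("m1", "s_PE", fp_min_padj)],
        columns=["motif", "dar_set", "padj"],
    )
    return MotifActivityInput(
        motif_z=pd.DataFrame([motif_z], index=["m1"], columns=CONDS),
        fp_padj=fp,
        condition_map={"s_DE": "DE", "s_AFE": "AFE", "s_PE": "PE"},
        tpm=pd.DataFrame([tpm], index=["tf1"], columns=CONDS),
        motif_tf={"m1": ("tf1",)},
        de_any={"tf1": de},
    )


class TestSelection:
    def test_coherent_profile_selected(self):
        inp = make_input([-2.5, 0.1, 2.6], 2e-4, [1.0, 2.0, 40.0])
        out = select_active_motifs(inp)
        assert out["selected"].tolist() == [True]
        assert out["pearson_z_fp"].iloc[0] > 0.5
        assert out["pearson_z_expr"].iloc[0] > 0.5

    def test_anticorrelated_expression_rejected(self):
        inp = make_input([-2.5, 0.1, 2.6], 2e-4, [40.0, 2.0, 1.0])
        out = select_active_motifs(inp)
        assert not out["selected"].iloc[0]
        assert out["pearson_z_expr"].iloc[0] < 0

    def test_weak_z_rejected_regardless(self):
        inp = make_input([-1.0, 0.1, 1.4], 2e-4, [1.0, 2.0, 40.0])
        out = select_active_motifs(inp)
        assert not out["selected"].iloc[0] and not out["pass_z"].iloc[0]

    def test_z_threshold_inclusive(self):
        inp = make_input([-1.0, 0.1, 2.0], 2e-4, [1.0, 2.0, 40.0])
        assert select_active_motifs(inp)["pass_z"].iloc[0]

    def test_condition_permutation_invariance(self):
        inp = make_input([-2.5, 0.1, 2.6], 2e-4, [1.0, 2.0, 40.0])
        perm = ["PE", "DE", "AFE"]
        inp2 = MotifActivityInput(
            motif_z=inp.motif_z[perm],
            fp_padj=inp.fp_padj,
            condition_map=inp.condition_map,
            tpm=inp.tpm[perm],
            motif_tf=inp.motif_tf,
            de_any=inp.de_any,
        )
        assert (
            select_active_motifs(inp)["selected"].tolist()
            == select_active_motifs(inp2)["selected"].tolist()
        )

    def test_unmapped_motif_skipped(self):
        inp = make_input([-2.5, 0.1, 2.6], 2e-4, [1.0, 2.0, 40.0])
        inp.motif_tf = {}
        assert select_active_motifs(inp).empty


@pytest.mark.parametrize("seed", [0, 7, 123])
def test_planted_recovery_with_single_filter_decoys(seed):
    cfg = SimulationConfig()
    inp, truth, decoys = simulate_tf_inputs(cfg, seed)
    out = select_active_motifs(inp)
    selected = set(map(tuple, out.loc[out["selected"], ["motif", "tf"]].to_numpy()))
    assert selected == truth
    # each decoy fails for its designed reason
    fail_col = {
        "low_z": "pass_z", "weak_fp": "pass_fp", "low_tpm": "pass_tpm",
        "not_de": "pass_de",
    }
    by_pair = out.set_index(["motif", "tf"])
    for pair, kind in decoys.items():
        row = by_pair.loc[pair]
        if kind in fail_col:
            assert not row[fail_col[kind]], (pair, kind)
        elif kind == "anti_expr":
            assert row["pearson_z_expr"] < 0.5
        elif kind == "anti_fp":
            assert row["pearson_z_fp"] < 0.5
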