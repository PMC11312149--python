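"""Association of state transitions with nearby expression / accessibility changes.

For every ordered state transition t (identical-state pairs included) the
bins undergoing t form the T group and all remaining bins the O (control)
group. In *genes* mode the groups are tallied as unique nearest expressed
genes labelled up / down / no (not differentially expressed); in *peaks*
mode as bins carrying a Gain summit, a Lose summit, or neither.

Three two-sided Fisher's exact tests are computed per transition (rows of
the 2x2 tables in brackets):

* P_UPDOWN:  [UP_T, DOWN_T]        vs [UP_O, DOWN_O]
* P_UP:      [UP_T, DOWN_T+NO_T]   vs [UP_O, DOWN_O+NO_O]
* P_DOWN:    [DOWN_T, UP_T+NO_T]   vs [DOWN_O, UP_O+NO_O]

each family BH-adjusted across transitions, together with the ratio
statistics

* RATIO_UPDOWN = ((UP_T-DOWN_T)/TOT_T) / ((UP_O-DOWN_O)/TOT_O)
* RATIO_UP     = (UP_T/TOT_T) / (UP_O/TOT_O)
* RATIO_DOWN   = (DOWN_T/TOT_T) / (DOWN_O/TOT_O)

A transition is *up_enriched* when RATIO_UPDOWN > 1, RATIO_UP > 1.2,
P_UPDOWN < 0.05 and P_UP < 0.05; *down_enriched* when RATIO_UPDOWN < 1,
RATIO_DOWN > 1.2, P_UPDOWN < 0.05 and P_DOWN < 0.05; otherwise *none*
(*undefined* when the T group is empty or RATIO_UPDOWN has a zero
denominator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .genes import assign_nearest_genes
from .grid import StateTrack
from .peaks import assign_peak_bins

LABELS = ("up", "down", "no")

COUNT_COLS = ["up_t", "down_t", "no_t", "up_o", "down_o", "no_o"]


def transition_codes(track_a: StateTrack, track_b: StateTrack) -> np.ndarray:
    """Per-bin joint transition code ``a * K + b``."""
    if track_a.grid != track_b.grid or track_a.alphabet != track_b.alphabet:
        raise ValueError("tracks must share grid and alphabet")
    k = len(track_a.alphabet)
    return track_a.codes.astype(np.int64) * k + track_b.codes


def _counts_frame(states, tallies: np.ndarray, observed: np.ndarray) -> pd.DataFrame:
    """Assemble the per-transition count table from per-(transition, label)
    tallies; the O group of each transition is the complement of its T group."""
    k = len(states)
    totals = tallies.sum(axis=0)
    idx = np.flatnonzero(observed)
    i, j = np.divmod(idx, k)
    out = pd.DataFrame(
        {
            "s_from": np.asarray(states, dtype=object)[i],
            "s_to": np.asarray(states, dtype=object)[j],
        }
    )
    for li, lab in enumerate(LABELS):
        out[f"{lab}_t"] = tallies[idx, li]
    for li, lab in enumerate(LABELS):
        out[f"{lab}_o"] = totals[li] - tallies[idx, li]
    return out


def tally_gene_neighbors(
    trans_codes: np.ndarray,
    states: tuple[str, ...],
    nearest: pd.DataFrame,
    gene_labels: pd.Series,
    unique_genes: bool = True,
) -> pd.DataFrame:
    """Per-transition (UP/DOWN/NO)_T and _O tallies of nearest genes.

    ``nearest`` is the per-bin assignment from
    :func:`statefate.genes.assign_nearest_genes`; bins without a qualifying
    gene are excluded. With ``unique_genes`` (default) a gene nearest to
    several bins of a transition counts once in that transition's T group,
    and counts in the O group of t only when it is also nearest to a bin
    outside t; with ``unique_genes=False`` tallies are per bin.
    """
    bad = set(gene_labels.unique()) - set(LABELS)
    if bad:
        raise ValueError(f"gene DE labels outside {LABELS}: {sorted(bad)}")
    k = len(states)
    has_gene = nearest["gene_id"].notna().to_numpy()
    df = pd.DataFrame(
        {
            "trans": trans_codes[has_gene],
            "gene_id": nearest["gene_id"].to_numpy()[has_gene],
        }
    )
    df["label"] = df["gene_id"].map(gene_labels)
    if df["label"].isna().any():
        missing = df.loc[df["label"].isna(), "gene_id"].unique()
        raise ValueError(f"genes without DE label: {missing[:5].tolist()}")
    lab_idx = {lab: i for i, lab in enumerate(LABELS)}

    observed = np.zeros(k * k, dtype=bool)
    observed[np.unique(trans_codes)] = True

    t_counts = np.zeros((k * k, len(LABELS)), dtype=np.int64)
    if unique_genes:
        dedup = df.drop_duplicates(["trans", "gene_id"])
        for (t, lab), grp in dedup.groupby(["trans", "label"], sort=False):
            t_counts[t, lab_idx[lab]] = len(grp)
        # O group of t excludes genes nearest *only* to t-bins
        per_gene = dedup.groupby("gene_id")["trans"].agg(["first", "size"])
        per_gene["label"] = gene_labels.loc[per_gene.index].to_numpy()
        g_totals = np.zeros(len(LABELS), dtype=np.int64)
        for lab, cnt in per_gene["label"].value_counts().items():
            g_totals[lab_idx[lab]] = cnt
        singles = per_gene[per_gene["size"] == 1]
        single_counts = np.zeros((k * k, len(LABELS)), dtype=np.int64)
        for (t, lab), grp in singles.groupby(["first", "label"], sort=False):
            single_counts[t, lab_idx[lab]] = len(grp)
        idx = np.flatnonzero(observed)
        i, j = np.divmod(idx, k)
        out = pd.DataFrame(
            {
                "s_from": np.asarray(states, dtype=object)[i],
                "s_to": np.asarray(states, dtype=object)[j],
            }
        )
        for li, lab in enumerate(LABELS):
            out[f"{lab}_t"] = t_counts[idx, li]
        for li, lab in enumerate(LABELS):
            out[f"{lab}_o"] = g_totals[li] - single_counts[idx, li]
        return out
    for (t, lab), grp in df.groupby(["trans", "label"], sort=False):
        t_counts[t, lab_idx[lab]] = len(grp)
    return _counts_frame(states, t_counts, observed)


def tally_peak_bins(
    trans_codes: np.ndarray,
    states: tuple[str, ...],
    gain_bins: np.ndarray,
    lose_bins: np.ndarray,
) -> pd.DataFrame:
    """Per-transition tallies of bins carrying Gain / Lose peak summits.

    A bin carrying both a Gain and a Lose summit counts as Gain (precedence
    documented; such bins are also reported via the ``conflict`` attribute
    on the returned frame).
    """
    k = len(states)
    n = trans_codes.size
    lab = np.full(n, 2, dtype=np.int64)  # 'no'
    lab[np.asarray(lose_bins, dtype=np.int64)] = 1
    conflict = np.intersect1d(gain_bins, lose_bins)
    lab[np.asarray(gain_bins, dtype=np.int64)] = 0  # Gain precedence
    tallies = np.zeros((k * k, len(LABELS)), dtype=np.int64)
    np.add.at(tallies, (trans_codes, lab), 1)
    observed = np.zeros(k * k, dtype=bool)
    observed[np.unique(trans_codes)] = True
    out = _counts_frame(states, tallies, observed)
    out.attrs["conflict_bins"] = conflict.tolist()
    return out


def fisher_triplet(c) -> tuple[float, float, float]:
    """Two-sided Fisher p-values (P_UPDOWN, P_UP, P_DOWN) for one tally row.

    Tables with an all-zero margin yield p = 1 by convention.
    """
    up_t, down_t, no_t = int(c["up_t"]), int(c["down_t"]), int(c["no_t"])
    up_o, down_o, no_o = int(c["up_o"]), int(c["down_o"]), int(c["no_o"])
    tables = (
        [[up_t, down_t], [up_o, down_o]],
        [[up_t, down_t + no_t], [up_o, down_o + no_o]],
        [[down_t, up_t + no_t], [down_o, up_o + no_o]],
    )
    out = []
    for t in tables:
        arr = np.asarray(t)
        if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
            out.append(1.0)
        else:
            out.append(float(fisher_exact(arr, alternative="two-sided")[1]))
    return tuple(out)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_ratios(c) -> tuple[float, float, float]:
    """(RATIO_UPDOWN, RATIO_UP, RATIO_DOWN); NaN where a denominator is zero."""
    up_t, down_t, no_t = float(c["up_t"]), float(c["down_t"]), float(c["no_t"])
    up_o, down_o, no_o = float(c["up_o"]), float(c["down_o"]), float(c["no_o"])
    tot_t = up_t + down_t + no_t
    tot_o = up_o + down_o + no_o
    nan = float("nan")
    if tot_t == 0 or tot_o == 0:
        return nan, nan, nan
    r_ud = nan if up_o == down_o else ((up_t - down_t) / tot_t) / ((up_o - down_o) / tot_o)
    r_up = nan if up_o == 0 else (up_t / tot_t) / (up_o / tot_o)
    r_down = nan if down_o == 0 else (down_t / tot_t) / (down_o / tot_o)
    return r_ud, r_up, r_down


def classify_association(
    ratios: tuple[float, float, float],
    pvals: tuple[float, float, float],
    ratio_min: float = 1.2,
    alpha: float = 0.05,
) -> str:
    """Apply the printed enrichment rule to one transition's statistics.

    ``pvals`` are whichever family the caller selected (adjusted by
    default in :func:`associate`). Comparisons are strict, and comparisons
    against NaN fail, so a missing directional ratio simply blocks that
    direction; a missing RATIO_UPDOWN makes the transition *undefined*.
    """
    r_ud, r_up, r_down = ratios
    p_ud, p_up, p_down = pvals
    if np.isnan(r_ud):
        return "undefined"
    if r_ud > 1 and r_up > ratio_min and p_ud < alpha and p_up < alpha:
        return "up_enriched"
    if r_ud < 1 and r_down > ratio_min and p_ud < alpha and p_down < alpha:
        return "down_enriched"
    return "none"


def _finalize(counts: pd.DataFrame, ratio_min: float, alpha: float, use_adjusted: bool) -> pd.DataFrame:
    res = counts.copy()
    trip = np.array([fisher_triplet(row) for _, row in counts.iterrows()])
    res["p_updown"], res["p_up"], res["p_down"] = trip.T
    for name in ("updown", "up", "down"):
        res[f"q_{name}"] = adjust_bh(res[f"p_{name}"].to_numpy())
    ratios = np.array([compute_ratios(row) for _, row in counts.iterrows()])
    res["ratio_updown"], res["ratio_up"], res["ratio_down"] = ratios.T
    pcols = ["q_updown", "q_up", "q_down"] if use_adjusted else ["p_updown", "p_up", "p_down"]
    res["label"] = [
        classify_association(tuple(r), tuple(p), ratio_min=ratio_min, alpha=alpha)
        for r, p in zip(ratios, res[pcols].to_numpy())
    ]
    empty = res[["up_t", "down_t", "no_t"]].sum(axis=1) == 0
    res.loc[empty, "label"] = "undefined"
    return res


def associate_genes(
    track_a: StateTrack,
    track_b: StateTrack,
    genes: pd.DataFrame,
    contrast: tuple[str, str],
    max_dist: int = 50_000,
    min_tpm: float = 1.0,
    ratio_min: float = 1.2,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    unique_genes: bool = True,
) -> pd.DataFrame:
    """Full transition-expression association table for one contrast."""
    codes = transition_codes(track_a, track_b)
    nearest = assign_nearest_genes(track_a.grid, genes, contrast, max_dist, min_tpm)
    labels = genes.set_index("gene_id")[f"de_{contrast[0]}_vs_{contrast[1]}"]
    counts = tally_gene_neighbors(
        codes, track_a.alphabet, nearest, labels, unique_genes=unique_genes
    )
    return _finalize(counts, ratio_min, alpha, use_adjusted)


def associate_peaks(
    track_a: StateTrack,
    track_b: StateTrack,
    peaks: pd.DataFrame,
    ratio_min: float = 1.2,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Full transition-accessibility association table.

    ``peaks`` must carry a ``klass`` column; summit bins are computed on
    the tracks' grid.
    """
    codes = transition_codes(track_a, track_b)
    bins = assign_peak_bins(peaks, track_a.grid).to_numpy()
    gain = bins[(peaks["klass"] == "Gain").to_numpy()]
    lose = bins[(peaks["klass"] == "Lose").to_numpy()]
    counts = tally_peak_bins(codes, track_a.alphabet, gain, lose)
    return _finalize(counts, ratio_min, alpha, use_adjusted)
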