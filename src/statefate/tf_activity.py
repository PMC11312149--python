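"""Integrated transcription-factor activity calling.

Three condition-level evidence tracks are combined per (motif, TF) pair:

* differential motif-enrichment Z-scores (one per condition),
* footprint (FP) enrichment scores: the per-condition mean of
  -log10(adjusted p) over that condition's DAR sets, zeros floored at
  1e-16 before the log,
* expression Z-scores of log2 mean TPM across conditions.

A pair is called active iff (1) max |motif Z| >= 2 in some condition,
(2) some FP adjusted p < 0.001, (3) TF mean TPM > 5 in some condition,
(4) the TF is differentially expressed in >= 1 contrast, and (5) the motif
Z profile is positively correlated (Pearson r > 0.5) with both the FP
score profile and the TF expression Z profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MotifActivityInput:
    """Inputs to the integrated activity call.

    Attributes
    ----------
    motif_z
        motif x condition matrix of differential motif-enrichment Z-scores.
    fp_padj
        (motif, dar_set) adjusted footprint-enrichment p-values; long
        DataFrame with columns motif, dar_set, padj.
    condition_map
        dar_set -> condition.
    tpm
        TF gene x condition mean TPM.
    motif_tf
        motif -> iterable of TF gene ids.
    de_any
        TF gene -> bool, differentially expressed in >= 1 contrast.
    """

    motif_z: pd.DataFrame
    fp_padj: pd.DataFrame
    condition_map: dict[str, str]
    tpm: pd.DataFrame
    motif_tf: dict[str, tuple[str, ...]]
    de_any: dict[str, bool]

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.motif_z.columns)


def prepare_scaled_accessibility(mean_counts: pd.DataFrame) -> pd.DataFrame:
    """log2-transform normalized mean counts and center each region row.

    Row means of the output are exactly zero; this is the scaled matrix a
    differential motif-enrichment tool consumes.
    """
    x = mean_counts.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("mean accessibility counts must be positive")
    lg = np.log2(x)
    return pd.DataFrame(
        lg - lg.mean(axis=1, keepdims=True),
        index=mean_counts.index,
        columns=mean_counts.columns,
    )


def fp_enrichment_scores(
    fp_padj: pd.DataFrame,
    condition_map: dict[str, str],
    floor: float = 1e-16,
    motifs=None,
) -> pd.DataFrame:
    """Per-condition FP enrichment score: mean of -log10(max(p, floor)).

    Each DAR set is mapped to exactly one condition; a motif absent from a
    set contributes p = 1 (score 0) to that set, keeping the per-condition
    means comparable across motifs.
    """
    unmapped = set(fp_padj["dar_set"]) - set(condition_map)
    if unmapped:
        raise ValueError(f"DAR set(s) without condition mapping: {sorted(unmapped)}")
    if ((fp_padj["padj"] < 0) | (fp_padj["padj"] > 1)).any():
        raise ValueError("adjusted p-values must lie in [0, 1]")
    sets = sorted(condition_map)
    if motifs is None:
        motifs = sorted(fp_padj["motif"].unique())
    wide = (
        fp_padj.pivot_table(index="motif", columns="dar_set", values="padj", aggfunc="first")
        .reindex(index=motifs, columns=sets)
        .fillna(1.0)
    )
    score = -np.log10(np.maximum(wide.to_numpy(dtype=float), floor))
    frame = pd.DataFrame(score, index=wide.index, columns=wide.columns)
    conds = pd.Series(condition_map)
    return frame.T.groupby(conds).mean().T


def expression_zscores(tpm: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Row-wise Z-scores of log2 TPM across conditions.

    Uses the population standard deviation by default (the conditions are
    the whole population of cell types); constant rows map to all-zero
    Z-scores. Rows must be positive — callers filter on TPM first.
    """
    if tpm.shape[1] < 2:
        raise ValueError("need >= 2 conditions for Z-scores")
    x = tpm.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative TPM")
    if (x == 0).any():
        raise ValueError("zero TPM rows must be filtered before Z-scoring")
    lg = np.log2(x)
    mu = lg.mean(axis=1, keepdims=True)
    sd = lg.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (lg - mu) / sd, 0.0)
    return pd.DataFrame(z, index=tpm.index, columns=tpm.columns)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def select_active_motifs(
    inp: MotifActivityInput,
    z_abs: float = 2.0,
    fp_alpha: float = 0.001,
    tpm_min: float = 5.0,
    r_min: float = 0.5,
) -> pd.DataFrame:
    """Integrated activity table with one row per (motif, TF) pair.

    Returns all evaluated pairs with their per-condition profiles,
    correlations, and a boolean ``selected`` column; motifs with no TF
    mapping are skipped.
    """
    conds = list(inp.conditions)
    fp = fp_enrichment_scores(
        inp.fp_padj, inp.condition_map, motifs=list(inp.motif_z.index)
    ).reindex(columns=conds)
    min_padj = inp.fp_padj.groupby("motif")["padj"].min()

    rows = []
    for motif in inp.motif_z.index:
        tfs = inp.motif_tf.get(motif, ())
        if not tfs:
            continue
        mz = inp.motif_z.loc[motif, conds].to_numpy(dtype=float)
        fps = fp.loc[motif].to_numpy(dtype=float)
        pass_z = bool(np.max(np.abs(mz)) >= z_abs)
        pass_fp = bool(min_padj.get(motif, 1.0) < fp_alpha)
        r_fp = _pearson(mz, fps)
        for tf in tfs:
            if tf not in inp.tpm.index:
                raise ValueError(f"TF {tf!r} missing from TPM table")
            tpm_row = inp.tpm.loc[[tf], conds]
            pass_tpm = bool((tpm_row.to_numpy() > tpm_min).any())
            pass_de = bool(inp.de_any.get(tf, False))
            if (tpm_row.to_numpy() > 0).all():
                ez = expression_zscores(tpm_row).to_numpy()[0]
                r_expr = _pearson(mz, ez)
            else:
                ez = np.full(len(conds), np.nan)
                r_expr = float("nan")
            pass_corr = bool(r_fp > r_min) and bool(r_expr > r_min)
            rows.append(
                {
                    "motif": motif,
                    "tf": tf,
                    **{f"motif_z_{c}": v for c, v in zip(conds, mz)},
                    **{f"fp_score_{c}": v for c, v in zip(conds, fps)},
                    **{f"expr_z_{c}": v for c, v in zip(conds, ez)},
                    "pearson_z_fp": r_fp,
                    "pearson_z_expr": r_expr,
                    "pass_z": pass_z,
                    "pass_fp": pass_fp,
                    "pass_tpm": pass_tpm,
                    "pass_de": pass_de,
                    "selected": pass_z and pass_fp and pass_tpm and pass_de and pass_corr,
                }
            )
    return pd.DataFrame(rows)
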