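"""Differential-accessibility peak classification and bin assignment.

For an A-vs-B contrast a consensus peak is

* ``Gain``  — called in both replicates of B, FDR < ``fdr_max`` and
  log2FC > ``lfc_min``;
* ``Lose``  — called in both replicates of A, FDR < ``fdr_max`` and
  log2FC < −``lfc_min``;
* ``Common`` — called in both replicates of A and/or B and
  (FDR > ``fdr_max`` or |log2FC| < ``lfc_min``);
* ``Unclassified`` otherwise.

log2FC is oriented B over A (positive = more accessible in B).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import GenomeGrid, StateTrack

KLASSES = ("Gain", "Lose", "Common", "Unclassified")


def _called_both(peaks: pd.DataFrame, condition: str) -> np.ndarray:
    cols = [c for c in peaks.columns if c.startswith(f"called_{condition}_rep")]
    if len(cols) < 2:
        raise ValueError(
            f"peak table lacks per-replicate call flags for condition {condition!r} "
            f"(expected >=2 'called_{condition}_rep*' columns, found {cols})"
        )
    return peaks[cols].all(axis=1).to_numpy()


def classify_dars(
    peaks: pd.DataFrame,
    contrast: tuple[str, str],
    fdr_max: float = 0.01,
    lfc_min: float = 1.0,
) -> pd.Series:
    """Classify each peak as Gain/Lose/Common/Unclassified for ``contrast=(A, B)``."""
    cond_a, cond_b = contrast
    if peaks[["log2fc", "fdr"]].isna().any(axis=None):
        bad = peaks.index[peaks[["log2fc", "fdr"]].isna().any(axis=1)].tolist()
        raise ValueError(f"peaks with missing log2fc/fdr statistics: {bad[:10]}")
    lfc = peaks["log2fc"].to_numpy(dtype=float)
    fdr = peaks["fdr"].to_numpy(dtype=float)
    in_a = _called_both(peaks, cond_a)
    in_b = _called_both(peaks, cond_b)

    klass = np.full(len(peaks), "Unclassified", dtype=object)
    klass[in_b & (fdr < fdr_max) & (lfc > lfc_min)] = "Gain"
    klass[in_a & (fdr < fdr_max) & (lfc < -lfc_min)] = "Lose"
    common = (in_a | in_b) & ((fdr > fdr_max) | (np.abs(lfc) < lfc_min))
    klass[common & (klass == "Unclassified")] = "Common"
    return pd.Series(klass, index=peaks.index, name="klass")


def assign_peak_bins(peaks: pd.DataFrame, grid: GenomeGrid) -> pd.Series:
    """Global index of the grid bin containing each peak summit."""
    out = np.empty(len(peaks), dtype=np.int64)
    for chrom, sub in peaks.groupby("chrom", sort=False):
        out[peaks.index.get_indexer(sub.index)] = grid.bin_index(
            chrom, sub["summit"].to_numpy()
        )
    return pd.Series(out, index=peaks.index, name="bin")


def stratify_peaks_by_state(
    peaks: pd.DataFrame,
    track_a: StateTrack,
    track_b: StateTrack,
) -> tuple[dict[tuple[str, str], pd.Index], dict[str, pd.Index]]:
    """Group classified peaks by chromatin state, with per-state backgrounds.

    Lose peaks are keyed by the state of their summit bin in condition A,
    Gain peaks by the state in condition B. The background for state ``s``
    is the set of Common peaks whose summit bin is in state ``s`` in A
    and/or in B.

    ``peaks`` must carry ``klass`` and ``bin`` columns (see
    :func:`classify_dars`, :func:`assign_peak_bins`).

    Returns
    -------
    groups
        ``(klass, state) -> peak index``, for klass in {Gain, Lose}.
    backgrounds
        ``state -> Common-peak index``.
    """
    if track_a.grid is not track_b.grid and track_a.grid != track_b.grid:
        raise ValueError("tracks are on different grids")
    for col in ("klass", "bin"):
        if col not in peaks:
            raise ValueError(f"peak table lacks {col!r} column")
    bins = peaks["bin"].to_numpy()
    if bins.min(initial=0) < 0 or (len(bins) and bins.max() >= track_a.grid.total_bins):
        raise ValueError("peak bin index outside grid")
    state_a = track_a.states[bins]
    state_b = track_b.states[bins]

    groups: dict[tuple[str, str], pd.Index] = {}
    is_gain = (peaks["klass"] == "Gain").to_numpy()
    is_lose = (peaks["klass"] == "Lose").to_numpy()
    for state in track_b.alphabet:
        idx = peaks.index[is_gain & (state_b == state)]
        if len(idx):
            groups[("Gain", state)] = idx
    for state in track_a.alphabet:
        idx = peaks.index[is_lose & (state_a == state)]
        if len(idx):
            groups[("Lose", state)] = idx

    is_common = (peaks["klass"] == "Common").to_numpy()
    backgrounds = {
        state: peaks.index[is_common & ((state_a == state) | (state_b == state))]
        for state in track_a.alphabet
    }
    return groups, backgrounds
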