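"""Nearest-expressed-gene assignment.

A gene qualifies as *expressed* when its mean TPM exceeds ``min_tpm`` in at
least one of the two compared conditions. The distance between an interval
and a TSS is the gap to the nearest base the interval covers (0 when the TSS
lies inside the half-open interval); a gene is assigned only when that gap
is within ``max_dist`` (inclusive). Ties are broken by lexicographically
smallest gene id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import GenomeGrid


def interval_point_gap(start, end, pos):
    """Gap in bp between half-open interval(s) ``[start, end)`` and point(s)."""
    start = np.asarray(start)
    end = np.asarray(end)
    pos = np.asarray(pos)
    return np.maximum(0, np.maximum(start - pos, pos - (end - 1)))


def expressed_mask(genes: pd.DataFrame, conditions: tuple[str, str], min_tpm: float = 1.0) -> np.ndarray:
    cols = [f"tpm_{c}" for c in conditions]
    missing = [c for c in cols if c not in genes]
    if missing:
        raise ValueError(f"gene table lacks TPM column(s): {missing}")
    tpm = genes[cols].to_numpy(dtype=float)
    if (tpm < 0).any():
        raise ValueError("negative TPM in gene table")
    return (tpm > min_tpm).any(axis=1)


def nearest_expressed_tss(
    interval: tuple[str, int, int],
    genes: pd.DataFrame,
    conditions: tuple[str, str],
    max_dist: int = 50_000,
    min_tpm: float = 1.0,
):
    """Nearest expressed gene for a single interval, or ``None``.

    Brute-force over the candidate set; use :func:`assign_nearest_genes`
    for genome-wide per-bin assignment.
    """
    chrom, start, end = interval
    cand = genes[expressed_mask(genes, conditions, min_tpm) & (genes["chrom"] == chrom)]
    if cand.empty:
        return None
    d = interval_point_gap(start, end, cand["tss"].to_numpy())
    order = np.lexsort((cand["gene_id"].to_numpy(), d))
    best = order[0]
    if d[best] > max_dist:
        return None
    return cand["gene_id"].iloc[best], int(d[best])


class _ArgminTable:
    """Sparse table answering vectorized range-argmin queries on a key array."""

    def __init__(self, keys: np.ndarray):
        self.keys = keys
        n = len(keys)
        levels = [np.arange(n, dtype=np.int64)]
        span = 1
        while 2 * span <= n:
            prev = levels[-1]
            a, b = prev[: len(prev) - span], prev[span:]
            levels.append(np.where(keys[a] <= keys[b], a, b))
            span *= 2
        self.levels = levels

    def query(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Argmin of keys over [lo, hi); requires hi > lo elementwise."""
        length = hi - lo
        if np.any(length <= 0):
            raise ValueError("empty range-argmin query")
        lev = np.floor(np.log2(length)).astype(np.int64)
        out = np.empty(len(lo), dtype=np.int64)
        for l in np.unique(lev):
            m = lev == l
            span = 1 << int(l)
            a = self.levels[int(l)][lo[m]]
            b = self.levels[int(l)][hi[m] - span]
            out[m] = np.where(self.keys[a] <= self.keys[b], a, b)
        return out


def assign_nearest_genes(
    grid: GenomeGrid,
    genes: pd.DataFrame,
    conditions: tuple[str, str],
    max_dist: int = 50_000,
    min_tpm: float = 1.0,
) -> pd.DataFrame:
    """Per-bin nearest expressed gene over the whole grid.

    Returns a DataFrame indexed by global bin with columns ``gene_id``
    (pandas NA where no gene qualifies) and ``distance`` (-1 where none).
    """
    total = grid.total_bins
    gene_out = np.full(total, None, dtype=object)
    dist_out = np.full(total, -1, dtype=np.int64)
    cand = genes[expressed_mask(genes, conditions, min_tpm)]
    # lexicographic rank of gene ids, for deterministic tie-breaking
    all_ids = cand["gene_id"].to_numpy()
    id_rank_all = pd.Series(np.argsort(np.argsort(all_ids)), index=cand.index)

    for chrom in grid.chroms:
        sub = cand[cand["chrom"] == chrom]
        if sub.empty:
            continue
        order = np.lexsort((sub["gene_id"].to_numpy(), sub["tss"].to_numpy()))
        tss = sub["tss"].to_numpy()[order]
        ids = sub["gene_id"].to_numpy()[order]
        ranks = id_rank_all.loc[sub.index].to_numpy()[order]

        off = grid.offsets[chrom]
        n = grid.n_bins(chrom)
        bs = grid.bin_size
        starts = np.arange(n, dtype=np.int64) * bs
        ends = np.minimum(starts + bs, grid.chrom_sizes[chrom])

        # minimal gap: only sorted neighbours of the interval can attain it
        j = np.searchsorted(tss, starts, side="left")
        k = np.searchsorted(tss, ends, side="left")
        big = np.int64(1 << 60)
        d = np.full((n, 4), big, dtype=np.int64)
        for col, idx in enumerate((j - 1, j, k - 1, k)):
            ok = (idx >= 0) & (idx < len(tss))
            d[ok, col] = interval_point_gap(starts[ok], ends[ok], tss[np.clip(idx, 0, len(tss) - 1)][ok])
        dmin = d.min(axis=1)
        within = dmin <= max_dist

        # all genes attaining dmin lie in the tss window [start-dmin, end-1+dmin]
        lo = np.searchsorted(tss, starts - dmin, side="left")
        hi = np.searchsorted(tss, ends - 1 + dmin, side="right")
        table = _ArgminTable(ranks)
        win = table.query(lo[within], hi[within])
        gene_out[off : off + n][within] = ids[win]
        dist_out[off : off + n][within] = dmin[within]

    return pd.DataFrame({"gene_id": gene_out, "distance": dist_out})
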