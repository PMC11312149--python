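"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular readers go through pandas and therefore transparently accept
gzip-compressed files. Coordinates are BED-style: 0-based, half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import DEFAULT_STATES, QUIESCENT, GenomeGrid, StateTrack

_BED_SKIP = ("track", "browser", "#")


def _read_bedlike(path, names) -> pd.DataFrame:
    import gzip
    import io

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        # tolerate UCSC-style header lines
        lines = [ln for ln in fh if ln.strip() and not ln.startswith(_BED_SKIP)]
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", header=None, dtype=str)
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def read_segmentation(
    path,
    grid: GenomeGrid,
    condition: str = "",
    alphabet: tuple[str, ...] = DEFAULT_STATES,
) -> StateTrack:
    """Rasterize a dense-segmentation BED file onto ``grid``.

    Each row is ``(chrom, start, end, state)``. Segments that tile the grid
    exactly are assigned directly; otherwise a bin takes the state covering
    the majority of it, ties going to the segment appearing earlier in the
    file. Bins not covered by any segment default to the quiescent state.

    Raises
    ------
    ValueError
        Unknown chromosome, unknown state, or overlapping segments carrying
        conflicting states.
    """
    df = _read_bedlike(path, ["chrom", "start", "end", "state"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)

    unknown = set(df["chrom"]) - set(grid.chrom_sizes)
    if unknown:
        raise ValueError(f"segmentation references unknown chromosome(s): {sorted(unknown)}")
    state_index = {s: i for i, s in enumerate(alphabet)}
    bad_states = set(df["state"]) - set(alphabet)
    if bad_states:
        raise ValueError(f"unknown chromatin state(s): {sorted(bad_states)}")

    codes = np.full(grid.total_bins, state_index[QUIESCENT], dtype=np.int32)
    bs = grid.bin_size
    for chrom, sub in df.groupby("chrom", sort=False):
        size = grid.chrom_sizes[chrom]
        if (sub["end"] > size).any() or (sub["start"] < 0).any():
            raise ValueError(f"segment outside chromosome {chrom!r} bounds")
        _check_conflicting_overlaps(sub, chrom)
        off = grid.offsets[chrom]
        n = grid.n_bins(chrom)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        seg_codes = sub["state"].map(state_index).to_numpy()
        if ((starts % bs == 0) & (ends % bs == 0)).all():
            for s, e, c in zip(starts, ends, seg_codes):
                codes[off + s // bs : off + e // bs] = c
        else:
            best = np.zeros(n, dtype=np.int64)  # bp of overlap backing current call
            for s, e, c in zip(starts, ends, seg_codes):
                b0, b1 = s // bs, (e - 1) // bs
                ov = np.full(b1 - b0 + 1, bs, dtype=np.int64)
                ov[0] = min(e, (b0 + 1) * bs) - s
                ov[-1] = e - max(s, b1 * bs)
                if b0 == b1:
                    ov[:] = e - s
                win = ov > best[b0 : b1 + 1]  # strict: earlier segment keeps ties
                best[b0 : b1 + 1][win] = ov[win]
                codes[off + b0 : off + b1 + 1][win] = c
    return StateTrack(grid=grid, condition=condition, alphabet=tuple(alphabet), codes=codes)


def _check_conflicting_overlaps(sub: pd.DataFrame, chrom: str) -> None:
    srt = sub.sort_values("start", kind="stable")
    starts = srt["start"].to_numpy()
    ends = srt["end"].to_numpy()
    states = srt["state"].to_numpy()
    overlap = starts[1:] < ends[:-1]
    conflict = overlap & (states[1:] != states[:-1])
    if conflict.any():
        i = int(np.flatnonzero(conflict)[0])
        raise ValueError(
            f"overlapping segments with conflicting states on {chrom!r} near "
            f"{starts[1:][i]}: {states[:-1][i]!r} vs {states[1:][i]!r}"
        )


def write_segmentation(track: StateTrack, path) -> None:
    """Write a track as a dense-segmentation BED, merging equal-state runs."""
    rows = []
    for chrom in track.grid.chroms:
        off = track.grid.offsets[chrom]
        n = track.grid.n_bins(chrom)
        size = track.grid.chrom_sizes[chrom]
        bs = track.grid.bin_size
        chunk = track.codes[off : off + n]
        change = np.flatnonzero(np.diff(chunk)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [n]])
        for s, e in zip(starts, ends):
            rows.append((chrom, s * bs, min(e * bs, size), track.alphabet[chunk[s]]))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


PEAK_COLUMNS = ["chrom", "start", "end", "name", "summit", "log2fc", "fdr"]


def read_peaks(path) -> pd.DataFrame:
    """Read a peak table (BED-like TSV with header).

    Expected columns: chrom, start, end, name, summit, log2fc, fdr, plus
    boolean ``called_<condition>_rep<i>`` flags and optionally ``klass``.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("start", "end", "summit"):
        df[col] = df[col].astype(np.int64)
    for col in df.columns:
        if col.startswith("called_"):
            df[col] = df[col].astype(bool)
    return df


def write_peaks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    """Read a gene table: gene_id, chrom, tss, strand, tpm_<cond>...,
    de_<contrast>..., is_tf."""
    df = pd.read_csv(path, sep="\t")
    df["tss"] = df["tss"].astype(np.int64)
    if "is_tf" in df:
        df["is_tf"] = df["is_tf"].astype(bool)
    return df


def write_genes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a labelled matrix TSV (first column is the row index)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_footprints(path) -> pd.DataFrame:
    """Footprint intervals: chrom, start, end, motif_id, tf_id."""
    df = pd.read_csv(path, sep="\t")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
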