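"""Rule-based TF->TF network assembly and RARA-binding classification.

Starting from a differential regulatory-network edge table (source TF,
target TF, differential score in [0, 1]), an edge survives iff

1. differential score > 0.7,
2. both TFs have mean TPM > 5 in the target condition (PE),
3. both TFs meet >= 1 of three activity criteria (integrated activity call,
   FP enrichment in >= 1 Gain-peak class at p < 0.001, or top-30 influence
   rank),
4. the source TF has a footprint inside a Gain peak lying < 50 kb from the
   target TF's TSS.

Edges whose closest mediating peak lies < 25 kb are additionally flagged
for display. RARA binding sites are classified Enriched / Equal / Depleted
from the log2 ratio of normalized PE over AFE counts (inclusive +/-1
bounds), and network TFs are stratified into RARA direct targets,
RA-responsive and RA-non-responsive nodes.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .genes import interval_point_gap

RA_CATEGORIES = ("RARA_direct_target", "RA_responsive", "RA_non_responsive")


def classify_rara_peaks(
    norm_counts: pd.DataFrame, pseudocount: float = 1.0
) -> pd.Series:
    """Enriched / Equal / Depleted per peak from (afe, pe) normalized counts.

    Input-subtracted counts are floored at zero and a pseudocount added
    before the log ratio; thresholds are inclusive: log2FC >= 1 Enriched,
    <= -1 Depleted, otherwise Equal.
    """
    afe = np.maximum(norm_counts["afe"].to_numpy(dtype=float), 0.0)
    pe = np.maximum(norm_counts["pe"].to_numpy(dtype=float), 0.0)
    lfc = np.log2((pe + pseudocount) / (afe + pseudocount))
    out = np.full(len(lfc), "Equal", dtype=object)
    out[lfc >= 1] = "Enriched"
    out[lfc <= -1] = "Depleted"
    return pd.Series(out, index=norm_counts.index, name="category")


def nearest_gene_per_peak(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Nearest protein-coding gene of each peak (no distance cap).

    Ties broken by smallest gene id; peaks on chromosomes without genes
    yield NA (skipped with a warning upstream).
    """
    out = pd.Series([None] * len(peaks), index=peaks.index, dtype=object)
    for chrom, sub in peaks.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        tss = g["tss"].to_numpy()
        gids = g["gene_id"].to_numpy()
        for i in sub.index:
            d = interval_point_gap(sub.at[i, "start"], sub.at[i, "end"], tss)
            best = np.lexsort((gids, d))[0]
            out.at[i] = gids[best]
    return out


def identify_direct_targets(
    pe_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    de_contrast: str = "de_DE_vs_PE",
) -> set[str]:
    """TFs that are the nearest protein-coding gene of a PE-called peak and
    upregulated in the PE-vs-earlier contrast."""
    nearest = nearest_gene_per_peak(pe_peaks, genes)
    info = genes.set_index("gene_id")
    targets = set()
    for gid in nearest.dropna().unique():
        if bool(info.at[gid, "is_tf"]) and info.at[gid, de_contrast] == "up":
            targets.add(gid)
    return targets


def mediating_distances(
    footprints: pd.DataFrame,
    gain_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    source_tfs,
    target_tfs,
) -> pd.DataFrame:
    """Minimum Gain-peak-to-target-TSS gap per (source TF, target TF).

    A peak mediates an edge when a footprint of the source TF's motif lies
    inside it (summit-to-summit containment is not required: any overlap of
    the footprint interval with the peak interval counts); the distance is
    the gap between the peak interval and the target TSS.
    """
    source_tfs = set(source_tfs)
    target_tfs = set(target_tfs)
    rows = []
    fp = footprints[footprints["tf_id"].isin(source_tfs)]
    tgt = genes[genes["gene_id"].isin(target_tfs)]
    for chrom, peaks_c in gain_peaks.groupby("chrom", sort=False):
        fp_c = fp[fp["chrom"] == chrom]
        tgt_c = tgt[tgt["chrom"] == chrom]
        if fp_c.empty or tgt_c.empty:
            continue
        ps = peaks_c["start"].to_numpy()
        pe_ = peaks_c["end"].to_numpy()
        for _, f in fp_c.iterrows():
            inside = (f["start"] < pe_) & (f["end"] > ps)
            for s, e in zip(ps[inside], pe_[inside]):
                d = interval_point_gap(s, e, tgt_c["tss"].to_numpy())
                for gid, dist in zip(tgt_c["gene_id"], d):
                    rows.append((f["tf_id"], gid, int(dist)))
    if not rows:
        return pd.DataFrame(columns=["source_tf", "target_tf", "distance"])
    df = pd.DataFrame(rows, columns=["source_tf", "target_tf", "distance"])
    return df.groupby(["source_tf", "target_tf"], as_index=False)["distance"].min()


def build_network(
    edges: pd.DataFrame,
    tf_annot: pd.DataFrame,
    mediating: pd.DataFrame,
    score_min: float = 0.7,
    tpm_min: float = 5.0,
    top_k: int = 30,
    dist_network: int = 50_000,
    dist_display: int = 25_000,
) -> pd.DataFrame:
    """Apply the edge filter chain; returns kept edges with a display flag.

    Parameters
    ----------
    edges
        Columns source_tf, target_tf, diff_score.
    tf_annot
        Indexed by TF id with columns tpm_pe, active_integrated (bool),
        fp_gain_enriched (bool), influence_rank (1 = most influential).
    mediating
        Output of :func:`mediating_distances` (minimum mediating Gain-peak
        distance per directed pair); pairs absent have no mediating peak.
    """
    tfs = set(edges["source_tf"]) | set(edges["target_tf"])
    missing = tfs - set(tf_annot.index)
    if missing:
        raise ValueError(f"edge TFs without annotation: {sorted(missing)[:5]}")

    qual = (
        (tf_annot["tpm_pe"] > tpm_min)
        & (
            tf_annot["active_integrated"].astype(bool)
            | tf_annot["fp_gain_enriched"].astype(bool)
            | (tf_annot["influence_rank"] <= top_k)
        )
    )
    med = mediating.set_index(["source_tf", "target_tf"])["distance"]
    key = pd.MultiIndex.from_frame(edges[["source_tf", "target_tf"]])
    dist = med.reindex(key).to_numpy(dtype=float)  # NaN = no mediating peak

    keep = (
        (edges["diff_score"].to_numpy() > score_min)
        & qual.reindex(edges["source_tf"]).to_numpy()
        & qual.reindex(edges["target_tf"]).to_numpy()
        & (dist < dist_network)
    )
    out = edges.loc[keep].copy()
    out["distance"] = dist[keep].astype(np.int64)
    out["display"] = out["distance"] < dist_display
    return out.reset_index(drop=True)


def categorize_ra_response(
    network_tfs,
    direct_targets: set[str],
    de_expanded: dict[str, str],
    forced: dict[str, str] | None = None,
) -> dict[str, str]:
    """RA-response category per network TF.

    Direct targets that are upregulated in the expanded AFE-vs-PE contrast
    are RARA direct targets; other upregulated TFs are RA-responsive; the
    rest RA-non-responsive. ``forced`` entries (e.g. externally validated
    targets absent from the network) are added with their given category.
    """
    out = {}
    for tf in network_tfs:
        up = de_expanded.get(tf) == "up"
        if tf in direct_targets and up:
            out[tf] = "RARA_direct_target"
        elif up:
            out[tf] = "RA_responsive"
        else:
            out[tf] = "RA_non_responsive"
    for tf, cat in (forced or {}).items():
        if cat not in RA_CATEGORIES:
            raise ValueError(f"unknown RA category {cat!r} for forced node {tf!r}")
        out[tf] = cat
    return out


def to_graph(kept_edges: pd.DataFrame, categories: dict[str, str] | None = None,
             node_lfc: dict[str, float] | None = None) -> nx.DiGraph:
    """networkx DiGraph with node/edge attributes, ready for GraphML export."""
    g = nx.DiGraph()
    for _, row in kept_edges.iterrows():
        g.add_edge(
            row["source_tf"],
            row["target_tf"],
            diff_score=float(row["diff_score"]),
            distance=int(row["distance"]),
            display=bool(row["display"]),
        )
    for node in g.nodes:
        if categories:
            g.nodes[node]["ra_category"] = categories.get(node, "RA_non_responsive")
        if node_lfc and node in node_lfc:
            g.nodes[node]["log2fc"] = float(node_lfc[node])
    return g
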