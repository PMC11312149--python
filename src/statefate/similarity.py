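"""Marker-panel similarity between bulk samples and reference cell clusters.

Each reference cluster carries an ordered panel of top TF marker genes; a
bulk sample's similarity to the cluster is the Spearman correlation between
log10 reference CPM and log10 query TPM over the panel's mapped markers
(rank-based, so the log and its pseudocount do not affect the value; they
are kept for exported log profiles). A coarser concordance measure simply
counts panel markers adequately expressed (TPM > 5) in the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


@dataclass
class MarkerPanel:
    """Top-marker panels per reference cluster with an ortholog map."""

    markers: dict[str, list[str]]  # cluster -> ordered reference gene ids
    ortholog_map: dict[str, str]  # reference gene id -> query gene id
    n_unmapped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cluster, panel in self.markers.items():
            if len(set(panel)) != len(panel):
                raise ValueError(f"duplicate markers in cluster {cluster!r}")

    def mapped(self, cluster: str) -> list[tuple[str, str]]:
        """(reference id, query id) pairs for a cluster's mappable markers;
        unmapped markers are dropped and counted."""
        pairs = [(m, self.ortholog_map[m]) for m in self.markers[cluster] if m in self.ortholog_map]
        self.n_unmapped[cluster] = len(self.markers[cluster]) - len(pairs)
        return pairs


def cluster_correlation(
    ref_profile: pd.DataFrame,
    query_profile: pd.DataFrame,
    panel: MarkerPanel,
    min_markers: int = 3,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """sample x cluster Spearman rho over each cluster's mapped markers.

    ``ref_profile`` is cluster x gene (CPM), ``query_profile`` sample x gene
    (TPM). Clusters with fewer than ``min_markers`` mapped markers present
    in both profiles yield NaN.
    """
    if not panel.markers:
        raise ValueError("empty marker panel")
    out = pd.DataFrame(
        index=query_profile.index, columns=list(panel.markers), dtype=float
    )
    for cluster in panel.markers:
        pairs = [
            (r, q)
            for r, q in panel.mapped(cluster)
            if r in ref_profile.columns and q in query_profile.columns
        ]
        if len(pairs) < min_markers or cluster not in ref_profile.index:
            out[cluster] = np.nan
            continue
        ref_ids = [r for r, _ in pairs]
        query_ids = [q for _, q in pairs]
        ref_vals = np.log10(ref_profile.loc[cluster, ref_ids].to_numpy(dtype=float) + pseudo)
        for sample in query_profile.index:
            q_vals = np.log10(query_profile.loc[sample, query_ids].to_numpy(dtype=float) + pseudo)
            out.at[sample, cluster] = spearmanr(ref_vals, q_vals).statistic
    return out


def marker_concordance(
    panel: MarkerPanel, query_tpm: pd.Series, threshold: float = 5.0
) -> pd.DataFrame:
    """Per-cluster count (and fraction) of markers with query TPM strictly
    above ``threshold``; unmapped or absent markers count as not expressed."""
    rows = []
    for cluster in panel.markers:
        pairs = panel.mapped(cluster)
        n = sum(
            1
            for _, q in pairs
            if q in query_tpm.index and query_tpm[q] > threshold
        )
        total = len(panel.markers[cluster])
        rows.append({"cluster": cluster, "n_expressed": n, "fraction": n / total if total else 0.0})
    return pd.DataFrame(rows).set_index("cluster")
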