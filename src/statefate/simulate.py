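"""Synthetic inputs with planted signal for every pipeline stage.

The generator emulates the statistical structure the downstream analyses
assume, without any sequencing data:

* paired per-bin chromatin-state calls drawn i.i.d. from a configurable
  joint distribution, with chosen ordered pairs planted at a target fold
  enrichment (the joint is solved by fixed-point iteration so the analytic
  fold enrichment of the planted pair equals the target);
* gene TSSs placed uniformly, log-normal TPMs, and differential-expression
  labels spatially associated with chosen transitions: a gene claimed as
  nearest expressed gene by a bin of a planted transition draws its label
  from that transition's (p_up, p_down) law, all others from the background
  law;
* peak summits dropped per bin with transition-dependent Gain/Lose
  probabilities, either labelled directly or emitted as (log2FC, FDR,
  replicate-call) statistics that reproduce the intended class through the
  classification rule;
* motif/footprint/expression matrices with coherent planted-active TFs and
  single-filter decoy TFs (one per filter, cycling), giving per-filter
  negative controls;
* a candidate TF->TF edge table in which true edges satisfy the whole
  filter chain (mediating Gain peak with a source footprint within 50 kb of
  the target TSS, half within 25 kb) and each false edge violates exactly
  one predicate, plus RARA peaks placed so designated TFs are their nearest
  genes.

Bins are sampled i.i.d. (no spatial autocorrelation): every downstream
statistic is bin-exchangeable, so i.i.d. sampling suffices for calibration.
All randomness flows through ``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genes import assign_nearest_genes
from .grid import DEFAULT_STATES, GenomeGrid, StateTrack
from .association import transition_codes

Pair = tuple[str, str]

#: Background state occupancy shared by both conditions (quiescent-dominated,
#: promoter/enhancer states each a few percent, as in real segmentations).
DEFAULT_MARGINAL: dict[str, float] = {
    "TssA": 0.02, "Tss": 0.02, "TssFlnk": 0.02, "TssBiv": 0.02,
    "ReprPC": 0.05, "EnhA": 0.05, "EnhPr": 0.04, "EnhBiv": 0.02,
    "Quies": 0.76,
}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic genome. Defaults: 2 x 10 Mb
    chromosomes at 200 bp (100 000 bins), 9 states, one transition
    (ReprPC -> EnhA) planted at fold enrichment 4 with a 6-fold
    up-label odds boost and a 25-fold Gain-peak boost."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    bin_size: int = 200
    states: tuple[str, ...] = DEFAULT_STATES
    marginal: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARGINAL))
    planted_fe: dict[Pair, float] = field(
        default_factory=lambda: {("ReprPC", "EnhA"): 4.0}
    )
    conditions: tuple[str, str] = ("DE", "PE")

    gene_count: int = 3000
    tpm_log_mean: float = 1.5  # natural-log scale of the log-normal TPM law
    tpm_log_sd: float = 1.5  # => ~84% of genes exceed 1 TPM
    de_background: tuple[float, float] = (0.1, 0.1)  # (p_up, p_down)
    de_association: dict[Pair, tuple[float, float]] = field(
        default_factory=lambda: {("ReprPC", "EnhA"): (0.6, 0.05)}
    )
    nearest_max_dist: int = 50_000
    nearest_min_tpm: float = 1.0

    # background (p_gain, p_lose) per bin; asymmetric, as genome-wide Gain
    # and Lose rates always differ in practice (exact equality makes the
    # control term of RATIO_UPDOWN degenerate)
    peak_background: tuple[float, float] = (0.02, 0.01)
    peak_association: dict[Pair, tuple[float, float]] = field(
        default_factory=lambda: {("ReprPC", "EnhA"): (0.5, 0.02)}
    )
    n_common_peaks: int = 4000
    peak_mode: str = "stats"  # or "labels"

    tf_conditions: tuple[str, ...] = ("DE", "AFE", "PE")
    n_coherent_tfs: int = 6
    n_decoy_tfs: int = 12  # cycles through the six single-filter decoy types

    n_true_edges: int = 6
    n_false_edges: int = 5
    n_direct_targets: int = 2

    @property
    def grid(self) -> GenomeGrid:
        return GenomeGrid(chrom_sizes=dict(self.chrom_sizes), bin_size=self.bin_size)

    def null(self) -> "SimulationConfig":
        """Copy with all association laws set to the background (no planted
        expression/accessibility signal; state joint unchanged)."""
        return dataclasses.replace(self, de_association={}, peak_association={})


def _pair_index(states: tuple[str, ...], pair: Pair) -> tuple[int, int]:
    return states.index(pair[0]), states.index(pair[1])


def build_joint(cfg: SimulationConfig, n_iter: int = 40) -> np.ndarray:
    """Joint (state-in-A, state-in-B) distribution with planted pairs tuned
    so the *analytic* fold enrichment equals the target exactly (fixed
    point over the perturbed marginals)."""
    p = np.array([cfg.marginal[s] for s in cfg.states], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("state marginal must sum to 1")
    if (p <= 0).any():
        raise ValueError("degenerate alphabet: zero-probability state")
    w = np.outer(p, p)
    for _ in range(n_iter):
        for pair, target in cfg.planted_fe.items():
            i, j = _pair_index(cfg.states, pair)
            if i == j:
                raise ValueError("cannot plant fold enrichment on the diagonal")
            pa, pb = w.sum(axis=1), w.sum(axis=0)
            mass = w[i, j] + w[j, i]
            # FE = (w_ij / pa_i pb_j) / (w_ji / pa_j pb_i) = target
            r = target * (pa[i] * pb[j]) / (pa[j] * pb[i])
            w[i, j] = mass * r / (1 + r)
            w[j, i] = mass / (1 + r)
    return w / w.sum()


def analytic_fe(joint: np.ndarray, i: int, j: int) -> float:
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)
    es_ij = joint[i, j] / (pa[i] * pb[j])
    es_ji = joint[j, i] / (pa[j] * pb[i])
    return es_ij / es_ji


def simulate_state_tracks(
    cfg: SimulationConfig, seed: int
) -> tuple[StateTrack, StateTrack, np.ndarray]:
    """Paired tracks with bins drawn i.i.d. from the planted joint.

    Returns (track_A, track_B, truth joint distribution).
    """
    if len(cfg.states) < 2:
        raise ValueError("degenerate alphabet")
    joint = build_joint(cfg)
    grid = cfg.grid
    rng = np.random.default_rng(seed)
    k = len(cfg.states)
    flat = rng.choice(k * k, size=grid.total_bins, p=joint.ravel())
    a, b = np.divmod(flat, k)
    track_a = StateTrack(grid=grid, condition=cfg.conditions[0], alphabet=cfg.states, codes=a)
    track_b = StateTrack(grid=grid, condition=cfg.conditions[1], alphabet=cfg.states, codes=b)
    return track_a, track_b, joint


def _draw_labels(rng, n: int, p_up: float, p_down: float) -> np.ndarray:
    u = rng.random(n)
    out = np.full(n, "no", dtype=object)
    out[u < p_up] = "up"
    out[(u >= p_up) & (u < p_up + p_down)] = "down"
    return out


def simulate_genes(
    cfg: SimulationConfig,
    track_a: StateTrack,
    track_b: StateTrack,
    seed: int,
) -> pd.DataFrame:
    """Gene table with TSSs, TPMs and planted DE labels.

    Labels are drawn from a planted transition's law for genes claimed as
    nearest expressed gene by that transition's bins, and from the
    background law otherwise; with no planted transitions every gene uses
    the background law (proper null).
    """
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    n = cfg.gene_count
    if n == 0:
        return pd.DataFrame(
            columns=["gene_id", "chrom", "tss", "strand", "is_tf"]
            + [f"tpm_{c}" for c in cfg.conditions]
        )
    sizes = np.array(list(grid.chrom_sizes.values()), dtype=float)
    chrom_idx = rng.choice(len(sizes), size=n, p=sizes / sizes.sum())
    chroms = np.array(list(grid.chrom_sizes), dtype=object)[chrom_idx]
    tss = rng.integers(0, sizes[chrom_idx].astype(np.int64))
    base = rng.lognormal(cfg.tpm_log_mean, cfg.tpm_log_sd, size=n)
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n)],
            "chrom": chroms,
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=n),
            "is_tf": False,
        }
    )
    for c in cfg.conditions:
        genes[f"tpm_{c}"] = base * np.exp(rng.normal(0, 0.2, size=n))

    # which genes do planted-transition bins claim as nearest expressed gene?
    nearest = assign_nearest_genes(
        grid, genes, cfg.conditions, cfg.nearest_max_dist, cfg.nearest_min_tpm
    )
    codes = transition_codes(track_a, track_b)
    k = len(cfg.states)
    law = np.tile(np.array(cfg.de_background), (n, 1))
    gid_pos = pd.Series(np.arange(n), index=genes["gene_id"])
    for pair, (p_up, p_down) in cfg.de_association.items():
        i, j = _pair_index(cfg.states, pair)
        in_t = nearest["gene_id"].notna().to_numpy() & (codes == i * k + j)
        claimed = pd.unique(nearest["gene_id"].to_numpy()[in_t])
        law[gid_pos.loc[claimed].to_numpy()] = (p_up, p_down)

    u = rng.random(n)
    labels = np.full(n, "no", dtype=object)
    labels[u < law[:, 0]] = "up"
    labels[(u >= law[:, 0]) & (u < law[:, 0] + law[:, 1])] = "down"
    genes[f"de_{cfg.conditions[0]}_vs_{cfg.conditions[1]}"] = labels
    return genes


def simulate_peaks(
    cfg: SimulationConfig,
    track_a: StateTrack,
    track_b: StateTrack,
    seed: int,
) -> pd.DataFrame:
    """Classified peak set with transition-dependent Gain/Lose placement.

    In ``stats`` mode (default) each peak carries (log2FC, FDR, replicate
    call flags) that reproduce its intended class through the
    classification rule; ``labels`` mode sets ``klass`` directly.
    """
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    codes = transition_codes(track_a, track_b)
    k = len(cfg.states)
    p_gain = np.full(k * k, cfg.peak_background[0])
    p_lose = np.full(k * k, cfg.peak_background[1])
    for pair, (pg, pl) in cfg.peak_association.items():
        i, j = _pair_index(cfg.states, pair)
        p_gain[i * k + j] = pg
        p_lose[i * k + j] = pl
    u = rng.random((codes.size, 2))
    gain_bins = np.flatnonzero(u[:, 0] < p_gain[codes])
    lose_bins = np.flatnonzero((u[:, 1] < p_lose[codes]) & (u[:, 0] >= p_gain[codes]))
    common_bins = rng.choice(
        np.setdiff1d(np.arange(codes.size), np.concatenate([gain_bins, lose_bins])),
        size=min(cfg.n_common_peaks, codes.size),
        replace=False,
    )

    cond_a, cond_b = cfg.conditions
    chrom_of = np.empty(grid.total_bins, dtype=object)
    local_start = np.empty(grid.total_bins, dtype=np.int64)
    for chrom in grid.chroms:
        off, nb = grid.offsets[chrom], grid.n_bins(chrom)
        chrom_of[off : off + nb] = chrom
        local_start[off : off + nb] = np.arange(nb) * grid.bin_size

    rows = []
    for klass, bins in (("Gain", gain_bins), ("Lose", lose_bins), ("Common", common_bins)):
        nb = len(bins)
        summits = local_start[bins] + rng.integers(0, grid.bin_size, size=nb)
        for m, (b, s) in enumerate(zip(bins, summits)):
            chrom = chrom_of[b]
            s = int(min(s, grid.chrom_sizes[chrom] - 1))
            if klass == "Gain":
                fdr, lfc = rng.uniform(1e-6, 9e-3), rng.uniform(1.2, 3.0)
                in_a, in_b = bool(rng.random() < 0.3), True
            elif klass == "Lose":
                fdr, lfc = rng.uniform(1e-6, 9e-3), -rng.uniform(1.2, 3.0)
                in_a, in_b = True, bool(rng.random() < 0.3)
            else:
                fdr, lfc = rng.uniform(0.02, 0.9), rng.uniform(-0.8, 0.8)
                in_a = in_b = True
            rows.append(
                (chrom, max(0, s - 100), s + 101, f"peak_{klass}_{m}", s, lfc, fdr,
                 in_a, in_a, in_b, in_b, klass)
            )
    peaks = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "summit", "log2fc", "fdr",
                 f"called_{cond_a}_rep1", f"called_{cond_a}_rep2",
                 f"called_{cond_b}_rep1", f"called_{cond_b}_rep2", "klass"],
    )
    peaks = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if cfg.peak_mode == "stats":
        intended = peaks.pop("klass")
        peaks.attrs["intended_klass"] = intended.tolist()
    return peaks


# --- TF activity inputs -----------------------------------------------------

#: DAR set -> condition map for the three-stage design (each contrast's
#: condition-specific peak class attributed to the stage it marks).
DEFAULT_CONDITION_MAP: dict[str, str] = {
    "Lose_DE_vs_AFE": "DE",
    "Lose_DE_vs_PE": "DE",
    "Gain_DE_vs_AFE": "AFE",
    "Lose_AFE_vs_PE": "AFE",
    "Gain_DE_vs_PE": "PE",
    "Gain_AFE_vs_PE": "PE",
}

DECOY_TYPES = ("low_z", "weak_fp", "low_tpm", "not_de", "anti_expr", "anti_fp")


def simulate_tf_inputs(cfg: SimulationConfig, seed: int):
    """Motif/footprint/expression inputs with planted-active and decoy TFs.

    Coherent TFs get condition-aligned motif-Z, footprint and expression
    profiles clearing every filter; each decoy violates exactly one filter
    (cycling through the six types). Returns
    (:class:`~statefate.tf_activity.MotifActivityInput`, truth set of
    (motif, tf) pairs, decoy-type map).
    """
    from .tf_activity import MotifActivityInput

    rng = np.random.default_rng(seed)
    conds = list(cfg.tf_conditions)
    cmap = {
        s: c
        for s, c in DEFAULT_CONDITION_MAP.items()
        if c in conds
    }
    sets_of = {c: [s for s, cc in cmap.items() if cc == c] for c in conds}

    motifs, tf_ids, truth, decoy_kind = [], [], set(), {}
    z_rows, tpm_rows, fp_rows, de_any = [], [], [], {}

    def profile(active: int, hi: float, lo: float) -> np.ndarray:
        out = np.full(len(conds), lo, dtype=float)
        out[active] = hi
        return out

    for i in range(cfg.n_coherent_tfs):
        motif, tf = f"M_COH{i}", f"TF_COH{i}"
        active = i % len(conds)
        motifs.append(motif)
        tf_ids.append(tf)
        truth.add((motif, tf))
        z_rows.append(profile(active, 3.0, -1.5) + rng.normal(0, 0.05, len(conds)))
        tpm_rows.append(profile(active, 50.0, 2.0) * np.exp(rng.normal(0, 0.05, len(conds))))
        de_any[tf] = True
        for c in conds:
            for s in sets_of[c]:
                fp_rows.append((motif, s, 1e-5 if c == conds[active] else 0.3))

    for i in range(cfg.n_decoy_tfs):
        kind = DECOY_TYPES[i % len(DECOY_TYPES)]
        motif, tf = f"M_DEC{i}_{kind}", f"TF_DEC{i}"
        active = i % len(conds)
        motifs.append(motif)
        tf_ids.append(tf)
        decoy_kind[(motif, tf)] = kind
        z = profile(active, 3.0, -1.5)
        tpm = profile(active, 50.0, 2.0)
        fp_active, fp_p = conds[active], 1e-5
        de = True
        if kind == "low_z":
            z = z * (1.4 / 3.0)  # max |Z| = 1.4 < 2
        elif kind == "weak_fp":
            fp_p = 0.01  # never below 1e-3, profile still correlated
        elif kind == "low_tpm":
            tpm = profile(active, 4.0, 0.3)
        elif kind == "not_de":
            de = False
        elif kind == "anti_expr":
            tpm = profile(active, 2.0, 50.0)  # reversed: r(z, expr) < 0
        elif kind == "anti_fp":
            fp_active = conds[(active + 1) % len(conds)]  # enrichment elsewhere
        z_rows.append(z + rng.normal(0, 0.05, len(conds)))
        tpm_rows.append(tpm * np.exp(rng.normal(0, 0.05, len(conds))))
        de_any[tf] = de
        for c in conds:
            for s in sets_of[c]:
                if kind == "anti_fp":
                    p = fp_p if c != conds[active] else 0.3
                else:
                    p = fp_p if c == fp_active else 0.3
                fp_rows.append((motif, s, p))

    inp = MotifActivityInput(
        motif_z=pd.DataFrame(z_rows, index=motifs, columns=conds),
        fp_padj=pd.DataFrame(fp_rows, columns=["motif", "dar_set", "padj"]),
        condition_map=cmap,
        tpm=pd.DataFrame(tpm_rows, index=tf_ids, columns=conds),
        motif_tf={m: (t,) for m, t in zip(motifs, tf_ids)},
        de_any=de_any,
    )
    return inp, truth, decoy_kind


# --- network inputs ---------------------------------------------------------

def simulate_network_inputs(
    cfg: SimulationConfig,
    genes: pd.DataFrame,
    seed: int,
):
    """Candidate edges, TF annotations, footprints, mediating Gain peaks and
    RARA peaks, with a known truth network.

    True edges pass the whole filter chain (score > 0.7, both TFs
    qualifying, mediating Gain peak with a source footprint < 50 kb from
    the target TSS, half < 25 kb); each false edge violates exactly one
    predicate. Designated direct-target TFs get a RARA peak whose nearest
    gene they are, and are marked upregulated.

    Returns a dict with keys edges, tf_annot, footprints, gain_peaks,
    rara_peaks, genes (annotated copy), truth_edges, direct_targets.
    """
    rng = np.random.default_rng(seed)
    genes = genes.copy()
    n_tfs = 2 * cfg.n_true_edges + 2 * cfg.n_false_edges + cfg.n_direct_targets + 2
    if len(genes) < n_tfs:
        raise ValueError("genome too small: not enough genes to host TFs")
    # spread TF genes out so mediating peaks don't collide
    tf_rows = genes.sort_values(["chrom", "tss"]).index[:: max(1, len(genes) // n_tfs)][:n_tfs]
    tf_ids = genes.loc[tf_rows, "gene_id"].tolist()
    genes.loc[tf_rows, "is_tf"] = True
    de_col = f"de_{cfg.conditions[0]}_vs_{cfg.conditions[1]}"
    info = genes.set_index("gene_id")

    annot = pd.DataFrame(
        {
            "tpm_pe": 20.0,
            "active_integrated": False,
            "fp_gain_enriched": False,
            "influence_rank": np.arange(1, n_tfs + 1),
        },
        index=pd.Index(tf_ids, name="tf"),
    )
    # qualify most TFs via one criterion each, cycling
    for i, tf in enumerate(tf_ids):
        annot.loc[tf, ["active_integrated", "fp_gain_enriched"][i % 2]] = True

    edges, fp_rows, peak_rows, truth = [], [], [], []
    grid = cfg.grid
    pool = list(tf_ids)

    def add_mediating(source: str, target: str, dist: int) -> None:
        # gap between the peak interval and the target TSS is exactly `dist`
        chrom = info.at[target, "chrom"]
        tss = int(info.at[target, "tss"])
        if tss + dist + 201 < grid.chrom_sizes[chrom]:
            start = tss + dist
        else:
            start = tss - dist - 200
        start = max(0, start)
        end = start + 201
        peak_rows.append((chrom, start, end, f"gain_{source}_{target}", (start + end) // 2))
        fp_rows.append((chrom, start + 50, start + 70, f"motif_{source}", source))

    for e in range(cfg.n_true_edges):
        s, t = pool[2 * e], pool[2 * e + 1]
        dist = int(rng.integers(2_000, 24_000)) if e % 2 == 0 else int(rng.integers(26_000, 49_000))
        add_mediating(s, t, dist)
        edges.append((s, t, float(rng.uniform(0.75, 0.95))))
        truth.append((s, t))

    falsifiers = ["low_score", "low_tpm", "no_criteria", "far_peak", "no_peak"]
    offset = 2 * cfg.n_true_edges
    for e in range(cfg.n_false_edges):
        kind = falsifiers[e % len(falsifiers)]
        # disjoint TF pairs so each false edge violates exactly one predicate
        s, t = pool[offset + 2 * e], pool[offset + 2 * e + 1]
        score = float(rng.uniform(0.75, 0.95))
        if kind == "low_score":
            score = 0.5
            add_mediating(s, t, 10_000)
        elif kind == "low_tpm":
            annot.loc[s, "tpm_pe"] = 3.0
            add_mediating(s, t, 10_000)
        elif kind == "no_criteria":
            annot.loc[s, ["active_integrated", "fp_gain_enriched"]] = False
            annot.loc[s, "influence_rank"] = 100
            add_mediating(s, t, 10_000)
        elif kind == "far_peak":
            add_mediating(s, t, int(rng.integers(60_000, 80_000)))
        # "no_peak": no mediating peak at all
        edges.append((s, t, score))

    # RARA direct targets: TFs from the pool tail whose TSS is isolated, so
    # a peak hugging the TSS has them as unambiguous nearest gene
    direct = []
    candidates = iter(pool[::-1])
    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")}
    for _ in range(cfg.n_direct_targets):
        for tf in candidates:
            chrom, tss = info.at[tf, "chrom"], int(info.at[tf, "tss"])
            gaps = np.sort(np.abs(tss_by_chrom[chrom] - tss))
            if len(gaps) < 2 or gaps[1] > 500:
                break
        else:
            raise ValueError("could not place an isolated RARA direct target")
        chrom, tss = info.at[tf, "chrom"], int(info.at[tf, "tss"])
        peak = (chrom, max(0, tss - 10), tss + 11, f"rara_{tf}", tss)
        genes.loc[genes["gene_id"] == tf, de_col] = "up"
        direct.append((tf, peak))

    rara = pd.DataFrame(
        [p for _, p in direct],
        columns=["chrom", "start", "end", "name", "summit"],
    )
    rara["afe"] = rng.uniform(1, 5, len(rara))
    rara["pe"] = rara["afe"] * rng.uniform(4, 8, len(rara))  # Enriched in PE

    return {
        "edges": pd.DataFrame(edges, columns=["source_tf", "target_tf", "diff_score"]),
        "tf_annot": annot,
        "footprints": pd.DataFrame(
            fp_rows, columns=["chrom", "start", "end", "motif_id", "tf_id"]
        ),
        "gain_peaks": pd.DataFrame(
            peak_rows, columns=["chrom", "start", "end", "name", "summit"]
        ),
        "rara_peaks": rara,
        "genes": genes,
        "truth_edges": truth,
        "direct_targets": [tf for tf, _ in direct],
    }


# --- marker-similarity fixture ---------------------------------------------

def simulate_marker_inputs(cfg: SimulationConfig, seed: int):
    """Small reference-cluster / bulk-sample marker fixture.

    Three reference clusters with 10-marker panels; each bulk sample's
    query profile tracks one cluster's reference profile (rank-preserving
    noise), so the similarity matrix has a strong diagonal.

    Returns (ref_profile, query_profile, markers dict, ortholog map).
    """
    rng = np.random.default_rng(seed)
    clusters = [f"cluster_{i}" for i in range(3)]
    samples = list(cfg.tf_conditions)
    markers = {
        c: [f"mm_{c}_{j}" for j in range(10)] for c in clusters
    }
    ortholog = {m: m.replace("mm_", "hs_").upper() for panel in markers.values() for m in panel}
    all_ref = [m for panel in markers.values() for m in panel]
    ref = pd.DataFrame(
        rng.lognormal(2, 1, size=(len(clusters), len(all_ref))),
        index=clusters,
        columns=all_ref,
    )
    # own-cluster markers strongly expressed in the reference
    for c in clusters:
        ref.loc[c, markers[c]] = rng.lognormal(5, 0.5, size=10)
    query = pd.DataFrame(
        index=samples, columns=[ortholog[m] for m in all_ref], dtype=float
    )
    for i, s in enumerate(samples):
        matched = clusters[i % len(clusters)]
        base = ref.loc[matched, all_ref].to_numpy()
        # monotone distortion + mild noise keeps ranks aligned with `matched`
        query.loc[s] = (base ** 0.8) * np.exp(rng.normal(0, 0.1, len(all_ref)))
    return ref, query, markers, ortholog


# --- bundle writer ----------------------------------------------------------

def write_bundle(cfg: SimulationConfig, outdir, seed: int) -> dict:
    """Generate every pipeline input with planted truth and write it as a
    plain-text bundle (segmentation BEDs, peak/gene TSVs, motif matrices,
    edge tables, marker fixture, truth.json). Returns the truth manifest."""
    from . import io as sfio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(0, 2**31 - 1)) for k in
             ("tracks", "genes", "peaks", "tf", "network", "markers")}

    track_a, track_b, joint = simulate_state_tracks(cfg, seeds["tracks"])
    genes = simulate_genes(cfg, track_a, track_b, seeds["genes"])
    peaks = simulate_peaks(cfg, track_a, track_b, seeds["peaks"])
    tf_inp, tf_truth, decoys = simulate_tf_inputs(cfg, seeds["tf"])
    net = simulate_network_inputs(cfg, genes, seeds["network"])
    genes = net["genes"]
    ref, query, markers, ortholog = simulate_marker_inputs(cfg, seeds["markers"])

    cond_a, cond_b = cfg.conditions
    sfio.write_segmentation(track_a, out / f"segmentation_{cond_a}.bed")
    sfio.write_segmentation(track_b, out / f"segmentation_{cond_b}.bed")
    sfio.write_peaks(peaks, out / "peaks.tsv")
    sfio.write_genes(genes, out / "genes.tsv")

    sfio.write_matrix(tf_inp.motif_z, out / "motif_z.tsv")
    tf_inp.fp_padj.to_csv(out / "fp_padj.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(tf_inp.condition_map.items()), columns=["dar_set", "condition"]
    ).to_csv(out / "condition_map.tsv", sep="\t", index=False)
    sfio.write_matrix(tf_inp.tpm, out / "tf_tpm.tsv")
    pd.DataFrame(
        [(m, t) for m, tfs in tf_inp.motif_tf.items() for t in tfs],
        columns=["motif", "tf"],
    ).to_csv(out / "motif_tf.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(tf_inp.de_any.items()), columns=["tf", "de_any"]
    ).to_csv(out / "tf_de_any.tsv", sep="\t", index=False)

    net["edges"].to_csv(out / "edges.tsv", sep="\t", index=False)
    net["tf_annot"].to_csv(out / "tf_annot.tsv", sep="\t")
    net["footprints"].to_csv(out / "footprints.tsv", sep="\t", index=False)
    net["gain_peaks"].to_csv(out / "gain_peaks.tsv", sep="\t", index=False)
    net["rara_peaks"].to_csv(out / "rara_peaks.tsv", sep="\t", index=False)

    sfio.write_matrix(ref, out / "marker_ref_cpm.tsv")
    sfio.write_matrix(query, out / "marker_query_tpm.tsv")
    pd.DataFrame(
        [(c, m) for c, panel in markers.items() for m in panel],
        columns=["cluster", "marker"],
    ).to_csv(out / "marker_panel.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(ortholog.items()), columns=["ref_gene", "query_gene"]
    ).to_csv(out / "ortholog_map.tsv", sep="\t", index=False)

    k = len(cfg.states)
    truth = {
        "seed": seed,
        "stage_seeds": seeds,
        "chrom_sizes": cfg.chrom_sizes,
        "bin_size": cfg.bin_size,
        "states": list(cfg.states),
        "conditions": list(cfg.conditions),
        "joint": np.asarray(joint).reshape(k, k).tolist(),
        "planted_fe": {f"{a}->{b}": v for (a, b), v in cfg.planted_fe.items()},
        "de_association": {f"{a}->{b}": list(v) for (a, b), v in cfg.de_association.items()},
        "peak_association": {f"{a}->{b}": list(v) for (a, b), v in cfg.peak_association.items()},
        "peak_mode": cfg.peak_mode,
        "intended_klass": peaks.attrs.get("intended_klass"),
        "tf_truth": sorted([list(p) for p in tf_truth]),
        "tf_decoys": {f"{m}|{t}": kind for (m, t), kind in decoys.items()},
        "truth_edges": [list(e) for e in net["truth_edges"]],
        "direct_targets": net["direct_targets"],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
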