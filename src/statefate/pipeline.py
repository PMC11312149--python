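"""Configuration-driven orchestration of the full analysis.

A single mapping (typically loaded from YAML) drives every stage; all
printed thresholds are surfaced with their default values and any override
is recorded in the run manifest. Stages run in dependency order:
segmentation -> transition enrichment -> gene/peak associations; peak
classification -> state stratification; TF activity; network assembly;
marker similarity. Results are written as TSV/GraphML under the output
directory together with ``manifest.json`` (package version, seed,
thresholds, input checksums — no timestamps, so reruns are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import io as sfio
from .association import associate_genes, associate_peaks
from .genes import assign_nearest_genes
from .grid import GenomeGrid
from .network import (
    build_network,
    categorize_ra_response,
    classify_rara_peaks,
    identify_direct_targets,
    mediating_distances,
    to_graph,
)
from .peaks import assign_peak_bins, classify_dars, stratify_peaks_by_state
from .similarity import MarkerPanel, cluster_correlation, marker_concordance
from .tf_activity import MotifActivityInput, select_active_motifs
from .transitions import transition_enrichment

log = logging.getLogger("statefate")

#: Every printed threshold, surfaced with its default.
DEFAULT_THRESHOLDS: dict = {
    "dar_fdr_max": 0.01,
    "dar_lfc_min": 1.0,
    "nearest_max_dist": 50_000,
    "nearest_min_tpm": 1.0,
    "ratio_min": 1.2,
    "alpha": 0.05,
    "use_adjusted": True,
    "z_abs": 2.0,
    "fp_alpha": 0.001,
    "tpm_min": 5.0,
    "r_min": 0.5,
    "score_min": 0.7,
    "top_k": 30,
    "dist_network": 50_000,
    "dist_display": 25_000,
    "mask_min_fe": 1.5,
    "mask_min_bins": 200,
    "n_perm": 1000,
    "marker_tpm": 5.0,
}

_NUMERIC = {k for k, v in DEFAULT_THRESHOLDS.items() if isinstance(v, (int, float)) and not isinstance(v, bool)}


def validate_config(config: dict) -> dict:
    """Validate and normalize a run configuration; all problems are
    reported at once, before any computation."""
    errors = []
    cfg = dict(config)
    if "seed" not in cfg:
        errors.append("missing required key 'seed'")
    if "outdir" not in cfg:
        errors.append("missing required key 'outdir'")
    thresholds = dict(DEFAULT_THRESHOLDS)
    for key, val in (cfg.get("thresholds") or {}).items():
        if key not in DEFAULT_THRESHOLDS:
            errors.append(f"unknown threshold {key!r}")
        elif key in _NUMERIC and not isinstance(val, (int, float)) or isinstance(val, bool) and key in _NUMERIC:
            errors.append(f"threshold {key!r} must be numeric, got {type(val).__name__}")
        else:
            thresholds[key] = val
    cfg["thresholds"] = thresholds
    inputs = cfg.get("inputs") or {}
    for name, path in inputs.items():
        if not Path(path).exists():
            errors.append(f"input {name!r}: file not found: {path}")
    conds = cfg.get("conditions", ["DE", "PE"])
    if len(conds) != 2:
        errors.append(f"'conditions' must name exactly two conditions, got {conds}")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute all configured stages; returns {stage: result object}.

    ``config`` keys: seed, outdir, conditions, chrom_sizes, bin_size,
    inputs (paths keyed by role), thresholds (overrides), simulate
    (optional SimulationConfig overrides: generate the input bundle first).
    """
    cfg = validate_config(config)
    th = cfg["thresholds"]
    outdir = sfio.ensure_dir(cfg["outdir"])
    seed = int(cfg["seed"])
    results: dict = {}

    if cfg.get("simulate") is not None:
        from .simulate import SimulationConfig, write_bundle

        sim_over = cfg.get("simulate") or {}
        sim_cfg = SimulationConfig(**sim_over)
        indir = outdir / "inputs"
        log.info("simulating input bundle under %s", indir)
        results["truth"] = write_bundle(sim_cfg, indir, seed)
        inputs = _bundle_paths(indir, sim_cfg.conditions)
        cfg["inputs"] = {k: str(v) for k, v in inputs.items()}
        cfg["chrom_sizes"] = dict(sim_cfg.chrom_sizes)
        cfg["bin_size"] = sim_cfg.bin_size
        cfg["conditions"] = list(sim_cfg.conditions)

    inputs = cfg.get("inputs", {})
    cond_a, cond_b = cfg.get("conditions", ["DE", "PE"])
    grid = GenomeGrid(chrom_sizes=dict(cfg["chrom_sizes"]), bin_size=int(cfg.get("bin_size", 200)))

    # --- transitions + associations ---------------------------------------
    if "segmentation_a" in inputs and "segmentation_b" in inputs:
        log.info("reading segmentations")
        track_a = sfio.read_segmentation(inputs["segmentation_a"], grid, condition=cond_a)
        track_b = sfio.read_segmentation(inputs["segmentation_b"], grid, condition=cond_b)
        log.info("transition enrichment (%d permutations)", th["n_perm"])
        enr = transition_enrichment(
            track_a, track_b, method="permutation", n_perm=int(th["n_perm"]), seed=seed
        )
        tidy = enr.to_frame(min_fe=th["mask_min_fe"], min_bins=int(th["mask_min_bins"]))
        tidy.to_csv(outdir / "transitions.tsv", sep="\t", index=False)
        results["transitions"] = enr

        if "genes" in inputs:
            log.info("transition-expression association")
            genes = sfio.read_genes(inputs["genes"])
            ag = associate_genes(
                track_a, track_b, genes, (cond_a, cond_b),
                max_dist=int(th["nearest_max_dist"]), min_tpm=th["nearest_min_tpm"],
                ratio_min=th["ratio_min"], alpha=th["alpha"],
                use_adjusted=bool(th["use_adjusted"]),
            )
            ag.to_csv(outdir / "association_genes.tsv", sep="\t", index=False)
            results["association_genes"] = ag

        if "peaks" in inputs:
            log.info("peak classification and transition-accessibility association")
            peaks = sfio.read_peaks(inputs["peaks"])
            if "klass" not in peaks:
                peaks["klass"] = classify_dars(
                    peaks, (cond_a, cond_b),
                    fdr_max=th["dar_fdr_max"], lfc_min=th["dar_lfc_min"],
                )
            peaks["bin"] = assign_peak_bins(peaks, grid)
            sfio.write_peaks(peaks, outdir / "peaks_classified.tsv")
            ap = associate_peaks(
                track_a, track_b, peaks,
                ratio_min=th["ratio_min"], alpha=th["alpha"],
                use_adjusted=bool(th["use_adjusted"]),
            )
            ap.to_csv(outdir / "association_peaks.tsv", sep="\t", index=False)
            results["association_peaks"] = ap

            groups, backgrounds = stratify_peaks_by_state(peaks, track_a, track_b)
            strat = pd.DataFrame(
                [
                    (klass, state, len(idx), len(backgrounds.get(state, ())))
                    for (klass, state), idx in sorted(groups.items())
                ],
                columns=["klass", "state", "n_peaks", "n_background"],
            )
            strat.to_csv(outdir / "peak_state_groups.tsv", sep="\t", index=False)
            results["peak_state_groups"] = (groups, backgrounds)

    # --- TF activity -------------------------------------------------------
    tf_keys = {"motif_z", "fp_padj", "condition_map", "tf_tpm", "motif_tf", "tf_de_any"}
    if tf_keys <= set(inputs):
        log.info("integrated TF activity")
        cmap = pd.read_csv(inputs["condition_map"], sep="\t").set_index("dar_set")["condition"].to_dict()
        mt = pd.read_csv(inputs["motif_tf"], sep="\t")
        de = pd.read_csv(inputs["tf_de_any"], sep="\t").set_index("tf")["de_any"].astype(bool).to_dict()
        inp = MotifActivityInput(
            motif_z=sfio.read_matrix(inputs["motif_z"]),
            fp_padj=pd.read_csv(inputs["fp_padj"], sep="\t"),
            condition_map=cmap,
            tpm=sfio.read_matrix(inputs["tf_tpm"]),
            motif_tf={m: tuple(g["tf"]) for m, g in mt.groupby("motif")},
            de_any=de,
        )
        act = select_active_motifs(
            inp, z_abs=th["z_abs"], fp_alpha=th["fp_alpha"],
            tpm_min=th["tpm_min"], r_min=th["r_min"],
        )
        act.to_csv(outdir / "tf_activity.tsv", sep="\t", index=False)
        results["tf_activity"] = act

    # --- network -----------------------------------------------------------
    net_keys = {"edges", "tf_annot", "footprints", "gain_peaks", "genes"}
    if net_keys <= set(inputs):
        log.info("TF network assembly")
        edges = pd.read_csv(inputs["edges"], sep="\t")
        annot = pd.read_csv(inputs["tf_annot"], sep="\t", index_col=0)
        fps = sfio.read_footprints(inputs["footprints"])
        gain = pd.read_csv(inputs["gain_peaks"], sep="\t")
        genes = sfio.read_genes(inputs["genes"])
        med = mediating_distances(
            fps, gain, genes, edges["source_tf"].unique(), edges["target_tf"].unique()
        )
        kept = build_network(
            edges, annot, med,
            score_min=th["score_min"], tpm_min=th["tpm_min"], top_k=int(th["top_k"]),
            dist_network=int(th["dist_network"]), dist_display=int(th["dist_display"]),
        )
        categories = None
        if "rara_peaks" in inputs:
            rara = pd.read_csv(inputs["rara_peaks"], sep="\t")
            rara["category"] = classify_rara_peaks(rara)
            rara.to_csv(outdir / "rara_classified.tsv", sep="\t", index=False)
            direct = identify_direct_targets(
                rara, genes, de_contrast=f"de_{cond_a}_vs_{cond_b}"
            )
            de_map = genes.set_index("gene_id")[f"de_{cond_a}_vs_{cond_b}"].to_dict()
            network_tfs = sorted(set(kept["source_tf"]) | set(kept["target_tf"]))
            categories = categorize_ra_response(
                network_tfs, direct, de_map, forced=cfg.get("forced_nodes")
            )
            results["direct_targets"] = direct
            results["ra_categories"] = categories
        kept.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        graph = to_graph(kept, categories)
        nx.write_graphml(graph, outdir / "network.graphml")
        results["network"] = kept

    # --- marker similarity -------------------------------------------------
    sim_keys = {"marker_ref", "marker_query", "marker_panel", "ortholog_map"}
    if sim_keys <= set(inputs):
        log.info("marker similarity")
        panel_df = pd.read_csv(inputs["marker_panel"], sep="\t")
        orth = pd.read_csv(inputs["ortholog_map"], sep="\t")
        panel = MarkerPanel(
            markers={c: list(g["marker"]) for c, g in panel_df.groupby("cluster", sort=False)},
            ortholog_map=dict(zip(orth["ref_gene"], orth["query_gene"])),
        )
        ref = sfio.read_matrix(inputs["marker_ref"])
        query = sfio.read_matrix(inputs["marker_query"])
        rho = cluster_correlation(ref, query, panel)
        rho.to_csv(outdir / "marker_similarity.tsv", sep="\t")
        conc = marker_concordance(panel, query.iloc[-1], threshold=th["marker_tpm"])
        conc.to_csv(outdir / "marker_concordance.tsv", sep="\t")
        results["marker_similarity"] = rho
        results["marker_concordance"] = conc

    manifest = {
        "statefate_version": __version__,
        "seed": seed,
        "conditions": [cond_a, cond_b],
        "chrom_sizes": dict(cfg["chrom_sizes"]),
        "bin_size": int(cfg.get("bin_size", 200)),
        "thresholds": th,
        "threshold_overrides": {
            k: v for k, v in th.items() if DEFAULT_THRESHOLDS[k] != v
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()
        },
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results


def _bundle_paths(indir: Path, conditions) -> dict:
    cond_a, cond_b = conditions
    return {
        "segmentation_a": indir / f"segmentation_{cond_a}.bed",
        "segmentation_b": indir / f"segmentation_{cond_b}.bed",
        "peaks": indir / "peaks.tsv",
        "genes": indir / "genes.tsv",
        "motif_z": indir / "motif_z.tsv",
        "fp_padj": indir / "fp_padj.tsv",
        "condition_map": indir / "condition_map.tsv",
        "tf_tpm": indir / "tf_tpm.tsv",
        "motif_tf": indir / "motif_tf.tsv",
        "tf_de_any": indir / "tf_de_any.tsv",
        "edges": indir / "edges.tsv",
        "tf_annot": indir / "tf_annot.tsv",
        "footprints": indir / "footprints.tsv",
        "gain_peaks": indir / "gain_peaks.tsv",
        "rara_peaks": indir / "rara_peaks.tsv",
        "marker_ref": indir / "marker_ref_cpm.tsv",
        "marker_query": indir / "marker_query_tpm.tsv",
        "marker_panel": indir / "marker_panel.tsv",
        "ortholog_map": indir / "ortholog_map.tsv",
    }
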