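# statefate

Downstream statistics for comparing the chromatin landscape of two cell
differentiation stages — e.g. definitive endoderm (DE) against pharyngeal
endoderm (PE) derived from it by retinoic-acid exposure. The package takes
the *outputs* of the usual upstream tools (a ChromHMM-style segmentation per
condition, a differential-accessibility peak table, gene TPM/DE tables,
motif-enrichment Z-scores, footprint-enrichment p-values, a differential
regulatory-network edge table) and implements the bespoke statistics layered
on top of them:

* **Transition enrichment.** The genome is split into 200-bp bins, each
  carrying one chromatin state per condition. For an ordered state pair
  (s₁ → s₂) the observed bin count O is compared with the expectation E from
  1000 genome-wide shuffles of the second condition's state calls (closed
  form: E = n_A(s₁)·n_B(s₂)/N). The enrichment score is ES = O/E and the
  directional **fold enrichment** FE(s₁→s₂) = ES(s₁→s₂)/ES(s₂→s₁), which
  cancels out mere co-occurrence of similar states. Display convention:
  cells with FE > 1.5 and ≥ 200 bins are highlighted; sparsely populated
  transitions (< 200 bins) are masked.

* **Transition–expression / transition–accessibility association.** For
  each transition, the bins undergoing it (T group) are compared with all
  other bins (O group) by tallying nearby upregulated/downregulated/stable
  genes (nearest expressed gene: TPM > 1 in either condition, TSS within
  50 kb) or Gain/Lose peak summits. Three two-sided Fisher tests
  (P_UPDOWN, P_UP, P_DOWN, each family BH-adjusted) and three ratio
  statistics (RATIO_UPDOWN, RATIO_UP, RATIO_DOWN) classify a transition as
  up-enriched (RATIO_UPDOWN > 1, RATIO_UP > 1.2, P_UPDOWN < 0.05,
  P_UP < 0.05), down-enriched (mirror rule), or neither.

* **Integrated TF activity.** Per (motif, TF): motif-enrichment Z-scores,
  footprint (FP) enrichment scores (mean −log10 adjusted p over each
  condition's DAR sets, zeros floored at 1e-16) and expression Z-scores of
  log2 TPM. A pair is called active iff max|Z| ≥ 2, some FP adjusted
  p < 0.001, TPM > 5 somewhere, the TF is differentially expressed, and the
  Z profile has Pearson r > 0.5 with both the FP and expression profiles.

* **TF→TF network assembly.** Edges of a differential regulatory network
  survive iff score > 0.7, both TFs are active in the target condition
  (TPM > 5 plus one of three activity criteria), and a Gain peak carrying a
  source-TF footprint lies < 50 kb from the target TSS (< 25 kb for the
  display subset). RARA binding sites are classified
  Enriched/Equal/Depleted by log2 count ratio (inclusive ±1), and network
  TFs stratified into RARA direct targets / RA-responsive /
  RA-non-responsive.

* **Marker similarity.** Spearman correlation between bulk profiles and
  reference single-cell cluster profiles over top-TF marker panels, plus a
  TPM > 5 concordance count.

A **synthetic-data generator** produces every input with known planted
structure (a transition planted at a target fold enrichment, DE labels and
Gain peaks spatially coupled to it, coherent active TFs plus single-filter
decoys, a truth network), so the whole pipeline is testable without any
sequencing data.

## Worked example

```sh
python examples/01_transition_enrichment.py
```

simulates a 100 000-bin genome with ReprPC → EnhA planted at fold
enrichment 4 and prints:

```
top directional transitions (O = observed bins, E = shuffled expectation, ES = O/E, FE = ES forward / ES reverse):
 s_from   s_to   O       E    ES    FE display
 ReprPC   EnhA 401 265.227 1.512 4.157 colored
 TssBiv    Tss  49  39.554 1.239 1.762    grey
```

401 bins switch from Polycomb-repressed to active enhancer, 1.5× the
shuffle expectation and 4.2× the reverse direction — the planted repressed-
to-active switch, and the only transition passing the display mask.
`examples/02_transition_association.py` then recovers the same transition
as `up_enriched` in both genes mode (RATIO_UP 3.3, q ≈ 3e-56) and peaks
mode; `03`–`06` walk through TF activity, network assembly, marker
similarity, and the end-to-end pipeline (`statefate all --seed 7 --outdir
out/` on the command line).

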