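# Methods

## Coordinate model

All coordinates are 0-based, half-open (BED convention). A `GenomeGrid`
partitions each chromosome into consecutive `bin_size`-bp bins (default
200 bp; the trailing bin may be shorter); chromosomes are concatenated in
declaration order to give every bin a global index. The distance between an
interval and a point (TSS, summit) is the gap to the nearest base the
interval covers — 0 on containment, `start − pos` to the left,
`pos − (end − 1)` to the right. This symmetric convention makes distances
independent of which side of the interval the point lies on; the 50-kb
nearest-gene cutoff is applied inclusively (≤ 50 000 bp) since the rule is
stated as "within 50 kb" without strictness.

Rasterizing a segmentation onto the grid: exact-tiling files (the common
case for 200-bp state calls) are assigned directly; otherwise a bin takes
the state covering the majority of it, ties resolved in favour of the
segment appearing earlier in the file (deterministic, and irrelevant for
exactly tiling inputs). Bins covered by no segment default to the
quiescent state, the semantic no-mark default. Overlapping segments with
conflicting states are an input error, not a tie.

Nearest-gene assignment is vectorised: per chromosome, candidate TSSs
(mean TPM > threshold in either compared condition, strict) are sorted;
the minimal gap for each bin is attained by a sorted neighbour of the bin
interval, and the winning gene among all genes attaining that gap is found
by a range-argmin (sparse-table) query on lexicographic gene-id ranks —
so ties always go to the smallest gene id, exactly as the brute-force
oracle in the tests defines it.

## Transition enrichment

Observed counts `O[s₁, s₂]` are per-bin joint state counts. The
permutation null shuffles the second condition's state vector genome-wide
(the first held fixed); which vector is shuffled, and whether shuffling is
restricted per chromosome, does not change the expectation, which equals
the product of marginals `E = n_A(s₁)·n_B(s₂)/N`. Both routes are exposed:
`analytic` as the fast closed form and oracle, `permutation` (default
1000 shuffles, seeded) as the procedure actually defined. Enrichment score
`ES = O/E`; fold enrichment `FE(s₁→s₂) = ES(s₁→s₂)/ES(s₂→s₁)`. FE is
reported missing (NaN) — not 0 or ∞ — when the reverse direction has no
observed bins; on the diagonal FE = 1 wherever defined. The permutation
distribution is not used for a significance test (only its mean enters the
statistic). Display mask: colored iff FE > 1.5 and O ≥ 200, grey iff
O < 200.

## Transition association

For every observed ordered transition (identical-state pairs included) the
T group is its bins and the O group all other bins. Genes mode counts
*unique* genes: a gene nearest to several T bins counts once, and enters
the O group of transition t only if it is also nearest to some bin outside
t (a per-bin multiplicity mode is available for sensitivity analysis).
Peaks mode counts bins carrying a Gain summit (UP), a Lose summit (DOWN),
or neither (NO); a bin with both kinds of summit counts as Gain
(precedence documented and such bins reported). The three Fisher tables
are

    P_UPDOWN: [UP_T, DOWN_T]          vs [UP_O, DOWN_O]
    P_UP:     [UP_T, DOWN_T + NO_T]   vs [UP_O, DOWN_O + NO_O]
    P_DOWN:   [DOWN_T, UP_T + NO_T]   vs [DOWN_O, UP_O + NO_O]

tested two-sided (the ratio conditions impose direction; sidedness is
otherwise the conventional default), with p = 1 by convention for tables
with an all-zero margin. Each family is BH-adjusted separately across all
transitions of a run. The ratio statistics follow the displayed formulas;
a zero denominator (empty group, or UP_O = DOWN_O for RATIO_UPDOWN) makes
that ratio undefined. Classification uses the adjusted p-values by default
(the procedure introduces BH adjustment before stating P < 0.05; a switch
reverts to raw p), with strict inequalities exactly as printed. A
transition with an empty T group or undefined RATIO_UPDOWN is labelled
`undefined`; an undefined directional ratio merely blocks that direction.

## TF activity

Accessibility preparation: per region, log2 of the library-normalised mean
counts minus the row mean across conditions (rows sum to zero). FP
enrichment score: per condition, the mean over its DAR sets of
−log10(max(p, 1e-16)); motifs untested in a set contribute p = 1 (score 0),
keeping means comparable across motifs. The DAR-set → condition map is
config-driven; the default for a three-stage design attributes each
contrast's condition-specific class to the stage it marks (Lose peaks to
the earlier stage, Gain peaks to the later one). Expression Z-scores use
log2 TPM with the population SD (ddof 0) — the conditions are the entire
population of cell types — and constant rows map to zero. No pseudocount
is used in the log because the TPM > 5 filter precedes it; a TF with a
zero TPM in any condition yields an undefined expression correlation and
is therefore never selected. Pearson correlations over as few as three
conditions are accepted as defined; zero-variance profiles give undefined
r, which fails the r > 0.5 filter.

## Network assembly

The four edge predicates (score > 0.7 strict; both TFs TPM > 5 in the
target condition; both TFs meeting ≥ 1 of the three disjunctive activity
criteria; a mediating Gain peak with a source-TF footprint < 50 kb from
the target TSS) commute, so the filter chain is order-independent. A
footprint mediates through a peak when the two intervals overlap; the
edge distance is the minimum peak-to-TSS gap over mediating peaks, and
edges with distance < 25 kb are flagged for display (the 25–50 kb band
stays in the exported network). RARA peak classification uses
input-subtracted counts floored at 0 plus a pseudocount of 1 before the
log ratio — the upstream normalisation does not specify its clipping, and
this choice only affects peaks with |log2FC| ≈ 1 — with inclusive ≥ 1 /
≤ −1 bounds as printed. "Called in PE" means present in the PE peak list
regardless of Enriched/Equal/Depleted category. Direct-target status
requires being the nearest protein-coding gene of such a peak (no distance
cap) plus upregulation; externally validated nodes can be forced in via
configuration rather than code.

## Synthetic data

The generator's defaults are the study conditions of every test: two
10-Mb chromosomes at 200 bp (100 000 bins), nine states with a
quiescent-dominated marginal (76% Quies, promoter/enhancer states 2–5%),
one planted transition ReprPC → EnhA at fold enrichment 4, gene TPMs
log-normal (log-mean 1.5, log-SD 1.5, ≈ 84% of genes above 1 TPM), 3000
genes, background DE law (p_up, p_down) = (0.1, 0.1) with the planted
transition's claimed genes at (0.6, 0.05) — a 6-fold odds boost — and
Gain-summit probability 0.5 on planted bins versus 0.02 background.

Bins are sampled i.i.d. from the joint state distribution; every
downstream statistic is bin-exchangeable, so i.i.d. sampling suffices for
calibration (run-length structure of real segmentations matters only for
IO, which the rasterizer tests cover separately). The joint is solved by
fixed-point iteration so that the *analytic* fold enrichment of each
planted pair equals its target exactly under the perturbed marginals.

DE labels are planted from the analysis's own point of view: a gene
claimed as nearest expressed gene by a planted transition's bins draws its
label from that transition's law, all other genes from the background law.
With no planted law, every gene is background — a proper null under which
the classification's false-positive behaviour is measured. The background
Gain/Lose rates are deliberately unequal (0.02 vs 0.01): with exactly
balanced rates the control term of RATIO_UPDOWN has expectation zero and
the statistic is undefined-in-the-limit, a degenerate configuration real
data never presents.

Peaks are emitted either with class labels or (default) with
(log2FC, FDR, replicate-call) statistics drawn to reproduce the intended
class through the classification rule, exercising the classifier in every
pipeline run. TF inputs comprise coherent TFs (condition-aligned motif-Z,
footprint and expression profiles clearing every filter) and decoys each
violating exactly one filter, cycling through six types — per-filter
negative controls. Network inputs give true edges the full predicate chain
(mediating distances drawn < 25 kb for half, 25–50 kb for the rest) and
false edges exactly one violated predicate over disjoint TF pairs.

What the generator does *not* emulate: spatial autocorrelation of states,
linked peaks/replicate noise structure, sequence content, or realistic
gene clustering. Passing tests therefore demonstrate the statistics'
correctness and calibration under the stated sampling model, not
robustness to structured artefacts in real data.

## Numerical choices

* Fisher exact tests delegate to `scipy.stats.fisher_exact`; the test
  suite verifies it against exhaustive same-margin enumeration (canonical
  two-sided definition: sum of probabilities ≤ the observed table's, with
  the standard 1 + 1e-7 relative tie tolerance) to 1e-12 over all tables
  with N ≤ 50 up to table symmetry.
* BH adjustment delegates to `statsmodels`; verified against the step-up
  closed form.
* Permutations and all simulation draw from `numpy.random.default_rng`
  (PCG64) with explicit seeds; identical seed ⇒ byte-identical outputs,
  which the end-to-end test asserts file by file.
* Problem sizes in the routine test run: 100 000-bin genomes, 1000
  shuffles, 100 planted / 200 null association seeds, 20 TF-activity
  seeds — the full study scale of the synthetic design, chosen so the
  Monte-Carlo bounds (5% relative error where E ≥ 10; ≥ 95% recovery;
  ≤ 3 spurious calls in 95% of null runs) are comfortably powered.

## Known limitations

* The DAR-set → condition attribution for FP score averaging is a
  reconstruction (config-driven); alternative attributions change scores
  but not the machinery.
* Genes mode counts unique genes; the per-bin alternative is exposed but
  not the default.
* Pearson r over three conditions is extremely coarse; it is applied as
  defined rather than replaced with a more powered statistic.
* No multi-condition (> 2) transition chains and no permutation p-values
  for transitions — only the mean of the shuffle distribution enters the
  statistic.
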