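# Methods

## Model and procedure

The pipeline treats each two-class expression dataset as evidence about
which of a fixed collection of pathways is transcriptionally up- or
down-regulated, and compares models only through those pathway-level calls.
The stages are:

1. **Namespace harmonisation.** Probe-level matrices are collapsed to gene
   symbols by keeping, per symbol, the probe with the largest across-sample
   mean (ties broken by lexicographically smallest probe id, so results do
   not depend on row order). Mouse symbols are renamed to human orthologs
   via an explicit two-column table when given; otherwise the uppercase
   heuristic is used (most mouse symbols differ from the human ortholog
   only by case). Many-to-one collisions are re-collapsed by the same
   max-mean rule. Collapse is idempotent and never touches the sample axis.

2. **Ranking.** The signal-to-noise metric
   s = (μ_case − μ_control)/(σ_case + σ_control) with sample (n−1) standard
   deviations, each floored at max(0.2·|class mean|, 0.2). The floor is the
   conventional adjustment that keeps near-constant genes from producing
   huge ratios and guarantees a positive denominator; it requires ≥ 2
   samples per class. Score ties are broken by ascending gene symbol.

3. **Enrichment.** The weighted running-sum statistic with exponent p = 1:
   member genes ("hits") add |r_j|^p/N_R, non-members subtract 1/(N − N_H);
   ES is the extreme with the largest magnitude, with an exact ± tie
   resolving to the positive extreme (arbitrary but fixed). The running sum
   of every proper subset ends exactly at zero, which is asserted on every
   call. If all hit scores are zero (N_R = 0) the hits are weighted
   uniformly 1/N_H — a documented fallback rather than an error, since the
   walk is still well defined. With p = 1 the ES is invariant under
   positive rescaling of all scores.

4. **Null model.** Gene-set permutation: n_perm random same-size gene sets
   drawn uniformly without replacement from the ranked universe. This is a
   deliberate, stated choice — phenotype permutation gives a different null
   (it preserves gene–gene correlation) and is out of scope. NES divides ES
   by the mean magnitude of same-signed null scores; the nominal p is the
   fraction of same-signed null scores at least as extreme, guarded as
   (k+1)/(n+1) so finite permutations never yield p = 0. A set whose null
   sample contains no same-signed score cannot be normalised and is
   degraded to `not_testable` (logged). The FDR q for NES* > 0 is
   [fraction of pooled same-signed null NES ≥ NES*] / [fraction of observed
   same-signed NES ≥ NES*], clipped to [0, 1], mirrored for NES* < 0. The
   null NES pool is one pool per direction across all tested sets
   (per-set-size stratification is a known refinement that is deliberately
   not done); sets excluded by the size filter enter neither the pool nor
   the observed denominator.

5. **Three-state calls.** up: q ≤ 0.25 and NES > 0; down: q ≤ 0.25 and
   NES < 0; null otherwise, including size-excluded and untested pathways.
   NES exactly 0 has no direction and is null. The 0.25 threshold is the
   conventional exploratory GSEA cutoff, boundary inclusive.

6. **Pairwise concordance.** PPV = |Up₁ ∩ Up₂|/|Up₂|, NPV mirrored on down
   calls; the chance baseline for the (1←2) direction is model 1's base
   rate |Up₁|/N (resp. |Down₁|/N), which is exactly the expected predictive
   value when model 2's states are independent of model 1's. The gain over
   chance is reported in percentage points — observed minus expected
   predictive value, averaged over the defined sides — rather than as a
   ratio; this reading of "increase over chance" matches how the difference
   to random overlap is displayed in concordance matrices. A zero
   denominator (no up calls in model 2) leaves that side undefined; it is
   excluded from averages rather than scored 0, to avoid penalising sparse
   profiles, and logged. Per pair both directions are computed; matrices
   report the direction-averaged mean, and both directions are retained in
   the pair table. Profile dependence is tested once per pair (the
   statistic is direction-symmetric) with Pearson chi-squared on the 3×3
   state table, no continuity correction, df = 4; rows/columns with zero
   margins are dropped with df adjusted, and a table that degenerates to a
   single row or column reports statistic 0, p = 1 with a warning (chosen
   over pseudocounts, which would bias small tables). Significance is
   P ≤ 0.05 with no multiple-testing correction across pairs — the
   convention for this descriptive matrix.

7. **Species-group statistics.** Kruskal–Wallis (tie-corrected) over the
   per-pair mean predictive values grouped as human–human, mouse–mouse,
   human–mouse, followed by Dunn's pairwise z-tests on mean ranks with
   tie-corrected variance and Bonferroni ×3 (capped at 1). Counts of
   significant pairs are compared with the two-sample proportions test with
   continuity correction, implemented as the Yates-corrected 2×2
   chi-squared whose correction is capped at |O − E| (identical to R's
   `prop.test`); it is computed both on pair counts per species group and
   on per-dataset significant-partner counts, labelled separately, because
   either reading of "species-related number of significantly correlated
   pairs" is defensible. Pairwise values sharing a dataset are not
   independent; these tests ignore that, which is stated in every run
   summary as a caveat.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| n_perm | 1000 | gene-set permutations per set; 200 suffices for calibration checks |
| weight exponent p | 1.0 | "weighted" running sum; 0 gives the unweighted KS form |
| min_size / max_size | 15 / 500 | detectable-gene bounds; outside → not tested |
| FDR threshold | 0.25 | up/down call boundary, inclusive |
| significance | P ≤ 0.05 | pairwise chi-squared cutoff |
| σ floor | max(0.2·\|μ\|, 0.2) | signal-to-noise denominator floor |

Expression values are used exactly as provided — no normalisation or log
transform is applied, and whether input intensities are log-scale is
recorded in the run summary for provenance only.

## Determinism and seeding

Every random step flows from one master seed. Each dataset receives an
independent substream (seed XOR CRC32 of its id), and each gene set its own
substream (seed + CRC32 of its name), so results are invariant to manifest
and collection order and adding a dataset never perturbs the others.
Identical config and seed give byte-identical output files (floats printed
at repr-level precision).

## Synthetic data: what it does and does not emulate

`simulate_dataset` draws per-gene baselines μ_g ~ Normal(8, 2) on a
log2-like intensity scale, per-gene noise SDs σ_g ~ LogNormal(ln 0.5, 0.3)
(typical microarray replicate variability), and adds ±δ·σ_g to every member
gene of each regulated set in case samples only. Effects are expressed in
per-gene SD units so that recovery thresholds are scale-free; δ = 2 with 10
vs 10 samples is a strong, clearly detectable effect, δ = 0 is an exact
null. A gene belonging to regulated sets of both signs is shifted once per
direction, so the shifts cancel (logged). `simulate_model_pair` gives model
B a designed fraction ρ of model A's regulated sets (same direction) and
draws the remainder from A-unregulated sets; at ρ = 0 the regulated sets
are deliberately disjoint — *below* chance overlap, not independent.

What this does not emulate: probe-level structure (the collapse step is
tested on its own fixtures), gene–gene correlation beyond the planted
shifts, RNA-seq counts, batch effects, or sample imbalance. Passing
recovery tests therefore shows the statistics behave correctly under the
model's own assumptions, not that any particular real dataset meets them.

## Problem sizes used in validation

The shipped checks run at desk scale, chosen to finish in minutes on one
CPU while leaving Monte-Carlo error well inside the tested tolerances:
null calibration uses 50 replicates of 1,000 genes / 20 disjoint 30-gene
sets / 10 vs 10 samples at 200 permutations (1,000 set-level p-values);
pairwise-test calibration uses 2,000 profile shuffles over 95 pathways;
overlap recovery uses ρ ∈ {0, 0.25, 0.5, 0.75, 1} × 10 seeds with 2,000
genes / 40 sets / 4 up + 4 down regulated sets at δ = 2; the demonstration
cohort is 8 + 9 datasets over 95 pathways (set sizes 20–40) at 1,000
permutations. The full protocol parameters (1,000 permutations, sizes
15–500) remain the library defaults.

## Known limitations

- Gene-set permutation understates the null spread for strongly correlated
  gene sets; phenotype permutation is not implemented.
- FDR pooling is not stratified by set size.
- The chi-squared test's asymptotics are doubtful when a profile has very
  few up or down calls; the zero-margin reduction handles the extreme case
  but small expected counts remain approximate.
- Species-group tests treat pairs as independent observations although
  pairs sharing a dataset are not.
- The uppercase ortholog heuristic misses genuine symbol changes between
  mouse and human; an explicit ortholog table is preferred whenever
  available.
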