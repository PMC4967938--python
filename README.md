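# pathconcord

Which animal model best mimics a human disease — at the pathway level?

`pathconcord` implements a reusable pipeline for comparing pathway
regulation across transcriptomic studies from different species, built for
the question that arises in translational research whenever the same
disease (e.g. sepsis or other severe inflammatory disorders) has been
profiled in patients and in several mouse models: instead of comparing
fold-changes gene by gene, each dataset is reduced to a per-pathway
regulation profile by gene set enrichment analysis (GSEA), and profiles are
compared between models with predictive-value statistics against a chance
baseline.

## Method

For each two-class dataset (disease vs control), genes are ranked by the
signal-to-noise metric

    s_g = (μ_case − μ_control) / (σ_case + σ_control),

with each class standard deviation floored at max(0.2·|μ|, 0.2). For a gene
set S with N_H detectable members in the N ranked genes, the weighted
Kolmogorov–Smirnov running sum gains |r_j|^p / N_R at members
(N_R = Σ_{j∈S} |r_j|^p, p = 1) and loses 1/(N − N_H) elsewhere; the
enrichment score ES is its signed extreme. Significance comes from a
gene-set permutation null (random same-size sets from the ranked universe,
1,000 permutations by default): the normalised enrichment score
NES = ES / mean|same-signed null ES|, a guarded nominal p, and a pooled
permutation FDR q per direction. Sets with fewer than 15 or more than 500
detectable genes are not tested.

Each pathway is then called **up** (NES > 0, q ≤ 0.25), **down** (NES < 0,
q ≤ 0.25) or **null** (not changed, or not testable). For two models the
positive predictive value is PPV = |Up₁ ∩ Up₂| / |Up₂| (NPV analogously for
down calls): how much of model 2's pathway regulation is recovered in model
1. Under independence the expected PPV is simply model 1's base rate
|Up₁|/N, so the gain over chance (in percentage points) measures genuine
concordance; dependence of the two three-state profiles is tested by a
Pearson chi-squared test on the 3×3 contingency table (P ≤ 0.05).
Species-group differences over the pair matrix use Kruskal–Wallis with
Dunn/Bonferroni post-hoc tests and a two-sample proportions test with
continuity correction.

Mouse datasets are brought into the human (HUGO) symbol namespace first:
probe-level matrices are collapsed to symbols (max-mean probe), and mouse
symbols are renamed via an ortholog table or the uppercase heuristic.

A synthetic-data module generates datasets with planted, pathway-coherent
shifts and dataset pairs whose truly-regulated sets overlap by a designed
fraction ρ, so every stage can be validated against known ground truth.

## Worked example

```python
from dataclasses import replace
from pathconcord import (GseaParams, SimulationDesign, classify,
                         compare_pair, run_gsea, simulate_model_pair)

design = SimulationDesign(n_genes=2000, n_sets=40, set_size=(30, 30),
                          n_up=4, n_down=4, effect_size=2.0, rng_seed=7)
ds_a, ds_b, truth_a, truth_b, sets = simulate_model_pair(design, rho=0.75)

params = GseaParams(n_perm=1000, rng_seed=7)
profiles = []
for i, ds in enumerate((ds_a, ds_b)):
    table = run_gsea(ds, sets, replace(params, rng_seed=7 + i))
    profiles.append(classify(table, sets, dataset_id=ds.dataset_id))

res = compare_pair(*profiles)
print(f"PPV(A<-B) = {res.ppv_12:.3f}   NPV(A<-B) = {res.npv_12:.3f}")
print(f"mean predictive value = {res.mean_pv:.3f}")
print(f"gain over chance = {res.delta_points:.1f} points")
print(f"chi-squared = {res.chi2_stat:.1f} (df {res.chi2_df}), P = {res.chi2_p:.2e}")
```

prints

```
PPV(A<-B) = 0.750   NPV(A<-B) = 0.750
mean predictive value = 0.750
gain over chance = 65.0 points
chi-squared = 41.4 (df 4), P = 2.21e-08
```

Two models were designed to share ρ = 0.75 of their regulated pathways (3
of 4 up sets, 3 of 4 down sets). The pipeline recovers exactly that: PPV and
NPV are 0.75 against a 0.10 chance baseline (4 regulated sets out of 40), a
65-point gain, and the pair's profiles are strongly dependent (chi-squared
P ≈ 2×10⁻⁸).

The same analysis runs from the shell on real files:

```
pathconcord simulate --seed 7 --out simdir          # or your own GCT/CLS/GMT
pathconcord run --manifest manifest.yaml --gmt sets.gmt --seed 7 --out outdir
```

`run` writes per-dataset enrichment tables, three-state profiles, the pair
comparison matrix, species-group summaries and a JSON run summary; reruns
with the same config and seed are byte-identical.

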