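# trmgs — trait-relevant markers in genomic selection

`trmgs` is a research pipeline for a question plant breeders face when
designing genotyping panels: **does ranking markers by a mapping statistic
(GWAS −log₁₀P or QTL-scan LOD) and feeding only the top markers into a
genomic-prediction model beat the same number of randomly chosen markers —
and when do nonadditive effects and population-structure covariates help?**

It provides, as one importable Python library:

* **Population simulation** with full ground truth: biparental RIL and F2
  populations (Poisson crossovers, no interference), a structured natural
  panel (Balding–Nichols allele frequencies), and replicated
  multi-environment phenotypes
  `y_ijl = μ + g_i + e_l + ge_il + r_jl + ε_ijl` whose additive, dominance
  and additive×additive variance fractions hit their targets exactly.
* **Marker QC and BLUEs**: missingness (>0.10), MAF (≤0.05) and
  segregation-distortion χ² (P ≤ 0.01) filters; per-line BLUEs and
  variance components by REML; broad-sense heritability.
* **Recombination bin maps**: 15-SNP sliding-window parental calls
  (≥ 11 of 15 rule), block merging, bins cut at the union of all
  individuals' breakpoints, and a Kosambi genetic map
  `d = 25 ln((1+2r)/(1−2r))` from RIL- or F2-appropriate recombination
  estimates.
* **Mapping**: Q+K mixed-model GWAS (P3D/EMMAX variance estimation on the
  kinship eigendecomposition), composite interval mapping by Haley–Knott
  regression with forward-selected cofactors, permutation LOD thresholds,
  1.5-LOD support intervals, and pleiotropic-QTL integration.
* **Kernels**: VanRaden additive `G = WW′ / 2Σp_k(1−p_k)`, the
  genotype-frequency dominance design with
  `θ = p₁₁ + p₂₂ − (p₁₁ − p₂₂)²` and `G_d = nDD′/tr(DD′)`, and the
  epistatic Hadamard square `G_aa = G_a ∘ G_a`.
* **Prediction models**: multi-kernel GBLUP (models A, A+AA, A+D, A+D+AA)
  by Gibbs sampling on kernel eigen-representations with masked-phenotype
  prediction, a fast single-kernel REML path, BayesC with spike-and-slab
  marker effects, and both with principal-component fixed effects
  (BC+PC, G+PC).
* **A cross-validation engine** (k-fold × replicates) that re-runs the
  mapping scan inside every training fold, selects top-k trait-relevant
  markers (TRMs) or seeded random baselines, and reports
  `r_MG = cor(GEBV, BLUE)` on the testing folds across a marker-count
  ladder.

## A worked example

```python
import trmgs as t

chroms = [t.ChromSpec(f"c{i+1}", 200_000_000, 180.0) for i in range(10)]
founders = t.simulate_founders(4000, chroms, seed=51)
ril = t.make_ril_population(founders, 212, seed=52)
binmap = t.make_binmap(ril)

arch = t.random_architecture(ril.n_markers, 30, fa=0.5, seed=53,
                             var_env=0, var_gxe=0, var_rep=0, var_resid=1.0)
records, _ = t.simulate_phenotypes(ril, arch, 1, 1, seed=54)
y = records.set_index("individual")["value"].reindex(ril.ids)

data = t.CVData(geno=ril, blues=y, population="RIL", binmap=binmap)
plan = t.make_folds(ril.ids, k=5, n_reps=3, seed=55)
table = t.sweep(data, plan, [20, 100, 500, "all"],
                sources=("TRM", "RAN"), models=("A",), seed=56)
print(t.aggregate_accuracy(table))
```

This prints (`r_mg_mean` over 3 replicates × 5 folds):

```
marker_source n_markers  r_mg_mean  r_mg_sd
          TRM        20   0.518378 0.159106
          TRM       100   0.554573 0.151234
          TRM       500   0.599176 0.122223
          TRM       all   0.568727 0.107698
          RAN        20   0.209227 0.168088
          RAN       100   0.433439 0.131343
          RAN       500   0.568475 0.106806
          RAN       all   0.568727 0.107698
```

Read it as: with only 20–100 markers, picking the in-fold top-LOD bins
beats random markers of the same count by a wide margin (0.52 vs 0.21 at
20 markers); the two converge as the count approaches the full bin map,
and the TRM curve plateaus by ~500 markers at or above the all-marker
level — a small targeted panel captures the full genomic-prediction
accuracy of this population.

`examples/` contains one short script per capability (simulation, QC+BLUEs,
bin map + QTL scan, kernels + extended GBLUP, TRM cross-validation), and the
same workflow is scriptable from the shell:

```bash
trmgs simulate --config cfg.yaml --workdir run --seed 1
trmgs qc --config cfg.yaml --workdir run
trmgs blue --config cfg.yaml --workdir run
trmgs binmap --config cfg.yaml --workdir run
trmgs qtl --config cfg.yaml --workdir run
trmgs cv --config cfg.yaml --workdir run
```

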