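# toxmod

Toxicogenomic analysis of organ injury from bulk expression data:
differential expression with a dual cutoff, aggregated fold-change
(AFC) pathway scoring, and aggregate absolute fold-change (AAFC)
injury-module activation z-scores, together with a synthetic-cohort
generator with known ground truth.

The package targets the study design common in rodent toxicology:
small cohorts (typically n = 5 treated vs n = 5 vehicle controls per
organ/dose/time cell) of log-transformed gene-level expression, and
curated gene sets — pathways, or "injury modules" of co-expressed
genes associated with specific histopathological phenotypes (necrosis,
fibrosis, cellular infiltration, ...). Its users are computational
toxicologists asking: *which injury phenotype does this expression
profile most resemble, and is the signal significant?*

## Methods at a glance

For a contrast between treatment and control cohorts, the per-gene
fold change on the log scale is the difference of cohort means,

    fc_g = mean(log x_g, treated) − mean(log x_g, control),

reported on both the natural-log and log2 scales, with a two-sided
equal-variance Student's t-test and Benjamini–Hochberg q-values.

**DEG calling** uses a dual cutoff: q ≤ 0.01 and an effect size
|ln FC| ≥ 0.60 (the 95% quantile of the no-change null; exp(0.60) ≈ a
1.8-fold change). The cutoff can be re-derived from control-only
pseudo-cohort splits via `derive_effect_cutoff`.

**AFC pathway score** = mean signed log fold change over a pathway's
genes, tested against a competitive null of random same-size gene sets
(gene-label sampling without replacement); the sign gives the
direction of regulation.

**AAFC module activation** filters genes by the t-test (p ≤ 0.05),
computes the background mean μ₀ and SD σ of |log2 FC| over all
retained genes, averages |log2 FC| over a module's n retained genes
(X̄), and standardizes by the Central Limit Theorem:

    z = (X̄ − μ₀) / (σ / √n),    p = 1 − Φ(z).

The top-ranked module by z is the predicted injury phenotype; modules
with p < 0.01 are called significantly activated; modules with too few
retained genes are reported as missing ("−").

## Worked example

```python
import toxmod as tm

# a synthetic cohort: 5000 genes, 5 vs 5, one module carrying a
# 1.0 log2-fold-change effect in 80% up / 20% down mixture
modules = tm.generate_gene_sets(n_sets=8, seed=11)
spec = tm.SyntheticSpec(
    n_genes=5000,
    effects={"module_3": tm.EffectSpec(mean_abs_log2fc=1.0, up_fraction=0.8)},
    seed=11,
)
expr, annotations, contrast, truth = tm.generate_dataset(spec, modules)

fc = tm.compute_fold_changes(expr, contrast)
degs = tm.call_degs(fc, q_max=0.01, min_effect=0.60)
print(f"DEGs called: {len(degs)}")
print(tm.score_module_collection(fc, modules).to_string(index=False))
```

Output:

```
DEGs called: 0
  module  n_used    x_bar         z      p_value  significant status
module_3      97 1.114793 11.379588 2.642440e-30         True scored
module_2      22 1.045583  4.277931 9.431924e-06         True scored
module_4      21 1.020819  3.780532 7.824670e-05         True scored
module_6      19 0.995400  3.206408 6.720167e-04         True scored
module_5       8 0.967647  1.804574 3.557070e-02        False scored
module_8       4 1.022765  1.663647 4.809149e-02        False scored
module_1       4 0.977634  1.346257 8.910988e-02        False scored
module_7       4 0.748130 -0.267755 6.055560e-01        False scored
```

With only five samples per cohort, per-gene DEG calling at q ≤ 0.01
finds nothing — yet the activated module is recovered decisively
(z ≈ 11.4, the largest score, correctly top-ranked). The other
significant modules overlap module_3's membership (`n_used` counts the
genes passing the t-filter): set-level aggregation pools weak per-gene
evidence into a strong module-level call. That is the point of the
AAFC score for early injury detection in small cohorts.

## Command line

```bash
toxmod simulate --out-dir sim --seed 3 --n-genes 5000 --activate module_3:1.0:0.8
toxmod run --config config.yaml --out-dir results --seed 3   # deg + pathways + modules
toxmod deg --config config.yaml        # or any single stage: deg / pathways / modules
```

The YAML config uses flat keys (`expression`, `contrasts`,
`module_gmts`, `pathway_gmts`, `q_max`, `min_effect`, `alpha_ttest`,
`alpha_module`, `n_permutations`, `seed`, ...). All result tables are
TSV with six-significant-digit floats; runs are byte-reproducible
under a fixed seed.

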