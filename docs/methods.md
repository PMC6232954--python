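# Methods

## Scope and data model

The package operates strictly downstream of quantification: its input
boundary is a gene-level expression matrix that has already been
log-transformed (the `log_base` flag records whether log2 or natural
log was applied), plus sample annotations (organ, dose group, time,
cohort) and gene-set collections in GMT format. Read alignment,
transcript aggregation, and abundance-uncertainty modelling are out of
scope by design; consequently DEG counts obtained here from real data
will not exactly match those of transcript-level pipelines that model
technical variance, although direction and ranking agree.

All fold changes are differences of cohort mean log-expression
(treatment minus control). Two scales coexist deliberately in the
fold-change table: the DEG effect size is defined on the natural-log
scale, while module activation aggregates |log2 FC|. Conversion is
exact (fc_ln = fc_log2 · ln 2), so no information is lost.

## Differential expression

Per gene, a two-sided Student's t-test with pooled (equal) variance
compares the two cohorts; with 5 + 5 samples this is a t on 8 degrees
of freedom. p-values are adjusted across all genes by the
Benjamini–Hochberg step-up procedure (delegated to statsmodels). A
gene is a DEG when q ≤ `q_max` (default 0.01) **and** |ln FC| ≥
`min_effect` (default 0.60, i.e. a ≈ 1.8-fold change).

Degenerate rows are resolved explicitly rather than left as NaN: zero
within-cohort variance with equal means gives t = 0, p = 1; zero
variance with unequal means is maximally significant (the smallest
positive float) and logged as a warning, since such a row is almost
always an artifact of constant or clipped values.

`derive_effect_cutoff` reconstructs the effect-size threshold from the
no-change null: control samples are repeatedly split at random
(default 200 splits) into two pseudo-cohorts, each split yields a
per-gene |ln FC| under the null, and the cutoff is the requested
quantile (default 95%) of the pooled distribution. For Gaussian
per-sample noise with SD s on the ln scale and a m₁/m₂ split, the
95% quantile is 1.96 · s · √(1/m₁ + 1/m₂), which the implementation
recovers within sampling error. 0.60 remains the shipped default
regardless, so standard analyses are insensitive to the cutoff's
re-derivation.

## AFC pathway scoring

The pathway score is the arithmetic mean of member genes' signed log
fold changes (natural-log scale by default); genes absent from the
data are skipped and the effective size n is the number present. The
null is competitive: random sets of n gene labels are drawn without
replacement from all genes in the table, and

    p = (1 + #{|S_rand| ≥ |S_obs|}) / (n_perm + 1).

Design choices worth noting:

* **Two-sided magnitude test, sign reported separately.** A single
  procedure produces both up- and down-regulated calls; the direction
  column carries the sign of the observed score.
* **Add-one estimator** avoids p = 0 and makes the smallest achievable
  p equal to 1/(n_perm + 1). Default n_perm = 10,000 resolves the
  0.01 significance level with adequate Monte-Carlo error.
* **Per-set reseeding.** Each pathway's null draws restart from the
  same base seed, so two pathways with identical membership receive
  identical scores and p-values, and results are independent of the
  order in which sets appear in the GMT file. The cost — shared null
  draws across same-size sets — is irrelevant for calibration.
* A set covering every gene in the table has a degenerate null (every
  draw reproduces the observed score) and correctly gets p = 1.
* Null subsets are drawn by arg-partitioning i.i.d. uniforms row-wise,
  in chunks of 512 draws, which is vectorised and memory-bounded.

Under a global-null cohort the permutation p-values over random gene
sets are approximately uniform (the acceptance suite applies a
Kolmogorov–Smirnov check at α = 0.01).

## AAFC module activation

Genes failing a per-gene t-test at `alpha_ttest` (default 0.05,
boundary kept) are discarded **once**, before both the background
statistics and the module means, so the background and every module
see the same retained universe — this makes the whole-background
module score exactly z = 0, a useful identity that the tests pin.

Over the retained genes, μ₀ and σ are the mean and SD (n − 1
denominator) of |log2 FC|. A module with n retained member genes and
mean absolute fold change X̄ scores

    z = (X̄ − μ₀) / (σ / √n),    p = 1 − Φ(z).

The p-value is one-sided (upper tail): activation is defined as
elevated absolute fold change. The standard error uses √n per the
Central Limit Theorem; a `se_convention="n"` switch exposes the σ/n
variant for auditing against sources that print the scaling
ambiguously, but √n is the statistically consistent default. Modules
with fewer than `min_genes` (default 3) retained members are reported
as missing and rendered "−" in output tables; a module score built on
one or two genes would be an unstandardisable point estimate.

Cross-organ application (`cross_organ_scores`) scores every module
collection against every organ's fold-change table, the design used to
probe whether injury modules are organ-specific.

### Accuracy of the normal approximation

The CLT approximation is the method's weakest link and is quantified
here rather than assumed. The background |log2 FC| population is
folded-normal-like (skewness ≈ 1 under the null), so the exact null of
X̄ — the mean of n labels sampled without replacement — deviates from
N(μ₀, σ²/n) by an Edgeworth-order term ≈ skew·(z² − 1)φ(z)/(6√n).
Numerically this is an absolute p-value error of roughly 0.01 at
n = 20, 0.005 at n = 60, and under 0.005 only as n approaches the
upper end of typical module sizes. The test suite compares the
analytic p against a 10⁵-draw gene-label resampling oracle at module
sizes 20/60/126; agreement at strict Monte-Carlo resolution (3 SE)
holds only for the largest size, and the smaller sizes document the
approximation's systematic skewness error. Two practical consequences:
(1) p-values near the 0.01 decision threshold are accurate to about
±0.01 for small modules — ranking by z is unaffected; (2) when the
retained background is small, sampling without replacement also makes
the analytic σ/√n conservative (the finite-population correction is
ignored), so the false-activation rate under the null sits at or below
the nominal α, which the calibration suite confirms.

## Synthetic cohorts

The generator emulates the statistical regime the analysis assumes,
not count-level sequencing noise: every downstream formula operates on
log-expression means, so Gaussian noise on the log2 scale is the
faithful abstraction. Per gene, baseline ~ N(8, 2²) log2 units;
control value = baseline + N(0, noise_sd²); treatment value adds the
true effect δ_g. Defaults: 5 vs 5 samples, noise_sd = 0.5 log2 units —
the cohort size matches the targeted study design, and the noise and
baseline spread are field-typical conventions rather than estimates
from any particular dataset. Gene sets are drawn with sizes uniform in
[8, 126] from a shared 629-gene pool, mirroring the published
injury-module regime, with overlap between sets permitted.

Injected effects are per-set: magnitude `mean_abs_log2fc` with sign +
with probability `up_fraction` per gene. Where activated sets overlap,
the largest-magnitude effect wins — a simple, documented rule for a
case the underlying model leaves open. Ground truth (per-gene δ_g,
per-set activation flags) is returned for recovery tests.

What passing tests on these cohorts do **not** show: robustness to
count-level overdispersion, library-size artifacts, correlated gene
noise, or batch structure — none of which the generator emulates.
They do show that the scoring machinery is calibrated under its own
assumptions and recovers known activations with high power (a 30-gene
module at δ = 1.0 log2, noise 0.5, is top-ranked in ≈ 100% of
replicates among 20 candidate modules).

## Numerical and reproducibility choices

* All randomized stages derive from one integer seed; pipeline runs
  are byte-identical under a fixed configuration (tables are written
  with six significant digits, fixed column order).
* Ranking ties are broken deterministically (stable mergesort, then
  set name), so output order never depends on dict iteration.
* Problem sizes in the test and acceptance suites (5,000-gene null
  cohorts, 200 random sets, 100 recovery replicates, 10³–10⁵
  permutation draws) were chosen to give each statistical check
  adequate resolution at interactive runtimes.

## Known limitations

* The CLT p-value's skewness error for small modules, quantified
  above; a resampling p-value could replace it at extra cost.
* The t-filter induces selection on the background: under the null
  only ~5% of genes are retained and their |FC| distribution is
  truncated from below. Both the background and the modules are
  subject to the same selection, so the z-score remains internally
  consistent, but μ₀ and σ should not be interpreted as genome-wide
  fold-change statistics.
* Modules reported missing (too few retained genes) carry no
  evidence either way; a missing necrosis module is not evidence of
  absent necrosis.
* No multiplicity correction is applied across modules or pathways by
  default (raw p < 0.01 is the reported decision rule); with dozens of
  sets the family-wise false-activation rate is correspondingly
  higher.
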