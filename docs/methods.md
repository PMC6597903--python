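# Methods

This note documents the statistical models behind `dualomics`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions made where more than one
reasonable choice existed.

## Study design assumed

Two genotype groups (control and mutant) of cultured neurons assayed at two
ages, 35 and 56 days in vitro (DIV), on two omics layers: bulk RNA-seq gene
counts and TMT-10plex protein reporter intensities. Default group size is 5
samples per genotype per timepoint, so one 10-channel TMT set holds exactly
one timepoint. The scale targets ~16k detected genes and ~10.5k quantified
proteins per timepoint; the test suite and the acceptance script run the same
machinery at 400–5,000 genes so the whole suite completes in seconds — the
statistics are per-feature, so nothing but Monte-Carlo resolution depends on
the feature count.

## RNA layer

**Normalization.** Median-of-ratios size factors: with geometric mean
`g_i = (∏_j k_ij)^{1/n}` over genes positive in every sample,
`s_j = median_i (k_ij / g_i)`. No rescaling to unit product is applied; the
estimator is used exactly as defined, and a rescaling of any one sample is
absorbed into its factor up to a common geometric-mean shift that cancels in
all group-mean ratios.

**Detection.** `FPKM_ij = k_ij · 10⁹ / (L_i · N_j)` with annotated gene
length `L_i` (no effective-length correction — none is defined for this
design) and library total `N_j`. A gene is robustly detected when its mean
FPKM across the timepoint's samples is strictly above 0.5. The detection
universe is the mean over *all* samples at the timepoint, not per group.

**Differential test.** Per gene, on normalized counts `k_ij/s_j`: group means
`μ̂_c, μ̂_m`; a pooled method-of-moments dispersion solving
`E[v_g] = μ_g·mean(1/s_j) + α μ_g²` across both groups, floored at 1e-8;
`log2fc = log2((μ̂_m+ε)/(μ̂_c+ε))` with pseudocount `ε = 0.5/median(s)` so
zero-mean groups give bounded fold changes; a delta-method standard error of
the log ratio from `Var(μ̂_g) = (μ_g·mean(1/s) + α μ_g²)/n_g`; and a
two-sided p-value from Student t with `n_c+n_m−2` degrees of freedom. The t
reference (rather than the normal limit) is deliberate: with 4–5 samples per
group the plug-in dispersion makes the normal reference anticonservative
(empirically ~7% of null genes at p < 0.05), while the t reference keeps the
null fraction at p < 0.05 inside [0.035, 0.065] — verified by simulation in
the acceptance suite. A full IRLS negative-binomial GLM with dispersion
shrinkage was not used: the two-group design has closed-form group means, and
shrinkage priors would add machinery without a specification to pin them to.

**Multiple testing.** BH is applied over detected genes only; undetected
genes keep their raw p but carry `p_adj = NaN` and can never enter the
signature.

## Protein layer

**Normalization.** Each channel is divided by its median intensity over all
proteins in the TMT set, then multiplied by the mean of the original channel
medians so the global scale is preserved; channel medians are equal
afterwards. Each protein is then divided by its own across-channel mean
("relative ratio"; row means are exactly 1). Analysis proceeds on log₂
relative ratios — a constant per-channel factor cancels and variances are
approximately stabilized.

**Moderated t.** Ordinary per-protein two-group fit (difference of log₂
means; pooled variance `s²` with `df = n_c+n_m−2`, reduced per protein when
channels are missing). The hierarchical model `s² ~ s₀²·F(df, d₀)` is fitted
by moment matching on `log s²`: with `e_g = log s²_g − ψ(df_g/2) +
log(df_g/2)`, the excess of `var(e)` over the mean sampling variance
`ψ′(df_g/2)` equals `ψ′(d₀/2)`, inverted by bracketed bisection (brentq) on
`d₀/2 ∈ [1e-6, 1e8]`; when the excess is non-positive the prior is degenerate
(`d₀ = ∞`, full shrinkage to `s₀²`). Then
`s²_post = (d₀ s₀² + df s²)/(d₀+df)`, `t = Δ/sqrt(s²_post(1/n_c+1/n_m))`,
two-sided p from t with `df + d₀` df (normal when `d₀ = ∞`). Forcing
`d₀ = 0` recovers the textbook pooled t exactly, which the test suite checks
at 1e-10 relative tolerance against an independent implementation.

**Missingness.** Zero intensities are treated as missing; proteins quantified
in fewer than two channels of either group are excluded with a warning. No
imputation and no missing-not-at-random model — the generator does not
simulate missingness, so this path is exercised only by targeted unit tests.

**Gene rollup.** Where several protein ids map to one gene symbol the protein
with the highest mean normalized intensity is kept, and BH is recomputed over
the gene-level universe. Symbols are upper-cased at every join.

## Integration

Protein log₂ fold changes are multiplied by 1.4 before merging. The
correction is applied on the log₂ fold-change scale: a constant multiplier on
raw intensities would cancel in relative ratios and have no effect, so the
ratio-scale reading is the only one that can compensate compression. The
factor is configurable.

The cascade takes, per gene symbol, the first significant source in the fixed
order protein-35 ▸ protein-56 ▸ RNA-35 ▸ RNA-56. "Significant" means
FDR-adjusted p < α (default 0.05), plus the detection flag for RNA rows; the
fold-change gate is *not* part of cascade significance — it applies only to
the enrichment signature (`p_adj < 0.05` and `|FC| > 1.5` in either
direction, strict inequalities). A symbol absent from a table is
non-significant there; duplicate symbols within one table are an error.

Genes significant nowhere are handled by the fallback mode: `carry_gene35`
(default) keeps them, sourced from the first table that quantified them
(RNA-35 first), flagged `significant_any = False`, so the enrichment universe
is the full quantified gene space; `exclude` drops them. Carried rows can
never enter the signature (their p already failed), so the choice affects the
universe, not the signature.

## Enrichment ensemble

Gene-level score: `−log10 p_adj_integrated` (missing p → score 0; p floored
at 1e-300). Universe: all symbols in the integrated table. Per set:

- **ORA** — hypergeometric upper tail `P(X ≥ k)` of the signature overlap.
- **Rank** — two-sided Wilcoxon rank-sum, in-set vs. out-of-set scores;
  exact distribution for small tie-free samples, otherwise normal
  approximation with tie and continuity corrections (scipy's Mann–Whitney U).
- **Permutation** — observed mean in-set score against `n_perm` uniform
  same-size gene subsets, `p = (1 + #{T_perm ≥ T_obs})/(n_perm+1)`; the p
  floor is therefore `1/(n_perm+1)`. Null draws are shared across sets of
  equal size (one null ensemble per size) — the null depends only on set
  size, so sharing changes nothing statistically and makes 50-set runs cheap.

Combination: Fisher's `X = −2Σ ln p ~ χ²(6)`. The three base tests are
positively dependent (same data), which makes the combination conservative-
to-nominal rather than exactly calibrated; the suite checks the global-null
reporting fraction stays ≤ 10%. Sets are ordered by the median of their ranks
under the three methods (ties share the best rank; ranking by `min` keeps a
set that tops one method from being penalized by ties elsewhere), with
`p_combined` as tie-break. BH runs across sets on `p_combined`; sets with
adjusted p < 0.05 are reported. Direction is the sign of the mean member
log₂ fold change — a qualitative activated/inhibited label, not a fourth
p-value.

Defaults: `n_perm = 9999` (tests and the acceptance script use 499–1999 for
speed; the planted-set p floor is still far below any threshold used), seed
explicit everywhere.

## Synthetic-data generator

What it emulates: NB counts with variance `μ + αμ²` (gamma–Poisson, default
`α = 0.05`), log-normal baseline expression (log₂ scale N(5, 2)), gene
lengths log-uniform in [500, 20000] bp, library-size factors log-normal with
CV 0.2, log-normal TMT intensities (baseline N(18, 1.5) log₂) with distinct
per-channel offsets (N(0, 0.25)) so median normalization is non-trivial,
Gaussian log₂ measurement noise (sd 0.25, roughly TMT reporter precision),
and planted effects: a fraction `frac_de` (default 0.1) of genes carry
`±effect_log2fc` (default 1.0), identical at both timepoints and shared with
the protein layer for the first `n_proteins` gene symbols; protein-layer
observed effects are attenuated by `compression_factor` (default 1/1.4),
mimicking reporter-ion co-isolation. Planted sets draw ≥ 60% of members from
the differential features; decoys draw uniformly.

Choices worth noting:

- Planted effects are restricted to genes with baseline mean ≥ 5 counts: an
  effect in an unexpressed gene is unrecoverable by construction and would
  only blur recovery metrics. Real differential signal below the detection
  floor is likewise invisible to any pipeline.
- Proteins are deterministically the first `n_proteins` gene symbols, so
  joins are reproducible and truth maps across layers by construction.
- One RNG stream per layer (master seed plus a fixed stream offset via
  numpy's seed-sequence mechanism): generating intensities never perturbs the
  count draws.
- `n_per_group ≤ 5` is enforced — 2×5 genotype channels fill one TMT
  10-plex; multi-set designs per timepoint are out of scope.

What it does **not** emulate: peptide/spectrum-level structure, missing-value
mechanisms (MNAR dropout), batch structure beyond channel offsets,
inter-gene correlation, isoform/effective-length effects, or timepoint-
specific effect sizes. Passing tests therefore demonstrate correctness of the
statistics under the stated model, not robustness to those real-data
phenomena.

## Numerical details

- Dispersion floor 1e-8; p-value floor 1e-300 before logs; permutation p
  floor `1/(n_perm+1)`.
- BH: stable sort, `min` cumulative from the largest rank, capped at 1;
  matches a brute-force oracle to 1e-12 on random vectors.
- PCA QC: SVD of the feature-centered matrix; deterministic sign convention
  (largest-magnitude feature loading positive per component); constant
  matrices yield zero coordinates with a warning.
- TSV output via pandas with default float repr — shortest round-trip
  representation, hence byte-stable across runs; the run manifest records a
  SHA-256 digest of every artifact and the thresholds actually applied.

## Problem sizes used in the checks

The acceptance script simulates 5,000 genes / 2,000 proteins (3 seeds) for
null calibration, 4,000 / 2,500 for effect recovery, and twenty end-to-end
runs at 4,000 / 2,500 with 51 sets of size 20 for pathway recovery — sizes
chosen so each check has ample Monte-Carlo resolution while the full script
completes in well under a minute on one core.

## Known limitations

- The RNA Wald test uses a pooled two-group moment dispersion; it is
  calibrated at the simulated conditions but has no dispersion trend or
  shrinkage, so very-low-count genes rely on the dispersion floor.
- The ensemble combination treats the three base p-values as independent in
  Fisher's formula; dependence makes reported sets conservative, not
  anticonservative.
- The cascade selects a single source per gene; it never pools evidence
  across layers or timepoints, by design.
- `carry_gene35` fallback rows inherit the RNA-35 adjusted p (possibly NaN
  for undetected genes), which maps to a zero enrichment score — an explicit
  "no evidence" convention.
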