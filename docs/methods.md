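# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical decisions that matter for reproducing its
output.

## Study design being emulated

The analyses target a two-generation blood-methylation cohort: the same
children sampled at birth (age 0), childhood (7) and adolescence (17),
and their mothers — different individuals — during pregnancy (nominal age
30) and in middle age (48). Methylation is measured as beta values
(proportion methylated, in (0,1)) on an array-like probe set with
manifest annotations (genic feature, CpG-island relation, QC flags);
genotypes are best-guess dosages in [0,2]. Because such data are
access-controlled, every analysis here runs on simulated cohorts with a
recorded truth table, and the tests are parameter-recovery and
calibration checks against that truth.

## Synthetic cohorts

`mqtlkit.simulate` generates:

* **Genotypes** in LD blocks: within a block all SNPs share one allele
  frequency (uniform on the configured MAF range, default 0.05–0.5) and
  haplotypes are built by first-order copying — SNP j+1 copies SNP j's
  allele with probability ρ, else draws fresh — so the adjacent-SNP
  haplotype correlation is exactly ρ (default 0.6). Blocks are laid ≥2 Mb
  apart across five chromosomes, which guarantees that cross-block pairs
  are *trans* under the ±1 Mb cis rule. Annotations are drawn from a fixed
  category distribution (mostly intronic/intergenic); a random ~50% subset
  is flagged as the "tagging" panel used for trait heritability.
* **Methylation**: each probe's latent value is
  `g_cis + g_trans + cell-composition term + batch term + N(0, env_sd(age)²)`.
  The genetic scores are computed once per individual and rescaled so the
  realized variance fractions equal the probe's targets (`h²_cis`,
  `h²_trans`) exactly at the reference environmental level; shared
  individuals therefore carry bit-identical genetic contributions at every
  timepoint — the "stable genetics" scenario. Environmental SD is
  multiplied by a non-decreasing function of age (default 1 + 0.01·age),
  which is the generating mechanism behind the falling-heritability /
  rising-CV analyses. Trans effects are spread over ≥20 distant SNPs with
  equal variance shares, encoding a highly polygenic trans architecture.
  Cell proportions are Dirichlet(5) with per-probe Gaussian loadings and
  batches are random categories — real confounding that the covariate
  regression must remove. The latent value maps to (0,1) through a
  logistic squash around a per-probe baseline drawn from 0.05–0.95; since
  the analysis rank-normalises each probe, only the map's monotonicity
  matters.
* **Traits**: liability = scaled allele score + normal noise at the
  configured liability-scale h²; cases are liability above Φ⁻¹(1−K); an
  ascertainment step subsamples to the requested case proportion P,
  dropping whichever group is in excess.
* **Mediation motifs**: a trans probe can receive `b ×` (cis probe's
  latent value) plus a direct path `c ×` standardized genotype, giving
  known attenuation targets `ab/(ab+c)`.

What the simulator does **not** emulate: realistic haplotype panels and
imputation error, probe-level technical noise structure (detection p,
intensity normalization), X-chromosome dosage, parent–child genetic
transmission, and any age-by-genotype interaction (an age-specific
override exists but no default claims to match a real cohort). Passing
tests therefore demonstrate that the estimators are correct and calibrated
under the stated generating model, not that real data meet that model.

## Preprocessing

Probes failing QC flags (`multi_mapping`, `snp_at_cpg`) are dropped;
`potentially_problematic` probes are kept and annotated. SNP QC applies
MAF ≥ 0.01, Hardy–Weinberg p ≥ 5e-7 (Wigginton-style exact test below
1,000 samples, 1-df χ² above), missingness ≤ 3%, and optionally a χ²
case/control differential-missingness filter. Rank normalization uses the
Blom offset, `Φ⁻¹((rank − 3/8)/(n + 1/4))` with average ranks on ties; any
monotone-quantile scheme would change downstream values, so this choice is
pinned. The pipeline order is rank-normalize, then OLS-residualize on the
covariate design (intercept, age, sex, ancestry PCs, batch dummies, cell
proportions with the last column dropped because the simplex is collinear
with the intercept); residuals are orthogonal to the design to ~1e-10.
Missing methylation values are set to the probe mean before the
regression; missing dosages are mean-imputed in the screen but deleted
listwise in exact refits.

## Association scan

The screen computes, per tile of probes, the correlation matrix between
standardized residual methylation and standardized dosage; the t statistic
is `r·sqrt((n−2)/(1−r²))` and two-sided p-values are evaluated through the
log-space t survival function. A pair survives at p ≤ 1e-7 and is refit
exactly (slope, SE, t, log10 p, partial r² = t²/(t²+df)). The ±1 Mb cis
boundary is inclusive. Sentinels: per CpG, the smallest-p cis SNP, and
greedy ±1 Mb clumps of trans SNPs; ties break by |t| then SNP id so
outputs are deterministic. log10 p is floored at −320; floored records
carry t for ordering.

## Conditional mapping

Forward–backward stepwise OLS on individual-level data: add the candidate
with the smallest conditional p while it is ≤ 1e-14, refit the joint
model, and drop any previously selected SNP whose joint p rises above the
threshold. Candidates with r² > 0.999 against the selected set are
skipped; selection is capped at 10 signals per probe with a warning. The
explained variance reported is the sum of marginal r² of the retained
SNPs — under LD this can exceed the joint-model r², so both are returned.
By default only cis candidates enter the stepwise model; a flag admits
trans candidates.

## REML variance partitioning

GRMs use the standard scaled cross-product
`G_ij = (1/m) Σ_k (x_ik − 2p_k)(x_jk − 2p_k)/(2p_k(1−p_k))` with sample
allele frequencies and mean imputation; monomorphic SNPs are skipped. The
two-component model is maximised by average-information REML: per
iteration the update solves `AI · Δσ = grad` with
`grad_i = −½(tr(P A_i) − y'P A_i P y)` and
`AI_ij = ½ y'P A_i P A_j P y`; steps that leave the parameter space or
reduce the restricted likelihood fall back to EM
(`σ_i ← σ_i + σ_i²(y'P A_i P y − tr(P A_i))/n`). Components are clamped
at a floor of 1e-8·var(y) and re-activated when the gradient points
inward; an all-zero GRM (no cis SNPs in the window) pins its component to
the floor. Convergence is |ΔlogL| < 1e-6 or 100 iterations (flagged).
Standard errors come from the inverse AI matrix and are reported as
infinite when AI is numerically singular — the behaviour on identical
GRMs, which are non-identifiable. For per-probe work the trans GRM is
formed by subtracting the cis GRM from a precomputed whole-panel GRM,
which makes a probe fit O(n³) in the REML only.

Unrelated-subset selection removes, greedily, the sample involved in the
most relatedness pairs ≥ threshold (ties by id). The canonical thresholds
are 0.05 for methylation and 0.025 for trait analyses; those presume
~1M-SNP GRMs whose off-diagonal noise is ~0.001. On small simulated
panels the GRM's sampling SD is 1/√m, so the analysis scripts place the
cut five sampling SDs out (`max(0.05, 5/√m)`) — otherwise the filter would
remove most of a genuinely unrelated cohort.

Trait partitions exclude chromosome 6 (MHC) from both SNP sets by
default, fit the 0/1 trait with the supplied covariates (sex + 20 PCs in
the canonical configuration), and transform both components to the
liability scale with `h²_liab = h²_obs·K²(1−K)²/(z²P(1−P))`, z the normal
density at the threshold.

## Temporal analyses

Replication counts sentinel pairs from a discovery timepoint that reach
p ≤ 1e-7 with the same slope sign in a target timepoint (sign-free mode by
flag); pairs missing from the target are counted separately as untested.
Cross-time correlations are computed per probe over shared samples only —
cross-generation comparisons use replication, never correlation, because
mothers and children are different people. The permutation null shuffles
one timepoint's sample order with a fixed seed. CV is computed on the beta
scale (residuals are mean-zero, so CV is meaningless there), and the
childhood→later comparison is the paired mean relative change with its
standard error. The heritability-on-age trend is pooled OLS of per-probe
total h² on timepoint age.

## Mediation

For each (SNP-or-score G, cis probe K, trans probe B) triple the package
fits `B ~ G` and `B ~ G + K`; attenuation is `1 − β_adj/β_unadj`, flagged
unstable when |β_unadj| < 2 SE and withheld when K is collinear with G
(r² > 0.999). The measurement-error sweep multiplies K by N(1, sd²) draws
— multiplicative by design, with an additive mode behind a flag — and
repeats the test; attenuation decays toward zero as error grows, so
observed attenuation under-estimates true mediation. Allele scores are
dosage sums weighted by conditional slopes (equal weights by flag).

## Enrichment

Targets are LD-pruned greedily by ascending mQTL p at r² > 0.1 — the
independence Fisher's method assumes, so pruning is enforced rather than
optional. Each target gets a joint matching cell: MAF bin (25 equal bins
on (0, 0.5]), LD-proxy-count bin ({0}, {1}, {2–4}, {5–9}, {≥10} proxies at
r² > 0.8 within ±1 Mb), and, in `annotation_matched` mode, the annotation
category; `genic_only` mode restricts the pool to gene-proximal
annotations instead. Null draws sample pool SNPs per cell without
replacement within a draw (uniqueness enforced globally). When `relax` is
set, cells whose pool holds fewer than ten times the demand fall back to
their marginal MAF bin, widened to neighbouring bins as needed — small
cells would otherwise recycle the same null SNPs across draws and distort
the rank distribution. The observed statistic is Fisher's `−2 Σ ln p`
(combined p via the log-space χ² survival function at 2k df); empirical p
is `(1 + #{null ≥ observed})/(1 + n_draws)` with an exact-tie tolerance,
so it is never zero. Defaults: 1,000 draws for GWAS enrichment, 100 for
trait variance components. The trait variant substitutes each matched draw
into the two-component trait REML and compares liability-scale mQTL
components, aborting if more than 20% of null fits fail to converge.

## Pipeline and seeds

`mqtlkit.pipeline.run_pipeline` chains the stages on a miniature cohort
(200 per generation, 500 SNPs, 50 probes by default), writing one table
per stage with a header carrying the config hash (computed over all
fields except the output directory) and the stage seed. Per-stage seeds
derive deterministically from the master seed by hashing the stage name,
so stages re-run in isolation reproduce exactly; end-to-end output is
byte-identical across runs of the same config and seed.

## Verification problem sizes

The verification suite (`scripts/acceptance.py`, mirrored in
`tests/test_acceptance.py`) runs at sizes chosen to make each check
statistically decisive on one desktop CPU: the REML/grid-oracle
equivalence on 20 instances at n = 50 with a 20³ grid; parameter recovery
on 50 probes at n = 800, 2,000 SNPs (mean absolute error bounds 0.07 cis /
0.10 trans); scan calibration on 10⁵ null tests; conditional recovery on
100 LD-free probes; enrichment calibration on 200 fresh runs of 1,000
draws (each run redraws its target set so runs are independent
experiments) and power on 20 planted-signal runs; the temporal contrast on
100 probes for CV and 30 probes × 3 timepoints for the heritability trend
at n = 400, 600 SNPs. The Bonferroni check is exact arithmetic on the
500,527 × 395,625 test grid; the liability multiplier at K = P = 0.5 is
the closed form π/2.

## Known limitations

* The stepwise conditional mapper uses individual-level OLS rather than a
  summary-statistic + LD-reference routine; estimands agree but the exact
  selected sets can differ under strong LD.
* AI-REML standard errors are asymptotic; at n ≤ 100 they are rough, and
  the grid oracle is the better check at that scale.
* The enrichment empirical p inherits a mild finite-pool effect (null
  draws share a finite SNP pool), visible only as a slight widening of the
  rank distribution; enlarging the pool relative to the target count
  suppresses it.
* Cell-composition adjustment uses the supplied (or simulated) proportions
  directly; reference-based deconvolution from raw methylation is out of
  scope, though externally computed counts can be passed in.
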