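# Methods

## Setting and assumptions

The pipeline implements two-sample summary-data Mendelian randomization
with cis-pQTL instruments. Per variant *j* we observe exposure effects
(β̂ˣⱼ, seˣⱼ) — SD units of a standardized plasma protein — and outcome
effects (β̂ʸⱼ, seʸⱼ) — log-odds of disease — estimated in *disjoint*
samples, so the two error series are independent. The causal parameter θ
is the log-odds of disease per 1-SD increase in protein level; under valid
instruments each Wald ratio θ̂ⱼ = β̂ʸⱼ/β̂ˣⱼ estimates θ.

Instrument validity is probed rather than assumed: heterogeneity across
ratios (Cochran's Q), directional pleiotropy (Egger intercept), and
confounding-by-LD (colocalization) each feed the final tier grade.

## Instrument selection

* cis window: gene body ± 1,000,000 bp, anchored to the annotated
  start/end (not the TSS) — the literal reading of "within 1 Mb of the
  gene". Both ends inclusive.
* Association threshold: exposure p **strictly** below 1×10⁻⁵.
* Clumping: greedy by ascending exposure p; the index variant removes all
  others within 10 Mb whose r² ≥ 0.01 against the user-supplied reference
  panel. Pairs farther apart than the window are never pruned. Ties at
  equal p break lexicographically on variant id, making the kept set
  deterministic. Variants absent from the LD reference are dropped with a
  warning *before* clumping — assuming independence for unseen variants
  would be anti-conservative — while `clump` itself raises on unknown
  variants so that silent keeps are impossible.
* Harmonization: outcome effects are aligned to the exposure effect
  allele; swapped-allele variants have β̂ʸ negated. Palindromic (A/T,
  C/G) variants are dropped by default; the optional
  `keep_if_eaf_informative` policy orients them by allele frequency when
  both EAFs lie outside [0.42, 0.58] and drops them otherwise. The
  defaults are deliberately conservative and deterministic.

## Estimators

All estimators are implemented from their defining formulas and are
cross-checked in the test suite against independent weighted-least-squares
oracles (explicit normal equations) and brute-force constructions.

* **Wald ratio** (k = 1): θ̂ = β̂ʸ/β̂ˣ with first-order delta-method SE
  seʸ/|β̂ˣ|. The second-order term is omitted by default — instruments
  passing the selection threshold have |β̂ˣ|/seˣ large enough that the
  correction is negligible.
* **IVW**: weighted regression through the origin with weights seʸⱼ⁻²;
  with one instrument it degenerates to the Wald ratio. The default SE is
  the fixed-effect SE times max(1, √(Q/(k−1))) — the multiplicative
  random-effects model with the underdispersion floor, the de-facto
  standard; `re_scale="fixed"` disables it.
* **MR-Egger**: weighted linear regression of β̂ʸ on β̂ˣ with intercept,
  after orienting every pair so β̂ˣ ≥ 0 (the intercept is only
  interpretable under this orientation). SEs carry the same
  max(1, √(RSS_w/(k−2))) scaling; inference uses t with k−2 df. Needs
  ≥ 3 instruments; fewer yield an explicit not-applicable result.
* **Weighted median**: ratios sorted ascending with normalized weights
  wⱼ = (seʸⱼ/|β̂ˣⱼ|)⁻²; the estimate linearly interpolates the weighted
  CDF midpoint crossing 0.5. SE by parametric bootstrap (β̂ˣ, β̂ʸ
  resampled from normals at their SEs; 1000 reps; the seed is required
  and recorded in the result).
* **Weighted mode**: argmax of the weight-scaled Gaussian kernel density
  over ratios, bandwidth `bandwidth_factor × 0.9 × min(sd, MAD/0.6745) ×
  k^(−1/5)` evaluated on a 512-point grid spanning [min θ − 3h,
  max θ + 3h]. Zero bandwidth (all ratios identical) returns the common
  ratio. SE by the same bootstrap.

Sensitivity: Q is computed around the fixed-effect IVW estimate with
first-order ratio weights and referred to χ²(k−1); the Egger intercept
p-value uses t(k−2). p < 0.05 counts as evidence of
heterogeneity/pleiotropy in tiering. Q needs ≥ 2 and Egger ≥ 3
instruments; inapplicable tests are NA, never errors.

## FDR and tiers

Benjamini–Hochberg q-values are computed across the screened panel
(statsmodels implementation). Proteins yielding no instrument are logged
and excluded from the family by default; a config switch counts them in
the denominator instead (both interpretations of a proteome-wide family
are defensible, so both are provided). Discovery significance is
FDR < 0.05.

Tier 1 requires replication consistency (primary replication estimator
p < 0.05 with the discovery sign), PPH4 > 0.75, and no significant
heterogeneity or pleiotropy; NA sensitivity tests — unavoidable for 1- and
2-instrument proteins — are non-disqualifying. Tier 2 requires only
PPH4 > 0.75. Everything else is Tier 3. A missing PPH4 is treated as
not-high (Tier 3 path) and logged.

## Colocalization

Per-SNP Wakefield log-ABFs, log ABF = ½[log(V/(V+W)) + z²·W/(V+W)] with
V = se², use prior effect SDs W^½ = 0.15 (SD scale, quantitative trait)
and 0.2 (log-odds scale, case-control) and per-SNP causality priors
p1 = p2 = 1e-4, p12 = 1e-5 — the canonical defaults of the enumeration
method, exposed in `ColocPriors` since no screen should hard-code them.
Hypothesis sums are assembled entirely in log space (log-sum-exp; H3 via a
guarded log-difference), so posteriors sum to 1 within 1e-12 even at
|z| ≈ 60 where raw ABFs overflow doubles. The coloc region is the same
cis window used for instrument selection but with **no** p-value filter:
the enumeration needs the full regional signal. PPH4 > 0.5 is reported as
"likely", > 0.75 as "high" colocalization.

## Synthetic data

The generator emulates the structure of the real study inputs, not any
particular cohort:

* **Haplotypes**: first-order allele-copy model — each haplotype copies
  the previous SNP's allele with probability `ld_rho` (default 0.9), else
  draws fresh at that SNP's MAF (uniform in 0.05–0.5). Adjacent-SNP
  correlation decays geometrically, giving realistic clumping behavior;
  real human LD block structure, recombination hotspots and allele-copy
  frequency drift beyond the configured range are *not* reproduced.
* **Protein**: X = Σc γc Gc + ε with `n_causal_exp` = 3 spaced causal
  cis-SNPs explaining `h2_protein` = 15% of unit variance. Per-SNP simple
  linear regression supplies β̂ˣ, seˣ, p.
* **Outcome**: an independent cohort; liability logit P(case) = α + θX +
  Σ δⱼGⱼ, with α set for the target case fraction and δ the optional
  pleiotropic direct effects (balanced: random ±magnitude; directional:
  constant +magnitude). Per-SNP marginal logistic regressions are fitted
  by a batched Newton solver (cross-checked against statsmodels to 1e-6);
  a linear-probability mode (β/ȳ(1−ȳ) rescaling) exists for large-m
  sweeps.
* **Coloc pairs**: one causal SNP driving both traits (shared) or two
  causal SNPs placed far enough apart that reference r² < 0.01
  (distinct); the binary trait's causal log-OR defaults to 0.8 so the
  regional signal is unambiguous (|z| ≈ 10).

Default scale is a desk-scale study: 5,000 individuals per cohort, 200
SNPs per region, a 500-sample LD reference, and a 10% case fraction (an
enriched case-control design; population-registry case fractions of a few
percent need far larger cohorts than a desk-scale run should use). The
calibration harnesses in `protmr.evaluate` run region replicates at 100
SNPs / 4,000 individuals / 400-sample reference so that 500 replicates
complete in under a minute; these sizes are recorded in the emitted
results. Identical `SimConfig` (including seed) reproduces outputs
byte-identically.

Because regions are simulated independently (one synthetic chromosome per
protein) and without covariates, assay noise, or sample overlap, passing
calibration here demonstrates correctness of the statistical machinery —
not robustness to the confounding structures of real cohort data.

## Numerical notes and limitations

* IVW/Egger/Q are exact closed forms; no optimization is involved. The
  logistic GWAS Newton solver iterates to a 1e-10 parameter tolerance.
* Bootstrap SEs are sample SDs over 1000 resamples by default; stochastic
  results always record seed and rep count.
* p-values are clipped away from exact 0 only where a downstream log
  would fail; BH input validation rejects p ∉ (0, 1].
* Monomorphic LD-reference variants raise by name rather than silently
  producing NaN correlations.
* Single-instrument proteins are fully supported (Wald ratio, NA
  sensitivity, coloc unaffected); zero-instrument proteins are reported
  and logged, never dropped silently.
* Not implemented (out of scope): trans-pQTL instruments, F-statistic
  weak-instrument filtering, MR-PRESSO/multivariable MR, SuSiE-style
  multi-causal colocalization, genome-build liftover, VCF-encoded summary
  statistics.
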