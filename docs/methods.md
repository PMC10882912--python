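# Methods

## Design and assumptions

`pwmr` implements two-sample summary-statistics Mendelian randomization with
cis-pQTL instruments. The core assumptions are the usual instrumental-variable
triad — instruments are (1) associated with the protein, (2) independent of
confounders of the protein–outcome relationship, and (3) affect the outcome
only through the protein — plus the two-sample conditions: exposure and
outcome GWAS come from non-overlapping cohorts of the same ancestry, and all
arithmetic for binary outcomes is done on the log-odds scale (odds ratios are
produced only at report time by exponentiation, so mediation decompositions
and CI algebra stay linear).

Cis instruments are restricted to ±500 kb of the gene's transcription start
site (inclusive at both boundaries; coordinates 1-based throughout). Two
selection presets are provided: *discovery* (p < 1e-5, clump r² > 0.01
discarded within 1000 kb of the index SNP) and *replication* (p < 5e-8,
r² > 0.001 within 10000 kb). Clumping is greedy on ascending p with ties
broken by ascending variant id, which makes selection deterministic and
invariant to input row order. The window is measured from the index SNP;
pairwise-window semantics would differ only for chains of variants spanning
more than one window.

## Harmonization

Variants present in both tables are aligned to the exposure's effect allele:
matching orientation is kept, swapped alleles flip the outcome beta's sign
(and eaf → 1−eaf), and strand-complemented records are resolved the same way
after complementing. Palindromic variants (A/T, C/G) cannot be resolved from
alleles, so after orientation alignment both allele frequencies must be
informative (min(eaf, 1−eaf) < 0.42) and on the same side of 0.5; otherwise
the variant is dropped, as is any palindromic variant with a missing
frequency. Every input variant receives exactly one recorded action
(kept / sign_flipped / dropped_palindromic / dropped_mismatch), and
harmonization is idempotent.

## Estimators

* **Wald ratio** (single instrument): θ̂ = β̂_Y/β̂_X with the first-order SE
  σ_Y/|β̂_X|, which ignores exposure-side uncertainty — acceptable for the
  strong instruments (F ≫ 10) the selection stage is designed to produce.
* **IVW**: weighted regression through the origin with weights 1/σ_Yi².
  Cochran's Q (χ², k−1 df) measures heterogeneity. The default mode is
  multiplicative random effects with the scale √(Q/(k−1)) floored at 1, so
  fixed and random coincide under homogeneity; both are reported for k ≥ 3.
* **MR-Egger**: instruments are oriented so all exposure betas are
  non-negative (both betas flipped together), then outcome betas are
  regressed on exposure betas with a free intercept (statsmodels WLS is the
  regression engine). The residual scale is floored at 1 as for IVW.
  Inference for slope and intercept uses t with k−2 df — appropriate for the
  small instrument counts of cis-only analyses.
* **Weighted median**: per-SNP ratios weighted by (β̂_Xi/σ_Yi)², the inverse
  first-order variance of the ratio; the estimate linearly interpolates the
  cumulative-weight function at 0.5. The SE is a parametric bootstrap
  (default 1000 resamples of both betas from their normal sampling
  distributions, seeded; the seed is part of the reported configuration).
* **Method dispatch**: 1 instrument → Wald; 2 → IVW; ≥ 3 → IVW (both modes),
  Egger and weighted median, with the random-effects IVW flagged primary.
* **95% CIs** use the fixed multiplier 1.959964 everywhere for
  bit-reproducibility.

### Instrument strength

Per-SNP variance explained uses R² = z²/(z²+n−2) from the squared t/z
statistic, which needs no allele frequency (an eaf-based alternative,
2·eaf·(1−eaf)·β² on a standardized trait, is available via
`variance_explained(method="eaf")`). Strength is F = R²(N−k−1)/((1−R²)k),
reported per SNP with k = 1 (primary) and for the whole set with the mean R²
and k = |set|. For k = 1, F ≈ z² with relative error below 5% once n ≥ 100;
F < 10 flags a weak instrument.

### MR-PRESSO

The observed statistic is Σᵢ wᵢ(β̂_Yi − θ̂₋ᵢβ̂_Xi)² with θ̂₋ᵢ the
leave-one-out IVW estimate. The null distribution resamples both betas
around their leave-one-out expectations (default 1000 simulations); p-values
use the add-one convention, so the global p is floored at 1/(n_sim+1).
Per-SNP outlier p-values come from the marginal null of each residual term,
Bonferroni-corrected over the instrument count, with α = 0.05. Outliers are
removed in a single pass; the original procedure's distortion stage is not
implemented.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor: with
z = β̂/σ and shrink = W/(W+σ²), log ABF = ½(log(1−shrink) + shrink·z²);
the effect-scale prior SD W^½ defaults to 0.15 for quantitative traits and
0.2 (log-odds) for binary traits. Under the single-causal-variant
assumption the five hypothesis weights are assembled from log-sum-exp
aggregates of the per-SNP log ABFs, with the H3 cross term
Σ_{i≠j} computed as logdiffexp(S1+S2, S12); a non-positive difference
(possible only by floating-point cancellation when one SNP dominates both
traits) clamps the H3 weight to −∞ with a logged warning, which is also the
exact answer for a single shared SNP. Priors default to p1 = p2 = 1e-4,
p12 = 1e-5 (all configurable, validated so p12 ≤ min(p1, p2)). The region
for colocalization is the same ±500 kb cis window used for instruments, and
PPH4 ≥ 80% is the pass threshold. Posteriors are invariant to SNP ordering
and to variants private to one region, and PPH4 is monotone in p12.

## MVMR and two-step mediation

Multivariable IVW regresses outcome betas on the variant × exposure beta
matrix (no intercept, weights 1/σ_Y², residual scale floored at 1); a
rank-deficient design raises an error naming the offending exposures. In
two-step mediation, β1 is the primary exposure→mediator estimate, β2 the
mediator's coefficient from MVMR adjusted for the exposure (the unadjusted
mediator-only fit is available via `adjusted=False`); the indirect effect is
β1·β2 exactly, direct = total − indirect, and the proportion mediated is
indirect/total, reported as a percentage. Mediator instruments overlapping
the exposure's instrument set are removed before estimating β2. A total
effect of zero raises rather than reporting an undefined proportion, and an
indirect effect opposing the total is flagged inconsistent instead of being
hidden. No delta-method CI is attached to the proportion; component SEs are
carried through.

## Screen orchestration

Per protein: cis filter → clump → harmonize → estimate. Proteins with no cis
variants, no instruments after clumping, or no overlap with the outcome are
excluded and logged, and the Bonferroni denominator is the number of
proteins actually tested against that outcome — exclusions do not inflate
the correction. Colocalization runs only for Bonferroni-significant rows
(`coloc_all` overrides); every significant row carries either a PPH4 or an
explicit skip reason. Per-protein bootstrap seeds are derived from the
screen seed in sorted protein order, so results are byte-identical across
runs. Replication of a discovery hit requires the same effect direction and
p < 0.05 in the independent dataset. The Manhattan report plots −log10 raw p
by gene start with the Bonferroni threshold line, positive effects in red
and negative in blue, and writes both raster and vector files.

## Synthetic data generator

The generator emulates the summary-statistics structure the estimators
assume, not genotype-level reality. True marginal exposure effects are
b_X = R·γ for sparse causal effects γ through an AR(1) LD matrix
(r_ij = ρ^|i−j|); outcome effects are b_Y = θ·b_X + R·δ with optional
per-SNP direct effects δ ~ N(μ_pleio, σ_pleio²) (μ_pleio ≠ 0 gives the
directional pleiotropy the Egger intercept should detect). Observed betas
are drawn from N(b, R/n) independently for the two samples, giving
SE = 1/√n — the standardized-effect approximation. Defaults mirror the
study conditions the pipeline targets: n_exp = 7,213 (a pQTL panel),
n_out = 346,631 (a large binary outcome GWAS), 200 SNPs at 1 kb spacing with
ρ = 0.8, one mid-region causal variant of 0.15 SD. Colocalization scenarios
(`coloc_mode` h0–h4) replace the θ path with explicit region structure;
mediation chains add a second, independent LD block of variants acting on
the mediator directly, so MVMR on the union identifies (direct, β2).

What the generator deliberately does not emulate: individual-level
genotypes, realistic MAF/LD drawn from reference panels, sample overlap,
case-control ascertainment (binary outcomes are simulated directly on the
log-odds summary scale), indels/multi-allelics, or strand errors. Passing
calibration tests therefore demonstrates correctness of the estimators under
the stated sampling model, not robustness to real-data pathologies such as
population stratification or winner's curse.

## Test problem sizes

The simulation suites use sizes chosen to make Monte-Carlo noise small
relative to each tolerance while keeping the default test run fast: IVW
recovery uses 20 independent instruments at n = 50,000 over 200 replicates;
the planted-signal screen uses 10 proteins × 100 replicates and the
family-wise-error check 100 all-null proteins × 40 replicates;
colocalization calibration uses 200-SNP regions at n = 20,000 × 100
replicates per scenario; MR-PRESSO calibration uses 20 instruments × 100
replicates; mediation recovery uses chains with ten 0.3-SD instruments per
block at n = 50,000 — the many-strong-instrument regime of real protein and
lipid mediators, under which the recovered proportion's sampling SD
(~1.7 points) sits well inside the 5-point recovery tolerance, which is
asserted on the mean of seeded replicates.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multiple-variant
extension); no trans-pQTL instruments; no Steiger filtering, mode-based or
penalized estimators; no proxy-SNP lookup, liftover or reference-panel LD —
the LD matrix is always supplied explicitly; one mediator per mediation run;
and the MR-PRESSO distortion test is omitted. The Wald-ratio SE ignores
exposure-side uncertainty, which understates the variance for weak
instruments — mitigated by the F > 10 screening convention.
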