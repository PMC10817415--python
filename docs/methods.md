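# Methods

## The analysis

`mrmediate` implements two-sample Mendelian randomization (MR) with a
two-step mediation decomposition on GWAS summary statistics. The target
application is a three-trait chain — a protein exposure (DKK1), a protein
mediator (PDGF-B) and a binary disease outcome (acute myocardial
infarction, effects on the log-odds scale) — but every stage is generic
over (SNP, beta, SE) summary data.

For one exposure–outcome pair, the per-SNP causal signal is the Wald ratio
ρ_j = β_Yj / β_Xj with first-order standard error se_Yj / |β_Xj| and
inverse-variance weight w_j. The battery comprises eight estimators:

- **IVW (primary)** — β̂ = Σ w_j ρ_j / Σ w_j; multiplicative random-effects
  SE = (Σ w_j)^(−1/2) · max(1, √(Q/(k−1))), where Q is Cochran's
  statistic. The inflation is floored at 1, so the random-effects SE never
  undercuts the fixed-effect SE. p-values are two-sided normal.
- **MR-Egger** — WLS of β_Y on β_X with an unconstrained intercept after
  orienting all SNPs to β_X ≥ 0, weights 1/se_Y². The slope is the causal
  estimate; the intercept estimates mean directional pleiotropy. SEs carry
  the same multiplicative floor on k−2 df; inference uses a t(k−2)
  reference. The intercept test is the pleiotropy diagnostic.
- **Simple and weighted median** — the (weighted) median of the Wald
  ratios, with the weighted version interpolating the ratio against
  standardized cumulative weights p_j = (S_j − w_j/2)/S_tot at 0.5.
- **Penalized weighted median** — per-SNP heterogeneity Q_j = w_j(ρ_j − β̂)²
  against χ²(1); weights multiplied by min(1, 20·q_j) and the weighted
  median re-run. The penalty constant (20) is configurable.
- **Simple and weighted mode** — argmax of a normal-kernel density over the
  ratios (unit or inverse-variance weights), bandwidth
  h = φ · 0.9 · min(sd, MAD/0.6745) · k^(−1/5) with φ the bandwidth factor
  (default 1), evaluated on a 512-point grid spanning [min−3h, max+3h];
  ties break toward the smaller ratio for determinism. If all ratios are
  identical the common value is returned without density evaluation.
- **Maximum likelihood** — the one estimator that models exposure-side
  error: β_Xj ~ N(ξ_j, se_Xj²), β_Yj ~ N(θξ_j, se_Yj²). Profiling the ξ_j
  out in closed form leaves ℓ(θ) ∝ −½ Σ (β_Yj − θβ_Xj)²/(se_Yj² + θ²se_Xj²),
  maximized by bounded 1-D optimization started at the IVW estimate; the SE
  comes from the numerical observed information of the profile.

Median- and mode-based SEs use a parametric bootstrap (default 1000
replicates): β_Xj, β_Yj resampled from N(β, se) on both sides, the point
estimator recomputed, SD taken over draws. Weights are held at their
observed values during resampling. All bootstrap seeds derive from one
configured seed, so reports are byte-reproducible.

Sensitivity diagnostics per pair: Cochran's Q around the IVW estimate
(k−1 df) and around the Egger fit (k−2 df), the Egger intercept test,
leave-one-out IVW refits (an exclusion is flagged if it changes the sign
of the estimate or leaves the full-set 95% CI — a numeric surrogate for
the usual visual check), and a reverse-direction run of the whole battery
with the trait roles swapped. A reverse direction without usable
instruments degrades to a structured not-estimable record.

## Instrument selection

Instruments are SNPs with exposure p < 5×10⁻⁸ (strict), greedily LD-clumped
(keep the lowest-p SNP, discard same-chromosome SNPs within 10,000 kb with
r² ≥ 0.001, repeat; ties in p break lexicographically by rsID for
determinism) and screened by the first-stage F-statistic,
F = (n−2)R²/(1−R²), with F < 10 flagged weak. R² is computed either as
2·EAF·(1−EAF)·β² (standardized trait; the default) or as t²/(t²+n−2);
the source publications leave the choice open, so both are exposed. LD is
always an input (a pairwise r² table or a reference dosage matrix); a
missing r² for an in-window pair is an error, never silently treated as
independence.

## Harmonization

Outcome effects are aligned to the exposure's effect allele: swapped allele
order negates the beta and reflects the EAF; complementary alleles are
strand-relabelled and re-checked; palindromic (A/T, C/G) SNPs are aligned
by EAF side unless either frequency falls in the ambiguity window
(0.42, 0.58), in which case they are dropped, as is any palindromic SNP
lacking an EAF. These defaults are conventional and configurable; the
original analysis does not document its palindrome policy, so no claim is
made to replicate it. Every input SNP appears exactly once in the
harmonization log with its action (kept / flipped / strand-corrected /
dropped-…), and harmonization is idempotent.

## Two-step mediation

With total effect (exposure→outcome IVW), β1 (exposure→mediator) and β2
(mediator→outcome), the mediated effect is β1·β2 with delta-method (Sobel)
SE √(β1²se2² + β2²se1²), normal CI and p. The direct effect is
total − β1·β2 (exact identity by construction), and the mediated
proportion is 100·β1β2/total, computed from the 5-decimal-rounded product
for the display chain (matching print precision) with the unrounded value
emitted alongside. A proportion is only reported when the indirect and
total effects share a sign; otherwise the result is flagged inconsistent
mediation. On the published inputs the delta method gives p ≈ 0.051 for
the mediated effect; the package reports this value (the source's printed
mediation p is not reproducible from its own table by this construction,
and no attempt is made to force agreement).

In the pipeline's step-2 (mediator→outcome) analysis, SNPs that are
genome-wide significant for the *exposure* are excluded from the mediator's
instrument set (flag `filter_mediator_instruments`, default on). An
upstream exposure with a direct outcome path turns its own instruments
into invalid instruments for the mediator — their Wald ratios estimate
θ_total/θ_xm rather than θ_my — and in a causal chain such SNPs do reach
significance in the mediator GWAS. The exclusion restores valid step-2
estimation without directionality modelling (Steiger filtering is out of
scope). On data where exposure and mediator instruments occupy distinct
loci, as in the motivating study (3 vs 7 rsIDs), the filter is a no-op.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
entirely at the summary level. For each of k exposure loci: MAF ~
U(maf_range); per-trait SE = (2·MAF(1−MAF)·n)^(−1/2) (standardized-trait
approximation; the binary outcome is treated on the log-odds scale with
normal summary statistics, no liability-threshold model); true effect γ_j
half-normal with SD `gamma_sd`, rejection-sampled (cap 1000 draws) until
the expected exposure z-score clears genome-wide significance, so every
simulated study has usable instruments. Observed betas are normal around
γ_j (exposure), θ_xm·γ_j (mediator) and (θ_direct + θ_xm·θ_my)·γ_j + α_j
(outcome), with α_j ~ N(pleiotropy_mean, pleiotropy_sd²) the per-SNP
horizontal pleiotropy. A further k mediator-specific loci carry their own
effects δ_j (zero on the exposure, θ_my·δ_j + α_j on the outcome). Effect
alleles are coded as the trait-increasing allele, which is what makes
"directional" pleiotropy directional relative to the oriented instruments,
and allele pairs are drawn non-palindromic so strand ambiguity never
silently consumes instruments. Loci are spaced beyond the clumping window
across chromosomes; optional LD proxies are planted within the window via
a latent-genotype construction (haplotype copying with probability √r²
over n_ref reference individuals), and the emitted r² table is the
empirical dosage correlation, not the nominal target.

Defaults are the study conditions used throughout the tests and the
acceptance script: k = 50, n = 50,000 per GWAS, θ_xm = 0.4, θ_my = 0.5,
θ_direct = 0.2 (total 0.4, 50% mediated), no pleiotropy. `gamma_sd = 0.35`
and MAF ∈ (0.1, 0.5) reflect pQTL-scale architectures, where per-allele
protein effects of a few tenths of an SD are routine; strong instruments
also keep winner's-curse selection bias negligible against Monte-Carlo
error at these replicate counts. p-values are clamped at 10⁻³⁰⁰ so written
files round-trip through the reader without losing extreme associations
to floating-point underflow.

What the generator does *not* emulate: realistic genome-wide LD and
allele-frequency spectra, population stratification, sample overlap
between the three GWAS, binary-trait liability scaling, or INDELs. Passing
recovery and calibration checks therefore demonstrates the correctness of
the estimators and pipeline under the model's own assumptions, not
robustness to those real-data complications.

## Numerical choices

- Genome-wide significance is strict inequality (p < 5×10⁻⁸).
- Wald-ratio SEs are first-order (exposure-side error ignored) for
  IVW/median/mode weighting; only maximum likelihood models it.
- The ML optimizer is bounded Brent (xatol 10⁻¹⁰) on a ±10·(|start|+max se)
  interval around the IVW start; non-convergence and non-positive observed
  information raise rather than returning silently.
- Mode grid: 512 points; bandwidth guards: if MAD is zero but the SD is
  not, the SD is used; if both vanish all ratios are identical and the
  common value is returned.
- Display formatting: effects and ORs to 5 decimals, p-values to 4
  significant figures — the precision at which the worked example's
  arithmetic chain (0.00116 / 0.00208 → 55.8%) is defined.
- Monte-Carlo problem sizes: 50 replicates for recovery, 200 each for the
  null and pleiotropy calibrations, with per-replicate seeds derived from
  one base seed (kept below 2³¹).

## Known limitations

- No Steiger filtering, proxy-SNP search, MR-PRESSO, multivariable MR or
  I² statistics (explicit non-goals).
- The reverse-direction analysis on a true causal chain will flag
  "signal": instruments of the forward exposure are significant for the
  downstream trait and act through it. Reverse calibration is therefore
  only meaningful under a simulated null, which is how it is tested.
- The mediation CI/p are normal-theory delta method; bootstrap or
  Monte-Carlo mediation intervals are not implemented.
- The confounder-exclusion step is an input rsID list; no external
  phenotype-lookup service is queried.
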