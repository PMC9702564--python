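# Methods

## Model and assumptions

The pipeline implements two-sample summary-statistic Mendelian randomization.
A variant is a valid instrument when it is (1) robustly associated with the
exposure, (2) independent of exposure–outcome confounders, and (3) affects
the outcome only through the exposure. With per-allele exposure effects
γ̂ⱼ (SE σ_Xj) and outcome effects Γ̂ⱼ (SE σ_Yj) from non-overlapping
samples, the per-SNP Wald ratio is β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SE
σ_Yj/|γ̂ⱼ| — exposure-side noise is ignored in the SE (the no-measurement-
error, NOME, approximation), which is accurate for strong instruments
(F ≫ 10) and is the reason the weak-instrument filter matters.

Estimators and when they are consistent:

| method | consistency requirement |
|---|---|
| IVW | all instruments valid, or pleiotropy balanced with zero mean |
| MR-Egger | InSIDE: instrument strength independent of direct effects |
| weighted median | ≥ 50% of instrument weight from valid instruments |
| weighted mode | the largest cluster of instruments is valid |

Agreement across the four is the usual qualitative robustness argument; the
quantitative diagnostics are the Egger intercept (directional pleiotropy),
Cochran's Q (heterogeneity), MR-PRESSO (outlying pleiotropic SNPs),
leave-one-out (single-SNP dominance) and the funnel sign statistic
(asymmetry).

## Stage-by-stage conventions

**Selection.** Strict p < 5×10⁻⁸ (genome-wide significance). Greedy LD
clumping on a supplied pairwise-r² table: repeatedly retain the smallest-p
candidate and discard candidates with r² > 0.01 against it; ties in p break
on variant id so the result is order-independent. An optional distance
window (default 10 Mb when enabled, off by default) additionally discards
candidates near a retained SNP on the same chromosome; it is skipped for
variants without positions. LD computation itself is out of scope — the
pipeline consumes a precomputed pair list, with absent pairs treated as
r² = 0.

**Instrument strength.** The summary-statistic variance-explained formula
R² = 2β²q(1−q)/(2β²q(1−q) + 2·SE²·N·q(1−q)) is evaluated as printed; the
2q(1−q) factor cancels algebraically, making R² = β²/(β² + SE²·N) and hence
symmetric in q ↔ 1−q. F = R²(N−2)/(1−R²); per-SNP F < 10 rejects that SNP.
The set-level mean F is reported but never used as a filter.

**Proxies.** An instrument absent from the outcome GWAS is replaced by the
outcome variant in strongest LD with it (r² > 0.8; ties by smaller outcome
p, then id). The exposure-side effect stays with the original instrument;
only the outcome effect comes from the proxy. Allele coding is assumed
shared between proxy and index (the synthetic generator guarantees this; for
real data a proxy whose alleles cannot be aligned is dropped). Confounder
pruning looks up exact ids only — no proxy search in the confounder GWAS.

**Harmonization.** The exposure table's effect allele is the reference.
Outcome records are aligned by exact match, allele swap (effect negated,
frequency complemented), strand complement, or both. Palindromic (A/T, G/C)
variants are oriented by frequency agreement and dropped when either side's
effect-allele frequency falls in [0.42, 0.58] (configurable): inside that
window the minor/major labels are too uncertain to orient a palindrome. When
outcome frequency is missing, palindromes are always dropped.

**Estimation.** IVW defaults to multiplicative random effects,
SE_fixed × max(1, √(Q/(n−1))): with no heterogeneity it reduces to the
fixed-effect SE (the floor), with heterogeneity it widens the interval
without reweighting. MR-Egger uses the same multiplicative overdispersion
floor on both slope and intercept SEs; no SIMEX correction for NOME
violation is applied. The weighted median interpolates at midpoint ranks
Sⱼ = Σ_{k≤j}w′ₖ − w′ⱼ/2; the weighted mode maximizes a normal-kernel
weighted density with bandwidth φ·0.9·min(sd, IQR/1.349)·n^(−1/5), φ = 1 by
default, evaluated on a 512-point grid spanning the ratios ± 3 bandwidths
(the grid resolution is checked against a 10× denser scan in tests). Both
take SEs from a seeded parametric bootstrap (default 1000 replicates)
resampling γ̂ⱼ and Γ̂ⱼ from their sampling distributions. All p-values are
two-sided normal; with the instrument counts in view (10–349) the
normal-vs-t difference is at most a few percent of the p-value and is
absorbed into the reported tolerance of the size experiments.

**MR-PRESSO.** Two-sample form. Per SNP j the leave-one-out IVW slope β̂₋ⱼ
defines the residual rⱼ = Γ̂ⱼ − β̂₋ⱼγ̂ⱼ; RSS_obs = Σⱼ rⱼ²/σ_Yj². The null
distribution comes from n_sim (default 1000) parametric datasets with
γ*ⱼ ~ N(γ̂ⱼ, σ_Xj), Γ*ⱼ ~ N(β̂₋ⱼγ̂ⱼ, σ_Yj), recomputing the leave-one-out
residual RSS each time; empirical p-values have resolution 1/(n_sim+1) and
are exactly reproducible under a fixed seed. Outliers are flagged when their
per-SNP empirical p falls below 0.05/n (Bonferroni within the instrument
set). The distortion test compares the raw-vs-corrected estimate shift
against 1000 random removals of equally many SNPs.

**Reporting.** Outcome GWAS effects are log-odds, so estimates are
exponentiated to odds ratios per unit exposure (years for the timing
exposures; no rescaling between per-year and per-SD units is attempted —
each exposure is labelled with its native unit). Significance is flagged at
the nominal 0.05 and at the Bonferroni family-wise threshold
α/(n_exposures × n_outcomes), computed once for the primary IVW family
(0.05/12 ≈ 0.004 for the 3×4 grid); sensitivity rows are not recounted.
Confounder-pruned analyses are appended as "<exposure> no <confounder>"
rows. Pipelines are deterministic given config + seed: every stochastic
component (bootstraps, PRESSO simulations) derives its stream from the
config seed and the exposure/outcome pair name.

## The synthetic generator

Traits are scaled to unit variance, so the sampling SD of a per-allele
effect at frequency q in N individuals is 1/√(2q(1−q)N) — the choice that
makes the R² formula exact in expectation. Per SNP: true exposure effect
γⱼ, direct (pleiotropic) outcome effect αⱼ, optional confounder loading λⱼ,
and Γⱼ = βγⱼ + αⱼ + c_y·λⱼ with γⱼ ← γⱼ + c_x·λⱼ for confounded SNPs.
Observed effects add independent noise on each side (the two-sample
property); p-values follow from the z-statistics. Binary outcomes are
approximated by the same Gaussian model on the log-odds scale.

Instrument effects are drawn at a reference frequency of 0.5 and scaled by
the frequency-dependent sampling SD, so the expected per-instrument
chi-square (hence F) does not depend on allele frequency — the
"equal-power" design standard in GWAS simulation, and the only way a target
mean F maps cleanly onto a scenario with frequencies spread over
(0.1, 0.9). The helper `gamma_for_mean_f` inverts E[F] ≈ E[z²] + 1 for the
reference effect. Directional pleiotropy is oriented relative to the
exposure-increasing allele (αⱼ sign tied to γⱼ's), and confounder loadings
are anti-aligned with it, emulating the inverse adiposity/reproductive-
timing correlation; without these orientations the per-SNP biases would
cancel in ratio space and the scenarios would not express the phenomena
they are named for.

Each instrument carries two LD "satellite" tags (r = 0.8, shared frequency,
r-scaled effects) so clumping has real work to do, and null SNPs come in
declared LD blocks. Palindromic allele coding, random allele-order and
strand presentation, and outcome missingness (with r² = 0.9 proxies sharing
the index variant's coding and frequency) are injected at configurable
rates.

Scenario presets are scale-matched to the motivating study design: AFB-like
(10 instruments, N = 251,151, mean F ≈ 36.5, true OR 0.80/year), AAM-like
(349 instruments, N = 329,345, mean F ≈ 64.3), ANM-like (54 instruments,
N = 69,360, null effect), a balanced-pleiotropy scenario (50 instruments,
mean-zero direct effects, τ = 0.004), a directional-pleiotropy scenario
(30 instruments, 30% invalid, μ_α = 0.012 — roughly twice the causal
ratio shift, a deliberately strong stress test), a confounded scenario
(50 instruments, 20% loading on a BMI-like trait with c_y = 0.5 on the
outcome), and an outlier-injection scenario (20 instruments, one SNP
shifted by 10 outcome SEs). The outcome sample size defaults to 450,000
(biobank scale); the confounder GWAS to 806,834. `simulate_study` composes
three exposures against four shared outcome GWAS tables with
subtype-specific true odds ratios matching the published table's pattern,
plus a BMI-like confounder covering every SNP.

### What the generator does and does not emulate

It emulates: two-sample noise scaled by sample size and allele frequency,
known causal effects, balanced/directional/confounded pleiotropy, LD
structure as a declared r² table, palindromes, strand and allele-order
heterogeneity between studies, and outcome missingness with proxies. It
does not emulate: realistic minor-allele-frequency spectra, LD-correlated
*noise* (the r² table is metadata; sampling errors are independent),
individual-level case-control ascertainment, sample overlap, or population
stratification. Passing tests therefore certify the statistical machinery
under the stated generative model, not robustness to those unmodelled
features of real data.

### Discovery selection and winner's curse

One property of the real design is reproduced but deliberately kept out of
the calibration experiments: when instruments are screened at p < 5×10⁻⁸ in
the same sample that supplies γ̂ⱼ, scenarios with mean F near 36 sit close
to the threshold (z ≈ 6 vs the cutoff 5.45), so the screen retains only
~60–70% of true instruments and inflates their γ̂ — winner's curse, which
attenuates the causal estimate by several percent. No generator with honest
sampling noise can both re-discover essentially all such instruments and
keep their mean F near 36. The calibration experiments therefore evaluate
the estimators on the scenario's *defined* instrument list (the analogue of
instruments fixed by prior discovery GWAS, and the convention of MR
simulation studies), while the screen and clumping are tested by their own
oracles and exercised by the full select-then-estimate pipeline in the grid
analysis — where the selected-set mean F runs higher than the generative
target and estimates are mildly attenuated, exactly as the curse predicts.

## Numerical choices

- Confidence intervals are β̂ ± 1.959964·SE (normal 97.5% quantile computed
  from scipy, not hard-coded).
- Empirical p-values are (1 + #exceedances)/(n_sim + 1), never 0.
- The weighted-mode bandwidth degenerates to returning the common ratio when
  all ratios coincide; when the IQR is zero but the SD is not, the SD is
  used.
- Bootstrap draws of γ* that land exactly on 0 are nudged to the smallest
  positive float before forming ratios.
- Clumping, proxy choice and report ordering all break ties
  deterministically (p-value, then lexicographic id).
- Per-pair seeds are derived from the config seed and the pair name via
  CRC32, keeping streams independent across pairs and below 2³¹.

## Problem sizes

The replicated studies run at: recovery 500 replicates (10-instrument
scenario), Egger intercept size 1000 (tests) / 600 (acceptance script),
median robustness 200, PRESSO detection 200/150 at n_sim = 1000, PRESSO
size 400/300. These sizes put the Monte-Carlo SE of each rate well inside
the asserted bands while keeping a full run in the tens of seconds on one
CPU.

## Known limitations

- No Steiger directionality filtering, multivariable MR, SIMEX-corrected
  Egger, radial MR or I² statistics.
- The NOME approximation in the ratio SE; acceptable at F ≥ 10, enforced by
  the filter.
- Proxy substitution attenuates the outcome effect by the LD correlation r;
  at the r² > 0.8 threshold this is ≤ ~10% on the affected SNP and is not
  corrected.
- The confounder-pruning sensitivity analysis keys on exact variant ids and
  a single confounder trait.
- Real-data reproduction of the motivating study's published table requires
  its instrument-level supplementary data, which cannot be bundled; the
  corresponding check documents its input format and runs only when those
  tables are supplied.
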