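# Methods

This note documents the models, statistics, numerical methods and design
choices behind `loyburden`, in the order the pipeline runs them.

## 1. The composite LOY phenotype

Mosaic loss of chromosome Y is measured on SNP arrays by three proxies of
the same latent quantity — the fraction of leukocytes carrying the LOY
clone:

* `mLRR-Y`: the median (optionally mean) log2 R ratio over probes in the
  male-specific region of Y. More negative values mean a larger clone. The
  median is the default summariser because it is robust to single-probe
  outliers.
* `PAR-LOY` ∈ {0, 1}: a phase-based dichotomous call from allelic imbalance
  in the pseudo-autosomal region, with `AF-LOY` ∈ [0, 1] the estimated
  clone cell fraction for called men.
* The composite score is `PAR-LOYq = PAR-LOY + 3·AF-LOY − 3·mLRR-Y`,
  cropped to [0, 2]. The weights (3, −3) are fixed constants of the score,
  not tunable parameters. Missing components propagate to a missing score;
  they are never zero-filled.

`compare_measures` quantifies the power gain of one measure over another:
each measure is standardised to unit variance, associated with age and
ever-smoking by univariable linear regression (|t| statistics), and with
supplied variant dosages (chi-square = squared z); percent improvement is
`100·(stat − ref)/ref` with the median across variants reported as the
summary. Measures are standardised first so the comparison is scale-free.

## 2. Exome QC

Operating on a multi-sample VCF with `GT:DP:GQ:AD` genotypes, site `QUAL`
and an `AQ` INFO field:

* **On-target flagging**: BED intervals are 0-based half-open; a 1-based
  site position `p` is on-target iff `p−1` lies in the interval union.
  Overlapping/unsorted BED input is accepted (union semantics).
* **ABratio** is defined only for heterozygous (0/1) calls at on-target
  bi-allelic sites: `AD_alt / (AD_ref + AD_alt)`. A het call with zero
  total AD is undefined and flagged malformed. Calls with
  `ABratio ≤ 0.25` or `≥ 0.8` (boundaries inclusive) are excluded, i.e.
  set missing. Multi-allelic sites skip ABratio screening but still get
  site metrics, one row per ALT allele after positional splitting (no
  left-normalisation).
* **Site metrics**: missingness; min/q1/median/q3/max/mean of DP and GQ
  over called genotypes; the count of called genotypes with GQ < 20;
  ABratio summaries over defined het calls; QUAL and AQ (recorded and
  summarised, never filtered on). Quartiles use linear interpolation
  between order statistics — the estimator is fixed so independent oracles
  can match it exactly. Metrics can be restricted to a sample subset
  (e.g. females for chromosome X) or, per variant, to rare-allele carriers.
* **Site filters**, with strict boundary semantics exactly as stated:
  filter 1 excludes missingness **> 5 %** (5.0 % passes); filter 2 excludes
  sites whose maximum called DP is **< 10** (a maximum of exactly 10
  passes); filter 3 excludes sites where **> 20 %** of called genotypes
  have GQ < 20 (exactly 20 % passes). The GQ<20 denominator is called
  (non-missing) genotypes, since missing calls carry no GQ. A site with no
  called genotypes fails filters 1 and 2 and is not evaluable for filter 3.

Order of operations: missingness is computed **after** ABratio exclusion,
so genotype-level exclusions can push a site over the missingness filter.
The alternative (missingness on raw genotypes) is the one design point the
original ordering leaves open; computing it post-exclusion is the
conservative choice and is what the truth sidecars and all oracles mirror.

## 3. Burden sets

* **Most-severe selection**: one annotation row per variant–gene pair, the
  transcript with the most severe consequence under a frozen
  Ensembl/VEP-style severity table (`loyburden.consequences`). Ties break
  deterministically (rank, then term alphabetically, then input order);
  unknown terms warn and rank below all known terms.
* **Impact classes**: HIGH = frameshift, transcript ablation/amplification,
  splice acceptor/donor, stop lost/gained, start lost/gained ("start
  gained" is non-standard vocabulary retained deliberately alongside the
  conventional `start_lost`); MODERATE = missense, inframe
  insertion/deletion, protein-altering. The moderate model never includes
  HIGH-impact variants.
* **Rarity**: MAF is computed on the analysis sample set (ALT frequency
  over non-missing calls, folded), not the full cohort, because analyses
  are run sex-specific and combined with different carrier counts. The
  single-trait burden scan uses strict `MAF < 0.5 %`; the variance-
  component set tests use `MAF ≤ 0.5 %` and require ≥ 2 qualifying
  variants. Both thresholds are configuration, defaulting as printed.
* **Collapse**: carrier indicator = 1 if the individual has dosage ≥ 1 at
  ≥ 1 qualifying variant; missing only if *all* qualifying dosages are
  missing (an individual missing at some variants but carrying at another
  is a carrier). Exclusion schemes (`multi_allelic`, `indel`,
  `non_HC_loftee`, explicit variant keys) rebuild the set for sensitivity
  analyses. Indels are detected by `len(ref) != len(alt)`.

## 4. Association tests

The null model is a fixed-effects covariate-only fit: ordinary least
squares for Gaussian traits, IRLS logistic regression (via statsmodels GLM)
for binary traits. Default covariates are age, genotyping chip and ten
genetic principal components for the single-trait scan; the set tests add
age² and sex where informative. **Mixed models are deliberately replaced
by fixed-effects regression with PC adjustment** — on unrelated simulated
cohorts the two coincide in expectation, and this is the single largest
deviation from the biobank-scale original, which used GRM-based linear
mixed models. Consequences: no protection against cryptic relatedness, and
test statistics on real, related cohorts would be mildly inflated.

For a fitted null with response residuals `r = y − μ` and variance weights
`W` (σ̂² for Gaussian, μ(1−μ) for binomial):

* **Score test** of any column g: `U = gᵀr`,
  `Var(U) = gᵀWg − gᵀWX (XᵀWX)⁻¹ XᵀWg`, two-sided normal p.
* **Burden**: the carrier indicator joins the design; Gaussian traits get
  an exact-t Wald test (effect in trait SD units when the trait is
  standardised), binary traits the carrier log-odds/odds ratio with a
  Firth (Jeffreys-penalised) fallback when separation or non-convergence
  is detected — flagged, never silently failing. Individuals with missing
  carrier status are dropped (complete case), with the null refitted on
  the subset when needed.
* **SKAT**: `Q = Σ_j w_j² (g_jᵀ r)²`; its null distribution is the
  chi-square mixture with eigenvalues of `W_d (Gᵀ Σ G) W_d`, where Σ is
  the covariate-projected residual covariance. Missing dosages are
  mean-imputed per variant; zero-variance columns are dropped with a log
  entry. Default weights are 1; CADD Phred weighting is optional. No
  MAF-based beta weights are applied anywhere.
* **ACAT-V**: Cauchy combination
  `T = Σ w_j tan((0.5 − p_j)π) / Σ w_j`, `p = 0.5 − arctan(T)/π` over the
  per-variant score-test p-values. For `p_j < 1e-15` the summand uses the
  tail expansion `1/(p_j π)`; p-values of exactly 0 are clipped to a
  1e-300 floor with a warning, and the combined value is floored there
  too.
* **Omnibus**: equal-weight Cauchy combination of the defined test-level
  p-values; undefined components are dropped.
* The exome scan flags `p < 1.6×10⁻⁶` (strict, configurable — an
  0.05-style budget over the number of testable genes) and ranks by
  omnibus p with gene-id tie-breaks for reproducibility.

### Mixture-of-chi-square tail (`quadform`)

`P(Σ λ_k χ²₁ > q)` is computed by a three-method ladder:

1. **Ruben's series**: the CDF expanded as a non-negative mixture of
   central chi-square CDFs in steps of two degrees of freedom with
   `β = λ_min`. Terms sum to one, so the truncation error is rigorously
   bounded by the unassigned mass; the series stops at bound 1e-14
   (budget 6000 terms) and is then effectively exact — it reduces to the
   closed form when all eigenvalues are equal.
2. **Imhof's inversion integral** by adaptive quadrature when the
   eigenvalue spread defeats the series budget.
3. **Kuonen's saddlepoint** (Lugannani–Rice) for deep tails where the
   oscillatory integral loses accuracy, with Liu's moment-matching
   chi-square as the last resort.

The method actually used is recorded in the result.

### Calibration properties (what the tests verify, and one caveat)

Null calibration is verified at n = 2000 with per-gene independent traits
and MAC ≈ 10–20 variants: burden, SKAT and ACAT-V p-values are uniform
(Kolmogorov–Smirnov) and all four tests, including the omnibus, hold their
size at α = 0.05. Two deliberate scoping notes:

* Asymptotic score tests are *known* to be miscalibrated for binary traits
  at singleton/doubleton MACs (the motivation for saddlepoint-corrected
  methods elsewhere); the calibration study therefore uses MACs where the
  implemented asymptotics apply. Results on singleton-heavy binary scans
  should be read with that caveat.
* The Cauchy omnibus of three *dependent* component p-values is
  tail-calibrated by construction but not bulk-uniform: with enough null
  genes a KS test reproducibly detects a small (~0.02) bulk deviation
  while the size at conventional α remains nominal. This is a property of
  dependent Cauchy combination, not an implementation artefact (the
  combination formula itself is verified against a high-precision oracle
  to 1e-10), so the omnibus is held to its size claim rather than bulk
  uniformity.

## 5. Sensitivity analyses

* **Leave-one-out** drops each qualifying variant, rebuilds the carrier
  indicator and re-runs the tests. Retention is judged at a nominal
  α = 0.05 by default (configurable): the claim under test is qualitative —
  no single variant drives the signal — and a power analysis at the
  reference scenario (40 carriers, 0.93 SD) shows the worst single drop
  (the 10-carrier frameshift) leaves an expected burden z ≈ 0.93·√30 ≈ 5.1,
  so demanding retention at the *discovery* threshold (|z| > 4.8) would
  fail ~40 % of replicates from sampling noise alone, regardless of
  implementation. Re-inserting a dropped variant reproduces the reference
  row exactly; dropping a variant with no carriers in the analysis subset
  leaves every statistic unchanged.
* **Subset re-analysis** rebuilds the set per exclusion scheme
  (no multi-allelics / no indels / LOFTEE HC only) through the same
  `build_burden_set` path, so a scheme that excludes nothing is bitwise
  identical to the full analysis.
* **Confounding check**: logistic regression of carrier status on each PC
  separately (OR + p per PC); constant PCs are flagged undefined, < 5
  carriers adds a low-power note but the check still runs.
* **Phenome scan**: the carrier indicator tested across a configured trait
  panel, each trait with its own family, optional Blom rank-inverse-normal
  transform, covariates, and optional extra adjustments (e.g. BMI for the
  T2D model). Effects are reported in native units or as odds ratios. The
  default 17-trait panel is illustrative — real analyses supply their own
  panel and transformations.

## 6. The synthetic-data generator

The generator emulates the *structure* of a UK-Biobank-like study, not any
individual-level data:

* **Cohort**: ages uniform 40–70; ever-smoking prevalence 0.45; genotyping
  chip indicator 0.10; PCs i.i.d. standard normal. The latent clone model
  is zero-inflated: presence follows a logistic model with baseline
  prevalence 0.20 at the mean age (roughly the fraction of older men with
  a detectable clone), +1.1 log-odds per decade of age (matching the steep
  observed age gradient), +0.336 for ever-smoking (OR ≈ 1.4), plus any
  configured carrier effect; the clone fraction, given presence, is
  Beta(1, 4) (small clones common, large rare). None of these are
  derivable from the formula-level description of the original analysis;
  they are the package's reference conditions and are fixed.
* **Measurements**: probe LRRs are Gaussian (sd 0.15, 20 probes) around
  `−0.5·fraction`; the PAR-LOY detector has logistic sensitivity in the
  cell fraction (midpoint 5 %, configurable, with a perfect-detector
  override) and configurable false-positive rate; AF-LOY is the fraction
  plus N(0, 0.02²) noise for called men. For uncalled men AF-LOY is 0 by
  default — the conservative convention, since the estimate is generated
  only with a call — with a `missing` alternative behind a flag. Females
  get missing LOY values.
* **Exome**: one contiguous interval per gene on chr1, unique variant
  positions; background minor-allele counts follow P(MAC = m) ∝ 1/m
  (singleton-heavy, as real rare-variant spectra are) up to MAC 20; all
  carriers heterozygous. Carrier genes follow an explicit variant plan —
  the flagship plan is one 10-carrier single-base-insertion frameshift,
  4 doubletons and 22 singletons on 40 distinct men. DP is Poisson around
  depth 30; het AD is Binomial(DP, ½); GQ is clipped Gaussian; QUAL and AQ
  are integers in [20, 99] (20 + Exp(25), clipped) matching the range of
  released exome data. Planted QC artefacts: per-filter failing sites
  (2 % each by default), exact boundary sites (missingness = 5 %,
  max DP = 10, GQ<20 fraction = 20 %, ABratio ∈ {0.25, 0.8}), imbalanced
  het calls (1 % of hets), multi-allelic sites (5 %), indels (10 %) and
  off-target sites (5 %). Planted carrier genotypes are protected from
  missingness and allele-balance exclusion so carrier counts are exact.
  **Truth sidecars are recomputed from the generated genotype arrays**, not
  from planting intent, so they match any faithful re-parse exactly even
  when random genotypes incidentally cross a threshold.
* **Phenotypes**: the quantitative trait is covariate effects plus unit
  normal noise, standardised to mean 0 / SD 1 *in non-carriers*, after
  which the carrier effect is added — so generating effects are exactly on
  the reported SD scale and recovery studies are unbiased by construction.
  The binary trait is logistic with the intercept solved numerically so
  the non-carrier prevalence matches the target (default 7.1 %) and
  carrier log-odds `ln(OR)`.
* **Determinism**: every stage draws from `default_rng([seed, stage_id])`,
  so outputs are byte-identical for a fixed seed and independent of stage
  call order.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium and haplotype structure,
relatedness and population stratification (PCs are pure noise), sequencing
read-level error processes, genotyping batch effects, and the phase-based
LOY caller itself (only its outputs are modelled).

## 7. Reference recovery studies and problem sizes

The benchmark scenarios (`loyburden.scenarios`) use cohorts of 20,000 men
and 200 replicates: a planted 40-carrier gene with a 0.93 SD quantitative
effect; a binary trait with baseline prevalence 7.1 %, ~64 carriers and
OR 6.10; and a dichotomous LOY-call trait (baseline 20 %, age log-odds
1.1/decade) with 40 carriers and OR 5.99. Replicate-mean estimates are
reported with Monte-Carlo CIs; with dozens of carriers the logistic MLE's
small-sample bias is at the percent level, well inside the Monte-Carlo
resolution. The calibration study uses n = 2000 and 500 genes per family;
the QC recount fixture uses 500 samples and ~1000 sites. These sizes are
the package's reference conditions, chosen so the full suite runs
comfortably on a laptop while keeping every check well-powered.

## 8. Known limitations

* Fixed-effects PC adjustment instead of mixed models (see §4).
* No saddlepoint correction for ultra-rare binary-trait score tests.
* Annotation is consumed as a table; no transcript-level logic beyond the
  frozen severity ranking.
* The GDS side of the original data processing is out of scope — plain
  VCF is the interchange format; multi-allelic splitting is positional
  without left-normalisation.
* The phenome-scan trait panel and transformations are placeholders to be
  replaced by study-specific configuration.
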