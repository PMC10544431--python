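# Methods

`admixmr` estimates the causal effect of an individual's Native American
ancestry proportion on breast-cancer risk by two-sample Mendelian
randomization, using ancestry-informative markers (AIMs) as instrumental
variables, and provides a synthetic-cohort generator with fully known causal
structure so that every stage of the analysis can be validated end to end.
This note records the models, the parameter choices, the numerical decisions,
and the limitations we established while validating the pipeline.

## The synthetic world

**Allele frequencies.** Each of M unlinked biallelic SNPs has an ancestral ALT
frequency p ~ U(0.05, 0.95). Subpopulation k (Native American, European,
African) drifts away under the Balding–Nichols model,
p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k). Defaults F = (0.25, 0.15, 0.10):
Native American reference populations are strongly drifted (serial bottleneck
into the Americas), Africans least. Reference panels draw dosages
Binomial(2, p_k); default panel sizes (30, 107, 108) mirror a small Native
American panel beside 1000-Genomes-sized European/African panels.

**Admixture.** Individual ancestry q ~ Dirichlet(α) with default
α = (10, 11, 1.5), giving a Colombian-style exposure distribution — mean
Native American proportion ≈ 44% with SD ≈ 10 percentage points (control
median ≈ 42%, IQR ≈ 36–49%). Genotypes are drawn Binomial(2, Σ_k q_k p_k):
admixture is modelled at the genotype level, so the *global* proportions (the
exposure of interest) are exact by construction and no local-ancestry segments
exist. Optional LD blocks (consecutive SNPs copied from a block leader with a
small per-entry resampling probability) exist solely to exercise LD pruning;
the default genome is unlinked.

**Disease.** With q% the Native American percentage,

    logit P(case) = c + β_anc·q% + β_conf·U + β_age·(age − 50)
    U = ρ·z(q%) + sqrt(1 − ρ²)·ε,  ε ~ N(0, 1)

where β_anc defaults to ln 0.974 (the protective per-1% odds ratio), U is a
continuous non-genetic risk factor never visible to the analysis (β_conf
defaults to ln 1.5), ρ = `conf_anc_corr` controls whether U is
ancestry-linked (default −0.3), and age ~ N(50, 8²) truncated to [25, 80] with
a small known effect (β_age = 0.01/year) so age adjustment is testable. The
intercept c is calibrated by bisection (tolerance 1e−6) so the population
prevalence equals `baseline_prev` (default 8%). Cases and controls are then
drawn from a population pool (random sampling; the matching of the emulated
studies is not modelled — age enters only as a covariate). Cases receive age
at diagnosis, family history and ER/PR/HER2 labels; triple-negative status is
by construction the conjunction ER−/PR−/HER2−. A two-process variant
(`subtype_effects`) generates ER-positive and ER-negative disease with
separate ancestry effects, for planting subtype heterogeneity.

**PheWAS catalog.** A configurable fraction of SNPs (default 10%) is flagged
with at least one catalog row naming a confounder phenotype (reproductive,
lifestyle, socio-economic, metabolic traits or breast cancer itself) at a
p-value log-uniform below 5×10⁻⁸; the instrument-selection stage must exclude
exactly these.

All randomness flows from one integer seed through fixed-purpose
`SeedSequence` children; identical configs give byte-identical outputs.

## The analysis pipeline

1. **AIM preselection.** Panel allele frequencies feed the informativeness
   for assignment, I_n = Σ_j [−p̄_j log p̄_j + Σ_i (p_ij/K) log p_ij], computed
   in nats for one population pair at a time (K = 2; the ranking is
   log-base-invariant, which is all that matters downstream). p̄_j is the
   unweighted average over subpopulations. Per comparison (Native American vs
   European, Native American vs African) the `top_k` SNPs are kept (ties
   broken by I_n descending then SNP id ascending) and the union retained.
2. **Supervised ancestry.** Per individual, the binomial likelihood
   Σ_i [g_i ln x_i + (2−g_i) ln(1−x_i)] with x_i = Σ_k q_k f_ik is maximised
   over the simplex with panel frequencies fixed (clipped to
   [1e−6, 1−1e−6]), by EM from the uniform start. The likelihood is concave
   in q, so no restarts are needed and the EM log-likelihood is monotone.
   Plain EM converges sublinearly when a component approaches zero, so the
   production path wraps the same EM map in squared-extrapolation cycles with
   a monotone guard (an extrapolated candidate is accepted only if it does not
   decrease the log-likelihood; the projection floor 1e−8 keeps coordinates
   off the absorbing zero face of the multiplicative update). The guarded
   accelerated fixed point agrees with long-run plain EM to <1e−3 in q on the
   test problems while being ~20× faster. Convergence: |Δ log L| < 1e−6
   (default), cap 2000 map evaluations; non-convergence is flagged, never
   hidden. Missing dosages are skipped per individual.
3. **Exposure scan.** Among controls only: OLS of q̂% on dosage plus age per
   SNP (batched closed-form normal equations, t-based two-sided p), threshold
   5×10⁻⁸.
4. **PheWAS exclusion** of any candidate with a confounder-phenotype catalog
   hit below 5×10⁻⁸.
5. **Explained variance and LD pruning.** Per SNP, β²·2·MAF·(1−MAF) with β on
   the 0–1 proportion scale of the exposure (per-allele percentage effect /
   100). Candidates are processed in explained-variance order; a SNP is kept
   iff its squared dosage correlation (composite LD, no phasing needed) with
   every retained SNP is ≤ 0.01, measured in the controls.
6. **Outcome scan.** Logistic regression of status on dosage plus age over
   cases + controls (vectorised Newton across SNPs; Wald normal p;
   quasi-complete separation flagged and dropped).
7. **Radial outlier exclusion.** With first-order weights
   w_j = (σ_Γj/γ_j)⁻², per-instrument contributions Q_j = w_j(β_j − β̂)² are
   tested against χ²₁; instruments with p < 0.1 are removed and the fit
   repeated to a fixed point (cap 20 rounds, stop at ≤ 3 instruments).
8. **Estimation.** Fixed-effect IVW (β̂ = Σw_jβ_j/Σw_j, se = (Σw)⁻½ — equal to
   the zero-intercept weighted regression slope), MR-Egger (weights σ_Γ⁻²,
   exposure effects oriented positive, t-based p with k−2 df), and the
   interpolated weighted median (SE by seeded parametric bootstrap,
   β_j* ~ N(β_j, w_j^−1/2), 1000 draws). Cochran's Q uses first-order weights.
   95% CIs are normal-approximation on the log-OR scale. A multiplicative
   random-effects switch exists but the fixed-effect estimate is the default.
9. **Reporting.** OR per 1% ancestry, percent risk decrease 100·(1−OR), and
   the interquartile risk difference (q75 − q25)·percent-decrease.
   Instrument strength is reported two ways: the cumulative
   F = ((n−k−1)/k)·(R²/(1−R²)) on the summed explained variance, and the mean
   per-instrument F computed on true per-SNP variance fractions
   ev_j/var(q̂) — the two conventions found in published instrument-strength
   tables. n is the control (exposure-sample) size.
10. **Strata.** The outcome arm (outcome scan → harmonisation → radial →
    estimators) is re-run on case subsets (diagnosis ≤ 45 y, familial,
    ER+/ER−, triple-negative) with all controls reused, so instrument counts
    may differ by stratum; strata under 30 cases are refused.

**Power.** For a binary outcome, with b = ln(OR per SD of exposure), r² the
variance explained by the instruments and K the case fraction,
z = |b|·√(n·r²·K(1−K)) and power = Φ(z − z₁₋α/₂) + Φ(−z − z₁₋α/₂). Validated
against a two-stage Monte-Carlo simulation (instrument score → exposure →
logistic disease; statsmodels fit) within 2 percentage points on a
three-point grid; the residual gap is the non-collapsibility attenuation of
the marginal logistic slope, below one point at the tested effect sizes.

## Scale of the explained variance

Summing marginal per-SNP R² values of ancestry instruments is only meaningful
on the raw proportion scale. Because every valid instrument correlates with
the same latent exposure, the *standardized* marginal R²_j (each 4–12% here)
sum to far more than 1 even when pairwise dosage r² is below the pruning
threshold — the shared exposure variance is counted once per instrument. On
the 0–1 proportion scale the summed contributions are small absolute
variances (a few percent), which matches the magnitudes such analyses print,
and the `instrument_strength` guard (error when the sum reaches 1) still
catches genuinely mis-scaled betas.

## What the validation studies show — and what they cannot

The replicate acceptance studies run the full flowchart on synthetic cohorts
and expose three structural properties of this design that users should know:

* **Same-sample selection (winner's curse).** Candidate instruments are
  thresholded at 5×10⁻⁸ in the same controls that supply the SNP–exposure
  estimates. Selected |γ̂| are therefore overestimated and the Wald ratios
  shrink toward the null: at 700 controls the mean IVW OR across replicate
  studies is ≈ 0.980 against a true 0.974; re-estimating γ on an independent
  sample removes most of the gap. At larger control samples (or with
  instruments far above the threshold) the effect fades.
* **Correlated instruments.** Instruments for a heritable global exposure are
  mutually correlated through that exposure (pairwise r at least the product
  of their exposure correlations, ~0.04–0.1 after pruning). The
  independent-instrument IVW standard error (Σw)⁻½ is then understated by
  roughly √(1+(k−1)r̄): nominal-95% CIs cover the truth in only ~70% of
  replicate studies, and the null rejection rate runs at ~9–16% instead of
  5%. Cochran's Q is simultaneously *deflated* (heterogeneity looks absent),
  so a large Q p-value is not reassurance here.
* **Iterative radial trimming.** Removing instruments at p < 0.1 and
  refitting to a fixed point is anticonservative even with independent
  instruments (measured ~8% null rejection vs 5.5% for plain IVW, which is
  calibrated).

Separately, the generator makes explicit a fundamental identification limit:
if the non-genetic risk factor U is *correlated with ancestry itself*
(`conf_anc_corr` ≠ 0), then every genotype-based instrument is correlated
with U through q, the MR estimand equals the confounded observational
estimand (shift β_conf·ρ/sd(q%) on the per-1% log-OR), and MR cannot remove
that confounding — meiosis randomizes alleles given parental ancestry, not
ancestry itself. What the instrument-based analysis *does* remove is
confounding that is independent of ancestry, and attenuation from exposure
measurement error. The validation suite therefore calibrates type-I error and
recovery under an ancestry-independent U, demonstrates the observational bias
under an ancestry-linked U, and documents that the MR and observational
biases coincide in the latter case.

## Problem sizes and defaults used in the shipped studies

Replicate studies use 700 cases / 700 controls over 5000 SNPs (parameter
recovery, 100 replicates; also the acceptance script's demonstration runs)
and 450/450 over 1200 SNPs (type-I calibration, 400 replicates); AIM
preselection keeps 400–800 markers per comparison at these genome sizes. The
planted-heterogeneity study uses 2000/2000 over 2500 SNPs with a two-process
ER model. These sizes are the package's chosen study conditions; per-SNP
counts at every stage are recorded in each report.

## Known limitations

* No haplotypes, local ancestry, genotyping error, relatedness, or X
  chromosome; unlinked SNPs by default.
* Sampling of cases/controls is unmatched random sampling from the pool.
* Supervised estimation only; reference panels are treated as correctly
  labelled and ancestrally appropriate.
* Fixed-effect IVW as primary; no MR-PRESSO, mode-based or multivariable
  estimators; no winner's-curse correction (deliberately: the workflow
  modelled here selects and estimates instruments in one control sample, and
  the validation quantifies what that costs).
* Composite (dosage-correlation) LD, not haplotype r².
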