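# Methods

## The causal model and its assumptions

The pipeline estimates the effect of a lipid trait *X* (HDL-c, LDL-c, TC or
TG) on binary disease status *D* using a genotype risk score *G* as an
instrument. The identifying assumptions are the usual instrumental-variable
triad: (1) *G* is associated with *X* (checked by the first-stage R²/F);
(2) *G* is independent of confounders of the *X*–*D* relationship (granted by
random allele assortment, threatened by population stratification — hence the
ancestry-PC adjustment of the second stage); (3) *G* affects *D* only through
*X* (no pleiotropy — probed by re-running with the trait-specific SNP sets).

Two estimators are provided. The **ratio (Wald) estimator** divides the
second-stage log OR per GRS SD by the first-stage slope (trait units per GRS
SD), giving the disease log OR per unit of trait. Its SE is the first-order
delta approximation with both stages' variances and zero covariance,

    se² = se₂²/β₁² + β₂²·se₁²/β₁⁴ ,

appropriate because the first stage is estimated in a separate (sub)sample
from the second. The **IVW estimator** pools per-SNP Wald ratios using
summary statistics only, with weights β₁ⱼ²/se₂ⱼ² (the trait-side SE is
ignored, standard first-order IVW); it is algebraically identical to
inverse-variance fixed-effects pooling of the per-SNP ratios with SEs
se₂ⱼ/|β₁ⱼ|, an identity the tests verify to 10⁻¹⁰.

**Instrument gate.** The ratio method is the headline estimator when the
first-stage R² ≥ 1.5% (inclusive, configurable); below the gate only the
summary-data IVW is reported. The gate reflects the finding that subsample
instruments lose little power down to roughly that strength.

## Key parameters

| parameter | default | units / meaning |
|---|---|---|
| `trait_r2_target` | 0.018–0.043 per trait | fraction of trait variance explained by the full score (the observed full-score instrument strengths) |
| `gate_threshold` | 0.015 | first-stage R² below which the ratio method is not headline |
| `max_missing` | 0.05 | per-score missing-SNP fraction at which an individual is excluded (inclusive) |
| `confounder_effect_trait/disease` | 0.3 / 0.3 | loadings of the shared standard-normal confounder *U* |
| `causal_log_or_per_unit` | 0 | generating causal effect; 0 is the null architecture |
| `base_prevalence` | 0.30 | marginal disease probability of the simulated base population (ascertainment efficiency, not an epidemiological claim) |
| unit conversions | ×38.67, ×88.57 | mmol/l → mg/dl for cholesterol fractions and TG |

## The synthetic-data generator

Genotypes are independent autosomal SNPs drawn binomial(2, f) under
Hardy–Weinberg with minor-allele frequencies uniform on the configured range;
there is no LD, no imputation-dosage uncertainty and no X chromosome. Each
trait is

    X = Σⱼ effⱼ·gⱼ (centred) + c·U + σ·ε ,

where the per-trait effect magnitudes are rescaled analytically so that
Var(Σ eff·g) under HWE equals `trait_r2_target` — no iterative calibration —
and σ is set so Var(X) = 1. The risk-direction convention is built in: the
risk allele raises LDL/TC/TG and lowers HDL, so HDL's signed effects are
negative while the weights table stores positive magnitudes. Disease
liability is

    logit P(D=1) = α + Σₜ θₜ·Xₜ + c_d·U + Σⱼ πⱼ·gⱼ ,

with θ the causal effects, π optional direct (pleiotropic) SNP effects, and
*U* the single shared confounder — the simplest structure that biases the
naive X–D regression while leaving the IV consistent. Cases and screened
controls are accumulated by rejection sampling from unconditional draws
(bounded by `max_oversample`; exceeding it raises a sampling error);
population controls and MCI individuals are drawn unconditionally. Serum
lipids in mmol/l are generated from the latent trait with affine age/sex
structure (log-scale for TG, so it is right-skewed and strictly positive) and
recorded only for the designated subset of the lipid cohort. Genotype
missingness is completely at random; the weights-table SNP overlap is built
greedily so that every shared SNP serves the two traits with the largest
remaining overlap quota (plus others at random), which reproduces the
full-set overlap / specific-set disjointness structure of published lipid
loci.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: linkage disequilibrium between instruments, weight
estimation error correlated with the analysis sample (winner's curse),
population stratification, genotyping batch effects correlated with status,
selection on survival, and medication-induced lipid changes. Tests on this
generator validate the *estimators*, not the robustness of MR to violated
assumptions. One structural difference worth noting: because specific-set
SNPs draw their effect magnitudes from the same distribution as shared SNPs,
the simulated trait-specific scores retain a proportionate share of the
full-score R² (e.g. ~1–3%), whereas the observed trait-specific instruments
were far weaker (≤0.5%); the instrument gate is still exercised on both
sides of the threshold at the default settings.

## Numerical and procedural choices

- **Rank inverse-normal transform** uses Blom offsets Φ⁻¹((r−0.375)/(n+0.25))
  with average ranks for ties, fit within the measured-lipid subset only
  (never across cohorts, avoiding rank leakage); MCI individuals are ranked
  together with cases and controls. Constant input is an error.
- **GRS standardization** is within cohort over included individuals;
  exclusion at ≥5% missing SNPs is applied per score, so one person can be
  excluded for TG but kept for HDL. Missing dosages shrink the denominator
  (score per non-missing SNP) rather than being mean-imputed. Fractional
  dosages in [0,2] are accepted (imputed genotypes).
- **Logistic fits** go through statsmodels maximum likelihood; perfect
  separation, non-convergence and unstable SEs raise loudly (no penalized
  fallback). Singular covariate matrices raise naming the offending column.
  Monomorphic SNPs in per-SNP scans are flagged with a reason, never dropped.
- **Meta-analysis**: I² is truncated at zero; CI→SE reconstruction assumes a
  symmetric log-scale 95% interval (÷3.92) and warns when the printed point
  estimate is >0.02 off the interval midpoint on the log scale.
- **Delta-SE validity**: the first-order delta SE agrees with Monte-Carlo
  error propagation to within ~1% when se₁/β₁ ≈ 0.08 and drifts below the
  Monte-Carlo SD by ~2–3% as se₁/β₁ approaches 0.12–0.2 (second-order ratio
  variance terms); the tests pin the 2% agreement in the strong-instrument
  regime.
- **Expected-OR chaining** uses exp(ln OR_a · ln OR_b), with CI bounds
  combined lower×lower / upper×upper on the log-product scale; this is the
  form that reproduces all six published worked values to ±0.01.
- **Power** uses the unmatched case-control normal approximation
  z = |ln OR|·√(n·φ(1−φ)); the simulation mode draws the standardized
  predictor as N(0,1) in controls and N(ln OR, 1) in cases (the retrospective
  representation of the same logistic law) and fits every replicate with a
  vectorised two-parameter Newton solver, cross-checked against statsmodels.
- **Seeding**: all randomness derives from one integer seed through named
  SeedSequence substreams (weights; one per cohort), so per-module reruns and
  full-pipeline reruns are byte-identical.

## Replicate-suite design (problem sizes)

The calibration suite runs 1,000 single-cohort null replicates (1,000 cases /
1,000 controls, measured-lipid subset ≈ 3,500 including MCI, first-stage
R² = 4%) and checks that the ratio-IV 95% CI covers zero 95% ± 2% of the
time; the subset size keeps se₁/β₁ ≈ 0.08, where the delta CI is close to
nominal (it becomes conservative for weaker first stages). The recovery
suite runs 200 replicates per causal value (0, 0.1, 0.25 log OR per unit) at
10,000 cases / 10,000 controls with a ≈6,500-person measured subset, sized so
the Monte-Carlo SE of the median (≈0.007) is well below the 10% recovery
band; each arm uses its own disjoint seed block. The observed median at
causal 0.25 sits ~5% below truth — real, and expected: marginalizing a
logistic model over the unexplained liability (trait noise and the shared
confounder) attenuates the second-stage log OR (non-collapsibility), a
property of the estimand that the tolerance accommodates.

## Known limitations

- The ratio and IVW estimators inherit logistic non-collapsibility: estimates
  are slightly attenuated toward the null relative to the conditional causal
  parameter, increasingly so for larger effects.
- The first stage is fit in an ascertained (case-control plus MCI) subset;
  under strong causal effects this can mildly distort the trait–GRS slope.
- No MR-Egger, weighted-median or other pleiotropy-robust estimators; the
  trait-specific score is the only pleiotropy probe.
- Printed-table pooling is reproducible only to the rounding of the published
  ORs and CIs (tolerance ±0.005 on the pooled OR).
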