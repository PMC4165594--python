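# lipidmr

A tested, reusable Mendelian-randomization (MR) pipeline for asking whether
genetically raised blood lipid levels — HDL-c, LDL-c, total cholesterol (TC)
and triglycerides (TG) — causally affect the risk of late-onset Alzheimer
disease (LOAD), built for epidemiologists and statistical geneticists who want
the classic allele-score IV workflow as composable, unit-tested functions
rather than a one-off analysis script.

## What it computes

Genetic variants are randomized at meiosis, so a genotype risk score (GRS)
built from lipid-associated SNPs is an instrument for lifetime lipid exposure
that is free of the confounding and reverse causation that plague
observational lipid–dementia studies. The pipeline implements:

- **Weighted genotype risk scores.** For individual *i* with risk-allele
  dosages *g<sub>ij</sub>* and external GWAS weights *β<sub>j</sub>*,

  GRS<sub>i</sub> = Σ<sub>j</sub> β<sub>j</sub> g<sub>ij</sub> / (number of non-missing SNPs for *i*),

  standardized within cohort; individuals missing ≥5% of a score's SNPs are
  excluded from that score. One *full* score per trait (all SNPs associated
  with the trait) and one *trait-specific* score (SNPs associated with that
  trait only, a pleiotropy guard).
- **Lipid phenotype preparation**: mmol/l → mg/dl conversion (×38.67
  cholesterol fractions, ×88.57 TG), OLS residualization on age, age² and sex,
  then rank-based inverse-normal transformation (Blom offsets).
- **Two-stage estimation.** First stage: OLS of the transformed lipid on the
  GRS, with R² and F(1, n−2) as instrument strength. Second stage: logistic
  regression of case status on the GRS adjusting for ancestry PCs (and batch
  / optional age, sex, APOE ε4).
- **Causal estimators.** The ratio (Wald) IV estimate β̂₂/β̂₁ — disease log OR
  per 1 unit of lipid trait — with the first-order delta-method SE
  √(se₂²/β₁² + β₂²se₁²/β₁⁴), used when first-stage R² ≥ 1.5%; and the
  summary-data inverse-variance weighted (IVW) estimator
  Σβ₁ⱼβ₂ⱼ/se₂ⱼ² ⁄ Σβ₁ⱼ²/se₂ⱼ² for weak-instrument (trait-specific) scores.
- **Meta-analysis.** Inverse-variance fixed-effects pooling across cohorts
  with Cochran's Q and I², a DerSimonian–Laird random-effects check, and
  SE reconstruction from printed OR (95% CI) rows.
- **Design calculators.** The expected GRS→disease OR from chaining a
  GRS→high-TC association with a published high-TC→dementia association,
  exp(ln OR<sub>a</sub> · ln OR<sub>b</sub>), and analytic/simulation power for a
  standardized-score logistic test.
- **A synthetic-cohort generator** with known causal truth (additive SNP
  effects, a shared confounder, optional pleiotropy, case-control
  ascertainment by rejection sampling) used to validate calibration and
  parameter recovery of the whole pipeline.

## Worked example

```python
import lipidmr as L

# a two-cohort synthetic study: TC causally raises disease risk
cfg = L.RunConfig(
    outdir="demo_out",
    simulation=L.SimulationConfig(
        n_snps_full={"HDL": 8, "LDL": 6, "TC": 8, "TG": 5},
        n_snps_specific={"HDL": 4, "LDL": 2, "TC": 2, "TG": 2},
        trait_r2_target=0.04,
        causal_log_or_per_unit={"HDL": 0.0, "LDL": 0.0, "TC": 0.25, "TG": 0.0},
        cohort_sizes=[(400, 300, 200), (300, 250, 0)],
        cohort_names=("A", "B"),
        lipid_cohort=1, n_mci=60,
    ),
    seed=11,
)
summary = L.run(cfg)
tc = summary["traits"]["TC"]["full"]
print(tc["first_stage_r2"], tc["headline_method"], tc["meta"]["iv_ratio"])
```

prints

```
0.016934974757990773 ratio {'or': 1.0473, 'ci': [0.4513, 2.4301], 'p': 0.9143428474220352, 'i_squared': 0.0}
```

i.e. in this (deliberately tiny) demo the realized full-TC first stage lands
at R² 1.7%, just above the 1.5% gate, so the individual-level ratio method is
the headline estimator; the pooled causal estimate is OR 1.05 per unit of
trait with a wide CI (0.45–2.43) that covers both the null and the generating
truth e^0.25 ≈ 1.28 — at demo sample sizes the instrument simply carries
little information, which is exactly what the acceptance-scale replicate
suites quantify.
`demo_out/` then contains `stages.tsv`, `iv.tsv`, `meta.tsv`, `summary.json`,
the echoed config and a log with every exclusion count.

The same steps are available from the shell:

```bash
lipidmr simulate --config sim.yaml --out data/ --seed 11
lipidmr score --dosages data/A/dosages.raw --weights data/weights.csv \
              --trait TC --set full --out scores.tsv
lipidmr design expected-or --or-a 1.679 --ci-a 1.35,2.10 --or-b 1.42 --ci-b 1.22,1.66
lipidmr design power --cases 3914 --controls 6664 --or 1.19
lipidmr run --config run.yaml --seed 11
```

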