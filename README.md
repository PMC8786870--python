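# depgrs

Unweighted genetic-risk-score (GRS) analysis of depression in a
case-control primary-care cohort, with a gene–environment (GRS × BMI)
interaction.

## The problem

Depression risk is polygenic: many common variants each shift the odds a
little, and no single SNP is a useful predictor. One pragmatic way to
aggregate them — especially when robust per-SNP effect estimates are not
available for weighting — is the *unweighted* GRS: for each subject,
count the risk alleles over a curated SNP panel,

```
GRS_i = Σ_j g*_ij ,   g*_ij ∈ {0, 1, 2}
```

where `g*_ij` is the dosage of SNP *j* oriented to its risk allele
(protective-oriented SNPs are flipped, `g → 2 − g`). The score then
enters nested logistic models of case status together with demographic
covariates and body-mass index (BMI), including a model with a
GRS × BMI product term that lets adiposity amplify the genetic risk:

```
Model 1: sex + age + province
Model 2: sex + age + province + BMI
Model 3: sex + age + province + GRS
Model 4: sex + age + province + GRS + BMI
Model 5: sex + age + province + GRS + BMI + GRS×BMI
```

Model improvement is quantified by ΔAUC (paired DeLong test), the
integrated discrimination improvement (IDI), the categorical net
reclassification improvement (NRI, risk categories <5%, 5–<25%, ≥25%)
and its category-free variant (cfNRI), in-sample and under stratified
5-fold cross-validation.

The package implements the full chain as a library plus thin drivers:

1. **synthetic cohort** (`depgrs.simulate`) — genotypes under
   Hardy–Weinberg proportions with optional LD blocks (Gaussian-copula
   coupling calibrated to a target dosage correlation), covariates, and
   outcomes from a logistic model with per-allele and interaction
   effects;
2. **genotype QC** (`depgrs.qc`) — underweight exclusion (BMI ≤ 18.5),
   call rate ≥ 95%, MAF ≥ 0.05, an exact Hardy–Weinberg test applied in
   controls, greedy LD pruning at R² > 0.8;
3. **GRS construction** (`depgrs.grs`) — keep SNPs whose fitted
   association sign in the sample agrees with the literature direction
   (significance not required), orient to risk, sum, complete cases
   only, quartile labels;
4. **association models** (`depgrs.models`) — per-SNP additive scans
   with Benjamini–Hochberg FDR, GRS and quartile-contrast models,
   the interaction model, effect sizes (Cohen's d, Cramér's V), and a
   closed-form power approximation for logistic regression;
5. **prediction metrics** (`depgrs.metrics`) — DeLong AUC/CIs and the
   reclassification metrics above;
6. **orchestration** (`depgrs.pipeline`, `depgrs.cli`) — TSV/CSV/VCF
   dialects, a YAML-configured `run_all`, and a `depgrs` console script
   with `simulate / qc / build-grs / associate / evaluate / all`
   subcommands.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort shaped like the emulated design: 1650 adults from 7
sites, ~6.3% depression cases, a 56-SNP candidate panel of which ~46%
carry effects whose sign contradicts the literature.

```bash
python analysis/01_simulate.py
python analysis/02_qc.py
python analysis/03_build_grs.py
python analysis/04_associate.py
python analysis/05_evaluate.py
python analysis/06_calibration.py
```

With the default seed this prints, among other things:

```
56 -> 54 SNPs; 1650 -> 1650 subjects
concordant SNPs: 28 of 54; GRS computed for 1650 subjects (0 dropped by the complete-case rule)
GRS mean (SD): cases 31.35 (3.72), controls 29.44 (3.14); Cohen's d = 0.60 (mann_whitney, p = 1.78e-07)
per-allele GRS effect (Model 4): OR = 1.21 [1.13, 1.29], p = 4.88e-09; D^2 = 0.0509
GRS x BMI interaction (Model 5): OR = 1.091 [1.072, 1.110], p = 7.84e-22
  Model 1: AUC = 0.560 [0.505, 0.616], D^2 = 0.0058
  Model 3: AUC = 0.663 [0.601, 0.725], D^2 = 0.0509
  Model 5: AUC = 0.821 [0.781, 0.861], D^2 = 0.1841
```

Reading this: two markers fail Hardy–Weinberg QC in controls; the
concordance screen keeps 28 of 54 surviving SNPs (26 of the 56 were
simulated discordant); cases carry about two more risk alleles than
controls (d ≈ 0.6); each additional risk allele multiplies the odds of
depression by ~1.2 after adjustment; the interaction term is strongly
positive, and the model ladder shows the characteristic pattern — BMI
alone adds nothing (Model 1 → 2), the GRS adds discrimination
(Model 1 → 3), and the interaction adds the most (Model 4 → 5). The
tables behind these lines land under `results/study/`.

`analysis/06_calibration.py` re-runs the simulation many times and
checks that the fitted models recover the generative odds ratios
(per-allele 1.35, interaction 1.14) with near-nominal confidence-interval
coverage, and that the interaction Wald test holds its 5% size under the
no-interaction null.

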