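# linkedscore

A Python toolkit for a **linked primary/secondary-care comorbidity
score**: an integer index of chronic disease burden built from UK
primary-care Read codes and hospital ICD-10 codes together, designed to
predict all-cause mortality and to adjust survival analyses for
confounding by coexisting illness.

The package has two faces:

* **Scoring.** Apply the published category weight table (transcribed
  from the source study) to coded patient histories.  Each category
  enters a patient's score once, with the highest applicable weight:
  the Read/combined weight when the condition was coded in primary
  care, an ICD-specific weight when hospital coding carries extra
  prognostic signal (11 of the 36 categories), the higher of the two
  when both are present.
* **Derivation and validation.** The full pipeline that produces such a
  table from a linked cohort: an age/sex-adjusted Cox proportional-
  hazards fit for *every* diagnostic code, re-estimation of those
  hazard ratios in a three-level Bayesian hierarchy over the coding
  hierarchies (codes within mapped Read subchapters within chapters,
  with a Normal(0, 1000&sup2;) top-level prior on the log scale),
  selection of codes whose 99% credible interval — or their group's —
  lies above hazard ratio 1.2, category building across the ICD→Read
  subchapter mapping, a multivariable Cox weighting model with separate
  per-source terms (combined when a Wald test finds no difference at
  p ≥ 0.005), and integer weights w = round(10·β).  Validation covers
  Harrell's C with jackknife (Somers'-D style) confidence intervals,
  AIC, bootstrap optimism of the whole model-building process,
  age/consultation/follow-up/deprivation strata, and condition
  adjustment analyses with a 60-day time split.

Because the original linked data (CPRD–HES–ONS) is access-restricted,
the package ships a seeded **synthetic linked-cohort generator** with
known true effects: two hierarchical terminologies joined by a
subchapter mapping, age-dependent code prevalence, subchapter-clustered
true log hazard ratios, ~3.3% first-year mortality, transfer-out
censoring, and admission/consultation processes.  Every pipeline stage
is tested against this generator's truth.

## The model

For patient *i* with exposure indicators *x<sub>ic</sub>* (code *c*
recorded before the cutoff, two calendar months before the index date),
the derivation screens each code with

&nbsp;&nbsp;&nbsp;&nbsp;h(t | x<sub>ic</sub>, age, sex) = h₀(t) · exp(β<sub>c</sub> x<sub>ic</sub> + β<sub>a</sub>·age + β<sub>s</sub>·sex),

then shrinks the estimates y<sub>c</sub> (with standard errors s<sub>c</sub>) in

&nbsp;&nbsp;&nbsp;&nbsp;y<sub>c</sub> ~ N(θ<sub>c</sub>, s<sub>c</sub>²), &nbsp; θ<sub>c</sub> ~ N(μ<sub>sub(c)</sub>, σ²<sub>code</sub>), &nbsp; μ<sub>sub</sub> ~ N(μ<sub>chap(sub)</sub>, σ²<sub>sub</sub>), &nbsp; μ<sub>chap</sub> ~ N(0, 1000²),

sampled by a collapsed Gibbs sampler (conjugate means; slice-sampled
Half-Normal(1) scales) with split-R-hat convergence checks.  The final
weights come from one multivariable Cox fit over all selected
categories, adjusted for age, sex and recent hospitalisation.

## Worked example

```python
import pandas as pd
from linkedscore import published_weight_table
from linkedscore.scorer import score_patient

table = published_weight_table()
print(f"categories: {len(table.categories)}, dual-weight: {table.n_dual_weight}, "
      f"max weight: {table.max_weight}")

history = pd.DataFrame({
    "patient_id": [1, 1, 1],
    "code": ["E00..", "F00", "J61.."],          # dementia (Read), dementia (ICD-10), cirrhosis (Read)
    "terminology": ["READ", "ICD10", "READ"],
})
s = score_patient(history, table, cap=20)
print(f"total: {s.total}, capped: {s.capped}")
for cat, (w, src) in s.contributions.items():
    print(f"  {cat}: weight {w} (from {src})")
```

prints

```
categories: 36, dual-weight: 11, max weight: 29
total: 12, capped: False
  Dementia: weight 7 (from icd)
  Cirrhosis: weight 5 (from read)
```

Dementia is coded in both settings, so it contributes once with the
higher (hospital) weight, 7 rather than 4; cirrhosis adds its combined
weight 5; the total 12 is under the cap of 20.  The category labels and
weights are the published ones; the packaged member code lists are
synthetic stand-ins in the published CSV layout (the original
supplementary lists are not redistributed), so real-data use should
substitute full code lists via `linkedscore.scorer.load_weight_table`.

A full synthetic derivation from the command line:

```bash
linkedscore pipeline --out runs/demo --seed 1
```

writes `patients.csv`, `estimates.csv` (per-code hazard ratios),
`posterior.csv` (shrunk estimates with 99% intervals), `weights.csv`
(the derived integer weight table), `scores.csv`, and `report.yaml`
(validation-half Harrell's C), plus a manifest that makes reruns
byte-identical.

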