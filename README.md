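# elastoconcord

Concordance, applicability and reliability analysis of liver elastography
devices against serum biomarker references.

## The problem

Liver fibrosis can be staged non-invasively either by elastography —
two-dimensional shear wave elastography (2D-SWE, stiffness imaged in a
region of interest, range 0–300 kPa) or transient elastography with the M
or XL probe (TE-M / TE-XL, single-location stiffness, range 0–75 kPa) — or
by serum biomarker scores on [0, 1]: FibroTest (fibrosis stage F0–F4),
ActiTest (necro-inflammatory activity A0–A3) and SteatoTest (steatosis
S0–S4). Comparing devices fairly raises questions this package answers for
hepatology methodologists and biostatisticians:

* **Applicability** — how often does each test fail or return a
  not-reliable result (TE: IQR/M ≥ 0.30, fewer than 10 valid shots or
  success rate < 60%; 2D-SWE: minimal region-of-interest signal below
  0.2 kPa), and are the applicability rates different?
* **Reliability screening** — with no histological gold standard, can the
  *strength of concordance between two imperfect references* identify
  quality criteria? A genuine reliability factor should destroy the
  concordance of the affected subgroup only.
* **Inflammation/steatosis impact** — how much do activity and steatosis
  inflate stiffness independently of fibrosis, per device?
* **Intention-to-diagnose** — how do diagnostic performances change when
  failed measurements are retained with the worst-case value
  1 − FibroTest substituted, instead of being discarded?

Because no patient-level data are deposited for this design, the package
ships a synthetic cohort generator with known ground truth; every analysis
is validated by parameter recovery against that truth.

## Core statistics

Elasticity `E` (kPa) is standardized to the unit interval before any
comparison with blood scores:

    s(E) = log10(clamp(E, 1, 75)) / log10(75)

Agreement between a standardized elasticity vector and a reference score is
the Lin concordance correlation coefficient,

    CCC = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²),

with a Fisher-z confidence interval using Lin's asymptotic variance.
Curve fits are ordinary least squares and a continuous three-part
piecewise-linear regression with two grid-searched breakpoints, compared by
R². Diagnostic accuracy uses the nonparametric (Mann–Whitney) AUROC with
DeLong variance and the paired placement-value comparison for correlated
curves; proportions carry Wilson score intervals and pooled two-proportion
z-tests.

## Worked example

```python
from elastoconcord import *

cfg = GeneratorConfig(n=2251, seed=1)              # study-like scenario
frame = add_standardized_columns(apply_applicability(generate_frame(cfg)))
pops = derive_populations(frame)
print({k.value: len(v) for k, v in pops.items()})
```

```
{'INVESTIGATED': 2251, 'INTENTION_TO_DIAGNOSE': 2236, 'SWE_RELIABILITY': 1733,
 'CONCORDANCE': 1604, 'CONCORDANCE_ST': 1290, 'NOT_APPLICABLE': 632}
```

The populations nest: everyone investigated; intention-to-diagnose drops
not-reliable FibroTests; the 2D-SWE reliability population needs both TE
probes and FibroTest applicable and a present 2D-SWE signal; the
concordance population additionally drops not-reliable 2D-SWE results.

Screening the minimal-elasticity quality criterion on the reliability
population:

```python
rel = frame[frame["id"].isin(pops[PopulationLabel.SWE_RELIABILITY])]
rep = screen_criterion(rel, Criterion.MIN_ELASTICITY)
print(rep.grid[rep.grid.reference == "fibrotest"])
print("discriminant:", rep.discriminant, "flagged:", rep.flagged_bins)
```

```
    bin reference  estimate    ci_low  ci_high   n
   <0.2 fibrotest  0.099093 -0.027962 0.222998 129
0.2-0.5 fibrotest  0.365050  0.318102 0.410211 395
  0.5-1 fibrotest  0.525273  0.478368 0.569189 364
    >=1 fibrotest  0.631168  0.605775 0.655276 845
discriminant: True flagged: ('<0.2',)
```

Only the < 0.2 kPa bin's concordance interval contains zero — those maps
carry no fibrosis information (the generator's planted "dead signal"
subgroup), so a minimal signal below 0.2 kPa marks a not-reliable result,
while the criterion separates reliable from unreliable maps cleanly.

Inflammation impact, stratified by fibrosis severity:

```python
conc = frame[frame["id"].isin(pops[PopulationLabel.CONCORDANCE])]
scheme = StratificationScheme(StratVariable.FIBROSIS, (0.58,), ("F0F1F2", "F3F4"))
print(stratified_ccc_table(conc, list(Device), "actitest", scheme))

res = compare_ccc_paired(conc[conc.fibrotest < 0.58],
                         Device.TE_M, Device.SWE, "actitest",
                         n_boot=2000, seed=1)
print(f"TE-M − SWE: {res.difference:.3f} [{res.ci_low:.3f};{res.ci_high:.3f}] p={res.p_value:.4f}")
```

```
stratum    n  swe_ccc  te_m_ccc  te_xl_ccc
   F3F4  401    0.151     0.161      0.204
 F0F1F2 1203    0.042     0.096      0.080
TE-M − SWE: 0.054 [0.033;0.072] p=0.0000
```

Within non-advanced fibrosis, stiffness measured by the M probe tracks
activity significantly more than 2D-SWE stiffness does (CCC 0.096 vs
0.042) — the generator's planted device contrast, recovered by the paired
bootstrap.

The same pipeline runs from a shell:

```bash
elastoconcord simulate --n 2251 --seed 1 --out cohort.csv
elastoconcord applicability cohort.csv
elastoconcord run --config pipeline.yaml     # full TSV report bundle
```

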