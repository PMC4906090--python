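# prrtdose

Internal dosimetry for preclinical Lu-177 radioligand therapy studies — from
per-organ time–activity data to MIRD-schema absorbed doses, with a
study-shaped synthetic data generator so every stage is testable without any
imaging data.

## The problem

Peptide receptor radionuclide therapy (PRRT) delivers a beta-emitting
radionuclide (here ¹⁷⁷Lu, half-life 6.647 d) to somatostatin-receptor-positive
tumours via a peptide vector such as the antagonist OPS201. Before human
dose escalation, preclinical biodistribution studies (e.g. in pigs, whose
physiology resembles ours) must establish that the absorbed doses to normal
organs stay below toxicity limits — 23 Gy cumulative dose for the kidneys,
the critical organ.

The measurement chain is standard: serial SPECT/CT and whole-body scans give
the fraction of injected activity (IA) in each organ over ~10 days; serial
blood samples give the early clearance kinetics; urine collection gives the
excreted fraction. This package implements everything downstream of those
measurements:

1. **Kinetics** — each decay-corrected organ curve is fitted with a sum of
   exponentials, `y(t) = Σᵢ Aᵢ e^(−λᵢt)` (Aᵢ, λᵢ ≥ 0), the number of terms
   chosen by the corrected Akaike criterion (AICc). The **time-integrated
   activity coefficient** (TIAC, in hours) re-adds physical decay
   analytically,

   `TIAC = Σᵢ Aᵢ / (λᵢ + λ_phys)`,

   with its standard error by first-order propagation of the fit covariance
   plus a 10% systematic quantification error in quadrature. Bladder
   contents, which fill and void rather than wash out, are integrated by
   trapezoids with a physical-decay tail after the last sample.
2. **Organ accounting** — first-scan whole-body normalization to 100%,
   left + right kidney summation, bone from the spine VOI (spine = 19% of
   skeleton mass), remainder of body = whole body − all source organs, and a
   blood-surrogate red-marrow estimate
   (`TIAC_marrow = TIAC_blood,conc · m_marrow · RMECFF/(1 − hematocrit)`).
3. **Dosimetry** — the MIRD schema
   `D(target) = Σ_sources TIAC(source) · S(target ← source)`
   against a pluggable phantom S-value table (CSV), including the
   mass-weighted remainder-of-body S-value; scaling to an administered
   activity; cohort mean ± SD; toxicity margins.
4. **Synthetic data** — a generator reproducing the study's structure:
   biexponential blood clearance (T½α = 2.0 min carrying 80.1% of the
   clearance, T½β = 36 min), organ uptake–washout curves calibrated to the
   study's cohort-mean TIACs, 23.4% urinary excretion by 4 h, the exact
   sampling/imaging schedules, and multiplicative lognormal noise.

The per-subject TIACs and dose coefficients of the five-pig ¹⁷⁷Lu-OPS201
study are shipped as fixtures (`prrtdose.study`) and anchor the regression
tests.

## Worked example

Cohort statistics and human extrapolation from the study's per-subject dose
coefficients (`python examples/04_dose_report.py`):

```
cohort dose coefficients (mGy/MBq, mean +- SD, n = 5):
  kidneys                   2.730 +- 1.034
  osteogenic_cells          0.789 +- 0.532
  urinary_bladder_wall      0.355 +- 0.449
  liver                     0.203 +- 0.055

predicted human doses for 5 GBq administered:
  kidneys                13.7 Gy
  osteogenic_cells       3.9 Gy

kidney toxicity check: 13.7 Gy vs 23.0 Gy limit -> pass (margin 9.3 Gy)
```

The kidneys receive the highest dose; at a therapeutic 5 GBq administration
the predicted 13.7 Gy leaves a 9.3 Gy margin below the 23 Gy toxicity limit.
The one subject without the nephroprotective amino-acid infusion roughly
doubled its kidney dose and is deliberately kept in the mean (a conservative
choice); excluding it drops the cohort mean to 2.30 mGy/MBq.

Blood kinetics recovery on synthetic data
(`python examples/02_blood_kinetics.py`):

```
recovered T1/2 alpha: 2.05 min (true 2.0)
recovered T1/2 beta:  36.7 min (true 36)
alpha-phase fraction: 0.811 (true 0.801)
```

The other examples simulate a full cohort (`01`) and walk one subject from
raw curves to a complete source-organ TIAC set (`03`). The same pipeline is
scriptable from the shell:

```bash
prrtdose run --n 5 --seed 1 --activity 5000 -o out/
prrtdose simulate --n 5 --seed 1 -o tacs.csv
prrtdose fit-tiac -i tacs.csv -o tiacs.csv
```

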