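# Methods

## Conventions

All times are hours post-injection; all activities are fractions of
injected activity (blood: fraction per litre). Measured values exist in two
decay conventions — *uncorrected* (physical decay included, as a counter
reads them) and *decay-corrected* to injection time (biology only) — and
every time series carries an explicit flag. Fitting always happens on
decay-corrected data; the ¹⁷⁷Lu physical decay constant
(λ_phys = ln 2 / 159.528 h ≈ 4.345 × 10⁻³ h⁻¹) is re-added analytically at
integration. This separation keeps the fitted rates purely biological and
makes organ TIACs finite even without biological clearance, with the hard
upper bound TIAC ≤ peak fraction / λ_phys (230.15 h for a region holding
the whole injected activity).

## Curve fitting and model selection

Organ and blood curves are fitted with sums of decaying exponentials under
non-negativity bounds, by weighted least squares
(`scipy.optimize.least_squares`, trust-region reflective). The default
weighting is 1/y² (constant fractional error), matching gamma-counting
practice where the standard deviation scales with the signal; uniform and
1/y weightings are selectable. Multistart initialization (default 20
starts; one deterministic log-spaced rate grid spanning the sampled time
range, the rest seeded random) with amplitudes initialized by non-negative
linear least squares at fixed rates makes the fit reproducible and robust
to the strong nonconvexity of exponential sums. Terms are reported in
canonical order (fastest first), so the fit is invariant under relabeling.

The number of terms (1–3) is chosen by AICc,
`N ln(SSR_w/N) + 2K + 2K(K+1)/(N−K−1)` with K = free parameters + 1.
Candidates whose small-sample correction is undefined (N − K − 1 ≤ 0)
receive an infinite AICc; when every candidate is in that regime (very
short series) the fittable model with the fewest terms is used, so a
three-point curve gets a single exponential. Ties break toward fewer terms.

Parameter covariance comes from the weighted Jacobian at the optimum,
C = (JᵀJ)⁻¹ s² with s² = SSR_w/(N − P) (pseudo-inverse for near-singular
fits). The TIAC standard error is first-order propagation, √(gᵀCg), with
g the gradient of Σᵢ Aᵢ/(λᵢ + λ_phys); a parametric-bootstrap oracle in the
test suite confirms this within 15% on the study's blood schedule. A
systematic activity-quantification error (default 10% of the value) is then
added in quadrature, once — double application is rejected.

Bladder contents follow a filling-and-voiding pattern outside the
exponential-sum family, so they are integrated non-parametrically on the
uncorrected curve: a linear rise from (0, 0) to the first sample,
trapezoids across samples, and a pure physical-decay tail
(last value / λ_phys) after the last sample. Its uncertainty is the
systematic term alone. The method can be reassigned per organ.

## Organ accounting

- **Normalization**: the study's quantification convention sets the first
  whole-body scan to 100%; all regions are rescaled by the same factor.
  Idempotent. Note the operation inflates true fractional values whenever
  activity has already been excreted before the first scan (~15% at the
  default schedule); this mirrors the real protocol, where the scanner
  cannot see voided urine.
- **Kidneys**: left + right values add; standard errors add in quadrature.
- **Bone**: the spine VOI is taken to contain 19% of the skeleton mass, so
  bone = spine / 0.19 (fraction configurable); the spine TIAC itself is
  retained for reporting.
- **Remainder of body**: whole body minus the six explicit source organs
  (liver, kidneys, heart, bladder contents, bone, red marrow). This
  composition was validated numerically against the study's remainder
  column (all five subjects within rounding) rather than taken from a
  stated formula. Negative reconstructions are clipped to zero with a
  warning.
- **Red marrow** (blood surrogate): marrow activity concentration is the
  blood concentration scaled by RMECFF/(1 − hematocrit) with defaults
  0.19/0.59 ≈ 0.322, times a marrow mass (default 0.9 kg at unit density).
  The study does not print its constants, so its red-marrow TIACs are not
  exactly reproducible; the defaults land inside the study's observed
  0.01–0.22 h span.

## Dose engine

MIRD schema over a pluggable S-value table (CSV: targets × sources,
mGy per MBq·h, plus a region–mass sidecar). The remainder source uses the
standard mass-weighted adjustment
`S(t←RoB) = [S(t←TB)·m_TB − Σ S(t←k)·m_k]/m_RoB`, floored at zero. Doses
are linear in the TIACs; with a diagonal matrix the engine reduces to
elementwise multiplication — both properties are exercised as oracles. The
shipped phantom table (`data/toy_s_matrix.csv`) is synthetic: hand-set
values at physically plausible magnitudes (self-dose ≈ mean beta energy per
unit mass, small photon cross terms, a consistent total-body column), built
for testing, not for clinical use. Human predictions scale the cohort-mean
coefficients by the administered activity (5 GBq default) and are reported
at 3 significant figures at or above 10 Gy, 2 below. The toxicity check is
boundary-inclusive (dose = limit fails) against a configurable limit table
(default: kidneys 23 Gy). The subject without amino-acid infusion stays in
cohort means by default (conservative); exclusion is an explicit flag.
Inter-species mass scaling is deliberately not performed.

## Synthetic data generator

The generator emulates the study's measured *structure*, with defaults
equal to the study's stated conditions:

| parameter | default | origin |
| --- | --- | --- |
| blood T½α, fα, T½β | 2.0 min, 0.801, 36 min | reported blood fit |
| blood intercept c₀ | 20 %IA/L | not reported; chosen so the model obeys the < 5 %IA/L bound at 10 min |
| urinary excretion | 23.4% by 4 h, half-time 0.6 h | reported excretion; half-time mirrors the β phase |
| organ washout half-times | kidneys 111.4 h, liver 93.8 h, heart 35.6 h, spine 135.5 h, bladder 5.9 h | solved once so the noise-free analytic TIACs equal the cohort means (9.42, 4.24, 1.25, 2.10 h) |
| uptake fractions | 0.10, 0.05, 0.03, 0.02, 0.08 | plausible magnitudes consistent with the above |
| remainder | amplitude 0.72; 30% at 1 h, 70% at 149.4 h | sized so the whole-body TIAC is 74.02 h |
| noise | 5% multiplicative lognormal | below the assumed 10% systematic error |
| between-subject CV | 20% lognormal (mean-one) on uptake | typical preclinical spread |
| schedules | blood 0.5–300 min + days 2, 4, 6, 10; scans 3 × day 0 + days 2, 4, 10 | study design |

The α-phase fraction is interpreted as an amplitude fraction (the
conventional reading of "clearance in the α phase"). The organ model is an
uptake–washout surrogate, `U(1 − 2^(−t/t_u)) Σ f_k 2^(−t/τ_k)`; the study
reports TIACs, not rate constants, so the rates are calibration constants,
not measurements. The whole body is constructed as the sum of the noisy
organ series plus a remainder series, guaranteeing WB ≥ Σ organs at every
time. A flag doubles one subject's kidney uptake to emulate the
no-amino-acid subject. Multiplicative lognormal noise keeps samples
positive and heteroscedastic, as counting data are; urine noise perturbs
increments so cumulative excretion stays monotone.

What the generator does **not** emulate: image-quantification artefacts
(partial volume, scatter, spill-over), organ-specific multi-phase washout,
circadian or renal-function variability, and any receptor-binding
saturation. Passing tests therefore demonstrate correctness of the
*analysis* under the stated kinetic model and noise, not robustness to
imaging systematics.

## Problem sizes and numerical choices

The Monte-Carlo checks use 1000 blood-curve replicates (blood-kinetics
recovery; 4 multistarts per fit, sufficient for a 12-point biexponential
with well-separated phases) and 20 replicate 5-subject cohorts (kidney-TIAC
calibration, fitted directly on the generated curves — the first-scan
normalization step is bypassed there because the generated values are
already true fractions of IA). The parametric bootstrap for the TIAC
uncertainty uses 2000 draws warm-started at the fitted optimum. Fit
tolerances are xtol = ftol = gtol = 10⁻¹²; weighted values are floored at
10⁻¹² of the series maximum to keep 1/y² weights finite.

## Known limitations

- The full phantom dose table and exact red-marrow TIACs of the study are
  not reproducible without the original OLINDA S-values and marrow
  constants; the engine is validated structurally instead.
- Whether the study's heart region is wall or contents is ambiguous; the
  single `heart` label is mapped to the heart-wall row by default.
- No population (mixed-effects) fitting, no compartmental identification,
  no biologically effective dose, no voxel dosimetry.
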