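"""Fit the biexponential blood clearance model and integrate it.

Simulates one noisy blood curve at the study's 12 early arterial sampling
times, fits a two-term exponential sum, and reports the recovered phase
half-lives, the alpha-phase amplitude fraction, and the blood concentration
TIAC with its propagated standard error.
"""

import numpy as np

from prrtdose import (
    LU177,
    BloodModelParams,
    NoiseModel,
    apply_systematic_error,
    fit_exp_sum,
    simulate_blood_tac,
    tiac_analytic,
)

times_h = np.array([0.5, 1, 2, 5, 10, 20, 30, 50, 75, 100, 200, 300]) / 60.0
rng = np.random.default_rng(42)

tac = simulate_blood_tac(BloodModelParams(), times_h, NoiseModel(0.05), rng)
fit = fit_exp_sum(tac, n_terms=2)

alpha_h, beta_h = fit.model.half_lives_h
amps = fit.model.amplitudes
print(f"recovered T1/2 alpha: {alpha_h * 60:.2f} min (true 2.0)")
print(f"recovered T1/2 beta:  {beta_h * 60:.1f} min (true 36)")
print(f"alpha-phase fraction: {amps[0] / sum(amps):.3f} (true 0.801)")

# integrate on a per-litre fraction basis, physical decay re-added
conc = tiac_analytic(fit, LU177, organ="blood")
conc = apply_systematic_error(conc, 0.10)
print(f"\nblood concentration TIAC: {conc.value_h / 100:.5f} +- "
      f"{conc.standard_error_h / 100:.5f} h/L (fraction of IA per litre)")
print("This TIAC feeds the blood-surrogate red-marrow estimate.")
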