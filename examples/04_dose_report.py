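"""Dose coefficients, human extrapolation and the kidney toxicity check.

Uses the transcribed per-subject dose coefficients of the pig study for the
cohort statistics, then scales the cohort-mean kidney and osteogenic-cell
coefficients to a 5 GBq human administration and checks the 23 Gy kidney
limit — reproducing the study's headline predictions.
"""

from prrtdose import cohort_mean_sd, round_dose_gy, scale_to_administered, toxicity_check
from prrtdose.study import load_study_dose_coefficients

coeffs = load_study_dose_coefficients()

print("cohort dose coefficients (mGy/MBq, mean +- SD, n = 5):")
for organ in ("kidneys", "osteogenic_cells", "urinary_bladder_wall", "liver"):
    mean, sd = cohort_mean_sd(dict(coeffs.loc[organ]))
    print(f"  {organ:<22} {mean:8.3f} +- {sd:.3f}")

mean_kid, _ = cohort_mean_sd(dict(coeffs.loc["kidneys"]))
mean_ost, _ = cohort_mean_sd(dict(coeffs.loc["osteogenic_cells"]))
human = scale_to_administered({"kidneys": mean_kid, "osteogenic_cells": mean_ost}, 5000.0)

print("\npredicted human doses for 5 GBq administered:")
for organ, dose in human.items():
    print(f"  {organ:<22} {round_dose_gy(dose):g} Gy")

verdict = toxicity_check({k: round_dose_gy(v) for k, v in human.items()})
kid = verdict["kidneys"]
print(f"\nkidney toxicity check: {kid.dose_gy} Gy vs {kid.limit_gy} Gy limit -> "
      f"{'pass' if kid.passed else 'FAIL'} (margin {kid.margin_gy:.1f} Gy)")

print("\nexcluding the subject without amino-acid infusion:")
mean_x, sd_x = cohort_mean_sd(dict(coeffs.loc["kidneys"]), exclude=["pig4"])
print(f"  kidneys {mean_x:.2f} +- {sd_x:.2f} mGy/MBq "
      f"(vs {mean_kid:.2f} with all five; kept in by default for conservatism)")
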