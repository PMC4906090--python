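"""From organ time-activity curves to source-organ TIACs.

Runs one simulated subject through the fitting stage: AICc-selected
exponential-sum fits for the modelled organs, trapezoid-plus-tail for
bladder contents, spine-to-bone scaling, blood-surrogate red marrow, and
remainder-of-body reconstruction.
"""

from prrtdose import PipelineConfig, process_subject, simulate_cohort

data = simulate_cohort(n_subjects=1, seed=7)[0]
tacs = {**data.organ_tacs, "blood": data.blood_tac}

config = PipelineConfig(n_starts=8)
tiacs, source_set = process_subject(tacs, config, seed=7)

print(f"subject {data.subject.subject_id}")
print(f"{'organ':<18} {'TIAC (h)':>10} {'SE (h)':>8}  method")
for organ, t in sorted(tiacs.items()):
    print(f"{organ:<18} {t.value_h:>10.3f} {t.standard_error_h:>8.3f}  {t.method}")

total = sum(tiacs[r].value_h for r in source_set.tiacs if r not in ("whole_body",))
print(f"\nsource organs + remainder = {total:.2f} h "
      f"(whole body {tiacs['whole_body'].value_h:.2f} h; equal by construction)")
print("Standard errors include the 10% systematic quantification error.")
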