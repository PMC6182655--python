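"""Cox proportional-hazards associations with incident type 2 diabetes.

One row per person (follow-up duration, event flag, fixed covariates);
hazard ratios are reported against the descriptive-table reference levels
(male, 1980s birth cohort, high education, born in Norway). The generator
plants known covariate effects — e.g. female HR 0.66 — which the model
should recover.
"""

from t2d_registry import (
    SimulationConfig,
    build_cox_frame,
    classify_bundle,
    cox_fit,
    eligibility_windows,
    generate_registry,
    incident_cases_in_windows,
)

bundle, _ = generate_registry(SimulationConfig(n_persons=120_000, seed=3))
cases = classify_bundle(bundle)
windows = eligibility_windows(bundle.persons, cases)
incident = incident_cases_in_windows(cases, windows)
frame = build_cox_frame(windows, incident, bundle.persons)

unadjusted = cox_fit(frame, ["sex"])
print("unadjusted sex hazard ratio:")
print(unadjusted.round(2).to_string(index=False))

adjusted = cox_fit(frame, ["sex", "birth_cohort", "education_level", "place_of_birth"])
print("\nadjusted hazard ratios (planted truths: female 0.66, low education 2.10, "
      "Asia 3.08, ...):")
print(adjusted.round(2).to_string(index=False))
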