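"""Show how simulated operator post-processing shifts the two models.

Applies two different operators' perturbation draws (valve plane, axis,
residual motion, inferior contamination) to one study pair and compares the
resulting territory MFR values under both models.
"""

from mfrkit import (
    ExperimentConfig,
    PerturbationConfig,
    PopulationConfig,
    aha17_scheme,
    apply_operator_perturbation,
    quantify_pair,
    simulate_patient,
)

pair = simulate_patient(PopulationConfig(), seed=3, patient_id="demo")
pcfg = PerturbationConfig()
cfg = ExperimentConfig()
scheme = aha17_scheme()

op1 = apply_operator_perturbation(pair, pcfg, operator_seed=101)
op2 = apply_operator_perturbation(pair, pcfg, operator_seed=202)

v1 = quantify_pair(op1, scheme, cfg.retention, cfg.extraction)
v2 = quantify_pair(op2, scheme, cfg.retention, cfg.extraction)

print("territory MFR, operator 1 vs operator 2:")
for model in ("RET", "1CM"):
    for terr in ("LAD", "LCx", "RCA", "TOT"):
        a, b = v1[model]["mfr"][terr], v2[model]["mfr"][terr]
        print(f"  {model} {terr}: {a:.2f} vs {b:.2f}  (|diff| {abs(a - b):.2f})")
# The compartment model's per-segment spillover term makes it the more
# sensitive of the two to these processing differences, most visibly in the
# RCA territory where the extracardiac contamination lands.
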