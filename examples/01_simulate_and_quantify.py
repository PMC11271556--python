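"""Simulate one patient and quantify flow with both kinetic models.

Builds a rest/dipyridamole-stress dynamic study pair with known segmental
kinetics, then estimates myocardial blood flow (MBF, ml/min/g) and flow
reserve (MFR) with the net-retention and one-compartment models.
"""

import numpy as np

from mfrkit import (
    ExperimentConfig,
    PopulationConfig,
    aha17_scheme,
    quantify_pair,
    simulate_patient,
)

pop = PopulationConfig()
pair = simulate_patient(pop, seed=7, patient_id="demo")
truth_mfr = float(np.mean(pair.stress.truth.mbf / pair.rest.truth.mbf))

cfg = ExperimentConfig(population=pop)
values = quantify_pair(pair, aha17_scheme(), cfg.retention, cfg.extraction)

print(f"true segmental-mean MFR: {truth_mfr:.2f}")
for model in ("RET", "1CM"):
    v = values[model]
    print(
        f"{model}: rest TOT MBF {v['rest_mbf']['TOT']:.2f} ml/min/g, "
        f"stress TOT MBF {v['stress_mbf']['TOT']:.2f} ml/min/g, "
        f"TOT MFR {v['mfr']['TOT']:.2f}"
    )
# The two models calibrate differently: the retention estimate carries the
# global-spillover and late-window truncation factors, so its absolute MBF
# runs lower and its MFR compresses somewhat through the nonlinear
# extraction correction, while the compartment fit recovers the underlying
# kinetics nearly exactly on clean data.
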