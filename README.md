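# mfrkit

Quantification of myocardial blood flow (MBF) and myocardial flow reserve
(MFR) from dynamic cardiac SPECT time-activity curves, plus an in-silico
testbed for the *processing repeatability* of the two kinetic models in
routine use.

Dynamic SPECT on solid-state (CZT) cameras makes flow quantification with
⁹⁹ᵐTc tracers widely available, but the numbers depend on operator
post-processing — valve-plane placement, axis orientation, motion
correction — and on the kinetic model.  `mfrkit` implements both standard
models over frame-averaged time-activity curves (TACs):

* **Net retention (RET)** — late-window myocardial activity, corrected by a
  single global blood-pool spillover fraction β and normalised by the early
  blood integral:
  `R = 60·[ C̄_myo(T1,T2) − β·C̄_blood(T1,T2) ] / ∫₀^{T0} C_b dt`  (1/min)
* **One-tissue compartment (1CM)** — per-segment weighted least-squares fit
  of `C(t) = (1−f_v)·K1·(e^{−k2 t} ⊗ C_b)(t) + f_v·C_b(t)` with uptake K1
  (ml/min/g), washout k2 (1/min), and a segmental spillover/partial-volume
  fraction f_v.

Uptake converts to flow through a Renkin–Crone extraction model
`uptake = MBF·(1 − e^{−PS/MBF})`; MFR is the segment-wise stress/rest flow
ratio, aggregated to the LAD/LCx/RCA territories and whole myocardium of
the AHA 17-segment scheme.

Around the models sits a complete repeatability experiment: a synthetic
generator for rest/dipyridamole-stress studies on the 23-frame schedule
(15×6 s, 4×30 s, 4×60 s) with known segmental kinetics and bolus quality
control, a seeded operator-perturbation model for the post-processing
failure modes, and the paired-measurement statistics battery (Spearman r,
Bland–Altman limits of agreement, SD of percentage differences, Fisher-z
tests for independent and dependent correlations, paired t, F-test).

Intended users: researchers in nuclear-cardiology image analysis who want
to study or teach how processing variability propagates through kinetic
modelling, and anyone needing a clean reference implementation of the two
estimators and the agreement statistics.

## Worked example

```python
from mfrkit import (ExperimentConfig, PopulationConfig, aha17_scheme,
                    quantify_pair, simulate_patient)

pair = simulate_patient(PopulationConfig(), seed=7)          # rest+stress, known truth
cfg = ExperimentConfig()
values = quantify_pair(pair, aha17_scheme(), cfg.retention, cfg.extraction)
for model in ("RET", "1CM"):
    v = values[model]
    print(model, round(v["rest_mbf"]["TOT"], 2),
          round(v["stress_mbf"]["TOT"], 2), round(v["mfr"]["TOT"], 2))
```

prints

```
RET 0.75 1.31 1.76
1CM 0.97 2.04 2.1
```

— rest MBF, stress MBF (ml/min/g) and MFR for the whole myocardium.  The
compartment fit recovers this patient's true mean reserve (2.09) almost
exactly; the retention estimate runs lower in absolute terms because it
carries the global-spillover and window-truncation factors (its strength
is repeatability, not absolute accuracy).  The scripts in `examples/`
walk through simulation, operator perturbation, the full repeatability
experiment, and correlation comparison; each prints a short interpretation
of its output.

Running the default experiment (200 simulated patients, two operators,
both models; ~35 s):

```python
from mfrkit import ExperimentConfig, run_repeatability_experiment
res = run_repeatability_experiment(ExperimentConfig())
print(res.report.summary("RET", "mfr", "RCA").r_spearman)  # 0.932
print(res.report.summary("1CM", "mfr", "RCA").r_spearman)  # 0.766
```

The inter-operator Spearman correlation of MFR is higher under the
retention model in every territory, and the compartment model is weakest
in the RCA territory — the clinically observed pattern, reproduced here
from an explicit mechanism (the compartment model's per-segment spillover
term absorbs blood-pool admixture but is destabilised by motion jitter and
inferior-wall extracardiac contamination).

A thin CLI mirrors the library: `mfrkit simulate`, `mfrkit fit`,
`mfrkit stats compare-r`, `mfrkit repeatability` (see `--help`).

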