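# Methods

`mfrkit` is an in-silico testbed for a question that matters clinically:
when dynamic cardiac SPECT studies are post-processed by different
operators, how repeatable are the myocardial blood flow (MBF) and flow
reserve (MFR) values, and how does that repeatability differ between the
two tracer-kinetic models in routine use — the net-retention model and the
one-tissue compartment model?  This note documents the models, the
synthetic-data generator, the operator-perturbation model, the statistical
battery, and the numerical and design choices behind them.

## Data model

A dynamic study is a set of frame-averaged time-activity curves (TACs) on a
23-frame schedule: fifteen 6-s frames through the bolus transit, four 30-s
and four 60-s frames over the retention phase, 450 s in total.  Curves are
kept for the left-ventricular blood pool (the arterial input function,
AIF), the 17 standard AHA segments of the left ventricle, and optionally an
extracardiac (hepatic/intestinal) region.  Activity is in arbitrary
concentration units: both kinetic models depend only on the
myocardium-to-blood ratio, so no Bq/ml calibration is carried.  Segments
map to vascular territories by the standard AHA convention (LAD:
1,2,7,8,13,14,17; LCx: 5,6,11,12,16; RCA: 3,4,9,10,15) with uniform mass
weights 1/17 by default; both are configurable because vendor software does
not publish its exact weighting.  Whole-myocardium values ("TOT") are the
weighted mean over all 17 segments (not the mean of the three territories —
the two differ under non-uniform weights; the segment-mean convention is
the package default and is what all reports use).

## Kinetic models

**One-tissue compartment (1CM).**  Each segment is modelled as

    C(t) = (1 − f_v) · K1 · (e^{−k2 t} ⊗ C_b)(t) + f_v · C_b(t)

with uptake K1 (ml/min/g), washout k2 (1/min) and a per-segment blood
spillover / partial-volume fraction f_v ∈ [0, 1].  Rates are quoted per
minute and the time axis is in seconds; the factor 60 is applied exactly
once, inside the forward-model evaluation.  The fit minimises
duration-weighted least squares of the frame-averaged forward model against
the observed frame values, with bounds K1 ∈ [0, 5], k2 ∈ [0, 5],
f_v ∈ [0, 1].

Because the model is linear in a = (1 − f_v)K1 and b = f_v once k2 is
fixed, the fit is solved by variable projection: the weighted residual is
profiled over k2 on a 24-point grid across [0, 5] 1/min followed by a
bounded scalar refinement (tolerance 1e-6) of the bracketing interval, with
a constrained 2×2 linear solve at every candidate k2.  This is
deterministic — no random starts, no start-point sensitivity — and solves a
17-segment study in ~30 ms.  Degenerate limits are exact by construction:
an all-zero segment returns K1 = k2 = f_v = 0, and a segment equal to the
blood curve returns a → 0, b → 1, reported as K1 = 0, f_v = 1.

The continuous input function needed by the convolution is reconstructed
from the frame-averaged blood TAC: shape-preserving PCHIP interpolation of
the frame means at frame midpoints, followed by eight multiplicative
corrections that make the reconstruction's frame averages match the
observed values.  On noiseless self-consistency tests (forward-simulate →
fit) the median K1 error is ~0.006%, far below the 0.5% acceptance bar, so
the reconstruction is not a limiting factor.  The convolution itself uses
the exact piecewise-linear ⊗ exponential recursion (implemented as an IIR
filter), which agrees with the closed-form constant-input solution to
machine precision.

**Net retention (RET).**  The uptake rate is estimated as

    R = 60 · [ mean_{[T1,T2]}(C_seg) − β · mean_{[T1,T2]}(C_b) ] / ∫₀^{T0} C_b dt

in 1/min, with one global blood-pool spillover fraction β (default 0.15)
applied identically to every segment.  Defaults put the blood integral on
the bolus transit, T0 = 210 s, and the myocardial window on the retention
plateau, [210, 450] s; both align with frame boundaries of the default
schedule.  Frame values are interval averages, so the blood integral is
computed as the duration-weighted sum of frame values, which is the exact
integral of the underlying curve (a midpoint trapezoid would only
approximate it); late-window means are duration-weighted.
Spillover-corrected numerators below zero are clipped to zero and flagged.
The estimator deliberately reproduces the known biases of the retention
approach: the (1 − β) spillover factor, washout over the late window, and
recirculation/background accumulation all scale R away from the true K1.
These biases are common to stress and rest and largely cancel in MFR,
which is what the repeatability experiment compares.

**Flow conversion.**  Uptake is mapped to flow by inverting a Renkin–Crone
extraction model, uptake = MBF·(1 − e^{−PS/MBF}), by bisection on
[1e-6, 10] ml/min/g to 1e-8.  The class default is PS = 1.0 ml/min/g, and
an identity mapping is available for testing and relative-flow work.  The
shipped experiment configuration uses PS = 2.0: with PS = 1.0 the uptake
curve saturates so strongly at vasodilator-stress flows (~2 ml/min/g) that
inversion amplifies uptake noise roughly ninefold, drowning the
operator-variability signal the experiment is designed to study; PS = 2.0
keeps the inversion moderately conditioned (~3× amplification) while
retaining the physiological flow-dependent extraction roll-off.  Uptake at
or above the extraction ceiling saturates to the 10 ml/min/g bound and the
segment is flagged; flagged segments are excluded from territory aggregates
(weights renormalised).  A territory whose members are all flagged falls
back to the unrestricted weighted mean, and an MFR aggregate with every
segment excluded falls back to the ratio of territory flows — these
fallbacks only matter under extreme, deliberately provoked contamination.

**MFR.**  Segment MFR is stress MBF / rest MBF, computed before
aggregation; segments with rest flow below 0.05 ml/min/g (near-scar) are
flagged and excluded from aggregates.

## Synthetic-study generator

The generator emulates a two-day rest / dipyridamole-stress rapid-bolus
protocol with a small pre-injection positioning dose:

* **AIF**: gamma-variate first pass (t/tp)^α e^{α(1−t/tp)}, default peak
  time 25 s and shape α = 3, plus a recirculation plateau (default 15% of
  peak, 60-s rise) and a constant background (3% of peak) representing the
  positioning pre-injection.  The first-pass-plus-tail curve is normalised
  to unit peak before background addition.  Bolus-to-bolus variability is
  log-normal jitter on the peak time (σ = 0.20) and tail fraction
  (σ = 0.40).
* **Population**: rest MBF log-normal with median 1.0 ml/min/g and
  log-SD 0.28; stress = rest × a log-normal reserve ratio (median 1.85,
  log-SD 0.30); 8% segmental heterogeneity.  These reproduce the reported
  clinical distributions (rest total ≈ 1.0 ± 0.3, stress ≈ 1.8 ± 0.7
  ml/min/g, MFR ≈ 1.9).  44% of patients carry a contiguous
  inferior/inferolateral scar block (segments 4, 5, 10, 11, 15) with a 55%
  flow deficit, echoing the prevalence of prior infarction in such
  referral cohorts.  Washout k2 is drawn in [0.03, 0.12] 1/min (a slowly
  washing, retained perfusion tracer); f_v is N(0.25, 0.06) clipped to
  [0, 0.6].  True K1 follows from MBF through the same extraction model
  the analysis inverts.
* **Noise**: Gaussian with SD ∝ √(value/duration) (a Poisson surrogate
  appropriate after frame averaging; scale 0.015), clipped at zero.
* **Extracardiac activity**: a blood-pool-like intestinal component
  (log-normal amplitude, median 1.7 × AIF) plus a slowly rising hepatic
  component (median 0.25), both drawn per study.
* **Bolus QC**: a study fails when the blood curve's peak-frame to
  late-plateau ratio falls below 3.0 or the peak lands after frame 15,
  mimicking clinical exclusion of slow or extravasated injections.  Under
  the default bolus variability ~8% of patients are excluded.

Seed policy: one master seed; per-patient and per-processing seeds are
derived through `numpy.random.SeedSequence` spawn keys, so enlarging the
cohort never reshuffles earlier patients, and every stage is
deterministic.

## Operator-perturbation model

The clinical variability arises in image post-processing (valve-plane
placement, long-axis orientation, manual motion correction, and automatic
contouring pulled toward extracardiac hotspots).  The generator has no
images, so each failure mode is mapped to its TAC-level consequence:

| source | TAC-level action | default SD |
|---|---|---|
| valve plane | basal segments (1–6) convexly mixed with the blood curve | 0.13 |
| axis orientation | circumferential neighbour mixing within each ring | 0.06 |
| residual motion | signed global additive blood-spillover offset | 0.025 |
| inferior contamination | RCA segments (3,4,9,10,15) convexly mixed with the extracardiac curve | 0.04 |

Mixing fractions are |N(0, SD)| clipped to [0, 0.5]; the motion offset is
signed.  An operator's draw is their systematic tendency; a same-operator
replicate adds jitter at 0.6 × the SDs, so intra-operator variance is
strictly below inter-operator variance, mirroring the
two-operators-plus-repeat design.

The mapping has a first-principles asymmetry that drives the headline
result.  Convex admixture of the blood curve is *exactly absorbed* by the
compartment model's f_v term (K1 is invariant), but shifts the retention
estimate; conversely, an additive spillover offset δ perturbs the
compartment K1 through 1/(1 − f_v − δ) while the retention model sees only
the small late-window blood amplitude; and blood-pool-like extracardiac
contamination inflates the compartment fit's f_v and hence K1, while its
late-window value roughly matches the myocardial plateau and nearly
cancels in the retention numerator.  The per-segment spillover fitting
that makes the compartment model attractive for high-resolution PET is
thus precisely what makes it fragile under SPECT processing variability —
the package reproduces this mechanism rather than asserting it.

The four SDs and PS are the calibration of the testbed: they were set once
so that the default 200-patient experiment lands inside the clinically
observed inter-observer correlation envelopes (retention MFR r 0.92–0.97;
compartment MFR r 0.72–0.92, minimum in RCA), and then frozen.  They are
configuration, not fitted parameters; no published magnitudes exist for
individual correction types, only 0–2 quality grades.

## Repeatability experiment and statistics

The default experiment simulates 200 patients, excludes QC failures,
processes each remaining study pair three times (operator 1 twice with
replicate jitter, operator 2 once), quantifies every processing with both
models, and fills a complete grid of agreement panels: {stress MBF, rest
MBF, MFR} × {LAD, LCx, RCA, TOT} × {RET, 1CM} × {inter, intra}.  Each
panel holds Spearman's rank correlation (mid-rank ties), the Bland–Altman
mean difference and 1.96·SD limits of agreement (sample SD, n−1), the SD
of pairwise percentage differences (denominator: the pair mean, matching
the precision convention of comparable studies; configurable), and a
Shapiro–Wilk annotation of whether the differences look normal enough for
Bland–Altman treatment.  Cross-model tests per cell: a dependent-correlations
Fisher-z comparison, a paired t on the per-patient difference series, and
an F-test on the difference SDs.  All p-values are two-sided; no
multiplicity correction is applied (none is applied in the clinical
practice being emulated).

**Comparing correlations.**  Independent groups use the classical
Fisher-z statistic (atanh r1 − atanh r2)/√(1/(n1−3) + 1/(n2−3)); no
Spearman variance-inflation factor is applied, because recomputing the
published group comparisons favours the plain form (agreement within
±0.002 of the printed p-values, inside the ±0.005 band that propagating
the 3-decimal rounding of r allows).  Dependent correlations sharing no
variable (two models, same patients) use a Steiger-type test: the caller
supplies the between-occasion correlation r12, the two cross-correlations
are imputed as r̄·r12, the Pearson–Filon covariance of the two
correlations is converted to a covariance c of the Fisher z's, and
z = Δz·√((n−3)/(2−2c)).  The implied 4×4 correlation matrix must be
positive definite; at r12 = 0 the statistic reduces exactly to the
independent-samples form at equal n.  In the built report r12 is estimated
from the data as the mean between-model Spearman correlation of the two
processings.  Published within-cohort dependent-test p-values cannot be
reproduced exactly because the underlying r12 values were never printed;
the test is provided with r12 as an explicit argument for that reason.

## Problem sizes and verification

The shipped experiment (200 patients × 3 processings × 2 conditions × 17
segments, both models) runs in about half a minute on one CPU; the
variable-projection fit is what makes that scale comfortable.  The test
suite verifies: exact closed forms (constant-input compartment solution,
constant-curve retention value, brute-force Spearman/Bland–Altman/percent-SD
oracles at 1e-12), noiseless parameter recovery (median K1 error < 0.5%
over 100 segments), the extraction round-trip (1e-6), the type-I error of
the Fisher-z test under a simulated bivariate-normal null (within
[0.04, 0.06] at α = 0.05, 10⁴ replicates at the clinical group sizes), the
seeded repeatability pattern and envelopes, determinism end to end, and
the degenerate-input contracts.

## Limitations

* The perturbation model acts on TACs, not images: geometric failure
  modes are represented only through their assumed curve-level
  consequences, and magnitudes are calibrated, not measured.
* The generator shares its forward model with the compartment fit, so
  compartment-model recovery tests are self-consistency checks; model
  mismatch (flow heterogeneity within segments, tracer metabolites,
  attenuation-related bias) is out of scope.
* Absolute MBF/MFR levels depend on the extraction parameters, which are
  not published for the emulated vendor chain; only relative and
  repeatability statements should be read off the simulation.  The
  retention estimator's absolute scale in particular carries its (1 − β)
  and window-truncation factors by design.
* Passing the seeded envelope checks shows the calibrated testbed
  reproduces the clinical pattern, not that real operator variability has
  the simulated composition.
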