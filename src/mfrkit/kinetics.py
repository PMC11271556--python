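"""Tracer-kinetic quantification of myocardial blood flow from TACs.

Two estimators of the segmental tracer uptake rate are provided:

* **Net retention (RET)** — the late-window myocardial concentration,
  corrected by a single global blood-pool spillover fraction ``beta`` and
  normalised by the early integral of the blood curve:

  .. math:: R = 60 \\cdot \\frac{\\bar C_m[T_1,T_2] - \\beta\\,\\bar C_b[T_1,T_2]}
                          {\\int_0^{T_0} C_b\\,dt} \\quad [1/\\mathrm{min}]

* **One-tissue compartment (1CM)** — weighted least-squares fit of

  .. math:: C(t) = (1-f_v)\\,K_1 \\,(e^{-k_2 t} \\otimes C_b)(t) + f_v\\,C_b(t)

  per segment, with uptake :math:`K_1` (ml/min/g), washout :math:`k_2`
  (1/min) and a segmental blood spillover / partial-volume fraction
  :math:`f_v`.

Uptake is converted to flow through a Renkin–Crone extraction model
``uptake = MBF * (1 - exp(-PS/MBF))`` (or an identity mapping), and segmental
flows are aggregated to the LAD/LCx/RCA territories and the whole myocardium
(TOT) as mass-weighted means.  Myocardial flow reserve (MFR) is the
segment-wise stress/rest flow ratio, aggregated the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._conv import DEFAULT_DT, exp_conv, fine_grid, reconstruct_fine_curve
from .study import SEGMENT_IDS, DynamicStudy, FrameSchedule, SegmentScheme, frame_average

__all__ = [
    "RetentionConfig",
    "OneCompartmentFit",
    "ExtractionModel",
    "FlowResult",
    "MfrResult",
    "ret_uptake",
    "fit_1cm",
    "flow_from_uptake",
    "compute_mfr",
    "aggregate_territories",
    "flow_result_from_uptake",
]

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class RetentionConfig:
    """Windows and global spillover fraction of the net-retention estimator.

    ``beta`` is the blood-pool spillover fraction applied identically to all
    segments; the blood integral runs over ``[0, T0]`` and the myocardial
    late window over ``[T1, T2]`` seconds.  Defaults put the blood window on
    the bolus transit (first 210 s of the 450-s study) and the myocardial
    window on the retention plateau (210–450 s); both align with frame
    boundaries of the default 23-frame schedule.
    """

    beta: float = 0.15
    blood_integral_window: tuple[float, float] = (0.0, 210.0)
    myocardial_window: tuple[float, float] = (210.0, 450.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must be in [0, 1)")
        t0a, t0b = self.blood_integral_window
        t1, t2 = self.myocardial_window
        if not (t0a == 0.0 and 0.0 < t0b <= t1 < t2):
            raise ValueError("windows must satisfy 0 < T0 <= T1 < T2")


@dataclass
class OneCompartmentFit:
    """Per-segment one-compartment estimates with fit diagnostics."""

    k1: np.ndarray  # ml/min/g
    k2: np.ndarray  # 1/min
    f_v: np.ndarray  # unitless in [0, 1]
    residual: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            s: {
                "K1": float(self.k1[i]),
                "k2": float(self.k2[i]),
                "f_v": float(self.f_v[i]),
                "residual": float(self.residual[i]),
                "converged": bool(self.converged[i]),
            }
            for i, s in enumerate(SEGMENT_IDS)
        }


@dataclass(frozen=True)
class ExtractionModel:
    """Link between tracer uptake and blood flow.

    ``renkin_crone``: uptake = MBF * (1 - exp(-PS/MBF)), PS in ml/min/g —
    strictly increasing in MBF with supremum PS, so inversion is unique.
    ``identity``: uptake is reported as flow unchanged (useful for testing
    and for relative-flow work).
    """

    form: str = "renkin_crone"
    ps: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("renkin_crone", "identity"):
            raise ValueError(f"unknown extraction form '{self.form}'")
        if self.form == "renkin_crone" and self.ps <= 0:
            raise ValueError("PS must be positive")

    def uptake_from_flow(self, mbf):
        mbf = np.asarray(mbf, dtype=float)
        if self.form == "identity":
            return mbf
        with np.errstate(divide="ignore"):
            e = np.where(mbf > 0, 1.0 - np.exp(-self.ps / np.maximum(mbf, 1e-300)), 1.0)
        return mbf * e


_FLOW_UPPER = 10.0  # ml/min/g; physiologic search bracket for inversion


def flow_from_uptake(uptake, model: ExtractionModel):
    """Invert the extraction model: solve ``uptake = MBF * E(MBF)`` for MBF.

    Bisection on [1e-6, 10] ml/min/g to 1e-8; uptake at or above the model's
    supremum on that bracket saturates to the upper bound.  Accepts scalars
    or arrays; uptake must be non-negative.
    """
    u = np.asarray(uptake, dtype=float)
    if np.any(u < 0):
        raise ValueError("uptake must be non-negative")
    if model.form == "identity":
        return u if u.ndim else float(u)

    lo = np.full(u.shape, 1e-6)
    hi = np.full(u.shape, _FLOW_UPPER)
    sat = u >= model.uptake_from_flow(_FLOW_UPPER)
    zero = u <= model.uptake_from_flow(1e-6)
    for _ in range(60):  # 10 / 2^60 << 1e-8
        mid = 0.5 * (lo + hi)
        too_low = model.uptake_from_flow(mid) < u
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    out = 0.5 * (lo + hi)
    out = np.where(sat, _FLOW_UPPER, out)
    out = np.where(zero, 0.0, out)
    return out if u.ndim else float(out)


# ---------------------------------------------------------------------------
# Net retention
# ---------------------------------------------------------------------------


def _window_mask(schedule: FrameSchedule, lo: float, hi: float) -> np.ndarray:
    mask = (schedule.starts >= lo - 1e-9) & (schedule.ends <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] s contains no complete frame")
    return mask


def ret_uptake(
    study: DynamicStudy, cfg: RetentionConfig = RetentionConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Net-retention uptake rate per segment, in 1/min.

    Frame values are interval averages, so the blood integral over [0, T0] is
    the exact duration-weighted sum of frame values; the late means are
    duration-weighted frame means.  Spillover-corrected numerators that come
    out negative are clipped to zero and flagged.

    Returns ``(retention, clipped_flags)``, both length 17.
    """
    sched = study.schedule
    t0 = cfg.blood_integral_window[1]
    t1, t2 = cfg.myocardial_window
    if t2 > sched.ends[-1] + 1e-9:
        raise ValueError("myocardial window exceeds the schedule")

    early = _window_mask(sched, 0.0, t0)
    late = _window_mask(sched, t1, t2)
    dur = sched.durations

    blood_integral = float(np.sum(study.blood.values[early] * dur[early]))
    if blood_integral <= 0:
        raise ValueError("blood integral over [0, T0] must be positive")
    w_late = dur[late] / dur[late].sum()
    blood_late = float(np.dot(study.blood.values[late], w_late))

    seg = study.segment_matrix()[:, late] @ w_late  # (17,)
    numer = seg - cfg.beta * blood_late
    clipped = numer < -1e-12 * max(1.0, blood_late)  # ignore FP dust
    retention = SECONDS_PER_MINUTE * np.clip(numer, 0.0, None) / blood_integral
    return retention, clipped


# ---------------------------------------------------------------------------
# One-tissue compartment fit
# ---------------------------------------------------------------------------

_K2_BOUNDS = (0.0, 5.0)  # 1/min
_K1_BOUND = 5.0  # ml/min/g
_K2_GRID = 24  # coarse profile points across the k2 range


def _solve_amplitudes(
    conv_f: np.ndarray, blood_f: np.ndarray, target: np.ndarray, w: np.ndarray
) -> tuple[float, float, float]:
    """Constrained weighted LSQ of ``target ~ a*conv_f + b*blood_f``.

    a = (1-f_v)*K1 >= 0,  b = f_v in [0, 1].  Solves the 2x2 normal equations
    and projects onto the constraint box by re-solving the active edges.
    Returns (a, b, weighted residual sum of squares).
    """
    cw, bw, tw = conv_f * w, blood_f * w, target * w

    def rss(a: float, b: float) -> float:
        r = tw - a * cw - b * bw
        return float(r @ r)

    def a_given_b(b: float) -> float:
        denom = cw @ cw
        if denom <= 0:
            return 0.0
        return max(0.0, float((cw @ (tw - b * bw)) / denom))

    def b_given_a(a: float) -> float:
        denom = bw @ bw
        if denom <= 0:
            return 0.0
        return min(1.0, max(0.0, float((bw @ (tw - a * cw)) / denom)))

    g = np.array([[cw @ cw, cw @ bw], [cw @ bw, bw @ bw]])
    rhs = np.array([cw @ tw, bw @ tw])
    det = g[0, 0] * g[1, 1] - g[0, 1] ** 2
    candidates: list[tuple[float, float]] = []
    if det > 1e-300:
        a0, b0 = np.linalg.solve(g, rhs)
        if a0 >= 0 and 0.0 <= b0 <= 1.0:
            candidates.append((float(a0), float(b0)))
    if not candidates:
        for b_edge in (0.0, 1.0):
            candidates.append((a_given_b(b_edge), b_edge))
        candidates.append((0.0, b_given_a(0.0)))
    best = min(candidates, key=lambda ab: rss(*ab))
    return best[0], best[1], rss(*best)


def fit_1cm(
    study: DynamicStudy,
    dt: float = DEFAULT_DT,
    fine_blood: np.ndarray | None = None,
) -> OneCompartmentFit:
    """Fit the one-tissue compartment model to every segment of a study.

    The model is linear in ``a = (1-f_v) K1`` and ``b = f_v`` once ``k2`` is
    fixed, so the fit profiles the weighted residual over ``k2`` (coarse grid
    plus bounded scalar refinement — deterministic, no random starts) and
    solves the constrained 2x2 problem at each candidate.  Residual weights
    are proportional to frame duration.  Bounds: K1 in [0, 5] ml/min/g,
    k2 in [0, 5] 1/min, f_v in [0, 1].

    ``fine_blood`` may supply the input function on the fine grid (as the
    simulator knows it); otherwise it is reconstructed from the frame-averaged
    blood TAC.
    """
    sched = study.schedule
    if sched.n_frames < 10:
        raise ValueError("one-compartment fit needs at least 10 frames")
    blood = study.blood.values
    peak, plateau = float(blood.max()), float(np.mean(blood[-4:]))
    if peak <= 0 or (plateau > 0 and peak / plateau <= 1.0):
        raise ValueError("degenerate blood TAC (no bolus peak)")

    t = fine_grid(sched, dt)
    if fine_blood is None:
        _, fine_blood = reconstruct_fine_curve(sched, blood, dt)
    fine_blood = np.asarray(fine_blood, dtype=float)
    if fine_blood.shape != t.shape:
        raise ValueError("fine_blood must live on the schedule's fine grid")

    w = np.sqrt(sched.durations)
    blood_f = frame_average(t, fine_blood, sched)
    targets = study.segment_matrix()

    conv_cache: dict[float, np.ndarray] = {}

    def conv_frames(k2: float) -> np.ndarray:
        key = round(k2, 12)
        if key not in conv_cache:
            # rates are quoted per minute; the grid is in seconds
            fine = exp_conv(fine_blood, k2 / SECONDS_PER_MINUTE, dt) / SECONDS_PER_MINUTE
            conv_cache[key] = frame_average(t, fine, sched)
        return conv_cache[key]

    k1 = np.zeros(17)
    k2_arr = np.zeros(17)
    f_v = np.zeros(17)
    resid = np.zeros(17)
    conv_flag = np.ones(17, dtype=bool)
    iters = np.zeros(17, dtype=int)

    k2_grid = np.linspace(_K2_BOUNDS[0], _K2_BOUNDS[1], _K2_GRID)

    for i in range(17):
        target = targets[i]
        if not np.any(np.abs(target) > 0):
            continue  # all-zero segment: K1 = k2 = f_v = 0 exactly

        def profile(k2v: float) -> float:
            return _solve_amplitudes(conv_frames(k2v), blood_f, target, w)[2]

        coarse = np.array([profile(k) for k in k2_grid])
        j = int(np.argmin(coarse))
        lo = k2_grid[max(j - 1, 0)]
        hi = k2_grid[min(j + 1, k2_grid.size - 1)]
        n_eval = k2_grid.size
        if hi > lo:
            res = minimize_scalar(
                profile, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            k2_best = float(res.x)
            n_eval += int(res.nfev)
            if profile(k2_best) > coarse[j]:
                k2_best = float(k2_grid[j])
        else:
            k2_best = float(k2_grid[j])

        a, b, rss = _solve_amplitudes(conv_frames(k2_best), blood_f, target, w)
        if a <= 1e-12:
            k1_i = 0.0
        elif b >= 1.0 - 1e-9:
            k1_i, conv_flag[i] = _K1_BOUND, False  # degenerate: all signal is blood
        else:
            k1_i = a / (1.0 - b)
        if k1_i > _K1_BOUND:
            k1_i, conv_flag[i] = _K1_BOUND, False
        k1[i], k2_arr[i], f_v[i] = k1_i, k2_best, b
        resid[i] = np.sqrt(rss)
        iters[i] = n_eval

    return OneCompartmentFit(
        k1=k1, k2=k2_arr, f_v=f_v, residual=resid, converged=conv_flag,
        iterations=iters,
    )


# ---------------------------------------------------------------------------
# Aggregation, flow and MFR
# ---------------------------------------------------------------------------


def aggregate_territories(
    per_segment: np.ndarray,
    scheme: SegmentScheme,
    include: np.ndarray | None = None,
) -> dict[str, float]:
    """Mass-weighted territory (LAD/LCx/RCA) and whole-myocardium (TOT) means.

    ``include`` masks flagged segments out; weights are renormalised over the
    included members of each aggregate.
    """
    vals = np.asarray(per_segment, dtype=float)
    if vals.size != 17:
        raise ValueError("expected 17 per-segment values")
    inc = np.ones(17, dtype=bool) if include is None else np.asarray(include, bool)
    weights = np.array([scheme.weight_of[s] for s in scheme.segment_ids])

    def wmean(mask: np.ndarray) -> float:
        m = mask & inc
        if not m.any():
            m = mask  # every member flagged: fall back to the full territory
        with np.errstate(invalid="ignore"):
            return float(np.dot(vals[m], weights[m]) / weights[m].sum())

    out: dict[str, float] = {}
    for terr in scheme.territories:
        mask = np.array([scheme.territory_of[s] == terr for s in scheme.segment_ids])
        out[terr] = wmean(mask)
    out["TOT"] = wmean(np.ones(17, dtype=bool))
    return out


@dataclass
class FlowResult:
    """Per-segment uptake and flow with territory aggregates for one condition."""

    condition: str
    uptake: np.ndarray  # per segment, 1/min (RET) or ml/min/g (1CM K1)
    mbf: np.ndarray  # per segment, ml/min/g
    territories: dict[str, float]  # LAD, LCx, RCA, TOT
    flags: np.ndarray = field(default_factory=lambda: np.zeros(17, dtype=bool))


@dataclass
class MfrResult:
    """Segmental and aggregated myocardial flow reserve (stress/rest)."""

    mfr: np.ndarray
    territories: dict[str, float]
    excluded: np.ndarray  # segments with unreliable rest flow


def flow_result_from_uptake(
    condition: str,
    uptake: np.ndarray,
    scheme: SegmentScheme,
    extraction: ExtractionModel,
    flags: np.ndarray | None = None,
) -> FlowResult:
    """Convert segmental uptake to MBF and aggregate to territories."""
    uptake = np.asarray(uptake, dtype=float)
    mbf = np.asarray(flow_from_uptake(uptake, extraction), dtype=float)
    if flags is None:
        flags = np.zeros(17, dtype=bool)
    flags = np.asarray(flags, dtype=bool).copy()
    if extraction.form != "identity":
        # inversion saturates where uptake reaches the extraction ceiling;
        # such segments carry no usable flow information
        flags |= uptake >= extraction.uptake_from_flow(_FLOW_UPPER)
    include = ~flags if not flags.all() else None
    return FlowResult(
        condition=condition,
        uptake=uptake,
        mbf=mbf,
        territories=aggregate_territories(mbf, scheme, include=include),
        flags=flags,
    )


MIN_REST_MBF = 0.05  # ml/min/g; below this, a segment's MFR is unreliable


def compute_mfr(
    stress: FlowResult,
    rest: FlowResult,
    scheme: SegmentScheme,
    min_rest_mbf: float = MIN_REST_MBF,
) -> MfrResult:
    """Segment-wise MFR = stress MBF / rest MBF, then weight-averaged.

    Segments whose rest flow falls below ``min_rest_mbf`` (near-scar) are
    flagged and excluded from the aggregates, which renormalise over the
    remaining segments.
    """
    excluded = (rest.mbf < min_rest_mbf) | rest.flags | stress.flags
    if excluded.all():
        raise ValueError("no segment has reliable rest flow; MFR undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        mfr = np.where(excluded, np.nan, stress.mbf / np.maximum(rest.mbf, 1e-300))
    territories = aggregate_territories(
        np.where(excluded, 0.0, mfr), scheme, include=~excluded
    )
    seg_terr = [scheme.territory_of[s] for s in scheme.segment_ids]
    for terr in list(territories):
        members = (
            np.ones(17, dtype=bool)
            if terr == "TOT"
            else np.array([t == terr for t in seg_terr])
        )
        if (members & ~excluded).sum() == 0 or not np.isfinite(territories[terr]):
            # whole aggregate excluded: fall back to the flow-aggregate ratio
            territories[terr] = stress.territories[terr] / max(
                rest.territories[terr], min_rest_mbf
            )
    return MfrResult(mfr=mfr, territories=territories, excluded=excluded)
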