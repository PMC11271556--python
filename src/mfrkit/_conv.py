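"""Low-level numerics shared by the forward simulator and the kinetic fits."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .study import FrameSchedule, frame_average

DEFAULT_DT = 0.25  # s; fine-grid step for forward models and fits


def fine_grid(schedule: FrameSchedule, dt: float = DEFAULT_DT) -> np.ndarray:
    """Uniform time grid covering the schedule, step ``dt`` seconds."""
    n = int(round(schedule.total_duration / dt))
    return schedule.starts[0] + dt * np.arange(n + 1)


def exp_conv(values: np.ndarray, k: float, dt: float) -> np.ndarray:
    """``y(t) = \\int_0^t e^{-k (t-s)} c(s) ds`` for piecewise-linear ``c``.

    Exact for a piecewise-linear input sampled on a uniform grid: each step
    adds the analytic integral of ``e^{-k(t_{n+1}-s)} c(s)`` over one interval,
    accumulated with the recursion ``y_{n+1} = e^{-k dt} y_n + A c_n + B c_{n+1}``.
    Implemented with an IIR filter so the recursion is vectorised.
    """
    c = np.asarray(values, dtype=float)
    if k < 0:
        raise ValueError("decay rate k must be non-negative")
    kd = k * dt
    if kd < 1e-8:  # k -> 0 limit: plain trapezoid accumulation
        a_coef = b_coef = 0.5 * dt
        decay = 1.0 - kd
    else:
        e = np.exp(-kd)
        # int over [0,dt] of e^{-k(dt-s)} (c0 + (c1-c0) s/dt) ds
        a_coef = (1.0 - e) / k - (dt - (1.0 - e) / k) / kd  # weight of c_n
        b_coef = (dt - (1.0 - e) / k) / kd  # weight of c_{n+1}
        decay = e
    y = lfilter([b_coef, a_coef], [1.0, -decay], c)
    if c[0] != 0.0:
        # the filter seeds y[0] = B c[0]; the true initial condition is y(0)=0
        n = np.arange(c.size)
        y = y - (b_coef * c[0]) * decay**n
    else:
        y[0] = 0.0
    return y


def reconstruct_fine_curve(
    schedule: FrameSchedule,
    frame_values: np.ndarray,
    dt: float = DEFAULT_DT,
    n_iter: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous curve consistent with observed frame averages.

    Interpolates frame means at frame midpoints (shape-preserving PCHIP,
    clipped at zero), then applies a few multiplicative corrections so the
    frame averages of the reconstruction match the observed values closely.
    Returns ``(times, values)``.
    """
    t = fine_grid(schedule, dt)
    mids = schedule.midpoints
    vals = np.asarray(frame_values, dtype=float)
    fine = np.clip(PchipInterpolator(mids, vals, extrapolate=True)(t), 0.0, None)
    if not np.any(fine > 0):
        return t, fine
    for _ in range(n_iter):
        fa = frame_average(t, fine, schedule)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(fa > 1e-12 * np.max(fa), vals / np.maximum(fa, 1e-300), 1.0)
        ratio = np.clip(ratio, 0.1, 10.0)
        corr = PchipInterpolator(mids, ratio, extrapolate=True)(t)
        fine = np.clip(fine * corr, 0.0, None)
    return t, fine
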