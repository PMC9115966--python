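"""Arterial input function: three-exponential (Feng-type) model.

The AIF is modelled, after an injection delay tau, as

    AIF(t) = (A1 (t - tau) - A2 - A3) e^{-mu1 (t - tau)}
           + A2 e^{-mu2 (t - tau)} + A3 e^{-mu3 (t - tau)},   t > tau

and zero before the delay; the form is continuous (AIF(tau) = 0) and has
a sharp first-pass peak governed by the linear term.  Rates are ordered
mu1 > mu2 > mu3 > 0.  Fits minimise the weighted residual sum of squares
with the frame weights of :func:`petflux.frames.compute_weights`, over a
multi-start grid of rate-constant initialisations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._expsum import ExpPolySum
from .frames import Curve, FrameSchedule, FrameWeights


@dataclass(frozen=True)
class AifParams:
    """Feng-type three-exponential AIF parameters.

    Units: tau min; A1 kBq mL^-1 min^-1; A2, A3 kBq/mL; mu1-3 1/min.
    """

    tau: float
    A1: float
    A2: float
    A3: float
    mu1: float
    mu2: float
    mu3: float

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("delay tau must be >= 0")
        if not (self.mu1 > self.mu2 > self.mu3 > 0):
            raise ValueError("rates must satisfy mu1 > mu2 > mu3 > 0")

    def as_expsum(self) -> ExpPolySum:
        return ExpPolySum(
            coef=[self.A1, -(self.A2 + self.A3), self.A2, self.A3],
            power=[1, 0, 0, 0],
            rate=[self.mu1, self.mu1, self.mu2, self.mu3],
            tau=self.tau,
        )

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.tau, self.A1, self.A2, self.A3, self.mu1, self.mu2, self.mu3]
        )


def eval_aif(params: AifParams, times) -> np.ndarray:
    """Analytic AIF evaluation at times (min); zero before the delay."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    return params.as_expsum()(times)


def frame_average_aif(params: AifParams, schedule: FrameSchedule) -> np.ndarray:
    """Exact frame-averaged AIF (what an idealised scanner records)."""
    f = params.as_expsum()
    return f.frame_averages(schedule.start_times_min, schedule.end_times_min)


@dataclass
class AifFit:
    params: AifParams
    wrss: float
    n_starts: int
    success: bool


def _canonical(x: np.ndarray) -> np.ndarray:
    """Sort the two free exponentials so mu2 > mu3 (the model is symmetric)."""
    tau, a1, a2, a3, m1, m2, m3 = x
    if m3 > m2:
        a2, a3, m2, m3 = a3, a2, m3, m2
    return np.array([tau, a1, a2, a3, m1, m2, m3])


def _i0(v, m):
    return (1.0 - np.exp(-m * v)) / m


def _i1(v, m):
    return (_i0(v, m) - v * np.exp(-m * v)) / m


def feng_frame_averages(x, starts_min, ends_min) -> np.ndarray:
    """Exact frame averages of the Feng AIF, vectorised over frames.

    ``x`` is the raw parameter vector (tau, A1, A2, A3, mu1, mu2, mu3);
    start/end times in minutes.  Frames fully before the delay average
    to zero; frames straddling it integrate from the delay onward.
    """
    tau, a1, a2, a3, m1, m2, m3 = x
    v0 = np.maximum(starts_min - tau, 0.0)
    v1 = np.maximum(ends_min - tau, 0.0)
    integral = (
        a1 * (_i1(v1, m1) - _i1(v0, m1))
        - (a2 + a3) * (_i0(v1, m1) - _i0(v0, m1))
        + a2 * (_i0(v1, m2) - _i0(v0, m2))
        + a3 * (_i0(v1, m3) - _i0(v0, m3))
    )
    return integral / (ends_min - starts_min)


def _residuals(x, starts, ends, y, sqrt_w):
    return sqrt_w * (feng_frame_averages(x, starts, ends) - y)


def fit_aif(
    aif_curve: Curve,
    weights: FrameWeights,
    max_delay: float = 2.0,
    n_rate_starts: int = 3,
) -> AifFit:
    """Weighted least-squares fit of the three-exponential AIF model.

    Fits exact frame averages of the model to the supplied frame values
    over all valid frames, multi-starting over a ``n_rate_starts``-per-rate
    decade grid; the start with the lowest achieved weighted RSS wins
    (ties broken by earliest start index).  The delay is bounded to
    [0, max_delay] min.
    """
    sched = aif_curve.schedule
    y = aif_curve.values
    m = weights.valid
    if m.sum() < 7:
        raise ValueError("need at least 7 valid frames to fit 7 parameters")
    starts = sched.start_times_min[m]
    ends = sched.end_times_min[m]
    t = sched.mid_times_min[m]
    y, sw = y[m], np.sqrt(weights.weights[m])

    peak = max(y.max(), 1e-6)
    t_peak = max(t[np.argmax(y)], 0.05)
    tail = max(y[-1], 1e-3 * peak)

    mu1_grid = np.geomspace(1.0, 10.0, n_rate_starts)
    mu2_grid = np.geomspace(0.05, 0.5, n_rate_starts)
    mu3_grid = np.geomspace(0.005, 0.05, n_rate_starts)

    lb = np.array([0.0, 0.0, 0.0, 0.0, 0.5, 0.02, 1e-4])
    ub = np.array([max_delay, np.inf, np.inf, np.inf, 50.0, 2.0, 0.1])

    best = None
    idx = 0
    for m1 in mu1_grid:
        for m2 in mu2_grid:
            for m3 in mu3_grid:
                a1 = peak * m1 * np.e  # peak of a1*v*exp(-m1 v) is a1/(m1 e)
                x0 = np.array(
                    [max(t_peak - 1.0 / m1, 0.0), a1, 0.3 * tail, tail, m1, m2, m3]
                )
                x0 = np.clip(x0, lb + 1e-9, np.where(np.isinf(ub), x0, ub - 1e-9))
                try:
                    res = least_squares(
                        _residuals,
                        x0,
                        bounds=(lb, ub),
                        args=(starts, ends, y, sw),
                        method="trf",
                        xtol=1e-12,
                        ftol=1e-12,
                        gtol=1e-12,
                        max_nfev=2000,
                    )
                except Exception:
                    idx += 1
                    continue
                wrss = float(np.sum(res.fun**2))
                if res.success and (best is None or wrss < best[0] - 1e-15):
                    best = (wrss, _canonical(res.x), idx)
                idx += 1
    if best is None:
        raise RuntimeError(
            "AIF fit failed to converge from any of the "
            f"{n_rate_starts**3} multi-start initialisations"
        )
    wrss, x, _ = best
    tau, a1, a2, a3, m1, m2, m3 = x
    # guard strict ordering required by AifParams
    eps = 1e-9
    m2 = min(m2, m1 - eps)
    m3 = min(m3, m2 - eps)
    params = AifParams(tau=tau, A1=a1, A2=a2, A3=a3, mu1=m1, mu2=m2, mu3=m3)
    return AifFit(params=params, wrss=wrss, n_starts=n_rate_starts**3, success=True)
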