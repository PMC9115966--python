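"""Model assessment: LOOCV, residual runs test, profile-likelihood errors.

Kinetic models fitted to the same TAC are inter-compared with
leave-one-time-frame-out cross-validation on the weighted residual
sum-of-squares metric, residual sign structure is tested with the
Wald-Wolfowitz runs test, and parameter uncertainties come from profile
likelihood on the weighted objective scaled by s = dof_best / WSS_best
(degrees of freedom of the best-fitting model over its weighted
sum-of-squares, which calibrates the otherwise relative weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import norm

from .aif import AifParams
from .frames import Curve, FrameSchedule, FrameWeights
from .kinetics import (
    COMPARTMENT_MODELS,
    KineticFit,
    fit_compartment,
    fit_spline_residue,
    model_tac_frame_values,
)

# --------------------------------------------------------------------------
# leave-one-frame-out cross-validation
# --------------------------------------------------------------------------


@dataclass
class LoocvResult:
    model_id: str
    score: float  # sum over frames of w_i (pred_i - obs_i)^2
    per_frame: np.ndarray
    partial: bool = False
    failed_frames: list = field(default_factory=list)


def loocv_score(
    model_id: str,
    tac: Curve,
    aif_params: AifParams,
    schedule: FrameSchedule,
    weights: FrameWeights,
    full_fit: KineticFit | None = None,
    seed: int = 0,
) -> LoocvResult:
    """Leave-one-time-frame-out prediction error of a kinetic model.

    Each valid frame is dropped in turn, the model refitted (warm-started
    from the full-data optimum), and the held-out frame predicted; the
    score accumulates w_i * (pred_i - obs_i)^2.  Supports the compartment
    models and the spline-residue model.
    """
    valid_idx = np.flatnonzero(weights.valid)
    per_frame = np.full(schedule.n_frames, np.nan)
    failed = []

    if model_id in COMPARTMENT_MODELS:
        if full_fit is None:
            full_fit = fit_compartment(
                model_id, tac, aif_params, schedule, weights, seed=seed
            )
        spec = COMPARTMENT_MODELS[model_id]
        x_full = np.array([full_fit.params[n] for n in spec.param_names])
        for i in valid_idx:
            w_i = FrameWeights(
                weights=np.where(np.arange(schedule.n_frames) == i, 0.0,
                                 weights.weights)
            )
            try:
                refit = fit_compartment(
                    model_id, tac, aif_params, schedule, w_i, x0=x_full
                )
                x = np.array([refit.params[n] for n in spec.param_names])
                pred = model_tac_frame_values(model_id, x, aif_params, schedule)[i]
            except Exception:
                failed.append(int(i))
                continue
            per_frame[i] = weights.weights[i] * (pred - tac.values[i]) ** 2
    elif model_id == "spline":
        base = full_fit or fit_spline_residue(tac, aif_params, schedule, weights)
        design = base.extras["design"]
        interior = base.extras["interior_knots"]
        for i in valid_idx:
            w_i = FrameWeights(
                weights=np.where(np.arange(schedule.n_frames) == i, 0.0,
                                 weights.weights)
            )
            try:
                refit = fit_spline_residue(
                    tac, aif_params, schedule, w_i, interior_knots=interior
                )
                # predict the held-out frame from the refitted coefficients
                from .aif import frame_average_aif

                theta = refit.extras["theta"]
                pred = design[i] @ theta + refit.params["Vb"] * (
                    frame_average_aif(aif_params, schedule)[i]
                )
            except Exception:
                failed.append(int(i))
                continue
            per_frame[i] = weights.weights[i] * (pred - tac.values[i]) ** 2
    else:
        raise ValueError(f"LOOCV not defined for model {model_id!r}")

    score = float(np.nansum(per_frame))
    return LoocvResult(
        model_id=model_id,
        score=score,
        per_frame=per_frame,
        partial=bool(failed),
        failed_frames=failed,
    )


# --------------------------------------------------------------------------
# Wald-Wolfowitz runs test
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RunsTest:
    n_runs: int
    n_pos: int
    n_neg: int
    z: float
    p: float  # two-sided; nan when undefined


def runs_test(residuals) -> RunsTest:
    """Wald-Wolfowitz runs test on residual signs.

    Zero residuals are dropped; the run count is exact, and the two-sided
    p-value uses the conditional normal approximation with a continuity
    correction.  With fewer than two residuals of either sign the test is
    degenerate and p is reported as nan.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0.0])
    if signs.size < 2:
        raise ValueError("need at least 2 nonzero residuals")
    n_runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    n = n_pos + n_neg
    if n_pos < 1 or n_neg < 1:
        return RunsTest(n_runs, n_pos, n_neg, z=np.nan, p=np.nan)
    mu = 1.0 + 2.0 * n_pos * n_neg / n
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return RunsTest(n_runs, n_pos, n_neg, z=np.nan, p=np.nan)
    diff = n_runs - mu
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(var) if diff != 0 else 0.0
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return RunsTest(n_runs, n_pos, n_neg, z=float(z), p=p)


def runs_distribution_exact(n_pos: int, n_neg: int) -> dict:
    """Exact conditional distribution of the run count given the sign
    counts, by enumeration over all arrangements (oracle-grade; small n)."""
    from itertools import combinations
    from math import comb

    n = n_pos + n_neg
    counts: dict[int, int] = {}
    for pos_positions in combinations(range(n), n_pos):
        s = np.full(n, -1)
        s[list(pos_positions)] = 1
        runs = int(1 + np.sum(s[1:] != s[:-1]))
        counts[runs] = counts.get(runs, 0) + 1
    total = comb(n, n_pos)
    return {k: v / total for k, v in sorted(counts.items())}


# --------------------------------------------------------------------------
# profile-likelihood uncertainties
# --------------------------------------------------------------------------


@dataclass
class ProfileBound:
    parameter: str
    estimate: float
    lower: float
    upper: float
    lower_censored: bool = False
    upper_censored: bool = False

    @property
    def half_width(self) -> float:
        return 0.5 * (self.upper - self.lower)


def wss_scale_factor(n_valid_frames: int, n_params: int, wrss: float) -> float:
    """Objective scale s = dof / WSS of the best model's fit."""
    dof = n_valid_frames - n_params
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    if wrss <= 0:
        raise ValueError("WSS must be positive to set the scale")
    return dof / wrss


def _profile_objective_factory(
    model_id: str,
    target: str,
    tac: Curve,
    aif_params: AifParams,
    schedule: FrameSchedule,
    weights: FrameWeights,
):
    """Return (wss_profiled(value, warm_start) -> (wss, x_opt), free names,
    full->free warm start extractor).

    ``target`` may be a micro-parameter or ``"kflux"`` (2C3K only), the
    latter profiled through the reparameterisation K1 = kflux (k2+k3)/k3.
    """
    spec = COMPARTMENT_MODELS[model_id]
    valid = weights.valid
    y = tac.values[valid]
    sw = np.sqrt(weights.weights[valid])
    lb_all, ub_all = spec.bounds()

    if target == "kflux":
        if model_id != "2C3K":
            raise ValueError("kflux profiling implemented for the 2C3K model")
        free = [n for n in spec.param_names if n != "K1"]  # k2, k3, Vb
        idx = [spec.param_names.index(n) for n in free]
        lb, ub = lb_all[idx], ub_all[idx]
        lb[free.index("k3")] = 1e-6  # K1 = kflux (k2+k3)/k3 needs k3 > 0

        def assemble(value, xfree):
            k2, k3, vb = xfree
            K1 = value * (k2 + k3) / k3
            return np.array([K1, k2, k3, vb])

    else:
        if target not in spec.param_names:
            raise ValueError(f"{target!r} is not a parameter of {model_id}")
        free = [n for n in spec.param_names if n != target]
        idx = [spec.param_names.index(n) for n in free]
        lb, ub = lb_all[idx], ub_all[idx]
        t_idx = spec.param_names.index(target)

        def assemble(value, xfree):
            x = np.empty(spec.n_params)
            x[t_idx] = value
            x[idx] = xfree
            return x

    def wss_profiled(value, warm):
        def residuals(xfree):
            x = assemble(value, xfree)
            pred = model_tac_frame_values(model_id, x, aif_params, schedule)[valid]
            return sw * (pred - y)

        res = least_squares(
            residuals, np.clip(warm, lb + 1e-12, ub - 1e-12),
            bounds=(lb, ub), method="trf",
            xtol=1e-10, ftol=1e-10, max_nfev=200,
        )
        return float(np.sum(res.fun**2)), res.x

    return wss_profiled, free, idx, assemble


def profile_uncertainty(
    model_id: str,
    fit: KineticFit,
    tac: Curve,
    aif_params: AifParams,
    schedule: FrameSchedule,
    weights: FrameWeights,
    scale: float | None = None,
    parameters=None,
    delta: float = 1.0,
) -> dict:
    """1-SD profile-likelihood bounds for each requested parameter.

    The profiled objective is s * WSS(theta) with all other parameters
    re-optimised; bounds sit where the profile rises ``delta`` (default
    1.0, the chi-square 1-dof 1-SD convention) above its minimum.  When
    ``scale`` is None it is computed from this fit (dof / WSS).  Bounds
    that never cross within the box are censored at the box edge.
    """
    spec = COMPARTMENT_MODELS[model_id]
    n_valid = int(weights.valid.sum())
    if scale is None:
        scale = wss_scale_factor(n_valid, spec.n_params, fit.wrss)
    if parameters is None:
        parameters = list(spec.param_names)

    out = {}
    for target in parameters:
        if target == "kflux":
            est = fit.k_flux
            box_lo, box_hi = 0.0, RATE_BOUND_FOR_FLUX
        else:
            est = fit.params[target]
            lb_all, ub_all = spec.bounds()
            i = spec.param_names.index(target)
            box_lo, box_hi = float(lb_all[i]), float(ub_all[i])
        wss_prof, free, idx, _ = _profile_objective_factory(
            model_id, target, tac, aif_params, schedule, weights
        )
        warm0 = np.array([fit.params[n] for n in free])
        f_min, _ = wss_prof(est, warm0)
        threshold = scale * f_min + delta

        def g(value, warm_box={"x": warm0}):
            wss, xopt = wss_prof(value, warm_box["x"])
            warm_box["x"] = xopt
            return scale * wss - threshold

        lower, lo_cens = _walk_crossing(g, est, box_lo, direction=-1)
        upper, hi_cens = _walk_crossing(g, est, box_hi, direction=+1)
        out[target] = ProfileBound(
            parameter=target, estimate=est, lower=lower, upper=upper,
            lower_censored=lo_cens, upper_censored=hi_cens,
        )
    return out


RATE_BOUND_FOR_FLUX = 5.0


def _walk_crossing(g, start, box_edge, direction, n_steps=40):
    """Expanding walk from the optimum to bracket g = 0, then brentq."""
    scale = max(abs(start), 1e-3)
    prev = start
    for k in range(1, n_steps + 1):
        step = scale * (0.08 * 1.6 ** (k - 1))
        x = start + direction * step
        if direction < 0 and x <= box_edge:
            x = box_edge
        if direction > 0 and x >= box_edge:
            x = box_edge
        val = g(x)
        if val >= 0:
            lo, hi = (x, prev) if direction < 0 else (prev, x)
            if lo == hi:
                return x, True
            root = brentq(g, lo, hi, xtol=1e-6 * max(scale, 1.0), rtol=1e-6)
            return float(root), False
        prev = x
        if x == box_edge:
            return float(box_edge), True
    return float(prev), True


# --------------------------------------------------------------------------
# linear-model recast (oracle hook for the profiling machinery)
# --------------------------------------------------------------------------


def profile_linear_wls(X, y, w, target_index, delta=1.0):
    """Profile-likelihood 1-SD bounds for a weighted linear regression,
    run through the same scaled-WSS machinery (scale = dof/WSS).

    Used to validate the profiling construction against closed-form WLS
    standard errors.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    wss = float(np.sum((sw * (X @ beta - y)) ** 2))
    dof = X.shape[0] - X.shape[1]
    s = dof / wss

    others = [j for j in range(X.shape[1]) if j != target_index]

    def wss_at(value):
        resid = y - value * X[:, target_index]
        if others:
            b, *_ = np.linalg.lstsq(X[:, others] * sw[:, None], resid * sw,
                                    rcond=None)
            resid = resid - X[:, others] @ b
        return float(np.sum((sw * resid) ** 2))

    threshold = s * wss + delta

    def g(v):
        return s * wss_at(v) - threshold

    est = beta[target_index]
    width = max(abs(est), 1.0)
    lo = est
    while g(lo) < 0:
        lo -= 0.5 * width
    hi = est
    while g(hi) < 0:
        hi += 0.5 * width
    lower = brentq(g, lo, est)
    upper = brentq(g, est, hi)
    return est, lower, upper
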