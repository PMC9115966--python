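"""Tracer kinetic models of tumour FDG uptake and their flux-constants.

Every model predicts a tumour time-activity curve from the arterial input
function through the convolution forward model

    TAC(t) = K1 * int_0^t AIF(s) R(t - s) ds  +  Vb * AIF(t)

where R(t) is the residue function (fraction of delivered tracer still in
tissue at time t, R(0) = 1) and Vb the fractional blood volume.  Models:

``2C3K``
    irreversible two-tissue compartment model (K1, k2, k3, Vb);
    R(inf) = k3/(k2+k3), flux-constant k_flux = K1 k3 / (k2 + k3).
``2C4K``
    reversible two-tissue model (adds k4); k_flux reported
    operationally as K1 * R(T_scan).
``3C5K``
    irreversible three-tissue chain: plasma ->(K1) free ->(k3, back k4)
    bound ->(k5) trapped, with efflux k2 from free;
    k_flux = K1 k3 k5 / (k2 k4 + k2 k5 + k3 k5).
``patlak``
    graphical late-time linear analysis; the slope K is the simplest
    flux-constant estimate.
``spline``
    nonparametric residue: R(t) a cubic B-spline constrained to
    R(0) = 1, non-increasing, >= 0; k_flux = K1 * R(T_scan).

Compartment residue functions are multi-exponential, obtained by
eigen-decomposition of the model's rate matrix, so model TACs and their
frame averages are fully analytic for an exponential-family AIF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import least_squares, lsq_linear
from scipy.signal import fftconvolve

from ._expsum import ExpPolySum
from .aif import AifParams, eval_aif, frame_average_aif
from .frames import Curve, FrameSchedule, FrameWeights

RATE_BOUND = 5.0  # 1/min, upper box bound for rate constants
VB_BOUND = 0.5  # upper box bound for fractional blood volume


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    param_names: tuple
    irreversible: bool

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def bounds(self):
        lb = np.zeros(self.n_params)
        ub = np.array(
            [VB_BOUND if n == "Vb" else RATE_BOUND for n in self.param_names]
        )
        return lb, ub


COMPARTMENT_MODELS = {
    "2C3K": ModelSpec("2C3K", ("K1", "k2", "k3", "Vb"), irreversible=True),
    "2C4K": ModelSpec("2C4K", ("K1", "k2", "k3", "k4", "Vb"), irreversible=False),
    "3C5K": ModelSpec("3C5K", ("K1", "k2", "k3", "k4", "k5", "Vb"), irreversible=True),
}

MODEL_IDS = ("patlak", "2C3K", "2C4K", "3C5K", "spline")


@dataclass
class KineticFit:
    """Result of fitting one kinetic model to one tumour TAC."""

    model_id: str
    params: dict
    wrss: float
    k_flux: float
    residue: Callable | None = None
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# residue functions
# --------------------------------------------------------------------------


def _rate_matrix(model_id: str, params: dict) -> np.ndarray:
    if model_id == "2C3K":
        k2, k3 = params["k2"], params["k3"]
        return np.array([[-(k2 + k3), 0.0], [k3, 0.0]])
    if model_id == "2C4K":
        k2, k3, k4 = params["k2"], params["k3"], params["k4"]
        return np.array([[-(k2 + k3), k4], [k3, -k4]])
    if model_id == "3C5K":
        k2, k3, k4, k5 = params["k2"], params["k3"], params["k4"], params["k5"]
        return np.array(
            [
                [-(k2 + k3), k4, 0.0],
                [k3, -(k4 + k5), 0.0],
                [0.0, k5, 0.0],
            ]
        )
    raise ValueError(f"unknown compartment model {model_id!r}")


def residue_coefficients(model_id: str, params: dict):
    """Multi-exponential residue  R(t) = sum_j c_j exp(-b_j t)  (b_j >= 0).

    Computed from the eigen-decomposition of the compartmental rate
    matrix; a deterministic 1e-9 relative jitter of the rates resolves
    the measure-zero parameter combinations whose matrix is defective.
    """
    for name, val in params.items():
        if name != "Vb" and val < 0:
            raise ValueError(f"rate constant {name} must be >= 0")
    p = dict(params)
    for attempt in range(3):
        a = _rate_matrix(model_id, p)
        lam, vec = np.linalg.eig(a)
        scale = max(np.max(np.abs(lam)), 1.0)
        dists = np.abs(lam[:, None] - lam[None, :])
        np.fill_diagonal(dists, np.inf)
        if dists.min() > 1e-9 * scale and np.linalg.cond(vec) < 1e12:
            break
        # nudge the rates to split repeated eigenvalues
        p = {
            k: (v * (1.0 + (i + 1) * (attempt + 1) * 1e-9) if k != "Vb" else v)
            for i, (k, v) in enumerate(p.items())
        }
    weights = np.linalg.solve(vec, np.eye(a.shape[0])[:, 0])
    coefs = (vec.sum(axis=0) * weights).real
    rates = np.maximum(-lam.real, 0.0)
    return coefs, rates


def residue_function(model_id: str, params: dict, times) -> np.ndarray:
    """Residue function values for a compartment model; R(0) = 1."""
    coefs, rates = residue_coefficients(model_id, params)
    times = np.asarray(times, dtype=float)
    return np.exp(-np.outer(times, rates)) @ coefs


# --------------------------------------------------------------------------
# flux constants
# --------------------------------------------------------------------------


def flux_constant_closed_form(model_id: str, params: dict) -> float:
    """Closed-form k_flux = K1 * R(inf) for the irreversible models."""
    K1 = params["K1"]
    if model_id == "2C3K":
        k2, k3 = params["k2"], params["k3"]
        if k2 + k3 == 0.0:
            return K1  # nothing leaves the free compartment
        return K1 * k3 / (k2 + k3)
    if model_id == "3C5K":
        k2, k3, k4, k5 = params["k2"], params["k3"], params["k4"], params["k5"]
        den = k2 * k4 + k2 * k5 + k3 * k5
        if den == 0.0:
            # degenerate wiring: fall back on the trapped fraction at t -> inf
            coefs, rates = residue_coefficients(model_id, params)
            return K1 * float(coefs[rates < 1e-12].sum())
        return K1 * k3 * k5 / den
    raise ValueError(f"no closed-form flux constant for model {model_id!r}")


def flux_constant(fit: KineticFit, schedule: FrameSchedule) -> float:
    """Flux-constant of a fitted model.

    Irreversible compartment models use their closed form (= K1 R(inf));
    the Patlak slope is its own flux-constant; the reversible 2C4K and
    the spline model use the operational K1 * R(T_scan).
    """
    if fit.model_id in ("2C3K", "3C5K"):
        return flux_constant_closed_form(fit.model_id, fit.params)
    if fit.model_id == "patlak":
        return fit.params["K"]
    if fit.model_id in ("2C4K", "spline"):
        r = fit.residue(np.array([schedule.t_scan_min]))[0]
        return fit.params["K1"] * float(r)
    raise ValueError(f"unknown model {fit.model_id!r}")


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------


def tissue_response(model_id: str, params: dict, aif_params: AifParams) -> ExpPolySum:
    """K1 * (AIF conv R) as an analytic curve (no blood-volume term)."""
    coefs, rates = residue_coefficients(model_id, params)
    aif = aif_params.as_expsum()
    total = None
    for c, b in zip(coefs, rates):
        piece = aif.convolve_exp(b, amplitude=params["K1"] * c)
        total = piece if total is None else total + piece
    return total


def model_tac(
    model_id: str, params: dict, aif_params: AifParams, schedule: FrameSchedule
) -> Curve:
    """Frame-averaged model TAC:  K1 (AIF conv R) + Vb AIF."""
    tissue = tissue_response(model_id, params, aif_params)
    starts, ends = schedule.start_times_min, schedule.end_times_min
    vals = tissue.frame_averages(starts, ends) + params.get("Vb", 0.0) * (
        aif_params.as_expsum().frame_averages(starts, ends)
    )
    return Curve(schedule=schedule, values=vals)


def model_tac_frame_values(
    model_id: str,
    param_vector: np.ndarray,
    aif_params: AifParams,
    schedule: FrameSchedule,
) -> np.ndarray:
    spec = COMPARTMENT_MODELS[model_id]
    params = dict(zip(spec.param_names, param_vector))
    return model_tac(model_id, params, aif_params, schedule).values


# --------------------------------------------------------------------------
# compartment-model fitting
# --------------------------------------------------------------------------

_DEFAULT_CENTRES = {"K1": 0.1, "k2": 0.3, "k3": 0.08, "k4": 0.02, "k5": 0.02,
                    "Vb": 0.05}


def multistart_points(model_id: str, n_starts: int, seed: int) -> np.ndarray:
    """Seeded log-normal jitter around physiological centres (first start
    is the unjittered centre)."""
    spec = COMPARTMENT_MODELS[model_id]
    centre = np.array([_DEFAULT_CENTRES[n] for n in spec.param_names])
    rng = np.random.default_rng(seed)
    starts = [centre]
    for _ in range(n_starts - 1):
        starts.append(centre * np.exp(rng.normal(0.0, 1.0, size=centre.size)))
    lb, ub = spec.bounds()
    return np.clip(np.array(starts), lb + 1e-6, ub - 1e-6)


def fit_compartment(
    model_id: str,
    tac: Curve,
    aif_params: AifParams,
    schedule: FrameSchedule,
    weights: FrameWeights,
    n_starts: int = 8,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> KineticFit:
    """Box-bounded weighted least-squares fit of a compartment model.

    Multi-start (``n_starts`` seeded initialisations) unless an explicit
    warm start ``x0`` is given; the lowest weighted RSS wins, ties broken
    by start index.
    """
    spec = COMPARTMENT_MODELS[model_id]
    valid = weights.valid
    if valid.sum() <= spec.n_params:
        raise ValueError("need more valid frames than parameters")
    y = tac.values[valid]
    sw = np.sqrt(weights.weights[valid])

    def residuals(x):
        pred = model_tac_frame_values(model_id, x, aif_params, schedule)[valid]
        return sw * (pred - y)

    lb, ub = spec.bounds()
    if x0 is not None:
        start_points = np.clip(np.asarray(x0, dtype=float), lb, ub)[None, :]
    else:
        start_points = multistart_points(model_id, n_starts, seed)

    best = None
    for i, s in enumerate(start_points):
        try:
            res = least_squares(
                residuals, s, bounds=(lb, ub), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=400,
            )
        except Exception:
            continue
        wrss = float(np.sum(res.fun**2))
        if best is None or wrss < best[0] - 1e-15:
            best = (wrss, res.x, i)
    if best is None:
        raise RuntimeError(f"{model_id} fit failed from every start point")
    wrss, x, _ = best
    params = dict(zip(spec.param_names, x))
    fit = KineticFit(
        model_id=model_id,
        params=params,
        wrss=wrss,
        k_flux=np.nan,
        residue=lambda t, p=dict(params): residue_function(model_id, p, t),
    )
    fit.k_flux = flux_constant(fit, schedule)
    return fit


# --------------------------------------------------------------------------
# Patlak graphical analysis
# --------------------------------------------------------------------------


def patlak_fit(
    tac: Curve,
    aif,
    schedule: FrameSchedule,
    t_star: float = 10.0,
) -> KineticFit:
    """Patlak plot: OLS of TAC/AIF against int_0^t AIF / AIF, t >= t_star.

    ``aif`` may be fitted :class:`AifParams` (analytic integral) or a
    measured blood :class:`~petflux.frames.Curve` (trapezoidal integral).
    The slope K is the Patlak flux-constant, the intercept the apparent
    distribution volume.
    """
    mids = schedule.mid_times_min
    if isinstance(aif, AifParams):
        f = aif.as_expsum()
        aif_vals = eval_aif(aif, np.maximum(mids, 0.0))
        aif_cum = f.cumulative(np.maximum(mids, 0.0))
    else:
        aif_vals = aif.values
        post = np.maximum(mids, 0.0)
        widths = schedule.durations_s / 60.0
        cum_edges = np.concatenate([[0.0], np.cumsum(aif.values * widths)])
        aif_cum = cum_edges[:-1] + aif.values * (
            post - np.maximum(schedule.start_times_min, 0.0)
        )
    late = (mids >= t_star) & (aif_vals > 0)
    if late.sum() < 3:
        raise ValueError("need at least 3 frames at or beyond t_star")
    x = aif_cum[late] / aif_vals[late]
    y = tac.values[late] / aif_vals[late]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return KineticFit(
        model_id="patlak",
        params={"K": float(slope), "V": float(intercept)},
        wrss=float(np.sum(resid**2)),
        k_flux=float(slope),
        extras={"n_frames": int(late.sum()), "t_star": t_star,
                "x": x, "y": y, "residuals": resid},
    )


# --------------------------------------------------------------------------
# spline-residue model
# --------------------------------------------------------------------------


def default_knots(t_scan: float, n_interior: int = 6) -> np.ndarray:
    """Geometrically spaced interior knots on (0, ~2/3 t_scan]."""
    return np.geomspace(0.5, t_scan * 2.0 / 3.0, n_interior)


def _spline_design(
    aif_params: AifParams,
    schedule: FrameSchedule,
    interior_knots: np.ndarray,
    grid_dt: float = 0.005,
):
    """Frame-averaged convolutions of the AIF with each B-spline basis.

    Returns (knot vector, frame x basis matrix, basis count).
    """
    t_end = schedule.end_times_min[-1]
    kv = np.concatenate([[0.0] * 4, np.asarray(interior_knots, float), [t_end] * 4])
    n_basis = len(interior_knots) + 4
    grid = np.arange(0.0, t_end + grid_dt, grid_dt)
    aif_vals = eval_aif(aif_params, grid)
    starts = np.maximum(schedule.start_times_min, 0.0)
    ends = schedule.end_times_min
    design = np.empty((schedule.n_frames, n_basis))
    for b in range(n_basis):
        c = np.zeros(n_basis)
        c[b] = 1.0
        basis = BSpline(kv, c, 3, extrapolate=False)(grid)
        basis = np.nan_to_num(basis)
        conv = fftconvolve(aif_vals, basis)[: grid.size] * grid_dt
        conv -= 0.5 * grid_dt * aif_vals * basis[0]  # trapezoid end correction
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (conv[1:] + conv[:-1]) * grid_dt)])
        frame_int = np.interp(ends, grid, cum) - np.interp(starts, grid, cum)
        width = ends - starts
        design[:, b] = np.divide(frame_int, width, out=np.zeros_like(width),
                                 where=width > 0)
    return kv, design, n_basis


def fit_spline_residue(
    tac: Curve,
    aif_params: AifParams,
    schedule: FrameSchedule,
    weights: FrameWeights,
    interior_knots: np.ndarray | None = None,
) -> KineticFit:
    """Constrained weighted least-squares fit of the spline-residue model.

    R(t) is a clamped cubic B-spline with R(0) = 1, non-increasing and
    non-negative, imposed through the sufficient condition of
    non-increasing, non-negative B-spline coefficients.  Writing
    theta_b = K1 w_b, the constraint cone is theta_0 >= theta_1 >= ...
    >= 0, which the substitution theta = L delta (delta >= 0, L lower
    triangular of ones) turns into a bounded *linear* least-squares
    problem in (delta, Vb) -- convex, solved globally by scipy's
    lsq_linear with no multi-start.  K1 = theta_0 and
    k_flux = K1 R(T_scan) = theta_last.
    """
    if interior_knots is None:
        interior_knots = default_knots(schedule.t_scan_min)
    kv, design, n_basis = _spline_design(aif_params, schedule, interior_knots)
    valid = weights.valid
    if valid.sum() <= n_basis + 1:
        raise ValueError("need more valid frames than free parameters")
    sw = np.sqrt(weights.weights[valid])
    aif_frames = frame_average_aif(aif_params, schedule)

    ltri = np.tril(np.ones((n_basis, n_basis))).T  # theta_b = sum_{j>=b} delta_j
    a_mat = np.column_stack([design[valid] @ ltri, aif_frames[valid]]) * sw[:, None]
    b_vec = tac.values[valid] * sw
    lb = np.zeros(n_basis + 1)
    ub = np.concatenate([np.full(n_basis, np.inf), [VB_BOUND]])
    sol = lsq_linear(a_mat, b_vec, bounds=(lb, ub), tol=1e-14)
    delta, vb = sol.x[:-1], sol.x[-1]
    theta = ltri @ delta
    K1 = float(theta[0])
    coeffs = theta / K1 if K1 > 0 else np.zeros_like(theta)
    spline = BSpline(kv, coeffs, 3, extrapolate=False)

    def residue(t, s=spline):
        return np.nan_to_num(s(np.asarray(t, dtype=float)))

    wrss = float(np.sum((a_mat @ sol.x - b_vec) ** 2))
    fit = KineticFit(
        model_id="spline",
        params={"K1": K1, "Vb": float(vb)},
        wrss=wrss,
        k_flux=float(theta[-1]),
        residue=residue,
        extras={"theta": theta, "coeffs": coeffs, "knots": kv,
                "interior_knots": np.asarray(interior_knots, float),
                "design": design},
    )
    return fit


# --------------------------------------------------------------------------
# static uptake measures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StaticMeasures:
    """SUV and tumour-to-blood ratio measures from the late static scan."""

    suv_max: float
    suv_mean: float
    tbr_max: float
    tbr_mean: float


def static_measures(
    tumour_max_conc: float,
    tumour_mean_conc: float,
    blood_mean_conc: float,
    injected_dose: float,
    body_weight: float,
) -> StaticMeasures:
    """SUV = concentration / (dose / weight); TBR = tumour conc / blood conc.

    Concentrations in kBq/mL, dose in kBq, weight in g (1 g/mL tissue
    density convention makes SUV unitless).
    """
    for name, v in [
        ("tumour_max_conc", tumour_max_conc),
        ("tumour_mean_conc", tumour_mean_conc),
        ("blood_mean_conc", blood_mean_conc),
        ("injected_dose", injected_dose),
        ("body_weight", body_weight),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    norm = injected_dose / body_weight
    return StaticMeasures(
        suv_max=tumour_max_conc / norm,
        suv_mean=tumour_mean_conc / norm,
        tbr_max=tumour_max_conc / blood_mean_conc,
        tbr_mean=tumour_mean_conc / blood_mean_conc,
    )
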