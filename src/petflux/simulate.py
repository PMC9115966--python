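"""Synthetic cohorts: AIFs, tumour TACs, static uptake inputs, expression.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without patient data:

* per-patient Feng-type three-exponential AIFs with log-normal
  between-patient variation;
* tumour TACs generated from a known kinetic model through the exact
  convolution forward model, with zero-mean Gaussian frame noise of
  variance proportional to A_i/dT_i * exp(lambda t_i) -- the inverse of
  the least-squares frame weight -- so the fitting weights are the
  matched inverse-variance scheme;
* static-scan inputs (tumour and blood concentrations, injected dose,
  body weight) derived from the late-time curves, so SUV and TBR come
  out of the same formulas as for real data and correlate with the true
  flux-constant by construction;
* a log2 gene-expression matrix in which planted pathway genes have a
  chosen population correlation with a named imaging measure
  (x = rho z + sqrt(1 - rho^2) eps on standardised scales) and filler
  genes are independent noise.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .aif import AifParams, frame_average_aif
from .frames import (
    F18_DECAY_CONSTANT,
    Curve,
    FrameSchedule,
    make_standard_schedule,
)
from .gsea import GeneSetCollection
from .kinetics import COMPARTMENT_MODELS, flux_constant_closed_form, model_tac

#: population-typical Feng AIF for a ~3 MBq/kg FDG injection, kBq/mL, 1/min
DEFAULT_AIF = AifParams(
    tau=0.3, A1=600.0, A2=6.0, A3=10.0, mu1=4.0, mu2=0.25, mu3=0.012
)

#: typical breast-tumour 2C3K micro-parameters (1/min; Vb unitless)
DEFAULT_2C3K = {"K1": 0.15, "k2": 0.35, "k3": 0.08, "Vb": 0.06}


def _noise_sd_per_frame(
    noiseless: np.ndarray,
    schedule: FrameSchedule,
    noise_scale: float,
    decay_constant: float = F18_DECAY_CONSTANT,
) -> np.ndarray:
    """sd_i = noise_scale * sqrt(A_i / dT_i * exp(lambda t_i)) (= 1/w_i)."""
    a = np.maximum(noiseless, 0.0)
    var = a / schedule.durations_s * np.exp(
        decay_constant * schedule.mid_times_min
    )
    return noise_scale * np.sqrt(var)


def simulate_aif(
    aif_params: AifParams,
    schedule: FrameSchedule,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> Curve:
    """Frame-averaged analytic AIF plus optional iid Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    vals = frame_average_aif(aif_params, schedule)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.size)
    return Curve(schedule=schedule, values=vals)


def simulate_tac(
    model_id: str,
    params: dict,
    aif_params: AifParams,
    schedule: FrameSchedule,
    seed: int = 0,
    noise_scale: float = 0.0,
) -> Curve:
    """Model TAC through the convolution forward model, plus frame noise.

    Noise per frame is zero-mean Gaussian with variance
    noise_scale^2 * A_i/dT_i * exp(lambda t_i), i.e. proportional to the
    inverse of the frame weight, making weighted least squares the
    matched estimator.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if model_id not in COMPARTMENT_MODELS:
        raise ValueError(f"unknown model_id {model_id!r}")
    curve = model_tac(model_id, params, aif_params, schedule)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = _noise_sd_per_frame(curve.values, schedule, noise_scale)
        curve = Curve(
            schedule=schedule,
            values=curve.values + rng.normal(0.0, 1.0, size=sd.size) * sd,
        )
    return curve


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass
class TruthDistributions:
    """Between-patient variation of the ground-truth generative process.

    Log-normal multiplicative scatter (geometric SD ``exp(sigma)``)
    around the population-typical AIF amplitudes/rates and kinetic
    micro-parameters.
    """

    aif: AifParams = DEFAULT_AIF
    aif_sigma: float = 0.15
    model_id: str = "2C3K"
    kinetic_centres: dict = field(default_factory=lambda: dict(DEFAULT_2C3K))
    kinetic_sigma: float = 0.35
    noise_scale: float = 1.0
    weight_mean_kg: float = 70.0
    weight_sd_kg: float = 12.0
    dose_per_kg_MBq: float = 3.0


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort (one row per patient)."""

    table: pd.DataFrame  # aif params, micro-parameters, true k_flux
    model_id: str


@dataclass
class StaticInputs:
    table: pd.DataFrame  # tumour max/mean, blood mean, dose, weight


def _draw_patient_aif(rng, dist: TruthDistributions) -> AifParams:
    base = dist.aif
    m = np.exp(rng.normal(0.0, dist.aif_sigma, size=6))
    mu1 = base.mu1 * m[3]
    mu2 = base.mu2 * m[4]
    mu3 = base.mu3 * m[5]
    # keep the rate ordering of the canonical form
    mu1 = max(mu1, 2.5 * mu2)
    mu2 = max(mu2, 3.0 * mu3)
    return AifParams(
        tau=float(rng.uniform(0.1, 0.6)),
        A1=base.A1 * m[0], A2=base.A2 * m[1], A3=base.A3 * m[2],
        mu1=mu1, mu2=mu2, mu3=mu3,
    )


def _draw_patient_params(rng, dist: TruthDistributions) -> dict:
    out = {}
    for name, centre in dist.kinetic_centres.items():
        if name == "Vb":
            out[name] = float(np.clip(centre * np.exp(
                rng.normal(0.0, dist.kinetic_sigma)), 0.005, 0.4))
        else:
            out[name] = float(centre * np.exp(
                rng.normal(0.0, dist.kinetic_sigma)))
    return out


def simulate_cohort(
    n_patients: int = 30,
    truth: TruthDistributions | None = None,
    seed: int = 0,
    schedule: FrameSchedule | None = None,
):
    """Simulate a cohort of (AIF, TAC) pairs with ground truth and
    static-scan inputs.

    Returns (curves, CohortTruth, StaticInputs) where ``curves`` is a
    list of per-patient dicts with keys ``aif`` and ``tac``.  Static
    inputs are tied to the late-time TAC so SUV/TBR correlate with the
    true flux-constant by construction.  A zero-variance truth
    distribution is flagged with a warning, not an error.
    """
    import warnings

    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    truth = truth or TruthDistributions()
    if truth.kinetic_sigma == 0.0 or truth.aif_sigma == 0.0:
        warnings.warn("degenerate truth distribution: zero between-patient "
                      "variance", stacklevel=2)
    schedule = schedule or make_standard_schedule()
    root = np.random.SeedSequence(seed)

    rows, statics, curves = [], [], []
    for pid, ss in enumerate(root.spawn(n_patients)):
        rng = np.random.default_rng(ss)
        aif_p = _draw_patient_aif(rng, truth)
        kin = _draw_patient_params(rng, truth)
        kflux = flux_constant_closed_form(truth.model_id, kin)
        aif_curve = simulate_aif(
            aif_p, schedule, seed=int(ss.generate_state(1)[0] % (2**31)),
            noise_sd=0.25 * truth.noise_scale,
        )
        tac = simulate_tac(
            truth.model_id, kin, aif_p, schedule,
            seed=int(ss.generate_state(2)[1] % (2**31)),
            noise_scale=truth.noise_scale,
        )
        weight_kg = float(np.clip(rng.normal(truth.weight_mean_kg,
                                             truth.weight_sd_kg), 45.0, 120.0))
        dose_kBq = truth.dose_per_kg_MBq * 1000.0 * weight_kg
        noiseless_late = model_tac(truth.model_id, kin, aif_p, schedule).values[-1]
        tumour_mean = noiseless_late * float(np.exp(rng.normal(0.0, 0.08)))
        tumour_max = tumour_mean * float(np.exp(rng.normal(np.log(1.6), 0.12)))
        blood_mean = float(
            aif_p.as_expsum()(np.array([schedule.t_scan_min]))[0]
            * np.exp(rng.normal(0.0, 0.05))
        )
        rows.append({
            "patient": pid,
            **{f"aif_{k}": v for k, v in vars(aif_p).items()},
            **kin,
            "k_flux": kflux,
        })
        statics.append({
            "patient": pid,
            "tumour_max_conc": tumour_max,
            "tumour_mean_conc": tumour_mean,
            "blood_mean_conc": blood_mean,
            "injected_dose_kBq": dose_kBq,
            "body_weight_g": weight_kg * 1000.0,
        })
        curves.append({"aif": aif_curve, "tac": tac, "aif_params": aif_p})

    truth_table = pd.DataFrame(rows).set_index("patient")
    static_table = pd.DataFrame(statics).set_index("patient")
    return (
        curves,
        CohortTruth(table=truth_table, model_id=truth.model_id),
        StaticInputs(table=static_table),
    )


# --------------------------------------------------------------------------
# gene expression
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedPathway:
    name: str
    gene_ids: tuple
    effect_size: float  # target correlation with the named measure
    measure: str

    def __post_init__(self):
        if not (-1.0 < self.effect_size < 1.0):
            raise ValueError("effect size must lie in (-1, 1)")


@dataclass
class SyntheticExpressionSpec:
    """Recipe for a synthetic log2 expression matrix."""

    n_genes: int = 2000
    n_patients: int = 30
    planted_pathways: tuple = ()
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        seen = set()
        for pw in self.planted_pathways:
            ids = set(pw.gene_ids)
            if ids & seen:
                raise ValueError(
                    f"pathway {pw.name!r} reuses genes planted elsewhere"
                )
            seen |= ids


def gene_ids(n_genes: int) -> list:
    width = max(5, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def make_planted_spec(
    n_genes: int = 2000,
    n_patients: int = 30,
    planted: Sequence[tuple] = (("PW_PLANTED", 50, 0.8, "k_flux"),),
    seed: int = 0,
    **kwargs,
) -> SyntheticExpressionSpec:
    """Convenience builder: ``planted`` holds (name, size, effect, measure)
    tuples; planted genes are assigned disjoint id blocks from the front."""
    ids = gene_ids(n_genes)
    pathways, cursor = [], 0
    for name, size, effect, measure in planted:
        pathways.append(
            PlantedPathway(name, tuple(ids[cursor:cursor + size]), effect,
                           measure)
        )
        cursor += size
    if cursor > n_genes:
        raise ValueError("planted pathways exceed the gene count")
    return SyntheticExpressionSpec(
        n_genes=n_genes, n_patients=n_patients,
        planted_pathways=tuple(pathways), seed=seed, **kwargs,
    )


def simulate_expression(
    spec: SyntheticExpressionSpec,
    measure_values: dict | pd.DataFrame | Sequence[float],
):
    """Generate the log2 expression matrix (genes x patients).

    ``measure_values`` supplies the imaging measure(s) named by the
    planted pathways -- a mapping/DataFrame of per-patient vectors, or a
    bare vector when a single measure is referenced.  Planted genes
    follow x = rho z + sqrt(1 - rho^2) eps with z the standardised
    measure, so their population correlation with the measure equals the
    effect size; filler genes are independent Gaussian noise.  Returns
    (DataFrame, annotation DataFrame flagging planted genes).
    """
    if isinstance(measure_values, (pd.DataFrame, dict)):
        measures = {k: np.asarray(measure_values[k], dtype=float)
                    for k in measure_values}
    else:
        vec = np.asarray(measure_values, dtype=float)
        names = {pw.measure for pw in spec.planted_pathways} or {"measure"}
        measures = {name: vec for name in names}
    for name, vec in measures.items():
        if vec.size != spec.n_patients:
            raise ValueError(
                f"measure {name!r} has {vec.size} values for "
                f"{spec.n_patients} patients"
            )

    rng = np.random.default_rng(spec.seed)
    ids = gene_ids(spec.n_genes)
    idx = {g: i for i, g in enumerate(ids)}
    means = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    X = means[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, spec.n_patients)
    )

    annot = pd.DataFrame({"gene": ids, "pathway": "", "effect_size": 0.0})
    for pw in spec.planted_pathways:
        z = measures[pw.measure]
        sdz = z.std()
        if sdz == 0:
            raise ValueError(f"measure {pw.measure!r} has zero variance")
        z = (z - z.mean()) / sdz
        rho = pw.effect_size
        for g in pw.gene_ids:
            i = idx[g]
            eps = rng.normal(0.0, 1.0, size=spec.n_patients)
            X[i] = means[i] + spec.noise_sd * (
                rho * z + np.sqrt(1.0 - rho**2) * eps
            )
            annot.loc[i, "pathway"] = pw.name
            annot.loc[i, "effect_size"] = rho
    if not np.all(np.isfinite(X)):
        raise RuntimeError("expression matrix contains non-finite entries")
    cols = [f"P{j:03d}" for j in range(spec.n_patients)]
    return pd.DataFrame(X, index=ids, columns=cols), annot.set_index("gene")


def make_collection(
    spec: SyntheticExpressionSpec,
    n_null_sets: int = 99,
    null_size: int = 50,
    seed: int = 1,
) -> GeneSetCollection:
    """Planted pathways plus random null sets drawn from filler genes."""
    ids = gene_ids(spec.n_genes)
    planted_ids = {g for pw in spec.planted_pathways for g in pw.gene_ids}
    filler = [g for g in ids if g not in planted_ids]
    rng = np.random.default_rng(seed)
    sets = {pw.name: list(pw.gene_ids) for pw in spec.planted_pathways}
    for j in range(n_null_sets):
        members = rng.choice(filler, size=null_size, replace=False)
        sets[f"PW_NULL_{j:03d}"] = list(members)
    return GeneSetCollection(sets=sets)
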