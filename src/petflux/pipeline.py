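"""End-to-end orchestration: simulate -> fit -> measures -> GSEA -> tables.

A single declarative YAML config drives the whole analysis; the master
seed fans out to per-stage substreams through numpy ``SeedSequence``
spawning (stage order is fixed, so changing one stage's inputs leaves the
other stages' draws unchanged).  Every output table is TSV with a header
comment naming the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .aif import fit_aif
from .cohort import permuted_phenotype_study
from .frames import compute_weights, make_standard_schedule
from .gsea import gsea_run, results_table
from .kinetics import (
    COMPARTMENT_MODELS,
    fit_compartment,
    fit_spline_residue,
    patlak_fit,
    static_measures,
)
from .simulate import make_collection, make_planted_spec, simulate_cohort, \
    simulate_expression

log = logging.getLogger(__name__)

_STAGES = ("simulate", "fit_aif", "fit_models", "measures", "expression",
           "gsea", "cohort_stats")


@dataclass
class RunConfig:
    """Declarative configuration of a full synthetic-cohort analysis."""

    out_dir: str = "petflux_run"
    seed: int = 0
    n_patients: int = 15
    models: tuple = ("patlak", "2C3K", "spline")
    t_star: float = 10.0
    n_knots: int = 6
    gsea_methods: tuple = ("pearson",)
    n_perm: int = 1000
    alpha_numerator: float = 0.035
    min_size: int = 15
    max_size: int = 500
    n_genes: int = 800
    planted: tuple = (("PW_PLANTED", 50, 0.8, "kflux_2C3K"),)
    n_null_sets: int = 49
    null_set_size: int = 50
    noise_scale: float = 1.0
    micro_parameter_gsea: bool = True
    fp_study_datasets: int = 0  # 0 disables the permuted-phenotype stage
    fp_study_measure: str = "SUVmean"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "gsea_methods", "planted"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in raw[key]
                )
        cfg = cls(**raw)
        for m in cfg.models:
            if m not in ("patlak", "spline") and m not in COMPARTMENT_MODELS:
                raise ValueError(f"unsupported model {m!r}")
        if cfg.seed < 0:
            raise ValueError("seed must be non-negative")
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # output location does not change identity
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def association_grid(gsea_outputs: dict) -> pd.DataFrame:
    """Pathway x measure grid of NES where significant, blank otherwise.

    ``gsea_outputs`` maps measure name -> list of EnrichmentResult.  The
    final row ``n_significant`` tallies each column.
    """
    sig_sets: list = []
    for results in gsea_outputs.values():
        for r in results:
            if r.significant and r.set_name not in sig_sets:
                sig_sets.append(r.set_name)
    grid = pd.DataFrame("", index=sig_sets, columns=list(gsea_outputs))
    counts = {}
    for measure, results in gsea_outputs.items():
        n_sig = 0
        for r in results:
            if r.significant:
                grid.loc[r.set_name, measure] = f"{r.nes:.4f}"
                n_sig += 1
        counts[measure] = n_sig
    grid.loc["n_significant"] = {m: str(c) for m, c in counts.items()}
    return grid


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a manifest of outputs written."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash()}"
    manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                "stages": {}}
    t0_all = time.time()
    schedule = make_standard_schedule()

    def _stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"t_start": time.time() - t0_all}
        return time.time()

    try:
        # ---------------------------------------------------------- simulate
        t0 = _stage("simulate")
        from .simulate import TruthDistributions

        truth_dist = TruthDistributions(noise_scale=config.noise_scale)
        curves, truth, statics = simulate_cohort(
            config.n_patients, truth_dist,
            seed=_stage_seed(config.seed, "simulate"), schedule=schedule,
        )
        pio.write_table(truth.table, out / "truth.tsv", tag)
        pio.write_table(statics.table, out / "static_inputs.tsv", tag)
        for pid, c in enumerate(curves):
            pio.write_curve(c["aif"], out / f"aif_{pid:03d}.tsv", tag)
            pio.write_curve(c["tac"], out / f"tac_{pid:03d}.tsv", tag)
        manifest["stages"]["simulate"]["seconds"] = time.time() - t0

        # ----------------------------------------------------------- fit AIF
        t0 = _stage("fit_aif")
        aif_fits = []
        for c in curves:
            w = compute_weights(schedule, c["aif"].values)
            aif_fits.append(fit_aif(c["aif"], w))
        pio.write_table(
            pd.DataFrame([vars(f.params) | {"wrss": f.wrss} for f in aif_fits]),
            out / "aif_fits.tsv", tag,
        )
        manifest["stages"]["fit_aif"]["seconds"] = time.time() - t0

        # ------------------------------------------------------- fit models
        t0 = _stage("fit_models")
        seed_fit = _stage_seed(config.seed, "fit_models")
        rows = []
        fits_by_patient = []
        for pid, (c, af) in enumerate(zip(curves, aif_fits)):
            w = compute_weights(schedule, c["tac"].values)
            fits = {}
            for model in config.models:
                if model == "patlak":
                    f = patlak_fit(c["tac"], af.params, schedule,
                                   t_star=config.t_star)
                elif model == "spline":
                    from .kinetics import default_knots

                    f = fit_spline_residue(
                        c["tac"], af.params, schedule, w,
                        interior_knots=default_knots(schedule.t_scan_min,
                                                     config.n_knots),
                    )
                else:
                    f = fit_compartment(model, c["tac"], af.params, schedule,
                                        w, seed=seed_fit + pid)
                fits[model] = f
                rows.append({"patient": pid, "model": model, **f.params,
                             "wrss": f.wrss, "k_flux": f.k_flux})
            fits_by_patient.append(fits)
        pio.write_table(pd.DataFrame(rows), out / "kinetic_fits.tsv", tag,
                        index=False)
        manifest["stages"]["fit_models"]["seconds"] = time.time() - t0

        # --------------------------------------------------------- measures
        t0 = _stage("measures")
        mrows = []
        for pid, fits in enumerate(fits_by_patient):
            srow = statics.table.loc[pid]
            sm = static_measures(
                srow["tumour_max_conc"], srow["tumour_mean_conc"],
                srow["blood_mean_conc"], srow["injected_dose_kBq"],
                srow["body_weight_g"],
            )
            row = {"patient": pid, "SUVmax": sm.suv_max, "SUVmean": sm.suv_mean,
                   "TBRmax": sm.tbr_max, "TBRmean": sm.tbr_mean}
            for model, f in fits.items():
                if model == "patlak":
                    row["patlak_K"] = f.k_flux
                else:
                    row[f"kflux_{model}"] = f.k_flux
                if config.micro_parameter_gsea:
                    for pname, val in f.params.items():
                        if model != "patlak":
                            row[f"{pname}_{model}"] = val
            mrows.append(row)
        measures = pd.DataFrame(mrows).set_index("patient")
        pio.write_table(measures, out / "measures.tsv", tag)
        manifest["stages"]["measures"]["seconds"] = time.time() - t0

        # ------------------------------------------------------- expression
        t0 = _stage("expression")
        planted = []
        for name, size, effect, measure in config.planted:
            if measure not in measures.columns:
                raise ValueError(
                    f"planted pathway {name!r} references unknown measure "
                    f"{measure!r}"
                )
            planted.append((name, size, effect, measure))
        spec = make_planted_spec(
            n_genes=config.n_genes, n_patients=config.n_patients,
            planted=planted, seed=_stage_seed(config.seed, "expression"),
        )
        expression, annot = simulate_expression(
            spec, {pw.measure: measures[pw.measure].to_numpy()
                   for pw in spec.planted_pathways},
        )
        collection = make_collection(
            spec, n_null_sets=config.n_null_sets,
            null_size=config.null_set_size,
            seed=_stage_seed(config.seed, "expression") + 1,
        )
        pio.write_expression(expression, out / "expression.tsv", tag)
        pio.write_table(annot, out / "gene_annotation.tsv", tag)
        from .gsea import write_gmt

        write_gmt(collection, out / "gene_sets.gmt")
        manifest["stages"]["expression"]["seconds"] = time.time() - t0

        # ------------------------------------------------------------- GSEA
        t0 = _stage("gsea")
        seed_gsea = _stage_seed(config.seed, "gsea")
        for method in config.gsea_methods:
            outputs = {}
            for j, measure in enumerate(measures.columns):
                results = gsea_run(
                    expression, measures[measure].to_numpy(), collection,
                    method=method, n_perm=config.n_perm,
                    seed=seed_gsea + j,
                    alpha_numerator=config.alpha_numerator,
                    min_size=config.min_size, max_size=config.max_size,
                )
                outputs[measure] = results
                pio.write_table(
                    results_table(results),
                    out / f"gsea_{method}_{measure}.tsv", tag, index=False,
                )
            grid = association_grid(outputs)
            pio.write_table(grid, out / f"association_grid_{method}.tsv", tag)
        manifest["stages"]["gsea"]["seconds"] = time.time() - t0

        # ----------------------------------------------------- cohort stats
        if config.fp_study_datasets > 0:
            t0 = _stage("cohort_stats")
            study = permuted_phenotype_study(
                expression, measures[config.fp_study_measure].to_numpy(),
                collection, n_datasets=config.fp_study_datasets,
                alpha_numerator=config.alpha_numerator,
                seed=_stage_seed(config.seed, "cohort_stats"),
                n_perm=config.n_perm, min_size=config.min_size,
                max_size=config.max_size,
                measure_name=config.fp_study_measure,
            )
            pio.write_table(
                pd.DataFrame({"dataset": np.arange(study.counts.size),
                              "n_false_positive": study.counts}),
                out / "false_positive_study.tsv", tag, index=False,
            )
            manifest["stages"]["cohort_stats"]["seconds"] = time.time() - t0
    except Exception as err:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    manifest["total_seconds"] = time.time() - t0_all
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
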