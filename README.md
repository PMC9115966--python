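# petflux

Kinetic modelling of dynamic FDG-PET tumour data and gene-set enrichment
analysis of imaging–transcriptome correlations, with a synthetic-cohort
generator so the whole pipeline runs and is testable without patient data.

## The problem

In dynamic FDG-PET of primary breast cancer, tumour time-activity curves
(TACs) and arterial input functions (AIFs) are recorded over ~45 minutes of
scanning. Tracer kinetic models turn these curves into **flux-constants**
k<sub>flux</sub> — the rate of irreversible FDG trapping per unit steady
blood concentration — which complement the static SUV and tumour-to-blood
(TBR) measures of a late scan. Correlating these imaging measures with
per-gene log2 expression across a cohort, and feeding the ranked gene lists
into preranked gene-set enrichment analysis (GSEA), asks which biological
pathways track tumour FDG uptake, and *which imaging measure is the best
phenotype for that question*. This package implements that analysis chain
for methodologists and imaging scientists who want to run it, stress-test
it, or power future study designs on simulated cohorts.

## Models and statistics

All kinetic models share the convolution forward model

```
TAC(t) = K1 ∫₀ᵗ AIF(s) R(t−s) ds + Vb·AIF(t)
```

with residue function R(t) (fraction of delivered tracer still in tissue,
R(0)=1) and fractional blood volume Vb:

| model | parameters | k_flux |
|---|---|---|
| Patlak | K, V (late-time line) | slope K |
| 2C3K (irreversible two-tissue) | K1, k2, k3, Vb | K1·k3/(k2+k3) |
| 2C4K (reversible two-tissue) | + k4 | K1·R(T_scan), operational |
| 3C5K (irreversible three-tissue) | + k4, k5 | K1·k3·k5/(k2k4+k2k5+k3k5) |
| spline-residue | K1, Vb, B-spline weights | K1·R(T_scan) |

Fits are weighted least squares with frame weights
`w_i = (ΔT_i/A_i)·exp(−λ t_i)` (frame duration, activity, mid-time; λ the
18F decay constant), matching the inverse of the scanner count-noise
variance. Model comparison uses leave-one-frame-out cross-validation and
the Wald–Wolfowitz runs test; parameter uncertainties come from profile
likelihood on the weighted objective scaled by dof/WSS of the best model.

Genes are ranked by Pearson or Spearman correlation with an imaging
measure (random tie-breaking), scored with the weighted Kolmogorov–Smirnov
running-sum ES of the FGSEA-simple algorithm, and compared against
gene-wise permutation nulls (default 10,000) with a Bonferroni-style
significance cut-off of 0.035/N over the N sets tested. Cohort-level
machinery: permuted-phenotype false-positive studies, bootstrap
(patients-with-replacement) comparisons of significant-pathway counts with
a paired t-test, leading-edge overlap matrices, and Wilcoxon signed-rank
comparisons of per-gene correlation distributions.

## Worked example

```python
import numpy as np
from petflux import (make_standard_schedule, compute_weights, fit_compartment,
                     patlak_fit, fit_aif, simulate_cohort)

schedule = make_standard_schedule()        # 40 frames, 45 min acquisition
curves, truth, statics = simulate_cohort(n_patients=5, seed=42)

patient = curves[0]
aif_fit = fit_aif(patient["aif"], compute_weights(schedule, patient["aif"].values))
w = compute_weights(schedule, patient["tac"].values)
fit = fit_compartment("2C3K", patient["tac"], aif_fit.params, schedule, w)
pat = patlak_fit(patient["tac"], aif_fit.params, schedule, t_star=10.0)

print(f"true k_flux   : {truth.table.loc[0, 'k_flux']:.4f} /min")
print(f"2C3K k_flux   : {fit.k_flux:.4f} /min  (K1={fit.params['K1']:.3f}, "
      f"k2={fit.params['k2']:.3f}, k3={fit.params['k3']:.3f}, Vb={fit.params['Vb']:.3f})")
print(f"Patlak K      : {pat.k_flux:.4f} /min")
```

prints

```
true k_flux   : 0.0262 /min
2C3K k_flux   : 0.0252 /min  (K1=0.122, k2=0.271, k3=0.071, Vb=0.034)
Patlak K      : 0.0235 /min
```

i.e. on a noisy synthetic patient both the compartment fit and the simple
Patlak slope recover the true trapping rate to within a few percent — the
flux-constant is far better determined than any individual micro-parameter,
which is the property that makes it the preferred imaging phenotype.

The full pipeline (simulate → fit AIFs → fit kinetic models → derive
measures → GSEA per measure → association grid) runs from one YAML config:

```sh
petflux run-all --config config.yaml --seed 7 --out my_run
```

and writes TSV tables (truth, fits, measures, per-measure GSEA results,
pathway × measure association grid) plus a JSON manifest. Individual
stages are exposed as `petflux simulate / fit-aif / fit / assess / gsea /
fpstudy / bootdiff / heatmap`.

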