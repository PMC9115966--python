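# Methods

## Scope and data model

The package analyses a dynamic FDG-PET acquisition grouped into the
40-frame sequence {1×30 s, 12×5 s, 6×10 s, 5×30 s, 10×60 s, 6×300 s} with
tracer injection 30 s after the start of data collection. The single 30 s
frame is therefore pre-injection background; the post-injection span ends
at T_scan = 44.5 min. Curves (AIF and tumour TAC) are decay-corrected
activity concentrations in kBq/mL, stored as exact frame averages — the
quantity a scanner integrates — rather than mid-point samples. All frame
times are minutes post-injection; all rate constants are min⁻¹.

## Arterial input function

The AIF is the Feng-type three-exponential form

    AIF(t) = (A1 v − A2 − A3) e^{−μ1 v} + A2 e^{−μ2 v} + A3 e^{−μ3 v},
    v = t − τ ≥ 0,

zero before the delay τ and continuous at it. μ1 > μ2 > μ3 > 0 is imposed
as the canonical ordering (the two free exponentials are symmetric; fits
are re-sorted after convergence). Fitting is weighted least squares on the
analytic frame averages, with weights

    w_i = (ΔT_i / A_i) · exp(−λ t_i),   λ = ln 2 / 109.77 min⁻¹ (18F),

computed from the supplied (decay-corrected) activities as measured;
frames with non-positive activity, and pre-injection frames, are excluded
rather than floored — flooring a near-zero measured frame would give it
an essentially infinite weight and let pure noise dominate the fit. The
optimiser is bounded trust-region least squares over a 3×3×3 grid of
rate-decade initialisations (27 starts); the lowest achieved weighted RSS
wins, ties broken by start index. τ is bounded to [0, 2] min.

## Kinetic models

Every model shares the convolution forward model
TAC(t) = K1·(AIF ⊛ R)(t) + Vb·AIF(t). Compartment residue functions are
multi-exponential, R(t) = Σ c_j e^{−b_j t}, obtained by eigen-decomposing
the compartmental rate matrix; because the Feng AIF is itself a
polynomial-exponential, the convolution, the model TAC and its frame
averages are all closed-form (`petflux._expsum`). A numerical-quadrature
dual path exists only in the tests, where the two agree to better than
1e-6 relative.

Topologies:

* **2C3K** free →(k3) bound, efflux k2; k_flux = K1 k3/(k2+k3).
* **2C4K** adds k4 (bound → free). Its long-time flux is strictly zero,
  so k_flux is reported operationally as K1·R(T_scan).
* **3C5K** plasma →(K1) free →(k3, back k4) bound →(k5) trapped, efflux
  k2 from free. This wiring is one defensible choice for a five-rate
  irreversible three-tissue chain; the identity k_flux = K1·R(∞) holds
  for any wiring, and the closed form here is
  K1 k3 k5/(k2 k4 + k2 k5 + k3 k5).
* **Patlak**: OLS of TAC/AIF against ∫AIF/AIF over frames with mid-time
  ≥ t* (default 10 min, configurable). The default reflects when the
  2C3K residue with typical breast-tumour rates (k2+k3 ≈ 0.4 min⁻¹) is
  within ~2 % of its asymptote.
* **Spline-residue**: R(t) is a clamped cubic B-spline on [0, T_scan]
  (default 6 interior knots, geometrically spaced from 0.5 min to
  (2/3)·T_scan, matching the early-fast/late-slow structure of tracer
  kinetics). Constraints R(0)=1, R non-increasing, R ≥ 0 are imposed via
  the standard shape-constrained-spline sufficient condition of
  non-increasing, non-negative B-spline coefficients. Substituting
  θ_b = K1·w_b and θ = Lδ (δ ≥ 0, L a lower-triangular matrix of ones)
  turns the fit into a bounded **linear** least-squares problem in
  (δ, Vb), solved globally and deterministically — no multi-start, and
  knot-nested refinements can never fit worse. K1 = θ_0 and
  k_flux = K1·R(T_scan) = θ_last. The coefficient condition is slightly
  stronger than collocation-grid constraints; for monotone residues the
  restriction is immaterial at these knot counts.

Compartment fitting uses box bounds (rates [0, 5] min⁻¹, Vb [0, 0.5]) and
8 seeded log-normal multi-starts around physiological centres
(K1 0.1, k2 0.3, k3 0.08, k4/k5 0.02, Vb 0.05); warm-started single-start
refits are used inside cross-validation and profiling. Degenerate rate
matrices (repeated eigenvalues on measure-zero parameter sets) receive a
deterministic 1e-9 relative rate jitter; nearly-degenerate exponential
pairs in the convolution switch to the confluent limit at 1e-9 relative
separation.

Static measures: SUV = concentration/(dose/weight), TBR = tumour
concentration / blood concentration, from the late-scan inputs.

## Model assessment

* **LOOCV** is leave-one-*time-frame*-out within each TAC: each valid
  frame is dropped, the model refitted (warm-started from the full-data
  optimum), and w_i·(pred−obs)² accumulated. Patient-level LOO would be
  meaningless for per-patient curve fits.
* **Runs test**: exact run count on residual signs (zeros dropped),
  normal approximation with continuity correction, two-sided p. At very
  small or strongly unbalanced sign counts the exact conditional runs
  distribution is too discrete for any normal approximation to track
  two-sided p-values closely (worst-case deviation ≈ 0.63 at n = 12 with
  a 1/11 split); agreement at the 0.02 level holds for balanced classes
  of n ≳ 20, which is the regime of the 36-39 post-injection frames the
  test is actually used on.
* **Profile likelihood**: the objective is s·WSS(θ) with
  s = dof_best/WSS_best (dof = valid frames − parameters of the best
  model). Each parameter is swept, all others re-optimised, and 1-SD
  bounds are read off where the profile rises 1.0 above its minimum (the
  χ²₁ convention; the scale factor makes the weighted objective an
  absolute chi-square, which is what the coverage test checks). k_flux of
  the 2C3K model is profiled directly through the reparameterisation
  K1 = k_flux·(k2+k3)/k3. Bounds that never cross inside the box are
  reported censored at the box edge.

## Enrichment analysis

Ranking: per-gene Pearson r (or Pearson on midranks for Spearman) against
the measure; descending order; exact ties permuted uniformly under a
dedicated seeded stream (independent of the permutation stream);
zero-variance genes dropped with a warning.

ES: the weighted KS running sum with weight exponent p = 1 (the
FGSEA/GSEA default; p = 0 reduces to the classic KS statistic, which is
verified in the tests). At an exact magnitude tie between the positive
and negative extrema, the extremum reached earlier in the list wins
(deterministic). Leading edge: set members up to (positive ES) or from
(negative ES) the extremal position.

Null and inference: gene-wise permutations are realised as uniformly
drawn same-size gene sets against the fixed ranking — exactly what
permuting gene labels induces — and are shared across sets of equal size.
This null ignores inter-gene correlation and can therefore overstate
significance on real data; the permuted-phenotype study exists precisely
to measure that. NES = ES / mean(|null ES| of the matching sign);
p = (1 + #{same-sign nulls at least as extreme})/(1 + #same-sign nulls),
so p ≥ 1/(n_perm+1) and never 0. Significance at alpha/N with
alpha = 0.035 and N the post-filter set count (size filter 15-500 by
default). Note the interplay between the permutation floor and the
threshold: at N = 100 sets the cut-off 3.5e-4 is only attainable with
n_perm ≳ 6,000 (sign-stratified); the package default is 10,000.

Cohort statistics: the permuted-phenotype study permutes the measure
across patients n_datasets times (default 100) and reruns the full GSEA
at the same cut-off; the bootstrap comparison resamples patients with
replacement (expression columns and measure rows jointly, tie-breaks
re-randomised per resample via derived seeds), reruns GSEA for both
measures, and applies the paired t-test to the per-resample significant
counts — an all-identical difference vector is reported as degenerate
rather than forced through the t-test. Heatmap tables exclude genes
below a mean-log2 floor (default 1.0). The Wilcoxon comparison reports
the signed rank sum W⁺−W⁻ so that swapping arguments flips the sign.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* per-patient Feng AIFs with log-normal scatter (geometric SD e^0.15)
  around a population-typical curve (A1 600 kBq mL⁻¹ min⁻¹, A2 6,
  A3 10 kBq/mL, μ1 4, μ2 0.25, μ3 0.012 min⁻¹, delay U(0.1, 0.6) min) —
  peak ≈ 55 kBq/mL and tail ≈ 6 kBq/mL, typical of a 3 MBq/kg injection;
* TACs from known 2C3K parameters (centres K1 0.15, k2 0.35, k3 0.08
  min⁻¹, Vb 0.06; geometric SD e^0.35 across patients) with zero-mean
  Gaussian frame noise of variance noise_scale²·(A_i/ΔT_i)·e^{λ t_i} —
  exactly 1/w_i, so the fitting weights are the matched inverse-variance
  scheme; noise_scale = 1 gives ≈ 2-3 % noise on late 300 s frames and
  ≈ 20-30 % on early 5 s frames;
* static inputs (body weight N(70, 12) kg, dose 3 MBq/kg, tumour and
  blood concentrations tied to the late-time noiseless TAC and AIF with
  small log-normal scatter), so SUV/TBR are computed by the same
  formulas as for real data and correlate with true k_flux by
  construction (r ≈ 0.94 at n = 30);
* expression matrices (default 2,000 genes — configurable up to the
  ~17,000 of a real transcriptome — kept small so 10,000-permutation
  GSEA stays desk-scale) on the log2 scale, filler genes iid Gaussian,
  planted genes x = ρz + √(1−ρ²)ε against the standardised measure, so
  their population correlation with the measure equals the effect size;
* GMT collections mixing planted sets with random filler-gene sets.

Everything is deterministic under a seed, fanned out to per-patient and
per-stage substreams with numpy `SeedSequence` spawning.

What the generator does **not** emulate: inter-gene correlation
(co-expression modules), heavy-tailed or zero-inflated expression,
AIF shape misspecification, patient motion, or scanner/reconstruction
effects. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under its own assumptions, not that real-data
false-positive rates will match: on real transcriptomes the gene-wise
permutation null is anti-conservative, which is why the
permuted-phenotype study should always accompany the headline counts.

## Problem sizes

The test-suite and acceptance runs use: 1,000 random parameter sets per
model for the flux identities; 100 noisy TACs for recovery RMS errors;
200 replicates for profile coverage; 500 instances for ES exactness;
200 gene sets at 2,000 permutations for null calibration; 20 replicate
cohorts at 10,000 permutations for planted-pathway power; 100 permuted
datasets at 10,000 permutations for the false-positive study; these sizes
give stable single-CPU runs in minutes while keeping the Monte-Carlo
error of each check well below its decision margin.

## Known limitations

* The 3C5K wiring is one of several three-tissue topologies; the config
  does not currently expose alternatives (the flux identity is
  topology-independent, the closed form is not).
* The Patlak intercept is reported but unused downstream.
* Profile bounds assume a unimodal profile; multi-modal objectives would
  need a grid sweep.
* The bootstrap comparison reruns GSEA at full permutation depth per
  resample; at the 10,000-permutation default this is the slowest stage
  and is typically run at reduced depth first.
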