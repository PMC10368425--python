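# Methods

## Scientific setting

`bindprof` quantifies two dose–response experiments on the EF-hand
Ca²⁺-binding protein CHP3 (tescalcin) and its myristoylated form:

1. **Binding affinity by microscale thermophoresis (MST).** A
   fluorescently labelled partner B\* (here CHP3 at a fixed total
   concentration of 10 nM) is titrated with an unlabelled partner A
   (the NHE1 CHP-binding-domain fusion). Because the labelled-partner
   concentration is comparable to the dissociation constant K_D
   (low-nanomolar), the free-ligand approximation fails: the fraction
   bound must come from the exact mass-action solution (ligand
   depletion, sometimes called the "tight-binding" regime).
2. **Ca²⁺ response by a fluorescent-probe hydrophobicity (FPH) assay.**
   An environment-sensitive dye reports the Ca²⁺-induced conformational
   change; the dose–response in total CaCl₂ follows a Hill curve with
   midpoint EC50 and slope n.

## Models

**Depletion isotherm.** With total concentrations A_tot and B_tot and
dissociation constant K_D, the equilibrium complex concentration AB is
the smaller root of the mass-action quadratic

    (A_tot − AB)(B_tot − AB) = K_D · AB
    AB = [S − √(S² − 4·A_tot·B_tot)] / 2,   S = K_D + A_tot + B_tot.

The observed normalized thermophoresis signal is the bound-fraction
mixture of the free and complexed labelled partner:

    F_n(A_tot) = (B/B_tot)·F_{n,B} + (AB/B_tot)·F_{n,AB},  B = B_tot − AB.

**Hill curve.** F(c) = F_0 + F_max / (1 + (EC50/c)^n), with F(0) ≡ F_0
taken as the continuity limit.

## Replicate hierarchy and error model

Biological quantities are global: K_D (MST) or EC50 and n (Hill) are
shared across biological replicates. Experimental quantities are
individual: each biological replicate carries its own amplitudes
(B_tot, F_{n,B}, F_{n,AB} for MST; F_0, F_max for Hill). Technical
replicates are i.i.d. observations under their biological replicate's
parameters.

Noise is Gaussian with a signal-dependent scale evaluated at the model
prediction f:

    σ(f) = √(σ_abs² + (σ_rel·f)²).

MST fits carry (σ_abs, σ_rel) per biological replicate; Hill fits use a
single dose-independent σ_abs shared across the condition's replicates
(σ_rel ≡ 0). With three biological replicates this gives 1 + 5·3 = 16
simultaneously estimated parameters for MST and 2 + 2·3 + 1 = 9 for
Hill. The negative log-likelihood (NLL) is

    Σ_i [ (y_i − f_i)²/(2σ_i²) + log σ_i ] + (N/2)·log 2π,

and noise parameters are estimated jointly with the curve parameters
(the log σ term makes the joint likelihood proper).

Evaluating σ at the prediction rather than the observation keeps the
likelihood well-defined for outlying observations and makes the noise
model part of the generative story rather than a per-point reweighting.

The MST parameter set treats the per-replicate total label
concentration B_tot as the free "individual" parameter (bounded around
the nominal 10 nM): the free-partner concentration B itself is
dose-dependent and therefore not a parameter.

## Numerical choices

- **Stable quadratic root.** The textbook root (S − √(S²−4P))/2 loses
  all precision when P = A_tot·B_tot ≪ S² (e.g. A_tot ≪ K_D). We
  evaluate the algebraically identical form 2P/(S + √(S²−4P)), which is
  accurate over the full picomolar–millimolar range (verified against a
  bisection root-finder to 1e−8 relative).
- **Units.** All concentrations are carried in mol/L internally and in
  data files; reports convert to nM/µM only for display.
- **Transforms.** K_D, EC50, B_tot, σ_abs and σ_rel are optimized as
  log10 values (they span decades); amplitudes and the Hill n are
  linear. n is bounded to [0.2, 6].
- **Bounds.** K_D ∈ [1 pM, 1 mM]; EC50 ∈ [1 nM, 0.1 M]; B_tot ∈
  [0.1 nM, 100 nM] around the nominal label concentration; amplitude
  boxes are the data range ± 3× the data span (F_max: ± 4× span,
  symmetric about zero since the direction of change is
  data-determined); σ_abs ∈ [1e−6, 10× data SD]; σ_rel ∈ [1e−6, 1].

## Optimization

Deterministic multistart maximum likelihood:

- Starts are a scrambled Sobol sequence over the transformed bounding
  box with a fixed seed constant (default 50 starts). Every second
  start replaces the amplitude coordinates with values read off the
  data (per-replicate means at the lowest/highest dose), which speeds
  convergence without sacrificing determinism.
- Each start is polished with L-BFGS-B using the analytic NLL gradient
  (chain rule through the isotherm/Hill curve and the log10
  transforms; verified against central finite differences). Tolerances:
  relative NLL change 1e−14, projected gradient 1e−8, ≤ 2000
  iterations, Hessian memory 30 pairs — the σ_abs/σ_rel decomposition
  is weakly identified when the signal scale is nearly constant, which
  produces a narrow curved valley that starves the default-memory
  quasi-Newton approximation.
- The reported optimum is the best converged start; ties within 1e−8 in
  NLL go to the lowest start index. A final polish pass at tighter
  tolerances from the winning start makes the reported optimum
  independent of where the coarse pass stopped (fits agree to ~1e−6 in
  K_D across equivalent unit systems).

## Profile-likelihood confidence intervals

Uncertainty for any single parameter is quantified by scanning it while
re-optimizing all other parameters at each scan value (warm-started
from the neighbouring point). Twice the log-likelihood deficit
2·(NLL_prof − NLL_min) is compared with the χ²₁ quantile (3.84 at 95%).
The scan runs in the parameter's transformed coordinate with an
adaptive step targeting an increment of ~0.3 in 2ΔNLL per step (step
clamped to [1e−4, 0.5] decades), stops once the profile exceeds the
threshold + 0.5, hits a parameter bound, or exhausts 100 steps, and the
crossing bracket is then bisected until it is at most 0.1 wide in 2ΔNLL
before linear interpolation of the endpoint. On a linear-Gaussian model
the resulting interval reproduces the analytic Wald interval to 1e−4.
A side that reaches a bound below threshold is reported open (status
`hit_bound`) rather than extrapolated.

## Synthetic data

The generator is the generative twin of the fitted models. Defaults
emulate the study conditions:

- **MST**: 16-point 2-fold serial dilution from 500 nM titrant
  (bracketing all preset K_D values), 3 biological × 5 technical
  replicates, B_tot = 10 nM, base amplitudes F_{n,B} = 1.0 and
  F_{n,AB} = 0.5 (arbitrary units; only their separation matters),
  σ_abs = 2% of the amplitude span, σ_rel = 0.
- **FPH**: 12 log-spaced CaCl₂ doses spanning 0.34 µM–8.0 mM, 3
  biological replicates with 4/3/3 technical replicates, F_0 = 0.2,
  F_max = 1.0, Hill n = 1.5 (the assay's slope is not a reported
  quantity; a mildly cooperative value is used), σ = 3% of F_max.
- Amplitudes are jittered ±10% (uniform) across biological replicates,
  deterministically from the seed; shared parameters are identical
  across replicates. Jitter and noise use independent seeded streams so
  the generating truth is recoverable exactly.
- Presets pin the true shared parameter to the study estimates: K_D =
  3.1 / 5.6 / 14.6 / 28.2 nM (Ca²⁺ and Mg²⁺ conditions, without/with
  myristoylation) and EC50 = 161.1 / 152.6 µM.

What the generator does **not** emulate: raw thermophoresis time
traces and their normalization, plate/well layout effects or
correlations between technical replicates (treated as i.i.d.),
chelator speciation of Ca²⁺ (doses are nominal total CaCl₂), dose
pipetting error, and non-Gaussian outliers. Passing recovery and
coverage tests therefore validates the inference machinery under the
assumed noise model, not robustness to real-world artefacts beyond it.

## Simulation study sizes

The calibration study uses 100 datasets at K_D = 10 nM with the default
MST conditions; parameter-recovery checks use the first 50 of those
fits plus one noise-free fit. These sizes give a binomial Monte-Carlo
standard error of ~2.2 percentage points on the 95% coverage estimate
while keeping the study cheap enough to re-run routinely.

## Known limitations

- One-site 1:1 binding only; no cooperative multi-site isotherms,
  kinetics, or competition formats.
- Profile intervals rely on the asymptotic χ²₁ calibration of the
  likelihood-ratio statistic; at very small sample sizes (few doses or
  replicates) coverage can deviate from nominal.
- σ_rel is weakly identified when model signals span a narrow range;
  its estimate often sits at the lower bound. This is harmless for the
  shared-parameter inference (the profile re-optimizes it) but the
  noise decomposition itself should not be over-interpreted.
- The Hill-model noise is homoscedastic by construction; strongly
  signal-dependent plate noise would be mis-specified.
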