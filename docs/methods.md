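# Methods

## Model

The package treats lipid modulation of a micelle-reconstituted membrane
enzyme as two sequential equilibrium stages.

**Composition.** The sole composition variable is the micellar mole
fraction `x = L/(L+D)` of phospholipid among micellar amphiphiles. The
critical micellar concentrations of the reference species (~0.5 nM for
DPPC, ~5 µM for C₁₂E₁₀) are negligible at mM working concentrations, so
totals are taken as micellar by default; `micellar_mole_fraction` accepts
optional per-species CMC subtractions (floored at zero) for systems where
monomers matter. A direct consequence, used as a validity check on data,
is the collapse property: observations at different total concentrations
but equal ratio predict identical activity.

**Stage 1 (exchange isotherm).** One double-chain lipid displaces β
single-chain detergent molecules from the boundary monolayer on the
transmembrane surface. Mass action gives the coverage

    θ(x) = K_ex·x / ((1−x)^β + K_ex·x)

with θ(0)=0, θ(1)=1, strictly increasing, and weakly sigmoidal in x for
β > 1. β is restricted to integers 1–4 and defaults to 2 (two acyl chains
per lipid vs. one per detergent). A symmetric alternative
K·x^β/((1−x)^β + K·x^β) is available as `variant="symmetric"` for
sensitivity analysis; it is not the default because, at the reference
parameter values, it places half-maximal activation near x ≈ 0.27,
inconsistent with the minimal-model estimate X₀.₅ ≈ 0.11–0.12 that the
default form reproduces. The inverse map uses the closed-form quadratic
root for β = 2 and bracketed bisection (tolerance 1e-12 on x) otherwise.

**Competition.** The labeled probe (a phosphatidylcholine like the
unlabeled lipid) shares K_ex; the multi-species isotherm is

    θ_probe = K_ex·x_p / (x_D^β + K_ex·(x_p + x_l)),  x_D = 1 − x_p − x_l,

and analogously for the unlabeled species. Note the displacement direction
is regime-dependent: raising x_l at fixed x_p lowers θ_probe only once
2·x_D < K_ex (lipid-rich micelles); below that, added lipid mainly
displaces detergent and θ_probe can rise. The probe-displacement assay
design (x_l = 0.34–0.48) sits entirely in the displacement regime.

**Stage 2 (logistic transduction).** Activity follows the differential
logistic law dA/dθ = (c_θ/(A₁−A₀))(A−A₀)(A₁−A), integrating to

    A(θ) = A₀ + (A₁−A₀)/(1 + exp(−c_θ(θ − θ₀.₅))).

This parameterization anchors two properties used as identities in tests:
the maximal slope c_θ(A₁−A₀)/4 occurs exactly at half-maximal activation,
and the tangent-line gain over a coverage increment Δθ starting there is
100·c_θ·Δθ/4 percent of the amplitude (for c_θ = 15 and Δθ = 0.04: 15%;
the exact logistic difference over the same increment is 14.57%). Any
variant of the differential form preserving these two properties is
observationally identical after rescaling c_θ, so the fitted c_θ is
defined relative to this parameterization. Coverage outside [0,1] is
rejected, not clamped.

**FRET observation model.** E_app = ξ·θ_probe/(1 + ξ·θ_probe). The
saturating form is required for physical consistency: with the reference
coupling ξ ≈ 51, a linear coupling would exceed E_app = 1 within the assay
window. The form is isolated in one function so an alternative coupling
can be swapped without touching the fitting engine. Donor intensities are
assumed background-subtracted; `apparent_efficiency` implements
E_app = 1 − I_da/I_d and rejects enhancement (I_da > I_d).

## Parameters

| parameter | meaning | units | reference value |
|---|---|---|---|
| A₀, A₁ | asymptotic minimal/maximal activity | µmol Pi·mg⁻¹·min⁻¹ | 1.1, 12.8 |
| θ₀.₅ | coverage at half-maximal activation | – | 0.16 |
| c_θ | transduction cooperativity (4·max slope/amplitude) | – | 15 |
| K_ex | lipid/detergent exchange constant | – | 1.4 |
| β | detergents displaced per lipid | – | 2 |
| ξ | protein/probe FRET coupling | – | 51 |
| X₀.₅, c_x | minimal-model half-activation and cooperativity | – | ~0.11–0.12, ~24–26 |

The reference values (used as defaults for simulation truth and sweep
bases) are global-fit estimates for PMCA in C₁₂E₁₀/DPPC.

## Fitting

The global objective is Σ w_A(A_obs − A(x))² + Σ w_F(E_obs − E(x_l,x_p))²
with K_ex shared between the two terms. Activity and efficiency are
incommensurate (ranges ~12 vs. ~0.5), so the default weighting is
inverse-variance: each dataset is first fit alone (activity: five free
parameters; FRET: K_ex and ξ), its residual variance σ̂² estimated, and one
re-weighted joint pass run with w = 1/σ̂². Unit weighting is available
(`weights="unit"`). Abscissae are treated as error-free and errors as
homoscedastic within a dataset.

The optimizer is Gauss–Newton with Levenberg damping: solve
(JᵀJ + λ·diag(JᵀJ))Δp = −Jᵀr, accept only objective-decreasing steps
(λ×10 on rejection, /10 on acceptance), so accepted objectives are
monotone non-increasing. Pure Gauss–Newton (λ ≡ 0) is available but, being
only locally convergent, needs a good start. Jacobians are central finite
differences with step 1e-6·max(|p|,1) — uniform and model-agnostic; all
model functions are smooth and the engine's minimizers agree with an
independent trust-region implementation to ~1e-6 in the objective.
Convergence: relative objective change < 1e-10 or step norm < 1e-10, at
most 500 iterations; the `converged` flag is honest and non-convergence
never raises. Bounds (A₀ ≥ 0, midpoints in (0.001, 0.999), c > 0,
K_ex ∈ (1e-3, 1e3), ξ ∈ (1e-3, 1e4)) are enforced by projection;
estimates at a bound are reported in `at_bound_`. Standard errors are the
square roots of the diagonal of (JᵀJ)⁻¹·SSR/(n−k) on the weighted
residuals.

**Initialization** is deterministic from the data: A₀/A₁ from the observed
extremes, the half-activation abscissa from the observation nearest
mid-activity, the cooperativity from the steepest finite-difference slope
of composition-binned means (bins of 2% of the abscissa span — raw
replicate differences at near-identical compositions would otherwise give
runaway slopes), K_ex = 1, and ξ inverted from the largest observed
efficiency under K_ex = 1. Data with no rising activity segment start from
a shallow logistic and end flagged at the slope bound. An optional seeded
multi-start (5 log-normal perturbations) is off by default for
determinism.

**Design requirements.** The global fit demands ≥ 8 activity points on
≥ 3 distinct compositions with nonzero span and ≥ 6 FRET points; the
minimal fit ≥ 5 points. Anything less raises an underdetermined-design
error rather than returning meaningless estimates.

**Diagnostics.** Per-dataset residual mean, SD, and a Wald–Wolfowitz runs
test on residual signs ordered by fitted value. The p-value is one-sided
against too few runs, i.e. clustered signs: that is the lack-of-fit
signature; an excess of runs (e.g. perfectly alternating signs) is not
evidence of misfit. Fewer than 5 residuals marks the diagnostic
unreliable.

## Synthetic data

The generator reproduces the study designs: activity at fixed detergent
(1.20/2.75/7.50 mM) with lipid titrated over a 12-point log grid spanning
x ≈ 0.01–0.6 per level, and at fixed lipid (0.06/0.22/0.53 mM) with
detergent titrated to span x ≈ 0.02–0.5, duplicate measurements
(144 activity points by default); FRET at unlabeled fractions
0.34/0.36/0.41/0.44/0.48 with the probe titrated over
x_p = 0.005–0.05 (30 points). Observations are exact model means plus
homoscedastic Gaussian noise; defaults sd_activity = 0.5
µmol Pi·mg⁻¹·min⁻¹ (~4% of the activation range, consistent with the
scatter such assays tolerate) and sd_fret = 0.02. Draws violating physical
bounds (activity < 0, E_app outside [0,1)) are resampled, not clipped, so
the noise stays unbiased away from the bounds. Seeds fully determine the
output.

What the generator does **not** emulate: composition-dependent
(heteroscedastic) assay error, abscissa (pipetting/concentration) error,
plate or day batch effects, free-monomer corrections near the CMC, and
probe photophysics beyond the scalar E_app. Parameter-recovery results on
these data therefore demonstrate the estimator's correctness and precision
under the model's own assumptions, not robustness to the full error
structure of real titrations.

## Parameter-mapping study

`run_sweep` varies one two-stage parameter at a time (defaults:
K_ex ∈ {0.5…3}, θ₀.₅ ∈ {0.05…0.40}, c_θ ∈ {5…30}; bases at the reference
values), simulates noise-free activity on 101 evenly spaced mole fractions
in [0,1], and fits the minimal model to each curve. Findings reproduced by
the tests: c_x is linear in K_ex (R² > 0.999), so the maximal slope of an
activation curve reads out relative lipid affinity even without a FRET
assay; X₀.₅ is quasi-linear and increasing in θ₀.₅; the cross-dependencies
are small in relative range. The mapping is treated numerically
throughout; no closed form is attempted.

## Numerical choices and limitations

- Composition grouping tolerance for the collapse check: 1e-6 (exact-ratio
  grouping), overridable.
- The logistic is evaluated with overflow-silenced exp; for |c·(z−z₀.₅)|
  beyond ~700 it saturates exactly at the asymptotes.
- Replicate recovery experiments spawn per-replicate seeds from a root
  seed via `SeedSequence`; all derived seeds stay below 2³¹.
- Asymptotic (inverse-Hessian) standard errors only — no bootstrap or
  profile likelihood; for strongly nonlinear posteriors near bounds these
  understate uncertainty.
- The two-stage parameters (c_θ, θ₀.₅, K_ex) are only jointly identifiable
  from activity data when the FRET dataset pins K_ex; activity-only fits
  of the full model can trade K_ex against the stage-2 shape. That is the
  point of the global fit, and why the minimal model exists for
  activity-only designs.
- Equilibrium coverage only: exchange kinetics (characteristic times
  1e-8–1e-4 s, fast relative to turnover) are outside scope, as are
  acidic-phospholipid activation modes and any mechanistic enzyme-cycle
  modelling.
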