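# Methods

This note documents the models implemented in `comdiss`, the defaults and
why they were chosen, the numerical machinery, and what the synthetic-data
tests do and do not demonstrate.

## Solution chemistry

**Model.** Total (analytical) concentrations of Ca²⁺, C₂O₄²⁻ (oxalate,
"Ox"), Na⁺ and Cl⁻ are related to free-ion concentrations through
mass-action formation of the complexes CaOx(aq), CaHOx⁺, HOx⁻, H₂Ox, OH⁻
and CaOH⁺, with the proton *activity* fixed by pH (the experiments are
pH-statted, so H⁺ is a boundary condition, not a conserved component).
Activity coefficients come from the Davies equation
log γ = −A z²(√I/(1+√I) − 0.3 I), adequate for I ≤ 0.5 mol dm⁻³; no Pitzer
or SIT model is offered. Equilibrium constants are read from
`data/constants.yaml` and are all overridable; each entry carries its
literature source. No temperature extrapolation of logK is performed —
25 °C compilation values are used where no 37 °C value is tabulated, an
error small compared with the constants' own spread.

**Defaults that matter.**

| parameter | default | unit | rationale |
|---|---|---|---|
| Davies A | 0.5215 | – (log₁₀) | water at 37 °C |
| H₀^½ | 1.994×10⁻⁴ | mol dm⁻³ | COM solubility at I = 0.15, 37 °C (input constant; its ionic-strength correction is not re-derived) |
| BET SSA | 3.73 | m² g⁻¹ | seed-crystal surface area |
| pKw | 13.62 | – | 37 °C |
| water molarity | 55.5 | mol dm⁻³ | standard-state factor in ΔG_ads |

Sodium and chloride are treated as fully dissociated background
electrolyte: the NaC₂O₄⁻ ion pair is shipped in the constants file but
disabled by default. With ~0.15 M Na⁺, literature NaOx⁻ constants
(logK ≈ 1.0) would sequester ~30% of the oxalate; the published σ values
are exactly reproduced from *total* concentrations, which is only
consistent with the background-electrolyte treatment. Users studying Na⁺
pairing explicitly can enable the reaction.

**Solver.** Newton iteration on ln-concentrations (positivity is
structural) with the analytic Jacobian J_ij = δ_ij c_i + Σ_s ν_is ν_js c_s,
direction-preserving step damping (‖Δu‖∞ ≤ 3) and residual-norm
backtracking; convergence at max |T_calc − T| ≤ 10⁻¹³·max(T). One
component — chloride by default — can be designated the charge-balancing
background: its mass balance is replaced by electroneutrality Σz·c = 0 and
its effective total is reported, which is how the small net charge carried
by H⁺/OH⁻ at a given pH is absorbed. An outer loop recomputes I from the
full species list and refreshes γ until |ΔI| ≤ 10⁻⁹ mol dm⁻³. The solver
is cross-checked in the test suite against an independently written damped
fixed-point iteration (plain scalar Python, no shared code) on randomized
recipes spanning totals of 10⁻⁵–10⁻² mol dm⁻³ and pH 4.5–7.5.

**Two σ conventions.** `total` mode takes H^½ = √(T_Ca·T_Ox) and
reproduces the published σ column exactly (all eight rows, two printed
figures); `speciated` mode takes H^½ = √([Ca²⁺][Ox²⁻]) from the solver and
sits ~0.02–0.03 higher because ion pairing removes ~3% of each lattice
ion. `total` is the default and the mode is recorded in every output. The
numerical coincidence of the published column with the `total` formula is
documented as an observation, not asserted as intent.

## Dissolution kinetics

Rates are fitted to R = k·s·σⁿ with the site factor s normalized to 1, by
unweighted OLS of log₁₀R on log₁₀σ (identical to the conventional
−logR/−logσ plot). The order is reported both free (n = 1.689 ± 0.076
control, 1.753 ± 0.028 additive on the reference table) and rounded
(2 for both); the free-fit k is reported but never asserted against the
published rate constant, which is not reproducible from the printed table
by any free OLS refit. Stirring speed is deliberately absent from the
model (transport-independent surface control); a test pins this contract.

Rate extraction from a constant-composition titration record is the OLS
slope of moles-added vs. time divided by seed area (mass × SSA), with an
optional burn-in trim (default 0 — the bundled traces are steady from
t = 0). The published rate unit ("mol m⁻¹ min⁻¹") is treated as the
dimensionally consistent mol m⁻² min⁻¹.

## Langmuir adsorption

Coverage is defined operationally as θ = 1 − Rᵢ/R₀ and always recomputed
from rates — derived columns of the source tables are never trusted (one
printed 1/C entry is arithmetically impossible). The kinetic route fits
R₀/(R₀−Rᵢ) on 1/C (K_L = 1/slope; ideal intercept 1); the equilibrium
route fits C/θ on C (K_ads = 1/intercept; ideal slope 1). Both are
unweighted OLS with no forced coefficients; points with zero measurable
inhibition are excluded with a warning. R₀ is the σ = 0.20 control rate,
configurable.

ΔG_ads = −RT·ln(55.5·K_ads) at 310 K. The 55.5 mol dm⁻³ factor refers the
dm³ mol⁻¹ constant to the mole-fraction standard state of displaced water;
the literal molar-scale form (water_molarity = 1) differs by
−RT·ln 55.5 ≈ 10.4 kJ mol⁻¹ and is available because only the 55.5
convention reproduces the published −36.2 kJ mol⁻¹ from the published
K_ads. Both conventions appear in outputs.

## Energetics bookkeeping

Only scalar arithmetic: E_g = E_LUMO − E_HOMO (with pre-computed gaps
accepted directly, since the underlying orbital energies of the bundled
systems were not published), E_a = E_complex − (E_A + E_B), and a
physisorption classification at the conventional −0.5 eV boundary
(configurable). No electronic-structure computation of any kind.

## Synthetic data and what the tests show

The generators draw from exactly the models the pipeline fits: R = k·σⁿ,
Rᵢ = R₀(1−θ(C)) with Langmuir θ, and linear titration traces.
Noise is multiplicative log-normal (rates are positive and span half a
decade, so relative error is the natural scale) with a default CV of 2%,
matching the visible scatter of the linearized rate-law data. Default
grids clone the experimental design: σ ∈ {0.10…0.28} (8 points),
C ∈ {2…10} µM (11 points); defaults for k, n and K_L are the reported
values (4.769×10⁻⁵, 2, 2.274×10⁴). Generators are bit-reproducible given
`rng_seed`.

Noise-free round trips recover every parameter to ≤10⁻¹⁰ relative — this
validates the algebra, not the statistics. At 2% noise over 500 seeded
replicates the rate order is recovered with median |n̂−2| ≈ 0.014, but the
Langmuir constants are *not* well recovered: median relative errors are
≈0.27 (K_L) and ≈0.22 (K_ads), with a −13% median bias. This is a real
property of the design, not a solver defect: at coverages of 0.04–0.19 the
response R₀−Rᵢ carries 10–50% relative noise when Rᵢ carries 2%, and the
reciprocal linearizations give the noisiest points the highest leverage.
Conversely, the near-exact (≤1%) agreement of the reference-table fits
with the published constants implies the measured rates scatter far less
than 2% about the Langmuir model. The recovery medians are recomputed by
`scripts/acceptance.py` and `analysis/05_synthetic_recovery.py` at every
run. Because the generative model is exactly the fitted model, passing
tests demonstrate correctness of the estimators under ideal assumptions;
they say nothing about model misspecification in real urine-like media
(competing ions, multi-component extracts, surface heterogeneity), which
the package does not attempt to simulate.

## Numerical details and degenerate inputs

- Regression is `scipy.stats.linregress` throughout (slopes, intercepts,
  r², standard errors); fits with <3 points, non-positive responses or
  zero design variance raise typed errors.
- The speciation solver treats an all-zero-totals recipe as a valid
  degenerate case (water + pH species only); infeasible charge balance
  (required background concentration ≤ 0) and iteration-cap exhaustion
  raise a convergence error carrying residuals.
- Supersaturated inputs (H^½ > H₀^½) are rejected: dissolution kinetics do
  not extrapolate across equilibrium.
- Rate promotion (Rᵢ > R₀) and negative coverage are flagged with
  warnings, not errors, so screening series containing promoters survive.
- Report JSON is deterministic: sorted keys, no timestamps; repeated runs
  on identical inputs are byte-identical.

## Problem sizes

The bundled analyses use the reference tables as printed (8 + 8 rate
points, 11 inhibition points); the synthetic recovery study uses 500
replicates of that same design, and the speciation oracle cross-check 100
randomized recipes. These sizes make the entire suite and the acceptance
script run in seconds while keeping the Monte-Carlo medians stable to well
under the tolerances tested.

## Known limitations

- Single temperature; no van 't Hoff treatment of any constant.
- Davies activities only; the model degrades above I ≈ 0.5 mol dm⁻³.
- The extract is treated as one effective adsorbing species at its nominal
  molarity; competitive multi-component adsorption is out of scope.
- emf-to-concentration (Nernst) conversion is not implemented; rate
  extraction works from titrant-volume records.
- H₀^½ is an input constant; its ionic-strength dependence is not
  re-derived.
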