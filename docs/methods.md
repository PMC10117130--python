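# Methods

## Model

`ssfkin` models a 30-day batch solid-state fermentation in which a
white-rot fungus colonises a lignocellulosic substrate. Four coupled
state variables, all expressed as mass fractions of the dry substrate
(g per g dry basis, abbreviated g/g d.b.):

| symbol | meaning | typical scale |
|---|---|---|
| X | fungal biomass (ergosterol-calibrated) | 0.005–0.09 g/g |
| S | holocellulose (cellulose + hemicellulose), the sole carbon/energy source | 0.6 → 0.3 g/g |
| L | lignin | 0.37 → 0.23 g/g |
| P | secreted enzyme protein | 0 → 0.02 g/g |

Growth follows the hybrid logistic-Monod law
dX/dt = μ_max·(S/(K_s+S))·(1−X/X_m)·X. Early in the batch, growth is
substrate-limited (Monod factor); as the mycelium fills the available
space and mass transfer degrades, the logistic factor (1−X/X_m) takes
over and growth ceases near the carrying capacity X_m. The limiting
cases are exposed and tested: K_s/S → 0 reduces the system to the
logistic closed form; X ≪ X_m reduces it to exponential growth at rate
μ_max·S₀/(K_s+S₀).

Holocellulose is spent on growth (1/Y_X/S per unit biomass), cell
maintenance (m_s·X), and the energetic coupling to delignification,
−k_LD·dL/dt. Note the sign of the third term: because dL/dt < 0 during
delignification, the term as written *adds* substrate while lignin is
degraded. The package's default keeps this literal convention, which is
the one the packaged parameter values were estimated under; a
`lignin_energy_sign="energy_cost"` switch replaces it with −k_LD·|dL/dt|
for users who prefer the physically-motivated convention in which lignin
breakdown always costs substrate. Fidelity first, physics as an option.

Lignin decays first order with a time-varying coefficient
k_l(t) = k₁·e^(−k₂t). The closed form
L(t) = L₀·exp((k₁/k₂)(e^(−k₂t) − 1)) is implemented with `expm1` so the
k₂ → 0 limit is numerically exact, and k₂ = 0 itself takes an explicit
plain-exponential branch. dL/dt is the analytic derivative
−k₁e^(−k₂t)·L(t), verified against finite differences in the tests.
Negative k₂ — the fitted sign for all six packaged treatments — makes
delignification accelerate over the batch, consistent with substrate
heterogeneity and continued ligninolytic enzyme production after growth
stops.

Gas exchange ties the model to the cheapest on-line observable. OUR =
(1/Y_X/O)·dX/dt + m_O·X and CPR = Y_C/X·dX/dt + m_C·X; headspace
volume-fraction changes convert to mmol per g dry substrate per day via
the ideal-gas law (R = 0.082057 L·atm·mol⁻¹·K⁻¹, 301 K, 1 atm, pure-O₂
flushing so the O₂ reference concentration is 1). Enzyme secretion is
Luedeking-Piret, dP/dt = α·dX/dt + β·X.

## Parameters, units, defaults

The fourteen parameters live in `KineticParams` (see its docstring for
units). Constraints: rates, yields and maintenance coefficients are
non-negative; k₂ and k_LD are unconstrained in sign — the packaged
switchgrass/*P. chrysosporium* treatment carries k_LD = −0.058, a
statistically insignificant estimate kept as-is. Six complete parameter
vectors (two substrates × three fungi) ship in `ssfkin.datasets` together
with the untreated substrate compositions (camelina straw S₀ = 0.586,
L₀ = 0.373 g/g; switchgrass S₀ = 0.662, L₀ = 0.263 g/g).

Defaults chosen where the study design leaves gaps, fixed once:

* **X₀ = 0.005 g/g** — the 2 mL liquid inoculum per 3 g substrate
  carries a small unmeasured biomass; 0.5% of dry matter is a realistic
  inoculation level and is below every treatment's X_m. P₀ = 0.
* **Headspace volume** — 250 mL flask minus water volume (75% wet-basis
  moisture → 9 mL) minus solid volume at an assumed 0.45 g/mL bulk
  density (6.7 mL), giving 0.234 L. All configurable.
* **CO₂ reference concentration** — the flushing gas contains no CO₂; the
  conversion applies the same ideal-gas formula with reference
  concentration 1, reading the headspace CO₂ fraction as the amount
  accumulated since flushing. This is an interpretation, documented
  rather than hidden.

## Numerical integration

`simulate_trajectory` integrates (X, S, L, P) plus three bookkeeping
channels — cumulative O₂, cumulative CO₂ and ∫X dt — with adaptive RK45
at rtol 1e-8 / atol 1e-10. The system is non-stiff at these parameter
scales. States are never clipped inside the solver; the Monod factor
guards against tiny negative S overshoot only. Solver failure raises
with diagnostics instead of returning NaN. Grid-refinement invariance of
OUR/CPR (factor-2 Richardson check, < 1e-5 relative) is asserted in the
tests.

## Calibration

Staging follows the model's triangular dependency; the package treats
this as its own design choice:

1. **Lignin** (k₁, k₂): Levenberg-Marquardt on the closed form. L₀ is
   fixed to the day-0 mean by default (configurable to free).
2. **Growth + substrate** (μ_max, K_s, X_m, Y_X/S, m_s, k_LD): LM over
   re-integrated ODE solutions, lignin fixed. X and S residuals are
   stacked after dividing by each response's observed standard deviation
   so the two scales contribute comparably. Initial guesses:
   μ_max = 1 d⁻¹, K_s = 0.5·S₀, X_m = 1.05·max(X); positivity bounds
   except k_LD. Five seeded, log-normally jittered restarts; best-SSE
   winner. The fit reports the μ_max–K_s correlation and flags
   |corr| > 0.95 instead of returning silently.
3. **Gas** (Y_X/O, m_O; Y_C/X, m_C): daily headspace sampling integrates
   the rate over 24 h, so the fit regresses interval-averaged rates on
   the matching interval averages from the fitted trajectory — ΔX over
   the day and the daily mean of X (from ∫X dt). This keeps the problem
   exactly linear in the two free parameters (non-negative linear least
   squares) and makes noise-free recovery exact. Only the log-phase
   window (default days 1–14, configurable to 22) is used, because the
   linear gas laws describe actively growing mycelium.
4. **Enzyme** (α, β): the integrated Luedeking-Piret form
   P−P₀ = α(X−X₀) + β∫X dt is exactly linear; non-negative linear least
   squares against the fitted trajectory.

dX/dt for stages 3–4 comes from the fitted model trajectory, never from
differencing noisy data. Estimates at a box bound, non-convergence and
the correlation ridge are reported as distinct flags on the results
object.

### Identifiability

On this design the μ_max–K_s pair is close to unidentifiable: S spans
only about 0.59 → 0.28 g/g, so the Monod factor varies between ~0.47 and
~0.30 and the two parameters trade off along a flat ridge
(corr ≈ 0.999). A linearised error analysis at the packaged CS-TV52J
truth (12 sampling days × 3 replicates, 5% CV) puts the attainable
standard deviation of μ_max at roughly 40% relative, while X_m (≈1.5%)
and Y_X/S (≈2.5%) are well determined. Consequences: noise-free
round-trip recovery is exact (the tests assert 1% on every parameter),
but on realistically noisy data the individual μ_max and K_s estimates
should be read jointly, through the reported covariance and the
`mu_Ks_correlated` flag, not as separate quantities. Designs that
deplete S further, or vary S₀ across flasks, would break the ridge.

## Synthetic data

`ssfkin.datasets` emulates the batch design: destructive sampling of
triplicate flasks on days {0,2,4,6,8,10,12,14,18,22,26,30} for X/S/L/P
and daily headspace gas on days 1–30, written as the same CSV schemas
the readers accept. Replicate noise is multiplicative Gaussian
(per-response CV, truncated at zero, truncations counted and warned);
multiplicative noise corrupts X (~0.08 g/g) and S (~0.5 g/g) comparably.
The experimental record reports triplicates but no replicate variance,
so the 5% default CV is a labelled stand-in, not an inference.

What the generator does **not** emulate: measurement-chemistry artefacts
(ergosterol-to-biomass calibration error, acid-hydrolysis losses, TKN
protein conversion), sterile-control drift, flask-to-flask moisture or
temperature gradients, day-to-day autocorrelated errors, and any
transport limitation (O₂ diffusion, heat). Passing recovery tests
therefore demonstrate that the estimation machinery is correct and
well-conditioned *given the model*, not that the model is correct for
any particular real substrate.

## Problem sizes

The packaged studies run at desk scale by choice: recovery tests use one
noise-free replicate per treatment; the noisy recovery study uses 20
seeds × 3 replicates at 5% CV; the replicate-consistency check uses 8
seeds at n ∈ {3, 10, 30}. The lignin closed form is verified against a
6000-step fixed-step RK4 oracle over k₁ ∈ [0, 0.02], k₂ ∈ [−0.1, 0.1].

## Known limitations

* Heat and mass transfer, water balance and O₂ diffusion are outside the
  model (the growth-kinetic sub-model feeds a transport sub-model that a
  bioreactor design would add).
* The linear OUR/CPR–biomass laws degrade late in the batch; the
  log-phase window exists precisely because the relationship turns
  nonlinear as the culture saturates.
* σ_est uses the n-denominator convention by default (`ddof`
  configurable); with replicated designs the difference is small but not
  zero.
* The μ_max–K_s ridge above: parameter *values* from single-batch data
  are design-limited even when the fitted curves are excellent.
* Parameters are treatment-specific; extrapolation to other fungi,
  substrates, moisture contents or temperatures is not supported by the
  model form.
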