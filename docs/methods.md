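# Methods

## Model

The package implements an abj-DEB model: the standard reserve/structure/
maturity partitioning plus a phase of metabolic acceleration between first
feeding (birth, *b*) and the completion of metamorphosis (*j*), during
which the surface-specific assimilation rate and the energy conductance
scale with structural length (`s = L/L_b`).  After metamorphosis the
factor is frozen at `s_M = L_j/L_b`, and the animal grows along a von
Bertalanffy curve toward `L_∞ = f·s_M·L_m` with rate
`r_B = (k_M/3)/(1 + f/g)·c(T)`.

The organism state is integrated as a four-variable ODE (reserve E,
structure V, maturity E_H, reproduction buffer E_R) with
`scipy.integrate.solve_ivp` (LSODA, with an automatic Radau retry on the
rare "unexpected istate" restart failure), piecewise over forcing segments
and life stages.  Stage transitions are located by the integrator's event
root finding on the maturity thresholds, so event states sit on the
thresholds to well below 1e-9 J.

### Parameters

Primary parameters (κ = 0.73, {p_Am}_b = 14.36 J cm⁻² d⁻¹,
v_b = 0.0053 cm d⁻¹, [E_G] = 2349 J cm⁻³, [p_M] = 29.22 J cm⁻³ d⁻¹,
maturity thresholds 1.04e-3 / 2.03e-2 / 1.65 J, shape coefficients
0.629/0.599) are the published estimates for *Xylonora atlantica*.  Four
auxiliary quantities are not published for this species and are set to the
standard reference values used throughout the DEB literature, all
configurable fields of `ParameterSet`:

* `k_J = 0.002 d⁻¹` (maturity maintenance rate coefficient),
* `κ_R = 0.95` (reproduction efficiency),
* `d_V = 0.09 g cm⁻³`, `w_E = 23.9 g mol⁻¹`, `μ_E = 5.5e5 J mol⁻¹`
  (composition constants behind the wet-weight coefficient
  ω = [E_m]·w_E/(d_V·μ_E) ≈ 1.31),
* `T_A = 8000 K`.  The Arrhenius temperature is pinned independently by
  the species' own printed numbers: the ratios of larval stage ages
  across the 4/11/16 °C scenario columns (e.g. 99.6/48.9 and 99.6/30.06)
  are Arrhenius factors implying T_A ≈ 8000 K, and the lifespan ratio
  821/404 d between 4 and 11 °C gives ≈ 7980 K.
* `E_H^h` (hatch threshold, also unpublished) is calibrated by requiring
  the simulated hatching age at 4 °C, f = 1 to equal the observed 5.6 d;
  the shipped value (1.365e-5 J) regenerates via
  `calibrate_hatch_threshold`.  Hatching has no dynamical effect (feeding
  starts at birth), so this is purely a reporting threshold.

The printed after-metamorphosis rates ({p_Am}_j = 38.77, v_j = 0.0143) are
stored and validated against each other (both must give the same
acceleration factor within 0.5%); the simulated `s_M` at satiety is ~2.67
versus the printed 2.70.

### Egg cost and the embryo

The initial reserve E_0 is fixed by the maternal-effect rule: the scaled
reserve density at birth equals the mother's f.  It is solved by shooting
(bracketing + Brent on E_0 over forward embryo integrations).  Because the
embryo does not feed and all rates share one thermal factor, its
state-space path is temperature-independent, so E_0 is computed once at
T_ref and cached.  The embryo starts from a negligible structural seed
(1e-10 cm³); results anchored at birth change by far less than 0.1% under
a tenfold change of the seed.

### Scenario conventions

Two conventions are needed to connect simulations to the published
scenario tables, and both are adopted package-wide:

* **Trait scenarios** (growth curves, maximum size over a lifespan, total
  reproductive output) run the whole life cycle at constant (T, f) with
  the egg provisioned at the scenario f, and the lifespan horizon (821 d
  at 4 °C, 404 d at 11 °C, given quantities) is counted **from birth**,
  while the age at puberty is reported as the actual age **since
  fertilization**.  Under these conventions the model reproduces the
  published grid: shell height 0.278 cm at the 410-d census (vs ~0.28),
  0.51 cm at 821 d (vs 0.52), puberty at 314 d (vs 316), TRO 5004 (vs
  5026).
* **Larval chronology** runs at the constant dispersal temperature; the
  hatching age is reported at the 4 °C spawning temperature via exact
  Arrhenius rescaling of the non-feeding pre-hatch phase, and
  PLD = a_j(T_dispersal) − a_h(4 °C) − 7 d, the one-week settlement
  convention.  The published stage-age columns are constant-temperature
  Arrhenius images of one another, which is what fixes this convention
  (temperature switching at hatch is inconsistent with the printed birth
  ages).

Simulated larval ages run ~4% fast at metamorphosis (~9% at birth)
relative to the printed values — the residual left by the unpublished
k_J — so chronology checks use 6–10% tolerances while conversion-level
quantities are checked at printed precision.

### Reproduction

After puberty the maturation flux is redirected into the reproduction
buffer with efficiency κ_R.  Total reproductive output converts the
buffer at the end of the horizon to oocytes, `TRO = floor(E_R/E_0)`, with
E_0 evaluated at the scenario f and κ_R applied during accumulation (not
at conversion) — the convention that keeps E_R in joules along the
trajectory and reproduces the published counts within a few percent.  The
maximum reproduction rate is exposed at the ultimate size at a given
temperature (T_ref by default; the published figure's evaluation
temperature is not stated, so it is not used as a check).

### Starvation

Two distinct things carry the name:

* `starvation_time` is the closed-form reserve drawdown used for the
  survival-without-food figure: structure held, reserve consumed by
  somatic maintenance alone, `t = e·[E_m]/([p_M]·c(T))` (448 d at 4 °C
  from e = 1); an ODE variant cross-checks it.
* the engine's general rule for any scenario in which κ·p_C < p_S:
  structure is frozen (no shrinking), the deficit is paid from the
  reproduction buffer while it lasts, then by an extra reserve drain, and
  the run terminates at E = 0.  Under this rule reserve also leaks into
  maturation, so a full f = 0 simulation dies somewhat earlier than the
  closed form — the closed form is the published quantity.  Maturity is
  never allowed to decrease (no rejuvenation).

### Dwarf males

The dwarf scenario develops normally (f = 1) through metamorphosis, then
switches κ to 0.06 and f to 0.8 instantaneously at the metamorphosis
event; s_M stays frozen at its achieved value.  This yields a mature male
of 0.062 cm at the 410-d census (buffer > 0, puberty at ~382 d) and
0.074 cm at 821 d.  The reproduction buffer at the census *increases*
with κ near 0.06 (a larger somatic share grows a larger feeding surface
and brings puberty forward); below κ ≈ 0.04 the buffer stays empty at
410 d.  The low-food alternative (κ unchanged, f = 0.05) matches the
dwarf size but never matures — the allocation switch, not food
limitation, is what reproduces the observations.

## Calibration

Observation sets hold weighted zerovariate entries (each with its T and f
context) and univariate shell-height series whose f may be free.
Weighting follows the convention that one series counts like one
zerovariate entry (its weight is split uniformly over its points), so
long series cannot dominate; weights are configurable.  The lifespan
entry is metadata (no aging submodel is included — the Weibull aging
parameters are unpublished) and must carry weight 0.

The loss is the weighted symmetric bounded form Σw(p−o)²/(o²+p²), i.e.
the SMSE; it is bounded in [0, 1], symmetric in (p, o), and invariant to
per-entry unit rescaling.  `DEBCalibration.fit()` runs Nelder–Mead over
log-scaled parameters with box bounds (a decade around the start unless
natural bounds apply) and a seeded lognormal restart schedule
(CV 20%); the best restart wins and the initial point is returned if
nothing improves on it.  Convergence uses xatol 1e-5 in log-parameter
space and up to 400 iterations per restart — tight enough that restarts
agree to ~1e-5 in loss while keeping a 20-restart study within minutes.
Inside calibration loops the integrator runs a documented looser
tolerance profile (rtol 1e-6 vs 1e-9) and the egg-cost shooting reuses a
warm bracket; predictions agree with the strict profile to ~1e-5
relative, far below observation noise.

Estimation is deterministic given the seed and restart order.  No
covariance matrix is reported (the optimizer is derivative-free); the
per-entry relative errors in `CalibrationResults.re_table` are the
fit diagnostics, mirroring how DEB calibrations are usually judged.

## Synthetic data

The study's calibration dataset is not deposited, so `xylodeb.synthetic`
generates observation sets with its design: 12 zerovariate traits (ages
and sizes at hatch/birth/metamorphosis/puberty, maximum size, wet weight
at puberty, maximum reproduction rate, lifespan), a pine growth series at
f = 1 and an oak series at f = 0.79 (both 11 °C, ~10 sampling ages over a
year), and a population shell-height sample.  Noise is multiplicative
lognormal, mean-preserving, with class-specific CVs defaulting to 0.05
(zerovariate) and 0.10 (univariate) — the order of the published relative
errors.  A single seed fans out into named substreams (one per entry and
series), so adding a series never perturbs existing draws.

The population sample emulates a colonization device recovered after
410 d: individuals settle at times uniform over a 120-d window, grow
deterministically along the scenario trajectory from the settlement-stage
age, and are measured with CV 0.10.  The 120-d spread is a modelling
convenience (the real settlement-time distribution in the devices is
unknown) tuned so the sample mean lands on the observed ~0.27 cm; the
manifest labels it as such.  What passing tests on these data show is
that the *pipeline* (generation → prediction → loss → estimation) is
correct and that the estimation problem is well-conditioned at realistic
noise; they cannot show that the real data were generated by this noise
model, that f was truly constant over a deployment, or that individual
growth variability is absent.

## Numerical choices

* Tolerances: rtol 1e-9, per-state atol (1e-12, 1e-15, 1e-13, 1e-10) for
  [E, V, E_H, E_R]; terminal shell height moves < 1e-6 cm under a 100×
  tightening.
* Event location: solve_ivp's Brent root finding on E_H − threshold;
  after an event the maturity coordinate is set exactly on the threshold
  before the next phase starts.
* Degenerate inputs: f = 0 is a valid forcing (starvation regime);
  r_B(f=0) is defined as k_M·c/3 but flagged in the docstring; zero
  observed values are excluded from MRE with a warning; entries whose
  predictor cannot run (e.g. puberty not reached in the horizon) predict
  NaN and make the loss saturate at 1 rather than crash the optimizer.
* Problem sizes: the acceptance script runs three desk-scale simulations
  (821-day horizons); the test suite's recovery study uses the full
  synthetic design (12 + 2×10 observations, 5 free parameters,
  20 restarts, ~11,000 loss evaluations), sized to finish in minutes on
  one core.

## Known limitations

* No aging/lifespan submodule: lifespans are input horizons, and the
  published predicted lifespan and Table-1 predicted ages (whose
  evaluation temperatures are unstated) are not reproduced.
* The published MRE = 0.148 / SMSE = 0.141 characterize a fit to the full
  unpublished dataset; the implemented scores reproduce their arithmetic
  (and the printed zerovariate RE column averages to ~0.147) but the
  exact values are not recomputable without that dataset.
* Shell height is discontinuous at metamorphosis (δ_ME → δ_M) — both
  shapes are published without an interpolation rule; the size at the
  metamorphosis event itself is reported with the juvenile/adult shape,
  which is what matches the published 0.047 cm.
* The dwarf κ-switch is instantaneous; a gradual allocation shift (as
  described for some other species) is not modelled.
* Single individuals only: no population dynamics, no density dependence
  within a wood fall, no biophysical dispersal.
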