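# Methods notes

## Model structure and assumptions

The population of each species × sex is a density over body length on a
shared uniform grid, advected by deterministic individual growth and
subject to length-dependent losses.  Key structural assumptions:

* **Exponential (density-independent) dynamics.**  No carrying capacity
  or food limitation: the model's purpose is the asymptotic net
  population growth rate (NPGR), which is only meaningful in the linear
  regime.  Predation is a supplemental mortality — predators gain no
  energy from consumed prey.
* **Females drive reproduction.**  The birth source depends on the
  female density only; males are a demographically passive compartment
  fed by a 50:50 birth sex ratio (configurable constant).  Mating and
  male availability never limit reproduction.
* **Predation kernels are ratios of body-volume integrals.**  The loss
  rate on a prey of length λ is the rate constant times the fraction of
  the predator pool's body volume (Λ³ proxy) that is eligible to eat it,
  eligibility being the vulnerability ramp α(λ, Λ).  These ratios are
  degree-0 homogeneous in the densities, so the full system remains
  degree-1 homogeneous and NPGRs are independent of the initial
  abundance scale.
* **Sign conventions.**  Growth transports mass toward larger lengths
  (flux −∂(gu)/∂l); all predation terms are nonnegative loss rates that
  the solver subtracts.

### Parameters that matter

| parameter | units | default / source | role |
|---|---|---|---|
| ρ, ρ_j, ρ_a | d⁻¹ | packaged per species × sex × treatment | logistic / size-dependent growth rates |
| l_max | mm | packaged | maximal length; pile-up point of the stable distribution |
| l_crit, β | mm, – | 3.8–4.4 / 7.7 | transition of juvenile→adult growth rate (size-dependent variants) |
| μ (μ_s, Δ_s) | d⁻¹, mm | packaged; senile branch off (μ_s = μ, Δ_s = 0) | background (senile) mortality |
| f_max, l_r, σ_r | wk⁻¹, mm | packaged | per-female birth-rate amplitude and its length window |
| l_b, σ_b | mm | 2.0, 0.25 | birth-length distribution (set, not measured) |
| υ, ϒ, τ | d⁻¹ | 0 / 0.01 / 0.01·θ | cannibalism, intraguild, terrestrial rates |
| Λ_min, Δ_min, Λ_u, S, l_P | mm | 15, 2, 25, 10, 12 | predation geometry (calibration constants, not measurements) |

The geometry constants encode the intended asymmetries: only
*I. balthica* reaches predator size (Λ_min above every *I. granulosa*
maximal length), and only *I. balthica* reproduces above the
terrestrial-predation threshold l_P.

**The steepness β** of the size-dependent growth-rate transition is the
one growth parameter without a packaged experimental estimate.  It was
calibrated once, to β = 7.7, against the no-predation tipping point of
the tidal gradient (the quantity most sensitive to it); the packaged
value is deliberately shared by both sexes.  A steep transition is
consistent with the tidal treatment's strongly hampered juvenile growth
(ρ_j ≈ ρ_a/5): juveniles grow slowly until ≈ l_crit and then switch to
the adult rate.

## Numerics

* **Discretization:** finite-volume, first-order upwind in flux form on
  [0, 31] mm with 310 cells (dl = 0.1 mm).  Growth is clamped at zero
  beyond l_max, making the upper boundary inert; births enter through a
  source term (cell-averaged normal via CDF differences, so the
  distributed mass is exact), not the boundary.  In this form the
  spatial operator conserves mass identically under pure advection, and
  Runge–Kutta time stepping preserves that linear invariant to
  round-off.  First-order upwinding was chosen over higher-order
  schemes because the rate kernels are only piecewise smooth and the
  target quantity (NPGR) is verified to be grid-converged: halving dl
  moves k by < 0.5 %.
* **Time integration:** adaptive RK45, rtol 1e-6, step capped at the
  advective CFL limit; output densities clipped at zero with the
  clipped mass recorded (≪ 1e-6 of the population in all tests).
* **NPGR runs:** 400 d horizon with the log-linear fit on [200, 400] d.
  At a 200 d horizon the juvenile cohort cycles have not damped
  (log-linearity R² ≈ 0.98–0.99 and up to 12 % disagreement with the
  eigenvalue oracle); at 400 d R² > 0.999 and the fit agrees with the
  dominant eigenvalue of the linear operator to < 1 % for all four
  parameter sets.
* **Tipping points** are located by scanning a coarse monotone bracket
  (1 h steps along the tidal gradient; log-spaced rates in sweeps) and
  refining by bisection (0.05 h, or 1e-4 week⁻¹ on the rate-sweep NPGR
  difference).  The bisection assumes a single sign change, which holds
  for every computed curve.
* **Gradient extrapolation** beyond the 5 h treatment is linear in every
  parameter, as defined; because the extrapolated juvenile growth rate
  of *I. granulosa* would cross zero near θ ≈ 10.7 h, all interpolated
  rate parameters are floored at zero.

## Intraguild predation: pool choice

The intraguild predatory mass is written as the pool of both species,
which in a coupled simulation makes large conspecifics (the
*I. balthica* males) the dominant "intraguild" predators on their own
females, on top of preying on *I. granulosa*.  Coupled dynamics with
this pool move the gradient tipping point *above* the no-predation one,
contradicting the observed asymmetry (*I. granulosa* barely reaches
predator size).  The package therefore exposes the pool as an option:

* `ig_pool="pooled"` (as defined) or `"cross"` (the other species only);
* gradient analyses default to **uncoupled per-species simulations** of
  the pooled kernel — intraguild predation then degenerates to predation
  by the conspecific volume above predator size, which affects
  *I. balthica* only and is the only variant that preserves the full
  tipping-point ordering none > intraguild > terrestrial > both;
* treatment-level rate sweeps default to the **coupled** system, where
  the mutual cross-species effect (strong on *I. granulosa*, negligible
  on *I. balthica*) is visible and the *I. granulosa* NPGR turns
  negative at moderate intraguild rates.

Neither variant can make the *I. granulosa* NPGR negative at a 5 h
tidal duration with ϒ = 0.01 d⁻¹: the volume-ratio kernel is bounded by
1, so the loss is bounded by ϒ and can depress k by at most
7ϒ ≈ 0.07 week⁻¹ — less than half the species' predation-free rate at
that duration.  The corresponding acceptance check fails for this
structural reason, not a numerical one.  Likewise the intraguild
gradient tipping point computes to ≈ 5.5 h under the default
(uncoupled) reading — the closest of the three kernel readings to the
reported ≈ 7 h, but still outside a ±1 h band; the discrepancy is
pinned by the fixed vulnerability geometry, and no remaining free
parameter moves it without breaking the (tighter) no-predation check.

## The synthetic-data generator

`idopspm.synth` emulates the rearing design: 72 individuals per
species × treatment, 21 weekly observations from hatching; sex assigned
Bernoulli(1/2); deterministic growth along the truth model from
l_b = 2 mm; death sampled from the exact survival curve of the
length-dependent hazard; weekly brood counts Poisson around
b(l) × 1 week for live females.

Observation noise is Gaussian with sd 0.25 mm (half the 1 mm reading
resolution), applied to the record only — the animal itself never
shrinks, but a recorded length may.  A `round_to_mm` option emulates
the raw protocol of reading lengths to the nearest millimetre; it is
off by default because quantization produces stepped plateaus in the
increment data that AIC reads, correctly but unhelpfully, as strong
evidence for size-dependent growth (the flexible variants win on
quantized data essentially always).  What passing recovery tests show
is therefore that the estimation stack is consistent and its
uncertainties honest under a faithful noise model — not that every
idiosyncrasy of hand-measured moult data is harmless.

Not emulated: moult-interval variability (moults are weekly by
construction), mating logistics, inter-individual growth heterogeneity,
and environmental fluctuations.

## Estimation details

* Growth models are fitted to per-moult increments (midpoint length vs
  increment per elapsed day) by trust-region nonlinear least squares
  with 5 multiplicative-perturbation restarts; β is capped at 8, beyond
  which the transition is numerically a step and unidentifiable.
  Model selection uses plain Gaussian AIC (n·ln(RSS/n) + 2p), ties
  broken toward fewer parameters.
* Reproduction is fitted to weekly brood counts after mapping week to
  maternal length through the selected growth curve; a single
  variance-reweighting step (variance ∝ fitted mean) accounts for the
  count nature of broods, and the growth curve's parameter uncertainty
  is propagated into the reproduction standard errors by refitting
  under parametric draws of the growth parameters.
* Mortality is fitted by matching predicted to observed weekly survivor
  counts along the growth trajectory.  Because the count series is a
  monotone staircase with strongly autocorrelated residuals, the
  standard error is taken from the exponential-survival Fisher
  information (√D / person-days, D = deaths) rather than the Jacobian.

## Known limitations

* The NPGR inherits first-order grid bias (≈ 0.3 % at the default
  resolution) and the fit-window choice; both are small against the
  ±20 % reproduction band but not against arbitrarily tight targets.
* The intraguild kernel ambiguity above is resolved by convention, not
  by data; conclusions that hinge on which species the intraguild loss
  falls on should be checked under both pool modes.
* Linear interpolation of every parameter along the tidal gradient is a
  strong assumption, and beyond 5 h an extrapolation; the rate floor is
  a pragmatic guard, not biology.
* Growth is deterministic given sex; real cohorts spread around the
  mean curve, so the synthetic tables understate length variance late
  in life.
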