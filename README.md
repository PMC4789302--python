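# idopspm

Size-structured population dynamics of two littoral isopods, *Idotea
balthica* and *Idotea granulosa*, built to ask why two species with nearly
identical requirements segregate sharply between permanently submerged
habitats and the intertidal zone.  The package is aimed at population
ecologists and modellers working with physiologically structured
population models (PSPMs), inverse demographic-rate estimation, or
size-selective trophic interactions.

## The model

For each species, sex and environmental condition, the population is a
density u(t, l) over body length l (mm) governed by a
McKendrick–von Foerster transport–reaction equation

    ∂u/∂t = −∂(g(l) u)/∂l − m(l) u − p(t, l) u + r(t, l)

with

* **growth** g(l): von Bertalanffy or (size-dependent) logistic, five
  variants G1–G5 subject to AIC model selection;
* **mortality** m(l): basic rate μ with an optional senile branch above
  l_s = l_max − Δ_s;
* **reproduction**: per-female birth rate b(l) = f_max·N(l; l_r, σ_r),
  offspring entering with normally distributed birth lengths
  N(l; l_b, σ_b);
* **predation** p(t, l): size-selective cannibalism, intraguild
  predation and terrestrial (bird) predation, gated by a vulnerability
  kernel α(λ, Λ) ∈ [0, 1] and weighted by the predators' share of the
  population's body volume (∝ Λ³).

The fitness currency is the **net population growth rate (NPGR)** k: the
total abundance U(t) = ∫u dl becomes asymptotically exponential,
U(t) ≈ U₀·e^(kt), and k is recovered by a log-linear fit — or, for the
predation-free linear system, by the dominant eigenvalue of the
discretized operator, which serves as an independent cross-check.
A **tipping point** is the parameter value (a predation rate, or a daily
tidal-emergence duration θ) at which both species' NPGRs coincide and
competitive dominance switches.

The packaged parameter files (`src/idopspm/params/`) carry the
experimentally estimated growth, mortality and reproduction parameters
for both species under permanent submersion ("reference") and 5 h daily
emergence ("tides"), plus default predation geometry.

## Worked example

```python
from idopspm import load_table3, load_predation_defaults, npgr, SimulationConfig

params = load_table3("reference")          # both species, submerged treatment
pp = load_predation_defaults()             # no predation (rates default to 0)
fits = npgr(params, pp, cfg=SimulationConfig(t_end=400.0))
for species, fit in fits.items():
    print(f"{species:10s} k = {fit.k:.3f} week^-1  (R^2 = {fit.r2:.5f})")
```

prints

```
balthica   k = 0.396 week^-1  (R^2 = 0.99987)
granulosa  k = 0.127 week^-1  (R^2 = 0.99979)
```

i.e. under permanent submersion *I. balthica* outgrows *I. granulosa*
by a factor of ~3 in weekly rate; the R² values confirm the populations
reached clean exponential growth inside the fit window.  Repeating with
`load_table3("tides")` gives 0.251 and 0.188 week⁻¹ — emergence hurts
*I. balthica* and helps *I. granulosa*, but is not by itself enough to
flip dominance at 5 h.

The same analyses are available from the shell:

```sh
idopspm synth --species granulosa --seed 1 --out rearing.csv   # synthetic experiment
idopspm fit rearing.csv --out fits.csv                         # growth/mortality/reproduction fits
idopspm npgr --treatment tides --out npgr.json                 # growth rates
idopspm gradient --scenario terrestrial --out gradient.csv     # tipping point along the tidal gradient
idopspm reproduce-table4 --out table4.csv                      # full scenario x sensitivity grid
```

Because no individual-level data were deposited with the original
experiments, `idopspm.synth` generates seeded synthetic rearing tables
(72 individuals per species and treatment, 21 weekly observations) from
any chosen "truth" parameters; the fitting stack is validated by
recovering those truths.

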