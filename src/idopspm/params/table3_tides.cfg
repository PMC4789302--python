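# Demographic parameter estimates, tidal treatment (5 h daily emergence).
# I. balthica: logistic growth with the maximal length fixed at the reference
# value (G3).  I. granulosa: size-dependent logistic growth (G4) with hampered
# juvenile rates; the steepness beta of the rate transition was not tabulated
# and defaults to 1 (simple exponential saturation around l_crit).
balthica:
  female:
    growth: {variant: G3, rho: 6.7e-2, l_max: 16.8, l_max_fixed: true}
    mortality: {mu: 2.9e-3}
  male:
    growth: {variant: G3, rho: 5.8e-2, l_max: 27.8, l_max_fixed: true}
    mortality: {mu: 1.4e-3}
  reproduction: {f_max: 14.9, l_r: 16.7, sigma_r: 0.64, l_b: 2.0, sigma_b: 0.25}
granulosa:
  female:
    growth: {variant: G4, rho_a: 8.2e-2, rho_j: 1.7e-2, l_crit: 3.8, beta: 7.7, l_max: 10.8}
    mortality: {mu: 6.5e-3}
  male:
    growth: {variant: G4, rho_a: 6.0e-2, rho_j: 1.3e-2, l_crit: 4.4, beta: 7.7, l_max: 13.2}
    mortality: {mu: 5.3e-3}
  reproduction: {f_max: 11.7, l_r: 9.94, sigma_r: 1.54, l_b: 2.0, sigma_b: 0.25}
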