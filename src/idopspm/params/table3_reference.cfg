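# Demographic parameter estimates, reference treatment (permanent submersion).
# Growth model selected by AIC per species x sex; rates in d^-1, lengths in mm,
# f_max in week^-1.  Senile mortality is off by default (mu_s = mu, delta_s = 0).
balthica:
  female:
    growth: {variant: G2, rho: 8.8e-2, l_max: 16.8}
    mortality: {mu: 6.4e-4}
  male:
    growth: {variant: G2, rho: 7.3e-2, l_max: 27.8}
    mortality: {mu: 6.4e-4}
  reproduction: {f_max: 21.0, l_r: 16.3, sigma_r: 0.39, l_b: 2.0, sigma_b: 0.25}
granulosa:
  female:
    growth: {variant: G2, rho: 3.2e-2, l_max: 9.7}
    mortality: {mu: 5.7e-3}
  male:
    growth: {variant: G2, rho: 2.7e-2, l_max: 14.6}
    mortality: {mu: 2.1e-3}
  reproduction: {f_max: 5.46, l_r: 8.43, sigma_r: 0.8, l_b: 2.0, sigma_b: 0.25}
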