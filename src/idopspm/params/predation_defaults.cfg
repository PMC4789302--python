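# Default predation geometry (calibration settings; lengths in mm, rates d^-1).
# lambda_min: minimum predator length -- I. granulosa never reaches it, so that
#   species neither cannibalizes effectively nor preys on I. balthica.
# l_p: critical prey length for terrestrial (bird) predation -- chosen between
#   the two species' mean reproduction lengths, so only I. balthica reproduces
#   inside the vulnerable size range.
# Rates default to zero; scenario runs override them.
upsilon: 0.0
upsilon_ig: 0.0
tau: 0.0
lambda_min: 15.0
delta_min: 2.0
lambda_u: 25.0
s_range: 10.0
l_p: 12.0
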