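# Published calibration of the ON-condition explanatory model.
# Covariate coding: strength = 1 for beat 3 (strong), 0 for beat 4 (weak).
condition: "ON"
beta:
  intercept: -0.76
  strength: 1.77
sigma_person: 1.19
sigma_track: 0.41
g: 0.40
u: 0.98
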