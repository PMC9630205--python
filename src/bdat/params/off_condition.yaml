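# Published calibration of the OFF-condition explanatory model.
# Coding: displacement = level index 1..7; direction = 0 early / 1 late;
# strength = 1 strong (beat 3) / 0 weak (beat 4); interaction = direction*strength.
condition: "OFF"
beta:
  intercept: 2.23
  displacement: 0.41
  direction: -1.91
  strength: 0.16
  interaction: -1.48
sigma_person: 1.30
sigma_track: 0.05
g: 0.40
u: 0.96
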