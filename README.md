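# bdat — Beat-Drop Alignment Test engine

`bdat` is a self-contained psychometric engine for the **Beat-Drop
Alignment Test (BDAT)**, a measure of musical beat perception that works
without any sensory cue to the beat.  Each trial plays a short 4/4 music
clip whose fourth bar contains a *beat drop*: all rhythmic content is
removed from beats 2–4 and replaced with a non-rhythmic drone.  A single
probe click is placed during the drop, either exactly on an (unheard) beat
or displaced from it, and the listener judges "on the beat" vs "off the
beat".  Doing well requires extracting the pulse from the music, continuing
it covertly through the gap, and comparing it against one probe — the
aspect of beat perception that click-alignment tests cannot isolate.

The package is aimed at auditory-cognition and individual-differences
researchers who want to generate the calibrated item bank and schematic
stimuli, fit the explanatory response models, administer the adaptive test,
or validate the whole pipeline by simulation.

## The model

Response accuracy is modelled per condition by a mixed-effects logistic
regression with modified asymptotes,

```
P(y = 1) = g + (u − g) · logistic(x'β + b_person + c_track),
b_person ~ N(0, σ_ID²),   c_track ~ N(0, σ_track²),
```

with guessing floor `g = 0.4` (the task is a one-alternative forced
choice) and inattention ceilings `u = 0.98` (ON) / `0.96` (OFF).  ON items
carry one covariate (metrical strength of the target beat: beat 3 strong,
beat 4 weak); OFF items carry displacement level (1–7), probe direction
(early/late), strength, and the direction × strength interaction.  Because
g, u and σ_ID are shared across the bank, the model is equivalent to a
four-parameter logistic (4PL) IRT model with constant guessing,
inattention and discrimination,

```
a = σ_ID,   b_item = −x'β / σ_ID,
P(θ) = g + (u − g) · logistic(a (θ − b)),
```

on a z-score ability scale.  The adaptive test re-estimates θ by EAP
(expected a posteriori, standard-normal prior) after every trial and picks
the unused-track item whose difficulty is closest to the running estimate;
the first item always has difficulty closest to 0.  Scores are also
reported as pseudo-IQ (100 + 15 θ).

Probe displacements are not spaced linearly but on a perceptual-accuracy
scale `PA(d) = cos(πd)⁴`: seven equally spaced PA values between the 15%
and 45% endpoints, inverted and rounded to whole percent, give the level
set 15/18/20/23/26/31/45% of the beat period.

Calibration fits the explanatory model by maximizing a marginal likelihood
that integrates participants out by exact Gauss–Hermite quadrature and the
crossed track effects by a Laplace approximation (see
[docs/methods.md](docs/methods.md)).

## Worked example

```python
import bdat
from bdat.simulate import simulated_responder

print(bdat.displacement_levels())
# [0.15, 0.18, 0.2, 0.23, 0.26, 0.31, 0.45]

bank = bdat.build_item_bank(n_tracks=30, exclusions=bdat.DEFAULT_EXCLUSIONS)
len(bank)   # 814: 900 minus the screened-out (track, condition) cells

params = bdat.default_params()       # bundled published calibration
res = bdat.run_session(simulated_responder(theta=1.0, params=params, seed=11),
                       bank, params, length=25, seed=7)
print(res.trials.head(5)); print(res.final, res.pseudo_iq)
```

Output (abridged):

```
 trial                 item_id condition        b  response    theta       se
     1 T28_OFF_B3_late_L2_t125       OFF 0.138462         1 0.206407 0.983888
     2 T18_OFF_B3_late_L2_t125       OFF 0.138462         1 0.399433 0.956389
     3 T23_OFF_B3_late_L1_t125       OFF 0.453846         1 0.587365 0.930530
     4          T07_ON_B4_t125        ON 0.638655         1 0.760031 0.903988
     5 T25_OFF_B3_late_L1_t125       OFF 0.453846         1 0.916476 0.867367
final theta = 0.922 (se 0.513), pseudo-IQ = 113.8
```

The session starts at the easiest-available difficulty near 0 (the
population mean), climbs as the simulated respondent (true θ = 1) keeps
answering correctly, and lands at θ̂ = 0.92 with a posterior SE of 0.51
after 25 trials — a pseudo-IQ of 114.

A command-line interface mirrors the library:

```
bdat genbank --tracks 30 --tempi varied --exclude-defaults --out bank.csv
bdat render --bank bank.csv --item-id T05_ON_B3_t125 --out stimuli/
bdat simulate study1 --n 125 --seed 42 --out resp.csv
bdat calibrate --data resp.csv --condition off --g 0.4 --u 0.96
bdat simulate recovery --mode adaptive --n 500
bdat run-session --bank bank.csv --respond simulated:theta=1.0 --length 25 --seed 7
```

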