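# frontforage

Movement-state modelling, space-use overlap and foraging-site-fidelity
statistics for GPS-tracked central-place foragers — built around the question
of how **age** changes the way a seabird responds to **ocean fronts**.

Northern gannets (*Morus bassanus*) and other marine predators forage at
meso- and sub-mesoscale fronts, which satellite altimetry maps as ridges of
the backward-in-time finite-size Lyapunov exponent (FSLE). `frontforage`
provides a tested, reusable pipeline for the full analysis:

1. **Trip preprocessing** — foraging trips are maximal runs of GPS fixes more
   than 10 km from the colony lasting over 40 min; fixes are projected into a
   colony-centred transverse-Mercator plane and linearly interpolated onto an
   exact 2-min lattice; seven trip characteristics are computed (duration,
   length, departure angle, range, terminal x/y, convex-hull area).
2. **A 3-state hidden Markov movement model** — step lengths are gamma, and
   turning angles von Mises, within each latent state (rest / forage /
   transit); the state transition probabilities are a multinomial logit in
   frontal intensity |FSLE|, age class and their interaction,

   γ<sub>ij</sub>(t) = exp(β<sub>ij</sub>·z<sub>t</sub>) / Σ<sub>j′</sub> exp(β<sub>ij′</sub>·z<sub>t</sub>),  z<sub>t</sub> = (1, fsle<sub>t</sub>, age, fsle<sub>t</sub>·age),

   fitted by maximum likelihood (exact forward-algorithm gradient, random
   restarts), ranked by AIC across candidate covariate structures, and
   decoded with the Viterbi algorithm.
3. **Space-use overlap** — kernel utilization distributions per age class
   (Gaussian kernel, σ = 10 km, 1 km cells), Bhattacharyya's affinity
   BA = Σ√(p₁p₂) within the 50%/95% volume contours, and a null distribution
   from 1000 reassignments of age labels among birds.
4. **Repeatability** — foraging-site fidelity as the intra-class correlation
   R = σ²<sub>id</sub>/(σ²<sub>id</sub>+σ²<sub>res</sub>) from one-random-intercept models (exact
   profile REML), parametric-bootstrap CIs, Fisher-z (Zr) differences between
   age classes, and a circular-ANOVA analogue for departure angles.
5. **Time budgets** — per-trip state proportions with a solar-elevation
   day/night split and bird-level permutation tests between age classes.

Because real tracking data of this kind are rarely shareable, the package
includes a first-class **synthetic cohort generator**: it runs the HMM
generatively over simulated ridge-structured FSLE fields and produces
central-place trips for a cohort of 31 adults and 15 immatures with known
emission parameters, transition coefficients and per-fix state truth, so
every stage of the pipeline can be validated against ground truth.

## Worked example

```python
import frontforage as ff
import pandas as pd

# simulate a small cohort over a synthetic frontal field
cfg = ff.SimConfig(n_adults=6, n_immatures=3, seed=42)
cohort = ff.simulate_cohort(cfg)

# preprocess: segment trips, regularize, attach |FSLE| covariates
fixes = cohort.tracks.assign(
    timestamp=pd.to_datetime(cohort.tracks.timestamp).dt.tz_localize(None))
trips = ff.segment_trips(fixes, cfg.colony)
trips = [ff.regularize(t, colony=cfg.colony) for t in trips]
series = ff.prepare_series(trips, cohort.fsle, cfg.colony)

# fit the interaction model and print the estimates
res = ff.MovementHMM(series, design="fsle*age").fit(n_restarts=5, seed=1)
print(res.summary())
```

Output (abridged):

```
Three-state movement HMM
  design: fsle*age   trips: 55   steps: 4195
  loglik: -3064.14   params: 39   AIC: 6206.27

State-dependent distributions
  state    step mean  step sd   turn mu  turn kappa
  rest        0.030    0.019     0.006      21.12
  forage      0.547    0.708    -0.048       0.92
  transit     1.665    0.413    -0.001      24.69

Transition coefficients (natural covariate scale)
  transition                   1        fsle         age    fsle:age
  ...
  transit->forage       -1.965       2.202      -0.289      -0.309
```

The three rows are the recovered behavioural modes: resting on the water
(30 m steps, concentrated turns), foraging (short tortuous flight) and
transit (1.7 km per 2 min, straight).  The generating values are
0.03/0.41/1.66 km; at this small cohort the forage-state parameters carry
visible sampling noise, and at the full default cohort (~20 000 steps) the
median relative error across emission parameters drops below a few
percent.  The positive `fsle` coefficient on transit→forage (+2.2,
generated +2.5) is the adults' frontal response — switching into foraging
rises steeply with frontal intensity; the age interaction that damps it
for immatures (generated −2.0) needs the full cohort to be estimated
reliably.

The same stages run from the shell:

```sh
frontforage run-all --outdir out --seed 7       # full pipeline + manifest
frontforage simulate --outdir out --seed 7      # just the synthetic cohort
frontforage fit-hmm out/tracks.csv out/fsle.nc --design "fsle*age"
```

`run-all` writes every artifact (trip metrics, AIC table, decoded states,
overlap JSON, repeatability and budget tables) plus `manifest.json` with a
SHA-256 checksum of each artifact, the config hash and the seed; rerunning
with the same seed reproduces the checksums byte-for-byte.

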