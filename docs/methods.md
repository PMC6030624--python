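# Methods

This note documents the models implemented in `frontforage`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Movement model

Trajectories are regular sequences of positions at a fixed interval
(default 120 s) in a planar, colony-centred transverse-Mercator projection.
Each step t has a length `s_t` (km) and a turning angle `φ_t` (signed change
of heading, radians in (−π, π]; undefined at the first step of a trip and on
either side of a zero-length step).  A latent 3-state Markov chain assigns
each step to rest, forage or transit; states are always reported in
ascending step-mean order, so the labelling is identifiable.

**Emissions.** Step lengths are gamma with a mean/sd parameterisation
(shape = mean²/sd², rate = mean/sd²); turning angles are von Mises(μ, κ).
If the data contain exact zero steps (a logger can report identical
consecutive positions) a point mass at zero is added per state, because the
gamma density carries no mass at 0.  Zero inflation is enabled
automatically only when zeros are present, and its three weights are then
counted in the AIC parameter count.

**Transitions.** The off-diagonal transition probabilities follow a
multinomial logit with the diagonal ("stay") as reference category — the
convention of the movement-HMM toolchain this package mirrors.  The design
can be intercept-only or include frontal intensity (|FSLE|, d⁻¹), age
(0 = adult, 1 = immature, adults the reference class) and their
interaction.  The covariate is sampled at the step's *origin* fix (the
value at time t drives the transition t→t+1) and z-scored internally for
optimizer conditioning; coefficients are reported on both the standardized
and the natural scale.  The natural scale is the right one for sign and
effect-size interpretation because standardization mixes slope terms into
the intercept and age columns.

**Likelihood and fitting.** Trips are independent sequences; the likelihood
is the scaled forward recursion summed over trips.  Each trip's initial
state distribution is uniform by default.  A stationary-at-first-covariate
option exists, but the uniform convention is what the optimizer maximises:
it makes the analytic gradient exact via Fisher's identity
(forward–backward smoothing for the emission terms, the softmax identity
∂log γ_ij/∂η_ij′ = 1[j=j′] − γ_ij′ for the transition terms).  With ~80-step
trips the initial-distribution term contributes a few hundred of ~20 000
log-density terms, and the two conventions agree to well within the
sampling noise of every parameter.  Working parameters are log step
mean/sd, the pair (κ cos μ, κ sin μ), logit zero mass and unconstrained β;
optimisation is L-BFGS-B with analytic gradients, 25 random restarts by
default (initial step means log-uniform between the 10th and 90th
percentile of observed steps, κ log-uniform in [0.5, 30], β ~ N(0, 0.5)
with intercepts shifted to −2 to favour state persistence).  Restarts that
exhaust the iteration budget while near-stationary (max |gradient| <
1e-4·|loglik|) are accepted; line-search failures are excluded.  Candidate
designs are ranked by AIC; nested designs are fitted smallest-first and
each larger design is warm-started from the previous fit, which enforces
the nesting inequality on the maximised likelihoods.

**Decoding.** The Viterbi algorithm with ties broken toward the lower state
index.  Decoded states feed the time budgets.

## Synthetic cohort generator

The generator runs the model above *forwards* to produce data with known
truth.  Its defaults describe the study system the package is built for:
31 adult and 15 immature birds, 2-min fixes, per-age trip counts of 3–5
(adults) and 7–9 (immatures) (~247 trips), gamma/von Mises emissions with
means 0.03/0.41/1.66 km, sds 0.02/0.54/0.43 km and κ = 22.3/1.0/27.1, and
transition coefficients in which frontal intensity raises transit→forage
switching and holds birds in the foraging state far more strongly for
adults than immatures, while immatures rest more.  Trip durations are drawn
uniformly from 1.0–2.4 h, which puts a default cohort near 20 000 steps —
the problem size used throughout the validation suite; the real birds'
trips are typically far longer, which changes sample size but not the
structure of any estimator.

The frontal field is a stand-in with the right statistical shape, not a
hydrodynamic product: band-pass-filtered (difference-of-Gaussians) Gaussian
noise, made ridge-like by taking |·|, sign-flipped to the non-positive
backward-FSLE convention, AR(1)-correlated across days, and scaled to a
maximum intensity of 1 d⁻¹.  Consumers take absolute values ("positive
scale") before use.

Central-place behaviour is imposed by steering, with care taken to keep the
emission distributions clean: the outbound leg is forced to transit until
the track passes the 12 km exit radius, a reflective barrier keeps the free
phase outside 1.02× the 10 km trip radius, and once a drawn trip duration
expires the transit-state turn *mean* is aimed at the colony (the von Mises
noise of the state is retained) with the final approach inside 11 km forced
to transit.  Consequences: segmentation by the 10 km/40 min rule recovers
the generated trips *exactly* at zero dropout; emission parameters are
essentially uncontaminated (steps are always drawn from the state's gamma);
but transition-intercept estimates absorb a small bias from the forced
transit segments, and the transit κ and forage sd carry a few tens of
percent of bias from steered turns near the boundaries.  The validation
criteria are set on medians across parameters, which these tails do not
move.

Adults draw a bird-specific preferred departure heading from a concentrated
population distribution (von Mises κ = 3 around a fixed bearing) and repeat
it across trips (κ = 8); immatures draw nearly uniform headings with low
repetition (κ = 0.6).  This encodes the system's two population-level
regularities — higher adult site fidelity and a narrower adult foraging
distribution with partial, statistically detectable segregation — and both
emerge in the pipeline output rather than being computed from the config.

What the synthetic data do **not** emulate: GPS position error, diel
rhythms in state switching (so day/night budget splits on synthetic data
show no day/night contrast), wind and flight energetics, tides, prey
memory beyond the fixed preferred heading, and hydrodynamically realistic
front evolution.  Passing tests therefore demonstrate the estimators are
correct and well calibrated under the model's own assumptions, not that
those assumptions hold for any particular field dataset.

## Space use

Kernel UDs use an isotropic Gaussian kernel whose bandwidth (10 km) is the
kernel's standard deviation, evaluated *exactly* on the shared 1 km lattice
through the kernel's x/y separability (two exponential matrices and one
BLAS product), then normalised to unit mass.  Volume contours take cells in
descending density order until the target mass is reached.  "BA within a
contour" is not uniquely defined in the field's verbal descriptions; here
each group's UD is masked to its *own* contour and renormalised before
Σ√(p₁p₂), a definition that reduces to full-grid BA as the level → 1.  The
permutation null reassigns age labels at the *bird* level, preserving class
sizes (birds are the exchangeable unit); the p-value is the strict
proportion of null BA values below the observed one, so p = 0 is possible —
the literal definition used in the field.

## Repeatability

The one-random-intercept Gaussian model is fitted by exact profile
REML/ML: for a single grouping factor the required matrix algebra collapses
to per-group scalars, and the REML stationary point is located by root
finding on the *analytic* derivative of the profile deviance (envelope
theorem), which reproduces balanced-ANOVA method-of-moments components to
~1e-13 and handles the σ²_id = 0 boundary explicitly.  R = σ²_id/(σ²_id +
σ²_res) is computed per age class *without* an age fixed effect (fidelity
within each population); duration, length and area are log₁₀-transformed
first.  CIs are percentile intervals from 1000 parametric-bootstrap refits;
Zr = atanh(R) (clipped at 1 − 1e-9), and the CI of an adult–immature Zr
difference comes from differences of the two independent bootstrap draw
vectors.  Group mean comparisons of trip metrics use the ML
likelihood-ratio test of the age effect; its χ²₁ calibration is adequate
from ~20 birds upward and mildly anticonservative below that.

For departure angles, the repeatability analogue is built on mean resultant
lengths: with R_i the resultant length of bird i's angles and R_tot of the
pooled angles, R_circ = (Σᵢ R_i − R_tot)/(N − R_tot), clipped to [0, 1];
CIs are a bird-level bootstrap.  It is 1 when every bird repeats its own
angle, rotation-invariant, and tends to 0 for i.i.d. angles as the per-bird
sample grows (it carries an O(1/√n_i) positive bias at small n, like any
resultant-length statistic).  The exact estimator used by the field's
circular-ANOVA references is not published in closed form; this
decomposition is our documented interpretation.

## Time budgets

Per-trip proportions of decoded states, optionally split day/night by solar
elevation (NOAA solar-position equations; horizon at −0.833°, the standard
refraction-corrected sunrise definition).  Age classes are compared per
state by permuting bird labels over bird-mean proportions (two-sided) — a
deliberate replacement of the original per-fix mixed-effects logistic
regression that tests the same group contrast at the correct exchangeable
unit without a GLMM dependency; this is the one analysis component that is
a statistical substitute rather than a reimplementation.

## Numerical conventions and edge cases

- Forward recursion in scaled linear space with per-step max-subtraction;
  transition softmax guarded the same way.  Row sums of every transition
  matrix are 1 to 1e-12 for any finite covariates.
- Headings use the compass convention atan2(Δx, Δy); wrap to (−π, π].
- Turning angles adjacent to zero-length steps are treated as missing, and
  missing turns contribute step density only.
- Segmentation runs on raw fixes; regularization afterwards (the
  threshold-order question is not settled in the field; this order keeps
  the rule's geometry exact).  Interpolation across gaps longer than 30 min
  is performed but flagged.
- Departure angle = circular mean of the first five colony-to-bird bearings
  beyond 10 km; with fewer than five the available ones are used and the
  count recorded.
- A single global seed spawns per-stage seeds (simulation, HMM restarts,
  permutations, bootstraps); reruns are byte-identical, and the pipeline
  manifest records a SHA-256 per artifact plus the config hash.

## Problem sizes in the validation suite

The test suite fits the full interaction model on ten ~20 000-step cohorts
(5 restarts each), checks the forward/Viterbi recursions against complete
path enumeration on series of length ≤ 8, calibrates the overlap
permutation test on 200 small replicates (199 permutations each) and the
bootstrap CI on 50 replicates of a 20-bird × 10-trip design, and runs the
end-to-end pipeline twice on a reduced cohort to verify checksum-level
determinism.  These sizes were chosen so the full validation runs in tens
of minutes on a single CPU while keeping every statistical check at a
sample size where its expected behaviour is unambiguous.

## Known limitations

- Three states, fixed; no hierarchical or random-effect HMM variants, no
  covariates on emission parameters.
- The FSLE stand-in matches texture, not physics; computing FSLE from
  altimetry velocity fields is out of scope.
- The circular repeatability estimator is an interpretation (above), and
  the contour-restricted BA definition is one of several defensible
  choices.
- Bandwidth is fixed (10 km), not cross-validated; UDs are 2-D and
  time-pooled.
- p-values from strict-inequality permutation counting can be exactly 0;
  users wanting the +1-corrected convention can compute it from the stored
  null vector.
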