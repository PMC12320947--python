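# Methods

This note documents the models and procedures implemented in `windforage`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The scientific problem

A central-place forager commutes tens to hundreds of kilometres between a
colony and pelagic feeding grounds. Wind acts on it at two scales: on the
commute, by making some routes cheaper than others (tailwinds and
crosswinds raise ground speed and let a flap-glider glide more), and at the
feeding site, by changing prey accessibility (aerial prey such as flying
fish glide further in strong winds). The package quantifies both: a
used–available route-selection analysis built on a rotation null, and a
behavioural-state model whose switching probabilities depend on wind and
wave covariates.

## Trip processing

**Trip definition.** A trip is a maximal run of fixes more than 1 km from
the colony lasting more than 30 min, extended to the adjacent boundary
fixes. Both thresholds are configuration parameters (`trips.*`); the
defaults match standard practice for colonial seabird telemetry.

**Regularization.** Fixes are interpolated onto a 5-min lattice by
piecewise great-circle (slerp) interpolation of burst centroids, with
lattice points inside observation gaps longer than 30 min flagged
`low_confidence`. This replaces a state-space (correlated-random-walk)
smoother deliberately: at 5-min resolution over 30-s or burst GPS schemes,
great-circle interpolation is deterministic, testable against simulation
truth (RMS displacement < 1 km in the suite), and free of tuning. The cost
is no position-error filtering; a max-speed sanity flag is the only outlier
guard, and noisy loggers would need pre-filtering.

**Stages.** The "middle" of a trip is the contiguous span from the first
to the last fix whose colony distance is at least 75% of the trip maximum;
outbound and inbound are the spans before and after. Reading the 75% rule
as distance-from-colony (rather than cumulative distance travelled) keeps
stage labels invariant to track rotation about the colony — an invariant
the suite asserts and which the rotation null requires. Contiguity makes
the rule robust to brief dips below the threshold.

**Step metrics.** Step length by haversine on a spherical Earth (mean
radius; error ~0.5% at these scales), bearing as initial great-circle
azimuth, turning angle as the wrapped bearing difference in (-pi, pi],
ground speed as step over elapsed time. Duplicate consecutive positions
yield a zero step and missing bearing/turn.

## Rotation null and used–available table

Alternative routes are generated by rotating each commute leg about the
axis through the colony and the Earth's centre (Rodrigues rotation of ECEF
vectors). This is an exact isometry: colony distances and the leg's
internal geometry are preserved (asserted to < 1 m on 200-km legs), while
the leg samples different wind. Timestamps are inherited unchanged — the
null asks "same times, different places". Twenty angles per leg, i.i.d.
uniform on [0, 360); no land-masking (open-ocean domain by assumption).

Ten rotated legs per observed leg enter the table (the ratio is
configurable, and `rotation.tune_ratio` provides the AUC sweep over
{1, 5, 10, 15, 20}). Within each stratum (trip × leg) the used rows are
weighted so used and available carry equal total weight; a global weighting
variant is exposed. Bearings of rotated legs are recomputed from the
rotated positions, so relative wind direction changes while wind speed (in
a spatially uniform field) does not — asserted in the suite.

## Environmental annotation

Wind u10/v10 are "toward" components; speed is sqrt(u² + v²) and direction
atan2(u, v) in compass convention. Wave mean direction arrives in the
"from" convention and is converted to "toward" at read time so all
downstream code handles one convention. Relative direction folds the
difference between travel bearing and flow direction to [0°, 180°]
(0 tailwind, 90 crosswind, 180 headwind). Extraction is nearest cell and
nearest hour with ties toward the earlier time and lower index; bilinear
spatial interpolation is available behind a flag but is not the default —
with hourly 0.25° fields and 5-min fixes the nearest-cell error is small
against the field's own uncertainty.

## Accelerometer behaviour classification

Orientation is standardized by rotating the stream so the median
acceleration vector over the quietest 1-s windows (lowest quartile of
VeDBA) maps to (0, 0, 1) g; the mounting offset is recovered to within ~2°
on simulated streams. Static and dynamic components are split with a 2-s
centred running mean (window exposed in config; the choice trades pitch
fidelity during slow manoeuvres against leakage of wingbeats into the
static channel). Per 1-s segment (25 samples) the features are mean ODBA
and VeDBA of the dynamic component, mean/sd of roll = atan2(sy, sz) and
pitch = atan2(sx, sqrt(sy² + sz²)) from the static component, mean/sd/
min/max per raw axis, and mean temperature — 19 quantities in all.

Classification is a random forest (default 10 000 trees, 5 features per
node, scikit-learn); per-class recall is reported out-of-bag by default
with a stratified holdout option, since the two can differ and both are
informative. The logic correction relabels any run of non-flight labels of
length ≤ 1 segment flanked on both sides by flight to the nearer flanking
flight label (ties to the preceding label); it is idempotent, and
property-based tests assert only sub-threshold flanked runs ever change.
The flapping proportion for a fix is flap/(flap+glide) seconds over the
5-min window ending at the fix, missing when the window holds no flight.

## The movement HMM

Three states with the field's canonical signatures: feeding (short,
tortuous), travelling (long, straight), resting (short, straight).
Emissions: gamma step lengths parametrized by (mean, sd) — the natural
reporting scale — and von Mises turning angles (mu, kappa). Transitions:
multinomial logit with the diagonal as reference,
eta_ij = beta0_ij + beta_ij·x on centred/standardized covariates, guarded
by log-sum-exp. The initial distribution of each trip is the stationary
distribution at its first covariate row (an estimated initial distribution
is the natural alternative; stationarity is the better default for trips
that start mid-behaviour at the colony).

**Likelihood and fitting.** The scaled forward algorithm runs over
independent per-trip blocks, with missing emissions contributing likelihood
1 and steps under 1 m jittered (seeded) to avoid the gamma density's
singularity at zero. The recursion is verified against exhaustive path
enumeration to 1e-10. Fitting maximizes the likelihood with L-BFGS-B in a
working parametrization (log means/sds/kappas, unconstrained logit
coefficients) from 25 random starts — step means drawn from the data's
5–95% quantiles, kappa log-uniform on [0.1, 30], intercepts implying
self-transition probabilities in [0.7, 0.95]. Each start gets a capped
screening run and the best few are polished to convergence; the lowest
negative log-likelihood wins. The forward pass is JIT-compiled (numba)
with an equivalent plain-numpy path.

**Identification.** Likelihood invariance to state relabelling is resolved
post hoc: travelling is the state with the largest step mean; of the
remaining pair, resting is the straighter (higher kappa) and feeding the
more tortuous. All parameters, including logit rows, are permuted
accordingly.

**Model set and inference.** The ten-model covariate enumeration spans the
null model, each of wind speed (ws), relative wind direction (rwd) and
relative wave direction (rwavd), their two- and three-way additive
combinations, and the two interaction models ws×rwd (+ rwavd) and
ws×rwd + ws×rwavd; AIC ranks them. Viterbi decoding is log-space dynamic
programming with ties resolved to the lowest state index (tolerance-based,
so solver noise of order 1e-16 cannot flip a tie). Stationary
probabilities solve delta Gamma(x) = delta by linear least squares with the
simplex constraint, flagged missing if Gamma(x) is reducible; uncertainty
comes from a parametric bootstrap of the transition coefficients using the
finite-difference curvature at the optimum (a delta-method analogue that
respects the simplex nonlinearity). Goodness of fit uses one-step-ahead
forward pseudo-residuals per channel (von Mises CDF taken on the (-pi, pi]
convention); they are uniform on well-specified simulations and reject a
deliberately lumped model.

## Selectivity and flight-metric splines

One fitting route serves three families: Bernoulli (route selection,
weighted), Beta (flapping proportion; boundary values shrunk by
(y(n-1)+0.5)/n and fitted by quasi-likelihood IRLS with variance
mu(1-mu), precision recovered by method of moments), and Gaussian (ground
speed). The smooth is a tensor product of rank-4 cubic B-spline margins
(the "four knots" restriction) with second-order difference penalties per
margin and a single shared smoothing parameter; a tiny ridge fixes the
intercept/partition-of-unity confounding. Grouping (individual, trip
within individual) enters as ridge-penalized random intercepts; intervals
for effect summaries come from a cluster bootstrap resampling trips.

**Smoothing-parameter selection.** For ungrouped fits, GCV over a
log-spaced grid. For grouped fits the default is cluster cross-validation:
whole trips are held out and predicted with their random intercepts at
zero. The reason is pseudo-replication — fixes within a leg are nearly
identical in (ws, rwd), so row-wise GCV sees thousands of observations
where there are effectively a few hundred legs and under-penalizes;
cluster CV targets out-of-trip generalization directly. For the same
reason the reported AUC is that of the population-level surface (random
intercepts marginalized): it measures what the covariates alone can
discriminate. With no injected preference this AUC sits at 0.5 within
sampling error; with a strong injected tailwind preference it exceeds 0.65
and the surface peaks at low relative wind direction (both computed by the
suite). This penalized-ML route deliberately replaces a Bayesian MCMC fit:
the surface and the AUC, not posterior draws, are the outputs consumed
downstream, and the fit is deterministic at desk scale.

**Effect summaries.** The fitted surface is decomposed functionally over
the training covariate distribution into main effects and an interaction
(f = f0 + f1(x1) + f2(x2) + f12); a term's effect size is its mean
absolute contribution to the linear predictor, with percentile intervals
from the cluster bootstrap. The linear-predictor scale is stated
explicitly because a response-scale summary would depend on the intercept.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions the rest of the package
is tested under:

* **Movement**: `hmm.reference_params()` — feeding 0.7 ± 0.8 km steps,
  kappa 0.7; travelling 3.1 ± 0.6 km, kappa 19.2; resting 0.1 ± 0.04 km,
  kappa 25.2; self-transition probabilities 0.91/0.92/0.88 with
  off-diagonal mass split equally. These are field-scale estimates for a
  flap-gliding tropical booby population at 5-min resolution.
* **Wind**: hourly 0.25° fields with speeds spanning 0.5–11.8 m/s and
  directions concentrated around a configurable mean (default spread 15°),
  generated by Gaussian-smoothed noise mapped through the normal CDF onto
  the speed interval — smooth in space and time, bit-identical under a
  seed.
* **Trips** step exactly on the sphere (destination-point formula) from
  emitted step lengths; headings are steered along a random departure
  bearing outbound, free in the middle, and home-bound inbound, so the
  track geometry is a steered CRW rather than a pure one. Wind
  selectivity, when injected, replaces a commute step's heading with a von
  Mises draw centred downwind with probability `selectivity_strength` —
  the simplest mechanism a used-available model must detect, and one that
  vanishes exactly at strength 0.
* **Accelerometry**: parametric per-behaviour archetypes (sinusoidal
  flapping at a configurable wingbeat frequency, default 4 Hz — the
  wingbeat frequency of the study species is not pinned by the analysis,
  so it is a parameter, not a constant; near-static gliding; transient
  dive spikes; high-amplitude take-off bursts) with Gaussian sensor noise
  (0.03–0.15 g by behaviour) and a 1-Hz temperature channel that cools
  when the logger is wet (sit/dive).

One consequence of the out-and-back geometry is worth flagging: injecting
a wind preference on the outbound leg alone still produces structure on
the inbound leg, because a downwind-selected departure forces an upwind
return. The inbound selectivity surface then mirrors the outbound one
(peak at 180° instead of 0°) rather than sitting at chance — commute legs
of a central-place trip are never statistically independent in their wind
exposure, and the suite asserts exactly this mirrored pattern.

What the generator does **not** emulate: GPS position error, logger clock
drift, tidal and current drift, wind shear with altitude, prey-driven area
restricted search, or inter-individual heterogeneity in movement
parameters. Tests passing on this synthetic data therefore demonstrate
that the estimators recover what they claim from data satisfying the
models' assumptions — not that real deployments satisfy those assumptions.
Behaviour classes in the accelerometer archetypes are separable at the
default noise levels; recall on real streams will be lower and should be
validated against labelled data.

## Problem sizes and numerical choices

The parameter-recovery benchmark runs 50 trips × 500 steps (25 000 steps)
with 25 starts, a deliberate desk-scale design that finishes in a couple of
minutes on one CPU while leaving sampling error far inside the acceptance
tolerances. The selectivity calibration uses 200 trips of 80 steps with 20
rotations and ratio 10 (~10⁵ table rows). The classification benchmark
uses 500 labelled segments per class and 1 000 trees — out-of-bag recall
is stable well below the 10 000-tree default, which remains the API
default for fidelity to field practice. Optimizer bounds, the 1-m step
jitter, the logit clipping at ±35, and the Viterbi tie tolerance of 1e-10
are all stated in code; none is data-dependent.

## Known limitations

* The regularizer does not model location error; burst centroids are
  treated as exact.
* Random intercepts are ridge-penalized with a fixed prior precision
  rather than an estimated variance component; the cluster bootstrap, not
  the ridge, carries the inferential weight.
* The beta family is fitted by quasi-likelihood, so its "precision" is a
  moment estimate, not an MLE.
* The HMM assumes shared parameters across individuals (no random
  effects) and exactly three states.
* Stationary-curve confidence intervals condition on the emission
  parameters (only transition coefficients are bootstrapped).
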