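# Methods

This note documents the models implemented in `paleomolar`, the choices
made where the underlying protocols leave freedom, and what the synthetic
data used by the test suite does and does not establish.

## 230Th/U dating (`paleomolar.useries`)

A closed-system carbonate accumulates 230Th from the decay of dissolved
uranium.  With `a230` = (230Th/238U) and `a234` = (234U/238U) *measured*
activity ratios, the age `t` solves

    a230 = 1 - e^(-l0 t) + (a234 - 1) * l0/(l0 - l4) * (1 - e^(-(l0-l4) t))

with decay constants `l0 = ln2/75,690 yr` (230Th) and `l4 = ln2/245,250 yr`
(234U); both half-lives are configurable on `DecayConstants`.  The root is
found by bisection on (0, 10 Myr] to 1 yr; ratios at or beyond secular
equilibrium have no finite age and raise a dedicated error.  Uncertainties
are propagated by seeded Monte Carlo over the input ratios (default 10,000
draws; the reported sigma is the standard deviation of the successful
draws).

**Detrital thorium.**  Dirty carbonates carry non-radiogenic 230Th along
with 232Th.  Two conventions are implemented for how that component
evolves:

* `equilibrium` (default): the detritus carries uranium with its thorium
  daughters in secular equilibrium, so the detrital (230Th/232Th) ratio
  `r0` is constant in time and the correction subtracts `r0 * a232_238`
  once.  This is the convention under which the isochron intercept of the
  *measured* (230Th/232Th) vs (234U/232Th) ratios of coeval sub-samples
  estimates `r0` directly, which is how `r0` is estimated here
  (ordinary least squares; an error-weighted fit would require isochron
  error covariances that the measured-ratio table does not carry).
* `initial`: the detrital 230Th entered at formation and decays
  unsupported (`r0 * a232_238 * e^(-l0 t)`); age and correction are then
  mutually dependent and the implementation solves the self-consistent
  equation `a230 = ingrowth(t) + detrital(t)` by bracketed bisection,
  taking the largest root (the stable fixed point of iterating age and
  correction from the uncorrected age).  Under this convention the
  isochron intercept estimates the *present-day* detrital ratio
  `r0 * e^(-l0 t)`, not `r0`; the package keeps the two conventions
  strictly separate so generator, intercept fit and correction are always
  mutually consistent.

A correction that drives the corrected ratio negative at every age is
flagged `over_corrected` (the classic symptom of assuming too high a
detrital ratio) rather than reported as a negative age.

Weighted means are inverse-variance means; both the internal error
`1/sqrt(sum 1/s_i^2)` and the MSWD-inflated error (multiplied by
`sqrt(MSWD)` when MSWD > 1) are reported, since conventions differ on
which to quote.

## Coupled US-ESR dating of teeth (`paleomolar.esr`)

The ESR equivalent dose comes from fitting the single saturating
exponential `I(D) = I_max (1 - e^-((D+De)/D0))` through the additive-dose
intensities at doses up to the `d_max` cut-off, either by weighted least
squares with Monte-Carlo errors or by MCMC (flat positive priors,
posterior median and sd reported) for a full probability distribution on
De.

Uranium uptake into dental tissues is modelled by the one-parameter
family `U(t)/U_final = (t/T)^(p+1)` with `p >= -1`: `p = -1` is early
(closed-system) uptake, `p = 0` linear, larger `p` increasingly recent.
Two consequences are implemented:

* the fraction of the closed-system dose accrued is `1/(p+2)` (closed
  form of the time integral of the uptake law), applied to the internal
  component with the enamel exponent and to the dentine beta component
  with the dentine exponent; the sediment beta, external gamma and cosmic
  components are time-constant;
* the present-day U-series ratios of a tissue are quadratures over uptake
  increments: an increment entering at time `t` carries incoming uranium
  at a configured initial (234U/238U) and ingrows 230Th for `T - t`.  The
  integral uses the substitution `u = (t/T)^(p+1)` (uniform increment
  weight in `u`), 257-point trapezoid by default, with the `p -> -1`
  limit evaluated in closed form so the closed-system degeneracy is exact.

The coupled age solves, per Monte-Carlo draw of all inputs from their
Gaussians: at each trial age each tissue's `p` is found by bisection so
the model reproduces its measured (230Th/238U), with the incoming
(234U/238U) back-projected from the measured ratio; the age then solves
"accumulated dose = drawn De" by bisection on (0, 3 Myr].  `p` is clamped
to [-1, 10] when a drawn ratio is unreachable at the trial age; draws
with no age root are rejected and counted, and more than 20% rejections
is an error rather than a silent answer.  Everything is vectorised across
draws, so the default 1,000-draw inversion of one tooth takes seconds.

External gamma dose rates use full-chain-equilibrium conversion constants
(mGy/kyr per ppm U: 111.6, per ppm Th: 47.9, per %K: 249.1; a config
table) scaled by the solid-angle fraction of the burial geometry
(`full_sphere` = 1.0; `current_burial` default 0.5, configurable — the
partially eroded-surface scenario).  Beta attenuation by enamel thickness
and removed surface layers is a single configured factor per tissue;
computing attenuation from first principles is out of scope.

## Single-grain luminescence (`paleomolar.lum`)

The central age model (CAM) and the 3-parameter minimum age model (MAM-3,
with MAM-4 behind a flag) use the standard log-dose-space likelihoods:
CAM treats grains as sharing one log dose up to an overdispersion
`sigma_OD` (fixed-point maximum likelihood; errors from the numerical
observed information), MAM-3 mixes a fully bleached component at the
minimum log dose `gamma` with a normal component truncated below `gamma`,
after adding `sigma_b` (default 0.2) in quadrature to the grain errors.
The error on `gamma` is the half-width of the profile-likelihood interval
at 0.5 log-units.  Non-positive doses force a flagged unlogged CAM
variant; MAM requires positive doses.  Single-grain acceptance screening
is upstream of this module: De tables are taken as already screened.

Anomalous fading: the g-value is the (weighted) slope of the remnant
signal on log10(delay/tc), in percent per decade; the correction solves
`T_meas = T [1 - kappa (ln(T/tc) - 1)]`, `kappa = g/(100 ln 10)`, by
fixed-point iteration to 0.01 kyr (tc default 48 h), with Monte-Carlo
errors over (age, g).  The correction applies to the age in aggregate,
not per grain, and measured residual doses are *not* subtracted.

Dose rates: `total = beta_dry/(1 + 1.25 W) + gamma_dry/(1 + 1.14 W) +
internal + cosmic` with water mass fraction `W` (attenuation factors are
the conventional constants, configurable), internal default 0.84 Gy/kyr
for coarse K-feldspar.  The cosmic parameterisation is hard + soft
components with altitude/geomagnetic-latitude scaling; every constant
lives in a config dictionary (`COSMIC_CONSTANTS`), and the tests pin the
function to a hand evaluation of those same constants rather than to an
external table.

## Bayesian stratigraphic model (`paleomolar.chronomodel`)

Units are ordered oldest (0) upward with one boundary age between each
adjacent pair; on the kyr-before-present scale boundary ages strictly
decrease upward.  Each dated event has a latent true age with a Gaussian
likelihood; `minimum`/`maximum` roles introduce a Gaussian auxiliary
variable bounded by the latent age (the flowstone above a deposit dates
an event that must be younger than everything below it).  Within a unit,
latent ages are uniform between the unit's boundaries, contributing
`span^-n` for an interior unit with n events; outer units get improper
flat priors beyond their single bounding boundary.

**Boundary prior.**  Two options ship: `uniform_span` (flat prior on the
ordered boundaries; the marginal prior of the model span is then uniform)
and `one_over_span` (an extra 1/span factor).  `uniform_span` is the
default: the 1/span variant compounds the `span^-n` phase factor and
collapses multi-date phases visibly (on the bundled event table it pulls
the two boundaries ~13 kyr inside the positions the flat-prior model —
and the published model — put them).  The default reproduces the
published boundary estimates; the alternative remains one keyword away.

Sampling is Metropolis-within-Gibbs: each latent age, auxiliary and
boundary gets a Gaussian random-walk update per iteration, with proposal
scales adapted towards ~40% acceptance during burn-in and frozen
afterwards (preserving detailed balance for the retained draws); the
whole state is vectorised across chains, which also lets simulation
studies run one replicate per chain with per-chain data.  Defaults: 4
chains x 50,000 iterations, 20% burn-in, thinning 5; split-R^ above 1.05
flags non-convergence.  Events are put in a canonical order at model
build, so posteriors are invariant to input order at fixed seed.
Luminescence dates enter as Gaussians by default (`role=direct`), with
`role=maximum` available where a partially bleached sample should bound
the deposition age from above.  No outlier down-weighting is applied.

Calibration: the test suite checks that 68% central intervals cover true
boundaries at the nominal rate over 200 synthetic sequences.  Exact
self-consistency requires the generator to match the model priors, so the
calibration study draws boundaries uniformly (matching `uniform_span`)
and scatters outer-unit events over wide margins (±150 kyr) — outer
events confined to a narrow band above/below their boundary would encode
a constraint the model's unbounded outer priors do not know about and
bias the check itself.

## Crown metrics (`paleomolar.dental`)

The adjusted Z-score `[(x - m)/(s sqrt(1 + 1/n))] / t_crit(n-1)` uses the
two-tailed 5% Student-t critical value, so |score| > 1 places a fossil
outside the reference sample's 95% tolerance band even for small
reference n (a one-tailed variant sits behind a flag).  Tissue
proportions: `Vcdp/Vc` in percent, `3D AET = Ve/SEDJ` (mm) and
`3D RET = 100 AET / Vcdp^(1/3)` (dimensionless, scale-free).  Enamel
thickness maps are nearest point-to-triangle distances from outer-enamel
vertices to the enamel-dentine junction — a deliberate convention choice
(robust on wrinkled crowns) that differs from normal-ray casting used by
some commercial tools.  The point-triangle distance is computed exactly
in-package (Voronoi-region clamping with a KD-tree candidate prefilter).
The half-maximum-height rule places a segmentation threshold midway
between two material grey-value peaks, with a batch variant averaging
repeated estimates across slices.

## EDJ geometric morphometrics (`paleomolar.gm`)

The 94-point template is 4 dentine-horn landmarks + 60 marginal-ridge
semilandmarks (12/12/24/12 interior points per horn-to-horn segment, the
shared cusp points counted once, in the anatomical set) + 30 cervix
semilandmarks.  Curves are interpolated by cubic splines through the
digitised polylines and resampled at equal arc-length spacing; no
bending-energy sliding is applied (a convention, stated openly: the
upstream protocol does not specify sliding).  Generalised Procrustes
alignment removes translation, scale and rotation with an iterated mean
(tolerance 1e-8); shape statistics work in the tangent space at the mean
(orthogonal projection; Procrustes distance = Euclidean distance there).

Ordinations: tangent-space PCA; between-group PCA as a PCA of the equally
weighted group means with all individuals (and unknowns) projected a
posteriori; CVA on a reduced PC basis (smallest k reaching ~90%
explained) via the generalised symmetric eigenproblem, scaled so the
pooled within-group covariance is the identity in canonical space.
Classification is by smallest Mahalanobis distance to group means with
equal priors; unknowns never influence axis estimation.
Cross-validation is leave-one-out with the full pipeline (PC reduction
included) refitted per fold.  Allometry is per-axis regression of score
on centroid size with permutation p-values (10,000 permutations, seeded)
and the classical F-test alongside.  Missing-cervix imputation is left to
the caller: the template builder requires complete curves.

## Enamel-proteome screening (`paleomolar.proteo`)

PSM tables (TSV) are filtered by removing blank-run spectra, proteins on
a contaminant list and proteins supported by a single distinct peptide.
PTM rates are relative spectral counts: PSMs carrying the PTM on a
modifiable residue over PSMs containing at least one such residue.
Phospho-serine context is tallied per offset (-5..+5) and the S-x-E
fraction uses only sites whose +2 position lies inside the peptide.
Diagnostic-site calls use only fragmentation-supported, non-conflicting
observations (conflicting supported observations exclude the site), treat
isoleucine/leucine as equivalent everywhere, and intersect compatible
lineages across resolved sites — so removing sites can only widen, never
narrow, the call.  AMELY screening reports "male" on a specific-peptide
match and otherwise "female or degraded beyond detection", never a bare
"female".  The bundled protein sequences, site panel and AMELY reference
peptides are synthetic stand-ins written for the toy proteome (marked as
such in the source); real analyses supply their own panel as data.

## Synthetic data (`paleomolar.synth`)

Every generator is seeded (`numpy.random.default_rng`), returns its
ground truth alongside the data, and is bit-reproducible for a fixed
seed.  Defaults mirror the study conditions where those are stated:
coeval flowstone sub-samples share one age and one detrital ratio
(default `r0 = 0.5`) across varying detrital fractions with 2% relative
noise; ESR dose ladders follow exponentially increasing irradiation steps
into the kGy range with saturation doses of hundreds of Gy; single-grain
De sets mix a lognormal bleached population (default overdispersion 0.25,
matching the 23-38% observed range) with uniformly inflated unbleached
grains up to 1,500 Gy; the US-ESR tooth forward model uses a
dose-rate budget of order 1,200-1,500 mGy/kyr.  The synthetic crown is a
superellipsoidal basin with four Gaussian dentine horns, the outer enamel
surface offset along analytic normals by a smooth positive thickness
field and closed by a cervix skirt; ground-truth volumes/areas come from
the same construction at 5x the mesh resolution (dense surface
quadrature), and a curvature guard rejects thickness fields that would
self-intersect the offset.

What the generators do **not** emulate: real measurement-error
covariances between isotope ratios, detrital U contributions, spatially
resolved uptake within tissues, luminescence sensitivity change and
signal-level phenomena, taphonomic distortion of crown surfaces, and
realistic spectral evidence behind PSMs.  Passing recovery tests
therefore establish internal correctness of each estimator under its own
assumptions — not robustness to the failure modes of real material.

## Problem sizes and numerical defaults

The test suite runs everything at desk scale: MCMC checks use 4 chains x
50,000 iterations for the headline model and 12,000 iterations per
replicate for the 200-sequence calibration study (one replicate per
vectorised chain); US-ESR recovery uses 20 teeth at 250 Monte-Carlo draws
each; SSE bias uses 50 replicates; mesh tests use a 36 x 72 polar grid
with truth at 5x resolution.  These sizes were chosen so the statistical
assertions have comfortable margins while the whole suite stays quick to
run; all of them are parameters, not constants.
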