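# Methods

`stdelta` implements a spatio-temporal species distribution model for trawl-survey
catch data, together with the derived quantities a survey programme reports —
an annual abundance index, the centre of gravity of the population, the
effective area it occupies — and the surrounding analyses: covariate effects on
density, percent deviance explained, stomach-content diet summaries, and
polynomial trend regressions among annual series.

## Observation model

Catch at station *i* (year *t_i*, effort = area swept *a_i* in km²) follows a
two-part (delta) model in the Poisson-link parameterisation. Two linear
predictors,

    p1_i = α1_{t_i} + ω1(s_i) + ε1(s_i, t_i) + Σ_p γ1_p X_p(i)
    p2_i = α2_{t_i} + ω2(s_i) + ε2(s_i, t_i) + Σ_p γ2_p X_p(i)

are log number density and log biomass per group. The link maps them to an
encounter probability and a positive catch rate:

    r1 = 1 − exp(−a e^{p1}),     r2 = a e^{p1} / r1 · e^{p2}

so that E[catch] = r1·r2 = a·e^{p1+p2} identically. A zero catch contributes
log(1 − r1); a positive catch contributes log r1 plus a gamma density with mean
r2 and a single shared coefficient of variation (shape 1/cv², scale r2·cv²).
The paper-style "delta-gamma with Poisson link" is thus closed under the
expected-catch identity, which the test suite asserts to 1e−12 relative error.

The gamma dispersion is parameterised by (mean, CV) with one CV for all years —
the source analysis states only "a gamma distribution", and a shared dispersion
is the parsimonious default; per-year dispersion is out of scope.

## Spatial structure

Random fields live at *knots* placed by k-means (10 restarts, seeded) over the
pooled station locations; stations and extrapolation-grid cells inherit their
nearest knot's value (piecewise-constant projection — at 25–50 knots the
difference from barycentric mesh interpolation is far below the field SDs).
The correlation function is Matérn with smoothness ν = 1 (the 2-D SPDE
default), parameterised by the distance at which correlation falls to 0.1
("range"). ω fields are time-invariant; ε fields are drawn independently per
year. A dense reduced-rank GP at the knots replaces sparse SPDE precision
matrices: at desk scale (≤ a few hundred knots) dense Cholesky factorisations
are faster and simpler to verify.

The range is **shared across the four fields and fixed at a configured value
(default 150 km)**. Estimating a Matérn range from one realisation of a
single-factor field at 25 knots is notoriously weakly identified; fixing it
keeps the outer optimisation low-dimensional and reproducible.
`estimate_range=True` adds log-range to the outer parameter vector for users
who want it.

Coordinates are planar: northing = 111.195·lat (km from the Equator), easting
= 111.195·cos(lat)·(lon + 180) (km from 180°). This matches the reporting
convention for the study region and keeps COG output in interpretable km; true
geodesy is a non-goal.

## Estimation

Random effects u = (ω1, ω2, ε1, ε2) are integrated out by a Laplace
approximation. The inner problem — the joint negative log likelihood over u —
is solved by damped Newton iteration with analytic gradients and Hessians
(per-record 2×2 derivative blocks scattered into the knot-year layout; the
prior precision is block diagonal per field and year). The marginal log
likelihood is

    log L(θ) = −f(û) + (n_u/2)·log 2π − ½·log det H(û),

exact when no fields are active. Fixed effects (year intercepts, covariate
coefficients) and variance parameters (log field SDs, log CV) are maximised by
bounded quasi-Newton (L-BFGS-B) on the *per-record-scaled* objective with
central-difference gradients, warm-starting the inner mode between
evaluations. Two numerical choices matter and were chosen after observed
failures, not taste:

- **Scaling.** With |log L| ~ 2·10⁴ and astronomically bad values (~10²⁴) at
  the parameter-bound corners, the Fortran line search can collapse at the
  starting point (its unit initial Hessian scaling steps onto the corner and
  cubic interpolation returns a zero step). Dividing the objective and
  gradient by the record count keeps every quantity O(1).
- **Gradient quality.** One-sided internal differencing is too noisy once the
  objective spans orders of magnitude; explicit central differences (step
  1e−5·(1+|θ|)) with a warm-started inner solve per evaluation are accurate to
  ~1e−5.

Convergence is declared only when the central-difference gradient of the
unscaled marginal log likelihood has max absolute element below 1e−3
(configurable) *and* no parameter sits at a bound; anything else raises a
warning and sets `converged=False` on the fit — never silently accepted.
Standard errors come from a central-difference Hessian of the negative
marginal log likelihood (inverse = Wald covariance); a non-PD Hessian falls
back to a pseudo-inverse with a warning.

Starting values: year intercepts by inverting the link at the yearly encounter
rate and mean positive catch; γ at 0; field SDs at 0.5 and CV at 0.8 on the
log scale.

The Laplace approximation itself is validated against adaptive and tensor
Gauss–Hermite quadrature on 1- and 2-random-effect toys. Its error is O(1/n)
in the records per random effect (measured: ≈3e−3 at 30, ≈1e−4 at 1200), so
oracle tests use toys with ≥400 records per effect where the 1e−3 agreement
band is comfortably met.

## Covariates

One covariate per fitted model (mirroring the source analysis, which fitted
each covariate separately to dodge collinearity). Forms:

- `linear`: one column, z-scored after the transform; coefficients are
  reported on both the standardized and natural scales.
- `spline2df`: quadratic B-spline with *no* interior knot, boundary knots at
  the observed (transformed) range, intercept column dropped — exactly the two
  Bernstein functions 2u(1−u) and u², which together with the year intercepts
  span all quadratics. A dome-shaped thermal response is therefore correctly
  specified, and the effect curve's arg-max estimates the thermal optimum.

Skewed biological covariates (prey and competitor densities) use log(x+1).
Boundary knots are stored in the fit, so prediction on new data is
bit-identical; values outside the knots are clipped with a warning.

Percent deviance explained by a covariate is reported under **both**
conventions found in the source: the deviance ratio 1 − D_cov/D_base with
D = −2·log L (saturated constant cancels between nested fits), and the
epsilon-variance ratio 1 − (σ²_ε1 + σ²_ε2)_cov / (σ²_ε1 + σ²_ε2)_base. The
epsilon-based number is the headline, because the prose definition of the
reported quantity is the change in spatio-temporal variance.

## Derived quantities

Density on the extrapolation grid (regular lattice, default 10 km spacing,
clipped to 25 km around any knot, each cell assigned uniquely to its nearest
knot) is d(s,t) = r1·r2 at unit effort = e^{p1+p2}. Annual quantities:

- index I_t = Σ_s a_s·d(s,t)
- COG z_{t,m} = Σ_s z_{s,m}·a_s·d(s,t) / I_t for m ∈ {northing, easting}
- EAO A_t = I_t / D_t with D_t = Σ_s a_s·d² / I_t (biomass-weighted mean
  density), so uniform density occupies the whole modelled area and a point
  mass occupies one cell; an unweighted-mean variant is available by flag.

Because d is log-scale convex in the random effects, plug-in indices at the
mode are biased low. The correction draws u ~ N(û, H⁻¹) — the Gaussian the
Laplace approximation already commits to — recomputes I/COG/EAO per draw
(default 500; seed-controlled), and reports the draw mean as the corrected
value and the draw SD as its SE. All three quantities are corrected (the
source is explicit only about the index). The mechanism is verified against
the closed-form lognormal mean E[e^{μ+X}] = e^{μ+Var(X)/2} computed from the
same Gaussian.

## Diet and trends

The stomach-content index of a prey taxon at a station is 10,000 × pooled prey
weight / pooled predator weight. Annual category SCIs are unweighted means
over stations (a stomach-count-weighted option exists; the source does not
weight), and proportions divide by the sum of category means, so they sum to
one exactly. Plankton densities sampled volumetrically are integrated over the
water column as density × (depth − 10 m), the net's off-bottom offset.

Annual indices are related to annual covariates by OLS quadratics
y ~ 1 + x + x² with x centred, coefficients tested at α = 0.05; the vertex
−b1/(2b2) (back on the raw x scale) is reported only when the quadratic term
is significant, and a linear-only submodel is reported otherwise. No
multiplicity correction is applied (matching the source); batch output carries
the number of tests run.

## Synthetic data

`simulate_survey` draws a complete study from the forward model: a jittered
station lattice (default 55 km spacing — roughly the 30–60 nautical-mile
spacing of the emulated survey) with per-year random dropouts; a temperature
field = stanza-level year mean (warm ≈ 11.5 °C, cool ≈ 9 °C, echoing the
reported 8.0–12.6 °C range of annual means) + a smooth southeast-to-northwest
spatial gradient (2 °C across the domain) + station noise (SD 0.5 °C); fields
simulated from the Matérn model; optional truth covariate effects (a quadratic
temperature dome peaking at a configurable value, default 11 °C, or a linear
effect on a unit-variance prey covariate with knot-level spatio-temporal
structure); and catches from the delta-gamma observation model (CV 0.8,
encounter rates ~0.5–0.9). The default desk scenario is 8 years × 120
stations, 25 knots, range 150 km, sd_ω1 = 0.7, sd_ε1 = 0.5 — sized so a full
pipeline runs in well under a minute on one CPU.

Truth surfaces evaluate the *smooth* covariate components (stanza mean +
gradient; the knot-level prey process) without station-level noise: the noise
belongs to the sampling process, not the latent density field. Truth indices
are computed from the truth surface with the same index arithmetic the
estimator uses.

What the generator does **not** emulate: shoreline/bathymetry masking, ocean
currents and cold-pool geometry, vessel effects, species interactions, or
temporal autocorrelation in ε. A green recovery test therefore establishes
that the estimator inverts its own forward model at realistic sizes and noise
— not that the model is correct for any particular sea.

`simulate_diet` draws pooled stomach samples whose Dirichlet-distributed
composition tracks the year's stanza (age-0 pollock dominating warm years,
euphausiids/Calanus cool years), with a contrast parameter interpolating to
no-stanza-difference at 0.

## Degenerate inputs and edge handling

- A field with SD exactly 0 is excluded from the random-effect vector (the
  marginal likelihood is then exact in that margin).
- Years with zero encounters are flagged on the fit (weakly identified
  intercepts) and the fit proceeds.
- Encounter residuals where r1 ∈ {0,1} are emitted as NaN with a counted
  warning.
- λ = a·e^{p1} is capped at e^30 so extreme predictors saturate rather than
  overflow; r1 uses expm1/log1p throughout.
- Grid cells missing a covariate value are excluded from the indices with a
  logged count; an entirely missing covariate-year is an error naming the year.

## Known limitations

- Outer gradients are finite differences, not algorithmic differentiation; at
  a few hundred knots the FD Hessian for standard errors dominates fit time.
- Single-factor fields; no anisotropy; no temporal autocorrelation in ε.
- The Laplace approximation is not corrected beyond the Gaussian term; at very
  low per-knot sample sizes (≲30 records per random effect) its error reaches
  the 1e−3 scale measured above.
- Cross-validation refits share the full-data mesh, so fold predictions are
  not fully out-of-sample with respect to knot placement.
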