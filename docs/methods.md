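# Methods

This note documents the models, the numerical choices, and what the
synthetic world does and does not emulate.

## State-space regularization

Each animal's fixes are projected into a single local equirectangular
tangent plane at the fix centroid (km east/north). The movement model is
a 2-D Brownian motion with one free parameter, the process SD σ_p
(km·day⁻¹ᐟ²); the observation model is Gaussian with the per-fix ARGOS
error-ellipse covariance, built from the 1σ semi-axes and the
orientation (degrees clockwise from north). Fixes without ellipses fall
back to a per-quality-class SD table (0.25/0.5/1/2/3/5 km for classes
3/2/1/0/A/B, configurable).

σ_p is estimated per animal by maximizing the conditional likelihood
(first fix excluded) through the Kalman filter, with a deterministic
bounded 1-D search over log σ_p seeded from a 9-point grid (three local
restarts). With exact observations this likelihood reduces to the
product of increment densities, so the MLE equals the closed-form
variance-of-increments estimator — the unit tests verify this
reduction. Daily positions come from the RTS smoother evaluated on a
24-h grid anchored at the first retained fix; between two exact fixes
the smoothed mean is the Brownian-bridge (linear) interpolant. The grid
never extends more than 3 days past the last fix. The per-day SD is
√((P_xx + P_yy)/2) from the smoother covariance; it is smallest at
fix-dense days and peaks mid-gap.

The tangent-plane approximation distorts distances by < 0.5 % for track
extents up to ~1200 km, far below the ARGOS error scale; tracks
approaching a pole or spanning hemispheres are out of scope.

## Current correction

Ground velocity between consecutive daily positions is computed in the
local plane at the segment midpoint latitude; the ocean current is
bilinearly interpolated from the gridded product and converted with the
exact constant 86.4 (m/s → km/day); `swim = ground − current` holds to
machine precision by construction. Missing current samples propagate as
missing — a day without a current estimate has no swim vector and is
excluded downstream, never zero-filled.

The current for each daily segment is sampled at the **segment
midpoint** (the start date's slice). The midpoint is the one-point
quadrature of the along-path current: its error is second order in the
field gradient, whereas sampling at the segment start is first order.
With a realistic mesoscale vortex (0.45 m/s peak tangential speed,
150 km core) start-sampling misestimates daily swim vectors by a median
~16 % even from perfect positions, midpoint sampling by ~1 %; this is
why midpoint is the default. `decompose(..., sample_at="start")`
exposes the alternative for sensitivity analyses.

Swim-vs-current alignment uses the signed angle between the two vectors
wrapped to (−180°, 180°]; |angle| ≥ 90° is classified "opposing" (the
boundary counts as opposing).

## Persistence velocity

V_t = L_t · cos θ_t with L_t the displacement between consecutive
current-corrected daily positions and θ_t the signed angle between the
swimming-velocity vectors of adjacent days. The first day has no θ; a
zero-length or missing swim vector makes both adjacent θ (and V)
missing. The projection definition makes V direction-agnostic: its sign
says "kept going" vs "turned back" relative to the previous day's
swimming direction, not east vs west.

## Circular statistics

The two-sample Watson U² statistic is computed from the cumulative
rank differences of the combined sorted sample,
U² = nm/N²·[Σd_k² − (Σd_k)²/N]; ties are broken by a stable sort.
p-values use a label-permutation null (default B = 9999) with
p = (b+1)/(B+1), which is exactly verifiable by enumeration at tiny n —
the test suite checks agreement with a brute-force oracle over all
C(6,3) assignments — and calibrated by construction
(P(p ≤ α) ≤ α under exchangeability). Daily headings are pooled across
animals within a period; this pseudo-replicates individuals and is a
known caveat of the contrast battery, documented rather than corrected.

## Persistence mixed model

V_it = β₀ + x_it'β + f(lat_it, lon_it) + b_i + e_it, Gaussian with
identity link. f uses a low-rank thin-plate-style radial basis
(η(r) = r² log r) on k knots chosen by deterministic farthest-point
sampling of the observed locations (default k = 30; k = 20–25 in the
simulation studies to match their smaller spatial support). The
polynomial null space is removed from the radial block by the usual
side condition and re-expressed so the penalty is λ·I; the linear
lat/lon terms stay unpenalized, so any a + b·lat + c·lon surface is
reproduced exactly (verified to 1e−8). Reported smoother EDF is the
trace of the hat sub-matrix of the penalized block, in [0, k−3]; under
pure noise it collapses toward 0.

The random intercept and the ARMA process live in the marginal
covariance of each animal's residual series:
V_i = τ²J + Toeplitz(γ_ARMA), with γ from the MA(∞) psi-weight
expansion (cross-checked against an independent implementation).
Complete-case gaps split a series into contiguous runs that share the
random intercept but not the ARMA recursion. Fitting alternates
penalized GLS for the mean (λ by GCV with the usual 1.4 inflation
against undersmoothing) with Nelder-Mead ML for (τ, σ, φ, ϑ)
(stationarity/invertibility enforced by the standard PACF
re-parameterization), iterating until the marginal AIC changes by
< 1e−4, then one final mean update so coefficients and variance
parameters are mutually consistent. With τ = 0 and ARMA(0,0) the
procedure reduces exactly to penalized least squares (verified to
1e−6 against a direct solve). REML adds the 0.5·log|X'V⁻¹X + λP|
correction to the variance objective. Coefficient SEs come from the
posterior covariance (X'V⁻¹X + λP)⁻¹.

Backward elimination drops, under ML fits, the candidate whose removal
most lowers the marginal AIC, strictly, until no drop improves it;
the smoother and the random intercept are never dropped, ties within
1e−6 drop the covariate later in the declared candidate order
(current speed, SST, sargassum, weight, period), and the final model is
refit by REML. An `aic_tolerance` option enables the parsimony
convention (drop also when AIC rises by less than the tolerance);
strict descent is the default because it never discards a genuinely
supported effect and keeps AIC monotone along the path. Strict AIC
retains any single null covariate with probability ≈ P(χ²₁ > 2) ≈ 0.16
— with four null candidates, roughly half of all fits keep at least one
spurious term. That is a property of AIC itself, not of this
implementation; no single-threshold rule can simultaneously keep a
t ≈ 4 true effect ≥ 90 % of the time and drop four nulls jointly ≥ 90 %
of the time. ARMA orders are selected on residual series by a grid
seeded from the last pooled ACF/PACF exceedance of the ±1.96/√N band,
scored by pooled-likelihood AIC.

Whether elimination AIC is conditional or marginal w.r.t. the random
effects was an open choice; marginal ML AIC is implemented. Predictions
are population-level (random effect excluded); a grid evaluator exports
the fitted surface for contour plots.

## Synthetic world

The generator encodes the study conditions the analysis assumes. Ocean
fields: uniform background plus a Rankine-style vortex (solid-body core,
1/r decay) with an exponential outer taper (e-folding 2× the core
radius) — pure 1/r never decays, which both misrepresents compact
mesoscale eddies and would sweep nearshore loiterers off the island
buffer. SST is a smooth latitudinal gradient kept in [20, 33] °C;
sargassum is a sparse, patchy, non-negative weekly field on its own
0.01° grid (the algae product's resolution), while currents and SST use
1/12°.

Swimmers draw a heading each 0.05-day step from a von Mises law centred
on the bearing to a goal (κ ≈ 5–12) and a speed from a Gamma law
(mean 22–50 km/day, CV 0.3, matching the observed swim-speed scale for
juvenile green turtles); ground motion is swim + current exactly, which
is the gold standard the correction chain must recover. Drifters are
swimmers with zero swim speed at 10-minute steps. The fine step is
0.05 day, at which daily aggregates are insensitive to discretization.
ARGOS observation: negative-binomial fixes/day (dispersive mean 12.6,
residential 4.2 — over-dispersed to span the observed ~1–17 range),
uniform fix times within days, lognormal-spread ellipse axes by quality
class, bivariate-normal position noise from each fix's own ellipse.

Cohort scenarios: the January-like release has heterogeneous goal
bearings spanning the compass plus (by default) 16 of 30 animals as
tight loiterers anchored just off the coastline; the July-like release
sends all animals north into the vortex. Residential animals are given
the good-quality fix classes (3/2/1) so the 10-km rule applied to raw
fixes agrees with the construction; heavy-tailed class-B errors
(5 km 1σ) would otherwise throw single spurious fixes past any buffer.
The residential behavioural model (constant-speed anchor attraction) is
a minimal loiterer sufficient for classifier testing — it is not a
model of real nearshore behaviour. The persistence-data generator
(`make_persistence_dataset`) plants a known period effect (default
6.2 km/day) with AR(1) = 0.5 residuals (innovation SD 6), per-animal
intercepts (SD 1.5) and independent null covariates; locations are slow
per-animal random walks so the spatial smoother has support.

What passing tests show — and do not. The generator's turtles are
strongly goal-directed, so persistence velocities sit near the step
lengths; real juvenile tracks turn far more, and their persistence
distributions are broader with means near zero. Recovery results
therefore demonstrate correctness of the chain under its own
assumptions (known currents, Gaussian ellipse errors, daily-constant
behaviour), not field accuracy where currents are themselves estimates
and behaviour varies within a day.

## Numerical conventions and degenerate inputs

Earth is a sphere of radius 6371.0 km; angles at interfaces are degrees
(headings clockwise from north), radians internally; m/s → km/day is
exactly 86.4. Longitudes normalize to [−180, 180). Magnetic headings
are true − declination with a single configurable declination (default
0). Headings of coincident points are undefined and dropped, never
coerced. A single fix yields a one-row degenerate track; animals with
fewer than four retained fixes are flagged unusable. Velocity requires
strictly positive Δt; displacements crossing a pole raise. Watson U²
of two identical constant samples is 0 with p = 1. Problem sizes in the
simulation studies (20 animals × 15 days; 100–200 replicates; B = 199–999
permutations) were chosen to give stable Monte-Carlo rates at desk
scale.

## Known limitations

Ellipsoidal geodesy, pole-proximal tracks, behavioural-state switching,
Stokes drift/windage, non-Gaussian persistence responses, and random
slopes are out of scope. The Watson battery pools daily observations
(pseudo-replication). The ARMA structure is pooled across animals (one
shared (p, q) and coefficient set). The elimination discussion above
documents the irreducible false-retention rate of AIC with multiple
null candidates.
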