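# swimtrack

Trajectory analysis for satellite-tracked marine animals: track
regularization, ocean-current correction, swimming-persistence
statistics, circular comparisons of headings against currents, and a
spatially smoothed mixed model of daily swimming persistence — together
with a synthetic-world generator that makes every stage of the chain
verifiable against known ground truth.

The package is aimed at movement ecologists working with ARGOS-class
satellite telemetry of animals that both swim and drift — juvenile sea
turtles are the motivating case — who need to separate active swimming
from passive advection before asking behavioural questions.

## What it computes

**Track regularization.** Irregular, noisy fixes are modelled as
observations of a 2-D continuous-time random walk in a local tangent
plane: `x(t+dt) = x(t) + N(0, σ_p² dt I)`, observed through each fix's
ARGOS error ellipse. σ_p is estimated by maximum likelihood via the
Kalman filter; an RTS smoother predicts daily positions (24-h grid) with
uncertainties.

**Current correction.** For each day-pair, the ground velocity between
daily positions is decomposed as

```
swim = ground − current
```

with the ocean-surface current sampled from a gridded product (m/s,
converted by the exact factor 86.4 to km/day) at the segment midpoint.
Integrating the swim vectors from the release point rebuilds the
current-corrected trajectory.

**Persistence velocity.** The daily statistic

```
V_t = L_t · cos θ_t
```

where `L_t` is the step length (km/day) along the corrected trajectory
and `θ_t` the signed turning angle between successive swimming-velocity
vectors. `V = L` for straight-ahead motion, `−L` for a reversal, and
`|V| ≤ L` always.

**Circular statistics.** Circular means and SDs (`sd = √(−2 ln R̄)`) and
the two-sample Watson U² test with an exact label-permutation null
(`p = (b+1)/(B+1)`), used to contrast heading and current-direction
distributions between release periods.

**Persistence mixed model.** `V_it = β₀ + x_it'β + f(lat, lon) + b_i + e_it`
with a penalized thin-plate-style spatial smoother `f`, per-animal random
intercepts `b_i ~ N(0, τ²)`, and ARMA(p, q) residuals; smoothing by GCV,
variance parameters by (RE)ML, fixed effects selected by AIC backward
elimination, ARMA orders by an ACF/PACF-seeded grid.

**Synthetic world.** Rankine-style vortices plus uniform drift, goal-
directed von Mises/Gamma swimmers, passive drifters, negative-binomial
fix timing and elliptical ARGOS errors, and two cohort scenarios (a
winter release with radial dispersal and a residential fraction; a
summer release drifting north into a vortex).

## Worked example

```python
from swimtrack import gamm, synthetic

series, truth = synthetic.make_persistence_dataset(n_animals=20, n_days=15, seed=3)
fit = gamm.fit(series, gamm.GammSpec(fixed_effects=("period",), k=20, arma=(1, 0)))
print(fit.coef["period[jan]"], fit.se["period[jan]"], fit.ar[0])
```

prints (seed 3): period estimate `5.80 ± 1.21` (SE) with AR(1) `0.50` —
the ±2 SE interval covers the planted period effect of 6.2 km/day and
the residual autocorrelation (true value 0.5) is recovered. Running the
full elimination on the same data
(`gamm.backward_eliminate(series, ...)`) drops current speed, body
weight and sargassum and refits the final model by REML.

The `examples/` directory has one short script per capability
(simulation and observation, regularization, current correction,
circular tests, the persistence model, and the end-to-end pipeline);
each prints the numbers it computes and a line on what they mean. The
same chain is available from a shell:

```
swimtrack simulate --scenario jan --n-turtles 30 --seed 1 --out study/
swimtrack analyze --data study/
swimtrack report --out study/
```

## Data dictionary

Fix tables (CSV, UTF-8, ISO-8601 UTC timestamps), one row per fix:

| column | meaning |
|---|---|
| `animal_id` | tag/animal identifier (string) |
| `time` | fix time, UTC |
| `lon`, `lat` | degrees east / north |
| `smaj_km`, `smin_km` | error-ellipse 1σ semi-axes, km (an optional `unit` column value `m` marks metres, converted on read) |
| `eor_deg` | ellipse orientation, degrees clockwise from north |
| `qclass` | ARGOS location class (opaque token) |

Gridded fields are CF-style NetCDF with regular `lon`/`lat` axes, daily
`time` (u, v in m/s; sst in °C) and weekly `week` (sargassum in g/m²,
on its own finer `lon_hi`/`lat_hi` axes). Daily products are a tidy CSV
(animal, date, positions, ground/current/swim components, step, turn,
persistence, SST, sargassum) plus GeoJSON LineStrings per animal;
summary and coefficient tables are TSV.
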