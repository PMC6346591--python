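# Methods

## Model

A seagrass stand is a point (d, b) in bi-logarithmic biomass–density
space (d = log₁₀ shoot density, b = log₁₀ above-ground biomass). The
dynamics are a pair of coupled discrete logistic updates,

    Δb = Δt · r · b · (K_b − b)/K_b · sin θ
    Δd = Δt · r · d · (K_d − d)/K_d · cos θ,

with a single joint rate r (day⁻¹) split between the axes by the
allometry angle θ. Working on log coordinates makes multiplicative growth
linear and lets rates measured over heterogeneous monitoring intervals be
standardized per day.

The carrying capacities are state-dependent: (K_d, K_b) is the
intersection of the taxon's interspecific boundary line (IBL,
b = β₀ + β₁d) with the line of slope α₁ = tan θ through the current
state. They are recomputed from the current state at the **start of every
step**, before the logistic update — the simplest scheme consistent with
forward-difference (Euler) semantics; no sub-stepping or ODE integration
is performed, because the model itself is defined as a discrete
instantaneous-rate update.

Assumptions worth keeping in mind:

* the model is valid for established stands below the boundary line;
  colonization, patch, and rhizome dynamics are out of scope;
* the boundary coefficients (seagrass: β₀ = 4.569, β₁ = −0.438) are
  treated as universal constants, not calibrated parameters;
* θ is constant per species; seasonality enters only through a
  time-varying rate schedule r(t), for which no functional form is
  imposed (constant, two-block seasonal and sinusoid schedules are
  provided, and any callable is accepted).

A state with b ≤ 0 or d ≤ 0 (biomass below 1 g DW m⁻², density below
1 shoot m⁻²) is arithmetically allowed but triggers a warning: the
logistic term reverses sign at zero, so the model's behaviour there is a
genuine ambiguity that should be surfaced, not hidden.

### Trajectories are curved

The instantaneous direction of a trajectory is
Δb/Δd = α₁²·(b·K_d)/(d·K_b), which equals the central-tendency slope α₁
only on the boundary itself. Model trajectories therefore bow away from
the straight line through their starting point even though start and
asymptote both lie on it. Two practical consequences: (i) simulated
stands approach the boundary along a slightly curved path, and (ii) the
PCA angle of a *single simulated trajectory* is a biased estimate of θ
(biases up to ~0.2 rad were measured for a converging stand). θ is a
property of the between-stand scatter, not of one trajectory — which is
why the estimator is defined on pooled multi-study data and why the
synthetic generator provides a central-tendency scatter layout (below).

### Isometric null model

H₀ sets α₁ = 1 exactly (θ = arctan 1 = π/4 ≈ 0.785): biomass grows only
by adding shoots of fixed adult mass. It is used identically in
projection and stepping, and serves as the comparison baseline: from far
below the boundary, isometric runs reach it at higher density and lower
biomass than allometric runs.

## Calibration

**Angle.** θ = arctan(α₁), with α₁ the slope of the dominant eigenvector
of the 2×2 **covariance** matrix (not the correlation matrix) of the
pooled (d, b) observations, sign-normalized to a positive d-loading. The
intercept α₀ passes the line through the centroid. PCA is the appropriate
type-II choice because both coordinates carry comparable observation
error. Degenerate inputs fail loudly: fewer than 3 points, an isotropic
cloud (relative eigen-gap ≤ 1e−9), a vertical dominant direction, or a
non-positive slope (outside the joint-growth domain).

**Rate.** Each consecutive observation pair within a series yields two
calibration points — biomass-sourced (x = b/K_b,
y = (Δb/Δt)/(b sin θ)) and density-sourced (x = d/K_d,
y = (Δd/Δt)/(d cos θ)) — with capacities projected from the interval's
**start** state (mirroring the simulator's step convention) and Δt the
actual day gap. Pooling both sources gives the closed-form estimator
r̂ = Σy(1−x) / Σ(1−x)², the least-squares solution of y = r(1−x).
Denominators |b|, |d| or |1−x| below 1e−6 are dropped and counted.

**Envelopes.** The growth/decay bounds r_max/r_min are reported as
configurable quantiles (default 0.95/0.05) of the per-interval rates
rᵢ = yᵢ/(1−xᵢ). The published envelopes were drawn as lines bounding the
calibration scatter without a stated formula; quantiles are one
defensible, reproducible reading that is robust to episodic extreme decay
events, so exact numeric agreement with published envelope values is not
claimed. **Seasonality** is purely descriptive: per-interval rates binned
by the phase of the interval's start day within a 365-day period
(12 bins), summarized by median and interquartile range.

### Known biases

With ground truth iterated daily but observations 30+ days apart, the
start-anchored linearization underestimates r: the logistic factor
(1 − x) decays during the gap while the formula evaluates it at the start
only. Under the package's stochastic-recovery conditions (start 1.5
log-units below the boundary, monthly sampling, two years, r = 0.03 d⁻¹,
noise sd 0.05) the median bias measured ≈ −14%. This is inherent to
calibrating a daily-rate model from coarse monitoring data and is
reported, not corrected.

## Forecasting (operational mode)

One-step-ahead only. For each interval, the capacities are projected from
the **observed** current state and the increment uses the actual day gap;
the interval rate is the arithmetic mean of the biomass- and
density-derived linearized rates (the mean is the package's choice — the
two estimates jointly determine one r, and averaging is the symmetric
combination). Because predictions never feed back, errors cannot
propagate or amplify; the price is a one-interval horizon. Two rate
sources are provided: `previous_interval` (honest forecasting, default)
and `same_interval` (in-sample reconstruction); which of the two matches
the published validation figure is ambiguous, so both exist and the
choice is logged. Δt = 0 gaps are rejected; intervals with unusable
denominators yield flagged records with NaN predictions.

## Synthetic data

The generator emulates compiled multi-study monitoring data: irregular
sampling (default monthly, optional day jitter, 2-year series), seasonal
growth/decay alternation, and additive Gaussian noise in log₁₀ space
(equivalently multiplicative on raw scales — matching the log-space
analysis; no noise model is prescribed by the data themselves). Raw
values are exactly B = 10ᵇ, D = 10ᵈ. Initial states above the boundary
are rejected; noisy observations more than 3 sd above it trigger a
warning. Everything is driven by one integer seed.

Two ground-truth layouts:

* **daily trajectories** (default) — simulated at dt = 1 day and read off
  at the sampled dates; finite-difference rates over long gaps then
  deviate from the generating rate exactly as they do in real data;
* **model-exact mode** — one forward step per observation gap, so the
  linearized calibration inverts the generator algebraically; this is the
  layout for exact-recovery tests (recovery to ~1e−16 measured);
* additionally, `sample_central_states` draws stand states along a
  species' central-tendency line (collinear when noise-free), the layout
  on which the PCA angle estimator is exact and which mimics a compiled
  multi-species snapshot.

What passing tests on these data do **not** show: robustness to real
spatial autocorrelation, environmental covariates, non-Gaussian outliers,
or dormant-shoot undercounting of density.

## Numerical choices and defaults

| Quantity | Default | Why |
|---|---|---|
| Projection parallel tolerance | 1e−9 (slope units) | below this, α₁ ≈ β₁ and the intersection is numerically meaningless; an explicit error beats a huge silent K |
| Denominator drop tolerance | 1e−6 (log units) | states this close to zero make the linearization explode; dropped points are counted and reported |
| PCA eigen-gap tolerance | 1e−9 (relative) | separates "no dominant direction" from legitimate elongated clouds |
| Envelope quantiles | 0.95 / 0.05 | robust to single extreme intervals; configurable (1/0 recovers exact block rates on noise-free data) |
| Step size dt | 1 day | the rates are per-day; forward-Euler error is first-order and O(r·dt) per step, negligible at r ≤ 0.1 |
| Seasonal window | days 80–260 | a generic northern-hemisphere growth season for the two-block schedule |
| Sampling default | 30-day interval, 24 obs | the modal monitoring design in compiled series (monthly, two years) |

Problem sizes used by the acceptance script (chosen as the package's
standard verification workload): 1000 random states for the projection
oracle; 6 presets × 3 initial stands for exact recovery; 200 replicates
for the stochastic median and 60 per noise level for spread monotonicity;
10 replicate series pooled for forecast accuracy; 4000-point clouds for
angle reproduction.

## Limitations

* Sensitivity of trajectories to initial conditions is reproduced as-is;
  whether it reflects reality or a structural weakness of the model is an
  open question the package does not resolve.
* r_max/r_min envelopes depend on the quantile convention; comparisons
  across datasets should fix the quantiles first.
* The forward-Euler update can overshoot for |r|·Δt approaching 1; with
  the shipped rates (|r| ≤ 0.075 d⁻¹) and daily steps this is far from
  binding, but calibrating over very long gaps implicitly uses one big
  step in model-exact reasoning.
* No confidence intervals are attached to θ or r̂ (none are defined for
  the published estimates either); replicate-based spread from the
  synthetic generator is the supported uncertainty measure.
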