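# seagrassibl

Modelling the joint biomass–density dynamics of seagrass stands bounded by
the interspecific boundary line (IBL).

## The problem

A monospecific seagrass stand is described by two areal quantities: its
above-ground biomass *B* (g DW m⁻²) and its shoot density *D*
(shoots m⁻²). On bi-logarithmic axes, *d* = log₁₀*D* and *b* = log₁₀*B*,
stands of all seagrass species stay below a common upper boundary — the
seagrass IBL,

    b = β₀ + β₁·d,   with β₀ = 4.569 and β₁ = −0.438,

which represents the maximum possible efficiency of space occupation.
Each species approaches or departs that boundary along its own
central-tendency line of slope α₁ = tan θ; θ is the **allometry angle**:
θ > π/4 means old shoots keep gaining individual mass while new shoots
are added, θ = π/4 (the isometric null model, H₀) means biomass grows
only by iterating new shoots of fixed adult size.

## The model

Both coordinates follow a discrete logistic update with a single joint
growth rate *r* (day⁻¹) partitioned by θ:

    Δb/Δt = r · b · (K_b − b)/K_b · sin θ
    Δd/Δt = r · d · (K_d − d)/K_d · cos θ

The carrying capacities (K_d, K_b) are **not free parameters**: at every
step they are re-projected onto the IBL along the line of slope α₁ through
the stand's current position,

    K_d = (b − β₀ − α₁·d) / (β₁ − α₁),    K_b = β₀ + β₁·K_d.

Calibration linearizes the same equations: scaling states by their
capacities gives points (x, y) with x = b/K_b (or d/K_d) and
y = (Δb/Δt)/(b·sin θ) (or the density analogue), which all fall on the
line y = r·(1 − x) — *r* is simultaneously its slope and intercept, and
biomass- and density-derived points pool into a single fit with twice the
sample size. θ itself is estimated by PCA (a type-II regression) on the
(d, b) covariance matrix of the pooled scatter. Quantiles of the
per-interval rates rᵢ = yᵢ/(1 − xᵢ) give each species' growth/decay
envelopes and, binned by day-of-year, its seasonality.

The package ships the published parameter presets for six species
(*Cymodocea nodosa*, *Halodule wrightii*, *Thalassia testudinum*,
*Zostera japonica*, *Z. marina*, *Z. noltii*), simulation of allometric
and isometric trajectories, calibration from CSV monitoring series,
operational one-step-ahead forecasting (re-anchored on every observation,
so errors never propagate), and a seeded synthetic-data generator that
emulates multi-study monitoring datasets.

## Worked example

Generate two years of noisy monthly monitoring data for a *Z. noltii*-like
meadow with seasonal growth (+0.03 day⁻¹, days 80–260) and decay
(−0.03 day⁻¹), then calibrate the rate with the published angle
θ = 0.874:

```sh
seagrassibl synth --scenario scenario.yaml --output demo.csv
seagrassibl calibrate --input demo.csv --theta 0.874 --output params.json
```

with `scenario.yaml`:

```yaml
species: Z. noltii
r: {type: seasonal, growth: 0.03, decay: -0.03}
initial_states: [[3.2, 2.367]]      # [d, b] in log10 units
sampling: {interval_days: 30, n_obs: 24}
noise_sd: 0.05
seed: 7
study_id: demo
```

`params.json` then contains

```json
{
  "Z. noltii": {
    "theta": 0.874,
    "r_hat": 0.007546945163107272,
    "r_max": 0.03262482499312072,
    "r_min": -0.04838316114298212,
    "n_points": 46,
    ...
  }
}
```

`r_hat` ≈ 0.008 day⁻¹ is the pooled rate over the whole series — close to
zero because growth and decay seasons cancel — while the 5%/95% envelopes
`r_min`/`r_max` bracket the seasonal rates (±0.03 plus observation noise).
`n_points` = 46 because each of the 23 intervals contributes one
biomass-derived and one density-derived point.

Simulating *Z. marina* at its maximum rate from one log-unit below the
boundary,

```sh
seagrassibl simulate --species "Z. marina" --b0 1.5 --d0 2.5 --r 0.043 --days 365 --output traj.csv
```

ends after a year at (d, b) = (3.784, 2.911), which sits on the IBL
(4.569 − 0.438·3.784 = 2.912): the stand has attained its carrying
capacity. Other subcommands: `forecast` (one-step-ahead predictions +
error summary) and `presets` (the shipped registry); the isometric null
model is available everywhere via `--h0`.

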