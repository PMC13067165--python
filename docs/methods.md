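# Methods

## Model

Swelling is treated as the product of two processes: solvent
penetration into the free volume, and expansion of the polymer network
that makes new free volume accessible. Penetration follows a
first-order mass balance — the uptake rate is proportional to the
unrealized uptake — giving a saturating factor `1 − e^(−kt)`. Network
expansion follows from the random-walk growth of the mean separation of
cross-linking points (`⟨r⟩ ∝ √t`), giving an affine factor in `√t`.
Collapsing the non-identifiable proportionality constants into two
amplitudes yields

```
S(t) = (1 − e^(−k·t)) · (a*·√t + b*),    S(0) = 0.
```

* `k` (1/h, > 0): solvent-penetration rate constant. Sets *how fast*
  equilibrium is approached; provably irrelevant to the mechanism split.
* `a*` ((g/g)·h^(−1/2), any sign): diffusive amplitude. Negative values
  produce overshoot-shaped curves — a unique interior uptake maximum
  followed by gradual solvent expulsion as the network relaxes.
* `b*` (g/g, any sign): relaxational amplitude. For `a* = 0` the model
  is exactly first-order kinetics with `S∞ = b*`.

The same expansion machinery yields the mechanism decomposition: the
uptake series splits into a diffusive sum (terms `t^(n−1/2)`) and a
relaxational sum (terms `t^n`), whose ratio collapses to the closed
form `CF(t) = 1/(1 + (b*/a*)√t)`, `CR = 1 − CF`. Both the truncated
series (`component_series`, `cf_series_oracle`) and the exact Taylor
expansion of the full equation (`taylor_partial_sum`, with the
alternating-series remainder bound) are implemented as independent
oracle chains and never mixed: the first reproduces the printed
two-term superposition, the second converges to the full equation.

The related classical models are kept as first-class estimators:
power law `S = k_pl·tⁿ`, Peppas–Sahlin `S = k_d√t + k_r·t`, first-order
`S = S∞(1 − e^(−kt))`, the short-time fractional uptake
`S/S_eq = 4x^(1/2) − πx − (π/3)x^(3/2)` with `x = Dt/(πr²)` (flagged
valid for `x ≤ 0.15` by default; the literature states no cutoff, so it
is a configurable threshold chosen where the truncation is still
monotone with a few-percent error), and the network-density decay.

### Density-law convention

The density law is implemented as `ρ_net(t) = β·t^(−1/2) + ρ_eq`.
Density must *decrease* toward its equilibrium floor as the gel expands
and is conventionally plotted against `t^(−1/2)`; a `+β√t` term would
diverge. The regression is ordinary least squares of `ρ` on `t^(−1/2)`
(slope `β`, intercept `ρ_eq`), with adjusted R² counting both fitted
parameters — the package-wide convention
`R²_adj = 1 − (1 − R²)(N − 1)/(N − p − 1)` with `p` the number of
fitted parameters.

## Fitting protocol

* **Objective.** Unweighted least squares on `S`; replicates are fitted
  independently and summarized as mean ± sd, which is what the
  ANOVA/Tukey comparison consumes.
* **Swelling equation.** Full-curve fit (no windowing). Multi-start
  local optimization (default 5 starts): a relaxation-only start taken
  from a first-order fit (`a* = 0`), a diffusion-only start (`b* = 0`),
  deterministic seeded jitters of their combination, and — when the data
  themselves overshoot — a negative-`a*` start. Bounds
  `k ∈ (10⁻⁶, 10³)` 1/h, amplitudes free (negative `a*` is needed for
  overshoot). Best residual sum of squares wins; near-ties go to the
  smallest `k`. Tolerances 10⁻¹⁰ on parameters and cost, ≤ 10⁴
  evaluations. Standard errors come from the linearized covariance
  `(JᵀJ)⁻¹·RSS/(n − p)` at the optimum. Failure of every start yields a
  flagged (`converged=False`) result, never a silent success; a flat
  curve is rejected.
* **Power law.** Restricted to the early-uptake window
  `S ≤ 0.6·S_eq` (`S_eq` = trailing-20% mean; on overshooting curves the
  window is computed against the plateau, not the peak). The default
  objective is ordinary least squares on `log S` vs `log t` — the
  classical protocol for the diffusional exponent, and what spreadsheet
  power-law trendlines compute. An original-scale refinement
  (`objective="nls"`) is available but not the default: because
  unweighted original-scale residuals overweight the top of the window,
  it biases the exponent of pure-relaxation data below the classical
  0.85–1.0 band (≈ 0.81–0.88 across realistic grids), whereas the
  log–log fit lands at ≈ 0.93–0.96. Goodness of fit is always reported
  on the original scale.
* **Windowed two-term fit.** Linear least squares in the `(√t, t)`
  basis on the same window.
* **Equilibrium estimate.** Plateau = trailing-20% mean. Overshoot is
  flagged when the pre-tail maximum exceeds the plateau by > 5%
  (configurable); requiring the peak to precede the tail window keeps
  monotone-but-still-rising curves (e.g. `√t`-dominated uptake on
  log-spaced grids) from being misflagged.
* **Mechanism call.** Hard label from `a*/b*`: Fickian for ratio ≥ 100,
  relaxation for 0 ≤ ratio ≤ 0.1, anomalous otherwise. The thresholds
  are configuration anchored to the 10×/100× contribution statements
  (`CR(1h) > 0.9` first at `b* = 10·a*`; `CF(1h) > 0.99` first at
  `a* = 100·b*`), not constants. A separate dominance label reports
  which mechanism contributes > 50% at a reference time (default: the
  fitted-window midpoint). Mixed-sign parameters push `CF` outside
  [0, 1]; those points are flagged invalid rather than re-normalized,
  and an overshoot regime (`a* < 0`) forces relaxation dominance, since
  transient over-swelling is a relaxation phenomenon.
* **Replicate statistics.** One-way ANOVA, then all-pairs Tukey HSD
  (studentized-range based, via `scipy.stats.tukey_hsd`). The compact
  letter display is built from the maximal cliques of the
  non-significance graph, which guarantees that two samples share a
  letter exactly when their difference is not significant; cliques are
  lettered by their largest-mean member, so the display is invariant
  under group relabeling.

## Synthetic data

The generator emulates the statistical structure of triplicate
gravimetric swelling experiments: a noise-free forward model plus
additive homoscedastic Gaussian noise on `S` (default sd = 2% of the
plateau), independent across points and replicates, with no
non-negativity clipping (keeping the error model exactly Gaussian for
estimator-property tests). Mass series are derived as
`w = w₀(1 + S_obs)`, so mass noise scales with the dry mass and the
pair round-trips exactly. Time grids are log-spaced by default — dense
early sampling is the standard kinetics design and is what makes the
early-uptake window informative.

Two presets freeze realistic study conditions:

* `pectin_like` — 3 samples × 3 replicates, 30 points over 0.25–150 h;
  `k ∈ {0.0211, 0.0239, 0.0148}` 1/h, ratios `a*/b* ∈ {20.79, 5.84,
  7.13}`, plateaus 12.2–12.8 g/g (amplitudes solved so the noise-free
  tail mean hits the plateau target).
* `alginate_like` — 3 samples × 3 replicates, 40 points over 0.1–50 h;
  `k ∈ {0.2802, 0.5080, 0.5200}` 1/h, ratios ≈ 0.27–0.35, plateaus
  ≈ 24/25/30 g/g, with A2 an overshoot variant
  (`a* = −0.8, b* = 30`; peak ≈ 27 g/g near 9 h, ~12% above plateau).

What the generator does **not** emulate: heteroscedastic or correlated
measurement error, evaporation/handling drift, inter-batch variability
beyond the seeded noise, or any pH/temperature/ionic-strength
covariates. Passing recovery tests therefore demonstrate estimator
correctness under the assumed error model, not robustness to real-world
systematics.

## Validation studies and known limitations

`swellkit.validation` runs the simulate-and-refit studies the test
suite and `scripts/acceptance.py` report: 100 Monte-Carlo replications
per preset sample (30 points, 2% plateau noise), plus a 1000-run null
study of the Tukey letter display.

* On `alginate_like` conditions all three parameters recover with mean
  relative bias well under 1%, and every fit reaches R² ≥ 0.99.
* On `pectin_like` conditions `k` and `a*` recover to ≈ 1–2% bias, but
  `b*` does **not**: at ratios of 5–21 with a ~12.5 g/g plateau, the
  true `b*` (≈ 0.05–0.25 g/g) lies at or below the noise sd
  (≈ 0.25 g/g), so the relaxational amplitude is weakly identified and
  its relative bias is tens of percent. This is an identifiability
  property of the model in the diffusion-leaning regime, not an
  optimizer artifact — the ratio's sampling scatter is comparable to
  its value there — and is the reason diffusion-leaning studies should
  interpret `a*/b*` (or `CF` profiles) rather than `b*` itself.
* The Tukey null study controls the familywise error as designed
  (shared letter in ≈ 95–96% of null draws at the 95% level), and the
  any-difference decision agrees with a label-permutation oracle on
  decisive small instances.

Numerical notes: `1 − e^(−kt)` is computed with `expm1` and the
exponent clamped at 700 to avoid overflow noise at extreme arguments;
`S(0) = 0` holds exactly. The component series is evaluated termwise
and restricted to `t > 0` (its leading diffusive term carries
`t^(−1/2)`). The overshoot peak is located by bracketed root-finding on
`dS/dt` (sign change guaranteed for `a* < 0 < b*`); series oracles
default to order 40. Degenerate inputs (flat curves, constant density
series, empty windows) are rejected or flagged, never silently fitted.
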