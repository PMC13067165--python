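# swellkit

Swelling kinetics of hydrogels, unified. `swellkit` models the water
uptake of a polymer network as the product of a solvent-penetration
kinetics term and a network-expansion term,

```
S(t) = (1 − e^(−k·t)) · (a*·t^(1/2) + b*)
```

where `S` is the swelling degree `(w(t) − w₀)/w₀` in grams of water per
gram of dry gel, `k` (1/h) is the solvent-penetration rate constant,
`a*` ((g/g)·h^(−1/2)) is the diffusive amplitude and `b*` (g/g) the
relaxational amplitude. The classical kinetic models are limiting cases
of this equation — the power law `S = k_pl·tⁿ` (order-1 expansion), the
Peppas–Sahlin two-term form `S = k_d·√t + k_r·t`, first-order kinetics
`S = S∞(1 − e^(−kt))` (pure relaxation, `a* = 0`), and the short-time
Higuchi-type fractional uptake — so one fit describes the *entire*
uptake profile, including the transient overshoot (`a* < 0`) that the
windowed classical models cannot represent.

Because the two amplitudes superpose a diffusive (`√t`) and a
relaxational (`t`) series, the Fickian contribution to uptake has the
closed form `CF(t) = 1/(1 + (b*/a*)·√t)` with `CR = 1 − CF`: the
mechanism is decided by the amplitude ratio `a*/b*` alone,
independently of `k`. Relaxation dominates (>90%) once `b*` exceeds
roughly ten times `a*`; uptake is essentially Fickian (>99%) once `a*`
exceeds roughly a hundred times `b*`.

The package is written for experimentalists characterizing hydrogels
(superabsorbents, drug-delivery matrices, tissue scaffolds): it takes
gravimetric time series per sample and replicate, fits all models with
uncertainties, classifies the transport mechanism, regresses the
network-density decay `ρ_net = β·t^(−1/2) + ρ_eq`, and compares samples
by ANOVA + Tukey letters. A seeded synthetic-data generator makes every
stage testable without experimental data.

## Worked example

Fit a synthetic three-sample alginate-like study (triplicates, 2%
plateau noise, one overshoot-shaped sample):

```python
import numpy as np
from swellkit import make_study_fixture, analyze_study, overshoot_peak

fixture = make_study_fixture("alginate_like", seed=7)
fits, calls, comparisons = analyze_study(fixture.curves)

for sample in sorted(calls):
    se = [f for f in fits if f.model_id == "swelling_eq" and f.sample_id == sample]
    pl = [f for f in fits if f.model_id == "power_law" and f.sample_id == sample]
    k = [f.params.k for f in se]; ratio = [f.params.ratio for f in se]
    n = [f.params.n for f in pl]
    call = calls[sample]
    print(f"{sample}:  n = {np.mean(n):.2f} +/- {np.std(n, ddof=1):.2f}   "
          f"k = {np.mean(k):.3f} +/- {np.std(k, ddof=1):.3f} 1/h   "
          f"a*/b* = {np.mean(ratio):.2f}   R2 = {np.mean([f.r2 for f in se]):.4f}   "
          f"{call.hard_label} / dominance {call.dominance_label}"
          + ("   [overshoot]" if call.overshoot_regime else ""))
```

prints

```
A1:  n = 1.00 +/- 0.07   k = 0.255 +/- 0.008 1/h   a*/b* = 0.29   R2 = 0.9974   anomalous / dominance macromolecular_relaxation
A2:  n = 0.88 +/- 0.05   k = 0.504 +/- 0.008 1/h   a*/b* = -0.03   R2 = 0.9974   anomalous / dominance macromolecular_relaxation   [overshoot]
A3:  n = 0.93 +/- 0.11   k = 0.529 +/- 0.074 1/h   a*/b* = 0.28   R2 = 0.9974   anomalous / dominance macromolecular_relaxation
```

Each row is a results-table line: the windowed power-law exponent `n`
(mean ± sd over replicates), the swelling-equation rate constant `k`,
the mechanism index `a*/b*`, the full-curve R², and the categorical
mechanism call. Small positive ratios mean strongly
relaxation-influenced anomalous transport; the negative ratio of A2
encodes its uptake overshoot, whose peak the fitted curve locates:

```python
a2 = next(f for f in fits if f.model_id == "swelling_eq" and f.sample_id == "A2")
print(overshoot_peak(a2.params))
# S = 27.1 g/g at t = 9.1 h, above the ~25 g/g plateau
```

Replicate comparison (`comparisons[0].letters`) assigns Tukey letters
`{'A1': 'b', 'A2': 'a', 'A3': 'a'}` on `k` (ANOVA p = 4.3e−4): the
slow-uptake sample separates from the two fast ones; samples sharing a
letter are statistically indistinguishable at the 95% level.

The same analysis runs from the shell:

```
swellkit simulate --preset alginate_like --seed 7 --out study
swellkit fit study/study.csv --out report
swellkit mechanism --a-star 1 --b-star 10 --t-max 50 --out profile.csv
```

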