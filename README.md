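# fertkin

Kinetics of mouse fertilization and the blocks to polyspermy, estimated
from interval-censored penetration/fusion chronograms.

## The problem

In mouse IVF, each oocyte is visited in discrete observation rounds, so the
time at which a spermatozoon crosses the zona pellucida (ZP) into the
perivitelline space (PVS), or fuses with the oolemma, is usually known only
to within a window — the gap between two rounds, possibly narrowed by the
stereotyped morphological landmarks that follow fusion (sperm head
internalization, second-polar-body extrusion stages). `fertkin` is for
reproductive biologists and biostatisticians who want to turn such
interval-censored *chronograms* into kinetic quantities:

* λ₀ — the baseline ZP permeability (sperm/oocyte/h entering the PVS),
* τ_PB — the time constant of the post-fertilization **penetration block**,
  via the saturating fit f(t) = A·(1 − e^(−t/τ_PB)) to the mean number of
  sperm entering the PVS after the first fusion (the implied initial rate
  is the derivative at t = 0, A/τ_PB),
* τ_FB — the time constant of the much faster **fusion block**, via a
  fixed-amplitude fit to the mean number of extra (polyspermic) fusions,
* the penetration→fusion delay distribution of the fertilizing sperm.

Event times inside their windows are imputed uniformly (there is no reason
to prefer one instant over another), curves are averaged over many such
realizations with the alignment event itself realized per draw, and 95%
bands come from a bootstrap over oocytes. A mechanistic Monte Carlo
simulator (Poisson entries, delayed fusion attempts, exponential
penetration/fusion blocks) closes the loop: it reproduces the fitted
kinetics, powers what-if scenarios (no fusion block, no penetration block,
3× permeability, halved fusion time), and — together with the
round/gap observation censoring model — generates fully synthetic
chronograms for end-to-end parameter-recovery tests.

## Worked example

```python
import numpy as np
from fertkin import (
    KineticParams, generate_truth, censor, count_curve,
    fit_penetration_block, implied_initial_rate, fusion_delay_curve,
)

params = KineticParams(n_oocytes=57)          # fitted defaults, 4 h horizon
truth = generate_truth(params, seed=1)
chronogram, obs_log = censor(truth, seed=2)

fert = chronogram.fertilized()
curve = count_curve(fert, "first_fusion", "penetration",
                    n_realizations=1000, seed=3, n_bootstrap=1000)
fit = fit_penetration_block(curve)
delay = fusion_delay_curve(fert, n_realizations=1000, seed=4)

print(f"fertilized oocytes: {fert.n_oocytes}/{chronogram.n_oocytes}")
print(f"tau_PB = {fit.tau_pb:.1f} min (95% CI {fit.tau_ci[0]:.1f}-{fit.tau_ci[1]:.1f})")
print(f"plateau A = {fit.A:.2f} sperm/oocyte")
print(f"implied initial rate = {implied_initial_rate(fit):.2f} sperm/oocyte/h")
print(f"fusion delay = {delay.mean_delay:.1f} min (95% CI {delay.ci_low:.1f}-{delay.ci_high:.1f})")
```

prints

```
fertilized oocytes: 56/57
tau_PB = 50.5 min (95% CI 40.1-64.4)
plateau A = 0.97 sperm/oocyte
implied initial rate = 1.16 sperm/oocyte/h
fusion delay = 18.6 min (95% CI 16.3-21.5)
```

One synthetic 57-oocyte cohort was generated at the default kinetics
(λ₀ = 1.21 sperm/oocyte/h, τ_PB = 48.3 min, τ_FB = 6.2 min, delay
15.8 ± 5.7 min), censored by the round/gap observation process, and
re-analysed: the penetration-block fit recovers the generating time
constant within its bootstrap CI, the plateau says ~1 sperm enters the PVS
after fertilization before the ZP closes, and the implied initial rate
recovers the baseline permeability. The delay estimate is biased a few
minutes high — the price of interval censoring at this cohort size (see
`docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
fertkin pipeline --config config.yaml --seed 1 --out run1/
```

which writes the chronogram/observation/truth tables, count-curve tables,
fit records, the five scenario simulations and a reproducibility manifest
(config hash, seed, output checksums); `fertkin synth`, `refine`,
`curves`, `fit`, `simulate` and `summarize` expose the individual stages.

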