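# heatccx

Tools for asking whether heat–health associations estimated from a
commercially insured sub-population generalize to the broader
population it is drawn from, when the two encounter datasets overlap in
space and time but cannot be linked at the person level.

`heatccx` implements the full analysis chain for this comparison:

1. **Exposure** — county-specific heatwaves defined as runs of ≥ 2
   consecutive days with daily maximum temperature above the county's
   year-round 97.5th percentile over a multi-year baseline, with a
   simple single-day exceedance indicator as a sensitivity variant.
2. **Encounters** — grouping of claim lines into ED / inpatient
   encounters (claims within 1 day of the previous claim chain into one
   encounter keyed by first claim date; any inpatient claim makes the
   encounter inpatient) and aggregation to daily counts per
   (county, age band, sex, cause, encounter type).
3. **Population** — person-time at risk from annual census counts
   (reference) or monthly enrollment (insured), direct standardization
   of insured counts to the reference population's age–sex–county–year
   composition, incidence rates per million person-days, and a
   demographic comparison table with between-dataset share ratios.
4. **Model** — a space-time-stratified case-crossover design fit by
   conditional quasi-Poisson regression, written from first principles:
   strata are (county, year, month, day-of-week) cells, stratum
   intercepts are eliminated by conditioning on stratum totals, and a
   Pearson dispersion factor scales the covariance,

   E(N<sub>t,s</sub>) = exp{β₁ hw<sub>t,s</sub> + β₂ RH<sub>t,s</sub> + β₃ h<sub>t</sub>}

   with hw the heatwave-day indicator, RH daily mean relative humidity
   (percent), and h a holiday indicator; IRR = exp(β₁).
5. **Comparison** — the two datasets are pooled with dataset-labelled
   strata and a fully interacted design

   E(N<sub>t,s</sub>) = exp{β₁ hw + β₂ RH + β₃ h + β₄ (d<sub>t</sub>·hw) + β₅ (d<sub>t</sub>·RH) + β₆ (d<sub>t</sub>·h)}

   where d<sub>t</sub> = 0 for the reference dataset and 1 for the
   insured one. exp(β₄) is the **ratio of incidence rate ratios
   (rIRR)**: > 1 means a stronger heat association among the insured.
   Naive comparators (difference of coefficients with independent SEs,
   and the non-overlapping-CI rule) are included as foils, and a Monte
   Carlo harness measures their type-I error, power and CI coverage.
6. **Synthetic data** — because datasets of this kind are restricted, a
   first-class generator produces county climates with multi-day heat
   spells, a census-like reference population plus a partially covering
   insured sub-population with a younger age skew, and overdispersed
   daily encounter counts with *known* effect sizes, so every stage is
   testable end to end.

## Worked example

```python
import numpy as np
from heatccx import ExperimentConfig, fit_rirr
from heatccx.comparison import _simulate_once

cfg = ExperimentConfig(true_irr_reference=1.1, true_irr_insured=1.2)
strata_ref, strata_ins = _simulate_once(cfg, seed=42)
res = fit_rirr(strata_ref, strata_ins)
print(f"IRR reference = {res.irr_reference['irr']:.3f}")
print(f"IRR insured   = {res.irr_insured['irr']:.3f}")
print(f"rIRR = {res.rirr:.3f}  (95% CI {res.ci[0]:.3f}, {res.ci[1]:.3f})")
print(f"dispersion = {res.fit_combined.dispersion:.3f}")
```

prints

```
IRR reference = 1.098
IRR insured   = 1.223
rIRR = 1.114  (95% CI 1.044, 1.188)
dispersion = 1.274
```

One simulated study of 20 counties over two warm seasons (May–
September): the reference heatwave IRR is estimated at 1.098 (truth
1.1), the insured IRR at 1.223 (truth 1.2), and the rIRR at 1.114
against a true ratio of 1.2/1.1 ≈ 1.091. The dispersion estimate 1.274
recovers the generator's variance/mean ratio of 1.3.

The same analysis is available from the shell via a YAML config:

```bash
heatccx validate --config config.yaml
heatccx run-all --config config.yaml --out results/ --seed 7
```

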