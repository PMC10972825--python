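# craburden

Comparative risk assessment (CRA) of cancer burden attributable to
modifiable risk factors: population attributable fractions, attributable
DALYs, age-standardised rates, 1990→2019-style trends, and
sociodemographic-index (SDI) gradients — with a synthetic-data generator
carrying known ground truth so the whole chain is testable without any
external download.

It is aimed at epidemiologists and biostatisticians who work with
results-tool-style extracts (stratified exposure moments, relative risks,
DALYs) and want the counterfactual arithmetic — not the upstream exposure
or dose–response modelling — as a tested, reusable library.

## The model

For a risk–outcome pair in one stratum, with current exposure distribution
P(x) on [l, m], dose–response RR(x), and theoretical minimum-risk exposure
level TMREL:

```
PAF = ( ∫_l^m RR(x) P(x) dx − RR(TMREL) ) / ∫_l^m RR(x) P(x) dx
```

(discrete exposures sum over categories).  Attributable DALYs are
PAF × total DALYs; independent risks combine as `1 − ∏(1 − PAFᵢ)`; all
arithmetic is propagated per uncertainty draw, with the draw mean as point
estimate and the 2.5th/97.5th percentiles as the 95% UI.  TMREL rules:
0 for harmful monotone risks, the curve nadir for V-shaped risks, the 85th
exposure percentile for protective risks.  See `docs/methods.md` for
numerics and conventions.

## Worked example

```python
import numpy as np
from craburden import fit_mom, RelativeRiskCurve, paf_continuous, combine_pafs

# BMI-like exposure in one stratum, reported as mean 26, SD 4 kg/m²
dist = fit_mom(26.0, 4.0, "lognormal")

# RR rising 10% per 5 kg/m² above a TMREL of 21
curve = RelativeRiskCurve(risk="high_bmi", cause="colorectal_cancer",
                          form="log_linear", shape="monotone_increasing",
                          beta=np.log(1.10) / 5.0, reference=21.0)

paf = paf_continuous(dist, curve, tmrel=21.0)
print(round(paf, 4))                      # 0.0936
print(round(combine_pafs([paf, 0.2324]), 4))  # 0.3042
```

The first number says ~9.4% of this stratum's colorectal-cancer burden is
attributable to body-mass index above 21 under the fitted exposure
distribution; combined with a second independent risk carrying a PAF of
23.24%, the joint preventable share is ~30.4% (less than the 32.6% sum,
because the formula never double-counts burden).

The numbered drivers under `analysis/` run the same machinery end to end
on the default synthetic world (10 locations × 2 years × 8 age bands ×
2 sexes, 3 risks, 1000 draws, seed 17):

```
python analysis/01_simulate_world.py    # generate the world + ground truth
python analysis/02_compute_pafs.py      # full pipeline, recovery report
python analysis/03_attributable_trends.py
python analysis/04_sdi_gradient.py
```

`02_compute_pafs.py` prints, among other things:

```
PAF cells computed: 1600
max |PAF - truth|: 0.00108  (mean 0.00015)
95% UI coverage of truth: 100.0%
```

i.e. the pipeline's quadrature recovers the generator's independently
computed ground-truth PAFs to ~1e-3 in every stratum, and the draw-based
uncertainty intervals cover the truth.  There is also a thin CLI
(`craburden simulate|paf|burden|trends|sdi|report --seed 17 --out DIR`)
over the same pipeline.

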