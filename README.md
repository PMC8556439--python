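# comxdyn

Quantitative analysis of ComX quorum-sensing pheromone dynamics during
*Bacillus subtilis* surfactin batch fermentations.

ComX is a secreted, farnesylated decapeptide pheromone (backbone
ADPITRQWGD) of the ComQXPA quorum-sensing system.  Its extracellular level,
measured in Miller units (MU) through a P*srfA*-*lacZ* reporter bioassay,
gates expression of the surfactin synthetase genes.  `comxdyn` is a toolkit
for people who run and model such fermentations: it bundles the kinetic
model of the pheromone time course, its parameter estimation from
cultivation data, the bioassay and batch-process arithmetic around it, and
a seeded synthetic-data generator for testing the whole chain.

## The model

ComX activity $a(t)$ is produced in proportion to the standing biomass and
to its growth rate, and degraded by a putative ComX-specific protease (CSP)
whose activity $EA(t)$ is itself induced by ComX:

$$\frac{da}{dt} = b\,c_\mathrm{CDW}(t) + d\,\frac{dc_\mathrm{CDW}}{dt} - e\,EA(t)$$

$$\frac{dEA}{dt} = f\,a(t) - g\,EA(t)$$

with $c_\mathrm{CDW}(t)$ the cell dry weight (g/L) supplied as a smooth
fitted curve.  Given the biomass forcing the system is linear; for constant
biomass $X$ it relaxes to the closed form
$a_{ss} = bXg/(ef)$, $EA_{ss} = bX/e$.  Default parameter values sit at the
midpoints of the admissible ranges (a0 21–32 MU, b 17.72–19.95 MU·L/(g·h),
d 436–516 MU·L/g, e 1.36–1.58 MU/(EA·h)); f = 0.115 EA/(MU·h) and
g = 0.328 1/h are fixed.  Estimation is bounded nonlinear least squares
with a seeded multistart.

Around the model, the package provides:

* `dataio` — tidy cultivation time-series container, CSV round trip,
  OD600→CDW conversion (factor 3.2);
* `curvefit` — 4-parameter logistic and 3-parameter exponential fits with
  analytic derivatives (scikit-learn estimator interface);
* `assays` — Miller units, blank screening with z-score exclusion,
  LOD/LOQ (mean + 3·SD / mean + 10·SD), azocasein endopeptidase activity,
  degradation rates;
* `metrics` — yields Y_X/S, Y_P/S, Y_P/X at the ≥90 % reference points,
  µ_max, specific productivity q and the q-versus-ComX correlation curve;
* `masscalc` — peptide monoisotopic masses, [M+zH]ᶻ⁺ m/z, µg/L→nM;
* `synthgen` — seeded generator of realistic cultivation datasets;
* `estimation`, `comx_model`, `pipeline`, `cli` — fitting, simulation,
  sensitivity envelopes and the end-to-end pipeline.

## Worked example

Generate a synthetic reference cultivation (48 h, sampled every 2 h, 5 MU
bioassay noise), refit the kinetic parameters against the generating
biomass curve, and inspect the result:

```python
from comxdyn import SynthConfig, generate_cultivation, fit_comx_params, steady_state

cfg = SynthConfig(seed=7, n_replicates=1)
series, truth = generate_cultivation(cfg)
result = fit_comx_params(series, truth.biomass_curve)
print("SSE:", round(result.sse, 1), "on", result.n_obs, "observations")
for name in ("a0", "b", "d", "e"):
    print(f"  {name}: fitted {getattr(result.params, name):.3f} "
          f"(truth {getattr(truth.comx_params, name):.3f})")
a_ss, ea_ss = steady_state(result.params, 5.4)
print(f"steady state at X = 5.4 g/L: a_ss = {a_ss:.1f} MU, ea_ss = {ea_ss:.1f}")
```

prints

```
SSE: 431.3 on 25 observations
  a0: fitted 27.034 (truth 26.500)
  b: fitted 18.808 (truth 18.835)
  d: fitted 476.919 (truth 476.000)
  e: fitted 1.471 (truth 1.470)
steady state at X = 5.4 g/L: a_ss = 196.9 MU, ea_ss = 69.0
```

The residual sum of squares of ~431 MU² over 25 points matches the
injected 5 MU observation noise (≈ n·σ² ≈ 625 expected scale), the
production/degradation coefficients are recovered to well under 1 %, and
the implied late-cultivation plateau of ~197 MU sits in the activity range
observed at the end of such fermentations.

The same steps are available from the shell:

```bash
comxdyn synth --seed 7 --out run1        # data + truth sidecar
comxdyn fit --input run1/cultivation.csv # parameter estimates as YAML
comxdyn mass --mod farnesyl --charge 2   # 1361.73431 Da, m/z 681.87443
comxdyn run --seed 7 --out report        # full pipeline with manifest
```

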