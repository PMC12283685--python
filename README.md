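# sifsalt

Soil-salinity monitoring from standardized solar-induced chlorophyll
fluorescence (SIF).

Salinity stress suppresses photosynthesis, and with it the chlorophyll
fluorescence a vegetated surface re-emits. `sifsalt` turns that link into a
monitoring chain for researchers working with CSIF-like gridded SIF
products, WoSIS-style georeferenced topsoil electrical-conductivity (EC)
samples and land-cover time series:

1. **SIFI** — the standardized SIF index. For time scales *i* = 1..12
   months, fluorescence accumulations are fitted to a Gamma distribution
   per site (maximum likelihood) and mapped to standard-normal scores,
   SIFIᵢ = Φ⁻¹(G(x; α, β)) — the SPI recipe applied to fluorescence.
2. **Screening** — sites with changed land cover are excluded; per month
   and stratum, a one-way ANOVA + Tukey HSD tests whether fluorescence
   differs across the five EC classes (non/slightly/moderately/highly/
   extremely saline: < 2, 2–4, 4–8, 8–16, ≥ 16 dS/m).
3. **Partition** — 1° × 1° cells are typed *typical* (Welch t-test,
   non-saline vs salt-affected fluorescence, p < 0.05) or *atypical*.
4. **Classification** — per typical cell, a random forest maps 12-scale
   SIFI vectors to the five salinity classes; the feature subset (2–10
   scales) and hyperparameters come from cross-validated search. The best
   typical-cell model is transferred to atypical cells, with weighted-refit
   adaptation when the target cell has labels.
5. **Mapping & trends** — per-year class maps on the 0.05° grid,
   salt-affected (EC ≥ 2) and saline (EC ≥ 4) areas in km² with spherical
   per-pixel weighting, per-site salinity trends and interannual
   variability.

A first-class synthetic-scene generator emulates all three inputs
(seasonal fluorescence with class-dependent suppression and Gamma noise,
a spatially correlated EC field spanning all five classes, mostly-stable
land cover) so the whole chain is testable offline with recoverable ground
truth. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import sifsalt as ss
from sifsalt.pipeline import run_pipeline

res = run_pipeline(ss.default_scene_config(seed=1))

print(res.partition)
print("selected scales:", res.feature_set.scales)
print("median native CV accuracy: %.3f" % res.median_native_cv_accuracy)
print("fraction of sites salinizing: %.3f" % res.trend_summary["frac_increasing"])
print(res.areas[["n_salt_affected_pixels", "salt_affected_km2",
                 "saline_km2"]].tail(3))
```

prints (seed 1):

```
{'n_typical_cells': 28, 'n_atypical_cells': 32, 'n_typical_samples': 17283, 'n_atypical_samples': 20496}
selected scales: (2, 3, 6, 7, 8, 9, 10, 11, 12)
median native CV accuracy: 0.820
fraction of sites salinizing: 0.426
      n_salt_affected_pixels  salt_affected_km2    saline_km2
year
2018                    1405       31742.251768  24021.809487
2019                    1403       31707.034382  24297.684128
2020                    1431       32324.373474  24067.549914
```

Reading this: of the 60 one-degree cells in the scene, 28 show a
significant fluorescence–salinity contrast and get native forests; the
other 32 are served by the transferred best model. The per-cell median
cross-validated accuracy (0.82 here) is the regional skill summary. Area
lines count classified 0.05° pixels and convert them with
cosine-of-latitude weighting; saline area is a subset of salt-affected
area by definition. The trend fraction is the share of sites whose
fitted class-index slope exceeds the stable dead-band — this scene plants
no trend, so the 42.6% increasing share reflects the class churn that the
scene's strong interannual salinity variability creates, and it is
matched by an almost equal decreasing share (42.1%; see
`res.trend_summary`).

The same chain is scriptable from the shell:

```sh
sif-salt simulate --out scene/ --seed 1
sif-salt sifi --in scene/fluor.csv --anchor 12 --out sifi.csv
sif-salt run --seed 1 --out products/
```

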