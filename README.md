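# stormflow

Storm-event extraction and before/after(-control-impact) flow-attenuation
analysis for 15-minute rainfall and discharge records.

`stormflow` is aimed at catchment hydrologists evaluating whether an
intervention — a leaky-dam sequence, a beaver dam complex, any
natural-flood-management measure — has attenuated storm flows downstream.
Given sub-hourly catchment rainfall and gauged discharge (or stage plus a
rating), it provides the full analysis chain:

1. **Rating** — stage → discharge via Manning's equation
   (`Q = K·A·R^0.667·S^0.5 / n`) for a surveyed cross-section, or a
   monotone piecewise-spline rating fitted to gaugings.
2. **Preparation** — regularization to the 15-minute grid; a rolling-quantile
   cleaning rule that smooths low-flow sensor noise while leaving storm
   samples untouched (a sample is *elevated* where the 12.5 h rolling
   Q75 − Q25 spread exceeds the one-month rolling 70th percentile; elsewhere
   a 7.5 h rolling mean replaces the measurement; event peaks are never
   altered); Lyne–Hollick recursive baseflow separation (α = 0.925, three
   passes, reflected padding) into slow flow and quick flow.
3. **Event extraction** — continuous-rainfall periods are paired with flow
   responses where quick flow exceeds slow flow; each event window yields
   total event rainfall ER (mm), total stormflow volume (m³), peak discharge
   (m³ s⁻¹) and the peak-rainfall-to-peak-flow lag (h).
4. **Statistics** — per-site before/after summaries (median, IQR,
   Mann–Whitney U), the Q5:Q95 flashiness index, Q5-exceedance subsets of
   the largest events, and Gamma GLMs with an identity link:

   ```
   Qpeak ~ rain + beaver                      (additive)
   Qpeak ~ rain + beaver * season             (seasonal)
   Qpeak ~ rain + beaver * site               (BACI)
   Qpeak ~ rain + beaver * season * site      (BACI seasonal)
   ```

   with equal-weight estimated marginal means (emmeans) so unbalanced
   before/after designs are compared fairly.
5. **Synthetic catchment** — a seeded paired-catchment simulator (Poisson
   storms, gamma unit-hydrograph routing, seasonal wetness, low-flow sensor
   noise) that injects a volume-conserving attenuation effect — post-impact
   response kernels with peak scaled by `a`, time-to-peak stretched by
   `1/a`, area exactly 1 — so the entire chain can be verified against
   ground truth without any field data.

## Worked example

```python
import stormflow as sf
from stormflow import evaluate

cfg = sf.SyntheticConfig(seed=7)          # 2 sites x 2 years, a = 0.6 wet-season attenuation
bundle = sf.generate_study(cfg)
events = evaluate.pipeline_events(bundle, clean=True)
print("events:", len(events))

fit = sf.fit_peakflow_glm(events, "baci_seasonal")
did, se = sf.baci_contrast(fit)
truth = evaluate.truth_implied_contrast(bundle, events, fit)
print(f"BACI contrast: {did:.3f} +/- {se:.3f} m3/s (truth-implied {truth:.3f})")
```

prints

```
events: 509
BACI contrast: -0.087 +/- 0.032 m3/s (truth-implied -0.104)
```

509 storm events were extracted across the impact and control sites over
two years. The difference-in-differences of the marginal means — the
before→after change in modelled peak flow at the impact site minus the same
change at the control site, rainfall held at its mean and seasons weighted
equally — is −0.087 m³ s⁻¹ (SE 0.032): peak flows at the impact site
dropped by about 0.09 m³ s⁻¹ relative to the control, within two standard
errors of the effect actually injected by the simulator (−0.104 m³ s⁻¹).
The fitted coefficient table (`fit.summary()`) and the full marginal-means
table (`sf.marginal_means(fit)`) show the seasonal structure: the reduction
is concentrated in wet-season events, where the attenuation was applied.

The same chain runs from the command line on CSV inputs:

```bash
stormflow simulate --seed 7 --out study/          # or bring your own CSVs
stormflow run --config study/run.yaml
```

producing per-site event tables, diagnostic time series, the before/after
summary table, and coefficient + emmeans CSVs per model, with a manifest
recording parameters and input digests.

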