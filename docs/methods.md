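# Methods

This note documents the models and procedures implemented in `stormflow`,
the parameter choices behind them, what the synthetic catchment does and
does not emulate, and the numerical decisions that matter when reproducing
results.

## Rating

Manning's equation is implemented exactly as conventionally printed for
gauged culverts, `Q = K·A·R^0.667·S^0.5 / n`, with the hydraulic-radius
exponent written as the rounded decimal 0.667 rather than 2/3 so converted
discharges match published rating computations digit-for-digit. `A` and the
wetted perimeter follow the standard formulas for rectangular, trapezoidal
and circular-segment sections; stage is depth above the section invert, so
stage 0 is a dry channel and maps to zero discharge. Depth at or above a
circular culvert's diameter raises an error: pressurized (surcharged) flow
is outside the validity of an open-channel rating and is deliberately not
modelled. Note that open-channel discharge in a circular conduit peaks near
94% of the diameter; the monotonicity guarantees below apply beneath that
region.

Empirical ratings are least-squares cubic splines with interior knots at
stage quantiles. A rating must be invertible, so after fitting, the
derivative is checked on a dense grid; any decrease triggers a refit with
one fewer interior knot, down to a plain cubic, before failing loudly. The
knot count is configuration (the right number depends on the structure's
geometry and the gauging range), and predictions outside the gauged stage
range are flagged as gaps rather than extrapolated.

## Cleaning rule

Automated event detection is sensitive to sensor noise at low flows. The
cleaning rule classifies each sample by comparing the 12.5 h rolling
inter-quartile spread (Q75 − Q25) against the one-month rolling 70th
percentile (MQ70): where the spread exceeds MQ70 the flow is storm-elevated
and the measurement is kept; elsewhere a 7.5 h rolling mean replaces it.
Implementation choices the rule's verbal definition leaves open:

* **Window alignment.** All rolling windows are *centred* (a width-w window
  at sample i covers offsets [−w/2, w − w/2)). Trailing windows would lag
  the spread statistic by half a window and shift detected event onsets.
* **"One month"** is a fixed 30-day (2880-sample) window, not a calendar
  month, keeping the rule translation-invariant along the record.
* **Record ends.** Windows shrink at the ends (minimum one sample) instead
  of emitting missing values.
* **Peak protection.** Elevated samples already keep their measured value;
  as an explicit final guard, any strict local maximum (±2 samples) of the
  measured series inside an elevated region is overwritten with its
  measured value, so event peaks are bit-identical to the raw record.
* Records shorter than the long window are rejected with a message giving
  the minimum length — MQ70 is meaningless on a shorter record.

Cleaning informs *detection only*: every event metric that touches flow
magnitudes (peak Q in particular) is computed from the measured series.

## Baseflow separation

The Lyne–Hollick recursive digital filter in its standardized usage:
filter parameter α = 0.925, three passes in alternating directions, and 30
samples of reflected padding at each end, with the quick-flow component
clipped to [0, Q] at every step. After filtering, slow flow is re-derived
as Q − quickflow so `slowflow + quickflow == flow` holds exactly at every
unmasked sample. The filter recursion cannot meaningfully cross telemetry
gaps, so each contiguous unmasked segment of at least 60 samples (15 h) is
filtered independently; shorter segments stay masked. All parameters are
configuration-overridable. At a 15-minute step, α = 0.925 gives the filter
a short memory (~3 h), so long compound events allocate much of their
recession to slow flow — a known property of sub-daily application that
motivates the bridging rule below.

## Event extraction

Rainfall periods are maximal wet intervals with internal dry gaps shorter
than 6 h bridged and a 1 mm minimum total depth. Flow responses are maximal
intervals where `quickflow > max(1.0 × slowflow, 0.001 m³ s⁻¹)` — literally
"quick flow exceeds slow flow", with a small absolute floor so numerically
tiny exceedances at near-zero flow do not trigger events. Sub-criterion
dips shorter than the dry-gap parameter are bridged on the flow side too:
a momentary dip between bursts of one compound response is not a recession
end, and without bridging the true flow peak of a two-burst event can fall
just outside its window. Each rainfall period pairs with the first flow
response overlapping it or starting within 24 h; the event window runs from
rainfall start to recession end, rain periods sharing one response merge
into a single event (keeping total stormflow mass well-defined), and
surviving windows are pairwise disjoint — overlap raises an error as a
symptom of misconfigured thresholds. Unpaired flow responses are candidate
misidentifications; the exclusion list (event ids or time ranges) flags
events rather than deleting them, and flagged or gap-affected events are
excluded from statistics by default. These default thresholds are declared
package defaults, fully exposed in configuration, not values inherited from
any particular field deployment.

Metrics per window: ER = Σ rain depths; total stormflow = Σ quickflow × 900 s;
peak Q = maximum *measured* flow; lag = t(max flow) − t(max 15-min rain
depth) in hours, ties resolving to the earliest timestamp. Peak rainfall is
the maximum 15-minute depth (no intensity smoothing). Timestamps label
interval starts and all windows are half-open.

## Statistics

Factors use treatment contrasts with reference levels before-beaver, dry
season, control site, so the beaver coefficient *is* the modelled change in
peak flow (m³ s⁻¹). The wet season is [1 Oct, 1 Apr) with half-open
boundaries; the hydrological year increments at 1 October.

The Gamma error family reflects the right-skew of event peak flows; the
identity link keeps effects additive on the discharge scale. The fit is
maximum likelihood via IRLS — for the identity link each iteration is a
weighted least squares with weights 1/μ² — with step-halving so every
iterate keeps all fitted means strictly positive and the deviance
non-increasing (the standard IRLS can step outside the Gamma domain with an
identity link; this is the same motivation that leads R users to `glm2`).
Initialization is the OLS fit, falling back to an intercept-only start if
OLS is infeasible. Dispersion is the Pearson statistic over residual
degrees of freedom; coefficient covariance is the dispersion-scaled
(XᵀWX)⁻¹ and p-values are Wald-normal. Tests verify the solution against
both `statsmodels` GLM and a generic likelihood optimizer (the Gamma shape
parameter cancels from the mean-parameter score, so the β MLE does not
depend on it), and against R's `glm` + `emmeans` as a fully independent
oracle.

Estimated marginal means are computed on a reference grid — every
combination of the model's factor levels with event rainfall fixed at its
*observed overall mean* (per-cell covariate means would reintroduce the
imbalance emmeans exist to remove) — and averaged with equal weight over
the factors not being reported. Under the identity link an emmean is a
linear form Lβ, so its standard error √(LΣLᵀ) is exact. Empty cells are
still predicted (model-based) and flagged. In a purely additive model the
difference between beaver-level emmeans equals the beaver coefficient
identically.

Mann–Whitney U uses midrank ties and the tie-corrected normal approximation
with continuity correction (sample sizes in this setting are far beyond
exact-table range; exact enumeration appears only as a test oracle), with
U oriented so complete separation with the first sample lower gives U = 0,
and p = 1 by convention when all values are identical. The Q5 threshold for
the largest-events subset is computed from each site's full combined record
so the threshold itself is period-neutral (a pre-period-only option
exists). No multiple-testing correction is applied across the summary
tables; outputs note this. Per-site models are fitted independently; BACI
models pool impact and control rows with site as an interacting factor.

## Synthetic catchment

The generator emulates the *structure* of a paired-catchment monitoring
dataset: Poisson storm arrivals whose daily rate is sinusoidally modulated
with a mid-January peak; exponential storm depths (mean 8 mm + 0.5 mm
floor) and durations (mean 5 h, 1 h floor) spread over a randomized
single-peak hyetograph; runoff = depth × seasonal runoff coefficient
(mean 0.30, winter-weighted) × catchment area (5 km²), routed through a
discrete gamma unit hydrograph (shape 3, time-to-peak 3 h) normalized to
sum exactly to 1; seasonal baseflow (mean 0.06 m³ s⁻¹); and multiplicative
Gaussian sensor noise (CV 0.05) applied only where the storm response is
small relative to baseflow, so event peaks remain exact ground truth —
mirroring the cleaning rule's peak-preservation contract. Defaults describe
a small temperate lowland catchment over two years with the impact date at
the mid-point, sized to give on the order of 150 detectable events per
period. The control site shares each storm with probability 0.9 (depth
jittered, timing shifted by up to ±30 min) plus its own independent storms
at the complementary rate.

Attenuation acts on the *response kernel*, not on realized flows: after the
impact date (impact sites only, optionally wet-season storms only) the
kernel k(t) is replaced by a·k(a·(t − Δt)) — ordinate scaled by a, time
stretched by 1/a — then renormalized to unit sum. Peak drops to a× the
original, time-to-peak lengthens, and area (volume) is conserved exactly;
before/after periods share identical rainfall statistics, isolating the
causal effect exactly as a BACI design assumes. The generator also returns
the counterfactual series (same storms, unattenuated kernel throughout) and
a per-storm truth table. All randomness flows from one master seed through
named sub-streams.

What the simulator does **not** emulate: spatially variable rainfall
fields, antecedent-moisture memory beyond the seasonal cycle, snow,
evapotranspiration, rating drift, or autocorrelated sensor error. Passing
recovery tests therefore demonstrate that the *pipeline* is correct and
well-calibrated under its own assumptions, not that field data meet those
assumptions.

## Evaluation experiments and the truth-implied effect

The BACI marginal-means contrast estimates a rainfall-adjusted,
precision-weighted difference of cell means: Gamma IRLS weights are 1/μ²,
so small events carry more weight than large ones. The injected attenuation
is multiplicative on storm responses, so its *absolute* effect grows with
event size, and the unweighted mean causal delta is systematically larger
in magnitude than what any Gamma GLM estimates. The recovery experiment
therefore expresses truth in the model's own metric: per post-impact event
at the impact site, the causal delta is the difference between the
event-window peak of the realized and of the counterfactual flow; the
truth-implied contrast is the 1/μ̂²-weighted mean of those deltas per
season, averaged over seasons with equal weight — exactly the functional
the emmeans difference-in-differences targets. A storm much longer than the
kernel approaches steady state, where the peak is insensitive to kernel
shape; per-storm peak ratios under a = 0.6 therefore range from ≈0.6 (short
storms) toward 1 (long storms), and the truth table records the realized
values.

Experiment sizes: the attenuation-recovery experiment runs 100 replicates
of the 2-site × 2-year default study (cleaning on) and checks that the
contrast is negative and within 2 SE of the truth-implied effect in ≥ 90%;
the null experiment runs 200 one-site replicates with a = 1 and checks the
additive beaver term rejects at α = 0.05 in ≤ 10%; the noise-free recovery
check uses one year at ~40 well-separated storms (0.11/day) with permissive
extraction thresholds, the regime in which per-storm identification is
well-posed — at the default storm rate, overlapping responses merge and
per-storm attribution is undefined, so merged truth windows are the unit of
comparison there. Storm peaks are compared for exactness bit-for-bit;
per-storm lags only for truth events mapping 1:1 onto extracted windows.

A note on flashiness: under volume-conserving kernel attenuation the Q5:Q95
ratio has no reliable sign. Peaks drop, but the stretched kernel holds
moderately high flows up longer, so the duration-based Q5 statistic (flow
exceeded 5% of the time) can rise; and the simulator routes each storm's
volume within its own response window rather than releasing it into
low-flow periods, so Q95 is untouched. Field reductions in Q5:Q95 after
impoundment rest partly on baseflow maintenance, which this generator
deliberately does not model. The reported before/after ratios are therefore
descriptive — dominated by inter-year weather — and are not a recovery
check.

## Known limitations

* No autocorrelation-aware or mixed-effects models: events are treated as
  exchangeable within factor cells.
* No return-period or flood-frequency estimation — monitoring records of
  this length cannot support it.
* The baseflow filter's α is taken from standardized daily practice; at a
  15-minute step the slow/quick split is conventional rather than physical,
  which is acceptable here because it is used for *detection*, with
  magnitudes always read from the measured series.
* Gap handling is conservative (flag and exclude); no infilling.
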