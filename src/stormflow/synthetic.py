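"""Synthetic paired-catchment rainfall/flow generator with known truth.

The simulator produces what the pipeline consumes — 15-minute catchment
rainfall (mm per step) and discharge (m³ s⁻¹) for an impact site and a
correlated control site — together with a per-storm truth table, so storm
extraction, metric computation and effect-recovery can all be verified
against ground truth.

Model sketch
------------
* Storm arrivals are an inhomogeneous Poisson process whose daily rate is
  sinusoidally modulated with a winter peak; each storm has an exponential
  depth and duration and spreads its depth over the wet spell with a
  randomized within-storm profile.
* Flow is baseflow plus the convolution of effective rainfall
  (depth × seasonal runoff coefficient × catchment area) with a discrete
  gamma-shaped unit-hydrograph kernel normalized to sum exactly to one, so
  each storm's response volume equals its effective rainfall volume.
* After the impact date, at impact sites only, the kernel is replaced by an
  attenuated kernel: time is stretched by 1/a (and optionally shifted by
  Δt) and the ordinate scaled by a, which lowers the peak to a × the
  original, lengthens the time to peak, and — after renormalization to unit
  sum — conserves volume exactly.  The attenuation can be confined to
  wet-season storms.
* Multiplicative sensor noise is applied only where the storm response is
  small relative to baseflow, so event peaks remain exact ground truth.

All randomness derives from one master seed through named sub-streams, so
every output is seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .series import RegularSeries, make_series, UNIT_FLOW, UNIT_RAIN
from .stats import SiteDesign, StudyDesign, season_of

SAMPLES_PER_DAY = 96
STEP_S = 900.0


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic paired-catchment study.

    Defaults describe a small (~5 km²) temperate lowland catchment at a
    15-minute step over two years, with the impact date at the mid-point,
    sized to yield on the order of 150 detectable storm events per period.
    """

    start: str = "2017-10-01"
    n_days: int = 730
    impact_day: int = 365                  # days after start
    catchment_km2: float = 5.0
    # storms
    storm_rate_per_day: float = 0.55       # annual mean arrival rate
    storm_rate_seasonality: float = 0.5    # relative winter/summer modulation
    storm_depth_mean_mm: float = 8.0       # exponential mean
    storm_duration_mean_h: float = 5.0     # exponential mean, floored at 1 h
    # runoff response
    runoff_coef_mean: float = 0.30
    runoff_coef_seasonality: float = 0.5   # relative winter/summer modulation
    kernel_time_to_peak_h: float = 3.0
    kernel_shape: float = 3.0              # gamma shape of the unit hydrograph
    # baseflow
    baseflow_m3s: float = 0.06
    baseflow_seasonality: float = 0.4
    # noise
    noise_cv: float = 0.05                 # multiplicative CV at low flows
    # attenuation (impact sites, after the impact date)
    attenuation_factor: float = 0.6        # a: post-impact peak scaling, (0, 1]
    attenuation_lag_h: float = 0.0         # extra kernel time shift Δt
    wet_season_only: bool = True           # apply attenuation to wet-season storms only
    # control site
    control_correlation: float = 0.9       # probability a storm is shared
    control_depth_jitter: float = 0.2      # lognormal sigma on shared depths
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.attenuation_factor <= 1:
            raise ConfigError("attenuation factor must lie in (0, 1]")
        for name in ("catchment_km2", "storm_depth_mean_mm",
                     "storm_duration_mean_h", "runoff_coef_mean",
                     "kernel_time_to_peak_h", "kernel_shape", "baseflow_m3s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.storm_rate_per_day < 0:
            raise ConfigError("storm rate must be non-negative")
        if not 0 <= self.control_correlation <= 1:
            raise ConfigError("control correlation must lie in [0, 1]")
        if not 0 < self.impact_day < self.n_days:
            raise ConfigError("impact date must fall inside the record span")

    @property
    def n_samples(self) -> int:
        return self.n_days * SAMPLES_PER_DAY

    @property
    def start_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.start, tz="UTC")

    @property
    def impact_ts(self) -> pd.Timestamp:
        return self.start_ts + pd.Timedelta(days=self.impact_day)


def _seasonal(day_of_year: np.ndarray, mean: float, rel_amp: float) -> np.ndarray:
    """Sinusoid with its maximum in mid-winter (~mid January)."""
    return mean * (1.0 + rel_amp * np.cos(2.0 * np.pi * (day_of_year - 15.0) / 365.25))


def unit_hydrograph(time_to_peak_h: float, shape: float,
                    attenuation: float = 1.0, lag_shift_h: float = 0.0) -> np.ndarray:
    """Discrete gamma unit-hydrograph kernel summing to exactly 1.

    ``attenuation`` a stretches time by 1/a and scales the ordinate by a
    (k_a(t) = a·k(a·(t − Δt))), so the peak drops to a× the original and
    the time to peak lengthens to t_p/a + Δt while the area is untouched;
    discretization is then renormalized so the kernel sums to one exactly.
    """
    from scipy.stats import gamma as gamma_dist
    a = attenuation
    scale_h = time_to_peak_h / (shape - 1.0) if shape > 1 else time_to_peak_h
    dist = gamma_dist(shape, scale=scale_h * 3600.0)
    length_s = dist.ppf(0.9995) / a + lag_shift_h * 3600.0
    n = max(int(np.ceil(length_s / STEP_S)) + 1, 4)
    t = (np.arange(n) + 0.5) * STEP_S
    k = a * dist.pdf(a * (t - lag_shift_h * 3600.0))
    total = k.sum()
    if total <= 0:
        raise ConfigError("degenerate unit-hydrograph kernel")
    return k / total


def _storm_profile(n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Within-storm hyetograph shape (sums to 1) with a single ragged peak."""
    base = np.sin(np.linspace(0.15, np.pi - 0.15, n_steps)) + 0.1
    base *= rng.uniform(0.6, 1.4, n_steps)
    return base / base.sum()


def _draw_storms(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Poisson storm arrivals with seasonal rate; depths, durations, profiles."""
    days = np.arange(cfg.n_days)
    doy = (cfg.start_ts.dayofyear + days) % 365
    rate = _seasonal(doy, cfg.storm_rate_per_day, cfg.storm_rate_seasonality)
    counts = rng.poisson(rate)
    rows = []
    for d in np.flatnonzero(counts):
        for _ in range(counts[d]):
            start = d * SAMPLES_PER_DAY + rng.integers(0, SAMPLES_PER_DAY)
            depth = rng.exponential(cfg.storm_depth_mean_mm) + 0.5
            dur_h = max(1.0, rng.exponential(cfg.storm_duration_mean_h))
            n_steps = max(2, int(round(dur_h * 4)))
            rows.append((int(start), float(depth), int(n_steps)))
    storms = pd.DataFrame(rows, columns=["start", "depth_mm", "n_steps"])
    return storms.sort_values("start", ignore_index=True)


def generate_rainfall(cfg: SyntheticConfig) -> tuple[RegularSeries, RegularSeries,
                                                     pd.DataFrame, pd.DataFrame]:
    """Rainfall for the impact and control sites plus their storm lists.

    The control shares each storm with probability ``control_correlation``
    (with jittered depth) and receives its own independent storms at the
    complementary rate, so both sites see realistic, correlated weather.
    Returns ``(rain_impact, rain_control, storms_impact, storms_control)``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_storm, r_ctrl = [np.random.default_rng(s) for s in ss.spawn(2)]
    storms = _draw_storms(cfg, r_storm)

    shared = r_ctrl.random(len(storms)) < cfg.control_correlation
    ctrl = storms[shared].copy()
    if len(ctrl):
        ctrl["depth_mm"] = ctrl["depth_mm"] * r_ctrl.lognormal(
            0.0, cfg.control_depth_jitter, len(ctrl))
        ctrl["start"] = ctrl["start"] + r_ctrl.integers(-2, 3, len(ctrl))
        ctrl["start"] = ctrl["start"].clip(0, cfg.n_samples - 1)
    extra_cfg = replace(cfg, storm_rate_per_day=max(
        cfg.storm_rate_per_day * (1.0 - cfg.control_correlation), 1e-9), seed=cfg.seed)
    extra = _draw_storms(extra_cfg, r_ctrl)
    parts = [t for t in (ctrl, extra) if len(t)]
    storms_ctrl = (pd.concat(parts, ignore_index=True).sort_values(
        "start", ignore_index=True) if parts else storms.iloc[0:0])

    def render(stormtab: pd.DataFrame, rng: np.random.Generator) -> RegularSeries:
        rain = np.zeros(cfg.n_samples)
        for start, depth, n_steps in stormtab.itertuples(index=False):
            prof = _storm_profile(int(n_steps), rng) * depth
            end = min(cfg.n_samples, int(start) + int(n_steps))
            rain[int(start):end] += prof[:end - int(start)]
        return make_series(cfg.start_ts, rain, UNIT_RAIN)

    rain_i = render(storms, np.random.default_rng(ss.spawn(1)[0]))
    rain_c = render(storms_ctrl, np.random.default_rng(ss.spawn(1)[0]))
    return rain_i, rain_c, storms, storms_ctrl


def generate_flow(rain: RegularSeries, cfg: SyntheticConfig, *,
                  impacted: bool, storms: pd.DataFrame,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[RegularSeries, pd.DataFrame, RegularSeries]:
    """Flow from rainfall via unit-hydrograph convolution, plus ground truth.

    Returns ``(flow, truth, counterfactual_flow)``.  The truth table has one
    row per storm with the realized (noise-free) peak, its time, the lag
    from the storm's peak-rain bin, the response volume, the counterfactual
    (never-attenuated) peak, and the attenuation factor actually applied;
    rows whose response windows overlap a neighbouring storm are flagged
    ``overlapped``.  The counterfactual series is the same storms routed
    through the unattenuated kernel throughout (noise-free) — the flow the
    site would have shown had the impact never happened.
    """
    rng = rng or np.random.default_rng(cfg.seed + 7)
    n = cfg.n_samples
    t_days = np.arange(n) / SAMPLES_PER_DAY
    doy = (cfg.start_ts.dayofyear + t_days) % 365
    runoff = _seasonal(doy, cfg.runoff_coef_mean, cfg.runoff_coef_seasonality)
    base = _seasonal(doy, cfg.baseflow_m3s, cfg.baseflow_seasonality)

    kern_pre = unit_hydrograph(cfg.kernel_time_to_peak_h, cfg.kernel_shape)
    kern_post = unit_hydrograph(cfg.kernel_time_to_peak_h, cfg.kernel_shape,
                                cfg.attenuation_factor, cfg.attenuation_lag_h)
    area_m2 = cfg.catchment_km2 * 1e6
    idx = rain.index
    impact_i = int(cfg.impact_day * SAMPLES_PER_DAY)

    response = np.zeros(n)
    response_cf = np.zeros(n)
    rows = []
    rain_v = rain.values
    for sid, (start, depth, n_steps) in enumerate(storms.itertuples(index=False)):
        start, n_steps = int(start), int(n_steps)
        end = min(n, start + n_steps)
        burst = rain_v[start:end]
        wet_storm = season_of(idx[start]) == "wet"
        attenuate = (impacted and start >= impact_i
                     and (wet_storm or not cfg.wet_season_only))
        kern = kern_post if attenuate else kern_pre
        # effective rainfall volume of each wet bin (m³)
        eff = burst * runoff[start:end] * area_m2 / 1000.0
        resp = np.convolve(eff, kern)
        resp_cf = np.convolve(eff, kern_pre)   # counterfactual, never attenuated
        seg = min(n - start, len(resp))
        response[start:start + seg] += resp[:seg] / STEP_S
        seg_cf = min(n - start, len(resp_cf))
        response_cf[start:start + seg_cf] += resp_cf[:seg_cf] / STEP_S
        r = resp[:seg] / STEP_S
        rcf = resp_cf[:seg_cf] / STEP_S
        i_peak = int(np.argmax(r))
        i_rain = start + int(np.argmax(burst))
        rows.append({
            "storm_id": sid,
            "start": idx[start],
            "window_start": start,
            "window_end": start + seg,
            "depth_mm": float(depth),
            "season": "wet" if wet_storm else "dry",
            "post_impact": bool(start >= impact_i),
            "attenuated": bool(attenuate),
            "attenuation_factor": cfg.attenuation_factor if attenuate else 1.0,
            "response_peak_m3s": float(r[i_peak]),
            "t_peak": idx[start + i_peak],
            "lag_h": (start + i_peak - i_rain) * STEP_S / 3600.0,
            "response_volume_m3": float(resp.sum()),
            "counterfactual_peak_m3s": float(np.max(rcf)),
            "counterfactual_volume_m3": float(resp_cf.sum()),
        })
    truth = pd.DataFrame(rows)

    flow = base + response
    # noise only where the storm response is small relative to baseflow,
    # so event peaks stay exact ground truth
    if cfg.noise_cv > 0:
        low = response < 0.2 * base
        noise = 1.0 + cfg.noise_cv * rng.standard_normal(n)
        flow = np.where(low, np.maximum(flow * noise, 1e-4), flow)

    if len(truth):
        # total-flow peak within each storm's response window, and overlap flags
        starts = truth["window_start"].to_numpy()
        ends = truth["window_end"].to_numpy()
        peaks, t_peaks, overlapped = [], [], []
        for k in range(len(truth)):
            s, e = starts[k], ends[k]
            j = s + int(np.argmax(flow[s:e]))
            peaks.append(float(flow[j]))
            t_peaks.append(idx[j])
            overlapped.append(bool(((starts < e) & (ends > s)).sum() > 1))
        truth["peak_q_m3s"] = peaks
        truth["t_peak_q"] = t_peaks
        truth["overlapped"] = overlapped

    cf_flow = make_series(cfg.start_ts, base + response_cf, UNIT_FLOW)
    return make_series(cfg.start_ts, flow, UNIT_FLOW), truth, cf_flow


@dataclass
class StudyBundle:
    """In-memory synthetic study: series, truth tables and the design."""

    cfg: SyntheticConfig
    rain: dict[str, RegularSeries]
    flow: dict[str, RegularSeries]
    truth: dict[str, pd.DataFrame]
    counterfactual_flow: dict[str, RegularSeries]
    design: StudyDesign = field(init=False)

    def __post_init__(self) -> None:
        self.design = StudyDesign(sites=(
            SiteDesign("impact", "impact", impact_date=self.cfg.impact_ts),
            SiteDesign("control", "control", control_partner="impact"),
        ))


def generate_study(cfg: SyntheticConfig) -> StudyBundle:
    """Simulate the full two-site study (impact + control)."""
    rain_i, rain_c, storms_i, storms_c = generate_rainfall(cfg)
    ss = np.random.SeedSequence(cfg.seed + 1)
    rng_i, rng_c = [np.random.default_rng(s) for s in ss.spawn(2)]
    flow_i, truth_i, cf_i = generate_flow(rain_i, cfg, impacted=True,
                                          storms=storms_i, rng=rng_i)
    flow_c, truth_c, cf_c = generate_flow(rain_c, cfg, impacted=False,
                                          storms=storms_c, rng=rng_c)
    return StudyBundle(
        cfg=cfg,
        rain={"impact": rain_i, "control": rain_c},
        flow={"impact": flow_i, "control": flow_c},
        truth={"impact": truth_i, "control": truth_c},
        counterfactual_flow={"impact": cf_i, "control": cf_c},
    )


def truth_events(truth: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping storm-response windows into truth *events*.

    Extraction cannot split storms whose responses overlap, so the
    ground-truth unit for recovery checks is the merged window: its peak is
    the maximum flow peak over member storms and its volume their sum.
    """
    if truth.empty:
        return truth
    t = truth.sort_values("window_start", ignore_index=True)
    groups = []
    cur = [0]
    cur_end = int(t.loc[0, "window_end"])
    for k in range(1, len(t)):
        if t.loc[k, "window_start"] < cur_end:
            cur.append(k)
            cur_end = max(cur_end, int(t.loc[k, "window_end"]))
        else:
            groups.append(cur)
            cur = [k]
            cur_end = int(t.loc[k, "window_end"])
    groups.append(cur)
    rows = []
    for g in groups:
        sub = t.loc[g]
        j = sub["peak_q_m3s"].idxmax()
        rows.append({
            "window_start": int(sub["window_start"].min()),
            "window_end": int(sub["window_end"].max()),
            "n_storms": len(sub),
            "depth_mm": float(sub["depth_mm"].sum()),
            "peak_q_m3s": float(sub.loc[j, "peak_q_m3s"]),
            "t_peak_q": sub.loc[j, "t_peak_q"],
            "lag_h": float(sub.loc[j, "lag_h"]),
            "response_volume_m3": float(sub["response_volume_m3"].sum()),
            "counterfactual_volume_m3": float(sub["counterfactual_volume_m3"].sum()),
            "attenuated": bool(sub["attenuated"].any()),
        })
    return pd.DataFrame(rows)


def write_study(bundle: StudyBundle, outdir) -> dict:
    """Write a pipeline-ready study to disk (CSV series, YAML design, truth CSVs)."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"sites": {}}
    for site in bundle.rain:
        rp = out / f"{site}_rain.csv"
        fp = out / f"{site}_flow.csv"
        tp = out / f"{site}_truth.csv"
        bundle.rain[site].to_csv(rp)
        bundle.flow[site].to_csv(fp)
        bundle.truth[site].to_csv(tp, index=False)
        paths["sites"][site] = {"rain": str(rp), "flow": str(fp), "truth": str(tp)}
    design_doc = {
        "sites": [
            {"site": "impact", "role": "impact",
             "impact_date": str(bundle.cfg.impact_ts.date())},
            {"site": "control", "role": "control", "control_partner": "impact"},
        ]
    }
    dp = out / "design.yaml"
    dp.write_text(yaml.safe_dump(design_doc, sort_keys=False))
    paths["design"] = str(dp)
    return paths
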