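"""Rainfall–runoff event extraction.

Periods of continuous rainfall are identified alongside flow responses where
quick flow exceeds slow flow; a rainfall period and its paired flow response
are combined into a single event window, over which the event metrics are
computed:

* ``event_rain_mm`` — total event rainfall ER (mm);
* ``total_stormflow_m3`` — quick-flow volume over the window (m³);
* ``peak_q_m3s`` — maximum *measured* discharge in the window (cleaning is a
  detection aid only and never alters peaks);
* ``lag_h`` — time from the peak 15-minute rainfall bin to the peak
  discharge (hours; ties resolve to the earliest timestamp).

Timestamps label the start of each 15-minute interval and all windows are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import BaseflowResult
from .series import RegularSeries

#: Stable column order of the event table.
EVENT_COLUMNS = [
    "event_id", "site", "start", "end",
    "event_rain_mm", "total_stormflow_m3", "peak_q_m3s",
    "t_peak_q", "t_peak_rain", "lag_h",
    "gap_affected", "excluded",
]


class EventError(ValueError):
    pass


@dataclass(frozen=True)
class EventParams:
    """Thresholds of the event identification rules.

    ``min_dry_gap_h`` — dry spells shorter than this are bridged inside one
    rainfall period.  ``min_event_rain_mm`` — rainfall periods with less
    total depth are discarded.  A flow response exists where
    ``quickflow > max(quickflow_fraction × slowflow, quickflow_floor)``;
    with the default fraction 1.0 this is literally "quick flow exceeds
    slow flow".  ``max_lead_h`` — a flow response must start within this
    lead time of its rainfall period (or overlap it) to be paired.
    """

    min_dry_gap_h: float = 6.0
    min_event_rain_mm: float = 1.0
    quickflow_fraction: float = 1.0
    quickflow_floor: float = 0.001
    max_lead_h: float = 24.0

    def __post_init__(self) -> None:
        if min(self.min_dry_gap_h, self.min_event_rain_mm,
               self.quickflow_floor, self.max_lead_h) < 0:
            raise EventError("event parameters must be non-negative")
        if not 0 <= self.quickflow_fraction <= 2:
            raise EventError("quickflow fraction must lie in [0, 2]")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where mask is True."""
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_rainfall_periods(rain: RegularSeries,
                            p: EventParams | None = None) -> list[tuple[int, int]]:
    """Maximal wet intervals (sample index ranges, half-open).

    Internal dry gaps shorter than ``min_dry_gap_h`` are bridged; intervals
    totalling less than ``min_event_rain_mm`` are discarded.
    """
    p = p or EventParams()
    wet = np.nan_to_num(rain.values) > 0
    runs = _runs(wet)
    if not runs:
        return []
    gap_samples = int(round(p.min_dry_gap_h * 3600 / rain.step.total_seconds()))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    v = np.nan_to_num(rain.values)
    return [(s, e) for s, e in merged if v[s:e].sum() >= p.min_event_rain_mm]


def detect_flow_responses(base: BaseflowResult,
                          p: EventParams | None = None) -> list[tuple[int, int]]:
    """Maximal intervals where quick flow exceeds the response criterion.

    The criterion is ``quickflow > max(fraction × slowflow, floor)``; each
    interval runs to the sample where quick flow falls back below it (the
    recession end).  Sub-criterion dips shorter than the dry-gap parameter
    are bridged — a momentary dip during a multi-burst response is not a
    recession end.
    """
    p = p or EventParams()
    qf = base.quickflow.values
    sf = base.slowflow.values
    with np.errstate(invalid="ignore"):
        above = qf > np.maximum(p.quickflow_fraction * sf, p.quickflow_floor)
    runs = _runs(above)
    if not runs:
        return []
    gap = int(round(p.min_dry_gap_h * 3600 / base.flow.step.total_seconds()))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


def pair_events(rain_intervals: list[tuple[int, int]],
                flow_intervals: list[tuple[int, int]],
                p: EventParams | None = None,
                step_s: float = 900.0,
                ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Combine rainfall periods with their flow responses into event windows.

    Each rainfall interval pairs with the first flow interval that overlaps
    it or starts within ``max_lead_h`` after the rain starts.  The event
    window spans from the rainfall start to the flow recession end.  Rain
    intervals sharing one flow response merge into a single event, and any
    remaining overlapping windows are merged, so windows are pairwise
    disjoint.  Flow intervals no rainfall claims are returned separately as
    unpaired (candidate misidentifications); rain with no response is
    dropped.

    Returns ``(event_windows, unpaired_flow_intervals)`` in sample indices.
    """
    p = p or EventParams()
    lead = int(round(p.max_lead_h * 3600 / step_s))
    paired_flow: set[int] = set()
    windows: list[list[int]] = []
    for rs, re_ in sorted(rain_intervals):
        for j, (fs, fe) in enumerate(flow_intervals):
            overlaps = fs < re_ and fe > rs
            within_lead = rs <= fs <= rs + lead
            if overlaps or within_lead:
                paired_flow.add(j)
                windows.append([min(rs, fs), max(re_, fe), j])
                break
    # merge windows sharing a flow response, then any overlap
    windows.sort()
    merged: list[list[int]] = []
    for w in windows:
        if merged and (w[0] < merged[-1][1] or w[2] == merged[-1][2]):
            merged[-1][1] = max(merged[-1][1], w[1])
        else:
            merged.append(w)
    unpaired = [iv for j, iv in enumerate(flow_intervals) if j not in paired_flow]
    return [(s, e) for s, e, _ in merged], unpaired


def compute_event_metrics(window: tuple[int, int], rain: RegularSeries,
                          base: BaseflowResult) -> dict:
    """Event metrics over one half-open sample-index window."""
    s, e = window
    idx = rain.index
    rv = rain.values[s:e]
    qv = base.flow.values[s:e]
    qf = base.quickflow.values[s:e]
    step_s = rain.step.total_seconds()
    gap = bool(np.isnan(rv).any() or np.isnan(qv).any())
    if np.all(np.isnan(qv)) or np.all(np.isnan(rv)):
        return {
            "start": idx[s], "end": idx[e - 1] + rain.step,
            "event_rain_mm": float(np.nansum(rv)),
            "total_stormflow_m3": np.nan, "peak_q_m3s": np.nan,
            "t_peak_q": pd.NaT, "t_peak_rain": pd.NaT, "lag_h": np.nan,
            "gap_affected": True,
        }
    i_pq = s + int(np.nanargmax(qv))          # earliest maximum (argmax ties → first)
    i_pr = s + int(np.nanargmax(rv))
    lag_h = (idx[i_pq] - idx[i_pr]).total_seconds() / 3600.0
    return {
        "start": idx[s],
        "end": idx[e - 1] + rain.step,
        "event_rain_mm": float(np.nansum(rv)),
        "total_stormflow_m3": float(np.nansum(qf) * step_s),
        "peak_q_m3s": float(np.nanmax(qv)),
        "t_peak_q": idx[i_pq],
        "t_peak_rain": idx[i_pr],
        "lag_h": lag_h,
        "gap_affected": gap,
    }


def extract_events(site: str, rain: RegularSeries, base: BaseflowResult,
                   p: EventParams | None = None,
                   exclusions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run detection, pairing and metric computation for one site.

    Exclusions (columns ``site`` and either ``event_id`` or
    ``start``/``end`` time ranges) flag events rather than deleting them;
    flagged and gap-affected events are retained in the table and filtered
    downstream.

    Raises
    ------
    EventError
        If surviving event windows overlap (indicates misconfigured
        thresholds) or the rain/flow grids are not aligned.
    """
    p = p or EventParams()
    if len(rain) != len(base.flow) or rain.start != base.flow.start:
        raise EventError("rain and flow series must share one time grid")
    rains = detect_rainfall_periods(rain, p)
    flows = detect_flow_responses(base, p)
    windows, _unpaired = pair_events(rains, flows, p, rain.step.total_seconds())
    for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
        if s2 < e1:
            raise EventError("overlapping event windows; check event parameters")
    rows = []
    for k, w in enumerate(windows):
        m = compute_event_metrics(w, rain, base)
        m["event_id"] = f"{site}-{k:04d}"
        m["site"] = site
        m["excluded"] = False
        rows.append(m)
    table = pd.DataFrame(rows, columns=EVENT_COLUMNS) if rows else pd.DataFrame(
        columns=EVENT_COLUMNS)
    if exclusions is not None and len(table):
        table = apply_exclusions(table, exclusions)
    return table


def apply_exclusions(events: pd.DataFrame, exclusions: pd.DataFrame) -> pd.DataFrame:
    """Flag manually reviewed events as excluded (never deleted)."""
    events = events.copy()
    sub = exclusions[exclusions.get("site", events["site"].iloc[0]) == events["site"].iloc[0]] \
        if "site" in exclusions.columns else exclusions
    if "event_id" in sub.columns:
        ids = set(sub["event_id"].dropna())
        events.loc[events["event_id"].isin(ids), "excluded"] = True
    if {"start", "end"}.issubset(sub.columns):
        for _, row in sub.dropna(subset=["start", "end"]).iterrows():
            s = pd.Timestamp(row["start"]).tz_localize("UTC") \
                if pd.Timestamp(row["start"]).tz is None else pd.Timestamp(row["start"])
            e = pd.Timestamp(row["end"]).tz_localize("UTC") \
                if pd.Timestamp(row["end"]).tz is None else pd.Timestamp(row["end"])
            hit = (events["start"] < e) & (events["end"] > s)
            events.loc[hit, "excluded"] = True
    return events
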