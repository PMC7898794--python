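"""Regular time-series container for 15-minute hydrological records.

A :class:`RegularSeries` is a strictly regular, gap-flagged series of one
quantity — rainfall depth per step (mm) or discharge (m³ s⁻¹) — backed by a
pandas Series with a UTC DatetimeIndex.  Gaps are represented as NaN and
mirrored in :attr:`RegularSeries.mask`; values at unmasked samples are finite
and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical unit strings.
UNIT_RAIN = "mm"      # depth per step
UNIT_FLOW = "m3s"     # cubic metres per second
UNIT_STAGE = "m"      # water depth above the section invert

DEFAULT_STEP = pd.Timedelta(minutes=15)


class SeriesError(ValueError):
    """Raised when a series violates the regular-series contract."""


@dataclass
class RegularSeries:
    """A gap-flagged series on a strictly regular time grid.

    Parameters
    ----------
    data
        Values indexed by a tz-aware (UTC) DatetimeIndex with a constant
        step.  NaN marks a gap.
    units
        One of ``"mm"`` (rain depth per step), ``"m3s"`` (discharge) or
        ``"m"`` (stage).
    step
        Grid spacing; 15 minutes throughout the pipeline.
    """

    data: pd.Series
    units: str
    step: pd.Timedelta = field(default=DEFAULT_STEP)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise SeriesError("RegularSeries requires a DatetimeIndex")
        if self.data.index.tz is None:
            self.data = self.data.tz_localize("UTC")
        self.data = self.data.astype(float)
        if len(self.data) > 1:
            deltas = np.diff(self.data.index.asi8)
            if not (deltas == self.step.value).all():
                raise SeriesError(
                    f"index is not regular at step {self.step}; "
                    "regularize() the raw record first"
                )
        vals = self.data.to_numpy()
        bad = np.isfinite(vals) & (vals < 0)
        if bad.any():
            raise SeriesError(f"{bad.sum()} negative values at unmasked samples")
        inf = np.isinf(vals)
        if inf.any():
            raise SeriesError("infinite values are not allowed; use NaN for gaps")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def mask(self) -> np.ndarray:
        """Boolean gap mask — True where the sample is missing."""
        return np.asarray(self.data.isna())

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "RegularSeries":
        return RegularSeries(
            pd.Series(np.asarray(values, dtype=float), index=self.data.index),
            units=units or self.units,
            step=self.step,
        )

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> "RegularSeries":
        """Half-open window [start, end)."""
        sub = self.data[(self.data.index >= start) & (self.data.index < end)]
        return RegularSeries(sub, units=self.units, step=self.step)

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write a 2-column CSV: ISO-8601 UTC timestamp, value (blank at gaps)."""
        out = self.data.rename("value").rename_axis("timestamp")
        out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%SZ")

    @classmethod
    def from_csv(cls, path, units: str, step: pd.Timedelta = DEFAULT_STEP) -> "RegularSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        idx = pd.DatetimeIndex(df["timestamp"])
        if idx.tz is None:
            idx = idx.tz_localize("UTC")
        return cls(pd.Series(df["value"].to_numpy(float), index=idx), units=units, step=step)


def make_series(start: str | pd.Timestamp, values, units: str,
                step: pd.Timedelta = DEFAULT_STEP) -> RegularSeries:
    """Convenience constructor from a start time and a value array."""
    start = pd.Timestamp(start)
    if start.tz is None:
        start = start.tz_localize("UTC")
    idx = pd.date_range(start, periods=len(values), freq=step)
    return RegularSeries(pd.Series(np.asarray(values, dtype=float), index=idx),
                         units=units, step=step)
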