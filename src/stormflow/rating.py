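"""Stage-to-discharge conversion.

Two routes are supported, matching how small-catchment gauging structures are
rated in practice:

* **Manning's equation** for a surveyed culvert or channel cross-section,
  ``Q = K · A · R^0.667 · S^0.5 / n`` with the hydraulic radius
  ``R = A / P`` computed from the section geometry at the observed depth.
  The exponent is 0.667 (the conventional rounded value), and ``K = 1``
  for metric inputs.
* An **empirical piecewise-spline rating curve** fitted to concurrent
  stage/discharge gaugings, with monotonicity enforced so the rating is
  invertible.

Stage is depth above the invert (lowest point) of the section; zero means a
dry channel and maps to zero discharge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

from .series import RegularSeries, UNIT_FLOW, UNIT_STAGE

MANNING_R_EXPONENT = 0.667


class GeometryError(ValueError):
    """Invalid channel geometry."""


class OverfullError(ValueError):
    """Depth at or above the capacity of a closed conduit."""


class RatingError(ValueError):
    """Rating curve could not be fitted."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Cross-section geometry for Manning's equation.

    Parameters
    ----------
    shape
        ``"rectangular"``, ``"circular"`` or ``"trapezoidal"``.
    width
        Bed width (m) for rectangular/trapezoidal sections.
    diameter
        Pipe diameter (m) for circular culverts.
    side_slope
        Horizontal run per unit rise of the banks (trapezoidal only).
    slope
        Bed slope S (dimensionless rise/run), > 0.
    roughness
        Manning n (s m^-1/3); 0.015 for a smooth lined culvert.
    K
        Unit constant, 1 for metric measurements.
    """

    shape: str
    slope: float
    roughness: float = 0.015
    width: float | None = None
    diameter: float | None = None
    side_slope: float = 0.0
    K: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("rectangular", "circular", "trapezoidal"):
            raise GeometryError(f"unknown shape {self.shape!r}")
        if self.slope <= 0:
            raise GeometryError("bed slope must be positive")
        if self.roughness <= 0:
            raise GeometryError("Manning roughness must be positive")
        if self.K <= 0:
            raise GeometryError("unit constant K must be positive")
        if self.shape == "circular":
            if self.diameter is None or self.diameter <= 0:
                raise GeometryError("circular section needs a positive diameter")
        else:
            if self.width is None or self.width <= 0:
                raise GeometryError(f"{self.shape} section needs a positive width")
            if self.side_slope < 0:
                raise GeometryError("side slope must be non-negative")

    def area_perimeter(self, depth: float) -> tuple[float, float]:
        """Flow area A (m²) and wetted perimeter P (m) at the given depth."""
        if depth < 0:
            raise GeometryError("depth must be non-negative")
        if self.shape == "rectangular":
            return self.width * depth, self.width + 2.0 * depth
        if self.shape == "trapezoidal":
            a = (self.width + self.side_slope * depth) * depth
            p = self.width + 2.0 * depth * math.hypot(1.0, self.side_slope)
            return a, p
        # circular segment
        d = self.diameter
        if depth >= d:
            raise OverfullError(
                f"depth {depth} m fills the {d} m culvert; pressurized flow "
                "is outside the rating's validity"
            )
        theta = 2.0 * math.acos(1.0 - 2.0 * depth / d)
        area = d * d / 8.0 * (theta - math.sin(theta))
        perim = d * theta / 2.0
        return area, perim


def manning_discharge(geom: ChannelGeometry, depth: float) -> float:
    """Discharge (m³ s⁻¹) through *geom* at the given flow depth (m).

    Implements Q = K·A·R^0.667·S^0.5 / n with R = A/P.  Returns 0 for a dry
    section (depth 0).
    """
    if depth == 0:
        return 0.0
    area, perim = geom.area_perimeter(depth)
    if area == 0.0 or perim == 0.0:
        return 0.0
    radius = area / perim
    return geom.K * area * radius ** MANNING_R_EXPONENT * math.sqrt(geom.slope) / geom.roughness


@dataclass
class RatingCurve:
    """Monotone empirical stage→discharge mapping.

    ``knots`` are the interior spline knots actually used (may be fewer than
    requested if monotonicity required a refit); ``stage_range`` is the
    closed interval of gauged stages over which the curve is valid.
    """

    _spline: LSQUnivariateSpline
    knots: np.ndarray
    stage_range: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)

    def __call__(self, stage: np.ndarray) -> np.ndarray:
        """Evaluate discharge; no validity handling (see :meth:`predict`)."""
        return np.maximum(np.asarray(self._spline(stage), dtype=float), 0.0)

    def predict(self, stage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate discharge and return (values, out_of_range mask)."""
        stage = np.asarray(stage, dtype=float)
        lo, hi = self.stage_range
        with np.errstate(invalid="ignore"):
            out = (stage < lo) | (stage > hi) | ~np.isfinite(stage)
        q = np.full(stage.shape, np.nan)
        ok = ~out
        q[ok] = self(stage[ok])
        return q, out


def _monotone_on(spline, lo: float, hi: float, n: int = 2001) -> bool:
    grid = np.linspace(lo, hi, n)
    dq = np.diff(spline(grid))
    span = float(np.ptp(spline(grid))) or 1.0
    return bool((dq >= -1e-9 * span).all())


def fit_rating_curve(stages, discharges, knots: int = 3) -> RatingCurve:
    """Fit a monotone piecewise cubic-spline rating to gauged pairs.

    Least-squares spline with ``knots`` interior knots at stage quantiles.
    The fitted curve is checked for a non-negative derivative on a dense
    grid; if it decreases anywhere, the fit is repeated with fewer interior
    knots (a rating must be invertible) down to a plain cubic.

    Raises
    ------
    RatingError
        For fewer than ``2 * knots`` pairs (or < 4 pairs overall),
        degenerate all-equal stages, or an irreparably non-monotone fit.
    """
    h = np.asarray(stages, dtype=float)
    q = np.asarray(discharges, dtype=float)
    if h.ndim != 1 or h.shape != q.shape:
        raise RatingError("stages and discharges must be equal-length 1-D arrays")
    if (h < 0).any():
        raise RatingError("stages must be non-negative")
    n_min = max(4, 2 * knots)
    if len(h) < n_min:
        raise RatingError(f"need at least {n_min} gauged pairs, got {len(h)}")
    order = np.argsort(h, kind="stable")
    h, q = h[order], q[order]
    if h[0] == h[-1]:
        raise RatingError("all gaugings at one stage; rating is degenerate")
    # LSQUnivariateSpline needs strictly increasing x: average duplicates.
    hu, inv = np.unique(h, return_inverse=True)
    qu = np.bincount(inv, weights=q) / np.bincount(inv)
    if len(hu) < 4:
        raise RatingError("too few distinct stages for a cubic rating")

    last_err: Exception | None = None
    for k in range(min(knots, len(hu) - 4), -1, -1):
        if k > 0:
            t = np.quantile(hu, np.linspace(0, 1, k + 2)[1:-1])
            t = np.unique(t[(t > hu[0]) & (t < hu[-1])])
        else:
            t = np.array([])
        try:
            spl = LSQUnivariateSpline(hu, qu, t, k=3)
        except Exception as err:  # ill-placed knots at this count
            last_err = err
            continue
        if _monotone_on(spl, hu[0], hu[-1]):
            resid = qu - spl(hu)
            diag = {
                "n_pairs": int(len(h)),
                "interior_knots": int(len(t)),
                "rmse": float(np.sqrt(np.mean(resid ** 2))),
                "max_abs_residual": float(np.max(np.abs(resid))),
            }
            return RatingCurve(spl, np.asarray(t), (float(hu[0]), float(hu[-1])), diag)
    raise RatingError(
        "could not fit a monotone rating even with zero interior knots"
    ) from last_err


def apply_rating(curve: RatingCurve, stage: RegularSeries) -> RegularSeries:
    """Map a stage series through a rating curve, flagging out-of-range stages.

    Samples below/above the gauged stage range become gaps in the output
    (flagged, never extrapolated); timestamps are unchanged.
    """
    if stage.units != UNIT_STAGE:
        raise ValueError(f"expected stage series in '{UNIT_STAGE}', got {stage.units!r}")
    q, out = curve.predict(stage.values)
    q[out] = np.nan
    return stage.copy_with(q, units=UNIT_FLOW)


def rate_with_manning(geom: ChannelGeometry, stage: RegularSeries) -> RegularSeries:
    """Convert a stage series to discharge via Manning's equation."""
    if stage.units != UNIT_STAGE:
        raise ValueError(f"expected stage series in '{UNIT_STAGE}', got {stage.units!r}")
    vals = stage.values
    q = np.full(vals.shape, np.nan)
    for i, d in enumerate(vals):
        if np.isfinite(d):
            q[i] = manning_discharge(geom, float(d))
    return stage.copy_with(q, units=UNIT_FLOW)
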