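"""Before/after(-control-impact) flow-attenuation statistics.

Events are labelled with the study factors (beaver presence, hydrological
season, hydrological year, site role), summarized per site with
Mann–Whitney U tests, and modelled with Gamma GLMs using an identity link:

    peak Q ~ total event rainfall + beaver presence            (additive)
    peak Q ~ rainfall + beaver * season                        (seasonal)
    peak Q ~ rainfall + beaver * site                          (BACI)
    peak Q ~ rainfall + beaver * season * site                 (BACI seasonal)

The Gamma family reflects the right-skewed distribution of event peak
flows; the identity link keeps coefficients on the m³ s⁻¹ scale, so the
beaver term is directly the modelled change in peak flow.  Estimated
marginal means average model predictions over factor cells with *equal*
weight, at the observed mean event rainfall, which makes the before/after
comparison robust to the unbalanced designs field monitoring produces.

Flow-regime flashiness is summarized by the Q5:Q95 ratio (discharge
exceeded 5% of the time over discharge exceeded 95% of the time), and the
analysis of the largest events uses the subset of events whose peaks exceed
the Q5 exceedance threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps

from .series import RegularSeries

SUMMARY_METRICS = ["event_rain_mm", "total_stormflow_m3", "peak_q_m3s", "lag_h"]

MODEL_FORMULAS = {
    "additive": "peak_q_m3s ~ event_rain_mm + beaver",
    "seasonal": "peak_q_m3s ~ event_rain_mm + beaver * season",
    "baci": "peak_q_m3s ~ event_rain_mm + beaver * site_role",
    "baci_seasonal": "peak_q_m3s ~ event_rain_mm + beaver * season * site_role",
}

#: Fixed level orders; the first level is the treatment-contrast reference.
FACTOR_LEVELS = {
    "beaver": ["no", "yes"],
    "season": ["dry", "wet"],
    "site_role": ["control", "impact"],
}


class StatsError(ValueError):
    pass


class GlmConvergenceError(RuntimeError):
    """IRLS failed to converge or produced non-positive fitted means."""


# ---------------------------------------------------------------------------
# study design and labelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteDesign:
    """Role of one monitored site in the before/after design."""

    site: str
    role: str                      # "impact" | "control"
    impact_date: pd.Timestamp | None = None
    control_partner: str | None = None   # impact site whose dates a control inherits

    def __post_init__(self) -> None:
        if self.role not in ("impact", "control"):
            raise StatsError(f"site role must be impact or control, got {self.role!r}")
        if self.role == "impact" and self.impact_date is None:
            raise StatsError(f"impact site {self.site!r} needs an impact date")


@dataclass(frozen=True)
class StudyDesign:
    """Per-site impact dates plus the season and year conventions.

    The wet season is the half-year [1 October, 1 April); the hydrological
    year increments at 1 October (GB convention), so an event on
    2 October 2018 belongs to hydrological year 2019.
    """

    sites: tuple[SiteDesign, ...]

    def __post_init__(self) -> None:
        if len({s.site for s in self.sites}) != len(self.sites):
            raise StatsError("duplicate site ids in study design")

    def site(self, name: str) -> SiteDesign:
        for s in self.sites:
            if s.site == name:
                return s
        raise StatsError(f"site {name!r} not in study design")

    def impact_date_for(self, name: str) -> pd.Timestamp:
        s = self.site(name)
        if s.impact_date is not None:
            d = s.impact_date
        elif s.control_partner is not None:
            d = self.site(s.control_partner).impact_date
        else:
            raise StatsError(
                f"control site {name!r} has no partner impact date to inherit")
        d = pd.Timestamp(d)
        return d.tz_localize("UTC") if d.tz is None else d


def hydrological_year(ts: pd.Timestamp) -> int:
    return ts.year + 1 if ts.month >= 10 else ts.year


def season_of(ts: pd.Timestamp) -> str:
    """'wet' in [1 Oct, 1 Apr), 'dry' otherwise (half-open boundaries)."""
    return "wet" if (ts.month >= 10 or ts.month < 4) else "dry"


def label_events(events: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Add beaver presence, season, hydrological year and site role columns."""
    out = events.copy()
    starts = pd.to_datetime(out["start"])
    impact = out["site"].map(lambda s: design.impact_date_for(s))
    out["beaver"] = pd.Categorical(
        np.where(starts >= impact, "yes", "no"), categories=FACTOR_LEVELS["beaver"])
    out["season"] = pd.Categorical(
        [season_of(t) for t in starts], categories=FACTOR_LEVELS["season"])
    out["hydro_year"] = [hydrological_year(t) for t in starts]
    out["site_role"] = pd.Categorical(
        out["site"].map(lambda s: design.site(s).role),
        categories=FACTOR_LEVELS["site_role"])
    return out


def usable(events: pd.DataFrame) -> pd.DataFrame:
    """Events not manually excluded and not gap-affected."""
    keep = ~events["excluded"].astype(bool) & ~events["gap_affected"].astype(bool)
    return events[keep]


# ---------------------------------------------------------------------------
# nonparametric summaries
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U (of the first sample) and two-sided p.

    Midrank tie handling with the tie-corrected normal approximation and
    continuity correction.  U is oriented so complete separation with every
    x below every y gives U = 0.  If all values across both samples are
    identical the test is vacuous and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return len(x) * len(y) / 2.0, 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    # scipy reports U1 = R1 - n1(n1+1)/2 (large when x tends to exceed y);
    # orient to "number of (x, y) pairs with x > y" which is the same thing.
    return float(res.statistic), float(res.pvalue)


def summarize_events(events: pd.DataFrame) -> pd.DataFrame:
    """Per site × beaver level: n, median and IQR of each event metric,
    with a Mann–Whitney p value per metric comparing before vs after.

    Mirrors the shape of a site-by-site before/after summary table.  Cells
    with fewer than two events report their statistics but skip the test
    (with a warning).
    """
    ev = usable(events)
    rows = []
    for site, g in ev.groupby("site", observed=True):
        pre = g[g["beaver"] == "no"]
        post = g[g["beaver"] == "yes"]
        for level, sub in (("no", pre), ("yes", post)):
            row: dict = {"site": site, "beaver": level, "n": len(sub)}
            for m in SUMMARY_METRICS:
                v = sub[m].dropna()
                row[f"{m}_median"] = float(v.median()) if len(v) else np.nan
                row[f"{m}_iqr"] = float(v.quantile(0.75) - v.quantile(0.25)) if len(v) else np.nan
            rows.append(row)
        for m in SUMMARY_METRICS:
            a, b = pre[m].dropna(), post[m].dropna()
            if len(a) < 2 or len(b) < 2:
                warnings.warn(f"{site}/{m}: group too small for a Mann–Whitney test",
                              stacklevel=2)
                p = np.nan
            else:
                _, p = mann_whitney_u(a, b)
            rows[-2][f"{m}_p"] = p
            rows[-1][f"{m}_p"] = p
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flow-duration statistics
# ---------------------------------------------------------------------------

def exceedance_flow(flow_values: np.ndarray, percent_exceeded: float) -> float:
    """Discharge exceeded `percent_exceeded`% of the time (e.g. 5 → Q5)."""
    v = np.asarray(flow_values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise StatsError("no unmasked flow samples")
    return float(np.percentile(v, 100.0 - percent_exceeded))


def flashiness_ratio(flow: RegularSeries, split: pd.Timestamp) -> dict:
    """Q5:Q95 flashiness index for the periods before and after *split*.

    Returns ``{"before": r, "after": r, "undefined": [...]}``; a period
    with Q95 = 0 has an undefined (infinite) ratio and is flagged rather
    than silently dropped.
    """
    split = pd.Timestamp(split)
    if split.tz is None:
        split = split.tz_localize("UTC")
    out: dict = {"undefined": []}
    for name, sel in (("before", flow.index < split), ("after", flow.index >= split)):
        v = flow.values[sel]
        q5 = exceedance_flow(v, 5.0)
        q95 = exceedance_flow(v, 95.0)
        if q95 == 0:
            out[name] = np.inf
            out["undefined"].append(name)
        else:
            out[name] = q5 / q95
    return out


def q5_subset(events: pd.DataFrame, flows: dict[str, RegularSeries],
              percent_exceeded: float = 5.0, combined_record: bool = True,
              design: StudyDesign | None = None) -> pd.DataFrame:
    """Keep events whose peak discharge exceeds the site's Q5 flow.

    The threshold is computed from each site's full flow record (both
    periods combined), so it is period-neutral; set
    ``combined_record=False`` (with a design) to use the pre-impact record
    only.
    """
    kept = []
    for site, g in events.groupby("site", observed=True):
        flow = flows[site]
        v = flow.values
        if not combined_record:
            if design is None:
                raise StatsError("pre-period thresholds need the study design")
            v = v[flow.index < design.impact_date_for(site)]
        thr = exceedance_flow(v, percent_exceeded)
        kept.append(g[g["peak_q_m3s"] > thr])
    if not kept:
        return events.iloc[0:0]
    out = pd.concat(kept).sort_index()
    if len(out) == 0:
        warnings.warn("Q5 subset is empty; downstream models will be skipped",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Gamma identity-link GLM (IRLS with step-halving)
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    """A fitted Gamma identity-link GLM.

    ``cov`` is the dispersion-scaled coefficient covariance
    φ·(XᵀWX)⁻¹ with IRLS weights W = 1/μ²; ``dispersion`` is the Pearson
    χ²/df estimate.  ``summary()`` tabulates estimates, standard errors,
    Wald z statistics and two-sided p values.
    """

    model_name: str
    formula: str
    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    deviance: float
    n_obs: int
    n_iter: int
    design_info: object
    covariate_means: dict
    factor_levels: dict
    cell_counts: pd.Series
    loglik: float = np.nan
    notes: dict = field(default_factory=dict)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        se = self.bse
        z = self.params / se
        p = 2.0 * sps.norm.sf(np.abs(z))
        return pd.DataFrame({"estimate": self.params, "se": se, "z": z, "p": p})

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        (X,) = patsy.build_design_matrices([self.design_info], newdata)
        return np.asarray(X) @ self.params.to_numpy()


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))


def _irls_gamma_identity(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                         tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, int]:
    """IRLS for a Gamma GLM with identity link.

    For the identity link the working response is y itself, so each
    iteration is a weighted least squares of y on X with weights 1/μ².
    Step-halving keeps every fitted mean strictly positive and the deviance
    non-increasing.
    """
    n, p = X.shape
    floor = 1e-6 * max(np.median(y), 1e-12)
    # feasible start: OLS if it stays positive, else intercept-only mean
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu = X @ beta
    if np.any(mu <= floor):
        beta = np.linalg.lstsq(X, np.full(n, y.mean()), rcond=None)[0]
        mu = X @ beta
        if np.any(mu <= floor):
            mu = np.maximum(X @ beta, floor)
            beta = np.linalg.lstsq(X, mu, rcond=None)[0]
            mu = np.maximum(X @ beta, floor)
    dev = _gamma_deviance(y, np.maximum(mu, floor))
    it = 0
    for it in range(1, max_iter + 1):
        w = 1.0 / np.maximum(mu, floor) ** 2
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        step = beta_new - beta
        # step-halving: positivity first, then non-increasing deviance
        lam = 1.0
        for _ in range(60):
            cand = beta + lam * step
            mu_c = X @ cand
            if np.all(mu_c > 0):
                dev_c = _gamma_deviance(y, mu_c)
                if dev_c <= dev + 1e-12 * (abs(dev) + 1.0):
                    break
            lam *= 0.5
        else:
            raise GlmConvergenceError(
                "step-halving could not keep fitted means positive; "
                "review the data/model (identity-link Gamma validity)")
        beta, mu, dev_prev, dev = cand, mu_c, dev, dev_c
        if abs(dev_prev - dev) < tol * (abs(dev) + 1.0) and np.max(np.abs(lam * step)) < 1e-8 * (
                1.0 + np.max(np.abs(beta))):
            break
    if np.any(mu <= 0):
        raise GlmConvergenceError("non-positive fitted means at convergence")
    return beta, mu, it


def fit_peakflow_glm(events: pd.DataFrame, model: str = "additive",
                     response: str = "peak_q_m3s") -> GlmFit:
    """Fit one of the peak-flow models to a labelled event table.

    ``model`` is one of ``additive``, ``seasonal``, ``baci``,
    ``baci_seasonal`` (see :data:`MODEL_FORMULAS`).  Factors use treatment
    contrasts with before-beaver / dry-season / control-site reference
    levels, so the beaver coefficient is directly the modelled change in
    peak flow (m³ s⁻¹).
    """
    if model not in MODEL_FORMULAS:
        raise StatsError(f"unknown model {model!r}; choose from {sorted(MODEL_FORMULAS)}")
    formula = MODEL_FORMULAS[model].replace("peak_q_m3s", response, 1)
    data = usable(events).dropna(subset=[response, "event_rain_mm"])
    if (data[response] <= 0).any():
        raise StatsError("Gamma response requires strictly positive peak flows")
    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    X = np.asarray(X_dm)
    y = np.asarray(y_dm).ravel()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("design matrix is rank deficient (empty factor cells?)")
    beta, mu, it = _irls_gamma_identity(X, y)
    n, p = X.shape
    pearson = float(np.sum(((y - mu) / mu) ** 2))
    dispersion = pearson / (n - p)
    w = 1.0 / mu ** 2
    cov = dispersion * np.linalg.inv(X.T @ (X * w[:, None]))
    names = X_dm.design_info.column_names
    # Gamma log-likelihood at the MLE of the shape given mu (moment shape 1/φ)
    shape = 1.0 / dispersion
    loglik = float(np.sum(sps.gamma.logpdf(y, a=shape, scale=mu / shape)))
    factors = [c for c in ("beaver", "season", "site_role") if c in formula]
    cells = data.groupby(factors, observed=False).size() if factors else pd.Series(dtype=int)
    return GlmFit(
        model_name=model,
        formula=formula,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        dispersion=dispersion,
        deviance=_gamma_deviance(y, mu),
        n_obs=n,
        n_iter=it,
        design_info=X_dm.design_info,
        covariate_means={"event_rain_mm": float(data["event_rain_mm"].mean())},
        factor_levels={f: list(FACTOR_LEVELS[f]) for f in factors},
        cell_counts=cells,
        loglik=loglik,
    )


# ---------------------------------------------------------------------------
# estimated marginal means
# ---------------------------------------------------------------------------

def _reference_grid(fit: GlmFit) -> pd.DataFrame:
    combos = list(itertools.product(*fit.factor_levels.values()))
    grid = pd.DataFrame(combos, columns=list(fit.factor_levels))
    for f, levels in fit.factor_levels.items():
        grid[f] = pd.Categorical(grid[f], categories=levels)
    for cov, val in fit.covariate_means.items():
        grid[cov] = val
    return grid


def marginal_means(fit: GlmFit, factors: list[str] | None = None) -> pd.DataFrame:
    """Equal-weight estimated marginal means with standard errors.

    Predictions are taken on a reference grid — every combination of the
    model's factor levels, with event rainfall fixed at its observed mean —
    and the emmean for each combination of the requested ``factors`` is the
    *unweighted* average of predictions over the other factors' levels.
    With the identity link the emmean is a linear form Lβ, so its standard
    error √(L Σ Lᵀ) is exact.  Combinations with no observed events are
    still predicted (model-based) but flagged ``empty_cell``.
    """
    factors = factors or list(fit.factor_levels)
    unknown = set(factors) - set(fit.factor_levels)
    if unknown:
        raise StatsError(f"factors {sorted(unknown)} are not in the model")
    grid = _reference_grid(fit)
    (Xg,) = patsy.build_design_matrices([fit.design_info], grid)
    Xg = np.asarray(Xg)
    beta = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    rows = []
    for combo, sub in grid.groupby(factors, observed=True, sort=False):
        combo = combo if isinstance(combo, tuple) else (combo,)
        L = Xg[sub.index.to_numpy()].mean(axis=0)
        emm = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        row = dict(zip(factors, combo))
        row.update({"emmean": emm, "se": se,
                    **{c: v for c, v in fit.covariate_means.items()}})
        if len(fit.cell_counts):
            try:
                counts = fit.cell_counts
                for f in factors:
                    counts = counts.xs(row[f], level=f) if counts.index.nlevels > 1 \
                        else counts.loc[[row[f]]]
                row["empty_cell"] = bool((np.asarray(counts) == 0).any())
            except KeyError:
                row["empty_cell"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def emmean_contrast(fit: GlmFit, factor: str, level_a: str, level_b: str,
                    by: dict | None = None) -> tuple[float, float]:
    """Difference of emmeans ``level_a − level_b`` of *factor* with its SE.

    ``by`` optionally conditions on levels of other factors (e.g. the
    impact site only in a BACI model); remaining factors are averaged with
    equal weight.  Returns ``(estimate, se)``.
    """
    grid = _reference_grid(fit)
    (Xg,) = patsy.build_design_matrices([fit.design_info], grid)
    Xg = np.asarray(Xg)
    sel = np.ones(len(grid), dtype=bool)
    for f, lev in (by or {}).items():
        sel &= np.asarray(grid[f] == lev)
    La = Xg[sel & np.asarray(grid[factor] == level_a)].mean(axis=0)
    Lb = Xg[sel & np.asarray(grid[factor] == level_b)].mean(axis=0)
    L = La - Lb
    est = float(L @ fit.params.to_numpy())
    se = float(np.sqrt(L @ fit.cov.to_numpy() @ L))
    return est, se


def baci_contrast(fit: GlmFit) -> tuple[float, float]:
    """Difference-in-differences of emmeans: (after−before at the impact
    site) − (after−before at the control site), other factors averaged with
    equal weight.  Negative values indicate attenuation attributable to the
    impact.  Returns ``(estimate, se)``."""
    grid = _reference_grid(fit)
    (Xg,) = patsy.build_design_matrices([fit.design_info], grid)
    Xg = np.asarray(Xg)

    def lvec(beaver: str, role: str) -> np.ndarray:
        sel = np.asarray(grid["beaver"] == beaver) & np.asarray(grid["site_role"] == role)
        return Xg[sel].mean(axis=0)

    L = (lvec("yes", "impact") - lvec("no", "impact")) \
        - (lvec("yes", "control") - lvec("no", "control"))
    est = float(L @ fit.params.to_numpy())
    se = float(np.sqrt(L @ fit.cov.to_numpy() @ L))
    return est, se
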