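"""Labelling, nonparametric summaries, Gamma GLM and marginal means."""

import itertools
import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import stormflow as sf
from stormflow.stats import (FACTOR_LEVELS, GlmConvergenceError, StatsError,
                             exceedance_flow, hydrological_year, season_of)


def design_one_site():
    return sf.StudyDesign(sites=(
        sf.SiteDesign("s1", "impact", impact_date=pd.Timestamp("2018-06-01")),
    ))


def event_frame(n, rng, site="s1", start="2017-01-01", peak=None, rain=None,
                freq="5D"):
    starts = pd.date_range(start, periods=n, freq=freq, tz="UTC")
    return pd.DataFrame({
        "event_id": [f"{site}-{i:04d}" for i in range(n)],
        "site": site,
        "start": starts,
        "end": starts + pd.Timedelta("6h"),
        "event_rain_mm": rain if rain is not None else rng.gamma(2, 5, n),
        "total_stormflow_m3": rng.gamma(2, 5000, n),
        "peak_q_m3s": peak if peak is not None else rng.gamma(4, 0.1, n),
        "lag_h": rng.gamma(3, 1, n),
        "gap_affected": False,
        "excluded": False,
    })


class TestLabelling:
    def test_mid_december_is_wet_season(self):
        assert season_of(pd.Timestamp("2018-12-15")) == "wet"

    def test_first_of_april_is_dry_half_open(self):
        assert season_of(pd.Timestamp("2018-04-01 00:00")) == "dry"
        assert season_of(pd.Timestamp("2018-03-31 23:45")) == "wet"

    def test_october_second_belongs_to_next_hydro_year(self):
        assert hydrological_year(pd.Timestamp("2018-10-02")) == 2019
        assert hydrological_year(pd.Timestamp("2018-09-30")) == 2018

    def test_beaver_presence_from_impact_date(self, rng):
        ev = event_frame(10, rng, start="2018-05-20", freq="5D")
        out = sf.label_events(ev, design_one_site())
        expected = (ev["start"] >= pd.Timestamp("2018-06-01", tz="UTC"))
        assert (out["beaver"] == "yes").tolist() == expected.tolist()

    def test_control_site_inherits_partner_impact_date(self, rng):
        design = sf.StudyDesign(sites=(
            sf.SiteDesign("imp", "impact", impact_date=pd.Timestamp("2018-06-01")),
            sf.SiteDesign("ctl", "control", control_partner="imp"),
        ))
        # starts: 20 May, 30 May, 9 Jun, 19 Jun → two at/after the 1 Jun impact
        ev = event_frame(4, rng, site="ctl", start="2018-05-20", freq="10D")
        out = sf.label_events(ev, design)
        assert out["site_role"].unique().tolist() == ["control"]
        assert (out["beaver"] == "yes").sum() == 2


class TestMannWhitney:
    def test_identical_samples_give_half_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = sf.mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2
        assert p > 0.9

    def test_complete_separation(self):
        u, p = sf.mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_all_identical_values_p_is_one(self):
        u, p = sf.mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_matches_exhaustive_permutation(self, rng):
        """Asymptotic two-sided p vs exact permutation enumeration (n ≤ 8)."""
        def exact_p(x, y):
            pooled = np.concatenate([x, y])
            n1 = len(x)
            ranks = pd.Series(pooled).rank().to_numpy()

            def u_of(idx):
                r1 = ranks[list(idx)].sum()
                return r1 - n1 * (n1 + 1) / 2

            u_obs = u_of(range(n1))
            centre = n1 * len(y) / 2
            dev = abs(u_obs - centre)
            us = [abs(u_of(c) - centre) >= dev - 1e-9
                  for c in itertools.combinations(range(len(pooled)), n1)]
            return np.mean(us)

        for _ in range(12):
            x = rng.integers(0, 12, 6).astype(float)
            y = rng.integers(0, 12, 7).astype(float) + rng.integers(0, 4)
            _, p_asym = sf.mann_whitney_u(x, y)
            assert abs(p_asym - exact_p(x, y)) < 0.06


class TestSummaries:
    def test_identical_groups_identical_medians(self, rng):
        pre = event_frame(20, rng, start="2017-01-01", freq="7D")
        post = pre.copy()
        post["start"] = post["start"] + pd.Timedelta(days=540)
        post["event_id"] = [f"s1-9{i:03d}" for i in range(len(post))]
        ev = sf.label_events(pd.concat([pre, post], ignore_index=True),
                             design_one_site())
        out = sf.summarize_events(ev)
        a, b = out[out["beaver"] == "no"].iloc[0], out[out["beaver"] == "yes"].iloc[0]
        assert a["peak_q_m3s_median"] == b["peak_q_m3s_median"]
        assert a["peak_q_m3s_p"] > 0.9

    def test_halved_peaks_halve_the_median(self, rng):
        pre = event_frame(30, rng, start="2017-01-01", freq="7D")
        post = pre.copy()
        post["start"] = post["start"] + pd.Timedelta(days=600)
        post["peak_q_m3s"] = post["peak_q_m3s"] * 0.5
        ev = sf.label_events(pd.concat([pre, post], ignore_index=True),
                             design_one_site())
        out = sf.summarize_events(ev)
        a = float(out.loc[out["beaver"] == "no", "peak_q_m3s_median"].iloc[0])
        b = float(out.loc[out["beaver"] == "yes", "peak_q_m3s_median"].iloc[0])
        assert b == pytest.approx(a / 2)

    def test_tiny_cell_skips_test_with_warning(self, rng):
        pre = event_frame(10, rng, start="2017-01-01", freq="10D")
        post = event_frame(1, rng, start="2018-07-01")
        post["event_id"] = ["s1-9999"]
        ev = sf.label_events(pd.concat([pre, post], ignore_index=True),
                             design_one_site())
        with pytest.warns(UserWarning, match="too small"):
            out = sf.summarize_events(ev)
        assert np.isnan(out["peak_q_m3s_p"]).all()


class TestFlashiness:
    def test_constant_flow_ratio_one(self):
        flow = sf.make_series("2018-01-01", np.full(400, 0.3), "m3s")
        r = sf.flashiness_ratio(flow, flow.index[200])
        assert r["before"] == pytest.approx(1.0)
        assert r["after"] == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        vals = rng.gamma(2, 0.2, 600)
        f1 = sf.make_series("2018-01-01", vals, "m3s")
        f2 = sf.make_series("2018-01-01", vals * 7.3, "m3s")
        split = f1.index[300]
        r1, r2 = sf.flashiness_ratio(f1, split), sf.flashiness_ratio(f2, split)
        assert r1["before"] == pytest.approx(r2["before"], rel=1e-12)
        assert r1["after"] == pytest.approx(r2["after"], rel=1e-12)

    def test_matches_sorting_oracle(self, rng):
        vals = rng.gamma(1.5, 0.5, 1000)
        flow = sf.make_series("2018-01-01", vals, "m3s")
        split = flow.index[400]
        r = sf.flashiness_ratio(flow, split)
        for name, v in (("before", np.sort(vals[:400])), ("after", np.sort(vals[400:]))):
            q5 = np.percentile(v, 95)
            q95 = np.percentile(v, 5)
            assert r[name] == pytest.approx(q5 / q95, rel=1e-12)

    def test_zero_q95_flagged_infinite(self):
        vals = np.concatenate([np.zeros(200), np.ones(100)])
        flow = sf.make_series("2018-01-01", vals, "m3s")
        r = sf.flashiness_ratio(flow, flow.index[150])
        assert np.isinf(r["before"])
        assert "before" in r["undefined"]


class TestQ5Subset:
    def _events_with_planted_peaks(self, rng):
        flow_vals = rng.gamma(2, 0.1, 2000)
        flow = sf.make_series("2017-01-01", flow_vals, "m3s")
        thr = exceedance_flow(flow_vals, 5.0)
        peaks = np.concatenate([np.linspace(thr * 1.05, thr * 2, 5),
                                np.linspace(thr * 0.2, thr * 0.95, 15)])
        ev = event_frame(20, rng, peak=peaks)
        return ev, flow, thr

    def test_planted_top_events_survive(self, rng):
        ev, flow, thr = self._events_with_planted_peaks(rng)
        out = sf.q5_subset(ev, {"s1": flow})
        assert set(out.index) == set(range(5))

    def test_all_below_threshold_gives_empty(self, rng):
        ev, flow, thr = self._events_with_planted_peaks(rng)
        ev["peak_q_m3s"] = thr * 0.5
        with pytest.warns(UserWarning, match="empty"):
            out = sf.q5_subset(ev, {"s1": flow})
        assert len(out) == 0

    def test_stricter_percentile_never_grows_subset(self, rng):
        ev, flow, _ = self._events_with_planted_peaks(rng)
        n5 = len(sf.q5_subset(ev, {"s1": flow}, percent_exceeded=5.0))
        n1 = len(sf.q5_subset(ev, {"s1": flow}, percent_exceeded=1.0))
        assert n1 <= n5


def make_glm_data(rng, n=200, beaver_effect=-0.15, noise_shape=None):
    rain = rng.gamma(2, 5, n)
    beaver = pd.Categorical(rng.choice(["no", "yes"], n), FACTOR_LEVELS["beaver"])
    mu = 0.3 + 0.02 * rain + np.where(np.asarray(beaver) == "yes", beaver_effect, 0)
    y = mu if noise_shape is None else rng.gamma(noise_shape, mu / noise_shape)
    return pd.DataFrame({"peak_q_m3s": y, "event_rain_mm": rain, "beaver": beaver,
                         "gap_affected": False, "excluded": False})


class TestGammaGlm:
    def test_noiseless_data_recovered_exactly(self, rng):
        df = make_glm_data(rng, beaver_effect=-0.05)
        fit = sf.fit_peakflow_glm(df, "additive")
        assert fit.params["Intercept"] == pytest.approx(0.3, abs=1e-6)
        assert fit.params["event_rain_mm"] == pytest.approx(0.02, abs=1e-8)
        assert fit.params["beaver[T.yes]"] == pytest.approx(-0.05, abs=1e-6)

    def test_matches_statsmodels_irls(self, rng):
        import statsmodels.api as sm
        df = make_glm_data(rng, n=300, noise_shape=5.0)
        fit = sf.fit_peakflow_glm(df, "additive")
        X = pd.DataFrame({
            "Intercept": 1.0,
            "beaver[T.yes]": (df["beaver"] == "yes").astype(float),
            "event_rain_mm": df["event_rain_mm"]})
        ref = sm.GLM(df["peak_q_m3s"], X,
                     family=sm.families.Gamma(sm.families.links.Identity())
                     ).fit(start_params=fit.params[X.columns].to_numpy())
        for name in X.columns:
            assert fit.params[name] == pytest.approx(ref.params[name], abs=1e-6)
            assert fit.bse[name] == pytest.approx(ref.bse[name], rel=1e-4)

    def test_gamma_monte_carlo_recovery_within_2se(self):
        hits = 0
        n_rep = 200
        for k in range(n_rep):
            r = np.random.default_rng(10_000 + k)
            df = make_glm_data(r, n=300, beaver_effect=-0.2, noise_shape=5.0)
            # ensure positivity of responses for the Gamma model
            df = df[df["peak_q_m3s"] > 0]
            fit = sf.fit_peakflow_glm(df, "additive")
            est, se = fit.params["beaver[T.yes]"], fit.bse["beaver[T.yes]"]
            hits += abs(est - (-0.2)) <= 2 * se
        assert hits / n_rep >= 0.90

    def test_non_positive_response_rejected(self, rng):
        df = make_glm_data(rng)
        df.loc[df.index[0], "peak_q_m3s"] = 0.0
        with pytest.raises(StatsError, match="positive"):
            sf.fit_peakflow_glm(df, "additive")

    def test_unknown_model_rejected(self, rng):
        with pytest.raises(StatsError, match="unknown model"):
            sf.fit_peakflow_glm(make_glm_data(rng), "cubic")

    def test_constant_shift_moves_only_intercept(self, rng):
        df = make_glm_data(rng, n=250, noise_shape=8.0)
        fit1 = sf.fit_peakflow_glm(df, "additive")
        df2 = df.copy()
        df2["peak_q_m3s"] = df2["peak_q_m3s"] + 1.0
        fit2 = sf.fit_peakflow_glm(df2, "additive")
        assert fit2.params["Intercept"] - fit1.params["Intercept"] == pytest.approx(1.0, abs=5e-3)
        assert fit2.params["event_rain_mm"] == pytest.approx(fit1.params["event_rain_mm"], abs=5e-4)
        emm1 = sf.marginal_means(fit1)
        emm2 = sf.marginal_means(fit2)
        np.testing.assert_allclose(emm2["emmean"], emm1["emmean"] + 1.0, atol=2e-2)


class TestMarginalMeans:
    def test_additive_difference_equals_beaver_coefficient(self, rng):
        df = make_glm_data(rng, n=240, noise_shape=6.0)
        fit = sf.fit_peakflow_glm(df, "additive")
        emm = sf.marginal_means(fit, ["beaver"]).set_index("beaver")
        diff = emm.loc["yes", "emmean"] - emm.loc["no", "emmean"]
        assert diff == pytest.approx(fit.params["beaver[T.yes]"], abs=1e-12)

    def test_cell_only_model_emmeans_equal_raw_means(self, rng):
        # with no covariate, the Gamma identity-link MLE of each cell mean
        # is the arithmetic mean, so emmeans reduce to raw group means
        from stormflow.stats import _irls_gamma_identity
        n = 120
        group = np.repeat([0, 1], n // 2)
        y = np.where(group == 1, 0.4, 0.7) * rng.gamma(50, 1 / 50, n)
        X = np.column_stack([np.ones(n), group.astype(float)])
        beta, mu, _ = _irls_gamma_identity(X, y)
        assert beta[0] == pytest.approx(y[group == 0].mean(), rel=1e-8)
        assert beta[0] + beta[1] == pytest.approx(y[group == 1].mean(), rel=1e-8)

    def test_unbalanced_2x2_matches_hand_computation(self):
        """Hand-computed reference grid on an unbalanced 2×2 design."""
        rows = []
        rng = np.random.default_rng(7)
        for (b, s), n in {("no", "dry"): 12, ("no", "wet"): 4,
                          ("yes", "dry"): 6, ("yes", "wet"): 18}.items():
            rain = rng.gamma(2, 5, n)
            mu = (0.2 + 0.03 * rain + (-0.05 if b == "yes" else 0)
                  + (0.1 if s == "wet" else 0)
                  + (-0.08 if (b == "yes" and s == "wet") else 0))
            for r, m in zip(rain, mu):
                rows.append({"peak_q_m3s": m, "event_rain_mm": r, "beaver": b,
                             "season": s, "gap_affected": False, "excluded": False})
        df = pd.DataFrame(rows)
        df["beaver"] = pd.Categorical(df["beaver"], FACTOR_LEVELS["beaver"])
        df["season"] = pd.Categorical(df["season"], FACTOR_LEVELS["season"])
        fit = sf.fit_peakflow_glm(df, "seasonal")
        b = fit.params
        rbar = df["event_rain_mm"].mean()
        # predictions at the covariate mean, averaged equally over seasons
        pred = {}
        for bv in ("no", "yes"):
            cells = []
            for sv in ("dry", "wet"):
                eta = (b["Intercept"] + b["event_rain_mm"] * rbar
                       + (b["beaver[T.yes]"] if bv == "yes" else 0)
                       + (b["season[T.wet]"] if sv == "wet" else 0)
                       + (b["beaver[T.yes]:season[T.wet]"]
                          if bv == "yes" and sv == "wet" else 0))
                cells.append(eta)
            pred[bv] = np.mean(cells)
        emm = sf.marginal_means(fit, ["beaver"]).set_index("beaver")
        for bv in ("no", "yes"):
            assert emm.loc[bv, "emmean"] == pytest.approx(pred[bv], abs=1e-10)

    def test_empty_cell_still_predicted_but_flagged(self, rng):
        df = make_glm_data(rng, n=120, noise_shape=6.0)
        starts = pd.date_range("2017-01-01", periods=len(df), freq="3D", tz="UTC")
        df["season"] = pd.Categorical(
            [season_of(t) for t in starts], FACTOR_LEVELS["season"])
        # remove one cell entirely but keep the model additive so it stays estimable
        df = df[~((df["beaver"] == "yes") & (df["season"] == "wet"))]
        formula_df = df.copy()
        fit = sf.fit_peakflow_glm(formula_df, "additive")
        fit.factor_levels["season"] = list(FACTOR_LEVELS["season"])
        emm = sf.marginal_means(fit, ["beaver", "season"])
        assert len(emm) == 4


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R not available for the cross-check")
class TestAgainstREmmeans:
    def test_glm_and_emmeans_match_r(self, tmp_path, rng):
        """Independent oracle: R glm(Gamma, identity) + the emmeans package."""
        n = 160
        rain = rng.gamma(2, 5, n)
        beaver = np.repeat(["no", "yes"], n // 2)
        season = np.tile(["dry", "wet"], n // 2)
        mu = 0.2 + 0.05 * rain + np.where(beaver == "yes", -0.15, 0.0) * \
            np.where(season == "wet", 1.0, 0.3)
        y = rng.gamma(6, mu / 6)
        df = pd.DataFrame({"peak_q_m3s": y, "event_rain_mm": rain,
                           "beaver": pd.Categorical(beaver, FACTOR_LEVELS["beaver"]),
                           "season": pd.Categorical(season, FACTOR_LEVELS["season"]),
                           "gap_affected": False, "excluded": False})
        fit = sf.fit_peakflow_glm(df, "seasonal")
        emm = sf.marginal_means(fit, ["beaver"]).set_index("beaver")

        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        r_code = f"""
        suppressMessages(library(emmeans))
        d <- read.csv("{csv}")
        d$beaver <- factor(d$beaver, levels=c("no","yes"))
        d$season <- factor(d$season, levels=c("dry","wet"))
        start <- coef(lm(peak_q_m3s ~ event_rain_mm + beaver*season, data=d))
        m <- glm(peak_q_m3s ~ event_rain_mm + beaver*season, data=d,
                 family=Gamma(link="identity"), start=start)
        e <- summary(emmeans(m, "beaver"))
        co <- summary(m)$coefficients
        cat(jsonlite::toJSON(list(terms=rownames(co), coef=as.numeric(co[,1]),
            se=as.numeric(co[,2]), emm=e$emmean, emm_se=e$SE), digits=12))
        """
        res = subprocess.run(["Rscript", "-e", r_code],
                             capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        out = json.loads(res.stdout)
        r_coef = dict(zip(out["terms"], out["coef"]))
        r_se = dict(zip(out["terms"], out["se"]))
        name_map = {"(Intercept)": "Intercept", "event_rain_mm": "event_rain_mm",
                    "beaveryes": "beaver[T.yes]", "seasonwet": "season[T.wet]",
                    "beaveryes:seasonwet": "beaver[T.yes]:season[T.wet]"}
        for r_name, py_name in name_map.items():
            assert fit.params[py_name] == pytest.approx(r_coef[r_name], abs=1e-5)
            assert fit.bse[py_name] == pytest.approx(r_se[r_name], rel=1e-3)
        np.testing.assert_allclose(emm["emmean"].to_numpy(), out["emm"], atol=1e-5)
        np.testing.assert_allclose(emm["se"].to_numpy(), out["emm_se"], rtol=1e-3)
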