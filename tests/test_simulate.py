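"""Synthetic data generator: exposure moments, event mechanism, true effects."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import heatsynergy as hs
from heatsynergy.simulate import RareOutcomeWarning
from heatsynergy.windows import windowed_exposures


def test_zero_noise_exposures_follow_the_sinusoid_exactly():
    dgp = hs.ExposureDGP(temp_sd=0.0, pm_log_sd=0.0, n_areas=2)
    out = hs.generate_exposures(dgp, seed=0)
    doy = pd.DatetimeIndex(out["date"]).dayofyear.to_numpy()
    np.testing.assert_allclose(out["tmax"], dgp.seasonal_mean(doy), rtol=0, atol=1e-12)
    np.testing.assert_allclose(out["pm25"], math.exp(dgp.pm_log_mean), rtol=0, atol=1e-12)


def test_temperature_pm_correlation_zero_when_configured_zero():
    dgp = hs.ExposureDGP(
        temp_pm_corr=0.0, n_areas=50, date_range=("2000-01-01", "2006-12-31")
    )
    out = hs.generate_exposures(dgp, seed=42)
    doy = pd.DatetimeIndex(out["date"]).dayofyear.to_numpy()
    dev = out["tmax"].to_numpy() - dgp.seasonal_mean(doy)
    corr = np.corrcoef(dev, np.log(out["pm25"]))[0, 1]
    assert abs(corr) < 0.02


def test_positive_correlation_recovered():
    dgp = hs.ExposureDGP(n_areas=30, date_range=("2010-01-01", "2013-12-31"))
    out = hs.generate_exposures(dgp, seed=9)
    doy = pd.DatetimeIndex(out["date"]).dayofyear.to_numpy()
    dev = out["tmax"].to_numpy() - dgp.seasonal_mean(doy)
    corr = np.corrcoef(dev, np.log(out["pm25"]))[0, 1]
    assert corr == pytest.approx(dgp.temp_pm_corr, abs=0.03)


def test_default_warm_season_temperature_moments():
    """Pooled warm-season tmax moments match the configured emulation target
    (mean 29.2 °C, SD 5.0 °C) over more than 10^5 area-days."""
    dgp = hs.ExposureDGP(n_areas=100, date_range=("2008-01-01", "2016-12-31"))
    out = hs.generate_exposures(dgp, seed=5)
    warm = out[pd.DatetimeIndex(out["date"]).month.isin([6, 7, 8, 9])]
    assert len(warm) >= 100_000
    assert warm["tmax"].mean() == pytest.approx(29.2, abs=0.2)
    assert warm["tmax"].std() == pytest.approx(5.0, abs=0.2)


def test_default_trimmed_pm_moments_roughly_match_study():
    dgp = hs.ExposureDGP(n_areas=50, date_range=("2010-01-01", "2013-12-31"))
    out = hs.generate_exposures(dgp, seed=6)
    win = windowed_exposures(out).dropna()
    warm = win[pd.DatetimeIndex(win["date"]).month.isin([6, 7, 8, 9])]
    pm3 = warm["pm25_w"].to_numpy()
    kept = pm3[pm3 <= np.quantile(pm3, 0.95)]
    assert kept.mean() == pytest.approx(9.4, abs=0.5)
    assert kept.std() == pytest.approx(3.7, abs=0.5)


def test_exposure_series_contiguous_and_unique():
    dgp = hs.ExposureDGP(n_areas=3)
    out = hs.generate_exposures(dgp, seed=1)
    assert not out.duplicated(["area_id", "date"]).any()
    assert (out["pm25"] > 0).all()
    for _, grp in out.groupby("area_id"):
        d = pd.DatetimeIndex(grp["date"])
        assert (np.diff(d.to_numpy()) == np.timedelta64(1, "D")).all()


def test_invalid_configurations_rejected():
    with pytest.raises(ValueError):
        hs.ExposureDGP(n_areas=0)
    with pytest.raises(ValueError):
        hs.ExposureDGP(date_range=("2016-09-30", "2016-05-30"))
    with pytest.raises(ValueError):
        hs.ExposureDGP(ar_coef=1.0)
    with pytest.raises(ValueError):
        hs.ExposureDGP(temp_pm_corr=1.0)


def test_generators_are_reproducible():
    dgp = hs.ExposureDGP(n_areas=4)
    a = hs.generate_exposures(dgp, seed=3)
    b = hs.generate_exposures(dgp, seed=3)
    pd.testing.assert_frame_equal(a, b)
    ev_a = hs.generate_events(a, hs.HazardDGP(), 500, seed=4)
    ev_b = hs.generate_events(b, hs.HazardDGP(), 500, seed=4)
    pd.testing.assert_frame_equal(ev_a, ev_b)


def test_degenerate_hazard_produces_no_events(tiny_exposures):
    ev = hs.generate_events(
        tiny_exposures, hs.HazardDGP(alpha=-50.0), n_persons=200, seed=0
    )
    assert ev.empty


def test_first_event_rule_no_person_twice():
    dgp = hs.ExposureDGP(n_areas=5)
    exposures = hs.generate_exposures(dgp, seed=8)
    # strong hazard: most persons would have several events without the rule
    ev = hs.generate_events(exposures, hs.HazardDGP(alpha=-3.0), 500, seed=9)
    assert ev["person_id"].is_unique
    assert len(ev) > 400


def test_common_hazard_warns_when_outcome_not_rare(tiny_exposures):
    with pytest.warns(RareOutcomeWarning):
        hs.generate_events(tiny_exposures, hs.HazardDGP(alpha=2.0), 50, seed=0)


def test_null_hazard_event_rate_matches_alpha():
    """With all effects zero the per person-day hazard is exactly
    expit(alpha); the empirical rate (events over person-days at risk)
    must sit within 3 Monte-Carlo SEs."""
    rate = 0.001
    dgp = hs.ExposureDGP(n_areas=10)
    exposures = hs.generate_exposures(dgp, seed=21)
    hz = hs.HazardDGP(alpha=float(logit(rate)), beta_T=0, beta_P=0, beta_TP=0)
    n_persons = 20_000
    ev = hs.generate_events(exposures, hz, n_persons, seed=22)

    n_days = windowed_exposures(exposures).dropna()["date"].nunique()
    dates = pd.date_range(*dgp.date_range)
    first_valid = dates[len(dates) - n_days]
    # person-days at risk under the first-event (geometric) mechanism
    days_to_event = np.asarray((pd.DatetimeIndex(ev["admission_date"]) - first_valid).days) + 1
    at_risk = days_to_event.sum() + (n_persons - len(ev)) * n_days
    est = len(ev) / at_risk
    se = math.sqrt(rate * (1 - rate) / at_risk)
    assert abs(est - rate) < 3 * se


def test_temperature_effect_frequency_ratio():
    """beta_T = 0.05/°C and nothing else: the per person-day event rate on
    ~35 °C days over ~25 °C days is exp(0.5) up to Monte-Carlo error. The
    hazard is kept rare and the at-risk denominator is corrected for the
    persons already removed by the first-event rule."""
    dgp = hs.ExposureDGP(n_areas=30)
    exposures = hs.generate_exposures(dgp, seed=31)
    hz = hs.HazardDGP(alpha=float(logit(2e-4)), beta_T=0.05, beta_P=0, beta_TP=0)
    n_persons = 150_000
    ev = hs.generate_events(exposures, hz, n_persons, seed=32)

    win = windowed_exposures(exposures).dropna()
    counts = (
        ev.groupby(["area_id", "admission_date"]).size().rename("events").reset_index()
    )
    win = win.merge(
        counts,
        left_on=["area_id", "date"],
        right_on=["area_id", "admission_date"],
        how="left",
    ).fillna({"events": 0})
    # expected persons still at risk in the area on each day: uniform
    # assignment minus the area's earlier events
    win = win.sort_values(["area_id", "date"])
    prior_events = win.groupby("area_id")["events"].cumsum() - win["events"]
    win["at_risk"] = n_persons / dgp.n_areas - prior_events

    hot = win[(win["tmax_w"] > 34.0) & (win["tmax_w"] < 36.0)]
    mild = win[(win["tmax_w"] > 24.0) & (win["tmax_w"] < 26.0)]
    n_hot, n_mild = hot["events"].sum(), mild["events"].sum()
    assert min(n_hot, n_mild) > 100
    rate_hot = n_hot / hot["at_risk"].sum()
    rate_mild = n_mild / mild["at_risk"].sum()
    se = math.sqrt(1 / n_hot + 1 / n_mild)
    assert abs(math.log(rate_hot / rate_mild) - 0.5) < 3 * se


class TestTrueEffects:
    def test_null_hazard(self):
        hz = hs.HazardDGP(alpha=-5, beta_T=0, beta_P=0, beta_TP=0)
        eff = hs.true_effects(hz, hs.ContrastSpec(t0=29.6, t1=36.9, p0=8.9, p1=16.1))
        assert eff.or10 == eff.or01 == eff.or11 == 1.0
        assert eff.reri == 0.0

    def test_closed_form_main_effects_only(self):
        hz = hs.HazardDGP(alpha=-5, beta_T=0.01, beta_P=0.002, beta_TP=0.0)
        c = hs.ContrastSpec(t0=29.6, t1=36.9, p0=8.9, p1=16.1)
        eff = hs.true_effects(hz, c)
        assert eff.or11 == pytest.approx(math.exp(0.01 * 7.3 + 0.002 * 7.2), rel=1e-12)
        expected_reri = (
            math.exp(0.0874) - math.exp(0.073) - math.exp(0.0144) + 1
        )
        assert eff.reri == pytest.approx(expected_reri, rel=1e-10)

    def test_pure_interaction_gives_positive_reri(self):
        hz = hs.HazardDGP(alpha=-5, beta_T=0, beta_P=0, beta_TP=0.001)
        c = hs.ContrastSpec(t0=29.6, t1=36.9, p0=8.9, p1=16.1)
        assert hs.true_effects(hz, c).reri > 0

    def test_invariant_to_baseline_alpha(self):
        c = hs.ContrastSpec(t0=29.6, t1=36.9, p0=8.9, p1=16.1)
        a = hs.true_effects(hs.HazardDGP(alpha=-9), c)
        b = hs.true_effects(hs.HazardDGP(alpha=-2), c)
        assert a == b
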