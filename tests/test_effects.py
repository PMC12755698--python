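"""Posterior effect summaries: ORs, RERI, multiplicative interaction, OR grid."""

import math

import numpy as np
import pandas as pd
import pytest

import heatsynergy as hs
from heatsynergy.splines import LinearExposureDesign


@pytest.fixture(scope="module")
def spline_design():
    rng = np.random.default_rng(14)
    table = pd.DataFrame(
        {
            "tmax_w": rng.normal(29, 5, 400),
            "pm25_w": np.exp(rng.normal(2.1, 0.7, 400)),
            "is_case": (np.arange(400) % 5 == 0).astype(int),
        }
    )
    _, _, design = hs.build_design(table)
    return design


@pytest.fixture(scope="module")
def random_draws(spline_design):
    rng = np.random.default_rng(15)
    return 0.02 * rng.standard_normal((500, len(spline_design.column_labels_)))


CONTRAST = hs.ContrastSpec(t0=29.0, t1=36.0, p0=9.0, p1=16.0)


class TestLogOddsSurface:
    def test_zero_draw_gives_zero_everywhere(self, spline_design):
        beta = np.zeros(len(spline_design.column_labels_))
        eta = hs.log_odds_surface(beta, spline_design, [25.0, 30.0, 35.0], [8.0, 9.0, 10.0])
        np.testing.assert_array_equal(eta, np.zeros(3))

    def test_deterministic(self, spline_design, random_draws):
        a = hs.log_odds_surface(random_draws, spline_design, 30.0, 10.0)
        b = hs.log_odds_surface(random_draws, spline_design, 30.0, 10.0)
        np.testing.assert_array_equal(a, b)

    def test_equals_design_row_dot_product(self, spline_design, random_draws):
        t, p = np.array([27.0, 33.0]), np.array([7.0, 12.0])
        eta = hs.log_odds_surface(random_draws, spline_design, t, p)
        rows = spline_design.transform((t, p))
        np.testing.assert_allclose(eta, rows @ random_draws.T, atol=1e-14)

    def test_label_mismatch_rejected(self, spline_design):
        with pytest.raises(ValueError):
            hs.log_odds_surface(np.zeros(3), spline_design, 30.0, 10.0)


class TestOddsRatio:
    def test_identity_contrast_is_one_with_zero_width(self, spline_design, random_draws):
        s = hs.odds_ratio(random_draws, spline_design, (30.0, 10.0), (30.0, 10.0))
        assert s.mean == 1.0 and s.ci_low == 1.0 and s.ci_high == 1.0

    def test_null_draws_give_unit_or(self, spline_design):
        draws = np.zeros((50, len(spline_design.column_labels_)))
        s = hs.odds_ratio(draws, spline_design, (36.0, 16.0), (29.0, 9.0))
        assert s.mean == 1.0

    def test_matches_closed_form_on_linear_design(self):
        design = LinearExposureDesign()
        beta = np.array([0.01, 0.002, 0.0003])
        s = hs.odds_ratio(beta[None, :], design, (36.9, 16.1), (29.6, 8.9))
        expected = math.exp(
            0.01 * 7.3 + 0.002 * 7.2 + 0.0003 * (36.9 * 16.1 - 29.6 * 8.9)
        )
        assert s.mean == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_and_transitivity_per_draw(self, spline_design, random_draws):
        a, b, c = (26.0, 7.0), (31.0, 11.0), (36.0, 15.0)
        log = lambda x, ref: np.log(
            hs.effects.or_draws(random_draws, spline_design, x, ref)
        )
        np.testing.assert_allclose(log(a, b), -log(b, a), atol=1e-12)
        np.testing.assert_allclose(
            log(a, c), log(a, b) + log(b, c), atol=1e-12
        )


class TestReri:
    def test_null_draws_give_zero_reri(self, spline_design):
        draws = np.zeros((50, len(spline_design.column_labels_)))
        r = hs.reri(draws, spline_design, CONTRAST)
        assert r.per_draw.mean == 0.0 and r.plugin == 0.0

    def test_reri_identity_holds_per_draw(self, spline_design, random_draws):
        from heatsynergy.effects import or_draws

        r10 = or_draws(random_draws, spline_design, (CONTRAST.t1, CONTRAST.p0), (CONTRAST.t0, CONTRAST.p0))
        r01 = or_draws(random_draws, spline_design, (CONTRAST.t0, CONTRAST.p1), (CONTRAST.t0, CONTRAST.p0))
        r11 = or_draws(random_draws, spline_design, (CONTRAST.t1, CONTRAST.p1), (CONTRAST.t0, CONTRAST.p0))
        reri_draws = r11 - r10 - r01 + 1.0
        np.testing.assert_allclose(reri_draws + r10 + r01 - r11, 1.0, atol=1e-12)

    def test_single_draw_matches_true_effects_closed_form(self):
        design = LinearExposureDesign()
        hz = hs.HazardDGP(alpha=-7.0, beta_T=0.05, beta_P=0.02, beta_TP=0.003)
        beta = np.array([hz.beta_T, hz.beta_P, hz.beta_TP])
        r = hs.reri(beta[None, :], design, CONTRAST)
        truth = hs.true_effects(hz, CONTRAST)
        assert r.per_draw.mean == pytest.approx(truth.reri, abs=1e-12)
        assert r.or11.mean == pytest.approx(truth.or11, abs=1e-12)

    def test_plugin_arithmetic(self):
        assert hs.reri_plugin(1.09, 1.05, 1.01) == pytest.approx(0.03)


class TestMultiplicativeInteraction:
    def test_zero_coefficient_gives_unit_or(self, spline_design):
        draws = np.zeros((10, len(spline_design.column_labels_)))
        assert hs.multiplicative_interaction(draws, spline_design).mean == 1.0

    def test_log_two_coefficient_gives_or_two(self, spline_design):
        draws = np.zeros((10, len(spline_design.column_labels_)))
        draws[:, spline_design.column_labels_.index("tmax:pm25")] = math.log(2.0)
        assert hs.multiplicative_interaction(draws, spline_design).mean == pytest.approx(2.0)

    def test_summary_matches_independent_percentiles(self, spline_design, random_draws):
        s = hs.multiplicative_interaction(random_draws, spline_design)
        col = np.exp(random_draws[:, spline_design.column_labels_.index("tmax:pm25")])
        # independent quantile computation: sort + linear interpolation
        srt = np.sort(col)
        def q(frac):
            h = (len(srt) - 1) * frac
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])
        assert s.ci_low == pytest.approx(q(0.025), rel=1e-12)
        assert s.ci_high == pytest.approx(q(0.975), rel=1e-12)
        assert s.mean == pytest.approx(col.mean(), rel=1e-12)

    def test_tensor_model_rejected(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            {
                "tmax_w": rng.normal(29, 5, 300),
                "pm25_w": np.exp(rng.normal(2.1, 0.7, 300)),
                "is_case": (np.arange(300) % 5 == 0).astype(int),
            }
        )
        _, _, design = hs.build_design(table, hs.ModelSpec(interaction="tensor_product"))
        draws = np.zeros((10, len(design.column_labels_)))
        with pytest.raises(ValueError):
            hs.multiplicative_interaction(draws, design)


class TestOrGrid:
    def test_reference_cell_is_exactly_one(self, spline_design, random_draws):
        grid = hs.or_grid(random_draws, spline_design, [29.0, 33.0], [9.0, 12.0], (29.0, 9.0))
        assert grid.loc[29.0, 9.0] == 1.0

    def test_null_draws_give_all_ones(self, spline_design):
        draws = np.zeros((10, len(spline_design.column_labels_)))
        grid = hs.or_grid(draws, spline_design, [27.0, 30.0, 33.0], [8.0, 11.0], (29.0, 9.0))
        np.testing.assert_array_equal(grid.to_numpy(), np.ones((3, 2)))

    def test_cells_equal_cellwise_odds_ratio(self, spline_design, random_draws):
        tg, pg = [27.0, 34.0], [8.0, 13.0]
        grid = hs.or_grid(random_draws, spline_design, tg, pg, (29.0, 9.0))
        for t in tg:
            for p in pg:
                cell = hs.odds_ratio(random_draws, spline_design, (t, p), (29.0, 9.0))
                assert grid.loc[t, p] == pytest.approx(cell.mean, rel=1e-10)


def test_or_curve_shapes_and_reference(spline_design, random_draws):
    curve = hs.or_curve(random_draws, spline_design, [27.0, 29.0, 31.0], "tmax", 9.0, (29.0, 9.0))
    assert list(curve.columns) == ["tmax", "or_mean", "ci_low", "ci_high"]
    ref_row = curve[curve["tmax"] == 29.0].iloc[0]
    assert ref_row["or_mean"] == pytest.approx(1.0)
    assert (curve["ci_low"] <= curve["ci_high"]).all()


def test_contrast_from_case_days():
    table = pd.DataFrame(
        {
            "tmax_w": np.concatenate([np.linspace(20, 40, 101), [0.0] * 50]),
            "pm25_w": np.concatenate([np.linspace(1, 21, 101), [99.0] * 50]),
            "is_case": [1] * 101 + [0] * 50,
        }
    )
    c = hs.ContrastSpec.from_case_days(table)
    # quantiles must come from case days only
    assert c.t0 == pytest.approx(30.0)
    assert c.t1 == pytest.approx(39.0)
    assert c.p0 == pytest.approx(11.0)
    assert c.p1 == pytest.approx(20.0)
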