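"""Parameter estimation: PCA allometry angle, linearized rate fit, seasonality."""

import math

import numpy as np
import pytest

import seagrassibl as sg
from seagrassibl.calibration import (
    CalibrationPoint,
    StandSeries,
    estimate_theta_pca,
    fit_r,
    linearize_series,
    pooled_states,
    seasonality_profile,
)
from seagrassibl.errors import (
    DegenerateDirectionError,
    IndeterminateRateError,
    InsufficientDataError,
)
from seagrassibl.synthetic import ScenarioConfig, SeasonalRate, generate_series

from conftest import make_exact_series

SEAGRASS = sg.IBL_PRESETS["seagrass"]


def closed_form_major_axis(d, b):
    """Independent closed-form dominant eigenvector of a 2x2 covariance.

    For cov [[sdd, sdb], [sdb, sbb]] the major-axis slope is
    (sbb - sdd + sqrt((sbb - sdd)^2 + 4 sdb^2)) / (2 sdb).
    """
    sdd = np.var(d, ddof=1)
    sbb = np.var(b, ddof=1)
    sdb = np.cov(d, b, ddof=1)[0, 1]
    return (sbb - sdd + math.sqrt((sbb - sdd) ** 2 + 4 * sdb ** 2)) / (2 * sdb)


class TestThetaPCA:
    def test_exact_line_recovered(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        states = [sg.StandState(d=x, b=1.5 * x + 0.2) for x in d]
        est = estimate_theta_pca(states)
        assert est.alpha1 == pytest.approx(1.5, abs=1e-12)
        assert est.theta == pytest.approx(math.atan(1.5), abs=1e-12)
        assert est.alpha0 == pytest.approx(0.2, abs=1e-12)

    def test_isometric_line_gives_pi_over_four(self):
        states = [sg.StandState(d=x, b=x) for x in (1.0, 2.0, 3.0)]
        assert estimate_theta_pca(states).theta == pytest.approx(math.pi / 4, abs=1e-12)

    def test_noisy_cloud_matches_closed_form_oracle(self, rng):
        """Anisotropic cloud along slope tan(1.052): PCA agrees with the
        independent closed-form eigen solution and recovers the angle."""
        alpha1 = math.tan(1.052)
        t = rng.uniform(-1.0, 1.0, 200)
        d = 3.0 + t + rng.normal(0, 0.02, 200)
        b = 2.0 + alpha1 * t + rng.normal(0, 0.02, 200)
        est = estimate_theta_pca([sg.StandState(d=x, b=y) for x, y in zip(d, b)])
        assert est.alpha1 == pytest.approx(closed_form_major_axis(d, b), abs=1e-10)
        assert est.theta == pytest.approx(1.052, abs=0.05)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            estimate_theta_pca([sg.StandState(d=1, b=1), sg.StandState(d=2, b=2)])

    def test_isotropic_cloud_rejected(self):
        # four points forming a perfect square: equal eigenvalues
        states = [sg.StandState(d=x, b=y)
                  for x, y in [(0, 0), (0, 1), (1, 0), (1, 1)]]
        with pytest.raises(DegenerateDirectionError):
            estimate_theta_pca(states)

    def test_negative_slope_warns_then_fails(self):
        states = [sg.StandState(d=x, b=-0.8 * x + 3) for x in (1.0, 2.0, 3.0)]
        with pytest.warns(UserWarning, match="non-positive"):
            with pytest.raises(DegenerateDirectionError):
                estimate_theta_pca(states)


class TestLinearize:
    def test_model_exact_points_lie_on_rate_line(self, znoltii):
        """A series generated by the model itself with constant r* yields
        points exactly on y = r* (1 - x)."""
        series = make_exact_series(znoltii, SEAGRASS, r=0.02)
        res = linearize_series(series, znoltii, SEAGRASS)
        assert res.n_dropped == 0
        for p in res.points:
            assert p.y == pytest.approx(0.02 * (1.0 - p.x), abs=1e-10)

    def test_pooling_doubles_sample_size(self, znoltii):
        series = make_exact_series(znoltii, SEAGRASS, n_obs=8)
        res = linearize_series(series, znoltii, SEAGRASS)
        assert len(res) == 2 * (len(series) - 1)

    def test_two_observations_give_two_points(self, znoltii):
        series = StandSeries("s", "sp", [0.0, 30.0], [1.0, 1.1], [2.0, 2.05])
        res = linearize_series(series, znoltii, SEAGRASS)
        assert len(res) == 2
        assert {p.source for p in res.points} == {"biomass", "density"}

    def test_zero_log_biomass_drops_only_biomass_point(self, znoltii):
        series = StandSeries("s", "sp", [0.0, 30.0, 60.0],
                             [0.0, 0.5, 0.8], [2.0, 2.1, 2.2])
        res = linearize_series(series, znoltii, SEAGRASS)
        assert res.n_dropped == 1
        first_interval = [p for p in res.points if p.t_start == 0.0]
        assert [p.source for p in first_interval] == ["density"]

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            StandSeries("s", "sp", [0.0, 30.0, 30.0], [1, 1, 1], [2, 2, 2])


class TestFitR:
    def _points(self, x, y):
        return [CalibrationPoint(x=xi, y=yi, source="biomass", study_id="s",
                                 t_start=30.0 * i, interval_days=30.0)
                for i, (xi, yi) in enumerate(zip(x, y))]

    def test_exact_line_recovers_rate_and_envelopes(self):
        x = np.linspace(0.1, 0.9, 9)
        est = fit_r(self._points(x, 0.03 * (1 - x)))
        assert est.r_hat == pytest.approx(0.03, abs=1e-14)
        assert est.r_max == pytest.approx(0.03, abs=1e-14)
        assert est.r_min == pytest.approx(0.03, abs=1e-14)

    def test_zero_rates(self):
        est = fit_r(self._points([0.2, 0.5, 0.8], [0.0, 0.0, 0.0]))
        assert est.r_hat == 0.0

    def test_closed_form(self, rng):
        x = rng.uniform(0, 0.9, 40)
        y = rng.normal(0.01, 0.005, 40)
        est = fit_r(self._points(x, y))
        w = 1 - x
        assert est.r_hat == pytest.approx(np.sum(y * w) / np.sum(w * w), abs=1e-14)

    def test_linearity_in_y(self, rng):
        x = rng.uniform(0, 0.9, 20)
        y = rng.normal(0.01, 0.005, 20)
        r1 = fit_r(self._points(x, y)).r_hat
        r3 = fit_r(self._points(x, 3 * y)).r_hat
        assert r3 == pytest.approx(3 * r1, abs=1e-14)

    def test_source_labels_do_not_matter(self, rng):
        x = rng.uniform(0, 0.9, 20)
        y = 0.02 * (1 - x) + rng.normal(0, 0.002, 20)
        pts = self._points(x, y)
        relabeled = [CalibrationPoint(p.x, p.y, "density", p.study_id,
                                      p.t_start, p.interval_days) for p in pts]
        assert fit_r(pts).r_hat == fit_r(relabeled).r_hat

    def test_all_points_at_capacity_rejected(self):
        with pytest.raises(IndeterminateRateError):
            fit_r(self._points([1.0, 1.0, 1.0], [0.0, 0.0, 0.0]))

    def test_seasonal_blocks_recovered_at_full_envelope(self):
        """Model-exact series with r alternating +/-0.04 in 180-day blocks:
        the q=1/0 envelopes are the two block rates, verified against
        per-interval finite differences."""
        params = sg.SPECIES_PRESETS["T. testudinum"]
        d0 = 3.0
        cfg = ScenarioConfig(
            species=params,
            r_schedule=SeasonalRate(0.04, -0.04, growth_start=0, growth_end=180,
                                    period=360),
            initial_states=[sg.StandState(d=d0, b=SEAGRASS.biomass_at(d0) - 0.8)],
            interval_days=30, n_obs=24, exact=True, seed=0,
        )
        series = generate_series(cfg)[0]
        res = linearize_series(series, params, SEAGRASS)
        est = fit_r(res.points, q_max=1.0, q_min=0.0)
        assert est.r_max == pytest.approx(0.04, abs=1e-10)
        assert est.r_min == pytest.approx(-0.04, abs=1e-10)
        # independent oracle: per-interval rate from raw finite differences
        for ir in est.per_interval:
            i = int(np.where(series.times == ir.t_start)[0][0])
            state = sg.StandState(d=series.d[i], b=series.b[i])
            caps = sg.project_to_ibl(state, params.alpha1, SEAGRASS)
            if ir.source == "biomass":
                y = (series.b[i + 1] - series.b[i]) / ir.interval_days / (
                    series.b[i] * params.sin_theta)
                x = series.b[i] / caps.K_b
            else:
                y = (series.d[i + 1] - series.d[i]) / ir.interval_days / (
                    series.d[i] * params.cos_theta)
                x = series.d[i] / caps.K_d
            assert ir.r == pytest.approx(y / (1 - x), abs=1e-12)


class TestExactRecovery:
    @pytest.mark.parametrize("name", list(sg.SPECIES_PRESETS))
    def test_rate_roundtrip_all_presets(self, name):
        """fit_r returns the generating rate to numerical precision on
        model-exact noise-free series (generator and calibration share
        forward-difference semantics)."""
        params = sg.SPECIES_PRESETS[name]
        series = make_exact_series(params, SEAGRASS, r=0.025, study_id=name)
        est = fit_r(linearize_series(series, params, SEAGRASS).points)
        assert est.r_hat == pytest.approx(0.025, abs=1e-10)

    def test_theta_roundtrip_on_central_scatter(self):
        """PCA is exact on noise-free states along the central tendency."""
        from seagrassibl.synthetic import sample_central_states
        params = sg.SpeciesParams.from_theta("cn", 1.052, alpha0=-3.094)
        states = sample_central_states(params, 50, d_range=(2.3, 3.3), seed=1)
        est = estimate_theta_pca(states)
        assert est.theta == pytest.approx(1.052, abs=1e-9)


class TestSeasonalityProfile:
    def test_two_block_schedule_separates_phases(self):
        """Growth window days 80-260, decay outside: bins inside the window
        have positive median rates, bins outside negative."""
        params = sg.SPECIES_PRESETS["C. nodosa"]
        d0 = 3.0
        cfg = ScenarioConfig(
            species=params, r_schedule=SeasonalRate(0.03, -0.03),
            initial_states=[sg.StandState(d=d0, b=SEAGRASS.biomass_at(d0) - 0.6)],
            interval_days=30, n_obs=36, exact=True, seed=0,
        )
        series = generate_series(cfg)[0]
        est = fit_r(linearize_series(series, params, SEAGRASS).points,
                    q_max=1.0, q_min=0.0)
        prof = seasonality_profile(est, period_days=365.0, n_bins=12)
        for _, row in prof.iterrows():
            mid = 0.5 * (row.phase_start + row.phase_end)
            if 110 <= mid <= 230:  # interval start well inside the window
                assert row.r_median > 0
            elif mid <= 50 or mid >= 290:
                assert row.r_median < 0

    def test_single_interval_occupies_one_bin(self, znoltii):
        series = StandSeries("s", "sp", [10.0, 40.0], [1.0, 1.1], [2.0, 2.05])
        est = fit_r(linearize_series(series, znoltii, SEAGRASS).points)
        prof = seasonality_profile(est)
        assert len(prof) == 1
        assert prof.n.iloc[0] == 2  # biomass + density point of the one interval

    def test_empty_per_interval_rejected(self):
        est = sg.RateEstimate(r_hat=0.0, r_max=0.0, r_min=0.0, n_points=0,
                              per_interval=[])
        with pytest.raises(InsufficientDataError):
            seasonality_profile(est)


def test_pooled_states_flattens(znoltii):
    s1 = make_exact_series(znoltii, SEAGRASS, n_obs=5, study_id="a")
    s2 = make_exact_series(znoltii, SEAGRASS, n_obs=7, study_id="b")
    assert len(pooled_states([s1, s2])) == 12
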