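"""Calibration of the ln k - activation-energy line and rate prediction."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tzreact as tz


def _points(xs, ks, ids=None):
    ids = ids or [f"p{i}" for i in range(len(xs))]
    return [tz.CalibrationPoint(i, x, k) for i, x, k in zip(ids, xs, ks)]


def _grid_ols_oracle(x, y):
    """Exhaustive SSE minimisation over (slope, intercept), refined."""
    s_lo, s_hi, b_lo, b_hi = -5.0, 5.0, -20.0, 20.0
    best = (math.inf, None)
    for _ in range(6):
        ss = np.linspace(s_lo, s_hi, 80)
        bs = np.linspace(b_lo, b_hi, 80)
        for s in ss:
            for b in bs:
                r = y - (s * x + b)
                sse = float(r @ r)
                if sse < best[0]:
                    best = (sse, (s, b))
        s_c, b_c = best[1]
        ds, db = (ss[1] - ss[0]) * 3, (bs[1] - bs[0]) * 3
        s_lo, s_hi, b_lo, b_hi = s_c - ds, s_c + ds, b_c - db, b_c + db
    return best[1]


class TestCalibrate:
    def test_hand_computed_three_point_fit(self):
        # ln k = x + 1 exactly
        model = tz.calibrate(_points([0, 1, 2], [math.e, math.e**2, math.e**3]))
        assert model.slope == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(1.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_line_recovered_exactly(self):
        xs = [-6.0, -2.0, 0.0, 3.0, 6.5]
        ks = [math.exp(-0.2 * x + 1.5) for x in xs]
        model = tz.calibrate(_points(xs, ks))
        assert model.slope == pytest.approx(-0.2, abs=1e-10)
        assert model.intercept == pytest.approx(1.5, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.se_slope == pytest.approx(0.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(tz.TzReactError, match=">= 3"):
            tz.calibrate(_points([0, 1], [1.0, 2.0]))

    def test_zero_design_variance_rejected(self):
        with pytest.raises(tz.TzReactError, match="variance"):
            tz.calibrate(_points([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))

    def test_nonpositive_rate_names_offender(self):
        with pytest.raises(tz.TzReactError, match="tz_bad"):
            tz.CalibrationPoint("tz_bad", 1.0, 0.0)

    def test_matches_grid_search_oracle(self):
        xs = np.array([-5.0, -1.0, 0.5, 2.0, 4.0, 6.0])
        ks = np.exp(-0.21 * xs + 1.3 + np.array([0.05, -0.1, 0.02, 0.07, -0.03, 0.0]))
        model = tz.calibrate(_points(xs, ks))
        s_o, b_o = _grid_ols_oracle(xs, np.log(ks))
        assert model.slope == pytest.approx(s_o, abs=1e-3)
        assert model.intercept == pytest.approx(b_o, abs=1e-3)

    def test_r_squared_agrees_with_descriptor_regression(self, fixture_model):
        pts = tz.fixture_calibration_points()
        corr = tz.correlate_descriptor([p.delta_e_act for p in pts],
                                       [math.log(p.k) for p in pts])
        assert fixture_model.r_squared == pytest.approx(corr.r_squared, abs=1e-12)

    def test_residuals_sum_to_zero(self, fixture_model):
        pts = tz.fixture_calibration_points()
        resid = [math.log(p.k) - (fixture_model.slope * p.delta_e_act
                                  + fixture_model.intercept) for p in pts]
        assert sum(resid) == pytest.approx(0.0, abs=1e-10)


class TestPredictRate:
    def test_intercept_only_evaluation(self, fixture_model):
        # at dE = 0 the prediction is e^intercept ~ 4.31 M^-1 s^-1
        p = tz.predict_rate(fixture_model, 0.0)
        assert p.k == pytest.approx(math.exp(fixture_model.intercept), rel=1e-12)
        assert p.k == pytest.approx(4.306, abs=0.01)
        assert not p.extrapolated

    def test_fastest_tetrazine_prediction(self, fixture_model):
        # the submerged-barrier tetrazine: predicted ~15.6 vs measured 14.6,
        # a residual of the calibration, not an error
        p = tz.predict_rate(fixture_model, -6.57)
        assert p.k == pytest.approx(15.6, abs=0.2)

    def test_monotone_decreasing_in_barrier(self, fixture_model):
        ks = [tz.predict_rate(fixture_model, x).k for x in np.linspace(-7, 7, 15)]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_zero_slope_gives_constant(self):
        model = tz.ReactivityModel(slope=0.0, intercept=1.460, r_squared=0.0,
                                   se_slope=0.0, se_intercept=0.0, n_points=3)
        for x in (-10.0, 0.0, 25.0):
            assert tz.predict_rate(model, x).k == pytest.approx(math.exp(1.460))

    def test_centroid_property(self, fixture_model):
        pts = tz.fixture_calibration_points()
        x_bar = np.mean([p.delta_e_act for p in pts])
        ln_k_bar = np.mean([math.log(p.k) for p in pts])
        assert tz.predict_rate(fixture_model, float(x_bar)).k == pytest.approx(
            math.exp(ln_k_bar), rel=1e-10)

    def test_training_rates_within_residual_band(self, fixture_model):
        factor = math.exp(2 * fixture_model.resid_se)
        for p in tz.fixture_calibration_points():
            pred = tz.predict_rate(fixture_model, p.delta_e_act).k
            assert pred / factor <= p.k <= pred * factor

    def test_interval_brackets_point_and_widens_off_centre(self, fixture_model):
        centre = tz.predict_rate(fixture_model, fixture_model.x_mean)
        edge = tz.predict_rate(fixture_model, fixture_model.x_max)
        for p in (centre, edge):
            assert p.k_lower < p.k < p.k_upper
        assert (edge.k_upper / edge.k_lower) > (centre.k_upper / centre.k_lower)

    def test_extrapolation_flagged(self, fixture_model):
        assert tz.predict_rate(fixture_model, 50.0).extrapolated
        assert not tz.predict_rate(fixture_model, 0.0).extrapolated

    def test_nonfinite_barrier_rejected(self, fixture_model):
        with pytest.raises(tz.TzReactError):
            tz.predict_rate(fixture_model, math.nan)


class TestDescriptorCorrelation:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 4.0, 6.0, 8.0]
        assert tz.correlate_descriptor(x, y).r_squared == pytest.approx(1.0)

    def test_zero_sample_covariance(self):
        x = [-1.0, 0.0, 1.0]
        y = [1.0, 0.0, 1.0]  # symmetric: Sxy = 0
        assert tz.correlate_descriptor(x, y).r_squared == pytest.approx(0.0, abs=1e-15)

    def test_matches_closed_form_sums_of_squares(self):
        pts = tz.fixture_calibration_points()
        x = np.array([p.delta_e_act for p in pts])
        y = np.log([p.k for p in pts])
        sxx = np.sum((x - x.mean()) ** 2)
        syy = np.sum((y - y.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert tz.correlate_descriptor(x, y).r_squared == pytest.approx(
            sxy**2 / (sxx * syy), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(tz.TzReactError, match="mismatch"):
            tz.correlate_descriptor([1.0, 2.0, 3.0], [1.0, 2.0])


class TestFmoGap:
    def test_simple_gap(self):
        tz_orb = tz.OrbitalEnergySet("tz9", -10.0, -2.0, -1.0)
        tco_orb = tz.OrbitalEnergySet("tco", -8.0, 1.0, 2.0)
        assert tz.fmo_gap(tz_orb, tco_orb) == pytest.approx(7.0)

    def test_self_gap_positive(self):
        orb = tz.OrbitalEnergySet("x", -9.0, -2.0, -1.5)
        assert tz.fmo_gap(orb, orb) > 0

    @given(shift=st.floats(-5.0, 5.0, allow_nan=False))
    def test_translation_invariance(self, shift):
        a = tz.OrbitalEnergySet("a", -10.0, -2.0, -1.0)
        b = tz.OrbitalEnergySet("b", -8.0, 1.0, 2.0)
        a2 = tz.OrbitalEnergySet("a", -10.0 + shift, -2.0 + shift, -1.0 + shift)
        b2 = tz.OrbitalEnergySet("b", -8.0 + shift, 1.0 + shift, 2.0 + shift)
        assert tz.fmo_gap(a2, b2) == pytest.approx(tz.fmo_gap(a, b), abs=1e-9)

    def test_unit_mismatch_rejected(self):
        a = tz.OrbitalEnergySet("a", -10.0, -2.0, -1.0, unit="eV")
        b = tz.OrbitalEnergySet("b", -0.3, 0.01, 0.05, unit="hartree")
        with pytest.raises(tz.TzReactError, match="unit"):
            tz.fmo_gap(a, b)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(tz.TzReactError, match="homo < lumo"):
            tz.OrbitalEnergySet("bad", -1.0, -2.0, 0.0)


class TestSimulateCalibration:
    def test_zero_residual_recovers_exactly(self):
        pts = tz.simulate_calibration(8, -0.1963, 1.460, 0.0, seed=11)
        model = tz.calibrate(pts)
        assert model.slope == pytest.approx(-0.1963, abs=1e-10)
        assert model.intercept == pytest.approx(1.460, abs=1e-10)

    def test_same_seed_identical(self):
        a = tz.simulate_calibration(6, -0.2, 1.5, 0.1, seed=5)
        b = tz.simulate_calibration(6, -0.2, 1.5, 0.1, seed=5)
        assert a == b

    def test_minimum_size_enforced(self):
        with pytest.raises(tz.TzReactError):
            tz.simulate_calibration(2, -0.2, 1.5, 0.1, seed=1)


class TestModelSerialization:
    def test_round_trip_bit_for_bit(self, fixture_model):
        buf = io.StringIO()
        tz.save_model(fixture_model, buf)
        back = tz.load_model(io.StringIO(buf.getvalue()))
        assert back == fixture_model

    def test_schema_tag_checked(self):
        with pytest.raises(tz.TzReactError, match="schema"):
            tz.load_model(io.StringIO("schema = something-else/9\n"))

    def test_missing_field_reported(self):
        buf = io.StringIO()
        tz.save_model(tz.calibrate_fixture(), buf)
        text = "\n".join(l for l in buf.getvalue().splitlines()
                         if not l.startswith("slope"))
        with pytest.raises(tz.TzReactError, match="slope"):
            tz.load_model(io.StringIO(text))
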