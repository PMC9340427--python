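import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_deoxy_window
from helpers import ols_normal_equations
from nirskinetics import (
    DeoxygenationRateModel,
    Segment,
    adjusted_rate,
    delta_tsi,
    fit_linear_deoxy,
)

T10 = np.arange(10.0)


class TestLinearFit:
    def test_exact_line_recovered(self):
        fit = fit_linear_deoxy(make_deoxy_window(80.0 - 2.4 * T10))
        assert fit.a == pytest.approx(-2.4, abs=1e-12)
        assert fit.tsi0 == pytest.approx(80.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_window_degenerate(self):
        fit = fit_linear_deoxy(make_deoxy_window(np.full(10, 75.0)))
        assert fit.a == 0.0
        assert fit.tsi0 == pytest.approx(75.0)
        assert not fit.r2_defined
        assert np.isnan(fit.r2)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            y = 80.0 + rng.normal(-2.5, 1.0) * T10 + rng.normal(0, 1, 10)
            model = DeoxygenationRateModel().fit(T10, y)
            slope, intercept, r2 = ols_normal_equations(T10, y)
            assert model.slope_ == pytest.approx(slope, abs=1e-10)
            assert model.intercept_ == pytest.approx(intercept, abs=1e-10)
            assert model.r2_ == pytest.approx(r2, abs=1e-10)

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_vertical_shift_moves_only_intercept(self, shift):
        rng = np.random.default_rng(6)
        y = 80.0 - 2.0 * T10 + rng.normal(0, 1, 10)
        base = DeoxygenationRateModel().fit(T10, y)
        moved = DeoxygenationRateModel().fit(T10, y + shift)
        assert moved.slope_ == pytest.approx(base.slope_, abs=1e-9)
        assert moved.intercept_ == pytest.approx(base.intercept_ + shift, abs=1e-9)
        assert moved.r2_ == pytest.approx(base.r2_, abs=1e-9)

    @given(scale=st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_time_scaling_scales_slope_inversely(self, scale):
        rng = np.random.default_rng(7)
        y = 80.0 - 2.0 * T10 + rng.normal(0, 1, 10)
        base = DeoxygenationRateModel().fit(T10, y)
        scaled = DeoxygenationRateModel().fit(T10 * scale, y)
        assert scaled.slope_ == pytest.approx(base.slope_ / scale, rel=1e-9)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError, match="expected 10"):
            DeoxygenationRateModel().fit(np.arange(8.0), np.arange(8.0))

    def test_explicit_override_allows_other_lengths(self):
        model = DeoxygenationRateModel(expected_points=None).fit(np.arange(6.0), 70 - 1.5 * np.arange(6.0))
        assert model.slope_ == pytest.approx(-1.5)

    def test_work_populates_adjusted_rate(self):
        fit = fit_linear_deoxy(make_deoxy_window(80.0 - 3.0 * T10), total_work=15.0)
        assert fit.a_adj == pytest.approx(-0.2)


class TestAdjustedRate:
    @pytest.mark.parametrize(
        "a, work, expected", [(-3.0, 15.0, -0.2), (-2.55, 17.0, -0.15), (0.0, 18.0, 0.0)]
    )
    def test_known_values(self, a, work, expected):
        assert adjusted_rate(a, work) == pytest.approx(expected)

    def test_nonpositive_work_rejected(self):
        with pytest.raises(ValueError, match="total_work"):
            adjusted_rate(-2.0, 0.0)


class TestDeltaTsi:
    def _sprint(self, values):
        values = np.asarray(values, dtype=float)
        return Segment("sprint", 1, 0.0, 30.0, np.arange(values.size, dtype=float), values)

    def test_constant_segment_zero_range(self):
        assert delta_tsi(self._sprint(np.full(30, 70.0))) == 0.0

    def test_monotone_decline_range(self):
        assert delta_tsi(self._sprint(np.linspace(80, 50, 30))) == pytest.approx(30.0)

    def test_matches_generator_extremes(self, noiseless_session):
        from nirskinetics import segment_session

        tsi, _, protocol, _ = noiseless_session
        sprints = [s for s in segment_session(tsi, protocol) if s.kind == "sprint"]
        for s in sprints:
            assert delta_tsi(s) == pytest.approx(np.max(s.tsi) - np.min(s.tsi))
            assert delta_tsi(s) > 0

    def test_empty_segment_rejected(self):
        seg = self._sprint(np.full(30, 70.0))
        seg.time = seg.tsi = np.array([])
        with pytest.raises(ValueError, match="empty"):
            delta_tsi(seg)
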