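import numpy as np
import pytest

from conftest import make_recovery_segment
from helpers import grid_oracle_rss, synthetic_recovery
from nirskinetics import (
    ReoxygenationKineticsModel,
    a_prime,
    adjusted_r2,
    fit_reoxy,
    mrt,
    passes_inclusion,
    predict_reoxy,
)


class TestPredict:
    def test_floor_until_delay(self):
        assert predict_reoxy(15.0, 55.0, 30.0, 15.0, 27.0) == pytest.approx(55.0)
        assert predict_reoxy(3.0, 55.0, 30.0, 15.0, 27.0) == pytest.approx(55.0)

    def test_one_time_constant(self):
        val = predict_reoxy(15.0 + 27.0, 55.0, 30.0, 15.0, 27.0)
        assert val == pytest.approx(55.0 + 30.0 * (1 - np.exp(-1)))

    def test_asymptote(self):
        assert predict_reoxy(1e6, 55.0, 30.0, 15.0, 27.0) == pytest.approx(85.0)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            predict_reoxy(10.0, 55.0, 30.0, 15.0, 0.0)

    def test_monotone_non_decreasing(self):
        t = np.linspace(0, 240, 2000)
        y = predict_reoxy(t, 50.0, 25.0, 20.0, 40.0)
        assert np.all(np.diff(y) >= -1e-12)


class TestDerivedQuantities:
    def test_a_prime_one_tau(self):
        assert a_prime(30.0, 10.0, 50.0, 60.0) == pytest.approx(30.0 * (1 - np.exp(-1)))

    def test_a_prime_asymptotic_limit(self):
        assert a_prime(30.0, 0.0, 1.0, 100.0) == pytest.approx(30.0, rel=1e-9)

    def test_a_prime_hand_value(self):
        assert a_prime(30.0, 15.0, 27.0, 240.0) == pytest.approx(30.0 * (1 - np.exp(-225.0 / 27.0)), abs=1e-9)
        assert a_prime(30.0, 15.0, 27.0, 240.0) == pytest.approx(29.993, abs=1e-3)

    def test_a_prime_requires_t_end_after_delay(self):
        with pytest.raises(ValueError, match="t_end"):
            a_prime(30.0, 50.0, 27.0, 40.0)

    def test_a_prime_approaches_amplitude_monotonically(self):
        vals = [a_prime(30.0, 15.0, 27.0, te) for te in (60, 120, 240, 480, 960)]
        assert np.all(np.diff(vals) > 0)
        assert all(v < 30.0 for v in vals)

    @pytest.mark.parametrize(
        "td, tau, expected",
        [(52.57, 50.12, 102.69), (24.20, 60.82, 85.02), (0.0, 33.3, 33.3)],
    )
    def test_mrt_is_sum(self, td, tau, expected):
        assert mrt(td, tau) == pytest.approx(expected, abs=1e-9)

    def test_mrt_domain(self):
        with pytest.raises(ValueError):
            mrt(-1.0, 10.0)
        with pytest.raises(ValueError):
            mrt(1.0, 0.0)

    @pytest.mark.parametrize(
        "r2, n, expected",
        [(1.0, 50, 1.0), (0.95, 226, 1 - 0.05 * 225 / 222), (0.0, 100, -(99 / 96 - 1))],
    )
    def test_adjusted_r2_values(self, r2, n, expected):
        assert adjusted_r2(r2, n) == pytest.approx(expected, abs=1e-12)
        assert adjusted_r2(r2, n) <= r2 + 1e-12

    def test_adjusted_r2_needs_enough_samples(self):
        with pytest.raises(ValueError, match="n > k"):
            adjusted_r2(0.9, 4)

    @pytest.mark.parametrize("r2, expected", [(0.95, True), (0.80, False), (0.81, True)])
    def test_inclusion_is_strict(self, r2, expected):
        assert passes_inclusion(r2) is expected


class TestFit:
    def test_noiseless_recovery_exact(self):
        t = np.arange(240.0)
        y = predict_reoxy(t, 55.0, 30.0, 15.0, 27.0)
        fit = fit_reoxy(make_recovery_segment(t, y))
        assert fit.tsib == pytest.approx(55.0, abs=1e-3)
        assert fit.amp_a == pytest.approx(30.0, abs=1e-3)
        assert fit.td == pytest.approx(15.0, abs=1e-3)
        assert fit.tau == pytest.approx(27.0, abs=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.included and fit.converged

    def test_mrt_identity_audit(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            t, y, _ = synthetic_recovery(rng)
            fit = fit_reoxy(make_recovery_segment(t, y))
            assert fit.mrt == fit.td + fit.tau  # exact identity, no tolerance
            assert fit.a_prime < fit.amp_a

    def test_beats_grid_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            t, y, _ = synthetic_recovery(rng)
            fit = fit_reoxy(make_recovery_segment(t, y))
            oracle = grid_oracle_rss(t, y)
            assert fit.rss <= oracle * (1 + 1e-9)

    def test_parameter_recovery_under_noise(self):
        """Median recovery error over noisy recoveries: td/tau <= 2 s, mrt <= 3 s."""
        rng = np.random.default_rng(13)
        errs = {"td": [], "tau": [], "mrt": []}
        for _ in range(60):
            t, y, (tsib, amp, td, tau) = synthetic_recovery(rng)
            fit = fit_reoxy(make_recovery_segment(t, y))
            errs["td"].append(abs(fit.td - td))
            errs["tau"].append(abs(fit.tau - tau))
            errs["mrt"].append(abs(fit.mrt - (td + tau)))
        assert np.median(errs["td"]) <= 2.0
        assert np.median(errs["tau"]) <= 2.0
        assert np.median(errs["mrt"]) <= 3.0

    def test_flat_segment_flagged_failed(self):
        t = np.arange(240.0)
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_reoxy(make_recovery_segment(t, np.full(240, 60.0)))
        assert not fit.converged
        assert not fit.included
        assert np.isnan(fit.tau)

    def test_short_segment_rejected(self):
        t = np.arange(100.0)
        with pytest.raises(ValueError, match="too short"):
            fit_reoxy(make_recovery_segment(t, np.linspace(50, 70, 100)), t_end=240.0)

    def test_fitted_curve_monotone(self):
        rng = np.random.default_rng(14)
        t, y, _ = synthetic_recovery(rng)
        model = ReoxygenationKineticsModel().fit(t, y)
        pred = model.predict(np.linspace(0, 240, 1000))
        assert np.all(np.diff(pred) >= -1e-12)

    def test_fix_baseline_mode_pins_tsib(self):
        t = np.arange(240.0)
        y = predict_reoxy(t, 55.0, 30.0, 15.0, 27.0)
        model = ReoxygenationKineticsModel(fix_baseline=True).fit(t, y)
        assert model.tsib_ == pytest.approx(float(y[0]))
        assert model.tau_ == pytest.approx(27.0, abs=1e-2)

    def test_goodness_of_fit_spans_exponential_onset_to_end(self):
        t = np.arange(240.0)
        y = predict_reoxy(t, 55.0, 30.0, 20.0, 27.0) + np.random.default_rng(15).normal(0, 0.5, 240)
        model = ReoxygenationKineticsModel().fit(t, y)
        assert model.n_fit_ == int(np.sum(t >= model.time_delay_))
        assert model.adj_r2_ <= model.r2_

    def test_sklearn_param_interface(self):
        model = ReoxygenationKineticsModel(t_end=180.0)
        assert model.get_params()["t_end"] == 180.0
        model.set_params(k_dof=4)
        assert model.k_dof == 4
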