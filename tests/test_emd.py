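"""Correlator stage: the four EMD variants."""

import numpy as np
import pytest

from emdscope import (
    EmdParams,
    FilterState,
    build_emd_field,
    estimate_saturation_gain,
    make_correlator,
    saturate_input,
)
from emdscope.emd import (
    AdaptiveParams,
    AdaptiveState,
    basic_emd_step,
    input_gain_control_step,
    update_tau_h,
)

DT = 1e-3


def _delay_states(tau=0.040):
    return (FilterState(None, tau), FilterState(None, tau))


class TestBasicEmd:
    def test_zero_input_zero_output(self):
        states = _delay_states()
        for _ in range(10):
            pp, pm = basic_emd_step(0.0, 0.0, states, DT)
        assert pp == 0.0 and pm == 0.0

    def test_outputs_rectified(self, rng):
        states = _delay_states()
        for x, y in rng.standard_normal((200, 2)):
            pp, pm = basic_emd_step(x, y, states, DT)
            assert pp >= 0.0 and pm >= 0.0

    def test_preferred_direction_and_reversal_swap(self):
        """A sinusoid drifting left-to-right favours P+; reversing the drift
        swaps the time-mean half-detector outputs exactly."""
        phi = np.deg2rad(1.25)
        lam = np.deg2rad(30.0)
        omega = 2 * np.pi * 60.0 / 30.0  # 60 deg/s, 30 deg wavelength
        t = np.arange(4000) * DT

        # phase progression: motion toward increasing azimuth advances the
        # right receptor's phase behind the left one
        def simulate(sign):
            states = _delay_states()
            pp_sum = pm_sum = 0.0
            for ti in t:
                phase = omega * ti * sign
                left = np.sin(phase)
                right = np.sin(phase - 2 * np.pi * phi / lam)
                pp, pm = basic_emd_step(left, right, states, DT)
                if ti >= 1.0:  # exactly 6 grating periods after the transient
                    pp_sum += pp
                    pm_sum += pm
            return pp_sum, pm_sum

        pp_f, pm_f = simulate(+1)
        pp_r, pm_r = simulate(-1)
        assert pp_f > pm_f
        # swap is exact up to rectifier aliasing of the sampled grating
        assert pp_f == pytest.approx(pm_r, rel=1e-5)
        assert pm_f == pytest.approx(pp_r, rel=1e-5)


class TestAdaptiveTauH:
    def _state(self, **kw):
        params = AdaptiveParams(**kw)
        return AdaptiveState(params.max_tauh, FilterState(0.0, params.tau_S), params)

    def test_zero_drive_relaxes_to_max(self):
        state = self._state()
        state.tau_h = 0.1
        for _ in range(100):
            tau = update_tau_h(state, 0.0, DT)
        assert tau == pytest.approx(0.5, abs=1e-3)

    def test_large_drive_collapses_to_min(self):
        state = self._state()
        for _ in range(5000):
            tau = update_tau_h(state, 1e6, DT)
        assert tau == pytest.approx(0.0, abs=1e-6)

    def test_equilibrium_matches_closed_form(self):
        """Constant drive S settles tau_h at (K max + gS min) / (K + gS)."""
        params = AdaptiveParams()
        S = 0.7
        drive = S  # held constant; the S low-pass passes it through at DC
        state = self._state()
        for _ in range(20000):
            tau = update_tau_h(state, drive, DT)
        g = params.gain
        expected = (params.K * params.max_tauh + g * S * params.min_tauh) / (params.K + g * S)
        assert tau == pytest.approx(expected, rel=1e-6)

    def test_tau_h_stays_in_bounds(self, rng):
        state = self._state()
        for x in rng.exponential(10.0, 2000):
            tau = update_tau_h(state, x, DT)
            assert 0.0 <= tau <= 0.5


class TestAdaptiveEmdStep:
    def test_scalar_step_rectified_and_bounded(self):
        from emdscope.emd import adaptive_emd_step

        params = AdaptiveParams()
        delay = _delay_states()
        arms = (
            AdaptiveState(params.max_tauh, FilterState(0.0, params.tau_S), params),
            AdaptiveState(params.max_tauh, FilterState(0.0, params.tau_S), params),
        )
        hp_states = [None, None]
        for t in range(500):
            left = np.sin(0.05 * t)
            right = np.sin(0.05 * t - 0.3)
            pp, pm = adaptive_emd_step(left, right, delay, arms, hp_states, DT)
            assert pp >= 0.0 and pm >= 0.0
            assert np.isfinite(pp) and np.isfinite(pm)
            for arm in arms:
                assert params.min_tauh <= np.max(arm.tau_h) <= params.max_tauh


class TestSaturation:
    def test_gain_from_constant_channels(self):
        samples = np.full((100, 4), 2.0)
        assert estimate_saturation_gain(samples) == pytest.approx(0.5)

    def test_gain_homogeneity(self, rng):
        samples = rng.standard_normal((500, 6))
        a = estimate_saturation_gain(samples)
        assert estimate_saturation_gain(3.0 * samples) == pytest.approx(a / 3.0, rel=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_saturation_gain(np.empty((0, 4)))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_saturation_gain(np.zeros((10, 4)))

    def test_saturate_values(self):
        assert saturate_input(0.0, 2.0) == 0.0
        samples = np.full((100, 4), 1.7)
        a = estimate_saturation_gain(samples)
        assert saturate_input(1.7, a) == pytest.approx(np.tanh(1.0), rel=1e-12)

    def test_odd_symmetry(self, rng):
        s = rng.standard_normal(100)
        assert np.allclose(saturate_input(-s, 1.3), -saturate_input(s, 1.3))


class TestInputGain:
    def test_constant_input_normalises_to_unity(self):
        state = FilterState(None, 0.2)
        for _ in range(5000):
            out = input_gain_control_step(5.0, state, tau_A=0.2, dt=DT, eps=1e-6)
        assert out == pytest.approx(1.0, abs=1e-4)

    def test_zero_input_zero_output(self):
        state = FilterState(None, 0.2)
        assert input_gain_control_step(0.0, state, tau_A=0.2, dt=DT) == 0.0

    def test_steady_state_scale_invariance(self):
        """After settling, the normalised output of a sinusoid is amplitude independent."""
        t = np.arange(4000) * DT
        x = np.sin(2 * np.pi * 5.0 * t)

        def settled(amplitude):
            state = FilterState(None, 0.2)
            return np.array(
                [input_gain_control_step(amplitude * xi, state, 0.2, DT, eps=1e-9) for xi in x]
            )[-800:]

        a, b = settled(1.0), settled(10.0)
        assert np.allclose(a, b, atol=1e-6)


class TestEmdFieldBuilding:
    @pytest.mark.parametrize("n_cols,periodic,expected", [(2, False, 1), (4, False, 3), (288, True, 288)])
    def test_emd_column_count(self, rng, n_cols, periodic, expected):
        field = rng.standard_normal((50, 1, n_cols))
        pp, pm = build_emd_field(field, EmdParams(), DT, periodic=periodic)
        assert pp.shape == (50, 1, expected)
        assert pm.shape == pp.shape

    def test_rejects_single_column(self, rng):
        with pytest.raises(ValueError):
            build_emd_field(rng.standard_normal((10, 1, 1)), EmdParams(), DT)

    def test_field_matches_scalar_steps(self, rng):
        """The vectorised basic correlator reproduces the per-pair scalar recursion."""
        field = rng.standard_normal((80, 2, 4))
        pp, pm = build_emd_field(field, EmdParams(), DT)
        for r in range(2):
            for j in range(3):
                states = _delay_states()
                for t in range(80):
                    e_pp, e_pm = basic_emd_step(field[t, r, j], field[t, r, j + 1], states, DT)
                    assert pp[t, r, j] == pytest.approx(e_pp, abs=1e-12)
                    assert pm[t, r, j] == pytest.approx(e_pm, abs=1e-12)

    def test_rectification_contract(self, rng):
        field = rng.standard_normal((60, 3, 10))
        for variant in ("basic", "adaptive", "saturation", "input_gain"):
            pp, pm = build_emd_field(field, EmdParams(variant=variant), DT)
            assert np.all(pp >= 0) and np.all(pm >= 0)
            assert np.all(np.isfinite(pp)) and np.all(np.isfinite(pm))

    def test_adaptive_zero_input_zero_output(self):
        field = np.zeros((50, 1, 4))
        pp, pm = build_emd_field(field, EmdParams(variant="adaptive"), DT)
        assert np.all(pp == 0) and np.all(pm == 0)
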