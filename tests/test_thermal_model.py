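"""Unit and property tests for the closed-form series solution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import implant_heat as ih


class TestThermalLoad:
    def test_boundary_curve_examples(self):
        load = ih.ThermalLoad(60.0, 37.0, 2.0)
        assert ih.load_temperature(load, 0.0) == pytest.approx(60.0)
        assert ih.load_temperature(load, 2.0) == pytest.approx(37 + 23 / math.e)
        assert ih.load_temperature(load, 1e6) == pytest.approx(37.0)

    def test_strictly_decreasing_for_hot_load(self):
        load = ih.ThermalLoad(60.0, 37.0, 0.7)
        ts = np.linspace(0, 20, 200)
        vals = ih.load_temperature(load, ts)
        assert np.all(np.diff(vals) < 0)

    def test_delta_t_recomputed(self):
        assert ih.ThermalLoad(60.0, 37.0, 1.0).delta_t == 23.0
        assert ih.ThermalLoad(20.0, 37.0, 1.0).delta_t == -17.0

    @pytest.mark.parametrize("t0", [0.0, -1.0, math.inf])
    def test_invalid_exposure_time_rejected(self, t0):
        with pytest.raises(ValueError):
            ih.ThermalLoad(60.0, 37.0, t0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ih.load_temperature(ih.ThermalLoad(), -0.5)


class TestIntrinsicTime:
    @pytest.mark.parametrize(
        "alpha, expected",
        [(2e-6, 8.6), (5e-6, 3.4), (9.0e-6, 1.9), (6.25e-7, 27.4)],
    )
    def test_reference_materials_round_to_reported_values(self, alpha, expected):
        model = ih.ImplantModel(0.013, alpha)
        assert round(ih.intrinsic_time(model), 1) == expected

    def test_scale_invariance(self):
        a = ih.ImplantModel(0.013, 2e-6)
        b = ih.ImplantModel(0.026, 8e-6)  # L doubled, alpha quadrupled
        assert ih.intrinsic_time(a) == pytest.approx(ih.intrinsic_time(b))

    @pytest.mark.parametrize("length, alpha", [(-0.01, 2e-6), (0.013, 0.0)])
    def test_invalid_geometry_rejected(self, length, alpha):
        with pytest.raises(ValueError):
            ih.ImplantModel(length, alpha)


class TestParticularComponent:
    def test_anchors_and_midpoint(self, implant_a, hot_load):
        L = implant_a.length
        assert ih.particular_component(implant_a, hot_load, 5.0, 0.0) == 37.0
        assert ih.particular_component(implant_a, hot_load, 0.0, L) == 60.0
        t0 = hot_load.exposure_time
        assert ih.particular_component(implant_a, hot_load, t0, L / 2) == pytest.approx(
            37 + 11.5 / math.e
        )

    def test_linear_in_position(self, implant_a, hot_load):
        ys = np.linspace(0, implant_a.length, 7)
        w = ih.particular_component(implant_a, hot_load, 1.3, ys)
        assert np.allclose(np.diff(w, 2), 0.0, atol=1e-12)

    def test_position_outside_domain_rejected(self, implant_a, hot_load):
        with pytest.raises(ValueError):
            ih.particular_component(implant_a, hot_load, 1.0, 2 * implant_a.length)


class TestFourierCoefficient:
    def test_first_coefficients(self):
        assert ih.fourier_coefficient(1, 0.013) == pytest.approx(2 * 0.013 / math.pi)
        assert ih.fourier_coefficient(2, 0.013) == pytest.approx(-0.013 / math.pi)

    def test_matches_quadrature_of_projection_integral(self):
        # A_n should equal (2/L) * int_0^L y sin(n pi y / L) dy
        L = 0.013
        for n in range(1, 11):
            integral, _ = quad(lambda y: y * math.sin(n * math.pi * y / L), 0, L)
            assert ih.fourier_coefficient(n, L) == pytest.approx(
                2 / L * integral, abs=1e-12
            )

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            ih.fourier_coefficient(0, 0.013)


class TestModeAmplitude:
    def test_initial_value_independent_of_timescale_ratio(self, implant_a):
        for n in (1, 2, 3, 7):
            for t0 in (0.2, 2.0, 8.6, 30.0):
                load = ih.ThermalLoad(exposure_time=t0)
                expected = -((-1.0) ** (n + 1)) / n
                assert ih.mode_amplitude(n, 0.0, load, implant_a) == pytest.approx(
                    expected, abs=1e-9
                )

    def test_decays_to_zero(self, implant_a, hot_load):
        assert ih.mode_amplitude(1, 500.0, hot_load, implant_a) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_resonance_limit_value(self, implant_a):
        # at t0 = tau the n=1 amplitude crosses zero exactly at t = t0
        tau = implant_a.intrinsic_time
        load = ih.ThermalLoad(exposure_time=tau)
        assert ih.mode_amplitude(1, tau, load, implant_a) == pytest.approx(0.0, abs=1e-12)

    def test_resonance_branch_continuous(self, implant_a):
        # general branch just off resonance vs limit branch at resonance
        tau = implant_a.intrinsic_time
        at = ih.ThermalLoad(exposure_time=tau)
        ts = np.linspace(0.0, 10 * tau, 200)
        on = np.array([ih.mode_amplitude(1, t, at, implant_a) for t in ts])
        for eps in (+1e-6, -1e-6):
            off_load = ih.ThermalLoad(exposure_time=tau * (1 + eps))
            off = np.array([ih.mode_amplitude(1, t, off_load, implant_a) for t in ts])
            assert np.max(np.abs(on - off)) < 1e-4


class TestTemperatureField:
    def test_boundary_exactness(self, implant_a, hot_load):
        ts = np.linspace(0.0, 25.0, 40)
        field = ih.evaluate_field(
            implant_a, hot_load, ih.EvaluationGrid(ts, [0.0, implant_a.length])
        )
        assert np.allclose(field.values[:, 0], 37.0, atol=1e-12)
        assert np.allclose(
            field.values[:, 1], ih.load_temperature(hot_load, ts), atol=1e-10
        )

    def test_interior_initial_condition_recovered(self, implant_a, hot_load):
        cfg = ih.SeriesConfig(n_terms=2000)
        ys = np.linspace(0.001 * implant_a.length, 0.9 * implant_a.length, 50)
        field = ih.evaluate_field(implant_a, hot_load, ih.EvaluationGrid([0.0], ys), cfg)
        assert np.max(np.abs(field.values - 37.0)) < 0.05 * hot_load.delta_t

    def test_long_time_decay_to_body_temperature(self, implant_a, hot_load):
        t = 10 * max(hot_load.exposure_time, implant_a.intrinsic_time)
        ys = np.linspace(0, implant_a.length, 30)
        field = ih.evaluate_field(implant_a, hot_load, ih.EvaluationGrid([t], ys))
        assert np.max(np.abs(field.values - 37.0)) < 0.01

    def test_constant_load_gives_uniform_field(self, implant_a):
        load = ih.ThermalLoad(t_hot=37.0, t_body=37.0, exposure_time=2.0)
        grid = ih.EvaluationGrid(
            np.linspace(0, 10, 11), np.linspace(0, implant_a.length, 11)
        )
        field = ih.evaluate_field(implant_a, load, grid)
        assert np.allclose(field.values, 37.0, atol=1e-12)

    def test_tau_only_dependence(self, implant_a, hot_load):
        # same tau via different (L, alpha) -> identical temperatures at y/L
        c = 2.5
        other = ih.ImplantModel(c * implant_a.length, c**2 * implant_a.diffusivity)
        assert other.intrinsic_time == pytest.approx(implant_a.intrinsic_time)
        ts = np.linspace(0.0, 20.0, 15)
        fracs = np.linspace(0, 1, 9)
        fa = ih.evaluate_field(
            implant_a, hot_load, ih.EvaluationGrid(ts, fracs * implant_a.length)
        )
        fb = ih.evaluate_field(
            other, hot_load, ih.EvaluationGrid(ts, fracs * other.length)
        )
        assert np.max(np.abs(fa.values - fb.values)) < 1e-9

    def test_maximum_principle(self, implant_a, hot_load):
        # 2000 terms push truncation well below the 1e-6 degC band (the
        # load-forced series tail decays only like 1/n^3, so the default
        # 200 terms leave ~1e-5 degC)
        grid = ih.EvaluationGrid(
            np.linspace(0.05, 40, 60), np.linspace(0, implant_a.length, 41)
        )
        field = ih.evaluate_field(
            implant_a, hot_load, grid, ih.SeriesConfig(n_terms=2000)
        )
        assert field.values.min() >= 37.0 - 1e-6
        assert field.values.max() <= 60.0 + 1e-6

    def test_linearity_in_delta_t(self, implant_a):
        t, y = 4.0, implant_a.length / 3
        base = ih.temperature(implant_a, ih.ThermalLoad(60.0, 37.0, 2.0), t, y)
        scaled = ih.temperature(implant_a, ih.ThermalLoad(37.0 + 2 * 23.0, 37.0, 2.0), t, y)
        assert scaled - 37.0 == pytest.approx(2 * (base - 37.0), rel=1e-12)

    def test_cold_load_supported_by_linearity(self, implant_a):
        load = ih.ThermalLoad(t_hot=5.0, t_body=37.0, exposure_time=2.0)
        grid = ih.EvaluationGrid(
            np.linspace(0.05, 30, 40), np.linspace(0, implant_a.length, 21)
        )
        field = ih.evaluate_field(implant_a, load, grid, ih.SeriesConfig(n_terms=2000))
        assert field.values.min() >= 5.0 - 1e-6
        assert field.values.max() <= 37.0 + 1e-6

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ih.EvaluationGrid([], [0.0])

    def test_position_outside_implant_rejected(self, implant_a, hot_load):
        grid = ih.EvaluationGrid([0.0], [2 * implant_a.length])
        with pytest.raises(ValueError):
            ih.evaluate_field(implant_a, hot_load, grid)


class TestPeakTemperature:
    def test_depth_ordering(self, implant_a, hot_load):
        L = implant_a.length
        peaks = {
            name: ih.peak_temperature(implant_a, hot_load, frac * L)
            for name, frac in [("B1", 0.75), ("B2", 0.5), ("B3", 0.25)]
        }
        assert peaks["B1"][1] > peaks["B2"][1] > peaks["B3"][1]
        assert peaks["B1"][0] < peaks["B2"][0] < peaks["B3"][0]

    def test_peak_increases_with_exposure_time(self, implant_a):
        y = implant_a.length / 2
        peaks = [
            ih.peak_temperature(implant_a, ih.ThermalLoad(exposure_time=t0), y)[1]
            for t0 in (2.0, 5.0, 8.0, 11.0, 14.0)
        ]
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_zero_excess_gives_body_temperature_peak(self, implant_a):
        load = ih.ThermalLoad(t_hot=37.0, t_body=37.0, exposure_time=2.0)
        _, T_peak = ih.peak_temperature(implant_a, load, implant_a.length / 2)
        assert T_peak == pytest.approx(37.0, abs=1e-9)

    def test_invalid_inputs_rejected(self, implant_a, hot_load):
        with pytest.raises(ValueError):
            ih.peak_temperature(implant_a, hot_load, 0.0)
        with pytest.raises(ValueError):
            ih.peak_temperature(implant_a, hot_load, implant_a.length / 2, horizon=-1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    t=st.floats(0.05, 50.0),
    t0=st.floats(0.1, 15.0),
    frac=st.floats(0.0, 1.0),
)
def test_field_bounded_by_load_extremes(t, t0, frac):
    """Maximum principle holds across random times, loads and depths
    (2000 terms keep truncation below the 1e-6 degC band)."""
    model = ih.preset_model("implant_A")
    load = ih.ThermalLoad(60.0, 37.0, t0)
    value = ih.temperature(
        model, load, t, frac * model.length, ih.SeriesConfig(n_terms=2000)
    )
    assert 37.0 - 1e-6 <= value <= 60.0 + 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(t=st.floats(0.0, 60.0), t0=st.floats(0.1, 15.0))
def test_boundaries_exact_for_random_times(t, t0):
    """Sine terms vanish at both ends, so boundaries hold regardless of t."""
    model = ih.preset_model("implant_B")
    load = ih.ThermalLoad(60.0, 37.0, t0)
    assert ih.temperature(model, load, t, 0.0) == pytest.approx(37.0, abs=1e-10)
    assert ih.temperature(model, load, t, model.length) == pytest.approx(
        ih.load_temperature(load, t), abs=1e-9
    )
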