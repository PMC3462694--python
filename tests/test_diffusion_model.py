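"""Propagator, RTOP, biphasic time course, normalization and fitting."""

import numpy as np
import pytest

from selfseed import (
    DiffusionTensor,
    FractalExponents,
    ModelConfig,
    PhysicalPoint,
    fit_rtop_series,
    normalization_check,
    peak_time,
    propagator,
    propagator_fractal,
    quadratic_form,
    rtop,
    spatial_profile,
    time_course,
)

# (4 pi)^(-3/2), frozen from 30-digit evaluation
INV_4PI_CUBED_HALF = 0.022448390265645820


class TestPropagator:
    def test_unit_density_at_special_time(self):
        # (4 pi t_hat)^(3/2) = 1 when t_hat = 1/(4 pi), det D = 1
        assert propagator_fractal([0.0, 0.0, 0.0], 1.0 / (4.0 * np.pi),
                                  DiffusionTensor.isotropic(1.0)) == pytest.approx(1.0, rel=1e-14)

    def test_origin_value_unit_time(self, classical_config):
        p = propagator(PhysicalPoint(0, 0, 0, 1.0), classical_config)
        assert p == pytest.approx(INV_4PI_CUBED_HALF, rel=1e-14)

    @pytest.mark.parametrize("x", [(0.5, 0.5, 0.5), (1.0, -2.0, 0.3)])
    def test_even_symmetry(self, x, fig3_config):
        p_plus = propagator(PhysicalPoint(*x, 5.0), fig3_config)
        p_minus = propagator(PhysicalPoint(*(-v for v in x), 5.0), fig3_config)
        assert p_plus == pytest.approx(p_minus, rel=1e-14)
        assert p_plus > 0

    def test_singular_time_rejected(self, fig3_config):
        with pytest.raises(ValueError):
            propagator(PhysicalPoint(0.5, 0.5, 0.5, 0.0), fig3_config)

    def test_invalid_tensor_rejected(self):
        with pytest.raises(ValueError):
            DiffusionTensor(0.01, -0.01, 0.01)

    def test_solves_diffusion_equation_in_fractal_frame(self):
        """Finite-difference residual of dp/dt - sum_i D_ii d2p/dr_i2 is tiny
        in the smooth regime (t_hat >= 0.5, |r| <= 3)."""
        from conftest import pde_rel_residual

        tensor = DiffusionTensor(1.0, 0.5, 2.0)
        worst = max(
            pde_rel_residual(tensor, r, t_hat)
            for t_hat in (0.5, 1.0, 2.0)
            for r in ([0.3, -0.7, 1.1], [0.0, 0.0, 0.0], [1.8, 1.0, -1.9])
        )
        assert worst < 1e-6


class TestRTOP:
    def test_equals_propagator_at_origin(self, fig3_config):
        for t in (0.5, 1.0, 10.0, 250.0):
            assert rtop(t, fig3_config) == pytest.approx(
                propagator(PhysicalPoint(0, 0, 0, t), fig3_config), rel=1e-14
            )

    def test_power_law_scalings(self, classical_config):
        # doubling t multiplies by 2^(-3/2); quadrupling det D halves it
        assert rtop(2.0, classical_config) == pytest.approx(
            rtop(1.0, classical_config) * 2.0**-1.5, rel=1e-14
        )
        scaled = ModelConfig(classical_config.exponents, DiffusionTensor.isotropic(4.0 ** (1 / 3)))
        assert rtop(1.0, scaled) == pytest.approx(0.5 * rtop(1.0, classical_config), rel=1e-14)

    def test_strictly_decreasing_and_loglog_linear(self, fig1_config):
        t = np.linspace(1.0, 1000.0, 400)
        series = rtop(t, fig1_config)
        assert np.all(np.diff(series) < 0)
        slope = np.polyfit(np.log(t), np.log(series), 1)[0]
        assert slope == pytest.approx(-1.5 * 0.4, abs=1e-9)

    def test_zero_time_rejected(self, fig3_config):
        with pytest.raises(ValueError):
            rtop(0.0, fig3_config)


class TestNormalization:
    @pytest.mark.parametrize(
        "tensor, t",
        [
            (DiffusionTensor.isotropic(1.0), 1.0),
            (DiffusionTensor(0.01, 0.02, 0.03), 5.0),
            (DiffusionTensor.isotropic(0.01), 100.0),  # biphasic-curve tensor
            (DiffusionTensor.isotropic(1e-6), 500.0),
            (DiffusionTensor(2.0, 0.5, 1.0), 0.5),
        ],
    )
    def test_total_probability_is_one(self, tensor, t):
        config = ModelConfig(FractalExponents(alpha=0.4, beta=0.9), tensor)
        assert normalization_check(config, t) == pytest.approx(1.0, abs=1e-6)

    def test_conserved_across_times(self, classical_config):
        totals = [normalization_check(classical_config, t) for t in (0.1, 1.0, 10.0, 100.0)]
        assert totals == pytest.approx([1.0] * 4, abs=1e-6)


class TestTimeCourse:
    def test_biphasic_off_origin(self, fig3_config):
        t = np.linspace(1.0, 1500.0, 500)
        course = time_course((0.5, 0.5, 0.5), t, fig3_config)
        d = np.diff(course.densities)
        sign_changes = np.sum(np.diff(np.sign(d)) != 0)
        assert sign_changes == 1  # exactly one interior maximum
        assert d[0] > 0 and d[-1] < 0

    def test_monotone_decreasing_at_origin(self, fig3_config):
        t = np.linspace(1.0, 1500.0, 200)
        course = time_course((0.0, 0.0, 0.0), t, fig3_config)
        assert np.all(np.diff(course.densities) < 0)

    def test_peak_matches_closed_form(self, fig3_config):
        t_star = peak_time((0.5, 0.5, 0.5), fig3_config)
        # dense-grid numerical maximization oracle
        t = np.linspace(0.9 * t_star, 1.1 * t_star, 4001)
        course = time_course((0.5, 0.5, 0.5), t, fig3_config)
        assert course.argmax_time() == pytest.approx(t_star, rel=1e-3)

    def test_peak_time_closed_form_value(self):
        # Q = 6, alpha = 1 -> t* = 1 (grid-search oracle confirms)
        config = ModelConfig(FractalExponents(alpha=1.0, beta=1.0), DiffusionTensor.isotropic(1.0))
        pos = (np.sqrt(2.0), np.sqrt(2.0), np.sqrt(2.0))  # Q = 6
        assert quadratic_form(pos, config.tensor) == pytest.approx(6.0, rel=1e-14)
        assert peak_time(pos, config) == pytest.approx(1.0, rel=1e-14)
        grid = np.linspace(0.5, 2.0, 30001)
        course = time_course(pos, grid, config)
        assert course.argmax_time() == pytest.approx(1.0, abs=1e-3)

    def test_origin_peak_degenerate(self, fig3_config):
        with pytest.raises(ValueError):
            peak_time((0.0, 0.0, 0.0), fig3_config)

    def test_invalid_grid_rejected(self, fig3_config):
        with pytest.raises(ValueError):
            time_course((0.5, 0.5, 0.5), [1.0, 3.0, 2.0], fig3_config)


class TestSpatialProfile:
    def test_zero_row_equals_rtop(self, fig1_config):
        t = np.linspace(1.0, 1000.0, 50)
        surface = spatial_profile(np.array([0.0, 0.5, 0.7]), t, fig1_config)
        assert surface[0] == pytest.approx(rtop(t, fig1_config), rel=1e-14)

    def test_decreasing_in_x1(self, fig1_config):
        # compare on the log scale: the linear density underflows float64
        # within a fraction of a mm at D_ii = 1e-6
        x1 = np.linspace(0.0, 0.7, 15)
        surface = spatial_profile(x1, np.array([10.0, 100.0, 1000.0]), fig1_config, log=True)
        assert np.all(np.diff(surface, axis=0) < 0)

    def test_surface_finite_positive_on_caption_grid(self, fig1_config):
        x1 = np.linspace(0.5, 0.7, 21)
        t = np.linspace(1.0, 1000.0, 101)
        log_surface = spatial_profile(x1, t, fig1_config, log=True)
        assert log_surface.shape == (21, 101)
        # finite log-density everywhere == the density is strictly positive
        # in exact arithmetic, even where exp() underflows float64
        assert np.all(np.isfinite(log_surface))
        surface = spatial_profile(x1, t, fig1_config)
        assert np.all(np.isfinite(surface)) and np.all(surface >= 0)


class TestFitRTOPSeries:
    def test_noise_free_round_trip(self, fig1_config):
        t = np.geomspace(1.0, 1000.0, 50)
        fit = fit_rtop_series(t, rtop(t, fig1_config))
        assert fit.alpha == pytest.approx(0.4, abs=1e-9)
        assert fit.det_d == pytest.approx(fig1_config.tensor.det, rel=1e-6)

    def test_classical_slope_is_minus_three_halves(self, classical_config):
        t = np.geomspace(1.0, 100.0, 20)
        fit = fit_rtop_series(t, rtop(t, classical_config))
        assert fit.slope == pytest.approx(-1.5, abs=1e-12)

    def test_recovery_under_lognormal_noise(self, fig3_config):
        rng = np.random.default_rng(42)
        t = np.geomspace(1.0, 1000.0, 50)
        noisy = rtop(t, fig3_config) * rng.lognormal(0.0, 0.05, size=t.size)
        fit = fit_rtop_series(t, noisy)
        assert abs(fit.alpha - 0.4) < 3 * fit.alpha_stderr
        assert abs(fit.det_d - fig3_config.tensor.det) < 3 * fit.det_d_stderr

    @pytest.mark.parametrize(
        "times, dens",
        [
            ([1.0, 2.0], [1.0, 0.5]),  # too few points
            ([1.0, 2.0, 3.0], [1.0, -0.5, 0.2]),  # non-positive density
            ([0.0, 2.0, 3.0], [1.0, 0.5, 0.2]),  # non-positive time
        ],
    )
    def test_invalid_series_rejected(self, times, dens):
        with pytest.raises(ValueError):
            fit_rtop_series(times, dens)
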