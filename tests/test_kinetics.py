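"""Tracer-kinetic model tests: forward simulation, linearised fitting and
the coefficient <-> parameter mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalmdr import (AIF, DynamicSeries, KineticParams2CFM,
                      coeffs_to_params, concentration_to_signal,
                      cumulative_integral, fit_linear_2cfm,
                      fit_modified_tofts, params_to_coeffs,
                      simulate_concentration_2cfm)
from renalmdr.kinetics import (epsilons, fit_linear_pixels, fit_tofts_pixels,
                               signal_to_concentration,
                               simulate_concentration_2cfm_ode,
                               simulate_concentration_tofts)


# ---------------------------------------------------------------------------
# cumulative integration
# ---------------------------------------------------------------------------

class TestCumulativeIntegral:
    def test_constant_series_gives_trapezoid_ramp(self):
        out = cumulative_integral(np.ones(5), dt=1.0, order=1)
        assert np.allclose(out, [0, 1, 2, 3, 4])

    @pytest.mark.parametrize("order", [1, 2])
    def test_zero_series_stays_zero(self, order):
        out = cumulative_integral(np.zeros(8), dt=0.5, order=order)
        assert np.all(out == 0) and out[0] == 0

    def test_sine_matches_analytic_antiderivative(self):
        t = np.arange(0, 6.28, 0.01)
        out = cumulative_integral(np.sin(t), dt=0.01)
        assert np.max(np.abs(out - (1 - np.cos(t)))) < 1e-3

    def test_exact_on_linear_functions(self):
        # trapezoid rule integrates polynomials up to degree 1 exactly
        t = np.arange(6, dtype=float)
        out = cumulative_integral(2 * t + 3, dt=1.0)
        assert np.allclose(out, t**2 + 3 * t)

    def test_non_uniform_times_rejected(self):
        with pytest.raises(ValueError, match="sampling"):
            cumulative_integral(np.ones(4), dt=1.0,
                                times=np.array([0.0, 1.0, 2.5, 3.0]))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            cumulative_integral(np.ones(4), dt=1.0, order=3)


# ---------------------------------------------------------------------------
# forward 2CFM
# ---------------------------------------------------------------------------

class TestSimulate2CFM:
    def test_zero_aif_gives_zero_concentration(self, reference_params):
        times = np.arange(0, 50, 0.1)
        aif = AIF(times, np.zeros_like(times))
        C = simulate_concentration_2cfm(reference_params, aif)
        assert np.allclose(C, 0)

    def test_impulse_response_single_compartment(self):
        # FT = 0 with a (discrete) impulse input decays as FP * exp(-t/TP);
        # the impulse sits at an interior sample so the trapezoid rule gives
        # it full weight
        dt = 0.01
        times = np.arange(0, 40, dt)
        ca = np.zeros_like(times)
        ca[1] = 1.0 / dt
        aif = AIF(times, ca)
        p = KineticParams2CFM(FP=120.0, TP=8.0, FT=0.0, TT=100.0)
        C = simulate_concentration_2cfm(p, aif)
        expect = (120.0 / 6000.0) * np.exp(-(times - dt) / 8.0)
        assert np.max(np.abs(C[5:] - expect[5:])) < 2e-3 * expect[1]

    def test_convolution_and_ode_routes_agree(self):
        # two independent forward implementations cross-validate
        dt = 0.01
        times = np.arange(0, 60, dt)
        ca = ((times > 5) & (times < 15)).astype(float)  # boxcar bolus
        aif = AIF(times, ca)
        p = KineticParams2CFM(FP=150.0, TP=10.0, FT=50.0, TT=120.0)
        c1 = simulate_concentration_2cfm(p, aif)
        c2 = simulate_concentration_2cfm_ode(p, aif)
        assert np.max(np.abs(c1 - c2)) < 1e-3 * np.max(c1)

    def test_equal_transit_times_confluent_branch(self):
        # the cancellation-free confluent branch agrees with the independent
        # ODE route when the two transit times coincide
        times = np.arange(0, 60, 0.01)
        ca = np.exp(-((times - 10) / 3.0) ** 2)
        aif = AIF(times, ca)
        with pytest.warns(UserWarning, match="kidney-like"):
            p = KineticParams2CFM(FP=100.0, TP=12.0, FT=40.0, TT=12.0)
        c_conf = simulate_concentration_2cfm(p, aif)
        c_ode = simulate_concentration_2cfm_ode(p, aif)
        assert np.max(np.abs(c_conf - c_ode)) < 1e-3 * np.max(c_conf)

    def test_nonpositive_transit_time_rejected(self):
        times = np.arange(0, 10, 0.1)
        aif = AIF(times, np.ones_like(times))
        with pytest.raises(ValueError):
            simulate_concentration_2cfm(
                KineticParams2CFM(FP=100, TP=0.0, FT=10, TT=100), aif)


class TestSignalConcentration:
    def test_zero_concentration_returns_baseline(self):
        S0 = np.full((3, 3), 2.0)
        S = concentration_to_signal(S0, np.zeros((3, 3, 5)))
        assert np.all(S == 2.0)

    def test_unit_baseline_convention(self):
        C = np.linspace(0, 1, 7)
        assert np.allclose(concentration_to_signal(1.0, C), 1.0 + C)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        S0 = rng.uniform(0.5, 2, (4, 4))
        C = rng.uniform(0, 1, (4, 4, 6))
        S = concentration_to_signal(S0, C)
        assert np.allclose(signal_to_concentration(S, S0), C)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            concentration_to_signal(np.ones((3, 4)), np.zeros((5, 5, 2)))


# ---------------------------------------------------------------------------
# linearised fit and parameter recovery
# ---------------------------------------------------------------------------

def _forward_signal(params, fine_aif):
    C = simulate_concentration_2cfm(params, fine_aif)
    return concentration_to_signal(1.0, C)


class TestLinearFit:
    def test_noise_free_self_consistency(self, fine_aif, reference_params):
        S = _forward_signal(reference_params, fine_aif)
        data = np.tile(S, (3, 1))
        coeffs, sigma = fit_linear_pixels(data, fine_aif.values,
                                          fine_aif.dt, n0=150)
        rel = np.sqrt(np.mean((sigma - data) ** 2)) / np.std(data)
        assert rel < 1e-3

    def test_constant_series_gives_zero_coefficients(self, frame_aif):
        data = np.full((4, frame_aif.values.size), 3.0)
        coeffs, sigma = fit_linear_pixels(data, frame_aif.values,
                                          frame_aif.dt, n0=13)
        assert np.all(coeffs.alpha1 == 0) and np.all(coeffs.beta2 == 0)
        assert np.all(sigma == 3.0)
        assert np.all(coeffs.flat)

    def test_linearity_of_fitted_curve(self, fine_aif, reference_params):
        # scaling the series by a and adding b reproduces a*Sigma + b
        S = _forward_signal(reference_params, fine_aif)[None, :]
        _, sig1 = fit_linear_pixels(S, fine_aif.values, fine_aif.dt, 150)
        _, sig2 = fit_linear_pixels(2.5 * S + 0.7, fine_aif.values,
                                    fine_aif.dt, 150)
        assert np.allclose(sig2, 2.5 * sig1 + 0.7, atol=1e-8)

    def test_fitted_curve_is_least_squares_optimal(self, fine_aif,
                                                   reference_params):
        rng = np.random.default_rng(1)
        S = _forward_signal(reference_params, fine_aif)
        S = S + rng.normal(0, 0.01, S.shape)
        data = S[None, :]
        coeffs, sigma = fit_linear_pixels(data, fine_aif.values,
                                          fine_aif.dt, 150)
        base_sse = np.sum((sigma - data) ** 2)
        c0 = np.array([coeffs.alpha1[0], coeffs.alpha2[0],
                       coeffs.beta1[0], coeffs.beta2[0]])
        y = data - coeffs.S0[:, None]
        X = np.stack([cumulative_integral(y[0], fine_aif.dt, 1),
                      cumulative_integral(y[0], fine_aif.dt, 2),
                      cumulative_integral(fine_aif.values, fine_aif.dt, 1),
                      cumulative_integral(fine_aif.values, fine_aif.dt, 2)],
                     axis=-1)
        for _ in range(20):
            pert = c0 * (1 + rng.normal(0, 0.01, 4))
            sse = np.sum((y[0] - X @ pert) ** 2)
            assert sse >= base_sse - 1e-12 * base_sse

    def test_fit_on_dynamic_series_interface(self, small_dro_still):
        inst = small_dro_still
        coeffs, sigma = fit_linear_2cfm(inst.series, inst.aif)
        assert sigma.shape == inst.series.data.shape
        assert coeffs.alpha1.shape == inst.series.spatial_shape


class TestParameterRecovery:
    @pytest.mark.parametrize("fp,tp,ft,tt", [
        (150.0, 10.0, 50.0, 120.0),
        (30.0, 6.0, 40.0, 90.0),
        (300.0, 20.0, 60.0, 300.0),
    ])
    def test_round_trip_recovers_parameters(self, fine_aif, fp, tp, ft, tt):
        p = KineticParams2CFM(FP=fp, TP=tp, FT=ft, TT=tt)
        S = _forward_signal(p, fine_aif)[None, :]
        coeffs, _ = fit_linear_pixels(S, fine_aif.values, fine_aif.dt, 150)
        pm = coeffs_to_params(coeffs)
        assert pm.valid[0]
        for name, truth in (("FP", fp), ("TP", tp), ("FT", ft), ("TT", tt)):
            rec = getattr(pm, name)[0]
            assert abs(rec - truth) / truth < 0.01

    def test_params_to_coeffs_inverse_pair(self, reference_params):
        a1, a2, b1, b2 = params_to_coeffs(reference_params)
        from renalmdr.kinetics import LinearCoeffs
        co = LinearCoeffs(alpha1=np.array(a1), alpha2=np.array(a2),
                          beta1=np.array(b1), beta2=np.array(b2),
                          S0=np.array(1.0))
        pm = coeffs_to_params(co)
        assert np.isclose(pm.FP, 150.0) and np.isclose(pm.TP, 10.0)
        assert np.isclose(pm.FT, 50.0) and np.isclose(pm.TT, 120.0)

    def test_one_compartment_limit(self):
        from renalmdr.kinetics import LinearCoeffs
        # alpha2 = beta2 = 0: single exponential, TT flagged absent
        co = LinearCoeffs(alpha1=np.array(-0.1), alpha2=np.array(0.0),
                          beta1=np.array(0.02), beta2=np.array(0.0),
                          S0=np.array(1.0))
        pm = coeffs_to_params(co)
        assert pm.single_compartment
        assert np.isclose(pm.TP, 10.0)
        assert np.isnan(pm.TT) and pm.FT == 0.0

    def test_complex_roots_flagged_not_raised(self):
        from renalmdr.kinetics import LinearCoeffs
        co = LinearCoeffs(alpha1=np.array(0.0), alpha2=np.array(-1.0),
                          beta1=np.array(0.01), beta2=np.array(0.01),
                          S0=np.array(1.0))
        pm = coeffs_to_params(co)
        assert not pm.valid
        assert np.isnan(pm.TP) and np.isnan(pm.FP)

    def test_epsilons_are_small_at_fine_sampling(self, reference_params):
        a1, a2, b1, b2 = params_to_coeffs(reference_params)
        from renalmdr.kinetics import LinearCoeffs
        co = LinearCoeffs(alpha1=np.array(a1), alpha2=np.array(a2),
                          beta1=np.array(b1), beta2=np.array(b2),
                          S0=np.array(1.0))
        e1, e2 = epsilons(co, dt=0.1)
        assert 0 < e1 < 0.05 and 0 < e2 < 0.05


# ---------------------------------------------------------------------------
# modified Tofts
# ---------------------------------------------------------------------------

class TestModifiedTofts:
    def test_round_trip_recovery(self, frame_aif):
        vp, kt, kep = 0.05, 0.003, 0.008
        C = simulate_concentration_tofts(vp, kt, kep, frame_aif)
        data = (1.0 + C)[None, :]
        maps, _ = fit_tofts_pixels(data, frame_aif.values, frame_aif.dt, 13)
        assert abs(maps.vp[0] - vp) / vp < 0.01
        assert abs(maps.ktrans[0] - kt) / kt < 0.01
        assert abs(maps.kep[0] - kep) / kep < 0.01

    def test_zero_aif_yields_zero_parameters(self):
        times = (np.arange(40) + 0.5) * 1.1
        data = 1.0 + np.linspace(0, 1, 40)[None, :]
        maps, sigma = fit_tofts_pixels(data, np.zeros(40), 1.1, 5)
        assert np.all(maps.vp == 0) and np.all(maps.ktrans == 0)
        assert np.allclose(sigma, data[:, :5].mean())

    def test_first_pass_misfit_on_filtration_data(self, fine_aif, frame_aif):
        # the Tofts model assumes infinite plasma flow and misfits the
        # dispersed first pass of the filtration model
        p = KineticParams2CFM(FP=300.0, TP=6.0, FT=60.0, TT=90.0)
        C = simulate_concentration_2cfm(p, fine_aif)
        S = concentration_to_signal(1.0, C.reshape(-1, 11).mean(axis=1))
        data = S[None, :]
        ca = frame_aif.values
        _, sig_lin = fit_linear_pixels(data, ca, frame_aif.dt, 13)
        _, sig_tof = fit_tofts_pixels(data, ca, frame_aif.dt, 13)
        first_pass = ca >= 0.3 * ca.max()
        r_lin = np.abs(data - sig_lin)[0][first_pass].mean()
        r_tof = np.abs(data - sig_tof)[0][first_pass].mean()
        assert r_tof > 2.0 * r_lin

    def test_dynamic_series_interface(self, small_dro_still):
        inst = small_dro_still
        maps, sigma = fit_modified_tofts(inst.series, inst.aif)
        assert sigma.shape == inst.series.data.shape
        assert maps.vp.shape == inst.series.spatial_shape


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class TestContainers:
    def test_aif_rejects_negative_values(self):
        with pytest.raises(ValueError, match="non-negative"):
            AIF(np.arange(5.0), np.array([0, 0, -1.0, 1, 1]))

    def test_aif_rejects_non_uniform_times(self):
        with pytest.raises(ValueError):
            AIF(np.array([0.0, 1.0, 3.0]), np.zeros(3))

    def test_aif_warns_on_nonzero_baseline(self):
        with pytest.warns(UserWarning, match="baseline"):
            AIF(np.arange(5.0), np.array([0.5, 0, 0, 1, 1]),
                baseline_duration=2.0)

    def test_aif_downsample_block_average(self):
        t = np.arange(6, dtype=float)
        a = AIF(t, np.array([0.0, 0, 2, 4, 6, 8]))
        d = a.downsample(2)
        assert np.allclose(d.values, [0, 3, 7])
        assert np.allclose(d.times, [0.5, 2.5, 4.5])

    @given(st.integers(min_value=2, max_value=40))
    @settings(max_examples=20, deadline=None)
    def test_series_needs_valid_n0(self, n0):
        data = np.zeros((3, 3, 20))
        if 1 <= n0 < 20:
            DynamicSeries(data, n0=n0)
        else:
            with pytest.raises(ValueError):
                DynamicSeries(data, n0=n0)

    def test_params_warn_on_inverted_transit_times(self):
        with pytest.warns(UserWarning, match="kidney-like"):
            KineticParams2CFM(FP=100, TP=200.0, FT=10, TT=100.0)

    def test_params_reject_negative(self):
        with pytest.raises(ValueError):
            KineticParams2CFM(FP=-1, TP=10, FT=10, TT=100)
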