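"""Resistive-force-theory energetics: drag law, dissipations, active moment
recovery, motor powers and cycle averaging."""

import numpy as np
import pytest

from flagkin import (
    BeatParams,
    MaterialParams,
    Waveform,
    compute_energetics,
    cycle_average,
    hydrodynamic_dissipation,
    internal_dissipation,
    motor_powers,
    recover_active_moment,
    rft_velocity_and_force,
    simulate_beat,
    to_waveform,
)
from flagkin.core import CenterlineSeries
from flagkin.energetics import RftFields, UM
from flagkin.errors import InsufficientRecordError, InvalidParameterError

from conftest import oscillating_rod_series, straight_rod_series


M = MaterialParams()


class TestRftFields:
    def test_static_filament_no_forces(self):
        fields = rft_velocity_and_force(straight_rod_series(), M)
        assert np.allclose(fields.velocity, 0.0)
        assert np.allclose(fields.force, 0.0)

    def test_axial_translation_pure_tangential_drag(self):
        """Rod sliding along its own axis: |f| = xi_t * U, tangential."""
        U = 50.0  # um/s
        s = np.arange(0.0, 100.0 + 0.5, 1.0)
        t = np.arange(5) / 250.0
        coords = np.zeros((t.size, s.size, 2))
        coords[..., 0] = s[None, :] + (U * t)[:, None]
        series = CenterlineSeries(coords, ds=1.0, fps=250.0)
        fields = rft_velocity_and_force(series, M)
        expected = M.xi_t * U * UM
        assert np.allclose(np.abs(fields.force[..., 0]), expected, rtol=1e-9)
        assert np.allclose(fields.force[..., 1], 0.0, atol=1e-25)

    def test_transverse_oscillation_matches_analytic_force(self):
        """y(t) = Y sin(wt): normal force density -xi_n Y w cos(wt)."""
        Y, f = 10.0, 5.0
        series = oscillating_rod_series(Y=Y, f=f, fps=250.0, duration=1.0)
        fields = rft_velocity_and_force(series, M)
        t = np.arange(series.n_frames) / series.fps
        w = 2 * np.pi * f
        expected = -M.xi_n * (Y * UM) * w * np.cos(w * t)
        got = fields.force[:, 10, 1]  # any interior station
        interior = slice(1, -1)  # central differences only
        scale = M.xi_n * Y * UM * w
        assert np.max(np.abs(got[interior] - expected[interior])) / scale < 0.01


class TestHydrodynamicDissipation:
    def test_static_zero(self):
        fields = rft_velocity_and_force(straight_rod_series(), M)
        assert np.allclose(hydrodynamic_dissipation(fields, M)["total"], 0.0)

    def test_rigid_oscillation_closed_form(self):
        """<D_h> = xi_n L (Y w)^2 / 2 for a rigidly oscillating rod."""
        Y, f, L = 10.0, 5.0, 100.0
        series = oscillating_rod_series(Y=Y, f=f, length=L, fps=250.0, duration=1.0)
        fields = rft_velocity_and_force(series, M)
        dh = hydrodynamic_dissipation(fields, M)["total"]
        closed = M.xi_n * (L * UM) * (Y * UM * 2 * np.pi * f) ** 2 / 2.0
        assert cycle_average(dh, f, series.fps) == pytest.approx(closed, rel=0.02)

    def test_matches_dense_quadrature(self, beat_series):
        """Segment-rule integral agrees with trapezoid quadrature of the
        same integrand within 1%."""
        fields = rft_velocity_and_force(beat_series, M)
        dh = hydrodynamic_dissipation(fields, M)["total"]
        integrand = M.xi_t * fields.v_t**2 + M.xi_n * fields.v_n**2
        oracle = np.trapezoid(integrand, dx=fields.ds, axis=1)
        assert np.allclose(dh[1:-1], oracle[1:-1], rtol=0.01)

    def test_regional_split_partitions_total(self):
        series = oscillating_rod_series(length=100.0, duration=0.4)
        fields = rft_velocity_and_force(series, M)
        dh = hydrodynamic_dissipation(fields, M)
        recon = dh["head"] + dh["mid"] + dh["principal"] + dh["distal"]
        assert np.allclose(recon, dh["total"], rtol=1e-10)

    def test_quadratic_scaling_in_amplitude_and_frequency(self):
        base = oscillating_rod_series(Y=5.0, f=4.0, duration=0.5)
        amp2 = oscillating_rod_series(Y=10.0, f=4.0, duration=0.5)
        freq2 = oscillating_rod_series(Y=5.0, f=8.0, duration=0.5)
        def mean_dh(series, f):
            fields = rft_velocity_and_force(series, M)
            return cycle_average(hydrodynamic_dissipation(fields, M)["total"],
                                 f, series.fps)
        d0 = mean_dh(base, 4.0)
        assert mean_dh(amp2, 4.0) == pytest.approx(4 * d0, rel=0.01)
        assert mean_dh(freq2, 8.0) == pytest.approx(4 * d0, rel=0.01)


class TestInternalDissipation:
    def test_static_zero(self):
        w = to_waveform(straight_rod_series())
        assert np.allclose(internal_dissipation(w, M), 0.0)

    def test_uniform_curvature_oscillation_closed_form(self):
        """kappa(s,t) = K sin(wt) over length L: <D_i> = eta L (K w)^2 / 2."""
        K, f, L, fps = 0.05, 5.0, 100.0, 250.0  # K in 1/um
        t = np.arange(int(fps)) / fps
        s = np.arange(0.0, L + 0.5, 1.0)
        psi = (K * np.sin(2 * np.pi * f * t))[:, None] * s[None, :]
        w = Waveform(psi=psi, ds=1.0, dt=1.0 / fps)
        d_i = internal_dissipation(w, M)
        closed = M.eta_i * (L * UM) * (K / UM * 2 * np.pi * f) ** 2 / 2.0
        assert cycle_average(d_i, f, fps) == pytest.approx(closed, rel=0.02)

    def test_linearity_in_eta(self):
        w = to_waveform(oscillating_rod_series(duration=0.2))
        d1 = internal_dissipation(w, M)
        m2 = MaterialParams(eta_i=2 * M.eta_i)
        assert np.allclose(internal_dissipation(w, m2), 2 * d1, rtol=1e-12)


class TestActiveMoment:
    def test_static_straight_filament_zero_moment(self):
        series = straight_rod_series()
        w = to_waveform(series)
        m_a = recover_active_moment(series, w, M)
        assert np.allclose(m_a, 0.0, atol=1e-30)

    def test_static_bent_filament_elastic_moment_only(self):
        """Static arc of curvature K: m_a = -EI K (no drag, no friction)."""
        R = 20.0
        s = np.arange(0.0, 80.0 + 0.5, 1.0)
        arc = np.stack([R * np.sin(s / R), R * (1 - np.cos(s / R))], axis=1)
        series = CenterlineSeries(arc[None].repeat(3, axis=0), ds=1.0, fps=250.0)
        m_a = recover_active_moment(series, to_waveform(series), M)
        expected = -M.EI * (1.0 / (R * UM))
        interior = m_a[:, 2:-2]
        assert np.allclose(interior, expected, rtol=0.01)

    def test_point_force_gives_piecewise_linear_moment(self):
        """A single point force produces a moment that is linear proximal to
        the load and zero distal to it, matching a brute-force summation."""
        series = straight_rod_series(length=100.0)
        w = to_waveform(series)
        n_p = series.n_points
        force = np.zeros((series.n_frames, n_p, 2))
        j0 = 60
        force[:, j0, 1] = 1e-6  # N/m on one node
        fields = rft_velocity_and_force(series, M)
        fields = RftFields(velocity=fields.velocity, v_t=fields.v_t,
                           v_n=fields.v_n, tangent=fields.tangent,
                           normal=fields.normal, force=force,
                           ds=fields.ds, dt=fields.dt)
        m_a = recover_active_moment(series, w, M, fields)  # kappa = 0 here
        # brute-force oracle: M_i = -sum_seg (r_mid - r_i) x f_mid ds
        r = series.coords * UM
        f_mid = 0.5 * (force[0, 1:] + force[0, :-1])
        r_mid = 0.5 * (r[0, 1:] + r[0, :-1])
        oracle = np.empty(n_p)
        for i in range(n_p):
            rel = r_mid[i:] - r[0, i]
            oracle[i] = -np.sum(rel[:, 0] * f_mid[i:, 1]
                                - rel[:, 1] * f_mid[i:, 0]) * fields.ds
        scale = np.abs(oracle).max()
        assert np.max(np.abs(m_a[0] - oracle)) / scale < 0.01
        assert abs(m_a[0, -1]) < 1e-12 * scale  # free distal end
        # linear in s proximal to the load
        prox = m_a[0, : j0 - 2]
        slopes = np.diff(prox)
        assert np.allclose(slopes, slopes[0], rtol=1e-6)


class TestMotorPowers:
    def test_frozen_shape_no_power(self):
        series = straight_rod_series()
        w = to_waveform(series)
        m_a = np.ones_like(w.psi) * 1e-18
        p_in, d_m = motor_powers(m_a, w)
        assert np.allclose(p_in, 0.0) and np.allclose(d_m, 0.0)

    def test_sign_split_is_complete(self, beat_series):
        """With m_a chosen as kappa_dot itself the power density is
        non-negative everywhere, so D_m = 0 and P_in = integral of pi."""
        w = to_waveform(beat_series)
        from flagkin.energetics import _curvature_rate, _segment_integrate
        kdot = _curvature_rate(w, 0)
        m_a = kdot * 1e-30
        p_in, d_m = motor_powers(m_a, w)
        assert np.allclose(d_m, 0.0)
        oracle = _segment_integrate(m_a * kdot, w.ds * UM,
                                    np.ones(w.n_s - 1, dtype=bool))
        assert np.allclose(p_in, oracle, rtol=1e-12)

    def test_p_in_matches_quadrature_oracle_and_scale(self):
        """P_in(t) equals a dense sign-split quadrature of the local power
        density, and its cycle average sits at the tens-to-hundreds fW scale
        implied by the default material parameters."""
        p = BeatParams(beat_frequency=5.0, duration=1.0, fps=250.0)
        series = simulate_beat(p, ds=1.0)
        w = to_waveform(series)
        fields = rft_velocity_and_force(series, M)
        m_a = recover_active_moment(series, w, M, fields)
        p_in, d_m = motor_powers(m_a, w)
        from flagkin.energetics import _curvature_rate
        pi = m_a * _curvature_rate(w, 0)
        oracle = np.trapezoid(np.maximum(pi, 0.0), dx=w.ds * UM, axis=1)
        assert np.allclose(p_in[1:-1], oracle[1:-1], rtol=0.01)
        mean_fw = cycle_average(p_in, 5.0, 250.0) * 1e15
        assert 10.0 < mean_fw < 1000.0


class TestCycleAverage:
    def test_unit_conversion(self):
        x = np.full(500, 5e-13)
        assert cycle_average(x, 5.0, 250.0) * 1e15 == pytest.approx(500.0)

    def test_zero_mean_sinusoid_over_integer_periods(self):
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * 5.0 * t)
        assert abs(cycle_average(x, 5.0, 250.0)) < 1e-12

    def test_partial_period_truncation(self):
        """A 4.7-period record is averaged over 4 whole periods; the full
        record mean is measurably biased, the truncated one is not."""
        f, fps, A, B = 2.0, 250.0, 3.0, 5.0
        t = np.arange(int(4.7 / f * fps)) / fps
        x = A + B * np.sin(2 * np.pi * f * t + 0.3)
        assert cycle_average(x, f, fps) == pytest.approx(A, rel=0.005)
        assert abs(x.mean() - A) > 0.05
    def test_short_record_raises(self):
        with pytest.raises(InsufficientRecordError):
            cycle_average(np.ones(10), 1.0, 250.0)


def test_material_params_validation():
    with pytest.raises(InvalidParameterError):
        MaterialParams(EI=-1.0)
    with pytest.raises(InvalidParameterError):
        MaterialParams(xi_n=0.5e-3, xi_t=0.7e-3)


def test_all_powers_nonnegative(beat_series):
    prof = compute_energetics(beat_series, smooth_window=0)
    for name in ("p_in", "d_m", "d_i", "d_h"):
        assert np.all(getattr(prof, name) >= 0.0)
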