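"""Kymograph, beat frequency, section amplitudes, flexibility classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flagkin import (
    BeatParams,
    FlexibilityClass,
    SectionBoundaries,
    Waveform,
    analytic_waveform,
    beat_frequency,
    classify_flexibility,
    curvature_kymograph,
    section_amplitude,
    simulate_beat,
    summarize,
)
from flagkin.core import CurvatureKymograph
from flagkin.errors import (
    GridError,
    InsufficientCyclesError,
    InvalidAmplitudeError,
    SectionOutOfRangeError,
)

from conftest import oscillating_rod_series, straight_rod_series


class TestCurvature:
    def test_circular_arc_constant_curvature(self):
        R = 10.0
        s = np.arange(0.0, 50.0 + 0.5, 1.0)
        w = Waveform(psi=(s / R)[None].repeat(4, axis=0), ds=1.0, dt=0.004)
        k = curvature_kymograph(w)
        assert np.allclose(k.kappa, 0.1, atol=1e-9)

    def test_straight_zero_curvature(self):
        w = Waveform(psi=np.full((4, 30), 0.7), ds=1.0, dt=0.004)
        assert np.allclose(curvature_kymograph(w).kappa, 0.0)

    def test_sinusoidal_profile_matches_analytic_derivative(self):
        s = np.arange(0.0, 100.0 + 0.5, 1.0)
        psi = 0.4 * np.sin(2 * np.pi * s / 70.0)
        w = Waveform(psi=psi[None].repeat(3, axis=0), ds=1.0, dt=0.004)
        k = curvature_kymograph(w).kappa[0]
        exact = 0.4 * (2 * np.pi / 70.0) * np.cos(2 * np.pi * s / 70.0)
        # central differences: interior within 1%; one-sided ends are looser
        denom = 0.4 * 2 * np.pi / 70.0
        assert np.max(np.abs(k[1:-1] - exact[1:-1])) / denom < 0.01
        assert np.max(np.abs(k - exact)) / denom < 0.05

    def test_too_few_stations(self):
        with pytest.raises(GridError):
            curvature_kymograph(Waveform(psi=np.zeros((4, 2)), ds=1.0, dt=0.01))

    def test_curvature_integrates_back_to_psi(self):
        w = analytic_waveform(BeatParams(duration=0.4, fps=60.0), ds=1.0)
        k = curvature_kymograph(w).kappa
        # trapezoid cumulative integral of kappa recovers psi - psi(0)
        rebuilt = np.concatenate(
            [np.zeros((w.n_t, 1)),
             np.cumsum(0.5 * (k[:, 1:] + k[:, :-1]) * w.ds, axis=1)], axis=1)
        target = w.psi - w.psi[:, :1]
        assert np.max(np.abs(rebuilt - target)) < 0.02


class TestBeatFrequency:
    @staticmethod
    def _kym(signal, fps=250.0, n_s=9):
        return CurvatureKymograph(kappa=signal[:, None].repeat(n_s, axis=1),
                                  ds=1.0, dt=1.0 / fps)

    def test_pure_tone(self):
        t = np.arange(1000) / 250.0
        k = self._kym(np.sin(2 * np.pi * 5.0 * t))
        assert beat_frequency(k) == pytest.approx(5.0, abs=1.0 / (2 * 4.0))

    def test_constant_curvature_raises(self):
        with pytest.raises(InsufficientCyclesError):
            beat_frequency(self._kym(np.full(1000, 0.3)))

    def test_noisy_tone_matches_extremum_count_oracle(self):
        rng = np.random.default_rng(11)
        t = np.arange(1000) / 250.0
        clean = np.sin(2 * np.pi * 4.0 * t)
        noisy = clean + 0.2 * rng.normal(size=t.size)
        est = beat_frequency(self._kym(noisy))
        # oracle: analytic turning points of the noiseless tone at
        # t = 1/16 + k/8 s, counted over the same record
        turns = np.arange(1 / 16.0, t[-1] + 1e-12, 1 / 8.0)
        oracle = (turns.size - 1) / (2 * (turns[-1] - turns[0]))
        assert oracle == pytest.approx(4.0, abs=1e-9)
        assert est == pytest.approx(oracle, rel=0.05)

    def test_invariance_to_sign_flip_and_scaling(self):
        t = np.arange(1000) / 250.0
        base = np.sin(2 * np.pi * 5.0 * t) + 0.1 * np.sin(2 * np.pi * 1.0 * t)
        f0 = beat_frequency(self._kym(base))
        assert beat_frequency(self._kym(-base)) == pytest.approx(f0, rel=1e-9)
        assert beat_frequency(self._kym(7.3 * base)) == pytest.approx(f0, rel=1e-9)


class TestSectionAmplitude:
    def test_static_cell_zero_amplitude(self):
        amps = section_amplitude(straight_rod_series())
        assert all(v == 0.0 for v in amps.values())

    def test_rigid_transverse_oscillation_uniform_sweep(self):
        """Uniform translation y = 10 sin(2 pi f t): every material point
        sweeps 20 um peak to peak, so every section reads 20 um."""
        series = oscillating_rod_series(Y=10.0, f=5.0, duration=0.2)
        amps = section_amplitude(series)
        for v in amps.values():
            assert v == pytest.approx(20.0, rel=0.01)

    def test_matches_brute_force_excursion_oracle(self, beat_params):
        """Set-point sweeps agree with a dense independent integration of
        the same psi field."""
        series = simulate_beat(beat_params, ds=1.0)
        amps = section_amplitude(series)
        t = np.arange(beat_params.n_frames) / beat_params.fps
        s_dense = np.arange(0.0, 110.0 + 0.005, 0.01)
        env = beat_params.amplitude_envelope(s_dense)
        psi = env[None, :] * np.sin(
            2 * np.pi * (beat_params.beat_frequency * t[:, None]
                         - s_dense[None, :] / beat_params.wavelength)
            + beat_params.phase0)
        y = np.cumsum(np.sin(psi), axis=1) * 0.01
        b = SectionBoundaries()
        for name, s_eval in [("mid", b.mid_end), ("principal", min(b.principal_end, 110.0))]:
            idx = int(round(s_eval / 0.01)) - 1
            oracle = y[:, idx].max() - y[:, idx].min()
            assert amps[name] == pytest.approx(oracle, rel=0.02)

    def test_section_beyond_traced_length_raises(self):
        short = straight_rod_series(length=20.0)
        with pytest.raises(SectionOutOfRangeError):
            section_amplitude(short)


class TestClassifier:
    @pytest.mark.parametrize("amp,expected", [
        (30.0, FlexibilityClass.HIGHLY_FLEXIBLE),
        (27.0, FlexibilityClass.HIGHLY_FLEXIBLE),
        (20.0, FlexibilityClass.RELATIVELY_FLEXIBLE),
        (16.0, FlexibilityClass.RELATIVELY_FLEXIBLE),
        (10.0, FlexibilityClass.MODERATELY_STIFF),
        (6.0, FlexibilityClass.MODERATELY_STIFF),
        (3.0, FlexibilityClass.HIGHLY_STIFF),
        (0.0, FlexibilityClass.HIGHLY_STIFF),
    ])
    def test_bin_map(self, amp, expected):
        assert classify_flexibility(amp) is expected

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidAmplitudeError):
            classify_flexibility(-0.1)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=60.0,
                     allow_nan=False, allow_infinity=False))
    def test_monotone_in_amplitude(self, amp):
        """Stiffness order never increases as the amplitude grows."""
        c = classify_flexibility(amp)
        c_up = classify_flexibility(amp + 0.5)
        assert c_up.order >= c.order

    def test_sweep_produces_four_ordered_labels(self):
        labels = [classify_flexibility(a) for a in np.linspace(0.0, 39.0, 500)]
        distinct = list(dict.fromkeys(labels))
        assert distinct == list(FlexibilityClass)


def test_summarize_class_consistent_with_amplitude(beat_series):
    summary = summarize(beat_series)
    assert summary.flexibility_class is classify_flexibility(summary.amplitude_mid)
    assert summary.beat_frequency == pytest.approx(5.0, abs=0.25)
    assert summary.frames_used == beat_series.n_frames
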