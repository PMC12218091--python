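"""Shared fixtures: short synthetic beats and rendered scenes.

Everything is generated at test time with fixed seeds; scenes are kept small
(tens of frames) so the whole suite stays fast.
"""

import numpy as np
import pytest

from flagkin import (
    BeatParams,
    OpticsParams,
    render_frames,
    simulate_beat,
    trace_scene,
)
from flagkin.core import CenterlineSeries


@pytest.fixture(scope="session")
def optics_snr10() -> OpticsParams:
    return OpticsParams.for_snr(10.0)


@pytest.fixture(scope="session")
def beat_params() -> BeatParams:
    """A flexible 5 Hz beat, 24 frames covering two cycles."""
    return BeatParams(beat_frequency=5.0, duration=0.4, fps=60.0, seed=1)


@pytest.fixture(scope="session")
def beat_series(beat_params) -> CenterlineSeries:
    return simulate_beat(beat_params, ds=1.0)


@pytest.fixture(scope="session")
def beat_scene(beat_series, optics_snr10):
    return render_frames(beat_series, optics_snr10, seed=1)


@pytest.fixture(scope="session")
def traced_beat(beat_scene):
    series, qc = trace_scene(beat_scene)
    return series, qc


def straight_rod_series(length=100.0, ds=1.0, n_frames=3, fps=250.0,
                        angle=0.0) -> CenterlineSeries:
    """Static straight filament along a given direction from the origin."""
    s = np.arange(0.0, length + ds / 2, ds)
    coords = np.zeros((n_frames, s.size, 2))
    coords[..., 0] = np.cos(angle) * s
    coords[..., 1] = np.sin(angle) * s
    return CenterlineSeries(coords=coords, ds=ds, fps=fps)


def oscillating_rod_series(Y=10.0, f=5.0, length=100.0, ds=1.0, fps=250.0,
                           duration=1.0) -> CenterlineSeries:
    """Rigid straight rod translating transversely, y(t) = Y sin(2 pi f t)."""
    t = np.arange(int(duration * fps)) / fps
    s = np.arange(0.0, length + ds / 2, ds)
    coords = np.zeros((t.size, s.size, 2))
    coords[..., 0] = s[None, :]
    coords[..., 1] = (Y * np.sin(2 * np.pi * f * t))[:, None]
    return CenterlineSeries(coords=coords, ds=ds, fps=fps)
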