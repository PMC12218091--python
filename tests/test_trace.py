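"""Tracer: segmentation contracts, geometry recovery, waveform round trip."""

import numpy as np
import pytest

from flagkin import (
    OpticsParams,
    TraceConfig,
    analytic_waveform,
    render_frames,
    to_waveform,
    trace_scene,
)
from flagkin.core import CenterlineSeries
from flagkin.errors import GridError, SegmentationError, TraceError
from flagkin.trace import extract_centerline, segment_frame

from conftest import straight_rod_series


def _rod_scene(angle=0.0, length=100.0, flip=False):
    series = straight_rod_series(length=length, n_frames=2, angle=angle)
    if flip:
        series = CenterlineSeries(series.coords * np.array([-1.0, 1.0]),
                                  series.ds, series.fps)
    return render_frames(series, OpticsParams(), seed=0, noise=False)


def test_straight_rod_traced_to_collinear_points():
    scene = _rod_scene()
    cfg = TraceConfig()
    mask = segment_frame(scene.images[0], cfg, scene.pixel_size, scene.origin)
    pts = extract_centerline(mask, cfg, scene.pixel_size, scene.origin,
                             image=scene.images[0])
    # 100 um at 1 um spacing; the distal tip can truncate by < ds
    assert pts.shape[0] in (100, 101)
    assert np.linalg.norm(pts[0]) < 1.0  # head end at the anchor
    assert np.max(np.abs(pts[:, 1])) < 0.2  # collinear along +x


def test_mirrored_rod_keeps_head_first():
    """Flipping the cell left-right must not change which end is point 0."""
    scene = _rod_scene(flip=True)
    cfg = TraceConfig()
    mask = segment_frame(scene.images[0], cfg, scene.pixel_size, scene.origin)
    pts = extract_centerline(mask, cfg, scene.pixel_size, scene.origin,
                             image=scene.images[0])
    assert np.linalg.norm(pts[0]) < 1.0
    assert pts[-1, 0] < -90.0  # tail extends toward -x


def test_blank_frame_raises_zero_components():
    img = np.full((64, 64), 100, dtype=np.uint16)
    with pytest.raises(SegmentationError) as exc:
        segment_frame(img, TraceConfig())
    assert exc.value.n_components == 0


def test_two_objects_raise_component_count():
    scene = _rod_scene()
    img = scene.images[0].copy()
    stacked = np.vstack([img, img])  # two parallel rods
    with pytest.raises(SegmentationError) as exc:
        segment_frame(stacked, TraceConfig())
    assert exc.value.n_components == 2


def test_circle_arc_curvature_recovered():
    """A rendered arc of radius 20 um traces back to kappa = 0.05/um."""
    R = 20.0
    s = np.arange(0.0, 60.0 + 0.5, 1.0)
    coords = np.stack([R * np.sin(s / R), R * (1.0 - np.cos(s / R))],
                      axis=1)[None].repeat(2, axis=0)
    series = CenterlineSeries(coords, ds=1.0, fps=250.0)
    scene = render_frames(series, OpticsParams(), seed=0, noise=False)
    traced, _ = trace_scene(scene)
    w = to_waveform(traced)
    kappa = np.gradient(w.psi[0], w.ds)
    interior = kappa[3:-3]
    assert np.abs(interior.mean() * R - 1.0) < 0.05


def test_mask_skeleton_close_to_truth_at_snr10(beat_scene):
    """Segmented skeleton stays within 1 px of the true centerline."""
    from skimage.morphology import skeletonize

    cfg = TraceConfig()
    i = 0
    mask = segment_frame(beat_scene.images[i], cfg, beat_scene.pixel_size,
                         beat_scene.origin)
    skel = np.argwhere(skeletonize(mask)).astype(float)
    skel_um = np.stack([
        beat_scene.origin[0] + skel[:, 1] * beat_scene.pixel_size,
        beat_scene.origin[1] + skel[:, 0] * beat_scene.pixel_size,
    ], axis=1)
    truth = beat_scene.ground_truth.coords[i]
    # dense true polyline for distance queries
    fine = np.linspace(0, truth.shape[0] - 1, truth.shape[0] * 10)
    base = np.arange(truth.shape[0])
    dense = np.stack([np.interp(fine, base, truth[:, 0]),
                      np.interp(fine, base, truth[:, 1])], axis=1)
    d = np.min(np.linalg.norm(skel_um[:, None, :] - dense[None, :, :], axis=2),
               axis=1)
    assert np.max(d) <= beat_scene.pixel_size + 1e-9


def test_waveform_round_trip_rms(traced_beat, beat_params):
    """render -> trace -> waveform reproduces psi within 0.05 rad RMS."""
    traced, qc = traced_beat
    assert qc["frames_traced"] == qc["frames_total"]
    wt = to_waveform(traced)
    wg = analytic_waveform(beat_params, ds=1.0)
    n = min(wt.n_s, wg.n_s)
    rms = np.sqrt(np.mean((wt.psi[:, :n] - wg.psi[:, :n]) ** 2))
    assert rms < 0.05


def test_noiseless_arc_length_within_one_percent(beat_series):
    optics = OpticsParams()
    scene = render_frames(beat_series, optics, seed=0, noise=False)
    cfg = TraceConfig(max_length=118.0)
    traced, _ = trace_scene(scene, cfg)
    assert abs(traced.length / 110.0 - 1.0) < 0.01


def test_head_endpoint_stable_across_frames(traced_beat):
    traced, _ = traced_beat
    assert np.all(np.linalg.norm(traced.coords[:, 0], axis=1) < 1.0)


def test_to_waveform_contracts():
    rod = straight_rod_series(length=50.0, n_frames=3)
    w = to_waveform(rod)
    assert np.allclose(w.psi, 0.0, atol=1e-12)
    R = 10.0
    s = np.arange(0.0, 30.0 + 0.5, 1.0)
    arc = np.stack([R * np.sin(s / R), R * (1 - np.cos(s / R))], axis=1)
    series = CenterlineSeries(arc[None].repeat(3, axis=0), ds=1.0, fps=100.0)
    w = to_waveform(series)
    slope = np.polyfit(series.s[1:-1], w.psi[0][1:-1], 1)[0]
    assert slope == pytest.approx(1.0 / R, rel=0.01)
    with pytest.raises(GridError):
        to_waveform(CenterlineSeries(np.zeros((2, 2, 2)), 1.0, 100.0))


def test_recording_rejected_when_most_frames_fail(beat_scene):
    """A config that cannot segment anything trips the 80% QC gate."""
    cfg = TraceConfig(threshold_method="fixed", fixed_threshold=1e6)
    with pytest.raises(TraceError):
        trace_scene(beat_scene, cfg)
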