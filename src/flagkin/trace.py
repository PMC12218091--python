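"""Centerline recovery from video frames and waveform assembly.

Per frame: threshold -> single-component mask -> skeletonize -> prune side
branches -> order pixels head-to-tip -> smoothing spline -> uniform
arc-length resampling.  Frames that fail (broken mask, self-crossing
skeleton) are reported so the pipeline can drop them; a recording is
rejected when fewer than 80% of its frames trace successfully.

The traced output is a :class:`~flagkin.core.CenterlineSeries` identical in
schema to the generator's ground truth, so simulated and traced recordings
are interchangeable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splev, splprep
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_holes, remove_small_objects, skeletonize

from .core import CenterlineSeries, Waveform
from .errors import GridError, InvalidParameterError, SegmentationError, TraceError

__all__ = ["TraceConfig", "segment_frame", "extract_centerline", "to_waveform",
           "trace_scene", "series_from_frames"]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class TraceConfig:
    """Parameters of the per-frame centerline tracer."""

    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.0  # counts, used when threshold_method == "fixed"
    min_object_px: int = 30
    head_anchor: tuple[float, float] = (0.0, 0.0)  # um
    head_mask_radius: float = 0.0  # um; exclude a head blob around the anchor
    spline_smoothing: float = 0.02  # um^2 residual budget per point
    resample_ds: float = 1.0  # um
    max_length: float = 100.0  # um, analysis length cap
    prune_length: float = 3.0  # um, side branches shorter than this are removed
    min_traced_fraction: float = 0.8  # recording QC gate
    refine_normal: bool = True  # re-center points on the intensity ridge
    refine_halfwidth: float = 1.5  # um, half-extent of the normal profile
    anchor_clamp: bool = True  # extend the trace to the known tether point
    anchor_clamp_max: float = 5.0  # um, ignore the anchor beyond this distance

    def __post_init__(self) -> None:
        if self.resample_ds <= 0:
            raise InvalidParameterError("resample_ds must be positive")
        if not 0 < self.max_length <= 120.0:
            raise InvalidParameterError("max_length must be in (0, 120] um")
        if self.threshold_method not in ("otsu", "fixed"):
            raise InvalidParameterError("threshold_method must be 'otsu' or 'fixed'")


def segment_frame(image: np.ndarray, config: TraceConfig,
                  pixel_size: float = 0.33,
                  origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Binary mask containing exactly the flagellum ridge.

    Raises :class:`SegmentationError` with the component count when zero or
    more than one connected component survives the small-object filter.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("segment_frame expects a 2-D grayscale image")
    if config.threshold_method == "fixed":
        thr = config.fixed_threshold
    else:
        if img.max() == img.min():
            raise SegmentationError(0)
        thr = threshold_otsu(img)
    mask = img > thr
    if config.head_mask_radius > 0.0:
        rr, cc = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        x = origin[0] + cc * pixel_size
        y = origin[1] + rr * pixel_size
        head = (x - config.head_anchor[0]) ** 2 + (y - config.head_anchor[1]) ** 2
        mask &= head > config.head_mask_radius**2
    # noise can punch pinholes into the ridge; filling them keeps the
    # skeleton loop-free
    mask = remove_small_holes(mask, max_size=64)
    mask = remove_small_objects(mask, max_size=config.min_object_px - 1)
    n = int(cc_label(mask, connectivity=2).max())
    if n != 1:
        raise SegmentationError(n)
    return mask


def _prune_and_order(skel: np.ndarray, prune_px: int) -> np.ndarray:
    """Ordered tip-to-tip skeleton path as (n, 2) row/col pixel coordinates.

    The centerline is the longest geodesic through the 8-connected skeleton
    graph (two Dijkstra passes), which makes the ordering immune to the
    corner-pixel junction artifacts of thinned masks.  Side branches shorter
    than ``prune_px`` are simply left off the path; any longer off-path
    residue means a genuinely branched or self-crossing flagellum and raises
    :class:`TraceError` so the frame can be excluded.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components, dijkstra

    coords = np.argwhere(skel)
    n = coords.shape[0]
    if n < 3:
        raise TraceError(f"skeleton too small ({n} px)")
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    rows, cols, wts = [], [], []
    for i, (r, c) in enumerate(coords):
        for dr, dc in _NEIGHBORS:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
                wts.append((dr * dr + dc * dc) ** 0.5)
    graph = csr_matrix((wts, (rows, cols)), shape=(n, n))
    d0 = dijkstra(graph, indices=0)
    if np.any(np.isinf(d0)):
        raise TraceError("disconnected skeleton")
    tip_a = int(np.argmax(d0))
    d_a, pred = dijkstra(graph, indices=tip_a, return_predecessors=True)
    tip_b = int(np.argmax(d_a))
    path = [tip_b]
    while path[-1] != tip_a:
        path.append(int(pred[path[-1]]))
    on_path = np.zeros(n, dtype=bool)
    on_path[path] = True
    residue = np.flatnonzero(~on_path)
    if residue.size:
        sub = graph[residue][:, residue]
        n_comp, comp = connected_components(sub, directed=False)
        sizes = np.bincount(comp, minlength=n_comp)
        if sizes.max() > prune_px:
            raise TraceError(
                f"skeleton branch of {int(sizes.max())} px off the main path "
                "(self-crossing or branched flagellum)"
            )
    return coords[path]


def _fit_resample(xy: np.ndarray, config: TraceConfig, smoothing: float
                  ) -> np.ndarray:
    """Smoothing-spline fit of an ordered polyline, resampled at uniform
    arc-length spacing up to ``max_length``."""
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
    if chord[-1] <= config.resample_ds:
        raise TraceError(f"traced length {chord[-1]:.2f} um too short")
    keep = np.concatenate([[True], np.diff(chord) > 1e-9])
    xy, chord = xy[keep], chord[keep]
    k = 3 if xy.shape[0] > 3 else 1
    tck, _ = splprep([xy[:, 0], xy[:, 1]], u=chord, s=smoothing * xy.shape[0], k=k)
    # measure arc length of the smoothed curve on a dense grid, then invert
    u_dense = np.linspace(chord[0], chord[-1], 8 * xy.shape[0])
    xd, yd = splev(u_dense, tck)
    dense = np.stack([xd, yd], axis=1)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    total = min(arc[-1], config.max_length)
    n_pts = int(np.floor(total / config.resample_ds + 1e-9)) + 1
    targets = np.arange(n_pts) * config.resample_ds
    u_t = np.interp(targets, arc, u_dense)
    xs, ys = splev(u_t, tck)
    return np.stack([xs, ys], axis=1)


def _refine_on_ridge(pts: np.ndarray, image: np.ndarray, config: TraceConfig,
                     pixel_size: float, origin: tuple[float, float]) -> np.ndarray:
    """Shift points onto the intensity ridge crest along local normals.

    Samples the image on a short profile perpendicular to the curve at each
    point and moves the point to the background-subtracted intensity
    centroid; this removes most of the +-half-pixel skeleton quantization
    jitter, especially at the filament tips.
    """
    from scipy.ndimage import map_coordinates

    tang = np.gradient(pts, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0.0] = 1.0
    tang /= norm
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    offsets = np.linspace(-config.refine_halfwidth, config.refine_halfwidth, 11)
    sample = pts[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    rows = (sample[..., 1] - origin[1]) / pixel_size
    cols = (sample[..., 0] - origin[0]) / pixel_size
    prof = map_coordinates(image.astype(float), [rows.ravel(), cols.ravel()],
                           order=1, mode="nearest").reshape(rows.shape)
    # local background from the profile wings
    bg = 0.5 * (prof[:, 0] + prof[:, -1])
    w = np.maximum(prof - bg[:, None], 0.0)
    total = w.sum(axis=1)
    ok = total > 0
    shift = np.zeros(pts.shape[0])
    shift[ok] = (w[ok] * offsets[None, :]).sum(axis=1) / total[ok]
    np.clip(shift, -config.refine_halfwidth / 2, config.refine_halfwidth / 2, out=shift)
    return pts + shift[:, None] * normal


def _extend_tip(pts: np.ndarray, image: np.ndarray, config: TraceConfig,
                pixel_size: float, origin: tuple[float, float]) -> np.ndarray:
    """Extend the distal end to the true ridge tip.

    Thresholding and skeletonization retreat a few pixels from the fading
    ridge end.  The intensity a distance d beyond the true endpoint of a
    blurred line falls off as an error function that passes 50% of the local
    ridge level exactly at the endpoint, so the curve is extended along its
    end tangent until the sampled intensity drops below half the local
    ridge level.
    """
    from scipy.ndimage import map_coordinates

    if pts.shape[0] < 5:
        return pts
    tang = pts[-1] - pts[-4]
    norm = np.linalg.norm(tang)
    if norm == 0.0:
        return pts
    tang /= norm

    def sample(points: np.ndarray) -> np.ndarray:
        rows = (points[:, 1] - origin[1]) / pixel_size
        cols = (points[:, 0] - origin[0]) / pixel_size
        return map_coordinates(image.astype(float), [rows, cols],
                               order=1, mode="nearest")

    # low percentile: robust background even when the ridge covers a large
    # fraction of a tightly cropped canvas
    bg = float(np.percentile(image, 20))
    level = float(np.median(sample(pts[-8:-2]))) - bg
    if level <= 0:
        return pts
    step = 0.25  # um
    probe_d = np.arange(step, 5.0 + step / 2, step)
    probe = pts[-1][None, :] + probe_d[:, None] * tang[None, :]
    intensity = sample(probe) - bg
    below = np.flatnonzero(intensity < 0.5 * level)
    n_ext = below[0] if below.size else probe_d.size
    if n_ext == 0:
        return pts
    return np.concatenate([pts, probe[:n_ext]], axis=0)


def extract_centerline(mask: np.ndarray, config: TraceConfig,
                       pixel_size: float = 0.33,
                       origin: tuple[float, float] = (0.0, 0.0),
                       image: np.ndarray | None = None) -> np.ndarray:
    """Ordered, spline-smoothed, uniformly resampled centerline (um).

    Point 0 is the skeleton endpoint nearest ``config.head_anchor``; points
    are spaced ``resample_ds`` apart up to ``max_length``.  When the source
    ``image`` is supplied and ``config.refine_normal`` is set, points are
    re-centered on the intensity ridge before the final spline pass.
    """
    skel = skeletonize(mask)
    prune_px = max(1, int(round(config.prune_length / pixel_size)))
    rc = _prune_and_order(skel, prune_px).astype(float)
    xy = np.stack([origin[0] + rc[:, 1] * pixel_size,
                   origin[1] + rc[:, 0] * pixel_size], axis=1)
    # orient head first
    anchor = np.asarray(config.head_anchor, dtype=float)
    if np.linalg.norm(xy[-1] - anchor) < np.linalg.norm(xy[0] - anchor):
        xy = xy[::-1]
    pts = _fit_resample(xy, config, config.spline_smoothing)
    if config.refine_normal and image is not None:
        pts = _refine_on_ridge(pts, image, config, pixel_size, origin)
        pts = _extend_tip(pts, image, config, pixel_size, origin)
    # skeletonization erodes the fading ridge tip; the tether point is known,
    # so re-root arc length there when the traced tip ends near it
    if config.anchor_clamp:
        gap = float(np.linalg.norm(pts[0] - anchor))
        if 1e-9 < gap < config.anchor_clamp_max:
            pts = np.concatenate([anchor[None, :], pts], axis=0)
    if config.refine_normal and image is not None or config.anchor_clamp:
        pts = _fit_resample(pts, config, config.spline_smoothing / 4.0)
    return pts


def series_from_frames(frames: list[np.ndarray], ds: float, fps: float) -> CenterlineSeries:
    """Stack per-frame centerlines, truncated to the common point count."""
    if not frames:
        raise TraceError("no successfully traced frames")
    n_common = min(f.shape[0] for f in frames)
    if n_common < 3:
        raise GridError("fewer than 3 common arclength stations across frames")
    coords = np.stack([f[:n_common] for f in frames])
    return CenterlineSeries(coords=coords, ds=ds, fps=fps)


def trace_scene(scene, config: TraceConfig | None = None
                ) -> tuple[CenterlineSeries, dict]:
    """Trace every frame of a :class:`~flagkin.render.SyntheticScene`.

    Returns the traced series and a QC dict (frames_total, frames_traced,
    failed_frames with reasons).  Raises :class:`TraceError` when fewer than
    ``min_traced_fraction`` of the frames trace successfully.
    """
    config = config or TraceConfig()
    traced: list[np.ndarray] = []
    failures: dict[int, str] = {}
    for i in range(scene.n_frames):
        try:
            mask = segment_frame(scene.images[i], config, scene.pixel_size, scene.origin)
            traced.append(extract_centerline(mask, config, scene.pixel_size,
                                             scene.origin, image=scene.images[i]))
        except (SegmentationError, TraceError) as exc:
            failures[i] = str(exc)
    qc = {
        "frames_total": scene.n_frames,
        "frames_traced": len(traced),
        "failed_frames": failures,
    }
    if len(traced) < config.min_traced_fraction * scene.n_frames:
        raise TraceError(
            f"only {len(traced)}/{scene.n_frames} frames traced "
            f"(QC gate {config.min_traced_fraction:.0%})"
        )
    series = series_from_frames(traced, config.resample_ds, scene.ground_truth.fps)
    return series, qc


def to_waveform(series: CenterlineSeries) -> Waveform:
    """Tangent-angle field psi(s, t) of a centerline series.

    psi is the finite-difference tangent angle, unwrapped along arc length
    per frame and made continuous in time by aligning each frame's base
    angle with the previous frame (2 pi multiples).
    """
    if series.n_points < 3:
        raise GridError("need at least 3 points per frame for tangent angles")
    dx = np.gradient(series.coords[..., 0], series.ds, axis=1)
    dy = np.gradient(series.coords[..., 1], series.ds, axis=1)
    psi = np.unwrap(np.arctan2(dy, dx), axis=1)
    base = psi[:, 0]
    shift = np.zeros_like(base)
    shift[1:] = np.cumsum(np.round(np.diff(base) / (2.0 * np.pi)))
    psi -= 2.0 * np.pi * shift[:, None]
    return Waveform(psi=psi, ds=series.ds, dt=series.dt)
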