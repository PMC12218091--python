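"""Waveform kinematics: curvature kymograph, beat frequency, section
amplitudes and the midpiece flexibility classification.

Conventions
-----------
* Curvature is the arc-length derivative of the tangent angle,
  kappa(s, t) = d psi / d s, in 1/um; positive values bend toward the head
  hook side.
* The beat frequency is read from curvature turning points (local extrema in
  time) at 50% and 75% of the analyzed length: consecutive turning points are
  half a beat apart, so f = (N - 1) / (2 * (t_last - t_first)) per station,
  averaged over the two stations.
* The "amplitude" of a tail section is the full peak-to-peak transverse sweep
  of the section's widest-sweeping material point, measured perpendicular to
  the cell axis (the time-averaged tangent of the head-adjacent 6.3 um).
  This is the only reading under which a midpiece whose distal end sits
  28.7 um from the tethered head can reach the 27-39 um amplitudes observed
  for highly flexible cells; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, savgol_filter

from .core import (
    CenterlineSeries,
    CurvatureKymograph,
    FlexibilityClass,
    KinematicSummary,
    SectionBoundaries,
    Waveform,
)
from .errors import (
    GridError,
    InsufficientCyclesError,
    InvalidAmplitudeError,
    SectionOutOfRangeError,
)

__all__ = [
    "curvature_kymograph",
    "beat_frequency",
    "station_amplitudes",
    "section_amplitude",
    "classify_flexibility",
    "summarize",
    "CLASS_BINS",
]


def curvature_kymograph(w: Waveform, smooth_sigma: float = 0.0) -> CurvatureKymograph:
    """Curvature field kappa = d psi / d s by central differences.

    One-sided differences are used at the two ends.  ``smooth_sigma`` is an
    optional Gaussian smoothing length along s, in micrometres.
    """
    if w.n_s < 3:
        raise GridError(f"need at least 3 arclength stations, got {w.n_s}")
    kappa = np.gradient(w.psi, w.ds, axis=1)
    if smooth_sigma > 0.0:
        kappa = gaussian_filter1d(kappa, smooth_sigma / w.ds, axis=1, mode="nearest")
    return CurvatureKymograph(kappa=kappa, ds=w.ds, dt=w.dt)


def _station_frequency(kt: np.ndarray, dt: float, prominence_frac: float,
                       smooth_window: int) -> float:
    if smooth_window >= 5 and kt.size > smooth_window:
        kt = savgol_filter(kt, smooth_window, polyorder=2)
    span = float(kt.max() - kt.min())
    if span <= 1e-12 * max(1.0, float(np.abs(kt).max())):
        raise InsufficientCyclesError("curvature series is constant; no turning points")
    prom = prominence_frac * span
    maxima, _ = find_peaks(kt, prominence=prom)
    minima, _ = find_peaks(-kt, prominence=prom)
    turns = np.sort(np.concatenate([maxima, minima]))
    if turns.size < 3:
        raise InsufficientCyclesError(
            f"only {turns.size} curvature turning points found (need >= 3)"
        )
    elapsed = (turns[-1] - turns[0]) * dt
    return (turns.size - 1) / (2.0 * elapsed)


def beat_frequency(k: CurvatureKymograph, stations: tuple[float, float] = (0.5, 0.75),
                   prominence_frac: float = 0.1, smooth_window: int = 11) -> float:
    """Beat frequency (Hz) from curvature turning points at fractional stations.

    Turning points (alternating curvature maxima and minima with prominence at
    least ``prominence_frac`` of the station's curvature range) are counted at
    each requested fraction of the analyzed length; the per-station estimates
    are averaged.
    """
    freqs = []
    for frac in stations:
        idx = int(round(frac * (k.n_s - 1)))
        freqs.append(_station_frequency(k.kappa[:, idx], k.dt,
                                        prominence_frac, smooth_window))
    return float(np.mean(freqs))


def _cell_axis(series: CenterlineSeries, head_end: float) -> float:
    """Axis angle (rad): mean unit tangent over the head-adjacent stations."""
    n_head = max(2, int(np.ceil(head_end / series.ds)) + 1)
    n_head = min(n_head, series.n_points)
    seg = np.diff(series.coords[:, :n_head], axis=1)
    norm = np.linalg.norm(seg, axis=2, keepdims=True)
    norm[norm == 0.0] = 1.0
    unit = seg / norm
    mean_vec = unit.reshape(-1, 2).mean(axis=0)
    return float(np.arctan2(mean_vec[1], mean_vec[0]))


def station_amplitudes(series: CenterlineSeries,
                       bounds: SectionBoundaries | None = None,
                       smooth_window: int = 1) -> np.ndarray:
    """Full peak-to-peak transverse sweep (um) of every material point.

    The transverse coordinate is measured perpendicular to the cell axis.
    ``smooth_window`` > 1 applies a centered moving average over frames before
    taking the sweep, damping tracing jitter.
    """
    bounds = bounds or SectionBoundaries()
    theta = _cell_axis(series, bounds.head_end)
    x = series.coords[..., 0]
    y = series.coords[..., 1]
    y_perp = -np.sin(theta) * x + np.cos(theta) * y
    if smooth_window > 1 and series.n_frames > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        y_perp = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="valid"), 0, y_perp
        )
    return y_perp.max(axis=0) - y_perp.min(axis=0)


def section_amplitude(series: CenterlineSeries,
                      bounds: SectionBoundaries | None = None,
                      smooth_window: int = 1) -> dict[str, float]:
    """Amplitude (um) of the head, midpiece and principal-piece sections.

    Each section's amplitude is the station sweep evaluated at the section's
    distal set point (6.3, 28.7 and 108.7 um by default) by linear
    interpolation in arc length, capped at the traced length.  Because the
    sweep grows monotonically away from the tethered head, this is the
    section's widest excursion, and interpolating at the set point makes the
    read-out independent of where the resampling grid happens to fall.
    """
    bounds = bounds or SectionBoundaries()
    sweeps = station_amplitudes(series, bounds, smooth_window)
    s = series.s
    out: dict[str, float] = {}
    for name in ("head", "mid", "principal"):
        lo, hi = bounds.window(name)
        if lo >= s[-1]:
            raise SectionOutOfRangeError(
                f"section '{name}' starts at {lo} um but traced length is {s[-1]:.1f} um"
            )
        out[name] = float(np.interp(min(hi, s[-1]), s, sweeps))
    return out


# Contiguous half-open classifier bins (um).  The printed category ranges
# (0.6-6, 6-15, 16-27, 27-39) leave a 15-16 um gap and an open bottom; these
# are treated as rounding, so every non-negative amplitude is classified.
CLASS_BINS: list[tuple[float, float, FlexibilityClass]] = [
    (0.0, 6.0, FlexibilityClass.HIGHLY_STIFF),
    (6.0, 16.0, FlexibilityClass.MODERATELY_STIFF),
    (16.0, 27.0, FlexibilityClass.RELATIVELY_FLEXIBLE),
    (27.0, float("inf"), FlexibilityClass.HIGHLY_FLEXIBLE),
]


def classify_flexibility(amplitude_mid: float) -> FlexibilityClass:
    """Map a midpiece amplitude (um) to its flexibility category."""
    if not np.isfinite(amplitude_mid) or amplitude_mid < 0:
        raise InvalidAmplitudeError(f"invalid midpiece amplitude {amplitude_mid!r}")
    for lo, hi, cls in CLASS_BINS:
        if lo <= amplitude_mid < hi:
            return cls
    raise AssertionError("unreachable: bins cover [0, inf)")


def summarize(series: CenterlineSeries, waveform: Waveform | None = None,
              bounds: SectionBoundaries | None = None,
              smooth_window: int = 1) -> KinematicSummary:
    """Convenience wrapper: frequency + amplitudes + class for one recording.

    The beat frequency is NaN when the record carries no resolvable
    oscillation (static cell).
    """
    from .trace import to_waveform  # local import to avoid a cycle

    bounds = bounds or SectionBoundaries()
    w = waveform if waveform is not None else to_waveform(series)
    kym = curvature_kymograph(w)
    try:
        freq = beat_frequency(kym)
    except InsufficientCyclesError:
        freq = float("nan")
    amps = section_amplitude(series, bounds, smooth_window)
    return KinematicSummary(
        beat_frequency=freq,
        amplitude_mid=amps["mid"],
        amplitude_principal=amps["principal"],
        amplitude_head=amps["head"],
        flexibility_class=classify_flexibility(amps["mid"]),
        frames_used=series.n_frames,
    )
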