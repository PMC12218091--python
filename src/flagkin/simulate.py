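"""Synthetic flagellar beat generator.

Beats are generated directly in the tangent-angle representation as an
amplitude-modulated traveling wave

    psi(s, t) = A(s) * sin(2 pi (f t - s / lambda) + phi0 + J(t)),

where ``A(s)`` is the tangent-angle amplitude envelope (radians) and ``J(t)``
an optional phase-diffusion term that makes beating irregular.  Positions are
obtained by stepping inextensible segments of length ``ds`` along the midpoint
tangent, with the head clamped at the origin (tethered-head assay).  Because
every segment has exactly length ``ds``, arc length is conserved to machine
precision in every frame.

The default amplitude envelope vanishes at the head junction, saturates over
~10 um and optionally suppresses the midpiece, emulating a stiffened
mitochondrial-sheath region.  A single weight ``mid_weight`` in [0, 1]
interpolates between a fully suppressed and a fully flexible midpiece; the
population sampler solves this weight by bisection to hit a requested
midpiece amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .core import CenterlineSeries, FlexibilityClass, SectionBoundaries, Waveform
from .errors import InvalidParameterError, SolverError
from .kinematics import section_amplitude

__all__ = [
    "BeatParams",
    "PopulationSpec",
    "saturating_envelope",
    "midpiece_envelope",
    "simulate_beat",
    "analytic_waveform",
    "sample_population",
    "DEFAULT_CATEGORY_INTERVALS",
]

# Envelope family constants (radians / micrometres).  ENVELOPE_SCALE is kept
# below pi/2 so the tangent never turns past +-90 degrees and the simulated
# flagellum cannot self-cross, which would break skeleton tracing.
ENVELOPE_SCALE = 1.45  # rad, peak tangent-angle amplitude
ENVELOPE_TAU = 10.0  # um, head-to-saturation length scale
SUPPRESSION_CENTER = 35.0  # um, logistic center of the midpiece suppression
SUPPRESSION_WIDTH = 2.0  # um


def saturating_envelope(scale: float = ENVELOPE_SCALE, tau: float = ENVELOPE_TAU
                        ) -> Callable[[np.ndarray], np.ndarray]:
    """Envelope rising from 0 at the head and saturating at ``scale`` rad."""

    def env(s: np.ndarray) -> np.ndarray:
        return scale * (1.0 - np.exp(-np.asarray(s, dtype=float) / tau))

    return env


def midpiece_envelope(mid_weight: float, scale: float = ENVELOPE_SCALE,
                      tau: float = ENVELOPE_TAU,
                      center: float = SUPPRESSION_CENTER,
                      width: float = SUPPRESSION_WIDTH,
                      ) -> Callable[[np.ndarray], np.ndarray]:
    """Saturating envelope with the midpiece scaled by ``mid_weight`` in [0, 1].

    ``mid_weight = 1`` reproduces :func:`saturating_envelope`; small weights
    leave the distal flagellum beating while the proximal ~30 um barely moves
    (the stiff-midpiece phenotype).
    """
    if not 0.0 <= mid_weight <= 1.0:
        raise InvalidParameterError("mid_weight must be in [0, 1]")
    base = saturating_envelope(scale, tau)

    def env(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        gate = 1.0 / (1.0 + np.exp(-(s - center) / width))
        return base(s) * (mid_weight + (1.0 - mid_weight) * gate)

    return env


@dataclass(frozen=True)
class BeatParams:
    """Parameters of one synthetic beat recording.

    ``amplitude_envelope`` maps arc length (um) to tangent-angle amplitude
    (radians) and must be non-negative.  ``phase_jitter`` is the intensity of
    a phase random walk in rad/sqrt(s); zero gives a perfectly periodic beat.
    """

    total_length: float = 110.0  # um
    beat_frequency: float = 5.0  # Hz
    wavelength: float = 110.0  # um
    amplitude_envelope: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=saturating_envelope
    )
    envelope_kind: str = "flexible"  # flexible | stiff-midpiece | custom
    phase0: float = 0.0  # rad
    duration: float = 4.0  # s
    fps: float = 250.0  # frames/s
    seed: int = 0
    phase_jitter: float = 0.0  # rad / sqrt(s)
    amplitude_jitter: float = 0.0  # relative sd of slow amplitude modulation

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise InvalidParameterError("total_length must be positive")
        if self.fps <= 0:
            raise InvalidParameterError("fps must be positive")
        if self.beat_frequency < 0 or self.wavelength <= 0:
            raise InvalidParameterError("beat_frequency >= 0 and wavelength > 0 required")
        if self.duration * self.beat_frequency < 2.0 - 1e-9:
            raise InvalidParameterError(
                "record must cover at least 2 full beat cycles "
                f"(duration*f = {self.duration * self.beat_frequency:.2f})"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


def _beat_field(params: BeatParams, s: np.ndarray, t: np.ndarray,
                rng: np.random.Generator | None) -> np.ndarray:
    """psi(s, t) on the given stations, including the stochastic terms.

    Phase noise is a Brownian walk (rad/sqrt(s)); amplitude noise is an
    Ornstein-Uhlenbeck modulation with relaxation time of one beat period,
    both shared by every station so the beat stays spatially coherent.
    """
    amp = np.asarray(params.amplitude_envelope(s), dtype=float)
    if amp.shape != s.shape or np.any(amp < 0):
        raise InvalidParameterError("amplitude_envelope must return non-negative "
                                    "values of the same shape as its input")
    phase = (2.0 * np.pi * (params.beat_frequency * t[:, None]
                            - s[None, :] / params.wavelength)
             + params.phase0)
    gain = np.ones(t.size)
    if params.phase_jitter > 0.0 or params.amplitude_jitter > 0.0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        dt = 1.0 / params.fps
        if params.phase_jitter > 0.0:
            steps = rng.normal(0.0, params.phase_jitter * math.sqrt(dt), size=t.size)
            steps[0] = 0.0
            phase = phase + np.cumsum(steps)[:, None]
        if params.amplitude_jitter > 0.0:
            tau = 1.0 / max(params.beat_frequency, 1e-6)
            a = np.empty(t.size)
            a[0] = rng.normal(0.0, params.amplitude_jitter)
            drive = rng.normal(0.0, params.amplitude_jitter
                               * math.sqrt(2.0 * dt / tau), size=t.size)
            for i in range(1, t.size):
                a[i] = a[i - 1] * (1.0 - dt / tau) + drive[i]
            gain = np.clip(1.0 + a, 0.1, None)
    return amp[None, :] * gain[:, None] * np.sin(phase)


def _grid(params: BeatParams, ds: float) -> tuple[int, float, np.ndarray, np.ndarray]:
    n_seg = max(2, int(round(params.total_length / ds)))
    ds_eff = params.total_length / n_seg
    s_mid = (np.arange(n_seg) + 0.5) * ds_eff
    t = np.arange(params.n_frames) / params.fps
    return n_seg, ds_eff, s_mid, t


def simulate_beat(params: BeatParams, ds: float = 1.0,
                  rng: np.random.Generator | None = None) -> CenterlineSeries:
    """Generate a head-tethered centerline series for one beat recording.

    Segments of length ``ds`` (adjusted so it divides ``total_length``) are
    stepped along the tangent evaluated at the segment midpoint, so every
    frame's polyline length equals ``total_length`` exactly.
    """
    if ds <= 0:
        raise InvalidParameterError("ds must be positive")
    n_seg, ds_eff, s_mid, t = _grid(params, ds)
    psi = _beat_field(params, s_mid, t, rng)
    n_t = t.size
    coords = np.empty((n_t, n_seg + 1, 2))
    coords[:, 0] = 0.0
    coords[:, 1:, 0] = np.cumsum(np.cos(psi), axis=1) * ds_eff
    coords[:, 1:, 1] = np.cumsum(np.sin(psi), axis=1) * ds_eff
    return CenterlineSeries(coords=coords, ds=ds_eff, fps=params.fps)


def analytic_waveform(params: BeatParams, ds: float = 1.0,
                      rng: np.random.Generator | None = None) -> Waveform:
    """Exact tangent-angle field of the generated beat on the node grid.

    Ground truth for round-trip tests of the render -> trace -> waveform
    chain.  Uses the same effective ``ds`` as :func:`simulate_beat`.
    """
    n_seg, ds_eff, _, t = _grid(params, ds)
    s_nodes = np.arange(n_seg + 1) * ds_eff
    psi = _beat_field(params, s_nodes, t, rng)
    return Waveform(psi=psi, ds=ds_eff, dt=1.0 / params.fps)


# Per-category midpiece-amplitude sampling intervals (um).  These are the
# printed category ranges; each is a subset of the contiguous classifier bin.
DEFAULT_CATEGORY_INTERVALS: dict[FlexibilityClass, tuple[float, float]] = {
    FlexibilityClass.HIGHLY_FLEXIBLE: (27.0, 39.0),
    FlexibilityClass.RELATIVELY_FLEXIBLE: (16.0, 27.0),
    FlexibilityClass.MODERATELY_STIFF: (6.0, 15.0),
    FlexibilityClass.HIGHLY_STIFF: (0.6, 6.0),
}

_CATEGORY_ORDER = (
    FlexibilityClass.HIGHLY_FLEXIBLE,
    FlexibilityClass.RELATIVELY_FLEXIBLE,
    FlexibilityClass.MODERATELY_STIFF,
    FlexibilityClass.HIGHLY_STIFF,
)


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture of flexibility categories driving the population sampler.

    ``weights`` are probabilities over (highly_flexible, relatively_flexible,
    moderately_stiff, highly_stiff) in that order.  Each sampled cell draws a
    category, then a target midpiece amplitude uniformly from that category's
    interval.
    """

    weights: tuple[float, float, float, float]
    n_cells: int
    seed: int = 0
    intervals: dict[FlexibilityClass, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_INTERVALS)
    )
    freq_range: tuple[float, float] = (3.0, 7.0)  # Hz, uniform per cell

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("weights must be 4 non-negative numbers summing to 1")
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")


def _midpiece_metric(params: BeatParams, ds: float, bounds: SectionBoundaries) -> float:
    series = simulate_beat(params, ds=ds)
    return section_amplitude(series, bounds)["mid"]


def solve_midpiece_weight(target_amp: float, template: BeatParams,
                          bounds: SectionBoundaries | None = None,
                          rel_tol: float = 0.02, ds: float = 0.5,
                          max_iter: int = 60,
                          require_range: tuple[float, float] | None = None,
                          ) -> tuple[float, float]:
    """Bisect the midpiece envelope weight to hit ``target_amp`` (um).

    Returns ``(mid_weight, achieved_amplitude)``.  The metric is evaluated on
    the same frame grid (fps, duration) carried by ``template``, so generator
    and analyzer agree about the finite temporal sampling of the peak sweep.
    When ``require_range`` is given the achieved amplitude must also fall
    inside that interval (so a target at a category boundary cannot land a
    hair on the wrong side of it).
    """
    bounds = bounds or SectionBoundaries()

    def metric(mu: float) -> float:
        p = replace(template, amplitude_envelope=midpiece_envelope(mu),
                    envelope_kind="custom")
        return _midpiece_metric(p, ds, bounds)

    def accept(val: float) -> bool:
        if abs(val - target_amp) > rel_tol * target_amp:
            return False
        if require_range is not None:
            lo_r, hi_r = require_range
            return lo_r <= val <= hi_r
        return True

    lo, hi = 0.0, 1.0
    f_lo, f_hi = metric(lo), metric(hi)
    if not (f_lo - 1e-12 <= target_amp <= f_hi * (1.0 + rel_tol)):
        raise SolverError(
            f"target midpiece amplitude {target_amp:.2f} um outside attainable "
            f"range [{f_lo:.2f}, {f_hi:.2f}] um for this envelope family"
        )
    if target_amp >= f_hi and accept(f_hi):
        return hi, f_hi
    mu, achieved = hi, f_hi
    for _ in range(max_iter):
        mu = 0.5 * (lo + hi)
        achieved = metric(mu)
        if accept(achieved):
            return mu, achieved
        if achieved < target_amp:
            lo = mu
        else:
            hi = mu
    raise SolverError(
        f"bisection failed to reach {target_amp:.2f} um within {rel_tol:.0%} "
        f"(last achieved {achieved:.2f} um)"
    )


def sample_population(spec: PopulationSpec,
                      total_length: float = 110.0,
                      wavelength: float = 110.0,
                      fps: float = 250.0,
                      duration: float = 4.0,
                      phase_jitter_stiff: float = 0.0,
                      amplitude_jitter_stiff: float = 0.0,
                      bounds: SectionBoundaries | None = None,
                      ) -> list[tuple[BeatParams, FlexibilityClass]]:
    """Draw a labelled population of beat parameter sets.

    For each cell a category is drawn from ``spec.weights``, a target
    midpiece amplitude uniformly from that category's interval, the beat
    frequency uniformly from ``spec.freq_range`` and a random phase; the
    midpiece envelope weight is then solved so the ground-truth midpiece
    amplitude hits the target within 2%.  ``phase_jitter_stiff`` optionally
    injects phase noise into the two stiff categories (irregular beating of
    the knockout phenotype).
    """
    bounds = bounds or SectionBoundaries()
    rng = np.random.default_rng(spec.seed)
    cats = rng.choice(4, size=spec.n_cells, p=np.asarray(spec.weights, dtype=float))
    cells: list[tuple[BeatParams, FlexibilityClass]] = []
    for i in range(spec.n_cells):
        cat = _CATEGORY_ORDER[cats[i]]
        lo, hi = spec.intervals[cat]
        target = rng.uniform(lo, hi)
        f = rng.uniform(*spec.freq_range)
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        # duration must still cover >= 2 cycles for the slowest cells
        dur = max(duration, 2.0 / f)
        stiff = cat in (FlexibilityClass.MODERATELY_STIFF,
                        FlexibilityClass.HIGHLY_STIFF)
        jitter = phase_jitter_stiff if stiff else 0.0
        amp_jitter = amplitude_jitter_stiff if stiff else 0.0
        template = BeatParams(
            total_length=total_length, beat_frequency=f, wavelength=wavelength,
            phase0=phi0, duration=dur, fps=fps,
            seed=int(rng.integers(0, 2**31 - 1)), phase_jitter=0.0,
        )
        mu, _ = solve_midpiece_weight(target, template, bounds,
                                      require_range=(lo, hi))
        params = replace(
            template,
            amplitude_envelope=midpiece_envelope(mu),
            envelope_kind="flexible" if mu > 0.5 else "stiff-midpiece",
            phase_jitter=jitter,
            amplitude_jitter=amp_jitter,
        )
        cells.append((params, cat))
    return cells
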