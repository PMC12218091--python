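"""Core containers shared by the simulation and analysis stages.

The central representation is the planar tangent angle psi(s, t): the angle of
the flagellum's local tangent against the lab x-axis, as a function of arc
length ``s`` (micrometres, 0 at the head-flagellum junction) and time ``t``
(seconds).  Centerlines are stored as ordered (x, y) point lists per frame,
head-anchored, at uniform arc-length spacing, so that simulated and traced
recordings are interchangeable everywhere downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import GridError, InvalidParameterError

__all__ = [
    "CenterlineSeries",
    "Waveform",
    "CurvatureKymograph",
    "SectionBoundaries",
    "FlexibilityClass",
    "KinematicSummary",
]


class FlexibilityClass(str, enum.Enum):
    """Four-level midpiece flexibility category, ordered stiff to flexible."""

    HIGHLY_STIFF = "highly_stiff"
    MODERATELY_STIFF = "moderately_stiff"
    RELATIVELY_FLEXIBLE = "relatively_flexible"
    HIGHLY_FLEXIBLE = "highly_flexible"

    @property
    def order(self) -> int:
        return list(FlexibilityClass).index(self)


# Stiff = either stiff category (used for the combined population percentage).
STIFF_CLASSES = (FlexibilityClass.HIGHLY_STIFF, FlexibilityClass.MODERATELY_STIFF)


@dataclass
class CenterlineSeries:
    """Per-frame ordered flagellum centerlines at uniform arc-length spacing.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_points, 2)`` holding (x, y) positions in
        micrometres.  Point 0 is the head anchor.
    ds
        Uniform arc-length spacing between consecutive points, micrometres.
    fps
        Frame rate, frames per second.
    """

    coords: np.ndarray
    ds: float
    fps: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise InvalidParameterError(
                f"coords must have shape (n_frames, n_points, 2), got {self.coords.shape}"
            )
        if self.ds <= 0 or self.fps <= 0:
            raise InvalidParameterError("ds and fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def s(self) -> np.ndarray:
        """Arc-length stations of the points, micrometres."""
        return np.arange(self.n_points) * self.ds

    @property
    def length(self) -> float:
        """Nominal arc length (n_points - 1) * ds, micrometres."""
        return (self.n_points - 1) * self.ds

    def arc_lengths(self) -> np.ndarray:
        """Measured polyline length of each frame, micrometres."""
        seg = np.diff(self.coords, axis=1)
        return np.linalg.norm(seg, axis=2).sum(axis=1)


@dataclass
class Waveform:
    """Tangent-angle field psi(s, t) on a uniform arc-length x time grid."""

    psi: np.ndarray  # (n_t, n_s), radians
    ds: float  # micrometres
    dt: float  # seconds

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.ndim != 2:
            raise GridError(f"psi must be 2-D (time x arclength), got {self.psi.shape}")
        if not np.all(np.isfinite(self.psi)):
            raise GridError("psi contains non-finite values")
        if self.ds <= 0 or self.dt <= 0:
            raise InvalidParameterError("ds and dt must be positive")

    @property
    def n_t(self) -> int:
        return self.psi.shape[0]

    @property
    def n_s(self) -> int:
        return self.psi.shape[1]

    @property
    def s(self) -> np.ndarray:
        return np.arange(self.n_s) * self.ds

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt

    @property
    def duration(self) -> float:
        return (self.n_t - 1) * self.dt


@dataclass
class CurvatureKymograph:
    """Curvature field kappa(s, t) = d psi / d s, 1/micrometre.

    Sign convention: positive curvature is a bend toward the side of the head
    hook (the +y side of the head-aligned frame).
    """

    kappa: np.ndarray  # (n_t, n_s), 1/um
    ds: float
    dt: float

    @property
    def n_t(self) -> int:
        return self.kappa.shape[0]

    @property
    def n_s(self) -> int:
        return self.kappa.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_t - 1) * self.dt


@dataclass(frozen=True)
class SectionBoundaries:
    """Tail section lengths (micrometres) and derived cumulative windows.

    Defaults follow the mouse sperm set points: head 6.3, midpiece 22.4 and
    principal piece 80 um, giving windows head [0, 6.3), midpiece [6.3, 28.7)
    and principal piece [28.7, 108.7).
    """

    head_len: float = 6.3
    mid_len: float = 22.4
    principal_len: float = 80.0

    def __post_init__(self) -> None:
        if not (self.head_len > 0 and self.mid_len > 0 and self.principal_len > 0):
            raise InvalidParameterError("section lengths must be positive")

    @property
    def head_end(self) -> float:
        return self.head_len

    @property
    def mid_end(self) -> float:
        return self.head_len + self.mid_len

    @property
    def principal_end(self) -> float:
        return self.head_len + self.mid_len + self.principal_len

    def window(self, section: str) -> tuple[float, float]:
        return {
            "head": (0.0, self.head_end),
            "mid": (self.head_end, self.mid_end),
            "principal": (self.mid_end, self.principal_end),
        }[section]


@dataclass
class KinematicSummary:
    """Per-cell kinematic read-out."""

    beat_frequency: float  # Hz; NaN when the record carries no oscillation
    amplitude_mid: float  # um
    amplitude_principal: float  # um
    flexibility_class: FlexibilityClass
    frames_used: int
    amplitude_head: float = field(default=float("nan"))
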