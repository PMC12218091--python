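"""Dark-field-like rendering of centerline series into image stacks.

Each frame is drawn as a bright anti-aliased ridge along the centerline:
sub-pixel samples along the curve are binned into the pixel grid and blurred
with a Gaussian point-spread function, scaled so an isolated straight ridge
peaks at ``ridge_peak`` counts above background.  Noise is Poisson shot noise
on (background + ridge) plus additive Gaussian read noise, the standard sCMOS
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import CenterlineSeries, FlexibilityClass
from .errors import GeometryError, InvalidParameterError

__all__ = ["OpticsParams", "SyntheticScene", "render_frames"]


@dataclass(frozen=True)
class OpticsParams:
    """Camera / illumination model for the synthetic renderer."""

    pixel_size: float = 0.33  # um / px
    psf_sigma: float = 0.6  # um
    background: float = 100.0  # counts
    ridge_peak: float = 160.0  # counts above background at the ridge crest
    read_noise: float = 2.0  # counts rms
    margin_px: int = 8  # canvas margin around the flagellum

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.psf_sigma < 0 or self.background < 0 or self.read_noise < 0:
            raise InvalidParameterError("psf_sigma, background, read_noise must be >= 0")
        if self.margin_px < 5:
            raise InvalidParameterError("margin_px must be >= 5")

    @property
    def snr(self) -> float:
        """Peak signal over total noise rms at the ridge crest."""
        return self.ridge_peak / math.sqrt(
            self.ridge_peak + self.background + self.read_noise**2
        )

    @classmethod
    def for_snr(cls, snr: float, **kwargs) -> "OpticsParams":
        """Optics whose ridge peak gives the requested crest SNR."""
        probe = cls(**kwargs)
        b = probe.background + probe.read_noise**2
        peak = 0.5 * (snr**2 + math.sqrt(snr**4 + 4.0 * snr**2 * b))
        return cls(**{**kwargs, "ridge_peak": peak})


@dataclass
class SyntheticScene:
    """Rendered image stack with its ground truth attached."""

    images: np.ndarray  # (n_frames, H, W) uint16
    pixel_size: float  # um / px
    psf_sigma: float  # um
    origin: tuple[float, float]  # um coordinates of pixel (row 0, col 0) center
    ground_truth: CenterlineSeries
    optics: OpticsParams
    label: FlexibilityClass | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.images.shape[0] != self.ground_truth.n_frames:
            raise InvalidParameterError(
                "image stack and ground truth must have equal frame counts"
            )

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]

    def um_to_px(self, xy: np.ndarray) -> np.ndarray:
        """Map (x, y) um to fractional (row, col) pixel coordinates."""
        xy = np.asarray(xy, dtype=float)
        col = (xy[..., 0] - self.origin[0]) / self.pixel_size
        row = (xy[..., 1] - self.origin[1]) / self.pixel_size
        return np.stack([row, col], axis=-1)


def _canvas(series: CenterlineSeries, optics: OpticsParams,
            bbox: tuple[float, float, float, float] | None
            ) -> tuple[tuple[float, float], int, int]:
    pad = optics.margin_px * optics.pixel_size
    if bbox is None:
        xmin = series.coords[..., 0].min() - pad
        xmax = series.coords[..., 0].max() + pad
        ymin = series.coords[..., 1].min() - pad
        ymax = series.coords[..., 1].max() + pad
    else:
        xmin, xmax, ymin, ymax = bbox
    w = int(math.ceil((xmax - xmin) / optics.pixel_size)) + 1
    h = int(math.ceil((ymax - ymin) / optics.pixel_size)) + 1
    return (xmin, ymin), h, w


def render_frames(series: CenterlineSeries, optics: OpticsParams | None = None,
                  seed: int = 0, noise: bool = True,
                  bbox: tuple[float, float, float, float] | None = None,
                  label: FlexibilityClass | None = None) -> SyntheticScene:
    """Render a centerline series into a noisy uint16 image stack.

    The canvas is auto-sized to the whole recording plus the optics margin
    unless an explicit ``bbox`` (xmin, xmax, ymin, ymax, um) is given; a
    flagellum leaving an explicit canvas raises :class:`GeometryError` naming
    the offending frame.
    """
    optics = optics or OpticsParams()
    origin, h, w = _canvas(series, optics, bbox)
    sigma_px = optics.psf_sigma / optics.pixel_size
    # sub-pixel sampling along the curve; weight calibrated so a straight
    # ridge peaks at ridge_peak counts after the PSF blur
    step_px = 1.0 / 3.0
    upsample = max(1, int(math.ceil(series.ds / (step_px * optics.pixel_size))))
    weight = optics.ridge_peak * math.sqrt(2.0 * math.pi) * max(sigma_px, 0.5) * (
        series.ds / upsample / optics.pixel_size
    )
    rng = np.random.default_rng(seed)
    images = np.empty((series.n_frames, h, w), dtype=np.uint16)
    pad = optics.margin_px  # px, minimum clearance kept by the invariant
    for i in range(series.n_frames):
        pts = series.coords[i]
        if upsample > 1:
            base = np.arange(pts.shape[0])
            fine = np.linspace(0, pts.shape[0] - 1, (pts.shape[0] - 1) * upsample + 1)
            pts = np.stack([np.interp(fine, base, pts[:, 0]),
                            np.interp(fine, base, pts[:, 1])], axis=1)
        col = (pts[:, 0] - origin[0]) / optics.pixel_size
        row = (pts[:, 1] - origin[1]) / optics.pixel_size
        if (col.min() < pad - 0.5 or col.max() > w - pad - 0.5
                or row.min() < pad - 0.5 or row.max() > h - pad - 0.5):
            if bbox is None:
                raise AssertionError("auto canvas failed to contain the flagellum")
            raise GeometryError(
                f"flagellum exceeds canvas in frame {i}", frame=i
            )
        img, _, _ = np.histogram2d(
            row, col, bins=(h, w),
            range=((-0.5, h - 0.5), (-0.5, w - 0.5)),
            weights=np.full(pts.shape[0], weight),
        )
        if sigma_px > 0:
            img = gaussian_filter(img, sigma_px, mode="constant")
        img += optics.background
        if noise:
            img = rng.poisson(img).astype(float)
            if optics.read_noise > 0:
                img += rng.normal(0.0, optics.read_noise, size=img.shape)
        images[i] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return SyntheticScene(
        images=images, pixel_size=optics.pixel_size, psf_sigma=optics.psf_sigma,
        origin=origin, ground_truth=series, optics=optics, label=label,
        meta={"seed": seed, "noise": noise},
    )
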