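"""Shape-mode decomposition of the waveform and the B1-B2 shape cycle.

The time-mean tangent-angle profile is subtracted and the centered
(time x arclength) matrix is factored by singular value decomposition.  The
right singular vectors are the spatial shape modes (orthonormal under the
ds-weighted inner product), the projections B_k(t) their time coefficients.
For a periodic traveling wave two modes in quadrature capture essentially
all variance, and the (B1, B2) orbit is a circle; deviations from a circular
orbit measure beat-to-beat irregularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Waveform
from .errors import DegenerateCycleError, InvalidParameterError, RankError

__all__ = ["ShapeCycle", "fit_shape_modes", "shape_cycle_circularity"]


@dataclass
class ShapeCycle:
    """First K shape modes of a waveform and their time coefficients.

    ``mode_basis[k]`` is orthonormal under the ds-weighted inner product
    ``sum(phi_j phi_k) * ds = delta_jk``; ``coefficients[:, k]`` carries the
    matching units (rad * sqrt(um)) so that
    ``coefficients @ mode_basis + mean`` reconstructs psi.
    """

    mode_basis: np.ndarray  # (K, n_s)
    coefficients: np.ndarray  # (n_t, K)
    variance_explained: np.ndarray  # (K,) fractions, non-increasing
    mean_profile: np.ndarray  # (n_s,) time-mean psi
    ds: float
    dt: float
    circularity: float | None = None  # None when < 2 modes or degenerate

    @property
    def b1(self) -> np.ndarray:
        return self.coefficients[:, 0]

    @property
    def b2(self) -> np.ndarray:
        return self.coefficients[:, 1]


def fit_shape_modes(w: Waveform, k: int = 2) -> ShapeCycle:
    """Fit the first ``k`` shape modes of a waveform by SVD.

    Raises :class:`RankError` for a waveform constant in time, for which
    shape modes are undefined.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if w.n_t <= k:
        raise InvalidParameterError(f"need more than {k} frames, got {w.n_t}")
    mean = w.psi.mean(axis=0)
    x = w.psi - mean
    total_var = float(np.sum(x**2))
    if total_var <= 1e-24 * w.psi.size:
        raise RankError("waveform is constant in time; no shape modes")
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    k = min(k, sv.size)
    sqrt_ds = np.sqrt(w.ds)
    modes = vt[:k] / sqrt_ds
    coeffs = (u[:, :k] * sv[:k]) * sqrt_ds
    var = sv**2 / np.sum(sv**2)
    circ: float | None = None
    if k >= 2:
        try:
            circ = shape_cycle_circularity(coeffs[:, 0], coeffs[:, 1])
        except DegenerateCycleError:
            circ = None
    return ShapeCycle(mode_basis=modes, coefficients=coeffs,
                      variance_explained=var[:k], mean_profile=mean,
                      ds=w.ds, dt=w.dt, circularity=circ)


def shape_cycle_circularity(b1: np.ndarray, b2: np.ndarray,
                            corr_limit: float = 0.98) -> float:
    """Circularity score of the (B1, B2) orbit, in [0, 1].

    B1 and B2 are whitened to zero mean and unit variance; the score is
    1 minus the coefficient of variation of the orbit radius, clipped to
    [0, 1].  A perfectly repeating beat traces a circle (score 1); phase or
    amplitude jitter spreads the radius and lowers the score.
    """
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    if b1.shape != b2.shape or b1.ndim != 1 or b1.size < 4:
        raise InvalidParameterError("b1 and b2 must be equal-length 1-D series")
    s1, s2 = b1.std(), b2.std()
    if s1 <= 1e-15 * max(1.0, np.abs(b1).max()) or \
       s2 <= 1e-15 * max(1.0, np.abs(b2).max()):
        raise DegenerateCycleError("zero-variance shape coefficient")
    z1 = (b1 - b1.mean()) / s1
    z2 = (b2 - b2.mean()) / s2
    corr = float(np.corrcoef(z1, z2)[0, 1])
    if abs(corr) > corr_limit:
        raise DegenerateCycleError(
            f"collinear shape coefficients (|corr| = {abs(corr):.3f})"
        )
    radius = np.hypot(z1, z2)
    score = 1.0 - radius.std() / radius.mean()
    return float(np.clip(score, 0.0, 1.0))
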