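"""Flagellar energetics: resistive-force-theory drag, Euler-Bernoulli
elasticity, internal friction, and sliding-filament motor power recovery.

Model
-----
At sperm Reynolds number inertia is negligible, so the filament is in
quasi-static force balance with the local (resistive-force-theory) drag

    f_h = -(xi_t v_t t_hat + xi_n v_n n_hat)        [N/m],

where ``v_t``/``v_n`` are the tangential/normal material velocities.  With a
free distal end, the internal contact force and bending moment follow by
integrating the drag from the tip,

    F(s) = -int_s^L f_h ds',
    M(s) = -int_s^L (r(s') - r(s)) x f_h ds'        [z-component],

and the active (dynein) moment is whatever the total moment cannot be
attributed to elasticity or internal friction:

    m_a = M - EI kappa - eta_i kappa_dot.

The local motor power density is pi = m_a * d(kappa)/dt; its positive part
integrated over the tail is the motor input P_in, the negative part the
motor dissipation D_m.  Internal dissipation is D_i = int eta_i kappa_dot^2 ds
and hydrodynamic dissipation D_h = int (xi_t v_t^2 + xi_n v_n^2) ds, split by
tail region.  Because the generator's envelopes vanish at the head junction,
the tether pin does no work and the cycle-averaged balance
<P_in> - <D_m> = <D_i> + <D_h> closes (the elastic storage averages out).

All computations are done in SI units internally; cycle averages are
reported in femtowatts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import CenterlineSeries, SectionBoundaries, Waveform
from .errors import (
    GridError,
    InsufficientRecordError,
    InvalidParameterError,
    NumericError,
)

__all__ = [
    "MaterialParams",
    "RftFields",
    "EnergeticsProfile",
    "rft_velocity_and_force",
    "hydrodynamic_dissipation",
    "internal_dissipation",
    "recover_active_moment",
    "motor_powers",
    "cycle_average",
    "compute_energetics",
]

UM = 1e-6  # metres per micrometre
W_TO_FW = 1e15


@dataclass(frozen=True)
class MaterialParams:
    """Material and drag parameters (SI units).

    Literature-scale defaults for mouse sperm; absolute power outputs scale
    with these, so only contrasts and orders of magnitude are meaningful
    unless they are calibrated against real recordings.
    """

    EI: float = 2e-21  # bending stiffness, N m^2
    eta_i: float = 1e-22  # internal friction coefficient, N m^2 s
    xi_t: float = 0.7e-3  # tangential drag per unit length, N s / m^2
    xi_n: float = 1.4e-3  # normal drag per unit length, N s / m^2
    a: float = 1.85e-7  # effective interfilament spacing, m

    def __post_init__(self) -> None:
        if min(self.EI, self.eta_i, self.xi_t, self.xi_n, self.a) <= 0:
            raise InvalidParameterError("all material parameters must be positive")
        if self.xi_n < self.xi_t:
            raise InvalidParameterError("drag anisotropy requires xi_n >= xi_t")


@dataclass
class RftFields:
    """Velocities, frames and drag force density on the node grid (SI)."""

    velocity: np.ndarray  # (n_t, n_p, 2) m/s
    v_t: np.ndarray  # (n_t, n_p) m/s
    v_n: np.ndarray  # (n_t, n_p) m/s
    tangent: np.ndarray  # (n_t, n_p, 2) unit
    normal: np.ndarray  # (n_t, n_p, 2) unit
    force: np.ndarray  # (n_t, n_p, 2) N/m
    ds: float  # m
    dt: float  # s


def rft_velocity_and_force(series: CenterlineSeries, m: MaterialParams) -> RftFields:
    """Material velocities and resistive-force-theory drag density.

    Velocities are central time differences of the node positions; the drag
    density is decomposed on the local tangent/normal frame.
    """
    if series.n_frames < 3:
        raise GridError("need at least 3 frames for central time differences")
    r = series.coords * UM  # (n_t, n_p, 2) in metres
    dt = series.dt
    v = np.gradient(r, dt, axis=0)
    tang = np.gradient(r, series.ds * UM, axis=1)
    norm = np.linalg.norm(tang, axis=2, keepdims=True)
    norm[norm == 0.0] = 1.0
    tang = tang / norm
    nrm = np.stack([-tang[..., 1], tang[..., 0]], axis=-1)  # n = z x t
    v_t = np.einsum("tpc,tpc->tp", v, tang)
    v_n = np.einsum("tpc,tpc->tp", v, nrm)
    force = -(m.xi_t * v_t[..., None] * tang + m.xi_n * v_n[..., None] * nrm)
    return RftFields(velocity=v, v_t=v_t, v_n=v_n, tangent=tang, normal=nrm,
                     force=force, ds=series.ds * UM, dt=dt)


def _segment_integrate(density: np.ndarray, ds_m: float, seg_mask: np.ndarray
                       ) -> np.ndarray:
    """Integrate a node density over the segments selected by ``seg_mask``.

    Each inter-node segment contributes the mean of its endpoint values, so
    regional integrals partition the total exactly.
    """
    seg_vals = 0.5 * (density[..., 1:] + density[..., :-1])
    return seg_vals[..., seg_mask].sum(axis=-1) * ds_m


def _region_masks(n_points: int, ds_um: float, b: SectionBoundaries
                  ) -> dict[str, np.ndarray]:
    mid_s = (np.arange(n_points - 1) + 0.5) * ds_um  # segment midpoints, um
    return {
        "head": mid_s < b.head_end,
        "mid": (mid_s >= b.head_end) & (mid_s < b.mid_end),
        "principal": (mid_s >= b.mid_end) & (mid_s < b.principal_end),
        "distal": mid_s >= b.principal_end,
    }


def hydrodynamic_dissipation(fields: RftFields, m: MaterialParams,
                             b: SectionBoundaries | None = None) -> dict[str, np.ndarray]:
    """Hydrodynamic dissipation rate D_h(t) in watts, with regional split.

    Returns a dict with keys ``total``, ``head``, ``mid``, ``principal`` and
    ``distal`` (the last non-zero only when the analyzed length exceeds the
    principal window).  total = head + mid + principal + distal exactly.
    """
    b = b or SectionBoundaries()
    density = m.xi_t * fields.v_t**2 + m.xi_n * fields.v_n**2  # W/m
    masks = _region_masks(density.shape[1], fields.ds / UM, b)
    out = {name: _segment_integrate(density, fields.ds, mask)
           for name, mask in masks.items()}
    out["total"] = _segment_integrate(density, fields.ds,
                                      np.ones(density.shape[1] - 1, dtype=bool))
    return out


def _curvature_rate(w: Waveform, smooth_window: int) -> np.ndarray:
    """d kappa / d t in 1/(m s) on the node grid."""
    kappa = np.gradient(w.psi, w.ds * UM, axis=1)  # 1/m
    if smooth_window >= 5 and w.n_t > smooth_window:
        kappa = savgol_filter(kappa, smooth_window, polyorder=2, axis=0)
    return np.gradient(kappa, w.dt, axis=0)


def internal_dissipation(w: Waveform, m: MaterialParams,
                         smooth_window: int = 0) -> np.ndarray:
    """Internal (cross-sectional friction) dissipation rate D_i(t), watts."""
    if w.n_t < 3:
        raise GridError("need at least 3 frames for curvature rates")
    kdot = _curvature_rate(w, smooth_window)
    density = m.eta_i * kdot**2  # W/m
    return _segment_integrate(density, w.ds * UM,
                              np.ones(w.n_s - 1, dtype=bool))


def recover_active_moment(series: CenterlineSeries, w: Waveform,
                          m: MaterialParams, fields: RftFields | None = None,
                          smooth_window: int = 0) -> np.ndarray:
    """Active (dynein) moment m_a(s, t) in N m from quasi-static balance.

    The total internal moment is the tip-integrated torque of the drag
    density about each station (free distal end: M(L) = 0 by construction);
    subtracting the elastic and internal-friction moments leaves the active
    moment.
    """
    fields = fields or rft_velocity_and_force(series, m)
    if w.psi.shape != fields.v_t.shape:
        raise GridError("waveform and RFT fields must share the (n_t, n_p) grid")
    r = series.coords * UM
    f = fields.force
    ds = fields.ds
    # M_i = -sum_{s' >= s_i} (r' - r_i) x f' ds'  via reverse cumulative sums
    cross_rf = r[..., 0] * f[..., 1] - r[..., 1] * f[..., 0]  # (r x f)_z
    seg = 0.5 * (cross_rf[:, 1:] + cross_rf[:, :-1]) * ds
    seg_f = 0.5 * (f[:, 1:] + f[:, :-1]) * ds
    rev_cross = np.zeros_like(cross_rf)
    rev_f = np.zeros_like(f)
    rev_cross[:, :-1] = np.cumsum(seg[:, ::-1], axis=1)[:, ::-1]
    rev_f[:, :-1] = np.cumsum(seg_f[:, ::-1], axis=1)[:, ::-1]
    moment = -(rev_cross - (r[..., 0] * rev_f[..., 1] - r[..., 1] * rev_f[..., 0]))
    kappa = np.gradient(w.psi, w.ds * UM, axis=1)
    kdot = _curvature_rate(w, smooth_window)
    # Sign of the friction term is fixed by energy conservation: under this
    # moment convention the deformation power of M equals D_h, and the motor
    # power P_in - D_m must balance D_h + D_i over a cycle, which requires
    # the internal-friction moment to enter the recovery with +eta_i*kdot.
    m_a = moment - m.EI * kappa + m.eta_i * kdot
    if not np.all(np.isfinite(m_a)):
        t_bad, s_bad = np.argwhere(~np.isfinite(m_a))[0]
        raise NumericError("non-finite active moment", frame=int(t_bad),
                           station=int(s_bad))
    return m_a


def motor_powers(m_a: np.ndarray, w: Waveform,
                 smooth_window: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Motor input P_in(t) and motor dissipation D_m(t), watts.

    The local motor power density pi = m_a * d kappa / d t is split by sign:
    stations where the motors drive sliding contribute to P_in, stations
    where sliding drives the motors contribute to D_m.
    """
    if m_a.shape != w.psi.shape:
        raise GridError("active moment and waveform must share the grid")
    kdot = _curvature_rate(w, smooth_window)
    pi = m_a * kdot  # W/m
    ones = np.ones(w.n_s - 1, dtype=bool)
    p_in = _segment_integrate(np.maximum(pi, 0.0), w.ds * UM, ones)
    d_m = _segment_integrate(np.maximum(-pi, 0.0), w.ds * UM, ones)
    return p_in, d_m


def cycle_average(x: np.ndarray, f: float, fps: float) -> float:
    """Mean of a power time series over a whole number of beat periods.

    The record is truncated to the largest integer number of periods of
    frequency ``f`` it contains; averaging over partial cycles would bias
    oscillating quantities.
    """
    x = np.asarray(x, dtype=float)
    duration = x.size / fps
    n_per = int(np.floor(duration * f + 1e-9))
    if n_per < 1:
        raise InsufficientRecordError(
            f"record of {duration:.3f} s covers less than one period at {f:.2f} Hz"
        )
    n_frames = int(round(n_per / f * fps))
    return float(x[:min(n_frames, x.size)].mean())


@dataclass
class EnergeticsProfile:
    """Power time series (watts) plus grid metadata for one recording."""

    p_in: np.ndarray
    d_m: np.ndarray
    d_i: np.ndarray
    d_h: np.ndarray
    d_h_head: np.ndarray
    d_h_mid: np.ndarray
    d_h_principal: np.ndarray
    fps: float

    def cycle_averages(self, f: float) -> dict[str, float]:
        """Cycle-averaged powers in femtowatts."""
        names = ["p_in", "d_m", "d_i", "d_h", "d_h_head", "d_h_mid", "d_h_principal"]
        return {name: cycle_average(getattr(self, name), f, self.fps) * W_TO_FW
                for name in names}


def compute_energetics(series: CenterlineSeries, w: Waveform | None = None,
                       m: MaterialParams | None = None,
                       b: SectionBoundaries | None = None,
                       smooth_window: int = 5) -> EnergeticsProfile:
    """Full energetics chain for one recording.

    ``smooth_window`` is the Savitzky-Golay window (frames) applied to the
    curvature field before time differentiation, controlling noise
    amplification in kappa_dot for traced recordings; set 0 to disable.
    """
    from .trace import to_waveform

    m = m or MaterialParams()
    b = b or SectionBoundaries()
    w = w if w is not None else to_waveform(series)
    fields = rft_velocity_and_force(series, m)
    dh = hydrodynamic_dissipation(fields, m, b)
    d_i = internal_dissipation(w, m, smooth_window)
    m_a = recover_active_moment(series, w, m, fields, smooth_window)
    p_in, d_m = motor_powers(m_a, w, smooth_window)
    return EnergeticsProfile(
        p_in=p_in, d_m=d_m, d_i=d_i, d_h=dh["total"], d_h_head=dh["head"],
        d_h_mid=dh["mid"], d_h_principal=dh["principal"], fps=series.fps,
    )
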