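"""Direction layer, LGMD layer, motion-direction estimation, and the
collision-peak report.

Direction layer
---------------
For each of the 8 canonical angles theta the correlation output at pixel
(i, j) is

    D_ij(t, theta) = S_ij(t) * S_xy(t-2)  -  S_ij(t-1) * S_xy(t-1),

where (x, y) is the pixel displaced by distance m along theta.  The first
product correlates the present signal with the displaced signal two
frames ago; the second subtracts the simultaneous spatial correlation at
the same displacement, so a static scene cancels exactly.  A pattern
travelling along theta lines up the two-frame-delayed product when the
correlation partner sits *upstream* (at -m along theta); the default
``offset_sign = -1`` therefore orients the displacement so that motion
along theta drives D(theta) positive.  ``offset_sign = +1`` keeps the
literal orientation, which responds to the opposite direction.

Screen coordinates: the first pixel index i runs rightward (columns),
j upward, so theta = 0 is rightward and theta = pi/2 upward motion.

LGMD layer
----------
Each direction channel integrates its D field over the grid,
R1(t, theta) = sum_ij D_ij, and feeds a single fractional membrane

    D^alpha L1 = g_leak (V_rest - L1) + xi_ex R1 (E_ex - L1),

whose rectified output L1hat(t, theta) is the directionally selective
LGMD response.  The per-frame aggregate C(t) = sum_theta L1hat is the
network's collision trace; for a looming object it peaks at the fill
("collision") frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fracdyn import AffineDrive, FracState, frac_step
from .params import ModelParams

__all__ = [
    "THETA_SET",
    "neighbor_offset",
    "shift_field",
    "direction_correlate",
    "lgmd_integrate",
    "lgmd_update",
    "local_angle",
    "direction_mode",
    "CollisionReport",
    "collision_peak",
    "TuningCurve",
    "tuning_curve",
]

#: The 8 canonical preferred directions (radians, counterclockwise from rightward).
THETA_SET = np.arange(8) * np.pi / 4.0


def _round_away(v: float) -> int:
    """Round half away from zero (numpy rounds half to even)."""
    return int(np.sign(v) * np.floor(abs(v) + 0.5))


def neighbor_offset(theta: float, m: float) -> tuple[int, int]:
    """Integer displacement (dx, dy) of the correlation partner along theta.

    dx counts columns rightward, dy counts rows upward.  For m = 1 the
    result is the 8-neighborhood.
    """
    if not np.any(np.isclose(theta, THETA_SET)):
        raise ValueError(f"theta {theta} not in the 8-angle set")
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    return _round_away(m * np.cos(theta)), _round_away(m * np.sin(theta))


def shift_field(S: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Field of displaced values ``out[i, j] = S[i + dx, j + dy]``.

    In array terms (row 0 at top): ``out[r, c] = S[r - dy, c + dx]``.
    Off-grid positions contribute 0.
    """
    H, W = S.shape
    out = np.zeros_like(S)
    dr = -dy
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dx), min(W, W - dx)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = S[r0 + dr : r1 + dr, c0 + dx : c1 + dx]
    return out


def _sample_displaced(S: np.ndarray, theta: float, p: ModelParams) -> np.ndarray:
    """Displaced copy of S along theta (sign per ``p.offset_sign``)."""
    s = p.offset_sign
    if p.interpolate_diagonals:
        fx, fy = s * p.m * np.cos(theta), s * p.m * np.sin(theta)
        x0, y0 = int(np.floor(fx)), int(np.floor(fy))
        wx, wy = fx - x0, fy - y0
        out = (1 - wx) * (1 - wy) * shift_field(S, x0, y0)
        if wx:
            out += wx * (1 - wy) * shift_field(S, x0 + 1, y0)
        if wy:
            out += (1 - wx) * wy * shift_field(S, x0, y0 + 1)
        if wx and wy:
            out += wx * wy * shift_field(S, x0 + 1, y0 + 1)
        return out
    dx, dy = neighbor_offset(theta, p.m)
    return shift_field(S, s * dx, s * dy)


def direction_correlate(S_t: np.ndarray, S_t1: np.ndarray, S_t2: np.ndarray,
                        theta: float, p: ModelParams) -> np.ndarray:
    """Per-pixel correlation output D(t, theta) from S at t, t-1, t-2."""
    if not (S_t.shape == S_t1.shape == S_t2.shape):
        raise ValueError("S fields must share one shape")
    return S_t * _sample_displaced(S_t2, theta, p) - S_t1 * _sample_displaced(S_t1, theta, p)


def lgmd_integrate(D: np.ndarray) -> float:
    """Grid integral R1 of a direction field (signed sum, no rectification)."""
    return float(D.sum())


def lgmd_update(R1: np.ndarray, state: FracState, p: ModelParams,
                xi_ex: float) -> tuple[np.ndarray, np.ndarray]:
    """One fractional step of the per-theta LGMD membranes.

    ``R1`` holds all 8 channels at once; returns (L1, L1_rect).

    With ``p.rectify_lgmd_input`` (the default) the synaptic drive is
    clamped at zero: a negative R1 with ``|xi_ex * R1| > g_leak`` would
    make the total membrane conductance negative, destabilizing the
    equation and handing the discrete solve a spurious positive
    equilibrium.  An excitatory synaptic conductance is nonnegative by
    construction, so the clamp is the physiological reading.
    """
    R1 = np.asarray(R1, float)
    drive = np.maximum(R1, 0.0) if p.rectify_lgmd_input else R1
    A = p.g_leak * p.V_rest + xi_ex * drive * p.E_ex
    B = p.g_leak + xi_ex * drive
    L1 = frac_step(state, AffineDrive(A, B))
    return L1, np.maximum(L1, 0.0)


def local_angle(D_horizontal: np.ndarray, D_vertical: np.ndarray,
                energy_floor: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel motion angle from the theta=0 and theta=pi/2 D fields.

    Returns (E_angle in [0, 2 pi), motion_mask).  Pixels whose correlation
    energy max(|D0|, |D90|) does not exceed the floor are masked out —
    the arctangent of (0, 0) carries no direction.  The floor is the
    larger of ``energy_floor`` (absolute, excludes numerically silent
    pixels) and 10% of the frame's peak correlation energy (relative,
    excludes the sea of near-zero background drift that would otherwise
    swamp the mode with meaningless angles).
    """
    if D_horizontal.shape != D_vertical.shape:
        raise ValueError("D fields must share one shape")
    E = np.mod(np.arctan2(D_vertical, D_horizontal), 2.0 * np.pi)
    energy = np.maximum(np.abs(D_horizontal), np.abs(D_vertical))
    floor = max(energy_floor, 0.1 * float(energy.max()))
    mask = energy > floor
    return E, mask


def direction_mode(E_angle: np.ndarray, motion_mask: np.ndarray,
                   bin_width: float = np.pi / 4.0) -> float | None:
    """Global motion direction: mode of the masked local angles.

    Angles are quantized to the nearest canonical direction (bin width
    pi/4); ties break toward the smaller angle.  Returns None when the
    mask is empty (no moving pixel).
    """
    angles = E_angle[motion_mask]
    if angles.size == 0:
        return None
    idx = np.round(angles / bin_width).astype(int) % 8
    counts = np.bincount(idx, minlength=8)
    return float(THETA_SET[int(np.argmax(counts))])


@dataclass(frozen=True)
class CollisionReport:
    """Peak location/prominence of the aggregate collision trace C(t)."""

    peak_frame: int | None   # 1-based; None when C is identically zero
    peak_value: float
    peak_prominence: float
    responded: bool


def collision_peak(C: np.ndarray, eps: float = 1e-12) -> CollisionReport:
    """Locate the collision peak of the aggregate output.

    ``peak_frame`` is the earliest argmax (1-based); ``peak_prominence``
    is the peak over the run median (floored at ``eps``).  An identically
    zero trace reports no response.
    """
    C = np.asarray(C, float)
    if C.size == 0:
        raise ValueError("empty output series")
    if not np.any(C > 0):
        return CollisionReport(None, 0.0, 0.0, False)
    k = int(np.argmax(C))
    med = max(float(np.median(C)), eps)
    return CollisionReport(k + 1, float(C[k]), float(C[k]) / med, True)


@dataclass(frozen=True)
class TuningCurve:
    """Time-integrated per-direction response and the preferred angle."""

    scores: np.ndarray       # shape (8,), sum over t of L1_rect(t, theta)
    preferred: float         # angle of the maximal score (ties -> smaller)
    no_motion: bool


def tuning_curve(L1_rect: np.ndarray) -> TuningCurve:
    """Integrate the rectified LGMD output over time per direction.

    ``L1_rect`` has shape (T, 8).  All-zero scores are flagged
    ``no_motion`` (the tie rule then reports theta = 0).
    """
    L1_rect = np.asarray(L1_rect, float)
    scores = L1_rect.sum(axis=0)
    return TuningCurve(
        scores=scores,
        preferred=float(THETA_SET[int(np.argmax(scores))]),
        no_motion=not bool(np.any(scores > 0)),
    )
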