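"""Photoreceptor layer and the ON/OFF channel split.

The photoreceptor membrane potential P integrates the current frame's
luminance excitatorily and the previous frame's luminance inhibitorily,

    D^alpha P = g_leak (V_rest - P) + lambda_ex L(t) (E_ex - P)
                                    + lambda_in L(t-1) (E_in - P),

so a static scene settles to a fixed point while a temporal luminance
change produces a transient excursion: upward for brightening (routed to
the ON channel) and downward for dimming (routed to OFF).  The channels
are half-wave rectified copies around small thresholds:

    P_ON  =  gamma1 * [P - V_th1]^+        P_OFF = -gamma2 * [P - V_th2]^-

At the first frame the "previous" luminance is defined to equal the
current one, so the run starts from a motionless view instead of a
spurious full-field transient.
"""

from __future__ import annotations

import numpy as np

from .fracdyn import AffineDrive, FracConfig, FracState, frac_step
from .params import ModelParams

__all__ = ["ModelParams", "RetinaState", "photoreceptor_drive",
           "photoreceptor_update", "split_on", "split_off"]


class RetinaState:
    """Photoreceptor fractional state plus the latest ON/OFF outputs."""

    def __init__(self, shape: tuple[int, int], params: ModelParams, cfg: FracConfig):
        self.P = FracState(np.full(shape, params.V_rest), cfg)
        self.P_on = np.zeros(shape)
        self.P_off = np.zeros(shape)


def photoreceptor_drive(L_t: np.ndarray, L_prev: np.ndarray, p: ModelParams) -> AffineDrive:
    """Affine right-hand side of the photoreceptor equation."""
    A = p.g_leak * p.V_rest + p.lambda_ex * L_t * p.E_ex + p.lambda_in * L_prev * p.E_in
    B = p.g_leak + p.lambda_ex * L_t + p.lambda_in * L_prev
    return AffineDrive(A, B)


def photoreceptor_update(
    L_t: np.ndarray,
    L_prev: np.ndarray,
    state: FracState,
    p: ModelParams,
) -> np.ndarray:
    """One fractional step of the photoreceptor field; returns new P."""
    L_t = np.asarray(L_t, float)
    L_prev = np.asarray(L_prev, float)
    if L_t.shape != L_prev.shape:
        raise ValueError(f"luminance shapes differ: {L_t.shape} vs {L_prev.shape}")
    return frac_step(state, photoreceptor_drive(L_t, L_prev, p))


def split_on(P: np.ndarray, p: ModelParams) -> np.ndarray:
    """ON channel: brightness increments, ``gamma1 * max(P - V_th1, 0)``."""
    return p.gamma1 * np.maximum(P - p.V_th1, 0.0)


def split_off(P: np.ndarray, p: ModelParams) -> np.ndarray:
    """OFF channel: brightness decrements, ``-gamma2 * min(P - V_th2, 0)``."""
    return -p.gamma2 * np.minimum(P - p.V_th2, 0.0)
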