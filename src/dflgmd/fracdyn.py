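"""Grünwald–Letnikov engine for fractional-order membrane dynamics.

Every dynamic layer of the network obeys a conductance equation of the
affine form

    D^alpha x = A - B * x,        0 < alpha <= 1,

where ``A`` collects the battery-weighted synaptic drives plus the leak
term ``g_leak * V_rest`` and ``B`` collects the total conductance.  The
fractional derivative is discretized with the Grünwald–Letnikov (GL)
weighted history sum applied to the deviation from the initial state
(the Caputo reading, under which a constant has zero derivative and a
nonzero initial condition relaxes along the Mittag-Leffler curve):

    D^alpha x(t_n)  ≈  h^(-alpha) * sum_{k=0..K} c_k * (x_{n-k} - x_0),

with the signed binomial weights ``c_k = (-1)^k * binom(alpha, k)``.
Treating the right-hand side semi-implicitly (the state enters linearly,
so the implicit solve is a scalar division) gives the update

    x_n = (x_0 + h^alpha * A - sum_{k=1..K} c_k * (x_{n-k} - x_0))
          / (1 + h^alpha * B),

which is unconditionally stable for ``B >= 0`` and reduces exactly to the
one-step implicit (backward) Euler scheme at ``alpha = 1`` (where the
initial-condition correction cancels identically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FracConfig",
    "FracState",
    "AffineDrive",
    "gl_coefficients",
    "frac_step",
    "simulate_affine",
]


@dataclass(frozen=True)
class FracConfig:
    """Scheme parameters of the fractional operator.

    Parameters
    ----------
    alpha : float
        Fractional order, ``0 < alpha <= 1``.  ``alpha = 1`` recovers the
        ordinary first derivative (memoryless dynamics).
    h : float
        Time step in frame units (the frame interval is the unit of time).
    memory_window : int or None
        Maximum number of past states kept in the GL memory sum.  ``None``
        keeps the full history (short runs), a finite value applies the
        short-memory truncation.
    """

    alpha: float = 0.4
    h: float = 1.0
    memory_window: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"fractional order must lie in (0, 1], got {self.alpha}")
        if self.h <= 0.0:
            raise ValueError(f"time step must be positive, got {self.h}")
        if self.memory_window is not None and self.memory_window < 1:
            raise ValueError("memory_window must be >= 1 or None (full history)")


def gl_coefficients(alpha: float, K: int) -> np.ndarray:
    """Grünwald–Letnikov weights ``c_0 .. c_K`` for order ``alpha``.

    ``c_k = (-1)^k * binom(alpha, k)``, evaluated with the stable
    recurrence ``c_k = c_{k-1} * (1 - (alpha + 1) / k)``.  ``c_0 = 1`` and
    all later weights are negative for ``0 < alpha < 1``; their total sum
    tends to zero, which is what lets a fractional pole relax without a
    finite time constant.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"fractional order must lie in (0, 1], got {alpha}")
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    c = np.empty(K + 1, dtype=float)
    c[0] = 1.0
    for k in range(1, K + 1):
        c[k] = c[k - 1] * (1.0 - (alpha + 1.0) / k)
    return c


@dataclass
class AffineDrive:
    """Right-hand side ``A - B * x`` of one layer at one frame.

    ``A`` and ``B`` are per-pixel fields (or scalars broadcastable to the
    state shape).  ``B`` is nonnegative whenever all synaptic inputs and
    conductances are nonnegative; signed inputs (the LGMD layer's R1) may
    push it below zero, which the semi-implicit solve tolerates as long as
    ``1 + h^alpha * B`` stays away from zero.
    """

    A: np.ndarray | float
    B: np.ndarray | float


class FracState:
    """History buffer backing the GL memory sum of one dynamic layer.

    The buffer is seeded with the initial condition (the resting potential
    for every membrane in the network) and grows by one field per frame,
    trimmed to ``memory_window`` when finite.
    """

    def __init__(self, x0: np.ndarray | float, cfg: FracConfig):
        self.cfg = cfg
        x0 = np.asarray(x0, dtype=float)
        self.shape = x0.shape
        self.x0 = x0.copy()
        self.history: list[np.ndarray] = [x0.copy()]
        self._coeffs = gl_coefficients(cfg.alpha, 1)

    @property
    def coeffs(self) -> np.ndarray:
        return self._coeffs

    @property
    def current(self) -> np.ndarray:
        return self.history[-1]

    def _grow_coeffs(self, K: int) -> None:
        if K + 1 > len(self._coeffs):
            self._coeffs = gl_coefficients(self.cfg.alpha, K)

    def memory_sum(self) -> np.ndarray:
        """``sum_{k=1..K} c_k * (x_{n-k} - x_0)`` over the retained history."""
        hist = self.history
        W = self.cfg.memory_window
        if W is not None:
            hist = hist[-W:]
        K = len(hist)
        self._grow_coeffs(K)
        # hist[-1] pairs with c_1, hist[-2] with c_2, ...
        stacked = np.stack(hist[::-1])
        c = self._coeffs[1 : K + 1]
        return np.tensordot(c, stacked, axes=(0, 0)) - c.sum() * self.x0


def frac_step(state: FracState, drive: AffineDrive, cfg: FracConfig | None = None) -> np.ndarray:
    """Advance one layer by one frame and return the new state field.

    Implements the semi-implicit GL update; the result is appended to the
    state history.
    """
    cfg = state.cfg if cfg is None else cfg
    if not state.history:
        raise ValueError("state history is empty; seed it with the initial condition")
    A = np.asarray(drive.A, dtype=float)
    B = np.asarray(drive.B, dtype=float)
    for f in (A, B):
        if f.shape not in ((), state.shape):
            raise ValueError(f"drive shape {f.shape} does not match state shape {state.shape}")
    ha = cfg.h ** cfg.alpha
    x_new = (state.x0 + ha * A - state.memory_sum()) / (1.0 + ha * B)
    x_new = np.asarray(x_new, dtype=float)
    if x_new.shape != state.shape:  # scalar drives on scalar state
        x_new = np.broadcast_to(x_new, state.shape).copy()
    state.history.append(x_new)
    if cfg.memory_window is not None:
        excess = len(state.history) - cfg.memory_window
        if excess > 0:
            del state.history[:excess]
    return x_new


def simulate_affine(
    A_seq,
    B_seq,
    x0: np.ndarray | float,
    cfg: FracConfig,
) -> np.ndarray:
    """Run ``frac_step`` over per-frame drive sequences ``A(t), B(t)``.

    Returns the trajectory of length ``T = len(A_seq)``; the first entry
    already reflects one step away from the seeded initial condition.
    """
    if len(A_seq) != len(B_seq):
        raise ValueError(f"drive sequences differ in length: {len(A_seq)} vs {len(B_seq)}")
    state = FracState(x0, cfg)
    out = []
    for A_t, B_t in zip(A_seq, B_seq):
        out.append(frac_step(state, AffineDrive(A_t, B_t), cfg))
    return np.array(out)
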