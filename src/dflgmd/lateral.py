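"""Excitatory/inhibitory layer, delayed Gaussian lateral inhibition, and
the ON/OFF summing layer.

Excitatory units pass their channel input through unchanged.  Inhibitory
units low-pass it through a fractional membrane,

    D^alpha I = g_leak (V_rest - I) + delta_ex P_chan (E_ex - I),

are rectified, and spread laterally by convolution with two small
Gaussian kernels: the nearest-neighbor kernel G1 acts on the current
frame and the wider next-nearest kernel G2 on the previous frame
(a one-frame synaptic delay weighted by beta):

    Ibar(t) = Ihat(t) * G1 + beta * (Ihat(t-1) * G2).

The summing units then stage the excitation/inhibition competition,

    D^alpha S = g_leak (V_rest - S) + eps_ex E (E_ex - S)
                                    + eps_in Ibar (E_in - S),

and the rectified ON and OFF sums combine superlinearly,

    S = mu1 Shat_ON + mu2 Shat_OFF + mu3 Shat_ON Shat_OFF.

Because excitation arrives instantaneously while inhibition is both
membrane-filtered and delayed, only spatiotemporal luminance *edges*
survive into S; static structure is crushed by the strong inhibitory
weight (eps_in = 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fracdyn import AffineDrive, FracConfig, FracState, frac_step
from .params import ModelParams

__all__ = [
    "Kernel",
    "make_kernel",
    "excitatory_pass",
    "inhibitory_update",
    "lateral_inhibition",
    "summing_update",
    "combine_on_off",
    "LateralState",
]


@dataclass(frozen=True)
class Kernel:
    """A (2r+1) x (2r+1) Gaussian lateral-inhibition kernel."""

    weights: np.ndarray
    F: float
    sigma: float
    radius: int

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def make_kernel(F: float, sigma: float, radius: int,
                variant: str = "literal") -> Kernel:
    """Evaluate ``G(x, y) = F / (2 pi sigma^2) * exp(-(x^2+y^2)/(2 sigma))``
    on integer offsets ``x, y in [-r, r]``.

    ``radius`` must be 1 (nearest neighbors, G1) or 2 (next-nearest, G2).
    ``variant="sigma_squared"`` uses ``2 sigma^2`` in the exponent denominator
    instead of the literal ``2 sigma``.
    """
    if F <= 0 or sigma <= 0:
        raise ValueError("F and sigma must be positive")
    if radius not in (1, 2):
        raise ValueError(f"kernel radius must be 1 or 2, got {radius}")
    if variant not in ("literal", "sigma_squared"):
        raise ValueError(f"unknown kernel variant {variant!r}")
    denom = 2.0 * sigma if variant == "literal" else 2.0 * sigma ** 2
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    w = F / (2.0 * np.pi * sigma ** 2) * np.exp(-(x ** 2 + y ** 2) / denom)
    w.flags.writeable = False
    return Kernel(weights=w, F=F, sigma=sigma, radius=radius)


def excitatory_pass(P_on: np.ndarray, P_off: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Identity relay of each channel onto its excitatory unit."""
    return P_on, P_off


def inhibitory_update(P_chan: np.ndarray, state: FracState,
                      p: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """One fractional step of the inhibitory membrane; returns (I, Ihat)."""
    P_chan = np.asarray(P_chan, float)
    A = p.g_leak * p.V_rest + p.delta_ex * P_chan * p.E_ex
    B = p.g_leak + p.delta_ex * P_chan
    I = frac_step(state, AffineDrive(A, B))
    return I, np.maximum(I, 0.0)


def lateral_inhibition(Ihat_t: np.ndarray, Ihat_prev: np.ndarray,
                       beta: float, G1: Kernel, G2: Kernel) -> np.ndarray:
    """Delayed Gaussian spread ``Ibar = Ihat(t)*G1 + beta*(Ihat(t-1)*G2)``.

    Borders use replicate padding so a uniform field stays uniform and no
    spurious "motion" is created against the image frame.
    """
    cur = ndimage.convolve(Ihat_t, G1.weights, mode="nearest")
    lag = ndimage.convolve(Ihat_prev, G2.weights, mode="nearest")
    return cur + beta * lag


def summing_update(E: np.ndarray, Ibar: np.ndarray, channel: str,
                   state: FracState, p: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """One fractional step of a summing unit; returns (S, Shat).

    The inhibitory term's battery is E_in for both channels by default.
    With ``on_inhibition_excitatory`` the ON channel instead uses E_ex, literally
    reproducing the literal ON equation (in which the "inhibitory" input
    is driven toward the excitatory battery).
    """
    if channel not in ("on", "off"):
        raise ValueError(f"channel must be 'on' or 'off', got {channel!r}")
    E = np.asarray(E, float)
    Ibar = np.asarray(Ibar, float)
    if E.shape != Ibar.shape:
        raise ValueError(f"field shapes differ: {E.shape} vs {Ibar.shape}")
    batt = p.E_ex if (channel == "on" and p.on_inhibition_excitatory) else p.E_in
    A = p.g_leak * p.V_rest + p.eps_ex * E * p.E_ex + p.eps_in * Ibar * batt
    B = p.g_leak + p.eps_ex * E + p.eps_in * Ibar
    S = frac_step(state, AffineDrive(A, B))
    return S, np.maximum(S, 0.0)


def combine_on_off(Shat_on: np.ndarray, Shat_off: np.ndarray,
                   p: ModelParams) -> np.ndarray:
    """Superlinear ON/OFF combination."""
    return p.mu1 * Shat_on + p.mu2 * Shat_off + p.mu3 * Shat_on * Shat_off


class LateralState:
    """All per-layer state between the retina and the direction layer."""

    def __init__(self, shape: tuple[int, int], p: ModelParams, cfg: FracConfig):
        v0 = np.full(shape, p.V_rest)
        self.I_on = FracState(v0, cfg)
        self.I_off = FracState(v0, cfg)
        self.S_on = FracState(v0, cfg)
        self.S_off = FracState(v0, cfg)
        self.Ihat_on_prev = np.zeros(shape)
        self.Ihat_off_prev = np.zeros(shape)
        self.G1 = make_kernel(p.F1, p.sigma1, 1, p.kernel_exponent_variant)
        self.G2 = make_kernel(p.F2, p.sigma2, 2, p.kernel_exponent_variant)

    def step(self, P_on: np.ndarray, P_off: np.ndarray, p: ModelParams) -> np.ndarray:
        """Advance E -> I -> Ibar -> S for both channels; return combined S."""
        E_on, E_off = excitatory_pass(P_on, P_off)
        _, Ihat_on = inhibitory_update(P_on, self.I_on, p)
        _, Ihat_off = inhibitory_update(P_off, self.I_off, p)
        Ibar_on = lateral_inhibition(Ihat_on, self.Ihat_on_prev, p.beta_on, self.G1, self.G2)
        Ibar_off = lateral_inhibition(Ihat_off, self.Ihat_off_prev, p.beta_off, self.G1, self.G2)
        _, Shat_on = summing_update(E_on, Ibar_on, "on", self.S_on, p)
        _, Shat_off = summing_update(E_off, Ibar_off, "off", self.S_off, p)
        self.Ihat_on_prev = Ihat_on
        self.Ihat_off_prev = Ihat_off
        return combine_on_off(Shat_on, Shat_off, p)
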