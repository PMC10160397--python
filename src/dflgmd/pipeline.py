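"""Frame-by-frame orchestration of the five-layer network.

``run_network`` consumes a T x H x W luminance stack and produces the
per-frame directional LGMD responses, the aggregate collision trace, the
estimated motion direction per frame, and summary reports (collision
peak, direction tuning curve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dslgmd import (THETA_SET, CollisionReport, TuningCurve, collision_peak,
                     direction_correlate, direction_mode, lgmd_integrate,
                     lgmd_update, local_angle, tuning_curve)
from .fracdyn import FracConfig, FracState
from .lateral import LateralState
from .params import ModelParams
from .retina import photoreceptor_update, split_on, split_off
from .stimgen import LuminanceSequence

__all__ = ["NetworkOutput", "run_network"]


@dataclass
class NetworkOutput:
    """Everything the network computes over one run.

    R1, L1, L1_rect have shape (T, 8) over the canonical angles; C is the
    per-frame aggregate sum_theta L1_rect; MD holds the per-frame global
    motion direction (NaN where undefined).
    """

    theta_set: np.ndarray
    R1: np.ndarray
    L1: np.ndarray
    L1_rect: np.ndarray
    C: np.ndarray
    MD: np.ndarray
    collision: CollisionReport
    tuning: TuningCurve
    S_last: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.C.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Per-frame table: frame, C, the 8 rectified channels, MD in degrees."""
        cols = {"frame": np.arange(1, self.n_frames + 1), "C": self.C}
        for k, th in enumerate(self.theta_set):
            cols[f"L1_theta_{int(round(np.degrees(th)))}"] = self.L1_rect[:, k]
        cols["MD_deg"] = np.degrees(self.MD)
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        """Run-level summary mirroring the per-frame table."""
        return {
            "n_frames": int(self.n_frames),
            "responded": bool(self.collision.responded),
            "peak_frame": self.collision.peak_frame,
            "peak_value": self.collision.peak_value,
            "peak_prominence": self.collision.peak_prominence,
            "preferred_theta_rad": None if self.tuning.no_motion else self.tuning.preferred,
            "preferred_theta_deg": None if self.tuning.no_motion
            else float(np.degrees(self.tuning.preferred)),
            "no_motion": bool(self.tuning.no_motion),
            "theta_scores": {f"{int(round(np.degrees(th)))}": float(s)
                             for th, s in zip(self.theta_set, self.tuning.scores)},
        }


def run_network(frames: np.ndarray | LuminanceSequence,
                params: ModelParams | None = None) -> NetworkOutput:
    """Run the full network over a luminance sequence.

    Parameters
    ----------
    frames : T x H x W array (luminance in [0, 1]) or LuminanceSequence.
    params : model constants; defaults to the reference parameter set.
    """
    if isinstance(frames, LuminanceSequence):
        frames = frames.frames
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a T x H x W stack")
    T, H, W = frames.shape
    if T < 3:
        raise ValueError("the direction layer needs at least 3 frames")
    p = params if params is not None else ModelParams()
    cfg = FracConfig(alpha=p.alpha1, h=p.h, memory_window=p.memory_window)
    xi = p.lgmd_gain(H, W)

    P_state = FracState(np.full((H, W), p.V_rest), cfg)
    lateral = LateralState((H, W), p, cfg)
    L1_state = FracState(np.full(8, p.V_rest), cfg)

    R1 = np.zeros((T, 8))
    L1 = np.zeros((T, 8))
    L1_rect = np.zeros((T, 8))
    MD = np.full(T, np.nan)
    S_prev1: np.ndarray | None = None  # S(t-1)
    S_prev2: np.ndarray | None = None  # S(t-2)

    for t in range(T):
        L_t = frames[t]
        L_prev = frames[t - 1] if t > 0 else frames[t]
        P = photoreceptor_update(L_t, L_prev, P_state, p)
        P_on = split_on(P, p)
        P_off = split_off(P, p)
        S = lateral.step(P_on, P_off, p)

        if t >= 2:
            D_fields = [direction_correlate(S, S_prev1, S_prev2, th, p)
                        for th in THETA_SET]
            R1[t] = [lgmd_integrate(D) for D in D_fields]
            E_angle, mask = local_angle(D_fields[0], D_fields[2], p.energy_floor)
            md = direction_mode(E_angle, mask)
            MD[t] = np.nan if md is None else md
        L1[t], L1_rect[t] = lgmd_update(R1[t], L1_state, p, xi)

        S_prev2, S_prev1 = S_prev1, S

    C = L1_rect.sum(axis=1)
    return NetworkOutput(
        theta_set=THETA_SET.copy(),
        R1=R1, L1=L1, L1_rect=L1_rect, C=C, MD=MD,
        collision=collision_peak(C),
        tuning=tuning_curve(L1_rect),
        S_last=S_prev1,
    )
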