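"""Model parameters: one dataclass holding every network constant.

Defaults follow the reference parameter table of the model.  Parameters
given there as ranges (``g_leak``, ``V_rest``, ``E_in``, ``beta_on``,
``beta_off``) default to mid-range values; a value outside its reference
range raises a warning, not an error, since the ranges are stated as
empirical tuning guidance.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["ModelParams", "ParamRangeWarning", "PARAM_RANGES", "load_params"]

#: Published tuning ranges for the ranged parameters.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "g_leak": (25.0, 50.0),
    "V_rest": (-0.001, 0.0),
    "E_in": (-1.0, -0.3),
    "beta_on": (1.0, 1.2),
    "beta_off": (1.0, 1.2),
}


class ParamRangeWarning(UserWarning):
    """A parameter lies outside its reference tuning range."""


@dataclass
class ModelParams:
    """All network constants plus numerical-scheme switches.

    Membrane / synaptic constants
    -----------------------------
    alpha1 : fractional order of every membrane equation (0 < alpha1 <= 1).
    g_leak : leak conductance; V_rest : resting potential.
    E_ex, E_in : excitatory / inhibitory synaptic batteries bounding the
        dynamic range of every membrane potential.
    lambda_ex, lambda_in : photoreceptor gains on the current and previous
        frame's luminance.
    gamma1, gamma2 : ON / OFF channel gains; V_th1, V_th2 : their
        rectification thresholds.
    delta_ex : inhibitory-neuron input gain.
    beta_on, beta_off : weights of the delayed (next-nearest) lateral
        inhibition term.
    eps_ex, eps_in : summing-layer excitatory / inhibitory weights.
    mu1, mu2, mu3 : ON/OFF superlinear combination coefficients.
    m : direction-layer displacement (px); F1, sigma1, F2, sigma2 : lateral
        inhibition kernel scale/width (nearest and next-nearest kernel).
    n : grid side; the LGMD gain is xi_ex = 5 * 128^2 / n^2 unless
        overridden via ``xi_ex``.

    Scheme switches
    ---------------
    h, memory_window : fractional-operator step and history truncation.
    on_inhibition_excitatory : give the ON summing unit's second synaptic term the
        excitatory battery, in the literal formulation (default True).  With
        the symmetric alternative (False: both channels use E_in) the
        strong inhibitory weight eps_in = 100 silences the summing layer
        for every input — the same-frame nearest-neighbor kernel alone
        carries ~20x more conductance than the excitatory path — so the
        network output is identically zero; the literal ON equation is
        what makes the reference network produce signal.
    rectify_lgmd_input : clamp the LGMD synaptic drive R1 at zero before
        it enters the conductance equation (default True).  A negative
        R1 with |xi_ex * R1| > g_leak makes the LGMD membrane equation
        unstable (negative total conductance) and the discrete solve then
        lands on a spurious positive equilibrium; a synaptic conductance
        cannot be negative, so the drive is rectified.  False keeps the
        literal signed drive.
    kernel_exponent_variant : "literal" uses exp(-(x^2+y^2)/(2*sigma));
        "sigma_squared" uses the conventional exp(-(x^2+y^2)/(2*sigma^2)).
    offset_sign : orientation of the direction-layer displacement; -1
        (default) places the correlation partner upstream of the preferred
        direction so that motion along theta yields a positive response
        (see dslgmd module notes); +1 is the literal orientation.
    interpolate_diagonals : bilinearly sample the displaced field at the
        exact distance m (default True), so all 8 channels use the same
        displacement magnitude; False rounds diagonal displacements to
        the integer 8-neighborhood (length sqrt(2) m), which biases the
        diagonal channels under noise.
    energy_floor : correlation-energy floor below which a pixel is
        excluded from the motion-direction mode.
    """

    alpha1: float = 0.4
    g_leak: float = 30.0
    V_rest: float = 0.0
    V_th1: float = 5e-4
    V_th2: float = 5e-4
    E_in: float = -0.5
    E_ex: float = 1.0
    lambda_ex: float = 1.2
    lambda_in: float = 1.2
    gamma1: float = 150.0
    gamma2: float = 150.0
    eps_ex: float = 1.0
    eps_in: float = 100.0
    delta_ex: float = 1.5
    beta_on: float = 1.1
    beta_off: float = 1.1
    m: float = 1.0
    F1: float = 5.0
    F2: float = 1.0
    sigma1: float = 0.3
    sigma2: float = 0.4
    mu1: float = 1.0
    mu2: float = 1.0
    mu3: float = 0.0
    n: int = 128
    xi_ex: float | None = None
    h: float = 1.0
    memory_window: int | None = None
    on_inhibition_excitatory: bool = True
    rectify_lgmd_input: bool = True
    kernel_exponent_variant: str = "literal"
    offset_sign: int = -1
    interpolate_diagonals: bool = True
    energy_floor: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha1 <= 1.0:
            raise ValueError(f"alpha1 must lie in (0, 1], got {self.alpha1}")
        if self.kernel_exponent_variant not in ("literal", "sigma_squared"):
            raise ValueError(f"unknown kernel_exponent_variant {self.kernel_exponent_variant!r}")
        if self.offset_sign not in (-1, 1):
            raise ValueError(f"offset_sign must be +1 or -1, got {self.offset_sign}")
        for name in ("g_leak", "gamma1", "gamma2", "lambda_ex", "lambda_in",
                     "eps_ex", "eps_in", "delta_ex", "m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.E_in <= self.V_rest <= self.E_ex:
            raise ValueError("batteries must bracket the resting potential: "
                             f"E_in={self.E_in}, V_rest={self.V_rest}, E_ex={self.E_ex}")
        self.check_ranges()

    def check_ranges(self) -> list[str]:
        """Warn (and return messages) for values outside reference ranges."""
        msgs = []
        for name, (lo, hi) in PARAM_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                msg = f"{name}={v} outside the reference tuning range [{lo}, {hi}]"
                msgs.append(msg)
                warnings.warn(msg, ParamRangeWarning, stacklevel=3)
        return msgs

    def lgmd_gain(self, H: int | None = None, W: int | None = None) -> float:
        """LGMD input gain xi_ex = 5 * 128^2 / n^2, or its override.

        For non-square grids ``n^2`` generalizes to ``H * W``.
        """
        if self.xi_ex is not None:
            return self.xi_ex
        if H is None:
            H = self.n
        if W is None:
            W = H
        return 5.0 * 128.0 ** 2 / (H * W)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_params(path: str | Path | None = None, **overrides) -> ModelParams:
    """Build :class:`ModelParams` from a YAML/JSON file plus overrides.

    Missing keys take the defaults above; unknown keys are rejected.  An
    empty file yields the full default parameter set.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ModelParams(**data)
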