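"""Shared fixtures: default parameters and small synthetic stimuli."""

import numpy as np
import pytest

from dflgmd import ModelParams, StimulusSpec, gen_translating


@pytest.fixture
def params() -> ModelParams:
    """Published defaults (mid-range values for ranged parameters)."""
    return ModelParams()


@pytest.fixture
def small_translate():
    """A small rightward dark-block stimulus at the correlator's matched speed."""
    spec = StimulusSpec(kind="translate", grid=(48, 48), n_frames=30,
                        direction=0.0, speed=0.5, size=7)
    return gen_translating(spec)


def mittag_leffler(alpha: float, z: float, n_terms: int = 300) -> float:
    """Truncated power series E_alpha(z) = sum_k z^k / Gamma(alpha k + 1).

    Independent oracle for the fractional relaxation trajectory; terms
    whose Gamma overflows contribute zero (they are far below machine
    precision for the |z| <= 10**0.4 arguments used in the tests).
    """
    from scipy.special import gamma

    ks = np.arange(n_terms)
    with np.errstate(over="ignore"):
        g = gamma(alpha * ks + 1.0)
    terms = np.where(np.isfinite(g), z ** ks / g, 0.0)
    return float(terms.sum())
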