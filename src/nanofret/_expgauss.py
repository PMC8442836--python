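"""Closed-form convolution of a one-sided exponential with a Gaussian.

The instrument response of both the TCSPC and transient-absorption fits is
modelled as a normalised Gaussian; every kinetic component is then an
exponential decay exp(-k t)·θ(t) convolved with it, which has the analytic
form

    h(x) = ½ exp(σ²k²/2 − kx) · erfc((σk − x/σ)/√2),   x = t − t0.

Evaluated via the scaled complementary error function erfcx to stay finite
for x ≫ σ (where the naive product overflows), with an asymptotic branch for
the extreme tail. k = 0 gives the Gaussian-broadened step, σ = 0 the sharp
exponential.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfcx

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


def exp_conv_gauss(x: np.ndarray, k: float, sigma: float) -> np.ndarray:
    """exp(-k·x)·θ(x) convolved with a unit-area Gaussian of std ``sigma``.

    ``k`` is a non-negative rate (k = 0 → step response); ``sigma = 0``
    returns the unconvolved one-sided exponential.
    """
    x = np.asarray(x, dtype=float)
    if k < 0:
        raise ValueError("rate k must be non-negative")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        out = np.zeros_like(x)
        pos = x >= 0
        out[pos] = np.exp(-k * x[pos])
        return out
    u = (sigma * k - x / sigma) / np.sqrt(2.0)
    out = np.empty_like(x)
    # erfcx overflows for arguments below ~ -26; there erfc ≈ 2 exactly.
    tail = u < -25.0
    safe = ~tail
    out[safe] = 0.5 * np.exp(-0.5 * (x[safe] / sigma) ** 2) * erfcx(u[safe])
    out[tail] = np.exp(k * (0.5 * k * sigma**2 - x[tail]))
    return out
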