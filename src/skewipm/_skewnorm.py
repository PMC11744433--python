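"""Skew-normal density, CDF, and sampling in the direct (xi, omega, alpha) form.

The density is f(y) = (2/omega) * phi(z) * Phi(alpha * z), z = (y - xi)/omega,
with phi/Phi the standard normal pdf/cdf.  ``xi`` is location, ``omega > 0``
scale, and ``alpha`` shape: alpha < 0 gives a left-skewed (shrinkage-heavy)
distribution, alpha = 0 recovers the normal.  The CDF has the closed form
Phi(z) - 2*T(z, alpha) with Owen's T function, which is what makes a
CDF-difference kernel discretization cheap.
"""

from __future__ import annotations

import numpy as np
from scipy import special

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def logpdf(y, xi, omega, alpha):
    """Log-density of the skew normal; arguments broadcast."""
    omega = np.asarray(omega, dtype=float)
    z = (np.asarray(y, dtype=float) - xi) / omega
    return (
        np.log(2.0)
        - np.log(omega)
        - 0.5 * z * z
        - _LOG_SQRT_2PI
        + special.log_ndtr(alpha * z)
    )


def pdf(y, xi, omega, alpha):
    return np.exp(logpdf(y, xi, omega, alpha))


def cdf(y, xi, omega, alpha):
    """Skew-normal CDF via Owen's T: F(z) = Phi(z) - 2*T(z, alpha)."""
    z = (np.asarray(y, dtype=float) - xi) / np.asarray(omega, dtype=float)
    z, alpha = np.broadcast_arrays(z, np.asarray(alpha, dtype=float))
    return np.clip(special.ndtr(z) - 2.0 * special.owens_t(z, alpha), 0.0, 1.0)


def inverse_mills(u):
    """phi(u)/Phi(u), computed stably for very negative u."""
    u = np.asarray(u, dtype=float)
    return np.exp(-0.5 * u * u - _LOG_SQRT_2PI - special.log_ndtr(u))


def rvs(xi, omega, alpha, size, rng):
    """Draw skew-normal variates via the bivariate-normal representation.

    Z = delta*|U0| + sqrt(1-delta^2)*U1 with delta = alpha/sqrt(1+alpha^2)
    is standard skew-normal(alpha); the draw is exact, not rejection-based.
    """
    alpha = np.asarray(alpha, dtype=float)
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    u0 = rng.standard_normal(size)
    u1 = rng.standard_normal(size)
    z = delta * np.abs(u0) + np.sqrt(1.0 - delta * delta) * u1
    return xi + omega * z
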