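"""Fluorescence decay models and IRF convolution kernels.

The sample's fluorescence impulse response (FIR) at one pixel and channel is
modelled as a biexponential,

    h(t) = a_fast * exp(-t / tau_fast) + (1 - a_fast) * exp(-t / tau_slow),

and the measured decay is the FIR convolved with the instrument response
function (IRF) ``u(t)``.  For a Gaussian IRF the convolution has the
exponentially-modified-Gaussian closed form, which this module evaluates in
an overflow-safe way (via ``erfcx``); for IRFs known only through their
samples a trapezoid-rule discrete convolution is provided.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfcx

__all__ = [
    "exp_conv_gauss",
    "multiexp_conv_gauss",
    "multiexp_fir",
    "discrete_reconvolve",
]

_SQRT2 = np.sqrt(2.0)


def exp_conv_gauss(t, tau, sigma: float, t0: float) -> np.ndarray:
    """Convolution of ``exp(-t/tau)`` (for t >= 0) with a unit-area Gaussian.

    The Gaussian pulse is centred at ``t0`` with standard deviation ``sigma``
    (ns).  ``sigma -> 0`` reduces to the shifted exponential itself.  The
    result is evaluated stably for any sigma/tau ratio using the scaled
    complementary error function.  ``tau`` may be an array broadcasting
    against ``t`` (batched evaluation over pixels).
    """
    t = np.asarray(t, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    s = t - t0
    if sigma == 0.0:
        return np.exp(-np.maximum(s, 0.0) / tau) * (s >= 0)
    z = (sigma / tau - s / sigma) / _SQRT2
    # For z >= 0: 0.5*erfcx(z)*exp(-s^2/(2 sigma^2)) avoids overflow of the
    # textbook 0.5*exp(sigma^2/(2 tau^2) - s/tau)*erfc(z) form.
    gauss = np.exp(-(s * s) / (2.0 * sigma * sigma))
    safe = 0.5 * erfcx(np.maximum(z, 0.0)) * gauss
    with np.errstate(over="ignore"):
        direct = 0.5 * np.exp(sigma**2 / (2 * tau**2) - s / tau) * _erfc_neg(z)
    return np.where(z >= 0, safe, direct)


def _erfc_neg(z: np.ndarray) -> np.ndarray:
    # erfc for z < 0 is in (1, 2): no stability concern.
    from scipy.special import erfc

    return erfc(np.minimum(z, 0.0))


def multiexp_conv_gauss(
    t: np.ndarray,
    weights: np.ndarray,
    taus: np.ndarray,
    sigma: float,
    t0: float,
) -> np.ndarray:
    """Weighted sum of Gaussian-convolved exponentials on the time grid ``t``.

    ``weights`` and ``taus`` broadcast over components; weights need not sum
    to one (an amplitude scale is applied by the caller).
    """
    out = np.zeros_like(np.asarray(t, dtype=float))
    for w, tau in zip(np.atleast_1d(weights), np.atleast_1d(taus)):
        out = out + w * exp_conv_gauss(t, float(tau), sigma, t0)
    return out


def multiexp_fir(t: np.ndarray, weights: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Sampled multiexponential FIR ``sum_i w_i exp(-t/tau_i)`` for t >= 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for w, tau in zip(np.atleast_1d(weights), np.atleast_1d(taus)):
        out = out + w * np.exp(-t / float(tau))
    return out


def discrete_reconvolve(irf: np.ndarray, fir: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoid-rule discrete convolution of sampled IRF and FIR.

    Approximates ``(u * h)(t_n)`` from samples, truncated to the acquisition
    window (the length of ``irf``).  Second-order accurate in ``dt``, which
    matters because the fast lifetime can be comparable to the sample spacing.
    """
    irf = np.asarray(irf, dtype=float)
    fir = np.asarray(fir, dtype=float)
    n = len(irf)
    full = np.convolve(irf, fir)[:n] * dt
    # trapezoid end-point correction: subtract half of the two boundary terms
    full -= 0.5 * dt * (irf[0] * fir[:n] + fir[0] * irf[:n])
    return full
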