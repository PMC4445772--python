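"""Gaussian lineshape conversions.

A time-domain Gaussian envelope ``exp(-beta * t**2)`` Fourier-transforms to
a frequency-domain Gaussian ``exp(-pi**2 f**2 / beta)`` whose full width at
half maximum is ``FWHM = 2 * sqrt(beta * ln 2) / pi``.  Inverting,

    beta = (pi * FWHM)**2 / (4 * ln 2)            [beta in s^-2, FWHM in Hz]

The one-sided (causal FID) transform halves the peak height but leaves the
FWHM of the absorption line unchanged, so the same conversion applies.
"""

from __future__ import annotations

import numpy as np

_LN2 = float(np.log(2.0))


def beta_of_fwhm(fwhm_hz):
    """Gaussian damping rate (s^-2) for a spectral FWHM in Hz."""
    fwhm_hz = np.asarray(fwhm_hz, dtype=float)
    return (np.pi * fwhm_hz) ** 2 / (4.0 * _LN2)


def fwhm_of_beta(beta):
    """Spectral FWHM in Hz of a Gaussian damping rate (s^-2)."""
    beta = np.asarray(beta, dtype=float)
    return 2.0 * np.sqrt(beta * _LN2) / np.pi


def gaussian_peak(t, amplitude, freq_hz, fwhm_hz, phase=0.0):
    """Complex FID of one Gaussian-damped resonance.

    ``amplitude`` is the time-domain amplitude at t = 0, which equals the
    integrated spectral area of the resonance.
    """
    beta = beta_of_fwhm(fwhm_hz)
    return amplitude * np.exp(
        1j * phase + 2j * np.pi * freq_hz * t - beta * t**2
    )
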