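"""Beta-decay energy spectra.

A beta emission line is stored by its endpoint (maximum) energy; the emitted
electron energy is drawn from a Fermi-theory-shaped allowed spectrum

    w(E) dE  ∝  F(Z, E) · p · (E + m_e c²) · (Q − E)² dE,

with the non-relativistic Coulomb correction F = x / (1 − e^(−x)),
x = 2π Z α / β, for daughter charge Z.  The shape is precomputed on a grid
and sampled by inverse-CDF lookup, which is fast enough for Monte Carlo use.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

ELECTRON_REST_KEV = 511.0  # m_e c²
FINE_STRUCTURE = 1.0 / 137.035999


class BetaSpectrum:
    """Allowed beta spectrum with endpoint ``endpoint_kev`` and daughter charge Z."""

    def __init__(self, endpoint_kev: float, z_daughter: int = 0, n_grid: int = 1024):
        if endpoint_kev <= 0:
            raise ValueError("beta endpoint must be positive")
        self.endpoint_kev = float(endpoint_kev)
        self.z_daughter = int(z_daughter)
        e = np.linspace(endpoint_kev * 1e-5, endpoint_kev * (1 - 1e-9), n_grid)
        etot = e + ELECTRON_REST_KEV
        p = np.sqrt(e * (e + 2.0 * ELECTRON_REST_KEV))
        w = p * etot * (endpoint_kev - e) ** 2
        if self.z_daughter:
            beta_v = p / etot
            x = 2.0 * np.pi * self.z_daughter * FINE_STRUCTURE / beta_v
            w = w * x / -np.expm1(-x)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(e))])
        self._e = e
        self._cdf = cdf / cdf[-1]
        self.mean_kev = float(np.trapezoid(e * w, e) / np.trapezoid(w, e))

    def sample(self, u):
        """Map uniform(0,1) deviates to beta energies (keV) by inverse CDF."""
        return np.interp(u, self._cdf, self._e)


@lru_cache(maxsize=32)
def beta_spectrum(endpoint_kev: float, z_daughter: int = 0) -> BetaSpectrum:
    return BetaSpectrum(endpoint_kev, z_daughter)
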