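"""Physical constants and the unit system used throughout the package.

All energies and frequencies are expressed in wavenumbers (cm^-1), all times
in femtoseconds.  In this system a quantum of frequency ``omega`` (cm^-1)
carries energy ``omega`` directly, and phases are ``omega * t / HBAR`` with
``HBAR`` in cm^-1 fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reduced Planck constant in cm^-1 fs (1 / (2 pi c) with c in cm/fs).
HBAR_CM_FS = 5308.8

#: Boltzmann constant in cm^-1 / K.
KB_CM_K = 0.695035


@dataclass(frozen=True)
class PhysicalConstants:
    """Unit constants plus the bath temperature.

    Parameters
    ----------
    temperature : float
        Bath temperature in kelvin. Must be strictly positive.
    hbar : float
        Reduced Planck constant in cm^-1 fs.
    kB : float
        Boltzmann constant in cm^-1 / K.
    """

    temperature: float
    hbar: float = HBAR_CM_FS
    kB: float = KB_CM_K

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError("temperature must be strictly positive")
        if not (self.hbar > 0 and self.kB > 0):
            raise ValueError("hbar and kB must be strictly positive")

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(kB T) in 1/cm^-1."""
        return 1.0 / (self.kB * self.temperature)


def coth(x: np.ndarray | float) -> np.ndarray:
    """Numerically safe hyperbolic cotangent.

    Uses the series ``1/x + x/3`` below ``x = 1e-3`` and saturates to 1 for
    large arguments to avoid overflow in ``cosh``/``sinh``.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    big = np.abs(x) > 20.0
    mid = ~(small | big)
    with np.errstate(divide="ignore"):
        out[small] = 1.0 / x[small] + x[small] / 3.0
    out[big] = np.sign(x[big])
    out[mid] = 1.0 / np.tanh(x[mid])
    return out
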