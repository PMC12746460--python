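"""Structured spectral densities: representation, slow/fast splitting,
discretization into effective modes, and thermodynamic summaries.

A spectral density J(omega) (cm^-1, tabulated on a frequency grid in cm^-1)
encodes the frequency-resolved coupling of one chromophore's electronic
excitation to its harmonic environment.  The reorganization energy is
``Lambda = int J(omega)/omega domega`` (no 1/pi prefactor in this
convention).  Non-Markovian low-frequency modes are separated from the
dynamical bath by a smooth splitting function with cutoff ``omega_star`` and
fed back into the simulation as quasi-static Gaussian site-energy disorder
of width ``sigma_slow``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import PhysicalConstants, coth

__all__ = [
    "SpectralDensity",
    "BathSplit",
    "DiscretizedBath",
    "reorganization_energy",
    "split_spectral_density",
    "splitting_function",
    "sigma_slow",
    "discretize_bath",
    "scaled_density",
]


@dataclass(frozen=True)
class SpectralDensity:
    """A tabulated spectral density J(omega).

    Attributes
    ----------
    omega : ndarray
        Strictly increasing frequency grid, cm^-1, all >= 0.
    values : ndarray
        J(omega) >= 0, cm^-1.  If ``omega[0] == 0`` then ``values[0]`` must
        be 0 so that J/omega stays finite.
    label : str
        Chromophore identifier.
    """

    omega: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "values", values)
        if omega.ndim != 1 or omega.size < 2:
            raise ValueError("frequency grid must be 1-D with at least 2 points")
        if values.shape != omega.shape:
            raise ValueError("values and omega must have identical shapes")
        if np.any(np.diff(omega) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if omega[0] < 0:
            raise ValueError("frequencies must be non-negative")
        if np.any(values < 0):
            raise ValueError("spectral density values must be non-negative")
        if omega[0] == 0 and values[0] != 0:
            raise ValueError("J(0) must vanish when the grid starts at omega = 0")

    def over_omega(self) -> np.ndarray:
        """J(omega)/omega with the omega -> 0 limit filled by the slope."""
        out = np.empty_like(self.values)
        if self.omega[0] == 0:
            out[1:] = self.values[1:] / self.omega[1:]
            # J ~ slope * omega near 0, so J/omega -> slope
            out[0] = self.values[1] / self.omega[1]
        else:
            out[:] = self.values / self.omega
        return out


def scaled_density(J: SpectralDensity, factor: np.ndarray | float, label: str | None = None) -> SpectralDensity:
    """Return a new density with values multiplied pointwise by ``factor``."""
    return SpectralDensity(J.omega, J.values * factor, label if label is not None else J.label)


@dataclass(frozen=True)
class BathSplit:
    """Slow/fast decomposition of a spectral density at cutoff omega_star."""

    omega_star: float
    slow: SpectralDensity
    fast: SpectralDensity
    slow_fraction: float


@dataclass(frozen=True)
class DiscretizedBath:
    """Equally spaced effective-mode representation of a spectral density.

    ``mode_lambdas[j]`` is the reorganization energy carried by the mode at
    ``mode_freqs[j]``; the sum over modes reproduces the continuous
    reorganization energy of the parent density.
    """

    mode_freqs: np.ndarray
    mode_lambdas: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.mode_freqs, dtype=float)
        lams = np.asarray(self.mode_lambdas, dtype=float)
        object.__setattr__(self, "mode_freqs", freqs)
        object.__setattr__(self, "mode_lambdas", lams)
        if freqs.shape != lams.shape:
            raise ValueError("mode_freqs and mode_lambdas must have the same shape")
        if np.any(lams < -1e-300):
            raise ValueError("mode reorganization energies must be non-negative")

    @property
    def delta(self) -> float:
        """Mode spacing in cm^-1."""
        return float(self.mode_freqs[1] - self.mode_freqs[0])


def reorganization_energy(J: SpectralDensity) -> float:
    """Total reorganization energy Lambda = int_0^inf J(omega)/omega domega.

    Composite trapezoid on the tabulated grid; the omega -> 0 limit of the
    integrand is filled analytically.
    """
    return float(np.trapezoid(J.over_omega(), J.omega))


def splitting_function(omega: np.ndarray, omega_star: float) -> np.ndarray:
    """Smooth low-pass splitting weight S(omega, omega*).

    ``S = [1 - (omega/omega*)^2]^2`` below the cutoff and 0 at and above it;
    continuous with continuous first derivative at the cutoff.
    """
    if omega_star <= 0:
        raise ValueError("omega_star must be positive")
    omega = np.asarray(omega, dtype=float)
    s = np.zeros_like(omega)
    below = omega < omega_star
    x = omega[below] / omega_star
    s[below] = (1.0 - x * x) ** 2
    return s


def split_spectral_density(J: SpectralDensity, omega_star: float) -> BathSplit:
    """Split J into slow (< omega*) and fast components.

    The two parts add back to the parent exactly, pointwise; the slow
    fraction is the share of the reorganization energy carried by the slow
    part.
    """
    s = splitting_function(J.omega, omega_star)
    # double subtraction keeps slow + fast == J exact at every grid point
    # (Sterbenz: one of the two subtractions is always error-free)
    fast_vals = J.values - s * J.values
    slow_vals = J.values - fast_vals
    slow = SpectralDensity(J.omega, slow_vals, J.label)
    fast = SpectralDensity(J.omega, fast_vals, J.label)
    lam_total = reorganization_energy(J)
    lam_slow = reorganization_energy(slow)
    frac = lam_slow / lam_total if lam_total > 0 else 0.0
    return BathSplit(float(omega_star), slow, fast, frac)


def sigma_slow(J_slow: SpectralDensity, consts: PhysicalConstants) -> float:
    """Width of quasi-static Gaussian site-energy disorder from the slow bath.

    ``sigma^2 = int J_slow(omega) coth(beta omega / 2) domega`` with the mode
    energy in cm^-1, which reduces to the classical ``2 Lambda_slow kB T`` in
    the high-temperature limit.
    """
    x = 0.5 * consts.beta * J_slow.omega
    integrand = np.empty_like(J_slow.values)
    pos = J_slow.omega > 0
    integrand[pos] = J_slow.values[pos] * coth(x[pos])
    if not pos.all():
        # J coth(beta omega/2) -> (2 kB T) * J/omega -> 2 kB T * slope
        slope = J_slow.over_omega()[0]
        integrand[~pos] = 2.0 * slope / consts.beta
    var = float(np.trapezoid(integrand, J_slow.omega))
    return float(np.sqrt(max(var, 0.0)))


def discretize_bath(J_fast: SpectralDensity, n_modes: int) -> DiscretizedBath:
    """Collapse a tabulated density onto ``n_modes`` equally spaced modes.

    The grid range [omega[0], omega[-1]] is divided into ``n_modes`` equal
    bins; mode j sits at the bin center and carries
    ``lambda_j = int_bin J(omega)/omega domega``.  Bin integrals are taken
    as differences of the cumulative trapezoid of J/omega (linearly
    interpolated at bin edges), so the sum over modes telescopes to the
    total reorganization energy of the parent density.
    """
    if n_modes < 2:
        raise ValueError("n_modes must be at least 2")
    omega = J_fast.omega
    f = J_fast.over_omega()
    if omega[-1] <= omega[0]:
        raise ValueError("empty frequency support")
    edges = np.linspace(omega[0], omega[-1], n_modes + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # cumulative integral F(omega) of J/omega, piecewise over the tabulated grid
    F = np.concatenate(
        ([0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(omega)))
    )
    F_edges = np.interp(edges, omega, F)
    lambdas = np.diff(F_edges)
    lambdas[lambdas < 0] = 0.0
    return DiscretizedBath(centers, lambdas)
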