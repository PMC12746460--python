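"""Complex line-broadening functions g(t) of structured harmonic baths.

g(t) is the second cumulant of the site-energy fluctuations and governs
dephasing in the golden-rule rate integrals.  With energies in cm^-1 and
time in fs,

    g(t) = int_0^inf domega J(omega)/omega^2 *
           [coth(beta omega/2) (1 - cos(omega t / hbar))
            + i (sin(omega t / hbar) - omega t / hbar)]

The real part is non-negative and grows without bound for any density with
nonzero reorganization energy; the imaginary part is temperature independent
and drifts asymptotically as -Lambda t / hbar.  g depends only on the bath,
so within a disorder ensemble it is computed once per chromophore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bath import SpectralDensity, reorganization_energy
from .constants import HBAR_CM_FS, PhysicalConstants, coth

__all__ = ["LineBroadening", "line_broadening", "asymptotic_slope_check"]


@dataclass(frozen=True)
class LineBroadening:
    """g(t) tabulated on a uniform time grid starting at zero.

    Attributes
    ----------
    t_grid : ndarray
        Uniform time points (fs), ``t_grid[0] == 0``.
    g_values : ndarray
        Complex g(t) per time point; ``g_values[0] == 0``.
    lambda_total : float
        Reorganization energy of the generating density, cm^-1.
    """

    t_grid: np.ndarray
    g_values: np.ndarray
    lambda_total: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        g = np.asarray(self.g_values, dtype=complex)
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "g_values", g)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid must be 1-D with at least 2 points")
        if t[0] != 0:
            raise ValueError("time grid must start at 0")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise ValueError("time grid must be uniform")
        if g.shape != t.shape:
            raise ValueError("g_values and t_grid must have identical shapes")


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += 0.5 * dx
    w[1:] += 0.5 * dx
    return w


def line_broadening(
    J: SpectralDensity,
    consts: PhysicalConstants,
    t_grid: np.ndarray,
    block_size: int = 512,
) -> LineBroadening:
    """Evaluate g(t) for one chromophore by quadrature over the tabulated grid.

    Uses a phasor recursion ``exp[i omega (t+dt)] = exp[i omega t] exp[i
    omega dt]`` along the uniform time grid, re-synchronized with an exact
    complex exponential every ``block_size`` steps; the result is
    independent of the block size to rounding accuracy.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0:
        raise ValueError("time grid must start at 0")
    steps = np.diff(t_grid)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
        raise ValueError("time grid must be uniform")
    dt = steps[0] if steps.size else 0.0

    omega = J.omega
    hbar = consts.hbar
    # quadrature weights folded into the frequency-only factors, with the
    # analytic omega -> 0 limit split off
    w = _trapezoid_weights(omega)
    pos = omega > 0
    j_over_w2 = np.zeros_like(J.values)
    j_over_w2[pos] = J.values[pos] / omega[pos] ** 2
    cth = np.ones_like(omega)
    cth[pos] = coth(0.5 * consts.beta * omega[pos])
    wr = w * j_over_w2 * cth     # multiplies (1 - cos)
    wi = w * j_over_w2           # multiplies sin; the -omega t/hbar drift is summed analytically
    lam_drift = float(wi @ (omega / hbar))  # = Lambda/hbar at trapezoid accuracy
    w0_term = 0.0
    if omega[0] == 0:
        # coth * (1-cos)/omega^2 -> 2 kB T * slope * t^2 / (2 hbar^2)
        w0_term = w[0] * J.over_omega()[0] * consts.kB * consts.temperature
        wr[0] = wi[0] = 0.0

    g_re = np.empty(t_grid.size)
    g_im = np.empty(t_grid.size)
    # half-angle phasor: 1 - cos(x) = 2 sin^2(x/2) and sin(x) = 2 sin(x/2) cos(x/2)
    # avoid cancellation in Re g at short times
    step = np.exp(1j * omega * (0.5 * dt / hbar))
    p = np.ones(omega.size, dtype=complex)
    for k, t in enumerate(t_grid):
        if k > 0:
            if k % block_size == 0:
                p = np.exp(1j * omega * (0.5 * t / hbar))  # re-synchronize the recursion
            else:
                p *= step
        g_re[k] = 2.0 * (wr @ (p.imag * p.imag)) + w0_term * (t / hbar) ** 2
        g_im[k] = 2.0 * (wi @ (p.real * p.imag)) - lam_drift * t
    g = g_re + 1j * g_im
    g[0] = 0.0  # exact by construction; enforce against rounding
    return LineBroadening(t_grid, g, reorganization_energy(J))


def asymptotic_slope_check(g: LineBroadening, tail_fraction: float = 0.1) -> float:
    """Relative deviation of the late-time slope of Im g from -Lambda/hbar.

    A convergence diagnostic for the time-grid length: once the bath
    correlation functions have decayed, Im g drifts linearly with slope
    -Lambda/hbar.  Returns 0 for a zero bath.
    """
    if g.lambda_total == 0:
        return 0.0
    n_tail = max(2, int(round(tail_fraction * g.t_grid.size)))
    t = g.t_grid[-n_tail:]
    y = g.g_values[-n_tail:].imag
    slope = np.polyfit(t, y, 1)[0]
    target = -g.lambda_total / HBAR_CM_FS
    return float(abs(slope - target) / abs(target))
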