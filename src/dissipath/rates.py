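"""Golden-rule transfer rates and their mode-resolved dissipation decomposition.

For a pair of chromophores A, B with electronic coupling V_AB, site energies
E_A, E_B, reorganization energies Lambda_A, Lambda_B and line-broadening
functions g_A, g_B, the population transfer rate constant is

    K_BA = (2 |V_AB|^2 / hbar^2) Re int_0^inf dt
           exp[-i t (E_B - E_A + Lambda_A + Lambda_B) / hbar]
           exp[-g_A(t) - g_B(t)]

The "dissipative potential" I_BA(omega) reweights the same integrand by
[cos(omega t / hbar) - i coth(beta omega / 2) sin(omega t / hbar)] and
measures how much energy a bath mode at frequency omega absorbs (positive)
or releases (negative) per unit reorganization energy during the A -> B
transfer.  Multiplying by the discrete mode reorganization energies yields
mode-resolved dissipation rate constants, and by J(omega)/omega the
continuous dissipative spectral densities.

These objects obey, exactly, the pairwise energy sum rule

    int domega [J_A/omega + J_B/omega] I_BA(omega) * (2 V^2 / hbar^2)
        = K_BA (E_A - E_B)

with bare site energies, which guarantees global energy conservation of the
accumulated dissipation, and the full quantum integrand satisfies detailed
balance K_BA / K_AB = exp[-(E_B - E_A) / kB T].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bath import DiscretizedBath, SpectralDensity
from .constants import PhysicalConstants, coth
from .lineshape import LineBroadening

__all__ = [
    "ExcitonModel",
    "RateSet",
    "ConvergenceWarning",
    "rate_constant",
    "dissipative_potential",
    "dissipative_spectral_densities",
    "mode_rate_constants",
    "RateCalculator",
]


class ConvergenceWarning(UserWarning):
    """Raised when a rate integrand has not decayed at the end of the grid."""


@dataclass(frozen=True)
class ExcitonModel:
    """Frenkel exciton Hamiltonian: site energies plus electronic couplings.

    ``couplings`` must be symmetric with zero diagonal; only site-energy
    differences enter the dynamics.
    """

    site_energies: np.ndarray
    couplings: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.site_energies, dtype=float)
        v = np.asarray(self.couplings, dtype=float)
        object.__setattr__(self, "site_energies", e)
        object.__setattr__(self, "couplings", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = e.size
        if v.shape != (n, n):
            raise ValueError("couplings must be an (n, n) matrix")
        if len(self.labels) != n:
            raise ValueError("need one label per site")
        if not np.all(np.isfinite(e)) or not np.all(np.isfinite(v)):
            raise ValueError("energies and couplings must be finite")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("couplings must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("coupling matrix must have zero diagonal")

    @property
    def n_sites(self) -> int:
        return self.site_energies.size

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def with_site_energies(self, energies: np.ndarray) -> "ExcitonModel":
        return ExcitonModel(energies, self.couplings, self.labels)


@dataclass(frozen=True)
class RateSet:
    """Pairwise rates plus their mode-resolved dissipation decomposition.

    Attributes
    ----------
    labels : tuple of str
        Site labels, defining the index order of all arrays.
    K : ndarray, shape (n, n)
        ``K[b, a]`` is the population transfer rate constant a -> b (fs^-1);
        the diagonal is zero.
    mode_freqs : ndarray, shape (n_modes,)
        Common effective-mode frequency grid (cm^-1).
    K_mode_out : ndarray, shape (n, n, n_modes)
        ``K_mode_out[a, b, j]``: rate constant for energy flow into mode j of
        chromophore a's bath driven by the population of a during a <-> b
        transfer (cm^-1/fs per unit population).
    K_mode_in : ndarray, shape (n, n, n_modes)
        Same, but driven by the population of partner b.
    site_energies : ndarray
        Site energies (cm^-1) the rates were evaluated at.
    """

    labels: tuple[str, ...]
    K: np.ndarray
    mode_freqs: np.ndarray
    K_mode_out: np.ndarray
    K_mode_in: np.ndarray
    site_energies: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    def rate_matrix_generator(self) -> np.ndarray:
        """Generator M with dP/dt = M P (columns sum to zero)."""
        M = self.K.copy()
        np.fill_diagonal(M, 0.0)
        M[np.diag_indices_from(M)] = -M.sum(axis=0)
        return M


def _pair_integrand(
    E_A: float,
    E_B: float,
    g_A: LineBroadening,
    g_B: LineBroadening,
    consts: PhysicalConstants,
) -> tuple[np.ndarray, np.ndarray]:
    """Common integrand exp[-i t X / hbar - g_A - g_B] and the time grid."""
    if g_A.t_grid.shape != g_B.t_grid.shape or not np.array_equal(g_A.t_grid, g_B.t_grid):
        raise ValueError("line-broadening functions must share a time grid")
    t = g_A.t_grid
    X = E_B - E_A + g_A.lambda_total + g_B.lambda_total
    f = np.exp(-1j * (X / consts.hbar) * t - g_A.g_values - g_B.g_values)
    return t, f


def _check_envelope(f: np.ndarray, tol: float = 1e-6) -> None:
    tail = np.abs(f[-1])
    peak = np.abs(f).max()
    if peak > 0 and tail > tol * peak:
        warnings.warn(
            f"rate integrand envelope at T_max is {tail / peak:.2e} of its peak "
            f"(> {tol:.0e}); extend the time grid",
            ConvergenceWarning,
            stacklevel=3,
        )


def rate_constant(
    E_A: float,
    E_B: float,
    V_AB: float,
    g_A: LineBroadening,
    g_B: LineBroadening,
    consts: PhysicalConstants,
) -> float:
    """Golden-rule rate constant K_BA for transfer A -> B, in fs^-1."""
    if V_AB == 0.0:
        return 0.0
    t, f = _pair_integrand(E_A, E_B, g_A, g_B, consts)
    _check_envelope(f)
    integral = np.trapezoid(f, t).real
    return float(2.0 * V_AB**2 / consts.hbar**2 * integral)


def dissipative_potential(
    omega_grid: np.ndarray,
    E_A: float,
    E_B: float,
    g_A: LineBroadening,
    g_B: LineBroadening,
    consts: PhysicalConstants,
    block_size: int = 1024,
) -> np.ndarray:
    """Dissipative potential I_BA(omega) on ``omega_grid`` (fs).

    Real by construction; positive where the A -> B transfer deposits energy
    into a mode at omega, negative where the mode supplies energy.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any(omega_grid <= 0):
        raise ValueError("omega grid must be strictly positive")
    t, f = _pair_integrand(E_A, E_B, g_A, g_B, consts)
    w = _trapezoid_weights(t)
    fr = w * f.real
    fi = w * f.imag
    cth = coth(0.5 * consts.beta * omega_grid)
    out = np.empty(omega_grid.size)
    for start in range(0, omega_grid.size, block_size):
        wb = omega_grid[start:start + block_size]
        ph = np.exp(1j * np.multiply.outer(wb, t / consts.hbar))
        # Re{(cos - i coth sin)(fr + i fi)} = cos*fr + coth*sin*fi
        out[start:start + block_size] = (
            ph.real @ fr + cth[start:start + block_size] * (ph.imag @ fi)
        )
    return out


def _trapezoid_weights(t: np.ndarray) -> np.ndarray:
    w = np.full(t.size, t[1] - t[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


def dissipative_spectral_densities(
    V_AB: float,
    J_A: SpectralDensity,
    I_BA: np.ndarray,
    I_AB: np.ndarray,
    consts: PhysicalConstants,
) -> tuple[np.ndarray, np.ndarray]:
    """Dissipative spectral densities of chromophore A for the pair (A, B).

    Returns ``(J^A_BA, J^A_AB)`` on ``J_A.omega``: frequency-resolved rates
    of energy deposition into A's bath driven by P_A (first) and by P_B
    (second), in cm^-1 fs^-1 per cm^-1 of frequency.  Either may be negative
    (energy absorption from the bath).
    """
    if I_BA.shape != J_A.omega.shape or I_AB.shape != J_A.omega.shape:
        raise ValueError("dissipative potentials must be tabulated on J_A's grid")
    pref = 2.0 * V_AB**2 / consts.hbar**2
    jw = J_A.over_omega()
    return pref * jw * I_BA, pref * jw * I_AB


def mode_rate_constants(
    V_AB: float,
    bath: DiscretizedBath,
    omega_grid: np.ndarray,
    I_values: np.ndarray,
    consts: PhysicalConstants,
) -> np.ndarray:
    """Mode-resolved dissipation rate constants K^Aj for one ordered pair.

    ``I_values`` is a dissipative potential tabulated on ``omega_grid``; it
    is interpolated linearly onto the bath's mode frequencies and scaled by
    each mode's reorganization energy.
    """
    freqs = bath.mode_freqs
    if freqs.min() < omega_grid.min() or freqs.max() > omega_grid.max():
        raise ValueError("mode frequencies fall outside the potential's grid")
    I_modes = np.interp(freqs, omega_grid, I_values)
    return 2.0 * V_AB**2 / consts.hbar**2 * bath.mode_lambdas * I_modes


class RateCalculator:
    """Shared-cache evaluator of rates and mode-resolved dissipation.

    Precomputes everything that does not depend on the site energies — the
    pairwise dephasing factors exp[-g_A - g_B], the trapezoid weights and
    the (mode frequency x time) trigonometric kernels — so that a disorder
    ensemble only re-evaluates the site-energy phase factor and two real
    matrix products per realization.

    All chromophores must share the line-broadening time grid and the
    discretized-mode frequency grid.
    """

    def __init__(
        self,
        model: ExcitonModel,
        lineshapes: dict[str, LineBroadening],
        baths: dict[str, DiscretizedBath],
        consts: PhysicalConstants,
        envelope_tol: float = 1e-6,
    ) -> None:
        self.model = model
        self.consts = consts
        self.envelope_tol = envelope_tol
        n = model.n_sites
        labels = model.labels

        g0 = lineshapes[labels[0]]
        self.t_grid = g0.t_grid
        for lab in labels:
            if not np.array_equal(lineshapes[lab].t_grid, self.t_grid):
                raise ValueError("all line-broadening functions must share one time grid")
        b0 = baths[labels[0]]
        self.mode_freqs = b0.mode_freqs
        for lab in labels:
            if not np.array_equal(baths[lab].mode_freqs, self.mode_freqs):
                raise ValueError("all discretized baths must share one mode grid")
        if np.any(self.mode_freqs <= 0):
            raise ValueError("mode frequencies must be strictly positive")

        self.lambdas = np.array([lineshapes[lab].lambda_total for lab in labels])
        self.mode_lambdas = np.stack([baths[lab].mode_lambdas for lab in labels])

        self._w = _trapezoid_weights(self.t_grid)
        self._pairs = [
            (a, b)
            for a in range(n)
            for b in range(a + 1, n)
            if model.couplings[a, b] != 0.0
        ]
        # dephasing factor per unordered coupled pair, weighted for quadrature
        self._G = {
            (a, b): np.exp(-lineshapes[labels[a]].g_values - lineshapes[labels[b]].g_values)
            for a, b in self._pairs
        }
        ph = np.exp(1j * np.multiply.outer(self.mode_freqs, self.t_grid / consts.hbar))
        cth = coth(0.5 * consts.beta * self.mode_freqs)
        self._cos_kernel = np.ascontiguousarray(ph.real)
        self._sin_kernel = cth[:, None] * ph.imag

    def compute(self, site_energies: np.ndarray | None = None) -> RateSet:
        """Evaluate the full RateSet at the given (possibly perturbed) energies."""
        consts = self.consts
        model = self.model
        E = model.site_energies if site_energies is None else np.asarray(site_energies, float)
        n = model.n_sites
        n_modes = self.mode_freqs.size
        K = np.zeros((n, n))
        K_mode_out = np.zeros((n, n, n_modes))
        K_mode_in = np.zeros((n, n, n_modes))
        if self._pairs:
            # stack the weighted integrands of all ordered pairs, then resolve
            # the mode kernels with two real matrix products
            F = np.empty((2 * len(self._pairs), self.t_grid.size), dtype=complex)
            prefs = np.empty(2 * len(self._pairs))
            for i, (a, b) in enumerate(self._pairs):
                lam_sum = self.lambdas[a] + self.lambdas[b]
                G = self._G[(a, b)]
                # ordered pair a -> b : phase with X = E_b - E_a + lam_sum
                X_ab = E[b] - E[a] + lam_sum
                X_ba = E[a] - E[b] + lam_sum
                phase = self.t_grid / consts.hbar
                F[2 * i] = self._w * np.exp(-1j * X_ab * phase) * G
                F[2 * i + 1] = self._w * np.exp(-1j * X_ba * phase) * G
                prefs[2 * i] = prefs[2 * i + 1] = (
                    2.0 * model.couplings[a, b] ** 2 / consts.hbar**2
                )
                tail = np.abs(G[-1])
                if tail > self.envelope_tol:
                    warnings.warn(
                        f"pair ({model.labels[a]}, {model.labels[b]}): integrand envelope "
                        f"{tail:.2e} at T_max exceeds {self.envelope_tol:.0e}",
                        ConvergenceWarning,
                        stacklevel=2,
                    )
            integrals = F.sum(axis=1).real           # trapezoid, weights folded in
            I_modes = self._cos_kernel @ F.real.T + self._sin_kernel @ F.imag.T
            for i, (a, b) in enumerate(self._pairs):
                pref = prefs[2 * i]
                K[b, a] = pref * integrals[2 * i]      # rate a -> b
                K[a, b] = pref * integrals[2 * i + 1]  # rate b -> a
                I_ba = I_modes[:, 2 * i]       # I for transfer a -> b
                I_ab = I_modes[:, 2 * i + 1]   # I for transfer b -> a
                # dissipation into a's modes: driven by P_a (a->b) and P_b (b->a)
                K_mode_out[a, b] = pref * self.mode_lambdas[a] * I_ba
                K_mode_in[a, b] = pref * self.mode_lambdas[a] * I_ab
                # dissipation into b's modes: driven by P_b (b->a) and P_a (a->b)
                K_mode_out[b, a] = pref * self.mode_lambdas[b] * I_ab
                K_mode_in[b, a] = pref * self.mode_lambdas[b] * I_ba
        return RateSet(
            labels=model.labels,
            K=K,
            mode_freqs=self.mode_freqs,
            K_mode_out=K_mode_out,
            K_mode_in=K_mode_in,
            site_energies=E.copy(),
        )
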