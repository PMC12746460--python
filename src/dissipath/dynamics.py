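"""Population propagation and accumulation of frequency-resolved dissipation.

The populations obey the Pauli master equation
``dP_A/dt = sum_B [-K_BA P_A + K_AB P_B]`` integrated with fixed-step RK4.
The dissipation function ``D_A(omega, t)`` is linear in the instantaneous
populations, so its time integral — the accumulated dissipation
``E_A(omega, t)`` — is obtained exactly (at trapezoid accuracy) from the
running time integrals ``Q_A(t) = int_0^t P_A dt'`` accumulated during
propagation.  ``E_A`` is reported as a spectral density over the effective
mode grid (cm^-1 of energy per cm^-1 of frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import RateSet

__all__ = [
    "PopulationTrajectory",
    "DissipationField",
    "BandSummary",
    "propagate_populations",
    "dissipation_function",
    "accumulate_dissipation",
    "band_summary",
]


@dataclass(frozen=True)
class PopulationTrajectory:
    """Stored population dynamics on a strided time grid.

    ``P[:, k]`` are the site populations at ``t_grid[k]``; ``Q[:, k]`` their
    running time integrals (fs), accumulated at the full integration step
    regardless of the storage stride.
    """

    t_grid: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class DissipationField:
    """Accumulated frequency-resolved dissipation at snapshot times.

    ``E_acc[a, s, j]`` is the energy accumulated in chromophore a's bath
    modes near ``omega_grid[j]`` by time ``snapshot_times[s]``, as a density
    per unit frequency (cm^-1 / cm^-1).  ``E_tot`` is the sum over
    chromophores.  Negative values indicate net energy absorption from the
    bath.
    """

    omega_grid: np.ndarray
    snapshot_times: np.ndarray
    E_acc: np.ndarray
    E_tot: np.ndarray
    labels: tuple[str, ...]

    @property
    def delta(self) -> float:
        return float(self.omega_grid[1] - self.omega_grid[0])

    def frequency_integral(self) -> np.ndarray:
        """Total accumulated energy per chromophore and snapshot (cm^-1)."""
        return self.E_acc.sum(axis=2) * self.delta

    def total_frequency_integral(self) -> np.ndarray:
        """Total accumulated energy of the whole complex per snapshot."""
        return self.E_tot.sum(axis=1) * self.delta


@dataclass(frozen=True)
class BandSummary:
    """Frequency-band integrals of the accumulated dissipation."""

    band_edges: tuple[tuple[float, float], ...]
    per_site: np.ndarray  # (n_sites, n_bands)
    total: np.ndarray     # (n_bands,)
    labels: tuple[str, ...]


def propagate_populations(
    rates: RateSet | np.ndarray,
    P0: np.ndarray,
    dt: float,
    t_end: float,
    store_stride: int = 1,
) -> PopulationTrajectory:
    """Integrate the Pauli master equation with fixed-step RK4.

    Parameters
    ----------
    rates : RateSet or ndarray
        Rate set, or directly a generator matrix M with dP/dt = M P.
    P0 : ndarray
        Initial populations; non-negative, summing to 1.
    dt : float
        RK4 step (fs).
    t_end : float
        Final time (fs); the grid is ``0, dt, ..., n*dt`` with n = round(t_end/dt).
    store_stride : int
        Keep every ``store_stride``-th step (the initial point is always kept).
    """
    M = rates.rate_matrix_generator() if isinstance(rates, RateSet) else np.asarray(rates, float)
    P0 = np.asarray(P0, dtype=float)
    if np.any(P0 < 0):
        raise ValueError("initial populations must be non-negative")
    if abs(P0.sum() - 1.0) > 1e-10:
        raise ValueError("initial populations must sum to 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(t_end / dt))
    if n_steps < 1:
        raise ValueError("t_end must be at least one step")

    n_stored = n_steps // store_stride + 2  # room for the final step if off-stride
    t_stored = np.empty(n_stored)
    P_stored = np.empty((P0.size, n_stored))
    Q_stored = np.empty((P0.size, n_stored))
    P = P0.copy()
    Q = np.zeros_like(P0)
    t_stored[0] = 0.0
    P_stored[:, 0] = P
    Q_stored[:, 0] = Q
    idx = 1
    for step in range(1, n_steps + 1):
        k1 = M @ P
        k2 = M @ (P + 0.5 * dt * k1)
        k3 = M @ (P + 0.5 * dt * k2)
        k4 = M @ (P + dt * k3)
        P_new = P + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        Q += 0.5 * dt * (P + P_new)
        P = P_new
        if step % store_stride == 0 or step == n_steps:
            t_stored[idx] = step * dt
            P_stored[:, idx] = P
            Q_stored[:, idx] = Q
            idx += 1
    return PopulationTrajectory(t_stored[:idx], P_stored[:, :idx], Q_stored[:, :idx])


def dissipation_function(rates: RateSet, P: np.ndarray) -> np.ndarray:
    """Instantaneous dissipation density D_A(omega) for populations ``P``.

    Returns an (n_sites, n_modes) array in cm^-1/fs per cm^-1 of frequency;
    negative entries mean the bath is supplying energy at that frequency.
    """
    P = np.asarray(P, dtype=float)
    delta = float(rates.mode_freqs[1] - rates.mode_freqs[0])
    own = rates.K_mode_out.sum(axis=1) * P[:, None]          # driven by P_A
    partner = np.einsum("abj,b->aj", rates.K_mode_in, P)     # driven by P_B
    return (own + partner) / delta


def accumulate_dissipation(
    rates: RateSet,
    traj: PopulationTrajectory,
    snapshot_times: np.ndarray,
) -> DissipationField:
    """Accumulated dissipation E_A(omega, t) at the requested snapshot times.

    Because D_A is linear in the populations, E_A follows from the running
    population integrals Q_A; snapshots between stored steps are linearly
    interpolated in Q.
    """
    snapshot_times = np.atleast_1d(np.asarray(snapshot_times, dtype=float))
    if snapshot_times.max() > traj.t_grid[-1] + 1e-9:
        raise ValueError("requested snapshot lies beyond the propagated time range")
    n_sites = traj.n_sites
    delta = float(rates.mode_freqs[1] - rates.mode_freqs[0])
    Q_snap = np.stack(
        [np.interp(snapshot_times, traj.t_grid, traj.Q[a]) for a in range(n_sites)]
    )  # (n_sites, n_snap)
    out_sum = rates.K_mode_out.sum(axis=1)  # (n_sites, n_modes)
    E = (
        Q_snap[:, :, None] * out_sum[:, None, :]
        + np.einsum("abj,bs->asj", rates.K_mode_in, Q_snap)
    ) / delta
    E_tot = E.sum(axis=0)
    return DissipationField(
        omega_grid=rates.mode_freqs,
        snapshot_times=snapshot_times,
        E_acc=E,
        E_tot=E_tot,
        labels=rates.labels,
    )


def band_summary(
    field: DissipationField,
    band_edges: list[tuple[float, float]],
    snapshot_index: int = -1,
) -> BandSummary:
    """Integrate the accumulated dissipation over frequency bands.

    Bands are half-open intervals [lo, hi) that must lie within the mode
    grid range and must not overlap.
    """
    grid = field.omega_grid
    lo_grid = grid[0] - 0.5 * field.delta
    hi_grid = grid[-1] + 0.5 * field.delta
    edges = sorted(band_edges)
    for lo, hi in edges:
        if hi <= lo:
            raise ValueError(f"band ({lo}, {hi}) is empty")
        if lo < lo_grid - 1e-9 or hi > hi_grid + 1e-9:
            raise ValueError(f"band ({lo}, {hi}) extends beyond the mode grid")
    for (_, hi_prev), (lo_next, _) in zip(edges[:-1], edges[1:]):
        if lo_next < hi_prev:
            raise ValueError("bands must not overlap")

    E = field.E_acc[:, snapshot_index, :]  # (n_sites, n_modes)
    per_site = np.empty((E.shape[0], len(band_edges)))
    for k, (lo, hi) in enumerate(band_edges):
        mask = (grid >= lo) & (grid < hi)
        per_site[:, k] = E[:, mask].sum(axis=1) * field.delta
    return BandSummary(
        band_edges=tuple((float(lo), float(hi)) for lo, hi in band_edges),
        per_site=per_site,
        total=per_site.sum(axis=0),
        labels=field.labels,
    )
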