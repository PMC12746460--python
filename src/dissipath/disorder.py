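"""Quasi-static disorder ensembles over the slow bath.

Low-frequency bath modes below the splitting cutoff act as frozen Gaussian
noise on the site energies (width ``sigma_slow`` per chromophore, sampled
independently per site and realization).  Every realization reuses the same
fast-bath quantities — line-broadening functions, reorganization energies
and mode decompositions are precomputed once in a
:class:`~dissipath.rates.RateCalculator` — and only the site-energy phase
factors of the rate integrals are re-evaluated.  Observables are arithmetic
means over realizations.

Draws are keyed on ``(seed, realization_index)`` through a SeedSequence, so
any execution order or worker count reproduces the same ensemble
byte-for-byte: realizations are processed in fixed-size blocks whose partial
sums are combined in block order.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .dynamics import DissipationField, accumulate_dissipation, propagate_populations
from .rates import RateCalculator

__all__ = ["DisorderSpec", "EnsembleResult", "sample_site_energies", "run_ensemble"]

_BLOCK = 25  # realizations per reduction block; fixed so results never depend on worker count


class ConvergenceError(RuntimeError):
    """A rate integrand had not decayed at the end of the time grid."""


@dataclass(frozen=True)
class DisorderSpec:
    """Static-disorder ensemble parameters.

    ``sigma_per_site`` are the Gaussian widths (cm^-1) of the quasi-static
    site-energy noise, one per chromophore.
    """

    sigma_per_site: np.ndarray
    n_realizations: int
    seed: int
    store_stride: int = 10

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigma_per_site, dtype=float)
        object.__setattr__(self, "sigma_per_site", sig)
        if np.any(sig < 0):
            raise ValueError("sigma values must be non-negative")
        if self.n_realizations < 1:
            raise ValueError("need at least one realization")


@dataclass(frozen=True)
class EnsembleResult:
    """Disorder-averaged observables.

    ``scalar_site_energy`` / ``scalar_site_stderr`` are the ensemble mean
    and standard error of the frequency-integrated final accumulated
    dissipation per chromophore (cm^-1), the natural scalar summary of a
    run.  ``electronic_energy_release`` is the ensemble mean of
    ``sum_A E'_A [P_A(0) - P_A(t_end)]`` evaluated with each realization's
    perturbed site energies; energy conservation demands it equal the total
    accumulated dissipation.
    """

    t_grid: np.ndarray
    mean_populations: np.ndarray
    mean_field: DissipationField
    n_effective: int
    scalar_site_energy: np.ndarray
    scalar_site_stderr: np.ndarray
    electronic_energy_release: float
    labels: tuple[str, ...]


def sample_site_energies(
    site_energies: np.ndarray,
    spec: DisorderSpec,
    realization_index: int,
) -> np.ndarray:
    """Site energies perturbed by the quasi-static slow-bath noise.

    The draw is fully determined by ``(spec.seed, realization_index)`` and
    the site ordering; ``sigma = 0`` returns the input unchanged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(realization_index)]))
    delta = spec.sigma_per_site * rng.standard_normal(spec.sigma_per_site.size)
    return np.asarray(site_energies, dtype=float) + delta


def _run_block(
    calc: RateCalculator,
    spec: DisorderSpec,
    indices: range,
    P0: np.ndarray,
    dt: float,
    t_end: float,
    snapshot_times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, int, np.ndarray]:
    sum_P = None
    sum_E = None
    sum_s = None
    sum_s2 = None
    sum_rel = 0.0
    t_grid = None
    for r in indices:
        energies = sample_site_energies(calc.model.site_energies, spec, r)
        rates = calc.compute(energies)
        traj = propagate_populations(rates, P0, dt, t_end, store_stride=spec.store_stride)
        field = accumulate_dissipation(rates, traj, snapshot_times)
        s = field.frequency_integral()[:, -1]
        sum_rel += float(energies @ (traj.P[:, 0] - traj.P[:, -1]))
        if sum_P is None:
            sum_P = traj.P.copy()
            sum_E = field.E_acc.copy()
            sum_s = s.copy()
            sum_s2 = s * s
            t_grid = traj.t_grid
        else:
            sum_P += traj.P
            sum_E += field.E_acc
            sum_s += s
            sum_s2 += s * s
    return sum_P, sum_E, sum_s, sum_s2, sum_rel, len(indices), t_grid


def run_ensemble(
    calc: RateCalculator,
    spec: DisorderSpec,
    P0: np.ndarray,
    dt: float,
    t_end: float,
    snapshot_times: np.ndarray,
    n_workers: int = 1,
) -> EnsembleResult:
    """Average populations and dissipation fields over the disorder ensemble.

    Raises :class:`ConvergenceError` up front if any pair's dephasing
    envelope has not decayed at the end of the rate time grid — the envelope
    is shared by every realization (site-energy noise only shifts phases),
    so a single check covers the whole ensemble.
    """
    snapshot_times = np.atleast_1d(np.asarray(snapshot_times, dtype=float))
    for (a, b), G in calc._G.items():
        tail = float(np.abs(G[-1]))
        if tail > calc.envelope_tol:
            raise ConvergenceError(
                f"pair ({calc.model.labels[a]}, {calc.model.labels[b]}): dephasing envelope "
                f"{tail:.2e} at T_max exceeds {calc.envelope_tol:.0e} for all realizations"
            )

    blocks = [
        range(start, min(start + _BLOCK, spec.n_realizations))
        for start in range(0, spec.n_realizations, _BLOCK)
    ]
    args = (calc, spec)
    kwargs = dict(P0=P0, dt=dt, t_end=t_end, snapshot_times=snapshot_times)
    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(lambda blk: _run_block(*args, blk, **kwargs), blocks))
    else:
        results = [_run_block(*args, blk, **kwargs) for blk in blocks]

    # in-order reduction: independent of scheduling and worker count
    sum_P = results[0][0].copy()
    sum_E = results[0][1].copy()
    sum_s = results[0][2].copy()
    sum_s2 = results[0][3].copy()
    sum_rel = results[0][4]
    n = results[0][5]
    t_grid = results[0][6]
    for bP, bE, bs, bs2, brel, bn, _ in results[1:]:
        sum_P += bP
        sum_E += bE
        sum_s += bs
        sum_s2 += bs2
        sum_rel += brel
        n += bn

    mean_P = sum_P / n
    mean_E = sum_E / n
    mean_s = sum_s / n
    if n > 1:
        var = np.maximum(sum_s2 / n - mean_s**2, 0.0) * n / (n - 1)
        stderr = np.sqrt(var / n)
    else:
        stderr = np.zeros_like(mean_s)

    mean_field = DissipationField(
        omega_grid=calc.mode_freqs,
        snapshot_times=snapshot_times,
        E_acc=mean_E,
        E_tot=mean_E.sum(axis=0),
        labels=calc.model.labels,
    )
    return EnsembleResult(
        t_grid=t_grid,
        mean_populations=mean_P,
        mean_field=mean_field,
        n_effective=n,
        scalar_site_energy=mean_s,
        scalar_site_stderr=stderr,
        electronic_energy_release=sum_rel / n,
        labels=calc.model.labels,
    )
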