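"""End-to-end simulation pipeline: bath preparation, lineshapes, rates,
disorder ensemble, dissipation accumulation.

``Simulation`` wires the library modules together for a RunConfig:

1. obtain per-chromophore spectral densities (synthetic preset or files);
2. split each into slow/fast parts at the cutoff, derive the quasi-static
   disorder width from the slow part, discretize the fast part into the
   shared effective-mode grid;
3. compute line-broadening functions once per chromophore;
4. run the static-disorder ensemble of golden-rule dynamics and accumulate
   chromophore- and frequency-resolved dissipation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from . import io as dio
from .bath import (
    BathSplit,
    DiscretizedBath,
    SpectralDensity,
    discretize_bath,
    sigma_slow,
    split_spectral_density,
)
from .config import ConfigError, RunConfig
from .constants import PhysicalConstants
from .disorder import DisorderSpec, EnsembleResult, run_ensemble
from .fixtures import fmo_like_model, load_hamiltonian_tsv, make_synthetic_density
from .lineshape import LineBroadening, line_broadening
from .rates import ExcitonModel, RateCalculator

log = logging.getLogger("dissipath")

__all__ = ["Simulation", "SimulationResult", "SLOW_FRACTION_WARN"]

#: Slow-bath share of the reorganization energy above which the cutoff
#: choice is flagged (selection criterion for omega_star).
SLOW_FRACTION_WARN = 0.05


@dataclass(frozen=True)
class SimulationResult:
    """Everything a run produces, ready for serialization."""

    config: RunConfig
    labels: tuple[str, ...]
    validation: list[dict]
    ensemble: EnsembleResult
    site_energies: np.ndarray
    warnings: tuple[str, ...]


class Simulation:
    """Orchestrates one configured dissipation-pathways run."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.consts = PhysicalConstants(temperature=config.temperature_K)
        self._load_inputs()
        self._prepare_baths()

    # ------------------------------------------------------------------ setup
    def _load_inputs(self) -> None:
        cfg = self.config
        if cfg.preset is not None:
            preset = fmo_like_model(cfg.preset)
            self.model = preset.model
            self.densities = {
                lab: make_synthetic_density(spec, label=lab)
                for lab, spec in preset.bath_specs.items()
            }
            self.initial_site = cfg.initial_site or preset.initial_site
        else:
            self.model = load_hamiltonian_tsv(cfg.hamiltonian_path)
            self.densities = {
                lab: dio.load_spectral_density(path, label=lab)
                for lab, path in cfg.density_files.items()
            }
            missing = set(self.model.labels) - set(self.densities)
            if missing:
                raise ConfigError(f"no spectral density for sites: {sorted(missing)}")
            if cfg.initial_site is None:
                raise ConfigError("initial_site is required for file-based models")
            self.initial_site = cfg.initial_site
        if self.initial_site not in self.model.labels:
            raise ConfigError(f"initial_site {self.initial_site!r} not in model")

    def _prepare_baths(self) -> None:
        cfg = self.config
        self.splits: dict[str, BathSplit] = {}
        self.sigmas: dict[str, float] = {}
        self.discretized: dict[str, DiscretizedBath] = {}
        self.warnings: list[str] = []
        for lab in self.model.labels:
            split = split_spectral_density(self.densities[lab], cfg.omega_star_cm1)
            self.splits[lab] = split
            self.sigmas[lab] = (
                cfg.sigma_override_cm1
                if cfg.sigma_override_cm1 is not None
                else sigma_slow(split.slow, self.consts)
            )
            self.discretized[lab] = discretize_bath(split.fast, cfg.n_modes)
            if split.slow_fraction > SLOW_FRACTION_WARN:
                msg = (
                    f"{lab}: slow-bath fraction {100 * split.slow_fraction:.1f}% exceeds "
                    f"{100 * SLOW_FRACTION_WARN:.0f}% — consider lowering omega_star"
                )
                self.warnings.append(msg)
                log.warning(msg)

    def validation_table(self) -> list[dict]:
        """Per-chromophore bath summary: Lambda, slow split, sigma_slow."""
        from .bath import reorganization_energy

        rows = []
        for lab in self.model.labels:
            split = self.splits[lab]
            lam_tot = reorganization_energy(self.densities[lab])
            rows.append(
                {
                    "site": lab,
                    "lambda_total_cm1": lam_tot,
                    "lambda_slow_cm1": lam_tot * split.slow_fraction,
                    "slow_fraction": split.slow_fraction,
                    "sigma_slow_cm1": self.sigmas[lab],
                }
            )
        return rows

    # -------------------------------------------------------------------- run
    def _lineshapes(self) -> dict[str, LineBroadening]:
        cfg = self.config
        n_t = int(round(cfg.t_max_rate_fs / cfg.dt_fs)) + 1
        t_grid = np.arange(n_t) * cfg.dt_fs
        out: dict[str, LineBroadening] = {}
        for lab in self.model.labels:
            t0 = time.perf_counter()
            cached = None
            if cfg.lineshape_cache:
                cached = dio.load_cached_lineshape(
                    cfg.lineshape_cache, self.splits[lab].fast, self.consts, t_grid
                )
            if cached is not None:
                out[lab] = cached
                continue
            out[lab] = line_broadening(self.splits[lab].fast, self.consts, t_grid)
            if cfg.lineshape_cache:
                dio.store_cached_lineshape(
                    cfg.lineshape_cache, self.splits[lab].fast, self.consts, out[lab]
                )
            log.info("lineshape %s: %.2f s", lab, time.perf_counter() - t0)
        return out

    def run(self) -> SimulationResult:
        cfg = self.config
        t0 = time.perf_counter()
        lineshapes = self._lineshapes()
        calc = RateCalculator(self.model, lineshapes, self.discretized, self.consts)
        log.info("shared fast-bath quantities ready: %.2f s", time.perf_counter() - t0)

        P0 = np.zeros(self.model.n_sites)
        P0[self.model.index(self.initial_site)] = 1.0
        spec = DisorderSpec(
            sigma_per_site=np.array([self.sigmas[lab] for lab in self.model.labels]),
            n_realizations=cfg.n_realizations,
            seed=cfg.seed,
            store_stride=cfg.store_stride,
        )
        t0 = time.perf_counter()
        ensemble = run_ensemble(
            calc,
            spec,
            P0,
            dt=cfg.dt_fs,
            t_end=cfg.t_end_dynamics_fs,
            snapshot_times=np.array(cfg.snapshot_times_fs),
            n_workers=cfg.n_workers,
        )
        log.info(
            "ensemble of %d realizations: %.2f s", cfg.n_realizations, time.perf_counter() - t0
        )
        return SimulationResult(
            config=cfg,
            labels=self.model.labels,
            validation=self.validation_table(),
            ensemble=ensemble,
            site_energies=self.model.site_energies,
            warnings=tuple(self.warnings),
        )
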