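"""Shared fixtures: analytic Drude baths, a two-site dimer pipeline, and the
disorder-averaged 7-site run that several dissipation tests share."""

from __future__ import annotations

import numpy as np
import pytest

from dissipath import (
    DisorderSpec,
    ExcitonModel,
    PhysicalConstants,
    RateCalculator,
    SpectralDensity,
    discretize_bath,
    line_broadening,
    run_ensemble,
)
from dissipath.fixtures import fmo_like_model, make_synthetic_density
from dissipath.bath import split_spectral_density, sigma_slow


def drude_density(lam=35.0, gamma=53.0, omega_max=4000.0, n=20000, label=""):
    """Dense tabulation of a Drude spectral density (Lambda = lam exactly
    for the untruncated integral)."""
    omega = np.linspace(omega_max / n, omega_max, n)
    J = (2.0 / np.pi) * lam * gamma * omega / (omega**2 + gamma**2)
    return SpectralDensity(omega, J, label)


@pytest.fixture(scope="session")
def t_grid_rate():
    """Rate-integral time grid: 0.5 fs steps out to 3 ps (ample for Drude
    baths whose dephasing kills the integrand within ~200 fs)."""
    return np.arange(0.0, 3000.1, 0.5)


@pytest.fixture(scope="session")
def dimer_300K(t_grid_rate):
    """Two-site Drude dimer at 300 K: gap 100 cm^-1, V = 20 cm^-1,
    lam = 35, gamma = 53 per site.  Returns a dict with everything the
    rate/dynamics tests need."""
    consts = PhysicalConstants(300.0)
    JA = drude_density(label="A")
    JB = drude_density(label="B")
    gA = line_broadening(JA, consts, t_grid_rate)
    gB = line_broadening(JB, consts, t_grid_rate)
    model = ExcitonModel([100.0, 0.0], [[0.0, 20.0], [20.0, 0.0]], ("A", "B"))
    baths = {"A": discretize_bath(JA, 1000), "B": discretize_bath(JB, 1000)}
    calc = RateCalculator(model, {"A": gA, "B": gB}, baths, consts)
    return {
        "consts": consts,
        "J": {"A": JA, "B": JB},
        "g": {"A": gA, "B": gB},
        "model": model,
        "baths": baths,
        "calc": calc,
        "rates": calc.compute(),
    }


@pytest.fixture(scope="session")
def fmo_ensemble_200():
    """Disorder-averaged 7-site run: 200 realizations, scaled-down grids
    (2 ps rate horizon, 500 modes).  Shared by the dissipation-pathway
    tests; seeds are fixed."""
    preset = fmo_like_model("fmo7")
    consts = PhysicalConstants(300.0)
    t_grid = np.arange(0.0, 2000.1, 0.5)
    densities = {lab: make_synthetic_density(s, lab) for lab, s in preset.bath_specs.items()}
    sigmas, lineshapes, baths = {}, {}, {}
    for lab, J in densities.items():
        split = split_spectral_density(J, 20.0)
        sigmas[lab] = sigma_slow(split.slow, consts)
        lineshapes[lab] = line_broadening(split.fast, consts, t_grid)
        baths[lab] = discretize_bath(split.fast, 500)
    calc = RateCalculator(preset.model, lineshapes, baths, consts)
    P0 = np.zeros(7)
    P0[preset.model.index(preset.initial_site)] = 1.0
    spec = DisorderSpec(
        sigma_per_site=np.array([sigmas[lab] for lab in preset.model.labels]),
        n_realizations=200,
        seed=2024,
        store_stride=10,
    )
    result = run_ensemble(
        calc, spec, P0, dt=0.5, t_end=5000.0,
        snapshot_times=np.array([40.0, 200.0, 600.0, 5000.0]),
    )
    return {
        "preset": preset,
        "consts": consts,
        "densities": densities,
        "calc": calc,
        "spec": spec,
        "result": result,
    }
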