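"""Population propagation, dissipation accumulation and band summaries."""

import numpy as np
import pytest

from dissipath import (
    ExcitonModel,
    PhysicalConstants,
    RateCalculator,
    accumulate_dissipation,
    band_summary,
    discretize_bath,
    dissipation_function,
    line_broadening,
    propagate_populations,
)
from dissipath.constants import KB_CM_K

from conftest import drude_density


class TestPropagation:
    def test_zero_rates_keep_initial_state(self):
        M = np.zeros((3, 3))
        traj = propagate_populations(M, [0.2, 0.3, 0.5], dt=0.5, t_end=100.0)
        np.testing.assert_allclose(traj.P, np.array([[0.2], [0.3], [0.5]]) * np.ones(traj.t_grid.size))

    def test_two_site_closed_form(self):
        # P1(t) = P_eq + (1 - P_eq) exp[-(k12 + k21) t]
        k_down, k_up = 2e-3, 5e-4
        M = np.array([[-k_down, k_up], [k_down, -k_up]])
        traj = propagate_populations(M, [1.0, 0.0], dt=0.5, t_end=5000.0, store_stride=20)
        p_eq = k_up / (k_down + k_up)
        expected = p_eq + (1 - p_eq) * np.exp(-(k_down + k_up) * traj.t_grid)
        np.testing.assert_allclose(traj.P[0], expected, atol=1e-6)

    def test_conservation_and_positivity(self, dimer_300K):
        traj = propagate_populations(dimer_300K["rates"], [1.0, 0.0], 0.5, 3000.0, 10)
        np.testing.assert_allclose(traj.P.sum(axis=0), 1.0, atol=1e-10)
        assert traj.P.min() > -1e-12

    def test_long_time_boltzmann_ratio(self, dimer_300K):
        # downhill dimer with gap 100 cm^-1 at 300 K
        traj = propagate_populations(dimer_300K["rates"], [1.0, 0.0], 0.5, 30000.0, 100)
        ratio = traj.P[1, -1] / traj.P[0, -1]
        assert ratio == pytest.approx(np.exp(100.0 / (KB_CM_K * 300.0)), rel=0.01)

    def test_rk4_step_halving(self, dimer_300K):
        t1 = propagate_populations(dimer_300K["rates"], [1.0, 0.0], 0.5, 1000.0, 2)
        t2 = propagate_populations(dimer_300K["rates"], [1.0, 0.0], 0.25, 1000.0, 4)
        np.testing.assert_allclose(t1.P, t2.P, rtol=1e-4, atol=1e-12)
        np.testing.assert_allclose(t1.Q, t2.Q, rtol=1e-4, atol=1e-9)

    def test_input_validation(self):
        M = np.zeros((2, 2))
        with pytest.raises(ValueError):
            propagate_populations(M, [0.6, 0.6], 0.5, 10.0)
        with pytest.raises(ValueError):
            propagate_populations(M, [-0.1, 1.1], 0.5, 10.0)
        with pytest.raises(ValueError):
            propagate_populations(M, [1.0, 0.0], -0.5, 10.0)


class TestDissipationFunction:
    def test_additive_over_partners(self, t_grid_rate):
        # three sites where C couples to A and B: D_C equals the sum of the
        # two single-partner evaluations
        consts = PhysicalConstants(300.0)
        J = drude_density(lam=35.0, gamma=53.0)
        g = line_broadening(J, consts, t_grid_rate)
        bath = discretize_bath(J, 400)
        labels = ("A", "B", "C")
        V_full = np.array([[0.0, 0.0, 30.0], [0.0, 0.0, 25.0], [30.0, 25.0, 0.0]])
        E = np.array([150.0, 80.0, 0.0])
        P = np.array([0.3, 0.3, 0.4])

        def build(V):
            model = ExcitonModel(E, V, labels)
            calc = RateCalculator(model, dict.fromkeys(labels, g), dict.fromkeys(labels, bath), consts)
            return calc.compute()

        D_full = dissipation_function(build(V_full), P)
        V_a = V_full.copy(); V_a[1, 2] = V_a[2, 1] = 0.0
        V_b = V_full.copy(); V_b[0, 2] = V_b[2, 0] = 0.0
        D_a = dissipation_function(build(V_a), P)
        D_b = dissipation_function(build(V_b), P)
        np.testing.assert_allclose(D_full[2], D_a[2] + D_b[2], rtol=1e-10, atol=1e-20)
        assert np.all(D_a[1] == 0.0)  # B is uncoupled in V_a, so its bath sees nothing
        # a fully uncoupled site dissipates nothing even with all population elsewhere
        V_bc = V_full.copy(); V_bc[0, 2] = V_bc[2, 0] = 0.0
        D_bc = dissipation_function(build(V_bc), np.array([0.0, 0.0, 1.0]))
        assert np.all(D_bc[0] == 0.0)

    def test_symmetric_dimer_equilibrium_nets_zero(self, t_grid_rate):
        consts = PhysicalConstants(300.0)
        J = drude_density(lam=35.0, gamma=53.0)
        g = line_broadening(J, consts, t_grid_rate)
        bath = discretize_bath(J, 800)
        model = ExcitonModel([50.0, 50.0], [[0.0, 20.0], [20.0, 0.0]], ("A", "B"))
        rates = RateCalculator(model, {"A": g, "B": g}, {"A": bath, "B": bath}, consts).compute()
        D = dissipation_function(rates, np.array([0.5, 0.5]))
        delta = rates.mode_freqs[1] - rates.mode_freqs[0]
        net = D.sum() * delta
        # scale: a typical dissipation rate for this coupling/bath strength
        scale = rates.K[1, 0] * g.lambda_total
        assert abs(net) < 1e-6 * scale


class TestAccumulatedDissipation:
    def test_zero_at_time_zero(self, dimer_300K):
        traj = propagate_populations(dimer_300K["rates"], [1.0, 0.0], 0.5, 100.0, 4)
        field = accumulate_dissipation(dimer_300K["rates"], traj, [0.0, 50.0])
        assert np.all(field.E_acc[:, 0, :] == 0.0)
        np.testing.assert_allclose(field.E_tot, field.E_acc.sum(axis=0), rtol=0, atol=0)

    def test_energy_conservation_two_site(self, dimer_300K):
        rates = dimer_300K["rates"]
        traj = propagate_populations(rates, [1.0, 0.0], 0.5, 20000.0, 50)
        field = accumulate_dissipation(rates, traj, [20000.0])
        dissipated = field.total_frequency_integral()[-1]
        released = (np.array([1.0, 0.0]) - traj.P[:, -1]) @ np.array([100.0, 0.0])
        assert dissipated == pytest.approx(released, rel=0.02)

    def test_energy_conservation_three_site(self, t_grid_rate):
        consts = PhysicalConstants(300.0)
        J = drude_density(lam=35.0, gamma=53.0)
        g = line_broadening(J, consts, t_grid_rate)
        bath = discretize_bath(J, 600)
        labels = ("A", "B", "C")
        E = np.array([200.0, 120.0, 0.0])
        V = np.array([[0.0, 40.0, 10.0], [40.0, 0.0, 35.0], [10.0, 35.0, 0.0]])
        model = ExcitonModel(E, V, labels)
        rates = RateCalculator(model, dict.fromkeys(labels, g), dict.fromkeys(labels, bath), consts).compute()
        P0 = np.array([1.0, 0.0, 0.0])
        traj = propagate_populations(rates, P0, 0.5, 20000.0, 50)
        field = accumulate_dissipation(rates, traj, [600.0, 20000.0])
        for s, t_snap in enumerate(field.snapshot_times):
            P_t = np.array([np.interp(t_snap, traj.t_grid, traj.P[a]) for a in range(3)])
            released = (P0 - P_t) @ E
            dissipated = field.E_tot[s].sum() * field.delta
            assert dissipated == pytest.approx(released, rel=0.02)

    def test_symmetric_dimer_long_time_null(self, t_grid_rate):
        consts = PhysicalConstants(300.0)
        J = drude_density(lam=35.0, gamma=53.0)
        g = line_broadening(J, consts, t_grid_rate)
        bath = discretize_bath(J, 600)
        model = ExcitonModel([50.0, 50.0], [[0.0, 20.0], [20.0, 0.0]], ("A", "B"))
        rates = RateCalculator(model, {"A": g, "B": g}, {"A": bath, "B": bath}, consts).compute()
        traj = propagate_populations(rates, [1.0, 0.0], 0.5, 10000.0, 50)
        field = accumulate_dissipation(rates, traj, [10000.0])
        # no net electronic energy change -> no net dissipation
        assert abs(field.total_frequency_integral()[-1]) < 1e-4

    def test_rejects_snapshot_beyond_range(self, dimer_300K):
        traj = propagate_populations(dimer_300K["rates"], [1.0, 0.0], 0.5, 100.0, 4)
        with pytest.raises(ValueError):
            accumulate_dissipation(dimer_300K["rates"], traj, [200.0])


@pytest.fixture(scope="module")
def field(dimer_300K):
    traj = propagate_populations(dimer_300K["rates"], [1.0, 0.0], 0.5, 5000.0, 10)
    return accumulate_dissipation(dimer_300K["rates"], traj, [5000.0])


class TestBandSummary:

    def test_full_band_equals_total(self, field):
        lo = field.omega_grid[0] - 0.5 * field.delta
        hi = field.omega_grid[-1] + 0.5 * field.delta
        summ = band_summary(field, [(lo, hi)])
        np.testing.assert_allclose(summ.per_site[:, 0], field.frequency_integral()[:, -1], rtol=1e-12)

    def test_complementary_bands_sum_to_total(self, field):
        lo = field.omega_grid[0] - 0.5 * field.delta
        hi = field.omega_grid[-1] + 0.5 * field.delta
        summ = band_summary(field, [(lo, 800.0), (800.0, hi)])
        np.testing.assert_allclose(
            summ.total.sum(), field.total_frequency_integral()[-1], rtol=1e-12
        )

    def test_rejects_bad_bands(self, field):
        with pytest.raises(ValueError):
            band_summary(field, [(100.0, 50.0)])
        with pytest.raises(ValueError):
            band_summary(field, [(0.0, 800.0), (700.0, 1000.0)])
        with pytest.raises(ValueError):
            band_summary(field, [(0.0, 10 * field.omega_grid[-1])])
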