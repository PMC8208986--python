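import numpy as np
import pytest

from lumenflow import hemodynamics as hemo
from lumenflow import leukocyte as leuko


class TestRateCoefficient:
    def test_above_threshold_zero(self):
        # neutrophil threshold 1.2 Pa: no adhesion at 2.0 Pa
        assert leuko.rate_coefficient(2.0, leuko.NEUTROPHIL) == 0.0

    def test_zero_wss_gives_k_max(self):
        sp = leuko.LeukocyteSpecies("n", 1e9, wss_th=1.2, k_max=3.0)
        assert leuko.rate_coefficient(0.0, sp) == pytest.approx(3.0)

    def test_half_threshold_linear_ramp(self):
        sp = leuko.LeukocyteSpecies("n", 1e9, wss_th=1.2, k_max=2.0)
        assert leuko.rate_coefficient(0.6, sp) == pytest.approx(1.0)

    def test_threshold_included_in_adhesive_regime(self):
        sp = leuko.LeukocyteSpecies("n", 1e9, wss_th=1.0, law="step")
        assert leuko.rate_coefficient(1.0, sp) == pytest.approx(sp.k_max)
        assert leuko.rate_coefficient(1.0 + 1e-12, sp) == 0.0

    def test_negative_wss_rejected(self):
        with pytest.raises(ValueError):
            leuko.rate_coefficient(-0.1, leuko.NEUTROPHIL)

    def test_nonincreasing_below_threshold(self):
        w = np.linspace(0, 1.2, 50)
        k = leuko.rate_coefficient(w, leuko.NEUTROPHIL)
        assert np.all(np.diff(k) <= 1e-15)

    def test_invalid_probe_nan_gives_zero(self):
        assert leuko.rate_coefficient(np.array([np.nan]),
                                      leuko.NEUTROPHIL)[0] == 0.0

    def test_unknown_law_rejected(self):
        with pytest.raises(ValueError):
            leuko.LeukocyteSpecies("n", 1e9, 1.0, law="cubic")


class TestApplySink:
    def test_zero_rate_no_change(self):
        rho, inc = leuko.apply_sink(np.array([1.0, 0.7]), np.zeros(2), 0.1)
        assert np.allclose(rho, [1.0, 0.7])
        assert np.allclose(inc, 0.0)

    def test_exponential_decay_conserves(self):
        k, t = 0.8, 2.5
        rho, inc = leuko.apply_sink(1.0, k, t)
        assert rho == pytest.approx(np.exp(-k * t), rel=1e-12)
        assert inc == pytest.approx(1 - np.exp(-k * t), rel=1e-12)
        assert rho + inc == pytest.approx(1.0, rel=1e-12)

    def test_uniform_mode_leaves_rho(self):
        rho, inc = leuko.apply_sink(np.array([0.3]), np.array([2.0]), 0.1,
                                    mode="uniform")
        assert rho[0] == pytest.approx(0.3)
        assert inc[0] == pytest.approx(0.2)


@pytest.fixture()
def channel_transport():
    """Small steady channel with a bound ScalarTransport."""
    h = 2e-3 / 8
    dom = hemo.ChannelDomain(0.0, 2e-3)
    grid = hemo.CartesianGrid.from_bounds([0, -2 * h, 0],
                                          [8e-3, 2e-3 + 2 * h, h], h)
    fluid = hemo.FluidProperties(rho=1000.0, mu=1e-3)
    sol = hemo.run_steady(dom, fluid, grid, 0.01, tol=1e-5, max_steps=4000)
    return sol, leuko.ScalarTransport(sol)


class TestAdvect:
    def test_uniform_field_stays_uniform(self, channel_transport):
        sol, tr = channel_transport
        conc = tr.fresh_state()
        for _ in range(50):
            tr.advect(conc, 1e-4)
        assert np.allclose(conc.rho[tr.fluid_cell], 1.0, atol=1e-12)

    def test_zero_velocity_unchanged(self, channel_transport):
        sol, tr = channel_transport
        u_save = sol.u.copy()
        sol.u[:] = 0.0
        sol.v[:] = 0.0
        conc = tr.fresh_state()
        conc.rho[tr.fluid_cell] = 0.5
        before = conc.rho.copy()
        tr.advect(conc, 1e-4)
        assert np.array_equal(conc.rho, before)
        sol.u[:] = u_save

    def test_front_advances_at_plug_speed(self, channel_transport):
        sol, tr = channel_transport
        # impose plug flow on open faces for a characteristics check
        sol_u = sol.u.copy()
        sol.u[:] = np.where(tr.solver.fluid_face[0], 0.02, 0.0)
        sol.v[:] = 0.0
        conc = tr.fresh_state()
        # step profile: zero downstream of x index 8
        conc.rho[8:] = 0.0
        conc.rho[~tr.fluid_cell] = 0.0
        h = tr.h
        dt = 0.2 * h / 0.02
        nsteps = 20
        for _ in range(nsteps):
            tr.advect(conc, dt, rho_inlet=1.0)
        j = tr.solver.grid.shape[1] // 2
        col = conc.rho[:, j, 0]
        front = np.argmax(col < 0.5)
        expected = 8 + 0.02 * dt * nsteps / h
        assert abs(front - expected) <= 1.5   # within a cell (upwind smear)
        sol.u[:] = sol_u

    def test_positivity_preserved(self, channel_transport):
        sol, tr = channel_transport
        conc = tr.fresh_state()
        rng = np.random.default_rng(0)
        conc.rho[tr.fluid_cell] = rng.uniform(0, 1, np.count_nonzero(tr.fluid_cell))
        for _ in range(100):
            tr.advect(conc, 1e-4)
        assert np.all(conc.rho >= -1e-15)

    def test_cfl_violation_raises(self, channel_transport):
        sol, tr = channel_transport
        conc = tr.fresh_state()
        with pytest.raises(ValueError, match="CFL"):
            tr.advect(conc, 1.0)


class TestLedger:
    def test_negative_increment_rejected(self):
        led = leuko.AdhesionLedger(np.arange(3.0), np.arange(2.0),
                                   np.ones((3, 2)))
        with pytest.raises(ValueError):
            led.add_flat(np.array([0]), np.array([-1.0]))

    def test_monotone_accumulation(self):
        led = leuko.AdhesionLedger(np.arange(3.0), np.arange(2.0),
                                   np.ones((3, 2)))
        tot = 0.0
        rng = np.random.default_rng(1)
        for _ in range(10):
            led.add_flat(rng.integers(0, 6, 4), rng.uniform(0, 1, 4))
            assert led.total() >= tot
            tot = led.total()

    def test_profile_uniform_sink(self):
        led = leuko.AdhesionLedger(np.arange(4.0), np.arange(3.0),
                                   np.full((4, 3), 2.0))
        led.accumulated[:] = 5.0e-9   # m^3 per bin
        led.elapsed = 1.0
        s, prof = leuko.adhesion_profile(led, 1.0)
        assert np.allclose(prof, prof[0])

    def test_profile_localized_sink(self):
        led = leuko.AdhesionLedger(np.arange(4.0), np.arange(3.0),
                                   np.ones((4, 3)))
        led.accumulated[2, 1] = 1e-9
        led.elapsed = 0.5
        s, prof = leuko.adhesion_profile(led, 0.5)
        assert prof[2] > 0
        assert np.allclose(np.delete(prof, 2), 0.0)

    def test_profile_hand_quadrature(self):
        # known analytic accumulation: sink rate r(t) = a + b t over [0, T]
        a, b, period = 2e-9, 3e-9, 0.8
        nt = 4000
        dt = period / nt
        led = leuko.AdhesionLedger(np.arange(3.0), np.arange(2.0),
                                   np.ones((3, 2)))
        for i in range(nt):
            t = (i + 0.5) * dt
            led.add_flat(np.array([0]), np.array([(a + b * t) * dt]))
        led.elapsed = period
        s, prof = leuko.adhesion_profile(led, period)
        expected = (a * period + 0.5 * b * period ** 2) / leuko.MM ** 3 / 2.0
        assert prof[0] == pytest.approx(expected, rel=1e-6)

    def test_partial_period_rejected(self):
        led = leuko.AdhesionLedger(np.arange(3.0), np.arange(2.0),
                                   np.ones((3, 2)))
        led.elapsed = 0.3
        with pytest.raises(ValueError):
            leuko.adhesion_profile(led, 0.8)


class TestSpeciesOrderingProperty:
    def test_larger_threshold_adheres_at_least_as_much(self, stenosis2d):
        # equal k_max, th(lymphocyte 0.6) < th(neutrophil 1.2):
        # wider adhesive window -> more total adhesion for the neutrophil
        c = stenosis2d["coupler"]
        low = c.ledgers["lymphocyte"].total()
        high = c.ledgers["neutrophil"].total()
        assert low <= high
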