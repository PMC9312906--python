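"""Bioheat solver: closed-form oracles, conservation, coupling loop."""

import dataclasses

import numpy as np
import pytest
from scipy.special import erfc

from mwablate.bioheat import (ThermalModel, initial_state,
                              run_simulation, step_bioheat)
from mwablate.damage import DamageParams
from mwablate.materials import PropertySet
from mwablate.phantoms import Label

from conftest import uniform_grid


def relaxed_damage() -> DamageParams:
    """Damage kinetics slowed to nothing, to isolate pure heat transfer."""
    return DamageParams(frequency_factor=1e-30)


class TestStepOracles:
    def test_equilibrium_is_stationary(self, props):
        """Uniform body temperature with no source stays put to round-off."""
        g = uniform_grid((5, 5, 5))
        model = ThermalModel(g, props, relaxed_damage())
        st = initial_state(g)
        for _ in range(20):
            model.step_inplace(st, np.zeros(g.shape), 0.25)
        assert np.allclose(st.T, 37.0, atol=1e-10)

    def test_adiabatic_heating_closed_form(self, no_perfusion_props):
        """Uniform Q with no gradients: dT = Q t / (rho c_eff)."""
        g = uniform_grid((4, 4, 4))
        model = ThermalModel(g, no_perfusion_props, relaxed_damage())
        st = initial_state(g)
        Q, t_end, n = 5e5, 10.0, 400
        for _ in range(n):
            model.step_inplace(st, np.full(g.shape, Q), t_end / n)
        expected = Q * t_end / (1040.0 * 3960.0)
        assert float(st.T[0, 0, 0]) - 37.0 == pytest.approx(expected,
                                                            rel=5e-3)

    def test_perfusion_relaxation_closed_form(self, props):
        """Uniform 60 degC decays to 37 at rate rho_b W_b c_b / (rho c)."""
        p = dataclasses.replace(props, perfusion_cutoff=1.0 - 1e-12)
        g = uniform_grid((4, 4, 4))
        model = ThermalModel(g, p, relaxed_damage())
        st = initial_state(g)
        st.T[:] = 60.0
        t_end, n = 100.0, 4000
        for _ in range(n):
            model.step_inplace(st, np.zeros(g.shape), t_end / n)
        rate = (1060.0 * 0.0064 * 3600.0) / (1040.0 * 3960.0)
        expected = 37.0 + 23.0 * np.exp(-rate * t_end)
        assert (float(st.T[0, 0, 0]) - 37.0) == pytest.approx(
            expected - 37.0, rel=0.01)

    def test_semi_infinite_slab_constant_flux_series(self, no_perfusion_props):
        """1D conduction oracle: constant surface flux into a long slab.

        Analytic solution for a semi-infinite solid with flux q0 at x=0:
        T(x,t) = q0/k * [2 sqrt(at/pi) exp(-x^2/4at) - x erfc(x/(2 sqrt(at)))].
        """
        n = 200
        h = 0.25e-3
        g = uniform_grid((n, 1, 1), spacing=h)
        model = ThermalModel(g, no_perfusion_props, relaxed_damage())
        st = initial_state(g)
        rho, c, k = 1040.0, 3960.0, 0.57
        a = k / (rho * c)
        q0 = 4000.0  # W/m^2 into the first cell
        src = np.zeros(g.shape)
        src[0] = q0 / h
        t_end = 30.0
        dt = 0.02  # stability bound ~ rho c h^2/(2k) = 0.226 s in 1D
        for _ in range(int(t_end / dt)):
            model.step_inplace(st, src, dt)
        x = (np.arange(n) + 0.5) * h  # flux enters at the x=0 face
        arg = x / (2.0 * np.sqrt(a * t_end))
        expected = q0 / k * (2.0 * np.sqrt(a * t_end / np.pi)
                             * np.exp(-arg ** 2) - x * erfc(arg))
        sim = st.T[:, 0, 0] - 37.0
        sel = expected > 0.02 * expected.max()
        err = np.abs(sim[sel] - expected[sel]).max() / expected.max()
        assert err < 0.01

    def test_energy_balance_insulated(self, no_perfusion_props):
        """Without perfusion, enthalpy gain equals deposited EM energy."""
        g = uniform_grid((16, 16, 16), spacing=0.8e-3)
        model = ThermalModel(g, no_perfusion_props, relaxed_damage())
        st = initial_state(g)
        rng = np.random.default_rng(3)
        Q = rng.random(g.shape) * 2e6
        dt, n = 0.2, 300  # 60 s
        T0 = st.T.copy()
        for _ in range(n):
            model.step_inplace(st, Q, dt)
        deposited = Q.sum() * g.voxel_volume * dt * n
        # enthalpy via the temperature path integral of rho c_eff
        fr = np.linspace(0.0, 1.0, 201)
        enthalpy = np.zeros(g.shape)
        for f0, f1 in zip(fr[:-1], fr[1:]):
            Tm = T0 + 0.5 * (f0 + f1) * (st.T - T0)
            enthalpy += (model.rho * model.effective_heat_capacity(Tm)
                         * (st.T - T0) * (f1 - f0))
        assert enthalpy.sum() * g.voxel_volume == pytest.approx(deposited,
                                                                rel=0.01)

    def test_antenna_voxels_stay_at_body_temperature(self, props):
        labels = np.full((7, 7, 9), np.uint8(Label.TUMOR))
        labels[3, 3, 2:] = np.uint8(Label.ANTENNA_METAL)
        g = uniform_grid((7, 7, 9), labels=labels)
        model = ThermalModel(g, props, relaxed_damage())
        st = initial_state(g)
        Q = np.full(g.shape, 1e6)
        Q[~g.active_mask] = 0.0
        for _ in range(100):
            model.step_inplace(st, Q, 0.25)
        assert np.allclose(st.T[3, 3, 2:], 37.0)
        assert st.T[g.active_mask].min() > 37.0

    def test_stability_bound_enforced(self, props):
        g = uniform_grid((5, 5, 5), spacing=0.5e-3)
        model = ThermalModel(g, props)
        st = initial_state(g)
        with pytest.raises(ValueError, match="stability"):
            model.step_inplace(st, np.zeros(g.shape), 10.0)

    def test_divergence_detected(self, props):
        g = uniform_grid((4, 4, 4))
        model = ThermalModel(g, props)
        st = initial_state(g)
        with pytest.raises(FloatingPointError, match="diverged"):
            for _ in range(100):
                model.step_inplace(st, np.full(g.shape, 5e9), 0.2)

    def test_functional_wrapper_leaves_input_untouched(self, props):
        g = uniform_grid((4, 4, 4))
        model = ThermalModel(g, props)
        st = initial_state(g)
        out = step_bioheat(st, np.full(g.shape, 1e5), 0.2, model)
        assert st.time == 0.0 and np.all(st.T == 37.0)
        assert out.time == pytest.approx(0.2)
        assert out.T.mean() > 37.0
        assert np.all(out.omega >= st.omega)


class TestRunSimulation:
    def test_zero_duration_returns_initial_state(self, small_case, props):
        _, grid = small_case
        res = run_simulation(grid, grid.antenna, 0.0, props,
                             em_backend="slots")
        assert res.final.time == 0.0
        assert np.all(res.final.T == 37.0)
        assert res.completed

    def test_linearity_in_frozen_limit(self, small_case):
        """With perfusion off and property curves frozen, T-37 scales with P."""
        _, grid = small_case
        frozen = PropertySet(
            blood=dataclasses.replace(PropertySet().blood,
                                      perfusion_rate=0.0),
            evaporation_midpoint=1e6)  # keeps W(T) flat: c_eff = c, eps(T) = eps
        ant = grid.antenna.with_power(2.0)
        kw = dict(materials=frozen, damage_params=relaxed_damage(),
                  dt=0.5, em_backend="slots", em_resolve_delta_T=1e9)
        r1 = run_simulation(grid, ant, 30.0, **kw)
        r2 = run_simulation(grid, ant.with_power(4.0), 30.0, **kw)
        d1 = r1.final.T - 37.0
        d2 = r2.final.T - 37.0
        assert np.allclose(d2, 2.0 * d1, rtol=1e-6, atol=1e-9)

    def test_snapshots_and_damage_monotonicity(self, small_case, props):
        _, grid = small_case
        res = run_simulation(grid, grid.antenna.with_power(8.0), 30.0, props,
                             dt=0.5, em_backend="slots",
                             snapshot_times=[10.0, 20.0, 30.0])
        assert [t for t, _ in res.snapshots] == [10.0, 20.0, 30.0]
        omegas = [s.omega for _, s in res.snapshots]
        assert np.all(omegas[1] >= omegas[0])
        assert np.all(omegas[2] >= omegas[1])
        times = res.center_series[:, 0]
        assert np.all(np.diff(times) > 0)
        assert res.center_series[-1, 1] > 37.0

    def test_grid_convergence_at_fixed_probe(self, props):
        """T(60 s) at a fixed physical point moves <2% when halving the spacing.

        The probe sits 2.5 mm off-axis at slot height — a steep part of the
        field but away from the one-voxel antenna staircase.
        """
        from scipy.ndimage import map_coordinates
        from mwablate.em import AntennaSpec
        from mwablate.phantoms import generate_tumor_phantom, voxelize
        mesh = generate_tumor_phantom(semi_axes=(4.7e-3, 4.7e-3, 5.9e-3))
        antenna = AntennaSpec(power=5.0)
        probe = np.array([2.5e-3, 0.0, 0.0])  # relative to the centroid
        temps = {}
        for h in (1e-3, 0.5e-3):
            grid = voxelize(mesh, antenna, spacing=h, margin=5e-3)
            res = run_simulation(grid, antenna, 60.0, props, dt=0.2,
                                 em_backend="slots")
            coords = ((mesh.centroid + probe - grid.origin) / h)[:, None]
            temps[h] = float(map_coordinates(res.final.T, coords,
                                             order=1)[0]) - 37.0
        assert abs(temps[1e-3] - temps[0.5e-3]) / temps[0.5e-3] < 0.02
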