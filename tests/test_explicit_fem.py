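"""Explicit solver: kinematics, stability bound, constitutive update,
contact, and conservation properties of full drop runs."""

import numpy as np
import pytest

from fruitdrop import explicit_fem as fem
from fruitdrop import synthetic_fruit as sf
from fruitdrop._kernel import _return_map_3d
from fruitdrop.tissue_mechanics import MaterialParams, get_material

from conftest import smoothed_peak_force


FLESH = get_material("flesh")
STEEL = get_material("steel")


class TestInitialVelocity:
    @pytest.mark.parametrize(
        "h,v", [(0.0, 0.0), (0.5, 3.1305), (1.0, 4.4272), (0.25, 2.2136)]
    )
    def test_free_fall(self, h, v):
        assert fem.initial_velocity(h) == pytest.approx(v, abs=5e-5)

    def test_negative_height(self):
        with pytest.raises(ValueError):
            fem.initial_velocity(-0.1)


class TestStableTimeStep:
    def _assembled_oracle(self, mesh, mat):
        """Brute force: maximum eigenfrequency of the assembled
        lumped-mass single element."""
        lam, mu = fem._elastic_moduli_si(mat)
        k = fem._cst_stiffness(mesh.points[mesh.tets[0]] * 1e-3, lam, mu)
        vol = mesh.tet_volumes()[0] * 1e-9
        m = mat.density * vol / 4.0
        w2 = np.linalg.eigvalsh(k / m).max()
        return 2.0 / np.sqrt(w2)

    def test_single_tet_matches_eigen_oracle(self):
        mesh = sf.make_fixture("single_tet", edge=2.0)
        cfg = fem.SolverConfig(time_step_safety=1.0)
        dt = fem.stable_time_step(mesh, {"flesh": FLESH}, cfg)
        assert dt == pytest.approx(self._assembled_oracle(mesh, FLESH), rel=0.01)

    def test_length_scaling(self):
        cfg = fem.SolverConfig(time_step_safety=1.0)
        dt1 = fem.stable_time_step(
            sf.make_fixture("single_tet", edge=2.0), {"flesh": FLESH}, cfg
        )
        dt2 = fem.stable_time_step(
            sf.make_fixture("single_tet", edge=4.0), {"flesh": FLESH}, cfg
        )
        assert dt2 == pytest.approx(2.0 * dt1, rel=1e-9)

    def test_safety_factor_linear(self):
        mesh = sf.make_fixture("single_tet", edge=2.0)
        dt_90 = fem.stable_time_step(
            mesh, {"flesh": FLESH}, fem.SolverConfig(time_step_safety=0.9)
        )
        dt_45 = fem.stable_time_step(
            mesh, {"flesh": FLESH}, fem.SolverConfig(time_step_safety=0.45)
        )
        assert dt_45 == pytest.approx(0.5 * dt_90, rel=1e-12)

    def test_contact_penalty_bounds_dt(self):
        mesh = sf.make_fixture("single_tet", edge=2.0)
        cfg = fem.SolverConfig(time_step_safety=1.0, foundation_modulus_cap=1e5)
        dt_free = fem.stable_time_step(mesh, {"flesh": FLESH}, cfg)
        dt_contact = fem.stable_time_step(mesh, {"flesh": FLESH}, cfg, STEEL)
        assert dt_contact < dt_free


class TestRadialReturn:
    def test_elastic_below_yield(self):
        de = np.diag([0.01, -0.004, -0.004])
        stress, state = fem.radial_return_update(de, fem.PlasticState(), FLESH)
        assert state.eqps == 0.0
        lam = 1.57 * 0.4 / (1.4 * 0.2)
        mu = 1.57 / 2.8
        expected = lam * np.trace(de) * np.eye(3) + 2 * mu * de
        np.testing.assert_allclose(stress, expected, rtol=1e-12, atol=1e-15)

    def test_uniaxial_bilinear_slopes(self):
        """Uniaxial stress driving reproduces slope E below the
        bio-yield point and slope Et above it, each within 1%."""
        eps = np.linspace(0, 0.4, 400)
        sig = fem.uniaxial_stress_response(FLESH, eps)
        e_pre = (sig[20] - sig[10]) / (eps[20] - eps[10])
        e_post = (sig[-1] - sig[-30]) / (eps[-1] - eps[-30])
        assert e_pre == pytest.approx(1.57, rel=0.01)
        assert e_post == pytest.approx(0.92, rel=0.01)
        i_yield = np.searchsorted(np.diff(sig) / np.diff(eps) < 1.2, True)
        assert sig[i_yield] == pytest.approx(0.26, rel=0.02)

    def test_unloading_is_elastic_with_residual_strain(self):
        eps = np.concatenate([np.linspace(0, 0.3, 150), np.linspace(0.3, 0.1, 100)])
        sig = fem.uniaxial_stress_response(FLESH, eps)
        unload_slope = (sig[150] - sig[170]) / (eps[150] - eps[170])
        assert unload_slope == pytest.approx(1.57, rel=0.02)
        # stress crosses zero before strain does: residual plastic strain
        crossing = eps[150:][np.argmin(np.abs(sig[150:]))]
        assert crossing > 0.05

    def test_kernel_matches_reference_implementation(self):
        """Dual route: the compiled return map agrees with the plain
        numpy reference on random strain paths."""
        rng = np.random.default_rng(42)
        lam = 1.57e6 * 0.4 / (1.4 * 0.2)
        mu = 1.57e6 / 2.8
        h = FLESH.hardening_modulus * 1e6
        state = fem.PlasticState()
        s6 = np.zeros(6)
        eqps = 0.0
        mat_si = MaterialParams(
            name="flesh-si", young_modulus=1.57e6, tangent_modulus=0.92e6,
            bio_yield_stress=0.26e6, density=1030, poisson_ratio=0.4,
        )
        for _ in range(25):
            de6 = rng.normal(0, 0.01, 6)
            de = np.array(
                [
                    [de6[0], de6[3], de6[5]],
                    [de6[3], de6[1], de6[4]],
                    [de6[5], de6[4], de6[2]],
                ]
            )
            stress_ref, state = fem.radial_return_update(de, state, mat_si)
            t0, t1, t2, t3, t4, t5, eqps, dg, vm = _return_map_3d(
                s6, de6, lam, mu, 0.26e6, h, eqps
            )
            s6 = np.array([t0, t1, t2, t3, t4, t5])
            ref6 = np.array(
                [
                    stress_ref[0, 0], stress_ref[1, 1], stress_ref[2, 2],
                    stress_ref[0, 1], stress_ref[1, 2], stress_ref[0, 2],
                ]
            )
            np.testing.assert_allclose(s6, ref6, rtol=1e-10, atol=1e-4)
        assert eqps == pytest.approx(state.eqps, rel=1e-10)

    def test_tangent_modulus_must_be_below_young(self):
        with pytest.raises(ValueError):
            MaterialParams(
                name="bad", young_modulus=1.0, tangent_modulus=1.5,
                bio_yield_stress=0.2, density=1000, poisson_ratio=0.3,
            )


class TestContactForce:
    def test_no_penetration_zero_force(self):
        mesh = sf.make_fixture("single_tet", edge=2.0)
        pos = mesh.points + [0.0, 0.0, 1.0]
        forces, ce = fem.contact_force(pos, mesh, STEEL)
        assert np.all(forces == 0.0)
        assert ce == 0.0

    def test_single_node_closed_form(self):
        mesh = sf.make_fixture("single_tet", edge=2.0)
        delta_mm = 0.05
        pos = mesh.points - [0.0, 0.0, delta_mm]  # one node dips below z=0
        cfg = fem.SolverConfig()
        forces, ce = fem.contact_force(pos, mesh, STEEL, cfg)
        below = pos[:, 2] < 0
        assert below.sum() >= 1
        areas_tri = mesh.skin_areas() * 1e-6
        area_node = np.zeros(mesh.n_nodes)
        np.add.at(area_node, mesh.skin_tris.ravel(), np.repeat(areas_tri / 3.0, 3))
        e_eff = min(STEEL.young_modulus, cfg.foundation_modulus_cap) * 1e6
        k = e_eff / (cfg.penalty_reference_thickness * 1e-3)
        for i in np.nonzero(below)[0]:
            expected = k * area_node[i] * (-pos[i, 2] * 1e-3)
            assert forces[i, 2] == pytest.approx(expected, rel=1e-12)

    def test_quasi_static_push_matches_summation_oracle(self):
        """Vectorized contact equals an independent per-node summation."""
        mesh = sf.make_fixture("elastic_sphere", radius=10.0, element_size=3.0)
        cfg = fem.SolverConfig()
        for delta in [0.1, 0.5, 1.0]:
            pos = mesh.points - [0.0, 0.0, mesh.points[:, 2].min() + delta]
            forces, ce = fem.contact_force(pos, mesh, STEEL, cfg)
            areas_tri = mesh.skin_areas() * 1e-6
            area_node = np.zeros(mesh.n_nodes)
            for t, a in zip(mesh.skin_tris, areas_tri):
                for n in t:
                    area_node[n] += a / 3.0
            e_eff = min(STEEL.young_modulus, cfg.foundation_modulus_cap) * 1e6
            k = e_eff / (cfg.penalty_reference_thickness * 1e-3)
            total = 0.0
            for n in mesh.skin_nodes:
                z = pos[n, 2] * 1e-3
                if z < 0:
                    total += k * area_node[n] * (-z)
            assert forces[:, 2].sum() == pytest.approx(total, rel=1e-10)


class TestDropSimulation:
    def test_nothing_happens_without_height_or_gravity(self):
        mesh = sf.make_fixture("elastic_sphere", radius=10.0, element_size=3.0)
        scn = fem.DropScenario(
            height=0.0, collision_angle=0, surface_material=STEEL,
            gravity=0.0, sim_duration=0.002,
        )
        res = fem.run_drop_simulation(
            mesh, {"flesh": FLESH}, scn, plasticity=True, use_skin=False
        )
        assert np.all(res.contact_force_total == 0.0)
        assert np.all(res.plastic_strain == 0.0)
        assert res.peak_flesh_stress == pytest.approx(0.0, abs=1e-9)

    def test_hertz_peak_force(self, hertz_run):
        """Elastic sphere vs the Hertz closed form (energy-balance
        d_max, peak force), after removing discrete-contact ringing."""
        res = hertz_run["result"]
        peak = smoothed_peak_force(res)
        assert peak == pytest.approx(hertz_run["f_hertz"], rel=0.05)

    def test_impulse_momentum_balance(self, hertz_run):
        res = hertz_run["result"]
        impulse = np.trapezoid(res.contact_force_total, res.times)
        dv = res.com_velocity[-1, 2] - res.com_velocity[0, 2]
        span = res.times[-1] - res.times[0]
        expected = res.total_mass * dv + res.total_mass * res.scenario.gravity * span
        assert impulse == pytest.approx(expected, rel=0.01)

    def test_energy_audit_closes(self, hertz_run):
        res = hertz_run["result"]
        assert res.max_energy_error_fraction < 0.01

    def test_elastic_restitution_near_unity(self, hertz_run):
        from fruitdrop.experiments_rsm import rebound_metrics

        reb = rebound_metrics(hertz_run["result"])
        assert reb.complete
        assert reb.restitution == pytest.approx(1.0, abs=0.05)
        assert reb.restitution <= 1.0

    def test_hourglass_energy_identically_zero(self, hertz_run):
        assert np.all(hertz_run["result"].hourglass_energy == 0.0)

    def test_energy_guard_raises(self):
        """The instability guard trips when the energy-balance tolerance
        is tightened below the scheme's discretization error."""
        mesh = sf.make_fixture("elastic_sphere", radius=10.0, element_size=3.0)
        scn = fem.DropScenario(
            height=0.5, collision_angle=0, surface_material=STEEL, sim_duration=0.004
        )
        cfg = fem.SolverConfig(instability_tolerance=1e-12)
        with pytest.raises(fem.SimulationInstabilityError):
            fem.run_drop_simulation(mesh, {"flesh": FLESH}, scn, cfg, use_skin=False)


class TestGridProperties:
    def test_restitution_bounded_by_unity(self, scenario_grid_4mm):
        for cell in scenario_grid_4mm.cells:
            if cell.rebound is not None:
                assert 0.0 <= cell.rebound.restitution <= 1.0

    def test_softer_surface_no_larger_peak_force(self, scenario_grid_4mm):
        """steel >= PVC >= neoprene peak contact force at fixed (h, angle)."""
        for h in (0.25, 0.5, 1.0):
            for ang in (0.0, 45.0, 90.0):
                f = {
                    s: scenario_grid_4mm.cell(s, h, ang).peak_force
                    for s in ("steel", "pvc", "neoprene")
                }
                assert f["steel"] >= f["pvc"] * 0.99
                assert f["pvc"] >= f["neoprene"] * 0.99

    def test_peak_force_monotone_in_height_on_steel(self, scenario_grid_4mm):
        for ang in (0.0, 45.0, 90.0):
            forces = [
                scenario_grid_4mm.cell("steel", h, ang).peak_force
                for h in (0.25, 0.5, 1.0)
            ]
            assert forces[0] <= forces[1] <= forces[2]
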