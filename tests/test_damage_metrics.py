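"""Bruise classification, volumes, areas, absorbed energy and BS."""

import numpy as np
import pytest

from fruitdrop import damage_metrics as dm
from fruitdrop import synthetic_fruit as sf
from fruitdrop.explicit_fem import SimulationResult


def _synthetic_result(peak_vm, region, volumes, skin_vm=None, skin_areas=None,
                      ie=None, wp=None, vz=None, mass=0.1, v0=3.0):
    n = len(peak_vm)
    nt = 0 if skin_vm is None else len(skin_vm)
    steps = 5
    times = np.linspace(0, 0.02, steps)
    return SimulationResult(
        times=times,
        contact_force_total=np.array([0, 10, 50, 10, 0.0]),
        com_velocity=np.column_stack(
            [np.zeros(steps), np.zeros(steps),
             np.array([-v0, -1, 0, 1, 1.0]) if vz is None else vz]
        ),
        kinetic_energy=np.ones(steps),
        internal_energy=np.array([0, 0.2, 0.5, 0.3, 0.25]) if ie is None else ie,
        elastic_energy=np.zeros(steps),
        plastic_energy=np.array([0, 0.05, 0.1, 0.15, 0.15]) if wp is None else wp,
        contact_energy=np.zeros(steps),
        viscous_energy=np.zeros(steps),
        hourglass_energy=np.zeros(steps),
        gravity_work=np.zeros(steps),
        energy_error=np.zeros(steps),
        peak_von_mises=np.asarray(peak_vm, dtype=float),
        peak_von_mises_skin=np.zeros(nt) if skin_vm is None else np.asarray(skin_vm),
        plastic_strain=np.zeros(n),
        plastic_strain_skin=np.zeros(nt),
        final_displacement=np.zeros((4, 3)),
        region=np.asarray(region, dtype=np.int8),
        element_volumes=np.asarray(volumes, dtype=float),
        skin_areas=np.zeros(nt) if skin_areas is None else np.asarray(skin_areas),
        total_mass=mass,
        initial_speed=v0,
        dt=1e-5,
    )


class TestClassification:
    def test_all_below_thresholds_empty(self):
        res = _synthetic_result([0.1, 0.2, 0.25], [0, 0, 0], [1, 1, 1])
        assert not dm.classify_bruised_elements(res).any()

    def test_exact_subset_brute_force(self):
        """Exactly the elements a direct scan flags are masked."""
        rng = np.random.default_rng(3)
        vm = rng.uniform(0, 0.6, 50)
        region = np.zeros(50, dtype=int)
        region[40:] = sf.REGION_CORE
        res = _synthetic_result(vm, region, np.ones(50))
        mask = dm.classify_bruised_elements(res)
        thr = dm.DamageThresholds()
        expected = np.array(
            [
                v > (thr.core_yield if r == sf.REGION_CORE else thr.flesh_yield)
                for v, r in zip(vm, region)
            ]
        )
        np.testing.assert_array_equal(mask, expected)

    def test_tie_at_threshold_not_bruised(self):
        res = _synthetic_result([0.26, 0.26000001], [0, 0], [1, 1])
        mask = dm.classify_bruised_elements(res)
        np.testing.assert_array_equal(mask, [False, True])

    def test_missing_region_threshold(self):
        res = _synthetic_result([0.3], [5], [1.0])
        with pytest.raises(KeyError):
            dm.classify_bruised_elements(res)


class TestVolumesAndAreas:
    def test_bruise_volume_empty_and_total(self, fruit_mesh_4mm):
        n = fruit_mesh_4mm.n_tets
        assert dm.bruise_volume(np.zeros(n, dtype=bool), fruit_mesh_4mm) == 0.0
        assert dm.bruise_volume(
            np.ones(n, dtype=bool), fruit_mesh_4mm
        ) == pytest.approx(fruit_mesh_4mm.total_volume(), rel=1e-12)

    def test_bruise_volume_subset_summation_oracle(self, fruit_mesh_4mm):
        rng = np.random.default_rng(11)
        mask = rng.random(fruit_mesh_4mm.n_tets) < 0.3
        vols = fruit_mesh_4mm.tet_volumes()
        expected = sum(float(v) for v, m in zip(vols, mask) if m)
        assert dm.bruise_volume(mask, fruit_mesh_4mm) == pytest.approx(
            expected, rel=1e-12
        )

    def test_skin_area_all_above_matches_surface(self, fruit_mesh_4mm, fruit_geometry):
        nt = fruit_mesh_4mm.skin_tris.shape[0]
        total = dm.bruised_skin_area(np.ones(nt, dtype=bool), fruit_mesh_4mm)
        assert total == pytest.approx(fruit_geometry.surface_area, rel=0.03)

    def test_skin_area_single_triangle(self, fruit_mesh_4mm):
        mask = np.zeros(fruit_mesh_4mm.skin_tris.shape[0], dtype=bool)
        mask[7] = True
        p = fruit_mesh_4mm.points[fruit_mesh_4mm.skin_tris[7]]
        expected = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        assert dm.bruised_skin_area(mask, fruit_mesh_4mm) == pytest.approx(expected)

    def test_region_partition(self):
        vm = np.array([0.3, 0.3, 1.2, 1.0])
        region = np.array([0, 0, 1, 1])
        vols = np.array([2.0, 3.0, 4.0, 5.0])
        res = _synthetic_result(vm, region, vols)
        rep = dm.damage_report(res, mesh=None)
        assert rep.flesh_bruise_volume == pytest.approx(5.0)
        assert rep.core_bruise_volume == pytest.approx(4.0)
        assert rep.bruise_volume == pytest.approx(9.0)

    def test_volume_monotone_under_threshold_decrease(self):
        rng = np.random.default_rng(5)
        vm = rng.uniform(0, 0.6, 200)
        res = _synthetic_result(vm, np.zeros(200, dtype=int), np.ones(200))
        vols = np.ones(200)
        v_hi = dm.bruise_volume(
            dm.classify_bruised_elements(res, dm.DamageThresholds(flesh_yield=0.4)),
            vols,
        )
        v_lo = dm.bruise_volume(
            dm.classify_bruised_elements(res, dm.DamageThresholds(flesh_yield=0.2)),
            vols,
        )
        assert v_lo >= v_hi


class TestAbsorbedEnergy:
    def test_default_is_peak_internal(self):
        res = _synthetic_result([0.1], [0], [1.0])
        assert dm.absorbed_energy(res) == pytest.approx(0.5)

    def test_plastic_only(self):
        res = _synthetic_result([0.1], [0], [1.0])
        assert dm.absorbed_energy(res, "plastic") == pytest.approx(0.15)

    def test_kinetic_loss(self):
        res = _synthetic_result([0.1], [0], [1.0], mass=0.2, v0=3.0)
        # rebound speed 1.0 from the synthetic COM trace
        assert dm.absorbed_energy(res, "kinetic_loss") == pytest.approx(
            0.5 * 0.2 * (9.0 - 1.0)
        )

    def test_sphere_drop_converts_kinetic_energy(self, hertz_run):
        """At peak compression essentially all kinetic energy sits in
        the (elastic) internal + contact store."""
        res = hertz_run["result"]
        et = dm.absorbed_energy(res)
        ke0 = res.kinetic_energy[0]
        assert et <= ke0 * 1.05
        assert et >= 0.5 * ke0  # the rest is contact-spring energy


class TestBS:
    @pytest.mark.parametrize(
        "vb,et,bs", [(0.0, 0.5, 0.0), (100.0, 0.05, 2000.0), (200.0, 0.05, 4000.0)]
    )
    def test_ratio(self, vb, et, bs):
        value, degenerate = dm.bruise_susceptibility(vb, et)
        assert value == pytest.approx(bs)
        assert not degenerate

    def test_degenerate_zero_energy(self):
        value, degenerate = dm.bruise_susceptibility(10.0, 0.0)
        assert value == 0.0
        assert degenerate

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            dm.bruise_susceptibility(-1.0, 0.5)

    def test_report_serializes(self, tmp_path):
        res = _synthetic_result([0.3], [0], [2.0])
        rep = dm.damage_report(res, mesh=None)
        text = rep.to_json(tmp_path / "report.json")
        import json

        data = json.loads(text)
        assert data["bruise_volume"] == pytest.approx(2.0)
        assert set(data["energy_alternatives"]) == {
            "internal_peak", "plastic", "kinetic_loss",
        }
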