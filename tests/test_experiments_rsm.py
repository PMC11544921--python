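"""Response-surface fitting, the published prediction equations,
rebound metrics, and the mesh-sensitivity machinery."""

import itertools

import numpy as np
import pytest

from fruitdrop import experiments_rsm as rsm
from fruitdrop import explicit_fem as fem
from fruitdrop import synthetic_fruit as sf
from fruitdrop.tissue_mechanics import MaterialParams, get_material

from conftest import smoothed_peak_force


GRID_XY = [(x, y) for x in rsm.HEIGHTS for y in rsm.ANGLES]


class TestPrintedModels:
    def test_steel_maximum(self):
        """The published steel equation evaluated at (1 m, 90 deg)
        reproduces the reported maximum bruise susceptibility."""
        assert rsm.evaluate_printed_model("steel", 1.0, 90.0) == pytest.approx(
            6716.07, abs=0.01
        )

    def test_neoprene_minimum(self):
        assert rsm.evaluate_printed_model("neoprene", 0.25, 0.0) == pytest.approx(
            1570.59, abs=0.01
        )

    @pytest.mark.parametrize(
        "material,intercept",
        [("steel", 1419.5306), ("pvc", 1021.1223), ("neoprene", -404.2321)],
    )
    def test_intercepts_at_origin(self, material, intercept):
        assert rsm.evaluate_printed_model(material, 0.0, 0.0) == pytest.approx(
            intercept
        )

    def test_unknown_material(self):
        with pytest.raises(KeyError):
            rsm.evaluate_printed_model("glass", 0.5, 45.0)

    def test_extrema_on_design_box(self):
        ext = rsm.find_extrema(rsm.printed_model("steel"))
        assert ext["max"]["value"] == pytest.approx(6716.0645, abs=0.01)
        ext = rsm.find_extrema(rsm.printed_model("neoprene"))
        assert ext["min"]["value"] == pytest.approx(1570.5939, abs=0.01)


class TestQuadraticFit:
    def test_exact_quadratic_recovered(self):
        coef = np.array([10.0, -3.0, 0.5, 2.0, 1.5, -0.01])
        z = [
            coef @ np.array([1, x, y, x * y, x * x, y * y]) for x, y in GRID_XY
        ]
        m = rsm.fit_quadratic_surface(
            [x for x, _ in GRID_XY], [y for _, y in GRID_XY], z
        )
        np.testing.assert_allclose(m.coefficients, coef, rtol=1e-8, atol=1e-8)
        assert m.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_response(self):
        m = rsm.fit_quadratic_surface(
            [x for x, _ in GRID_XY], [y for _, y in GRID_XY], [7.0] * 9
        )
        assert m.coefficients[0] == pytest.approx(7.0, abs=1e-8)
        np.testing.assert_allclose(m.coefficients[1:], 0.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        """OLS equals a direct normal-equations solve to 1e-10."""
        rng = np.random.default_rng(8)
        z = rng.normal(1000, 300, 9)
        x = np.array([x for x, _ in GRID_XY])
        y = np.array([y for _, y in GRID_XY])
        m = rsm.fit_quadratic_surface(x, y, z)
        a = np.column_stack([np.ones(9), x, y, x * y, x * x, y * y])
        oracle = np.linalg.solve(a.T @ a, a.T @ z)
        np.testing.assert_allclose(m.coefficients, oracle, rtol=1e-10, atol=1e-8)

    @pytest.mark.parametrize("material", ["steel", "pvc", "neoprene"])
    def test_printed_model_roundtrip(self, material):
        """Fitting a printed model's own 3x3 evaluations recovers its
        coefficients."""
        z = [rsm.evaluate_printed_model(material, x, y) for x, y in GRID_XY]
        m = rsm.fit_quadratic_surface(
            [x for x, _ in GRID_XY], [y for _, y in GRID_XY], z, material
        )
        np.testing.assert_allclose(
            m.coefficients,
            rsm.PRINTED_MODELS[material],
            rtol=1e-6,
            atol=1e-6,
        )

    def test_rank_deficient_design_reports_confounding(self):
        with pytest.raises(ValueError, match="confounded|rank"):
            rsm.fit_quadratic_surface(
                [0.25, 0.5, 1.0, 0.25, 0.5, 1.0],
                [0.0] * 6,  # single angle level: Y, XY, Y^2 unidentifiable
                [1, 2, 3, 1, 2, 3],
            )

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            rsm.fit_quadratic_surface([0.25, 0.5], [0, 45], [1, 2])


class TestRebound:
    def test_closed_form_rebound_height(self):
        # e = 0.5 at v0 = 3.13 m/s -> h_r = (0.5*3.13)^2 / (2*9.8)
        v0 = 3.13
        vr = 0.5 * v0
        assert vr**2 / (2 * 9.8) == pytest.approx(0.125, abs=2e-4)

    def test_elastic_sphere_restitution(self, hertz_run):
        reb = rsm.rebound_metrics(hertz_run["result"])
        assert reb.complete
        assert reb.restitution == pytest.approx(1.0, abs=0.05)
        expected_h = reb.rebound_speed**2 / (2 * 9.8)
        assert reb.rebound_height == pytest.approx(expected_h, rel=1e-12)

    def test_no_contact_flagged_incomplete(self):
        from test_damage_metrics import _synthetic_result

        res = _synthetic_result([0.1], [0], [1.0])
        res.contact_force_total = np.zeros_like(res.contact_force_total)
        reb = rsm.rebound_metrics(res)
        assert not reb.complete
        assert reb.restitution == 0.0


class TestScenarioGrid:
    def test_grid_is_complete_factorial(self, scenario_grid_4mm):
        assert len(scenario_grid_4mm.cells) == 27
        combos = {
            (c.surface, c.height, c.angle) for c in scenario_grid_4mm.cells
        }
        assert len(combos) == 27
        assert not any(c.failed for c in scenario_grid_4mm.cells)

    def test_dataframe_export(self, scenario_grid_4mm):
        df = scenario_grid_4mm.to_dataframe()
        assert len(df) == 27
        assert {"material", "height_m", "angle_deg", "BS_mm3_per_J"} <= set(df.columns)
        assert df["BS_mm3_per_J"].notna().all()

    def test_bs_increases_with_height_on_stiff_surfaces(self, scenario_grid_4mm):
        """The height main effect: angle-averaged BS grows monotonically
        with drop height on the stiff surfaces."""
        for surf in ("steel", "pvc"):
            bs = [
                np.mean(
                    [
                        scenario_grid_4mm.cell(surf, h, a).report.bruise_susceptibility
                        for a in rsm.ANGLES
                    ]
                )
                for h in rsm.HEIGHTS
            ]
            assert bs[0] < bs[1] < bs[2], (surf, bs)

    def test_fitted_models_have_diagnostics(self, scenario_grid_4mm):
        models = scenario_grid_4mm.fit_surface_models()
        assert set(models) == {"steel", "pvc", "neoprene"}
        for m in models.values():
            assert 0.0 <= m.r_squared <= 1.0
            assert m.p_values is not None and len(m.p_values) == 6
            assert "height" in m.standardized_effects

    def test_cache_makes_grid_resumable(self):
        cache = {}
        kw = dict(
            element_size=5.0, heights=[0.0], angles=[0.0], surfaces=["steel"],
            cache=cache,
        )
        g1 = rsm.run_scenario_grid(**kw)
        cell = g1.cells[0]
        g2 = rsm.run_scenario_grid(**kw)
        assert g2.cells[0] is cell  # reused, not recomputed

    def test_zero_height_grid_degenerate_bs(self):
        """Dropping from zero height bruises nothing: BS = 0 everywhere."""
        g = rsm.run_scenario_grid(
            element_size=5.0, heights=[0.0], angles=[0.0], surfaces=["steel"]
        )
        rep = g.cells[0].report
        assert rep.bruise_volume == 0.0
        assert rep.bruise_susceptibility == 0.0


class TestMeshSensitivity:
    def test_study_shape_and_counts(self):
        study = rsm.mesh_sensitivity_study(
            sizes=[5.0, 4.0], height=0.25, sim_duration=0.008
        )
        rows = study["rows"]
        assert len(rows) == 2
        assert rows[0]["element_size_mm"] < rows[1]["element_size_mm"]
        assert rows[0]["elements"] > rows[1]["elements"]
        assert study["recommended_size"] >= rows[0]["element_size_mm"]

    def test_sizes_validated(self):
        with pytest.raises(ValueError):
            rsm.mesh_sensitivity_study(sizes=[0.1, 2.0])

    def test_sphere_fixture_converges_to_hertz(self):
        """The two finest sphere meshes agree with each other and with
        the Hertz oracle on the smoothed peak force."""
        mat = MaterialParams(
            name="hertz-gel", young_modulus=2.0, density=1000.0, poisson_ratio=1e-3
        )
        peaks = []
        for es in (1.5, 1.2):
            mesh = sf.make_fixture("elastic_sphere", radius=10.0, element_size=es)
            scn = fem.DropScenario(
                height=0.05, collision_angle=0,
                surface_material=get_material("steel"), sim_duration=0.005,
            )
            res = fem.run_drop_simulation(
                mesh, {"flesh": mat}, scn, plasticity=False, use_skin=False
            )
            peaks.append(smoothed_peak_force(res))
            m, v0 = res.total_mass, res.initial_speed
        e_star = 2.0e6 / (1 - 1e-6)
        d = (0.5 * m * v0**2 * 15 / (8 * e_star * 0.1)) ** 0.4
        f_hertz = 4.0 / 3.0 * e_star * 0.1 * d**1.5
        assert peaks[0] == pytest.approx(peaks[1], rel=0.05)
        assert peaks[1] == pytest.approx(f_hertz, rel=0.06)
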