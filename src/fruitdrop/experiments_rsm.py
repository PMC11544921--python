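"""Computational experiments: the 27-scenario factorial sweep, the mesh
sensitivity study, rebound analysis, and quadratic response-surface
models of bruise susceptibility.

The factor space is drop height X (0.25/0.5/1 m), collision angle Y
(0/45/90 deg) and contact surface (steel/PVC/neoprene).  Per surface, a
quadratic polynomial

    BS(X, Y) = b0 + bX*X + bY*Y + bXY*X*Y + bXX*X^2 + bYY*Y^2

is fitted by ordinary least squares in raw units, matching the form of
the published prediction equations, which are also carried verbatim for
direct evaluation.  With 9 design points and 6 parameters the t-tests
have 3 degrees of freedom: significance calls are reported but are
low-powered, and factor importance is better judged from the
coded-unit (standardized) effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .damage_metrics import DamageReport, DamageThresholds, damage_report
from .explicit_fem import (
    DropScenario,
    SimulationResult,
    SimulationInstabilityError,
    SolverConfig,
    default_materials,
    run_drop_simulation,
)
from .synthetic_fruit import FruitGeometry, build_fruit_geometry, generate_mesh
from .tissue_mechanics import MaterialParams, get_material

__all__ = [
    "HEIGHTS",
    "ANGLES",
    "SURFACES",
    "PRINTED_MODELS",
    "ScenarioGrid",
    "GridCell",
    "ResponseSurfaceModel",
    "ReboundMetrics",
    "run_scenario_grid",
    "mesh_sensitivity_study",
    "rebound_metrics",
    "fit_quadratic_surface",
    "evaluate_printed_model",
    "printed_model",
    "find_extrema",
]

HEIGHTS = (0.25, 0.5, 1.0)  # m
ANGLES = (0.0, 45.0, 90.0)  # deg
SURFACES = ("steel", "pvc", "neoprene")

# Published per-surface quadratic coefficients for bruise susceptibility
# (mm^3/J) with X = drop height (m) and Y = collision angle (deg), in the
# basis (1, X, Y, XY, X^2, Y^2).
PRINTED_MODELS: dict[str, tuple[float, ...]] = {
    "steel": (1419.5306, 4039.4034, 0.2218, -4.4657, 956.2515, 0.0843),
    "pvc": (1021.1223, 4839.5683, 2.5997, -2.1677, 42.4485, 0.0132),
    "neoprene": (-404.2321, 8672.6431, 0.3499, -0.5917, -3093.3563, 0.0076),
}


def _design_row(x: float, y: float) -> np.ndarray:
    return np.array([1.0, x, y, x * y, x * x, y * y])


def evaluate_printed_model(material: str, x: float, y: float) -> float:
    """Evaluate the published quadratic BS model for one surface at
    height x (m) and angle y (deg).  Pure polynomial evaluation."""
    key = material.lower()
    if key not in PRINTED_MODELS:
        raise KeyError(f"no printed model for {material!r}; have {sorted(PRINTED_MODELS)}")
    return float(_design_row(x, y) @ np.array(PRINTED_MODELS[key]))


@dataclass
class ResponseSurfaceModel:
    """Quadratic BS model for one surface material.

    coefficients in the basis (1, X, Y, XY, X^2, Y^2); source is
    'fitted' (OLS on grid data) or 'printed' (published equation).
    standardized_effects are the centred coded-unit first-order effects
    of each factor (derivative at the design centre times the factor
    half-range) — the basis for the height-vs-angle importance ranking.
    """

    surface_material: str
    coefficients: np.ndarray
    source: str = "fitted"
    r_squared: Optional[float] = None
    p_values: Optional[np.ndarray] = None
    standardized_effects: Optional[dict] = None
    _sm_results: object = field(default=None, repr=False, compare=False)

    def predict(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        b = self.coefficients
        return b[0] + b[1] * x + b[2] * y + b[3] * x * y + b[4] * x * x + b[5] * y * y

    def summary(self) -> str:
        lines = [
            f"Response surface ({self.source}) for {self.surface_material}",
            "BS = b0 + bX*X + bY*Y + bXY*X*Y + bXX*X^2 + bYY*Y^2",
        ]
        names = ["b0", "bX", "bY", "bXY", "bXX", "bYY"]
        for i, n in enumerate(names):
            p = f"  p={self.p_values[i]:.4f}" if self.p_values is not None else ""
            lines.append(f"  {n:>3} = {self.coefficients[i]:12.4f}{p}")
        if self.r_squared is not None:
            lines.append(f"  R^2 = {self.r_squared:.4f}  (df_resid = 3 for the 3x3 grid)")
        if self.standardized_effects:
            se = self.standardized_effects
            lines.append(
                f"  standardized effects: height {se['height']:.1f}, "
                f"angle {se['angle']:.1f} mm^3/J"
            )
        return "\n".join(lines)


def printed_model(material: str) -> ResponseSurfaceModel:
    return ResponseSurfaceModel(
        surface_material=material.lower(),
        coefficients=np.array(PRINTED_MODELS[material.lower()]),
        source="printed",
    )


def fit_quadratic_surface(
    heights: Sequence[float],
    angles: Sequence[float],
    bs_values: Sequence[float],
    surface_material: str = "",
) -> ResponseSurfaceModel:
    """OLS fit of the quadratic response surface in raw units.

    heights, angles, bs_values are aligned 1-D sequences (one entry per
    design point).  Raises on a rank-deficient design, naming the
    confounded columns.
    """
    import statsmodels.api as sm

    x = np.asarray(heights, dtype=float)
    y = np.asarray(angles, dtype=float)
    z = np.asarray(bs_values, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("heights, angles and bs_values must be aligned 1-D")
    if x.size < 6:
        raise ValueError("need at least 6 design points for 6 coefficients")
    a = np.column_stack([_design_row(xi, yi) for xi, yi in zip(x, y)]).T
    rank = np.linalg.matrix_rank(a)
    if rank < 6:
        names = np.array(["1", "X", "Y", "XY", "X^2", "Y^2"])
        _, s, vt = np.linalg.svd(a)
        null = vt[rank:]
        confounded = names[np.any(np.abs(null) > 1e-8, axis=0)]
        raise ValueError(
            f"rank-deficient design (rank {rank} < 6); confounded terms: "
            + ", ".join(confounded)
        )
    res = sm.OLS(z, a).fit()
    coef = np.asarray(res.params, dtype=float)
    # coded-unit first-order effects at the design centre
    xc, xh = (x.max() + x.min()) / 2.0, (x.max() - x.min()) / 2.0
    yc, yh = (y.max() + y.min()) / 2.0, (y.max() - y.min()) / 2.0
    eff_x = (coef[1] + coef[3] * yc + 2 * coef[4] * xc) * xh
    eff_y = (coef[2] + coef[3] * xc + 2 * coef[5] * yc) * yh
    return ResponseSurfaceModel(
        surface_material=surface_material,
        coefficients=coef,
        source="fitted",
        r_squared=float(res.rsquared),
        p_values=np.asarray(res.pvalues, dtype=float),
        standardized_effects={"height": float(eff_x), "angle": float(eff_y)},
        _sm_results=res,
    )


def find_extrema(
    model: ResponseSurfaceModel,
    x_bounds: tuple[float, float] = (0.25, 1.0),
    y_bounds: tuple[float, float] = (0.0, 90.0),
) -> dict:
    """Extrema of the quadratic on the factor box: closed-form interior
    critical point plus a grid+polish search of the boundary."""
    from scipy import optimize

    b = model.coefficients
    # critical point: grad = 0 -> [2bXX, bXY; bXY, 2bYY] [x, y] = -[bX, bY]
    h = np.array([[2 * b[4], b[3]], [b[3], 2 * b[5]]])
    candidates = []
    if abs(np.linalg.det(h)) > 1e-12:
        crit = np.linalg.solve(h, -np.array([b[1], b[2]]))
        if x_bounds[0] <= crit[0] <= x_bounds[1] and y_bounds[0] <= crit[1] <= y_bounds[1]:
            candidates.append(tuple(crit))
    xs = np.linspace(*x_bounds, 41)
    ys = np.linspace(*y_bounds, 41)
    gx, gy = np.meshgrid(xs, ys)
    vals = model.predict(gx, gy)
    for pick in (np.argmin(vals), np.argmax(vals)):
        x0 = np.array([gx.ravel()[pick], gy.ravel()[pick]])
        for sign in (1.0, -1.0):
            r = optimize.minimize(
                lambda p: sign * model.predict(p[0], p[1]),
                x0,
                bounds=[x_bounds, y_bounds],
                method="L-BFGS-B",
            )
            candidates.append(tuple(r.x))
    pts = np.array(candidates)
    v = model.predict(pts[:, 0], pts[:, 1])
    imin, imax = int(np.argmin(v)), int(np.argmax(v))
    return {
        "min": {"x": pts[imin, 0], "y": pts[imin, 1], "value": float(v[imin])},
        "max": {"x": pts[imax, 0], "y": pts[imax, 1], "value": float(v[imax])},
    }


# ---------------------------------------------------------------------------
# Rebound
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReboundMetrics:
    """Impact/rebound kinematics of the fruit's centre of mass."""

    impact_speed: float
    rebound_speed: float
    restitution: float
    rebound_height: float
    complete: bool = True


def rebound_metrics(result: SimulationResult, gravity: float = 9.8) -> ReboundMetrics:
    """Restitution e = v_rebound/v0 and rebound height v_r^2/(2g).

    The rebound speed is the largest upward COM speed after the fruit
    separates from the surface (contact force back to zero); flagged
    incomplete if separation never happens within the simulated window.
    """
    fc = result.contact_force_total
    vz = result.com_velocity[:, 2]
    v0 = result.initial_speed
    in_contact = fc > 0
    if not in_contact.any():
        return ReboundMetrics(v0, 0.0, 0.0, 0.0, complete=False)
    last_contact = int(np.nonzero(in_contact)[0][-1])
    complete = last_contact < len(fc) - 1
    v_reb = float(max(vz[last_contact:].max(), 0.0))
    e = v_reb / v0 if v0 > 0 else 0.0
    return ReboundMetrics(
        impact_speed=v0,
        rebound_speed=v_reb,
        restitution=e,
        rebound_height=v_reb**2 / (2.0 * gravity),
        complete=complete,
    )


# ---------------------------------------------------------------------------
# Scenario grid
# ---------------------------------------------------------------------------

@dataclass
class GridCell:
    surface: str
    height: float
    angle: float
    report: Optional[DamageReport] = None
    peak_force: float = np.nan
    peak_flesh_stress: float = np.nan
    rebound: Optional[ReboundMetrics] = None
    failed: bool = False
    failure_reason: str = ""


@dataclass
class ScenarioGrid:
    """Results of the complete 3x3x3 factorial sweep."""

    cells: list[GridCell]
    element_size: float
    energy_definition: str = "internal_peak"

    def cell(self, surface: str, height: float, angle: float) -> GridCell:
        for c in self.cells:
            if (
                c.surface == surface
                and np.isclose(c.height, height)
                and np.isclose(c.angle, angle)
            ):
                return c
        raise KeyError(f"no cell ({surface}, {height}, {angle})")

    _DF_COLUMNS = (
        "material", "height_m", "angle_deg", "Vb_mm3", "Et_J", "BS_mm3_per_J",
        "peak_force_N", "peak_vm_MPa", "restitution", "failed",
    )

    def to_dataframe(self):
        import pandas as pd

        if not self.cells:
            return pd.DataFrame(columns=list(self._DF_COLUMNS))
        rows = []
        for c in self.cells:
            r = c.report
            rows.append(
                {
                    "material": c.surface,
                    "height_m": c.height,
                    "angle_deg": c.angle,
                    "Vb_mm3": r.bruise_volume if r else np.nan,
                    "Et_J": r.absorbed_energy if r else np.nan,
                    "BS_mm3_per_J": r.bruise_susceptibility if r else np.nan,
                    "peak_force_N": c.peak_force,
                    "peak_vm_MPa": c.peak_flesh_stress,
                    "restitution": c.rebound.restitution if c.rebound else np.nan,
                    "failed": c.failed,
                }
            )
        return pd.DataFrame(rows)

    def fit_surface_models(self) -> dict[str, ResponseSurfaceModel]:
        models = {}
        for surf in SURFACES:
            pts = [
                c for c in self.cells if c.surface == surf and not c.failed and c.report
            ]
            if len(pts) >= 6:
                models[surf] = fit_quadratic_surface(
                    [c.height for c in pts],
                    [c.angle for c in pts],
                    [c.report.bruise_susceptibility for c in pts],
                    surface_material=surf,
                )
        return models


def run_scenario_grid(
    element_size: float = 3.0,
    geometry: Optional[FruitGeometry] = None,
    materials: Optional[dict[str, MaterialParams]] = None,
    config: SolverConfig = SolverConfig(),
    thresholds: DamageThresholds = DamageThresholds(),
    heights: Sequence[float] = HEIGHTS,
    angles: Sequence[float] = ANGLES,
    surfaces: Sequence[str] = SURFACES,
    seed: int = 0,
    energy_definition: str = "internal_peak",
    progress: Optional[Callable[[str], None]] = None,
    cache: Optional[dict] = None,
) -> ScenarioGrid:
    """Run the factorial sweep (27 cells by default) on one shared mesh.

    A cell that goes unstable is marked failed and the grid completes.
    ``cache`` (a dict) makes the sweep resumable: finished cells are
    reused across calls with the same key.
    """
    geometry = geometry or build_fruit_geometry()
    materials = materials or default_materials()
    mesh = generate_mesh(geometry, element_size, seed=seed)
    cells: list[GridCell] = []
    for surf, h, ang in itertools.product(surfaces, heights, angles):
        key = (surf, float(h), float(ang), float(element_size))
        if cache is not None and key in cache:
            cells.append(cache[key])
            continue
        if progress:
            progress(f"running {surf} h={h} m angle={ang} deg")
        cell = GridCell(surface=surf, height=float(h), angle=float(ang))
        try:
            scn = DropScenario(
                height=float(h),
                collision_angle=float(ang),
                surface_material=get_material(surf),
                element_size=element_size,
            )
            res = run_drop_simulation(mesh, materials, scn, config)
            cell.report = damage_report(
                res, mesh, thresholds, energy_definition=energy_definition
            )
            cell.peak_force = res.peak_contact_force
            cell.peak_flesh_stress = res.peak_flesh_stress
            cell.rebound = rebound_metrics(res, gravity=scn.gravity)
        except SimulationInstabilityError as exc:
            cell.failed = True
            cell.failure_reason = str(exc)
        cells.append(cell)
        if cache is not None:
            cache[key] = cell
    return ScenarioGrid(
        cells=cells, element_size=element_size, energy_definition=energy_definition
    )


# ---------------------------------------------------------------------------
# Mesh sensitivity
# ---------------------------------------------------------------------------

def mesh_sensitivity_study(
    sizes: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
    height: float = 0.5,
    angle: float = 0.0,
    surface: str = "steel",
    geometry: Optional[FruitGeometry] = None,
    materials: Optional[dict[str, MaterialParams]] = None,
    config: SolverConfig = SolverConfig(),
    tolerance: float = 0.05,
    mesh_factory: Optional[Callable[[float], object]] = None,
    plasticity: bool = True,
    use_skin: bool = True,
    sim_duration: float = 0.02,
) -> dict:
    """Grid-sensitivity study of the reference drop scenario.

    Runs the same scenario on meshes of each element size and reports
    per size the element count and peak equivalent stress, plus the
    coarsest size whose peak stress is within ``tolerance`` of the
    finest.  Non-monotone convergence is reported, not fatal.
    """
    sizes = sorted(float(s) for s in sizes)
    if any(not 0.5 <= s <= 10.0 for s in sizes):
        raise ValueError("sizes must lie in [0.5, 10] mm")
    geometry = geometry or build_fruit_geometry()
    materials = materials or default_materials()
    rows = []
    for s in sizes:
        mesh = mesh_factory(s) if mesh_factory else generate_mesh(geometry, s)
        scn = DropScenario(
            height=height,
            collision_angle=angle,
            surface_material=get_material(surface),
            element_size=s,
            sim_duration=sim_duration,
        )
        res = run_drop_simulation(
            mesh, materials, scn, config, plasticity=plasticity, use_skin=use_skin
        )
        rows.append(
            {
                "element_size_mm": s,
                "elements": mesh.n_tets,
                "peak_vm_MPa": res.peak_flesh_stress,
                "peak_force_N": res.peak_contact_force,
            }
        )
    finest = rows[0]["peak_vm_MPa"]
    converged = [
        r["element_size_mm"]
        for r in rows
        if finest > 0 and abs(r["peak_vm_MPa"] - finest) <= tolerance * finest
    ]
    diffs = np.diff([r["peak_vm_MPa"] for r in rows])
    return {
        "rows": rows,
        "recommended_size": max(converged) if converged else rows[0]["element_size_mm"],
        "monotone": bool(np.all(diffs <= 0) or np.all(diffs >= 0)),
        "tolerance": tolerance,
    }
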