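"""Explicit-dynamics finite element drop-impact solver.

The fruit mesh (constant-strain tetrahedra for flesh and core, a bonded
triangular membrane for the 0.3 mm skin) is dropped onto a rigid plane
at z=0 carrying an elastic-foundation penalty whose stiffness derives
from the contact-surface material's modulus.  Time integration is the
standard lumped-mass central-difference scheme; the tissues follow J2
(von Mises) bilinear elastoplasticity with linear isotropic hardening
H = E*Et/(E-Et) and a radial-return stress update; the skin membrane is
elastic-perfectly-plastic in plane stress.  All elements are fully
integrated (single-point exact for linear elements), so hourglass
control is unnecessary and the hourglass energy channel is identically
zero.

Orientation convention for the collision angle: theta is the angle
between the fruit's long (polar) axis and the contact plane — 0 deg is
an equatorial (side) impact with maximal contact area, 90 deg an end
impact on the fruit tip.

Internally the solver works in SI (m, kg, s, Pa); inputs and reported
results use the laboratory units (mm meshes, N forces, MPa stresses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .synthetic_fruit import FruitMesh, REGION_CORE, REGION_FLESH
from .tissue_mechanics import MaterialParams, get_material

__all__ = [
    "DropScenario",
    "SolverConfig",
    "SimulationResult",
    "SimulationInstabilityError",
    "initial_velocity",
    "stable_time_step",
    "radial_return_update",
    "PlasticState",
    "contact_force",
    "run_drop_simulation",
    "uniaxial_stress_response",
    "default_materials",
]

GRAVITY = 9.8  # m/s^2, as used throughout the study


class SimulationInstabilityError(RuntimeError):
    """Raised when the explicit integration loses stability (energy
    growth beyond tolerance, inverted elements, or non-finite state)."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the explicit solver.

    time_step_safety : Courant factor on the stable time step.
    penalty_reference_thickness : foundation layer thickness h_ref (mm);
        contact pressure is E_surf/h_ref * penetration.
    foundation_modulus_cap : cap (MPa) on the effective foundation
        modulus.  Very stiff plates (steel) otherwise drive the penalty
        node-spring frequency, and hence the stable time step, far below
        the element limit while the plate is already effectively rigid
        relative to fruit tissue; the cap is a standard explicit-contact
        regularization and leaves compliant surfaces (PVC, neoprene)
        untouched.
    bulk_viscosity_linear : linear bulk-viscosity coefficient b1.
    output_interval : record the time series every this many steps.
    contact_friction : Coulomb coefficient (0 = frictionless default).
    nodal_pressure_averaging : volumetric-strain nodal averaging to
        relieve mild locking of linear tets at nu ~ 0.4.
    instability_tolerance : allowed |energy balance error| as a fraction
        of the initial kinetic energy before the run aborts.
    """

    time_step_safety: float = 0.9
    penalty_reference_thickness: float = 10.0
    foundation_modulus_cap: float = 250.0
    bulk_viscosity_linear: float = 0.06
    output_interval: int = 1
    contact_friction: float = 0.0
    nodal_pressure_averaging: bool = False
    instability_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.time_step_safety <= 1:
            raise ValueError("time_step_safety must be in (0, 1]")
        if self.penalty_reference_thickness <= 0:
            raise ValueError("penalty_reference_thickness must be > 0")
        if self.contact_friction != 0.0:
            raise NotImplementedError("only frictionless contact is implemented")


@dataclass(frozen=True)
class DropScenario:
    """One drop case: height (m), collision angle (deg), surface material.

    The impact velocity is the free-fall speed v0 = sqrt(2 g h); the
    fruit starts tangent to the plane with that downward velocity and
    gravity stays on for the whole 0.02 s event.
    """

    height: float
    collision_angle: float
    surface_material: MaterialParams
    gravity: float = GRAVITY
    sim_duration: float = 0.02
    element_size: float = 2.0

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("height must be >= 0")
        if not 0 <= self.collision_angle <= 90:
            raise ValueError("collision_angle must be in [0, 90] deg")
        if self.sim_duration <= 0:
            raise ValueError("sim_duration must be > 0")

    @property
    def initial_speed(self) -> float:
        return initial_velocity(self.height, self.gravity)


def initial_velocity(height: float, gravity: float = GRAVITY) -> float:
    """Free-fall impact speed v0 = sqrt(2 g h) (m/s), directed downward."""
    if height < 0:
        raise ValueError("height must be >= 0")
    return float(np.sqrt(2.0 * gravity * height))


def default_materials() -> dict[str, MaterialParams]:
    """Tissue assignment used by the drop model: skin membrane, flesh
    and core solids, from the built-in library."""
    return {
        "skin": get_material("skin"),
        "flesh": get_material("flesh"),
        "core": get_material("core"),
    }


# ---------------------------------------------------------------------------
# Constitutive update (reference implementation; the solver kernel
# duplicates this logic in compiled form and is tested against it)
# ---------------------------------------------------------------------------

@dataclass
class PlasticState:
    """Stress (Pa or MPa, caller's choice — consistent units) and
    accumulated equivalent plastic strain at one material point."""

    stress: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    eqps: float = 0.0


def radial_return_update(
    strain_increment: np.ndarray,
    state: PlasticState,
    material: MaterialParams,
) -> tuple[np.ndarray, PlasticState]:
    """One J2 radial-return step with linear isotropic hardening.

    strain_increment : (3,3) symmetric tensor (tensor shear components).
    Stress units follow the material's modulus units (MPa in, MPa out).
    Plasticity is active only when the material has a bio-yield stress;
    the hardening modulus is H = E*Et/(E-Et) (0 for perfectly plastic).
    """
    e = material.young_modulus
    nu = material.poisson_ratio
    if material.tangent_modulus is not None and material.tangent_modulus >= e:
        raise ValueError("tangent modulus must be < Young's modulus")
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    de = np.asarray(strain_increment, dtype=float)
    if de.shape != (3, 3) or not np.allclose(de, de.T):
        raise ValueError("strain_increment must be a symmetric (3,3) tensor")
    trial = state.stress + lam * np.trace(de) * np.eye(3) + 2 * mu * de
    dev = trial - np.trace(trial) / 3.0 * np.eye(3)
    vm = float(np.sqrt(1.5 * np.sum(dev * dev)))
    new = PlasticState(stress=trial, eqps=state.eqps)
    if material.bio_yield_stress is not None:
        h = material.hardening_modulus
        f = vm - (material.bio_yield_stress + h * state.eqps)
        if f > 0:
            dg = f / (3 * mu + h)
            new.stress = trial - 3 * mu * dg / vm * dev
            new.eqps = state.eqps + dg
    return new.stress, new


def uniaxial_stress_response(
    material: MaterialParams, axial_strains: np.ndarray
) -> np.ndarray:
    """Uniaxial-stress path driven through the radial-return map.

    The lateral strain increment is iterated at every step so the
    lateral stresses vanish, giving the engineering stress–strain
    response an extensometer would see (slope E, then Et past yield).
    """
    eps = np.asarray(axial_strains, dtype=float)
    state = PlasticState()
    out = np.zeros_like(eps)
    prev = 0.0
    lat_guess = 0.0
    for i, ea in enumerate(eps):
        dea = ea - prev
        prev = ea
        # solve for lateral increment d such that sigma_yy = sigma_zz = 0
        d = -material.poisson_ratio * dea if lat_guess == 0.0 else lat_guess

        def lateral_stress(dl: float) -> float:
            de = np.diag([dea, dl, dl])
            s, _ = radial_return_update(de, state, material)
            return float(s[1, 1])

        # secant iteration
        d0, d1 = d, d * 0.9 - 1e-9
        g0, g1 = lateral_stress(d0), lateral_stress(d1)
        for _ in range(40):
            if g1 == g0:
                break
            d2 = d1 - g1 * (d1 - d0) / (g1 - g0)
            d0, g0 = d1, g1
            d1 = d2
            g1 = lateral_stress(d1)
            if abs(g1) < 1e-12 * material.young_modulus + 1e-15:
                break
        de = np.diag([dea, d1, d1])
        s, state = radial_return_update(de, state, material)
        lat_guess = d1
        out[i] = s[0, 0]
    return out


# ---------------------------------------------------------------------------
# Stable time step
# ---------------------------------------------------------------------------

def _elastic_moduli_si(mat: MaterialParams) -> tuple[float, float]:
    e = mat.young_modulus * 1e6
    nu = mat.poisson_ratio
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    return lam, mu


def _cst_stiffness(coords: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """12x12 stiffness of one linear tetrahedron (coords in m, moduli Pa)."""
    d = (coords[1:] - coords[0]).T
    det = np.linalg.det(d)
    vol = det / 6.0
    dinv = np.linalg.inv(d)
    g = np.zeros((4, 3))
    g[1:] = dinv
    g[0] = -dinv.sum(axis=0)
    b = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = g[a]
        b[0, 3 * a] = gx
        b[1, 3 * a + 1] = gy
        b[2, 3 * a + 2] = gz
        b[3, 3 * a] = gy
        b[3, 3 * a + 1] = gx
        b[4, 3 * a + 1] = gz
        b[4, 3 * a + 2] = gy
        b[5, 3 * a] = gz
        b[5, 3 * a + 2] = gx
    c = np.zeros((6, 6))
    c[:3, :3] = lam
    c[np.arange(3), np.arange(3)] += 2 * mu
    c[np.arange(3, 6), np.arange(3, 6)] = mu
    return vol * b.T @ c @ b


def _materials_per_tet(mesh: FruitMesh, materials: dict[str, MaterialParams]):
    names = {REGION_FLESH: "flesh", REGION_CORE: "core"}
    region_to_mat = {
        int(r): materials[names[int(r)]] for r in np.unique(mesh.region)
    }
    return list(region_to_mat.values()), region_to_mat


def stable_time_step(
    mesh: FruitMesh,
    materials: dict[str, MaterialParams],
    config: SolverConfig = SolverConfig(),
    surface_material: Optional[MaterialParams] = None,
) -> float:
    """Courant-stable time step (s).

    Element bound: dt_e = 2/omega_max with omega_max the largest
    eigenfrequency of each lumped-mass element (exact per-element
    Rayleigh bound; for a single-element mesh this equals the assembled
    value).  If a contact surface is given, the penalty node-spring
    frequency additionally bounds dt.  The configured safety factor
    multiplies the result.
    """
    pts = mesh.points * 1e-3
    _, region_to_mat = _materials_per_tet(mesh, materials)
    vols = mesh.tet_volumes()
    if np.any(vols <= 0):
        bad = int(np.argmin(vols))
        raise ValueError(f"degenerate element {bad} (volume {vols[bad]:g} mm^3)")
    dt_min = np.inf
    for e in range(mesh.n_tets):
        mat = region_to_mat[int(mesh.region[e])]
        lam, mu = _elastic_moduli_si(mat)
        coords = pts[mesh.tets[e]]
        k = _cst_stiffness(coords, lam, mu)
        vol = vols[e] * 1e-9
        m_node = mat.density * vol / 4.0
        w2 = np.linalg.eigvalsh(k).max() / m_node
        dt_min = min(dt_min, 2.0 / np.sqrt(w2))
    # membrane bound: min altitude / plane-stress wave speed
    if mesh.skin_tris.shape[0] and "skin" in materials:
        skin = materials["skin"]
        c = np.sqrt(skin.young_modulus * 1e6 / ((1 - skin.poisson_ratio**2) * skin.density))
        p = pts[mesh.skin_tris]
        e0 = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        e1 = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
        e2 = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
        areas = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        lmin = 2.0 * areas / np.maximum(e0, np.maximum(e1, e2))
        dt_min = min(dt_min, float(lmin.min()) / c)
    if surface_material is not None:
        k_found = _foundation_stiffness(surface_material, config)
        areas, masses = _surface_node_areas_masses(mesh, materials)
        w = np.sqrt(k_found * areas / masses)
        dt_min = min(dt_min, float((2.0 / w).min()))
    return config.time_step_safety * float(dt_min)


def _foundation_stiffness(surface: MaterialParams, config: SolverConfig) -> float:
    """Foundation stiffness per unit area, Pa/m."""
    e_eff = min(surface.young_modulus, config.foundation_modulus_cap) * 1e6
    return e_eff / (config.penalty_reference_thickness * 1e-3)


def _lumped_masses(mesh: FruitMesh, materials: dict[str, MaterialParams]) -> np.ndarray:
    """Nodal masses (kg): rho*V/4 per tet node plus rho*A*t/3 per skin node."""
    _, region_to_mat = _materials_per_tet(mesh, materials)
    rho_e = np.array([region_to_mat[int(r)].density for r in mesh.region])
    vols = mesh.tet_volumes() * 1e-9
    mass = np.zeros(mesh.n_nodes)
    np.add.at(mass, mesh.tets.ravel(), np.repeat(rho_e * vols / 4.0, 4))
    if mesh.skin_tris.shape[0] and "skin" in materials:
        skin = materials["skin"]
        a = mesh.skin_areas() * 1e-6
        tri_mass = skin.density * a * (mesh.skin_thickness * 1e-3) / 3.0
        np.add.at(mass, mesh.skin_tris.ravel(), np.repeat(tri_mass, 3))
    return mass


def _surface_node_areas_masses(mesh, materials):
    areas_tri = mesh.skin_areas() * 1e-6
    area_node = np.zeros(mesh.n_nodes)
    np.add.at(area_node, mesh.skin_tris.ravel(), np.repeat(areas_tri / 3.0, 3))
    mass = _lumped_masses(mesh, materials)
    sn = mesh.skin_nodes
    return area_node[sn], mass[sn]


# ---------------------------------------------------------------------------
# Contact
# ---------------------------------------------------------------------------

def contact_force(
    node_positions_mm: np.ndarray,
    mesh: FruitMesh,
    surface: MaterialParams,
    config: SolverConfig = SolverConfig(),
) -> tuple[np.ndarray, float]:
    """Elastic-foundation penalty forces against the plane z=0.

    For every penetrating skin node the pressure E_surf/h_ref times the
    penetration acts over the node's tributary area.  Returns (nodal
    forces (n,3) in N, stored contact energy in J).
    """
    pos = np.asarray(node_positions_mm, dtype=float) * 1e-3
    k_found = _foundation_stiffness(surface, config)
    areas_tri = mesh.skin_areas() * 1e-6
    area_node = np.zeros(mesh.n_nodes)
    np.add.at(area_node, mesh.skin_tris.ravel(), np.repeat(areas_tri / 3.0, 3))
    forces = np.zeros_like(pos)
    z = pos[mesh.skin_nodes, 2]
    pen = np.where(z < 0.0, -z, 0.0)
    k_node = k_found * area_node[mesh.skin_nodes]
    forces[mesh.skin_nodes, 2] = k_node * pen
    ce = float(0.5 * np.sum(k_node * pen**2))
    return forces, ce


# ---------------------------------------------------------------------------
# Drop simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Time series, energy audit, and per-element peak fields of one run.

    Times in s, forces in N, velocities in m/s, energies in J, stresses
    in MPa, displacements in mm.  internal_energy is the accumulated
    stress power (elastic strain energy + plastic dissipation);
    elastic_energy and plastic_energy report the split.
    hourglass_energy is identically zero (fully integrated elements).
    """

    times: np.ndarray
    contact_force_total: np.ndarray
    com_velocity: np.ndarray
    kinetic_energy: np.ndarray
    internal_energy: np.ndarray
    elastic_energy: np.ndarray
    plastic_energy: np.ndarray
    contact_energy: np.ndarray
    viscous_energy: np.ndarray
    hourglass_energy: np.ndarray
    gravity_work: np.ndarray
    energy_error: np.ndarray
    peak_von_mises: np.ndarray
    peak_von_mises_skin: np.ndarray
    plastic_strain: np.ndarray
    plastic_strain_skin: np.ndarray
    final_displacement: np.ndarray
    region: np.ndarray
    element_volumes: np.ndarray
    skin_areas: np.ndarray
    total_mass: float
    initial_speed: float
    dt: float
    scenario: Optional[DropScenario] = None

    @property
    def peak_contact_force(self) -> float:
        return float(self.contact_force_total.max())

    def peak_von_mises_region(self, region: int) -> float:
        sel = self.peak_von_mises[self.region == region]
        return float(sel.max()) if sel.size else 0.0

    @property
    def peak_flesh_stress(self) -> float:
        return self.peak_von_mises_region(REGION_FLESH)

    @property
    def max_energy_error_fraction(self) -> float:
        """Energy-balance error relative to the dominant energy scale of
        the run (initial KE for a drop; the largest energy channel for a
        quasi-static settling run)."""
        scale = max(
            float(self.kinetic_energy[0]),
            float(self.kinetic_energy.max()),
            float(self.internal_energy.max()),
            float(self.contact_energy.max()),
            float(np.abs(self.gravity_work).max()),
            1e-30,
        )
        return float(np.abs(self.energy_error).max() / scale)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "contact_force_N": self.contact_force_total,
                "com_velocity_mps": self.com_velocity[:, 2],
                "ke_J": self.kinetic_energy,
                "ie_J": self.internal_energy,
                "ce_J": self.contact_energy,
                "plastic_J": self.plastic_energy,
                "hourglass_J": self.hourglass_energy,
            }
        )


def _rotation_about_y(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.array(
        [[np.cos(t), 0.0, np.sin(t)], [0.0, 1.0, 0.0], [-np.sin(t), 0.0, np.cos(t)]]
    )


def run_drop_simulation(
    mesh: FruitMesh,
    materials: dict[str, MaterialParams],
    scenario: DropScenario,
    config: SolverConfig = SolverConfig(),
    plasticity: bool = True,
    use_skin: bool = True,
) -> SimulationResult:
    """Run one drop-impact event and return the full result.

    The mesh's long axis (x) is rotated by the collision angle about y,
    the fruit is placed tangent to the plane (zero gap), given the
    uniform downward free-fall velocity, and integrated for the
    scenario's duration.  Deterministic for fixed inputs.

    plasticity=False freezes all yield surfaces (purely elastic run,
    used by the Hertz-contact and restitution oracles); use_skin=False
    drops the membrane (bare solid).
    """
    rot = _rotation_about_y(scenario.collision_angle)
    pts = mesh.points @ rot.T
    pts = pts - [0.0, 0.0, pts[:, 2].min()]
    x = np.ascontiguousarray(pts * 1e-3)
    v = np.zeros_like(x)
    v[:, 2] = -scenario.initial_speed

    mats = dict(materials)
    if not use_skin:
        mats.pop("skin", None)
    use_membrane = use_skin and "skin" in mats and mesh.skin_tris.shape[0] > 0

    mass = _lumped_masses(mesh, mats if use_membrane else {k: v_ for k, v_ in mats.items() if k != "skin"})

    _, region_to_mat = _materials_per_tet(mesh, mats)
    ne = mesh.n_tets
    lam_e = np.zeros(ne)
    mu_e = np.zeros(ne)
    sy_e = np.full(ne, 1e300)
    h_e = np.zeros(ne)
    rho_e = np.zeros(ne)
    for rid, mat in region_to_mat.items():
        sel = mesh.region == rid
        lam, mu = _elastic_moduli_si(mat)
        lam_e[sel] = lam
        mu_e[sel] = mu
        rho_e[sel] = mat.density
        if plasticity and mat.bio_yield_stress is not None:
            sy_e[sel] = mat.bio_yield_stress * 1e6
            h_e[sel] = mat.hardening_modulus * 1e6
    vols = mesh.tet_volumes() * 1e-9
    # characteristic length for bulk viscosity: min altitude = 3V/A_max
    p = x
    t = mesh.tets
    amax = np.zeros(ne)
    for fidx in [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]:
        nrm = np.cross(
            p[t[:, fidx[1]]] - p[t[:, fidx[0]]], p[t[:, fidx[2]]] - p[t[:, fidx[0]]]
        )
        amax = np.maximum(amax, 0.5 * np.linalg.norm(nrm, axis=1))
    lchar_e = 3.0 * vols / amax

    if use_membrane:
        skin = mats["skin"]
        tri = mesh.skin_tris
        nt = tri.shape[0]
        lam_s, mu_s = _elastic_moduli_si(skin)
        tlam = np.full(nt, lam_s)
        tmu = np.full(nt, mu_s)
        tsy = np.full(
            nt,
            skin.bio_yield_stress * 1e6
            if (plasticity and skin.bio_yield_stress is not None)
            else 1e300,
        )
        th_h = np.full(nt, skin.hardening_modulus * 1e6 if plasticity else 0.0)
        tthk = np.full(nt, mesh.skin_thickness * 1e-3)
        trho = np.full(nt, skin.density)
    else:
        tri = np.empty((0, 3), dtype=np.int32)
        tlam = tmu = tsy = th_h = tthk = trho = np.empty(0)

    k_found = _foundation_stiffness(scenario.surface_material, config)
    areas_tri = mesh.skin_areas() * 1e-6
    area_node = np.zeros(mesh.n_nodes)
    np.add.at(area_node, mesh.skin_tris.ravel(), np.repeat(areas_tri / 3.0, 3))
    surf_nodes = mesh.skin_nodes.astype(np.int64)
    trib_area = area_node[surf_nodes]

    dt = stable_time_step(mesh, mats, config, scenario.surface_material)
    nsteps = max(1, int(np.ceil(scenario.sim_duration / dt)))
    out_every = max(1, int(config.output_interval))
    n_out = nsteps // out_every + 2

    sig = np.zeros((ne, 6))
    eqps = np.zeros(ne)
    qvisc = np.zeros(ne)
    peak_vm = np.zeros(ne)
    sig_tri = np.zeros((max(tri.shape[0], 1), 4))[: tri.shape[0]]
    if tri.shape[0] == 0:
        sig_tri = np.zeros((0, 4))
    eqps_tri = np.zeros(tri.shape[0])
    peak_vm_tri = np.zeros(tri.shape[0])

    times = np.zeros(n_out)
    fc_out = np.zeros(n_out)
    vcom_out = np.zeros((n_out, 3))
    ke_out = np.zeros(n_out)
    ie_out = np.zeros(n_out)
    ue_out = np.zeros(n_out)
    wp_out = np.zeros(n_out)
    ce_out = np.zeros(n_out)
    qv_out = np.zeros(n_out)
    wg_out = np.zeros(n_out)
    err_out = np.zeros(n_out)

    x_work = x.copy()
    status, n_rec = _kernel.run_explicit(
        x_work,
        v,
        mass,
        np.ascontiguousarray(mesh.tets, dtype=np.int64),
        lam_e,
        mu_e,
        sy_e,
        h_e,
        rho_e,
        lchar_e,
        np.ascontiguousarray(tri, dtype=np.int64),
        tlam,
        tmu,
        tsy,
        th_h,
        tthk,
        trho,
        surf_nodes,
        trib_area,
        k_found,
        scenario.gravity,
        dt,
        nsteps,
        out_every,
        config.bulk_viscosity_linear,
        config.nodal_pressure_averaging,
        sig,
        eqps,
        qvisc,
        peak_vm,
        sig_tri,
        eqps_tri,
        peak_vm_tri,
        times,
        fc_out,
        vcom_out,
        ke_out,
        ie_out,
        ue_out,
        wp_out,
        ce_out,
        qv_out,
        wg_out,
        err_out,
    )
    if status == _kernel.STATUS_INVERTED:
        raise SimulationInstabilityError("element inverted during integration")
    if status == _kernel.STATUS_NAN:
        raise SimulationInstabilityError("non-finite energies during integration")

    sl = slice(0, n_rec)
    result = SimulationResult(
        times=times[sl].copy(),
        contact_force_total=fc_out[sl].copy(),
        com_velocity=vcom_out[sl].copy(),
        kinetic_energy=ke_out[sl].copy(),
        internal_energy=ie_out[sl].copy(),
        elastic_energy=ue_out[sl].copy(),
        plastic_energy=wp_out[sl].copy(),
        contact_energy=ce_out[sl].copy(),
        viscous_energy=qv_out[sl].copy(),
        hourglass_energy=np.zeros(n_rec),
        gravity_work=wg_out[sl].copy(),
        energy_error=err_out[sl].copy(),
        peak_von_mises=peak_vm * 1e-6,
        peak_von_mises_skin=peak_vm_tri * 1e-6,
        plastic_strain=eqps.copy(),
        plastic_strain_skin=eqps_tri.copy(),
        final_displacement=(x_work - x) * 1e3,
        region=mesh.region.copy(),
        element_volumes=mesh.tet_volumes(),
        skin_areas=mesh.skin_areas(),
        total_mass=float(mass.sum()),
        initial_speed=scenario.initial_speed,
        dt=dt,
        scenario=scenario,
    )
    ke0 = result.kinetic_energy[0]
    if ke0 > 0 and result.max_energy_error_fraction > config.instability_tolerance:
        raise SimulationInstabilityError(
            f"energy balance error {result.max_energy_error_fraction:.1%} of the "
            f"initial kinetic energy exceeds the "
            f"{config.instability_tolerance:.0%} tolerance (dt={dt:.3e} s)"
        )
    return result
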