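"""Bruise quantification: damaged volume, skin area, absorbed energy,
and bruise susceptibility BS = Vb/Et.

An element counts as bruised when its peak von Mises stress over the
whole impact strictly exceeds the bio-yield threshold of its tissue
(flesh 0.26 MPa, skin 0.52 MPa, core 1.12 MPa by default) — the von
Mises criterion applied to the peak stress is the conservative reading
of comparing "the stress distribution during the collision" against
yield.  Bruised volume uses undeformed element volumes (deformations
are small and this avoids dependence on output-frame timing); the skin
membrane is reported as a bruised area, not part of Vb.

Absorbed energy Et is, by default, the peak over time of the fruit's
internal energy (elastic strain energy plus plastic dissipation).  The
ratio of damage to energy is not operationally pinned down by a single
convention in the field, so two alternatives are computed alongside:
plastic dissipation only, and the kinetic-energy loss
1/2 m (v0^2 - v_rebound^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .explicit_fem import SimulationResult
from .synthetic_fruit import FruitMesh, REGION_CORE, REGION_FLESH

__all__ = [
    "DamageThresholds",
    "DamageReport",
    "classify_bruised_elements",
    "bruise_volume",
    "bruised_skin_area",
    "absorbed_energy",
    "bruise_susceptibility",
    "damage_report",
]


@dataclass(frozen=True)
class DamageThresholds:
    """Von Mises bruise thresholds per tissue (MPa)."""

    flesh_yield: float = 0.26
    skin_yield: float = 0.52
    core_yield: float = 1.12

    def __post_init__(self) -> None:
        for name in ("flesh_yield", "skin_yield", "core_yield"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def for_region(self, region: int) -> float:
        if region == REGION_FLESH:
            return self.flesh_yield
        if region == REGION_CORE:
            return self.core_yield
        raise KeyError(f"no threshold for region {region}")


EnergyDefinition = Literal["internal_peak", "plastic", "kinetic_loss"]


@dataclass
class DamageReport:
    """Damage quantities of one simulated drop.

    bruise_volume Vb in mm^3 (flesh + core solids), bruised_skin_area in
    mm^2, absorbed_energy Et in J (per the chosen definition),
    bruise_susceptibility BS = Vb/Et in mm^3/J.  degenerate is True when
    Et = 0 (BS reported as 0).
    """

    bruise_volume: float
    bruised_skin_area: float
    absorbed_energy: float
    bruise_susceptibility: float
    flesh_bruise_volume: float
    core_bruise_volume: float
    energy_definition: str = "internal_peak"
    energy_alternatives: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def classify_bruised_elements(
    result: SimulationResult, thresholds: DamageThresholds = DamageThresholds()
) -> np.ndarray:
    """Boolean mask over solid elements: peak von Mises strictly above
    the element's regional threshold."""
    vm = result.peak_von_mises
    mask = np.zeros(vm.shape[0], dtype=bool)
    for region in np.unique(result.region):
        thr = thresholds.for_region(int(region))
        sel = result.region == region
        mask[sel] = vm[sel] > thr
    return mask


def classify_bruised_skin(
    result: SimulationResult, thresholds: DamageThresholds = DamageThresholds()
) -> np.ndarray:
    return result.peak_von_mises_skin > thresholds.skin_yield


def bruise_volume(mask: np.ndarray, mesh_or_volumes) -> float:
    """Total undeformed volume (mm^3) of the masked elements."""
    if isinstance(mesh_or_volumes, FruitMesh):
        vols = mesh_or_volumes.tet_volumes()
    else:
        vols = np.asarray(mesh_or_volumes, dtype=float)
    if mask.shape[0] != vols.shape[0]:
        raise ValueError("mask is not aligned with the element volumes")
    return float(vols[mask].sum())


def bruised_skin_area(mask_skin: np.ndarray, mesh_or_areas) -> float:
    """Total area (mm^2) of skin triangles whose peak stress exceeded
    the skin threshold."""
    if isinstance(mesh_or_areas, FruitMesh):
        areas = mesh_or_areas.skin_areas()
    else:
        areas = np.asarray(mesh_or_areas, dtype=float)
    if mask_skin.shape[0] != areas.shape[0]:
        raise ValueError("mask is not aligned with the skin triangles")
    return float(areas[mask_skin].sum())


def absorbed_energy(
    result: SimulationResult, definition: EnergyDefinition = "internal_peak"
) -> float:
    """Energy (J) absorbed by the fruit during the collision.

    internal_peak : max over time of internal energy (default),
    plastic      : final plastic dissipation,
    kinetic_loss : 1/2 m (v0^2 - v_rebound^2) from the COM velocity.
    """
    if result.times.size == 0:
        raise ValueError("empty time series")
    if definition == "internal_peak":
        return float(result.internal_energy.max())
    if definition == "plastic":
        return float(result.plastic_energy[-1])
    if definition == "kinetic_loss":
        v0 = result.initial_speed
        v_reb = max(float(result.com_velocity[:, 2].max()), 0.0)
        return float(0.5 * result.total_mass * (v0**2 - v_reb**2))
    raise ValueError(f"unknown energy definition {definition!r}")


def bruise_susceptibility(vb: float, et: float) -> tuple[float, bool]:
    """BS = Vb/Et (mm^3/J); returns (value, degenerate flag)."""
    if vb < 0 or et < 0:
        raise ValueError("bruise volume and absorbed energy must be >= 0")
    if et == 0.0:
        return 0.0, True
    return vb / et, False


def damage_report(
    result: SimulationResult,
    mesh: FruitMesh,
    thresholds: DamageThresholds = DamageThresholds(),
    energy_definition: EnergyDefinition = "internal_peak",
) -> DamageReport:
    """Full damage evaluation of one simulation."""
    mask = classify_bruised_elements(result, thresholds)
    vols = result.element_volumes
    vb_flesh = float(vols[mask & (result.region == REGION_FLESH)].sum())
    vb_core = float(vols[mask & (result.region == REGION_CORE)].sum())
    vb = vb_flesh + vb_core
    skin_mask = classify_bruised_skin(result, thresholds)
    skin_area = bruised_skin_area(skin_mask, result.skin_areas)
    et = absorbed_energy(result, energy_definition)
    bs, degenerate = bruise_susceptibility(vb, et)
    alternatives = {
        d: absorbed_energy(result, d)  # type: ignore[arg-type]
        for d in ("internal_peak", "plastic", "kinetic_loss")
    }
    return DamageReport(
        bruise_volume=vb,
        bruised_skin_area=skin_area,
        absorbed_energy=et,
        bruise_susceptibility=bs,
        flesh_bruise_volume=vb_flesh,
        core_bruise_volume=vb_core,
        energy_definition=energy_definition,
        energy_alternatives=alternatives,
        degenerate=degenerate,
    )
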