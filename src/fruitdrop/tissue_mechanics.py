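"""Reduction of force–displacement tests to constitutive parameters.

Fruit tissues (skin, flesh/pulp, core) are characterised by uniaxial
tension/compression tests.  This module converts the recorded
force–displacement curves into engineering stress–strain curves
(sigma = F/S, eps = dL/L), extracts the bilinear elastic–plastic
parameters (Young's modulus E, bio-yield stress sigma_y, tangent modulus
E_t), and carries the built-in library of tissue and contact-surface
materials used by the drop solver.

Units follow the laboratory convention throughout: force in N, lengths in
mm, areas in mm^2, stress/moduli in MPa, density in kg m^-3.  The solver
converts to SI at its own boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional

import numpy as np
from scipy import optimize

__all__ = [
    "ForceDisplacementRecord",
    "StressStrainCurve",
    "MaterialParams",
    "BulkSample",
    "InvalidSpecimenError",
    "UnderdeterminedFitError",
    "compute_stress_strain",
    "fit_bilinear_params",
    "compute_density",
    "make_bilinear_curve",
    "read_force_displacement_csv",
    "load_material_library",
    "get_material",
]


class InvalidSpecimenError(ValueError):
    """Specimen geometry (cross-section, gauge length) is non-physical."""


class UnderdeterminedFitError(ValueError):
    """Too few points to identify the requested parameters."""


Mode = Literal["tension", "compression"]


@dataclass(frozen=True)
class ForceDisplacementRecord:
    """Raw uniaxial test record.

    force : test load F (N); displacement : crosshead travel dL (mm),
    non-decreasing; initial_length : gauge length L (mm);
    cross_section : specimen area S (mm^2).
    """

    force: np.ndarray
    displacement: np.ndarray
    initial_length: float
    cross_section: float
    mode: Mode = "compression"

    def __post_init__(self) -> None:
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        object.__setattr__(self, "displacement", np.asarray(self.displacement, dtype=float))
        if self.force.ndim != 1 or self.displacement.ndim != 1:
            raise InvalidSpecimenError("force and displacement must be 1-D arrays")
        if self.force.size != self.displacement.size:
            raise InvalidSpecimenError("force and displacement must have equal length")
        if self.force.size < 1:
            raise InvalidSpecimenError("record needs at least one sample")
        if self.initial_length <= 0:
            raise InvalidSpecimenError("initial_length must be > 0")
        if self.cross_section <= 0:
            raise InvalidSpecimenError("cross_section must be > 0")
        if np.any(np.diff(self.displacement) < 0):
            raise InvalidSpecimenError("displacement must be non-decreasing")
        if self.mode not in ("tension", "compression"):
            raise InvalidSpecimenError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering stress (MPa) vs strain (dimensionless)."""

    stress: np.ndarray
    strain: np.ndarray
    mode: Mode = "compression"

    def __post_init__(self) -> None:
        object.__setattr__(self, "stress", np.asarray(self.stress, dtype=float))
        object.__setattr__(self, "strain", np.asarray(self.strain, dtype=float))
        if self.stress.size != self.strain.size:
            raise ValueError("stress and strain must have equal length")


@dataclass(frozen=True)
class MaterialParams:
    """One material's constitutive record (tissue or contact surface).

    young_modulus and tangent_modulus in MPa, bio_yield_stress in MPa,
    density in kg m^-3.  tangent_modulus/bio_yield_stress are None for
    materials treated as purely elastic (no plasticity) or, for the skin,
    elastic–perfectly-plastic (yield stress without hardening).
    """

    name: str
    young_modulus: float
    density: float
    poisson_ratio: float
    tangent_modulus: Optional[float] = None
    bio_yield_stress: Optional[float] = None
    spread: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError(f"{self.name}: young_modulus must be > 0")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError(f"{self.name}: poisson_ratio must be in (0, 0.5)")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        if self.tangent_modulus is not None and not (
            0.0 <= self.tangent_modulus < self.young_modulus
        ):
            raise ValueError(f"{self.name}: need 0 <= tangent_modulus < young_modulus")
        if self.bio_yield_stress is not None and self.bio_yield_stress <= 0:
            raise ValueError(f"{self.name}: bio_yield_stress must be > 0")

    @property
    def hardening_modulus(self) -> float:
        """Plastic hardening modulus H = E*Et/(E-Et); 0 if perfectly plastic."""
        if self.tangent_modulus is None or self.tangent_modulus == 0.0:
            return 0.0
        e, et = self.young_modulus, self.tangent_modulus
        return e * et / (e - et)


@dataclass(frozen=True)
class BulkSample:
    """Whole-fruit mass (g) and volume (cm^3) for the density estimate."""

    mass: float
    volume: float

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.volume <= 0:
            raise ValueError("mass and volume must both be > 0")


def compute_stress_strain(record: ForceDisplacementRecord) -> StressStrainCurve:
    """Engineering stress sigma = F/S (MPa) and strain eps = dL/L."""
    sigma = record.force / record.cross_section
    eps = record.displacement / record.initial_length
    return StressStrainCurve(stress=sigma, strain=eps, mode=record.mode)


def compute_density(sample: BulkSample) -> float:
    """Bulk density rho = m/v, converted from g/cm^3 to kg m^-3."""
    return sample.mass / sample.volume * 1000.0


def make_bilinear_curve(
    young_modulus: float,
    yield_stress: float,
    tangent_modulus: float | None = None,
    max_strain: float | None = None,
    n_points: int = 60,
    noise_std: float = 0.0,
    rng: np.random.Generator | None = None,
    mode: Mode = "compression",
) -> StressStrainCurve:
    """Synthesize a bilinear stress–strain curve (generator for the
    fit oracle: fitting its output must recover the inputs).

    The curve rises with slope ``young_modulus`` to ``yield_stress`` then
    continues with slope ``tangent_modulus`` (omit for a purely linear
    curve up to ``max_strain``).  ``noise_std`` is the absolute standard
    deviation (MPa) of Gaussian noise added to the stress.
    """
    e = float(young_modulus)
    sy = float(yield_stress)
    eps_y = sy / e
    if max_strain is None:
        max_strain = 2.5 * eps_y
    eps = np.linspace(0.0, max_strain, n_points)
    if tangent_modulus is None:
        sigma = e * eps
    else:
        et = float(tangent_modulus)
        sigma = np.where(eps <= eps_y, e * eps, sy + et * (eps - eps_y))
    if noise_std > 0.0:
        rng = np.random.default_rng() if rng is None else rng
        sigma = sigma + rng.normal(0.0, noise_std, size=sigma.shape)
        sigma[0] = 0.0
    return StressStrainCurve(stress=sigma, strain=eps, mode=mode)


def _hinge_fit(eps: np.ndarray, sig: np.ndarray, brk: float) -> tuple[np.ndarray, float]:
    """Least-squares continuous piecewise-linear fit with a hinge at brk.

    Basis: [1, eps, max(0, eps-brk)].  Returns (coeffs, SSE).
    """
    a = np.column_stack([np.ones_like(eps), eps, np.maximum(0.0, eps - brk)])
    coef, *_ = np.linalg.lstsq(a, sig, rcond=None)
    resid = sig - a @ coef
    return coef, float(resid @ resid)


def fit_bilinear_params(
    curve: StressStrainCurve,
    density: float,
    poisson_ratio: float,
    name: str = "fitted",
    slope_change_rtol: float = 1e-3,
    smooth_window: int = 0,
) -> MaterialParams:
    """Identify (E, sigma_y, Et) from a monotone stress–strain curve.

    A two-segment continuous piecewise-linear model is fitted by least
    squares; candidate breakpoints are scanned over the interior strain
    samples and the best one polished by a bounded 1-D minimisation of
    the SSE.  The breakpoint stress is reported as the bio-yield stress.
    If the post-yield slope is indistinguishable from the initial slope
    (relative difference below ``slope_change_rtol``) the curve is
    treated as purely linear: Et and sigma_y are absent.

    ``smooth_window`` > 1 applies a centred moving average to the stress
    before fitting (off by default).
    """
    eps = np.asarray(curve.strain, dtype=float)
    sig = np.asarray(curve.stress, dtype=float)
    if np.any(np.diff(eps) <= 0):
        raise ValueError("strain must be strictly increasing for the bilinear fit")
    if eps.size < 6:
        raise UnderdeterminedFitError("need at least 6 points for a bilinear fit")
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(sig, pad, mode="edge")
        sig = np.convolve(padded, kernel, mode="same")[pad:-pad] if pad else sig

    # Scan interior samples, keeping >=2 points per segment.
    lo, hi = 2, eps.size - 2
    if hi <= lo:
        raise UnderdeterminedFitError("need at least 2 points per segment")
    sses = np.array([_hinge_fit(eps, sig, eps[i])[1] for i in range(lo, hi)])
    i_best = int(np.argmin(sses)) + lo
    # Polish the breakpoint continuously between the neighbouring samples.
    a, b = eps[max(i_best - 1, 1)], eps[min(i_best + 1, eps.size - 1)]
    res = optimize.minimize_scalar(
        lambda x: _hinge_fit(eps, sig, x)[1], bounds=(a, b), method="bounded",
        options={"xatol": 1e-12 * max(eps[-1], 1.0)},
    )
    brk = float(res.x)
    coef, sse_two = _hinge_fit(eps, sig, brk)
    e1 = float(coef[1])
    e2 = float(coef[1] + coef[2])
    if e1 <= 0:
        raise UnderdeterminedFitError("initial slope is non-positive")

    linear = abs(e2 - e1) <= slope_change_rtol * abs(e1)
    if linear:
        # Refit a single line through the data for the modulus.
        a1 = np.column_stack([np.ones_like(eps), eps])
        c, *_ = np.linalg.lstsq(a1, sig, rcond=None)
        return MaterialParams(
            name=name, young_modulus=float(c[1]), density=density,
            poisson_ratio=poisson_ratio,
        )

    sigma_y = float(coef[0] + coef[1] * brk)
    et: Optional[float] = e2
    if e2 < 0:
        # Softening beyond the bio-yield point (fracture); no meaningful
        # tangent modulus for a hardening law.
        et = None
    return MaterialParams(
        name=name, young_modulus=e1, tangent_modulus=et,
        bio_yield_stress=sigma_y, density=density, poisson_ratio=poisson_ratio,
    )


def read_force_displacement_csv(
    path, initial_length: float, cross_section: float, mode: Mode = "compression"
) -> ForceDisplacementRecord:
    """Read a test record from CSV with header columns
    ``displacement_mm, force_N``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"displacement_mm", "force_N"}
    if not required.issubset(df.columns):
        raise InvalidSpecimenError(
            f"CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return ForceDisplacementRecord(
        force=df["force_N"].to_numpy(float),
        displacement=df["displacement_mm"].to_numpy(float),
        initial_length=initial_length,
        cross_section=cross_section,
        mode=mode,
    )


def load_material_library() -> dict[str, MaterialParams]:
    """Built-in material library (tissues and contact surfaces), mean
    values with measurement spreads kept as metadata."""
    text = resources.files("fruitdrop.data").joinpath("materials.json").read_text()
    raw = json.loads(text)
    lib = {}
    for name, rec in raw.items():
        lib[name] = MaterialParams(
            name=name,
            young_modulus=rec["young_modulus"],
            tangent_modulus=rec["tangent_modulus"],
            bio_yield_stress=rec["bio_yield_stress"],
            density=rec["density"],
            poisson_ratio=rec["poisson_ratio"],
            spread=rec.get("spread", {}),
        )
    return lib


def get_material(name: str) -> MaterialParams:
    lib = load_material_library()
    try:
        return lib[name.lower()]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; have {sorted(lib)}") from None
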