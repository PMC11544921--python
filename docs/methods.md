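# Methods

## The model in brief

`fruitdrop` simulates a kiwifruit falling onto a flat surface and
quantifies the bruise it sustains.  The fruit is a three-region solid —
a thin skin, the flesh (pulp), and a central core — each an isotropic
elastic–plastic material characterised by uniaxial tests: Young's
modulus `E`, a bio-yield stress `σ_y` at which irreversible cell damage
begins, and a post-yield tangent modulus `E_t`.  A drop from height `h`
gives the fruit the free-fall impact speed `v0 = sqrt(2 g h)`
(g = 9.8 m s⁻²); the impact event is integrated for 0.02 s.  Damage is
read from the stress history with the von Mises criterion: an element
is bruised if its peak equivalent stress strictly exceeds its tissue's
bio-yield threshold (flesh 0.26 MPa, skin 0.52 MPa, core 1.12 MPa).
The headline quantity is the bruise susceptibility

    BS = Vb / Et   [mm³ J⁻¹]

with `Vb` the bruised solid volume and `Et` the energy absorbed by the
fruit during the collision.  A 3×3×3 factorial sweep over drop height
(0.25/0.5/1 m), collision angle (0/45/90°) and surface material
(steel/PVC/neoprene) feeds per-surface quadratic response surfaces
`BS(X=height, Y=angle)`, the same model family as the published
prediction equations that the package also evaluates verbatim.

## Tissue parameter reduction

Force–displacement records reduce to engineering stress and strain by
`σ = F/S` and `ε = ΔL/L`.  The bilinear parameters are identified by a
two-segment continuous piecewise-linear least-squares fit: candidate
breakpoints are scanned over the interior strain samples, then the best
breakpoint is polished by a bounded 1-D minimisation of the SSE.  The
stress at the breakpoint is reported as the bio-yield stress (the
"biological yield point" convention, not a 0.2 % offset).  A curve whose
two segment slopes agree within 0.1 % relative is declared purely
linear (no yield point, no tangent modulus) — the skin's tensile
records, which run linearly to fracture, take this path.  No smoothing
is applied by default; a moving-average window is available.

The built-in material library (mean values, with measurement spreads as
metadata):

| material | E (MPa) | E_t (MPa) | σ_y (MPa) | ρ (kg m⁻³) | ν |
|---|---|---|---|---|---|
| skin | 10.69 | — | 0.53 | 960 | 0.30 |
| flesh | 1.57 | 0.92 | 0.26 | 1030 | 0.40 |
| core | 5.11 | 0.83 | 1.12 | 1120 | 0.40 |
| steel | 2.1·10⁵ | — | 235 | 7850 | 0.33 |
| PVC | 70 | — | — | 60 | 0.30 |
| neoprene | 7.8 | — | — | 930 | 0.47 |

The PVC density is carried as published; it does not enter the contact
model (only the surface modulus does).  The skin's damage threshold
defaults to 0.52 MPa (the value applied in the reference damage
analysis) while the library stores the measured 0.53 MPa; both are
config-exposed.

## Synthetic fruit geometry

The real fruit surface would come from a 3-D scan; only three overall
dimensions of the reference fruit are available (length 64.18 mm,
equatorial diameters 53.46 and 50.72 mm), so the solid is modelled as a
tri-axial ellipsoid with those axes.  This is a stated approximation:
the scanned fruit's surface area (10 182 mm²) is within ~3 % of the
equivalent ellipsoid's Thomsen estimate (9 870 mm²), but the rounded
ellipsoid poles are the model's weakest feature (see Limitations).
The core is a coaxial inner ellipsoid spanning 55 % of the length and
25 % of the diameters — the source geometry gives no core dimensions,
so these fractions are package assumptions, config-exposed.  The skin
is a 0.3 mm membrane of the boundary triangles, sharing the flesh
surface nodes (a fully bonded skin–flesh interface); the core–flesh
interface is conformal with shared nodes, equivalent to a fully bonded
embedded coupling.

### Meshing

The mesh is the classical butterfly (O-grid) ball topology: an inner
Cartesian hex block spanning 45 % of each semi-axis, surrounded by six
shell blocks whose nodes lie on straight rays from the inner-cube
surface to the sphere, affinely scaled to the ellipsoid.  Every hex is
split into 24 tetrahedra through its face and body centroids — a
decomposition that is conforming across block boundaries without any
diagonal bookkeeping.  Single-block cube-to-ball maps were rejected
because every such map degenerates near the cube corners (inverted or
sliver cells whose characteristic length collapses, and with it the
explicit stable time step); the butterfly construction keeps the
minimum element quality near 0.25–0.35 at every size used here.
Boundary-quad centroids are raised to radius `r̄ + 1.5·(1−r̄)` so the
four boundary triangles recover the spherical-cap volume their flat
facets would lose; meshed volume then agrees with the analytic
ellipsoid volume to 0.4 % at 2 mm and 0.9 % at 3 mm.  Hexes are sized
at √2× the nominal element size so that the 24-split yields tets at the
nominal scale (75 360 tets / 17 567 nodes at 2 mm, the same order as a
conventional tet mesher produces at that size).  Generation is
deterministic for fixed inputs; the seed only enters if the quality
floor (default 0.05) ever forces a jittered retry, which the structured
construction does not trigger in practice.

## Explicit solver

Standard lumped-mass central-difference explicit dynamics, SI units
internally.  Elements are 4-node constant-strain tetrahedra (single
point integration, which is exact for linear elements — there are no
hourglass modes, so the hourglass-energy channel is identically zero)
and 3-node plane-stress membrane triangles for the skin.  The
kinematics are updated-Lagrangian with a small-strain rate form and a
Jaumann (corotational) stress increment, adequate for the ≤15 % strains
of these impacts.  Plasticity is J2 with linear isotropic hardening
`H = E·E_t/(E−E_t)` via the radial-return map; the skin is
elastic–perfectly-plastic in plane stress (no tangent modulus was
measured for skin), solved by enforcing zero normal stress inside the
3-D return map with a scalar Newton iteration.

**Contact.**  The surface is a rigid plane at z = 0 with an
elastic-foundation penalty: each penetrating skin node feels the
pressure `E_surf/h_ref` times its penetration over its tributary area
(`h_ref` = 10 mm reference layer, config-exposed), frictionless by
default.  The effective foundation modulus is capped at 250 MPa
(config-exposed): a raw steel modulus (2.1·10⁵ MPa) would drive the
penalty node-spring frequency — and hence the stable time step — two
orders of magnitude below the element limit while the plate is already
effectively rigid compared to fruit tissue (capped-foundation
penetration stays below ~2 % of the fruit's own deformation).  This is
the standard soft-constraint regularization of explicit contact codes.
PVC (70 MPa) and neoprene (7.8 MPa) sit below the cap and are
unaffected, so the stiffness ordering steel > PVC > neoprene is
preserved.

**Stable time step.**  `dt = safety · min(2/ω_max)` where `ω_max` is
computed exactly per element from the 12×12 stiffness eigenproblem with
lumped masses (for a single-element mesh this equals the assembled
bound); membranes use min-altitude over plane-stress wave speed, and
the contact penalty contributes a node-spring bound `2·sqrt(m/k)`.
Safety defaults to 0.9.

**Energy audit.**  Internal energy is accumulated as midpoint stress
power (`½(σⁿ+σⁿ⁺¹):Δε·V`), split into elastic strain energy (closed
form from the current stress) and plastic dissipation; contact energy
is the stored spring energy `½kδ²`; a linear bulk viscosity (b₁ = 0.06)
stabilises the compression shock and its dissipation is tracked.  The
balance `KE + IE + CE + Q_visc − W_gravity = KE₀` is checked at every
output step; drops in this study close within 0.2 %, and the run aborts
with a diagnostic beyond 5 % (config-exposed).  The guard scales the
error by the dominant energy channel so quasi-static settling runs
(zero drop height) are judged fairly.  One known pathological case: a
perfectly flat face slammed onto the plane excites every contact spring
at the stability limit simultaneously and can leak a few tens of
percent of a tiny kinetic energy; curved geometries (the fruit, the
sphere fixtures) are unaffected.

**Orientation convention.**  The collision angle θ is the angle between
the fruit's long axis and the plane: θ = 0° is an equatorial (side)
impact with maximal contact area, θ = 90° an end impact on the pole.
This matches the reasoning that small angles spread the load over a
larger contact patch (and indeed reproduces the lower peak stress at
0°).

**Nodal pressure averaging** (experimental, default off): a
volumetric-strain/pressure nodal averaging intended to relieve the mild
volumetric locking of linear tets at ν = 0.4.  The force pass applies
the averaging adjoint to the pressure so the virtual work is
consistent, but the scheme can ring near the stability limit in
plastic runs and is not used for the study results.

## Damage metrics

Bruised elements are classified by peak-over-time von Mises stress,
strict inequality at the threshold (a tie is not bruised; a
measure-zero convention).  `Vb` sums undeformed volumes of bruised
flesh and core tets; the skin is reported separately as a bruised
membrane area.  `Et` defaults to the peak internal energy — the energy
absorbed by the fruit at maximal compression, including the recoverable
part — because the ratio's denominator is not operationally pinned
down by a single field convention; plastic-only and kinetic-loss
definitions are computed alongside and stored in every report.

## Response surfaces

Per surface material a quadratic in raw units
`(1, X, Y, XY, X², Y²)` is fitted by OLS (statsmodels) to the nine
(height, angle) cells — a full factorial; a Box–Behnken design is not
defined for two continuous factors, so the full 3×3 grid the sweep
actually runs is used.  With 9 points and 6 parameters the residual has
3 degrees of freedom: coefficient p-values are reported with that
explicit low-power caveat, and factor importance is judged from
coded-unit effects (the centred derivative times the factor half-range).
The published Z1–Z3 coefficient sets are carried verbatim for direct
evaluation; fitting a printed model to its own 3×3 evaluations returns
its coefficients to 1e-6, and the printed steel/neoprene extrema are
reproduced by evaluation at (1 m, 90°) and (0.25 m, 0°).

## Problem sizes used by the test suite and acceptance script

The acceptance script runs the steel 1 m drops on the production 2 mm
mesh (75 k tets, ≈1 min per run on one core).  The test suite's
ordering/trend checks run the full 27-cell sweep on a 4 mm mesh (10 k
tets, ≈4 s per run): peak-force and BS orderings are insensitive to
this coarsening, which is the package's chosen economy for routine
testing.  The Hertz benchmark uses a 10 mm elastic sphere at 1.2–1.5 mm
resolution with a near-zero Poisson ratio, so that `E* = E` exactly and
the closed form isolates contact/integration accuracy from the
volumetric overstiffness of linear tetrahedra; the quoted peak force is
taken after a 0.2 ms moving average that removes discrete-contact
ringing (the window is a tenth of the ~2 ms contact duration).  With
those choices the simulated peak force lands within ~2.5 % of the
Hertz value; at ν = 0.3 the same benchmark sits ~6 % high — the
documented CST locking bias.

## Verification summary

- bilinear generator→fit round trip: exact to 1e-6 (noiseless); mean
  parameter error ≤ 5 % at 1 % stress noise over 100 replicates;
- single-element uniaxial response reproduces slopes E and E_t and the
  yield stress within 1 %;
- stable time step equals the per-element eigenfrequency bound (1 %);
- contact force equals the independent per-node summation to 1e-10;
- impulse–momentum balance closes to machine precision, energy audit
  to <1 % of the initial kinetic energy;
- elastic-sphere drop vs Hertz closed form: within 5 %;
- restitution ≤ 1 in all 27 scenarios; steel ≥ PVC ≥ neoprene peak
  force at every (height, angle).

## Known limitations

- **Rounded poles.**  The ellipsoidal stand-in has smoothly rounded
  ends, whereas real kiwifruit (and the scanned reference fruit) have
  distinctly flatter poles.  End-on (90°) impacts on the ellipsoid
  start from a near-point contact whose pressure is capped by tissue
  yield, so the simulated peak *force* at 90° falls below the 0° value
  — the opposite of the reference measurements on the scanned geometry
  (608 N vs 493 N), even though the peak *stress* ordering
  (90° > 0°) is reproduced.  Reproducing the force ordering would
  require pole-flattened geometry that three diameters cannot encode.
- **Stress magnitudes run high.**  Peak flesh von Mises stress is an
  extreme single-element statistic on locking-prone linear tets; the
  simulated peaks (≈0.45–0.64 MPa at 1 m on steel) exceed the
  reference contour readings (0.28–0.34 MPa) by ~60 %, and bruised
  volumes (hence BS) carry the same upward bias of roughly 1.7×.
  Orderings and trends — the quantities the response-surface analysis
  rests on — are insensitive to this bias.
- The fruit rebounds more elastically (e ≈ 0.75–0.96) than real fruit,
  because the bilinear hardening law stores most impact energy
  reversibly; no rate dependence or tissue damage softening is
  modelled.
- Frictionless contact only; no skin bending stiffness; no fruit–fruit
  contact; no browning kinetics (the bruise is read instantaneously
  from the stress field).
- The synthetic force–displacement generator produces ideal bilinear
  curves with optional Gaussian noise; it does not emulate toe-in
  regions, viscoelastic relaxation, or fracture stochasticity, so the
  parameter-recovery tests certify the estimator, not robustness to
  every laboratory artefact.
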