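"""Parametric multiscale fruit solid and its tetrahedral/membrane mesh.

The fruit body is a tri-axial ellipsoid with the measured length and
equatorial diameters; the core is a coaxial inner ellipsoid; the skin is
a thin membrane of the boundary triangles (sharing the flesh surface
nodes, i.e. a fully bonded skin–flesh interface).  This parametric solid
stands in for a scanned free-form fruit surface: only the three overall
diameters of the reference fruit are available, and the scanned surface
area is itself within a few percent of the equivalent ellipsoid's.

Meshing uses the classical butterfly (O-grid) ball topology: an inner
Cartesian hexahedral block surrounded by six shell blocks whose nodes
run along straight rays from the inner-cube surface to the sphere, then
an affine scaling onto the ellipsoid semi-axes.  Every hexahedral cell
is split into 24 tetrahedra through its face and body centroids, which
is conforming across block boundaries by construction and keeps element
quality bounded everywhere (no polar or central singularities).  A
translation-invariant 6-tet hex decomposition provides the unit-cube
fixture; single-tetrahedron and one-region sphere fixtures support the
solver's closed-form oracle tests.

All mesh coordinates are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FruitGeometry",
    "FruitMesh",
    "MeshQualityError",
    "build_fruit_geometry",
    "generate_mesh",
    "make_fixture",
    "ellipsoid_volume",
    "ellipsoid_surface_area",
    "REGION_FLESH",
    "REGION_CORE",
]

REGION_FLESH = 0
REGION_CORE = 1
REGION_NAMES = {REGION_FLESH: "flesh", REGION_CORE: "core"}

# Default reference-fruit dimensions (mm): measured length, max/min
# equatorial diameters of the modelled sample; 0.3 mm skin shell.
DEFAULT_LENGTH = 64.18
DEFAULT_DMAX = 53.46
DEFAULT_DMIN = 50.72
DEFAULT_SKIN_THICKNESS = 0.3
# Core proportions are not available from measurements; these are stated
# modelling assumptions (see docs/methods.md), config-exposed.
DEFAULT_CORE_LENGTH_FRACTION = 0.55
DEFAULT_CORE_DIAMETER_FRACTION = 0.25


class MeshQualityError(RuntimeError):
    pass


@dataclass(frozen=True)
class FruitGeometry:
    """Tri-axial ellipsoid fruit with coaxial ellipsoidal core.

    length is along x; d_max along y; d_min along z.  Core semi-axes are
    the body semi-axes scaled by the core fractions.
    """

    length: float = DEFAULT_LENGTH
    d_max: float = DEFAULT_DMAX
    d_min: float = DEFAULT_DMIN
    skin_thickness: float = DEFAULT_SKIN_THICKNESS
    core_length_fraction: float = DEFAULT_CORE_LENGTH_FRACTION
    core_diameter_fraction: float = DEFAULT_CORE_DIAMETER_FRACTION

    def __post_init__(self) -> None:
        if not (self.length >= self.d_max >= self.d_min > 0):
            raise ValueError("require length >= d_max >= d_min > 0")
        if not 0 < self.skin_thickness < 0.2 * self.d_min:
            raise ValueError("skin_thickness must be small and positive")
        for f in (self.core_length_fraction, self.core_diameter_fraction):
            if not 0 < f < 1:
                raise ValueError("core fractions must be in (0, 1)")

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        return (self.length / 2.0, self.d_max / 2.0, self.d_min / 2.0)

    @property
    def core_semi_axes(self) -> tuple[float, float, float]:
        a, b, c = self.semi_axes
        return (
            a * self.core_length_fraction,
            b * self.core_diameter_fraction,
            c * self.core_diameter_fraction,
        )

    @property
    def volume(self) -> float:
        """Analytic ellipsoid volume, mm^3."""
        return ellipsoid_volume(*self.semi_axes)

    @property
    def surface_area(self) -> float:
        """Thomsen-approximation surface area, mm^2."""
        return ellipsoid_surface_area(*self.semi_axes)


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_surface_area(a: float, b: float, c: float, p: float = 1.6) -> float:
    """Thomsen's approximation (max error ~1% at p~1.6)."""
    t = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * np.pi * t ** (1.0 / p)


def build_fruit_geometry(**overrides) -> FruitGeometry:
    """Reference fruit geometry; keyword overrides replace any field."""
    return FruitGeometry(**overrides)


@dataclass
class FruitMesh:
    """Tetrahedral solid with a triangular skin membrane.

    points : (n_nodes, 3) mm.  tets : (n_tets, 4) 0-based node ids with
    positive signed volume.  region : per-tet label (REGION_FLESH /
    REGION_CORE).  skin_tris : (n_tris, 3) outward-oriented boundary
    triangles carrying the membrane of thickness skin_thickness.
    """

    points: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    skin_tris: np.ndarray
    skin_thickness: float
    element_size: float
    skin_nodes: np.ndarray = field(default=None)
    interface_nodes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int32)
        self.region = np.ascontiguousarray(self.region, dtype=np.int8)
        self.skin_tris = np.ascontiguousarray(self.skin_tris, dtype=np.int32)
        if self.skin_nodes is None:
            self.skin_nodes = np.unique(self.skin_tris)
        if self.interface_nodes is None:
            self.interface_nodes = _interface_nodes(self.tets, self.region)

    # -- derived quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def tet_volumes(self) -> np.ndarray:
        p = self.points
        t = self.tets
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        d3 = p[t[:, 3]] - p[t[:, 0]]
        return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def region_volume(self, region: int) -> float:
        v = self.tet_volumes()
        return float(v[self.region == region].sum())

    def skin_areas(self) -> np.ndarray:
        p = self.points
        t = self.skin_tris
        n = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def tet_quality(self) -> np.ndarray:
        """Shape quality 6*sqrt(2)*V / l_rms^3 (1 for a regular tet)."""
        p = self.points
        t = self.tets
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        l2 = np.zeros(self.n_tets)
        for i, j in pairs:
            d = p[t[:, i]] - p[t[:, j]]
            l2 += np.einsum("ij,ij->i", d, d)
        lrms = np.sqrt(l2 / 6.0)
        return 6.0 * np.sqrt(2.0) * self.tet_volumes() / lrms**3

    # -- validity -----------------------------------------------------------
    def boundary_faces(self) -> np.ndarray:
        """Faces of tets that belong to exactly one tet."""
        faces = _tet_faces(self.tets)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T)
        k = key[order]
        dup = np.ones(len(k), dtype=bool)
        same_next = np.all(k[:-1] == k[1:], axis=1)
        dup[:-1] &= ~same_next
        dup[1:] &= ~same_next
        return faces[order][dup]

    def validate(self) -> None:
        """Raise if the mesh breaks a structural invariant."""
        vols = self.tet_volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValueError(f"tet {bad} has non-positive volume {vols[bad]:g}")
        bf = self.boundary_faces()
        if bf.shape[0] != self.skin_tris.shape[0]:
            raise ValueError(
                f"skin triangles ({self.skin_tris.shape[0]}) do not tile the "
                f"boundary ({bf.shape[0]} faces)"
            )
        want = {tuple(sorted(f)) for f in bf}
        have = {tuple(sorted(f)) for f in self.skin_tris}
        if want != have:
            raise ValueError("skin triangles differ from the tet boundary")
        # Watertight: every boundary edge shared by exactly 2 skin triangles.
        e = np.concatenate(
            [self.skin_tris[:, [0, 1]], self.skin_tris[:, [1, 2]], self.skin_tris[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("skin is not watertight (edge not shared by 2 triangles)")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.tets.ravel()] = True
        if not used.all():
            raise ValueError(f"{int((~used).sum())} orphan nodes")


def _tet_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-ordered faces (opposite-node convention) of each tet."""
    f = np.concatenate(
        [
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 1]],
        ]
    )
    return f


def _interface_nodes(tets: np.ndarray, region: np.ndarray) -> np.ndarray:
    in_core = np.zeros(int(tets.max()) + 1 if tets.size else 0, dtype=bool)
    in_flesh = np.zeros_like(in_core)
    in_core[tets[region == REGION_CORE].ravel()] = True
    in_flesh[tets[region == REGION_FLESH].ravel()] = True
    return np.nonzero(in_core & in_flesh)[0].astype(np.int32)


# ---------------------------------------------------------------------------
# Structured hex grid -> 6 tets per cell
# ---------------------------------------------------------------------------

# 6-tet decomposition of a hex around the main diagonal p0-p6; conforming
# across a translation-invariant structured grid.
_HEX_TO_TETS = np.array(
    [
        [0, 1, 2, 6],
        [0, 2, 3, 6],
        [0, 3, 7, 6],
        [0, 7, 4, 6],
        [0, 4, 5, 6],
        [0, 5, 1, 6],
    ],
    dtype=np.int64,
)


def _structured_cube_tets(nx: int, ny: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-cube [-1,1]^3 grid nodes and its 6-tet-per-cell connectivity."""
    xs = np.linspace(-1.0, 1.0, nx + 1)
    ys = np.linspace(-1.0, 1.0, ny + 1)
    zs = np.linspace(-1.0, 1.0, nz + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ],
        axis=1,
    )
    tets = corners[:, _HEX_TO_TETS].reshape(-1, 4)
    return points, tets


def _dedup_points(points: np.ndarray, decimals: int = 9) -> tuple[np.ndarray, np.ndarray]:
    """Merge coincident nodes; returns (unique_points, old->new index map)."""
    key = np.round(points, decimals)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return points[first], inverse


# Local corner ids of the 6 quad faces of a hex, in cyclic order.
_HEX_FACES = np.array(
    [
        [0, 1, 2, 3],
        [4, 5, 6, 7],
        [0, 1, 5, 4],
        [1, 2, 6, 5],
        [2, 3, 7, 6],
        [3, 0, 4, 7],
    ],
    dtype=np.int64,
)


def _butterfly_ball(
    nx: int, ny: int, nz: int, n_layers: int, s: float = 0.45
) -> tuple[np.ndarray, np.ndarray]:
    """Hex mesh of the unit ball: inner Cartesian block [-s,s]^3 plus six
    shell blocks along straight rays from the inner-cube surface to the
    sphere.  Returns (points, hexes)."""
    xs = np.linspace(-s, s, nx + 1)
    ys = np.linspace(-s, s, ny + 1)
    zs = np.linspace(-s, s, nz + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts_blocks = [np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])]
    hex_blocks = []

    def block_hexes(offset, d0, d1, d2):
        """Hexes of a structured block with (d0+1)(d1+1)(d2+1) nodes."""
        i, j, k = np.meshgrid(np.arange(d0), np.arange(d1), np.arange(d2), indexing="ij")
        i, j, k = i.ravel(), j.ravel(), k.ravel()

        def nid(a, b_, c_):
            return offset + (a * (d1 + 1) + b_) * (d2 + 1) + c_

        return np.stack(
            [
                nid(i, j, k),
                nid(i + 1, j, k),
                nid(i + 1, j + 1, k),
                nid(i, j + 1, k),
                nid(i, j, k + 1),
                nid(i + 1, j, k + 1),
                nid(i + 1, j + 1, k + 1),
                nid(i, j + 1, k + 1),
            ],
            axis=1,
        )

    hex_blocks.append(block_hexes(0, nx, ny, nz))
    offset = pts_blocks[0].shape[0]

    # Six shell blocks: base = the matching inner-cube face grid.
    faces = [
        (0, +s, ys, zs),
        (0, -s, ys, zs),
        (1, +s, xs, zs),
        (1, -s, xs, zs),
        (2, +s, xs, ys),
        (2, -s, xs, ys),
    ]
    t = np.linspace(0.0, 1.0, n_layers + 1)
    for axis, val, u1, u2 in faces:
        g1, g2 = np.meshgrid(u1, u2, indexing="ij")
        base = np.empty((g1.size, 3))
        base[:, axis] = val
        others = [a for a in range(3) if a != axis]
        base[:, others[0]] = g1.ravel()
        base[:, others[1]] = g2.ravel()
        outer = base / np.linalg.norm(base, axis=1, keepdims=True)
        # layer-major node layout: (n_layers+1, len(u1), len(u2))
        pts = base[None] + t[:, None, None] * (outer - base)[None]
        pts_blocks.append(pts.reshape(-1, 3))
        hex_blocks.append(block_hexes(offset, n_layers, len(u1) - 1, len(u2) - 1))
        offset += pts.size // 3

    points = np.concatenate(pts_blocks)
    hexes = np.concatenate(hex_blocks)
    points, remap = _dedup_points(points)
    return points, remap[hexes]


def _hexes_to_tets_centroid(
    points: np.ndarray, hexes: np.ndarray, project_boundary: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Split hexes into 24 tets via face + body centroids (conforming
    regardless of block structure).  Boundary-face centroids are
    projected radially onto the unit sphere when requested (caller must
    still be in unit-ball coordinates).  Returns (points, tets)."""
    h = hexes.shape[0]
    faces = hexes[:, _HEX_FACES].reshape(-1, 4)  # (6h, 4) cyclic order
    key = np.sort(faces, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    n0 = points.shape[0]
    fc = points[uniq].mean(axis=1)
    if project_boundary:
        # Volume-compensating projection: raise the centroid of each
        # boundary quad to radius rbar + 1.5*(1 - rbar) so the pyramid of
        # its four triangles recovers the spherical-cap volume the flat
        # facets would otherwise lose (apex height h = 1.5 * sagitta).
        on_boundary = counts == 1
        rbar = np.linalg.norm(fc[on_boundary], axis=1, keepdims=True)
        fc[on_boundary] = fc[on_boundary] / rbar * (1.5 - 0.5 * rbar)
    bc = points[hexes].mean(axis=1)
    all_points = np.concatenate([points, fc, bc])
    fc_id = n0 + inv.reshape(h, 6)  # per hex, per face
    bc_id = n0 + uniq.shape[0] + np.arange(h)

    edges = faces[:, [[0, 1], [1, 2], [2, 3], [3, 0]]]  # (6h, 4, 2)
    e1 = edges[:, :, 0].reshape(h, 6, 4)
    e2 = edges[:, :, 1].reshape(h, 6, 4)
    tets = np.stack(
        [
            e1,
            e2,
            np.broadcast_to(fc_id[:, :, None], e1.shape),
            np.broadcast_to(bc_id[:, None, None], e1.shape),
        ],
        axis=-1,
    ).reshape(-1, 4)
    # Orient positively (flips are local: face triangles are unchanged).
    d1 = all_points[tets[:, 1]] - all_points[tets[:, 0]]
    d2 = all_points[tets[:, 2]] - all_points[tets[:, 0]]
    d3 = all_points[tets[:, 3]] - all_points[tets[:, 0]]
    vol = np.einsum("ij,ij->i", np.cross(d1, d2), d3)
    flip = vol < 0
    tmp = tets[flip, 0].copy()
    tets[flip, 0] = tets[flip, 1]
    tets[flip, 1] = tmp
    return all_points, tets


def _fix_orientation(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    d1 = points[tets[:, 1]] - points[tets[:, 0]]
    d2 = points[tets[:, 2]] - points[tets[:, 0]]
    d3 = points[tets[:, 3]] - points[tets[:, 0]]
    vol = np.einsum("ij,ij->i", np.cross(d1, d2), d3)
    flip = vol < 0
    if np.any(flip):
        tets = tets.copy()
        tmp = tets[flip, 2].copy()
        tets[flip, 2] = tets[flip, 3]
        tets[flip, 3] = tmp
    return tets


def generate_mesh(
    geom: FruitGeometry,
    element_size: float,
    seed: int = 0,
    include_core: bool = True,
    quality_floor: float = 0.05,
    max_retries: int = 3,
) -> FruitMesh:
    """Structured tetrahedral mesh of the fruit ellipsoid.

    A butterfly (O-grid) hex mesh of the unit ball — cell counts matched
    to ``element_size`` — is scaled onto the ellipsoid and every hex is
    split into 24 tets through its centroids.  Tets whose centroid lies
    inside the core ellipsoid are labelled core.  Deterministic for
    fixed (geom, element_size, seed); the seed only enters if the
    quality floor forces a jittered retry.
    """
    if not 0.5 <= element_size <= 10.0:
        raise ValueError("element_size must be in [0.5, 10] mm")
    a, b, c = geom.semi_axes
    if include_core:
        core_min = 2.0 * min(geom.core_semi_axes)
        if element_size > core_min:
            raise ValueError(
                f"element_size {element_size:g} mm cannot resolve the core: "
                f"limiting dimension is the core minor diameter {core_min:g} mm"
            )
    # The 24-tet hex split yields tets of roughly 0.7x the hex size, so
    # hexes are sized up to keep the tet scale at element_size.
    hex_size = element_size * 2.0 ** 0.5
    s = 0.45
    nx = max(2, int(round(2 * s * a / hex_size)))
    ny = max(2, int(round(2 * s * b / hex_size)))
    nz = max(2, int(round(2 * s * c / hex_size)))
    mean_semi = (a + b + c) / 3.0
    n_layers = max(2, int(round((1.0 - s) * mean_semi / hex_size)))

    unit, hexes = _butterfly_ball(nx, ny, nz, n_layers, s)
    unit, tets = _hexes_to_tets_centroid(unit, hexes)
    points = unit * np.array([a, b, c])

    rng = np.random.default_rng(seed)
    mesh = _finalize(points, tets, geom, element_size, include_core)
    q = mesh.tet_quality()
    tries = 0
    while q.min() < quality_floor and tries < max_retries:
        # Jitter interior nodes slightly and retry (seeded).
        tries += 1
        interior = np.ones(points.shape[0], dtype=bool)
        interior[mesh.skin_nodes] = False
        pts = points.copy()
        pts[interior] += rng.uniform(-0.1, 0.1, size=(interior.sum(), 3)) * element_size
        mesh = _finalize(pts, tets, geom, element_size, include_core)
        q = mesh.tet_quality()
    if q.min() < quality_floor:
        raise MeshQualityError(
            f"minimum tet quality {q.min():.3g} below floor {quality_floor} "
            f"after {max_retries} jitter retries"
        )
    return mesh


def _finalize(points, tets, geom, element_size, include_core) -> FruitMesh:
    region = np.full(tets.shape[0], REGION_FLESH, dtype=np.int8)
    if include_core:
        ca, cb, cc = geom.core_semi_axes
        cent = points[tets].mean(axis=1)
        inside = (
            (cent[:, 0] / ca) ** 2 + (cent[:, 1] / cb) ** 2 + (cent[:, 2] / cc) ** 2
        ) <= 1.0
        region[inside] = REGION_CORE
    mesh = FruitMesh(
        points=points,
        tets=tets,
        region=region,
        skin_tris=np.empty((0, 3), dtype=np.int32),
        skin_thickness=geom.skin_thickness,
        element_size=element_size,
        skin_nodes=np.empty(0, dtype=np.int64),
        interface_nodes=np.empty(0, dtype=np.int32),
    )
    skin = mesh.boundary_faces()
    return FruitMesh(
        points=points,
        tets=tets,
        region=region,
        skin_tris=skin,
        skin_thickness=geom.skin_thickness,
        element_size=element_size,
    )


# ---------------------------------------------------------------------------
# Oracle fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, **params) -> FruitMesh:
    """Small meshes for closed-form oracle tests.

    kind='single_tet'      : one regular tetrahedron (edge=..., mm)
    kind='unit_cube'       : n^3-cell cube, 6 tets per cell (n=..., edge=...)
    kind='elastic_sphere'  : one-region sphere (radius=..., element_size=...)
    """
    if kind == "single_tet":
        edge = float(params.get("edge", 1.0))
        pts = edge * np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0],
                [0.5, np.sqrt(3.0) / 2.0, 0.0],
                [0.5, np.sqrt(3.0) / 6.0, np.sqrt(2.0 / 3.0)],
            ]
        )
        tets = np.array([[0, 1, 2, 3]], dtype=np.int32)
        region = np.array([REGION_FLESH], dtype=np.int8)
        mesh = FruitMesh(
            points=pts,
            tets=tets,
            region=region,
            skin_tris=np.empty((0, 3), dtype=np.int32),
            skin_thickness=float(params.get("skin_thickness", 0.3)),
            element_size=edge,
            skin_nodes=np.arange(4),
            interface_nodes=np.empty(0, dtype=np.int32),
        )
        skin = mesh.boundary_faces()
        return FruitMesh(
            points=pts, tets=tets, region=region, skin_tris=skin,
            skin_thickness=mesh.skin_thickness, element_size=edge,
        )
    if kind == "unit_cube":
        n = int(params.get("n", 1))
        edge = float(params.get("edge", 1.0))
        unit, tets = _structured_cube_tets(n, n, n)
        pts = (unit + 1.0) * (edge / 2.0)
        tets = _fix_orientation(pts, tets)
        region = np.full(tets.shape[0], REGION_FLESH, dtype=np.int8)
        mesh = FruitMesh(
            points=pts, tets=tets, region=region,
            skin_tris=np.empty((0, 3), dtype=np.int32),
            skin_thickness=float(params.get("skin_thickness", 0.3)),
            element_size=edge / n,
        )
        skin = mesh.boundary_faces()
        return FruitMesh(
            points=pts, tets=tets, region=region, skin_tris=skin,
            skin_thickness=mesh.skin_thickness, element_size=edge / n,
        )
    if kind == "elastic_sphere":
        r = float(params.get("radius", 10.0))
        size = float(params.get("element_size", 2.0))
        geom = FruitGeometry(
            length=2 * r, d_max=2 * r, d_min=2 * r,
            skin_thickness=float(params.get("skin_thickness", 0.3)),
        )
        # Oracle fixture: size the hexes at element_size directly (finer
        # surface than the fruit default) since the sphere serves volume
        # and contact-patch accuracy checks.
        mesh = generate_mesh(geom, max(0.5, size / 2.0 ** 0.5),
                             include_core=False, seed=int(params.get("seed", 0)))
        mesh.element_size = size
        return mesh
    raise ValueError(f"unknown fixture kind {kind!r}")
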