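"""Multizone tetrahedral lung phantoms and mesh I/O.

The lung lobe is represented as an ellipsoidal poroelastic body partitioned
into concentric "shells" (zones) standing in for the branching generations of
the airway tree: a core zone with wide, conductive airways and peripheral
zones with progressively narrower branches.  Zones carry integer labels
1 (core) .. N (periphery) and drive both the permeability profile and the
mesh grading — the core is meshed finer because pressure, velocity and stress
gradients concentrate there.

Meshes are plain linear-tetrahedron unstructured grids with named boundary
node sets (``inlet``, ``fixed``, ``free``).  I/O uses two text formats:
legacy ASCII VTK unstructured grids and Gmsh 2.2 ``.msh`` files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay

logger = logging.getLogger("porolung")

__all__ = [
    "MeshError",
    "PhantomSpec",
    "ZonedMesh",
    "build_multizone_phantom",
    "build_box_mesh",
    "assign_boundary_patches",
    "export_mesh",
    "load_mesh",
    "tet_volumes",
    "scaled_radius",
]


class MeshError(ValueError):
    """Raised for invalid mesh specifications, degenerate elements or bad files."""


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for the fixed ordering convention)."""
    p = nodes[elements]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def scaled_radius(points: np.ndarray, semi_axes) -> np.ndarray:
    """Ellipsoidal radius sqrt(sum (x_i/a_i)^2); 1.0 on the bounding surface."""
    ax = np.asarray(semi_axes, dtype=float)
    return np.sqrt(np.sum((np.atleast_2d(points) / ax) ** 2, axis=1))


def _orient_positive(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Swap first two node indices of any tet with negative signed volume."""
    elements = elements.copy()
    neg = tet_volumes(nodes, elements) < 0
    elements[neg, 0], elements[neg, 1] = elements[neg, 1].copy(), elements[neg, 0].copy()
    return elements


def _face_counts(elements: np.ndarray) -> dict[tuple[int, int, int], int]:
    faces: dict[tuple[int, int, int], int] = {}
    local = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))
    for tet in elements:
        for li in local:
            key = tuple(sorted((int(tet[li[0]]), int(tet[li[1]]), int(tet[li[2]]))))
            faces[key] = faces.get(key, 0) + 1
    return faces


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic multizone ellipsoidal lobe.

    Defaults give a human-lung-scale lobe (semi-axes 6 x 8 x 12 cm) with three
    concentric shells and mesh grading that refines toward the core.  The
    inlet (trachea side) is a circular patch on the surface around
    ``inlet_location`` (default: the superior pole ``(0, 0, c)``); the
    displacement anchor is the annulus of surface nodes between
    ``inlet_radius`` and ``fixed_radius`` around the same point.
    """

    semi_axes: tuple[float, float, float] = (0.06, 0.08, 0.12)
    n_shells: int = 3
    shell_fractions: tuple[float, ...] = (0.4, 0.7, 1.0)
    target_edge_length: tuple[float, ...] = (0.018, 0.024, 0.030)
    inlet_location: tuple[float, float, float] | None = None
    inlet_radius: float = 0.025
    fixed_radius: float = 0.045

    def __post_init__(self) -> None:
        if self.n_shells < 1:
            raise MeshError(f"n_shells must be >= 1, got {self.n_shells}")
        if any(a <= 0 for a in self.semi_axes) or len(self.semi_axes) != 3:
            raise MeshError(f"semi_axes must be 3 positive lengths, got {self.semi_axes}")
        fr = self.shell_fractions
        if len(fr) != self.n_shells:
            raise MeshError(f"need {self.n_shells} shell_fractions, got {len(fr)}")
        if any(b <= a for a, b in zip(fr, fr[1:])) or not math.isclose(fr[-1], 1.0):
            raise MeshError(f"shell_fractions must be strictly increasing with last = 1, got {fr}")
        h = self.target_edge_length
        if len(h) != self.n_shells:
            raise MeshError(f"need {self.n_shells} target_edge_length values, got {len(h)}")
        if any(v <= 0 for v in h):
            raise MeshError(f"target_edge_length must be positive, got {h}")
        if any(b < a for a, b in zip(h, h[1:])):
            raise MeshError(
                f"target_edge_length must be non-decreasing from core to periphery, got {h}"
            )
        if self.inlet_radius <= 0 or self.fixed_radius <= self.inlet_radius:
            raise MeshError(
                "need 0 < inlet_radius < fixed_radius, got "
                f"{self.inlet_radius}, {self.fixed_radius}"
            )

    @property
    def inlet_point(self) -> np.ndarray:
        if self.inlet_location is not None:
            return np.asarray(self.inlet_location, dtype=float)
        return np.array([0.0, 0.0, self.semi_axes[2]])


@dataclass
class ZonedMesh:
    """Tetrahedral mesh with per-element zone labels and named boundary node sets.

    ``zone_label`` is 1 for the innermost (core) shell, increasing outward.
    ``boundary_tags`` maps patch names to sorted arrays of surface node
    indices; the conventional names are ``inlet`` (pore-pressure drive),
    ``fixed`` (displacement anchor) and ``free``.
    """

    nodes: np.ndarray
    elements: np.ndarray
    zone_label: np.ndarray
    boundary_tags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int32)
        self.zone_label = np.ascontiguousarray(self.zone_label, dtype=np.int32)
        self.boundary_tags = {
            k: np.unique(np.asarray(v, dtype=np.int64)) for k, v in self.boundary_tags.items()
        }

    # -- basic sizes -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_zones(self) -> int:
        return int(self.zone_label.max()) if self.n_elements else 0

    # -- derived geometry --------------------------------------------------
    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.elements)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def surface_faces(self) -> np.ndarray:
        """Triangular faces belonging to exactly one tetrahedron."""
        counts = _face_counts(self.elements)
        return np.array([f for f, c in counts.items() if c == 1], dtype=np.int64)

    def surface_nodes(self) -> np.ndarray:
        faces = self.surface_faces()
        return np.unique(faces.ravel()) if faces.size else np.empty(0, dtype=np.int64)

    def element_neighbors(self) -> list[list[int]]:
        """Face-adjacent element neighbors (used for field smoothing)."""
        owners: dict[tuple[int, int, int], list[int]] = {}
        local = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))
        for ei, tet in enumerate(self.elements):
            for li in local:
                key = tuple(sorted((int(tet[li[0]]), int(tet[li[1]]), int(tet[li[2]]))))
                owners.setdefault(key, []).append(ei)
        neigh: list[list[int]] = [[] for _ in range(self.n_elements)]
        for elems in owners.values():
            if len(elems) == 2:
                a, b = elems
                neigh[a].append(b)
                neigh[b].append(a)
        return neigh

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise MeshError on the first violation."""
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= self.n_nodes
        ):
            raise MeshError("element connectivity references nodes outside the mesh")
        vols = self.volumes()
        bad = np.flatnonzero(vols <= 0.0)
        if bad.size:
            raise MeshError(
                f"{bad.size} inverted/degenerate tetrahedra (first: element {int(bad[0])}, "
                f"volume {vols[bad[0]]:.3e})"
            )
        labels = np.unique(self.zone_label)
        if self.n_elements and not np.array_equal(labels, np.arange(1, labels.max() + 1)):
            raise MeshError(f"zone labels must be contiguous 1..N, got {labels.tolist()}")
        counts = _face_counts(self.elements)
        for f, c in counts.items():
            if c > 2:
                raise MeshError(f"non-manifold face {f} shared by {c} tetrahedra")
        surf = set(self.surface_nodes().tolist())
        tagged: set[int] = set()
        for name, nodes in self.boundary_tags.items():
            extra = set(nodes.tolist()) - surf
            if extra:
                raise MeshError(
                    f"boundary tag '{name}' contains non-surface nodes {sorted(extra)[:5]}"
                )
            tagged |= set(nodes.tolist())
        if "inlet" in self.boundary_tags and "fixed" in self.boundary_tags:
            overlap = np.intersect1d(self.boundary_tags["inlet"], self.boundary_tags["fixed"])
            if overlap.size:
                raise MeshError(f"inlet and fixed patches overlap at nodes {overlap[:5].tolist()}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ZonedMesh):
            return NotImplemented
        return (
            np.array_equal(self.nodes, other.nodes)
            and np.array_equal(self.elements, other.elements)
            and np.array_equal(self.zone_label, other.zone_label)
            and set(self.boundary_tags) == set(other.boundary_tags)
            and all(
                np.array_equal(self.boundary_tags[k], other.boundary_tags[k])
                for k in self.boundary_tags
            )
        )


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistributed unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def build_multizone_phantom(spec: PhantomSpec, seed: int = 0) -> ZonedMesh:
    """Generate the multizone ellipsoidal phantom mesh.

    Seed point clouds are laid out on concentric spherical layers in the unit
    ball — layer spacing and in-layer density follow the per-shell target edge
    length, so the core is refined — then mapped to the ellipsoid and
    tetrahedralized with Delaunay (the ellipsoid is convex, so the Delaunay
    complex of surface + interior points is a watertight fill of the hull).
    Each element is labelled with the innermost shell whose scaled ellipsoidal
    radius contains its centroid.  Deterministic for fixed ``(spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    ax = np.asarray(spec.semi_axes, dtype=float)
    scale = float(np.cbrt(np.prod(ax)))  # normalizing length for edge sizing
    fractions = np.asarray(spec.shell_fractions, dtype=float)
    h_shell = np.asarray(spec.target_edge_length, dtype=float) / scale

    def h_at(r: float) -> float:
        zone = int(np.searchsorted(fractions, min(r, 1.0) - 1e-12))
        return float(h_shell[min(zone, len(h_shell) - 1)])

    # radial layers marching outward; final layer exactly on the surface
    radii: list[float] = []
    r = 0.0
    while True:
        h = h_at(r + 1e-9)
        nxt = r + h
        if nxt >= 1.0 - 0.45 * h_at(1.0):
            break
        radii.append(nxt)
        r = nxt

    pts = [np.zeros((1, 3))]
    for rr in radii:
        h = h_at(rr)
        n = max(6, int(round(4.0 * math.pi * rr * rr / (h * h))))
        layer = _fibonacci_sphere(n) @ _random_rotation(rng).T
        layer = layer * rr + rng.normal(0.0, 0.18 * h, size=(n, 3))
        pts.append(layer)
    h1 = h_at(1.0)
    n_surf = max(12, int(round(4.0 * math.pi / (h1 * h1))))
    surf = _fibonacci_sphere(n_surf) @ _random_rotation(rng).T
    surf = surf + rng.normal(0.0, 0.12 * h1, size=(n_surf, 3))
    surf /= np.linalg.norm(surf, axis=1, keepdims=True)  # keep exactly on the sphere
    pts.append(surf)

    unit_points = np.vstack(pts)
    nodes = unit_points * ax

    tri = Delaunay(unit_points)
    elements = _orient_positive(nodes, tri.simplices.astype(np.int32))
    vols = tet_volumes(nodes, elements)
    if np.any(vols <= 0.0):
        bad = int(np.flatnonzero(vols <= 0.0)[0])
        raise MeshError(f"meshing produced a degenerate tetrahedron (element {bad})")

    centroids = nodes[elements].mean(axis=1)
    rho = scaled_radius(centroids, ax)
    zone = np.searchsorted(fractions, rho) + 1
    zone = np.clip(zone, 1, spec.n_shells).astype(np.int32)
    present = np.unique(zone)
    if not np.array_equal(present, np.arange(1, spec.n_shells + 1)):
        raise MeshError(
            f"mesh too coarse to populate all {spec.n_shells} zones (labels {present.tolist()}); "
            "reduce target_edge_length or shell count"
        )

    mesh = ZonedMesh(nodes=nodes, elements=elements, zone_label=zone)
    assign_boundary_patches(mesh, spec.inlet_point, spec.inlet_radius, spec.fixed_radius)
    mesh.validate()
    logger.info(
        "phantom: %d nodes, %d tets, %d zones (core/periphery tets: %d/%d)",
        mesh.n_nodes, mesh.n_elements, spec.n_shells,
        int(np.sum(zone == 1)), int(np.sum(zone == spec.n_shells)),
    )
    return mesh


def assign_boundary_patches(
    mesh: ZonedMesh,
    inlet_location,
    inlet_radius: float,
    fixed_radius: float,
) -> None:
    """Tag surface nodes as inlet patch / fixed annulus / free surface (in place).

    The inlet patch is the set of surface nodes within ``inlet_radius`` of
    ``inlet_location``; the fixed patch is the surrounding annulus out to
    ``fixed_radius`` (disjoint from the inlet).  On very coarse meshes both
    sets fall back to the nearest surface nodes so they are never empty.
    """
    surf = mesh.surface_nodes()
    if surf.size == 0:
        raise MeshError("mesh has no surface nodes")
    loc = np.asarray(inlet_location, dtype=float)
    d = np.linalg.norm(mesh.nodes[surf] - loc, axis=1)
    inlet = surf[d <= inlet_radius]
    if inlet.size == 0:
        inlet = surf[[int(np.argmin(d))]]
    in_inlet = np.isin(surf, inlet)
    fixed = surf[(d <= fixed_radius) & ~in_inlet]
    if fixed.size == 0:
        order = np.argsort(d)
        fixed = surf[order[~in_inlet[order]][:3]]
    free = np.setdiff1d(surf, np.union1d(inlet, fixed))
    mesh.boundary_tags = {"inlet": inlet, "fixed": fixed, "free": free}


def build_box_mesh(
    lengths=(1.0, 1.0, 1.0),
    divisions=(2, 2, 2),
    origin=(0.0, 0.0, 0.0),
) -> ZonedMesh:
    """Structured single-zone box mesh (6 tets per hexahedron, Kuhn subdivision).

    Used for verification problems (patch test, steady Darcy bar, 1D
    consolidation columns).  Face node sets are tagged ``x0,x1,y0,y1,z0,z1``
    plus ``all`` (every node, for roller-type constraints in 1D tests).
    """
    nx, ny, nz = (int(v) for v in divisions)
    if min(nx, ny, nz) < 1:
        raise MeshError(f"divisions must be >= 1, got {divisions}")
    lx, ly, lz = (float(v) for v in lengths)
    xs = np.linspace(0, lx, nx + 1) + origin[0]
    ys = np.linspace(0, ly, ny + 1) + origin[1]
    zs = np.linspace(0, lz, nz + 1) + origin[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Kuhn/Freudenthal: 6 tets along axis permutations; faces match across cubes
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = (i, j, k)
                for perm in perms:
                    path = [base]
                    cur = list(base)
                    for axis in perm:
                        cur[axis] += 1
                        path.append(tuple(cur))
                    tets.append([nid(*p) for p in path])
    elements = _orient_positive(nodes, np.asarray(tets, dtype=np.int32))
    mesh = ZonedMesh(
        nodes=nodes,
        elements=elements,
        zone_label=np.ones(len(elements), dtype=np.int32),
    )
    tol = 1e-12 * max(lx, ly, lz)
    tags = {
        "x0": np.flatnonzero(np.abs(nodes[:, 0] - origin[0]) < tol),
        "x1": np.flatnonzero(np.abs(nodes[:, 0] - origin[0] - lx) < tol),
        "y0": np.flatnonzero(np.abs(nodes[:, 1] - origin[1]) < tol),
        "y1": np.flatnonzero(np.abs(nodes[:, 1] - origin[1] - ly) < tol),
        "z0": np.flatnonzero(np.abs(nodes[:, 2] - origin[2]) < tol),
        "z1": np.flatnonzero(np.abs(nodes[:, 2] - origin[2] - lz) < tol),
        "all": np.arange(mesh.n_nodes),
    }
    surf = set(mesh.surface_nodes().tolist())
    mesh.boundary_tags = {k: v[np.isin(v, list(surf))] if k != "all" else v for k, v in tags.items()}
    # "all" intentionally includes interior nodes; skip it in surface validation
    all_nodes = mesh.boundary_tags.pop("all")
    mesh.validate()
    mesh.boundary_tags["all"] = all_nodes
    return mesh


# ---------------------------------------------------------------------------
# mesh I/O (legacy ASCII VTK and Gmsh 2.2)
# ---------------------------------------------------------------------------

def export_mesh(mesh: ZonedMesh, path, zone_field_name: str = "zone") -> None:
    """Write a ZonedMesh to ``.vtk`` (legacy ASCII) or ``.msh`` (Gmsh 2.2).

    Boundary tags are stored as 0/1 integer point-data masks named
    ``tag_<name>``; the zone labels as integer cell data.  ``load_mesh`` of
    the written file round-trips to an equal mesh (full float precision).
    """
    path = Path(path)
    if path.suffix == ".vtk":
        _write_vtk(mesh, path, zone_field_name)
    elif path.suffix == ".msh":
        _write_msh(mesh, path, zone_field_name)
    else:
        raise MeshError(f"unsupported mesh format '{path.suffix}' (use .vtk or .msh)")


def load_mesh(path, zone_field_name: str = "zone") -> ZonedMesh:
    """Read a tetrahedral mesh with zone labels from ``.vtk`` or ``.msh``.

    Nodes are re-indexed contiguously.  If the zone cell field is absent the
    mesh is treated as single-zone (warning logged).  Boundary node sets are
    taken from ``tag_*`` point-data masks when present, otherwise the whole
    surface is tagged ``free``.  Non-tetrahedral cells and watertightness
    violations are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise MeshError(f"mesh file not found: {path}")
    if path.suffix == ".vtk":
        nodes, elements, zone, tags = _read_vtk(path, zone_field_name)
    elif path.suffix == ".msh":
        nodes, elements, zone, tags = _read_msh(path, zone_field_name)
    else:
        raise MeshError(f"unsupported mesh format '{path.suffix}' (use .vtk or .msh)")

    if zone is None:
        logger.warning(
            "mesh %s has no cell field '%s'; treating as single zone", path, zone_field_name
        )
        zone = np.ones(len(elements), dtype=np.int32)
    zone = np.asarray(zone, dtype=np.int32)
    if zone.min() != 1:  # normalize label origin
        zone = zone - zone.min() + 1

    vols = tet_volumes(nodes, elements)
    bad = np.flatnonzero(vols <= 0.0)
    if bad.size:
        raise MeshError(
            f"file contains an inverted/degenerate tetrahedron (element {int(bad[0])})"
        )
    mesh = ZonedMesh(nodes=nodes, elements=elements, zone_label=zone, boundary_tags=tags)
    if not mesh.boundary_tags:
        mesh.boundary_tags = {"free": mesh.surface_nodes()}
    counts = _face_counts(mesh.elements)
    for f, c in counts.items():
        if c > 2:
            raise MeshError(f"mesh is not watertight: face {f} shared by {c} tetrahedra")
    mesh.validate()
    return mesh


def _fmt_floats(arr: np.ndarray) -> list[str]:
    return [" ".join(f"{v:.17g}" for v in row) for row in arr]


def _write_vtk(mesh: ZonedMesh, path: Path, zone_field_name: str) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "porolung zoned tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += _fmt_floats(mesh.nodes)
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}")
    lines += ["4 " + " ".join(str(int(v)) for v in tet) for tet in mesh.elements]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["10"] * mesh.n_elements
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append(f"SCALARS {zone_field_name} int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(z)) for z in mesh.zone_label]
    if mesh.boundary_tags:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name in sorted(mesh.boundary_tags):
            mask = np.zeros(mesh.n_nodes, dtype=int)
            mask[mesh.boundary_tags[name]] = 1
            lines.append(f"SCALARS tag_{name} int 1")
            lines.append("LOOKUP_TABLE default")
            lines += [str(int(v)) for v in mask]
    path.write_text("\n".join(lines) + "\n")


def _read_vtk(path: Path, zone_field_name: str):
    tokens_lines = path.read_text().splitlines()
    i = 0

    def next_line():
        nonlocal i
        while i < len(tokens_lines) and not tokens_lines[i].strip():
            i += 1
        if i >= len(tokens_lines):
            return None
        line = tokens_lines[i].strip()
        i += 1
        return line

    nodes = elements = zone = None
    tags: dict[str, np.ndarray] = {}
    n_points = n_cells = 0
    section = None  # CELL_DATA / POINT_DATA context
    line = next_line()
    while line is not None:
        up = line.upper()
        if up.startswith("POINTS"):
            n_points = int(line.split()[1])
            vals: list[float] = []
            while len(vals) < 3 * n_points:
                vals += [float(v) for v in next_line().split()]
            nodes = np.array(vals, dtype=float).reshape(n_points, 3)
        elif up.startswith("CELLS"):
            n_cells = int(line.split()[1])
            cells = []
            for _ in range(n_cells):
                parts = [int(v) for v in next_line().split()]
                if parts[0] != 4:
                    raise MeshError(f"non-tetrahedral cell with {parts[0]} nodes rejected")
                cells.append(parts[1:5])
            elements = np.array(cells, dtype=np.int32)
        elif up.startswith("CELL_TYPES"):
            n = int(line.split()[1])
            types: list[int] = []
            while len(types) < n:
                types += [int(v) for v in next_line().split()]
            if any(t != 10 for t in types):
                raise MeshError("non-tetrahedral VTK cell type rejected (expect type 10)")
        elif up.startswith("CELL_DATA"):
            section = "cell"
        elif up.startswith("POINT_DATA"):
            section = "point"
        elif up.startswith("SCALARS"):
            name = line.split()[1]
            nxt = next_line()  # LOOKUP_TABLE
            if nxt is None or not nxt.upper().startswith("LOOKUP_TABLE"):
                raise MeshError(f"malformed VTK SCALARS block '{name}'")
            count = n_cells if section == "cell" else n_points
            vals = []
            while len(vals) < count:
                vals += [float(v) for v in next_line().split()]
            arr = np.array(vals)
            if section == "cell" and name == zone_field_name:
                zone = arr.astype(np.int32)
            elif section == "point" and name.startswith("tag_"):
                tags[name[4:]] = np.flatnonzero(arr > 0.5)
        line = next_line()
    if nodes is None or elements is None:
        raise MeshError(f"{path} is not a valid legacy VTK unstructured grid")
    return nodes, elements, zone, tags


def _write_msh(mesh: ZonedMesh, path: Path, zone_field_name: str) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for idx, row in enumerate(mesh.nodes, start=1):
        lines.append(f"{idx} " + " ".join(f"{v:.17g}" for v in row))
    lines += ["$EndNodes", "$Elements", str(mesh.n_elements)]
    for idx, (tet, z) in enumerate(zip(mesh.elements, mesh.zone_label), start=1):
        conn = " ".join(str(int(v) + 1) for v in tet)
        lines.append(f"{idx} 4 2 {int(z)} {int(z)} {conn}")
    lines.append("$EndElements")
    for name in sorted(mesh.boundary_tags):
        mask = np.zeros(mesh.n_nodes, dtype=int)
        mask[mesh.boundary_tags[name]] = 1
        lines += [
            "$NodeData", "1", f'"tag_{name}"', "1", "0.0", "3", "0", "1",
            str(mesh.n_nodes),
        ]
        lines += [f"{idx + 1} {int(v)}" for idx, v in enumerate(mask)]
        lines.append("$EndNodeData")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path, zone_field_name: str):
    lines = path.read_text().splitlines()
    i = 0
    nodes_raw: dict[int, list[float]] = {}
    elems_raw: list[tuple[int, list[int]]] = []
    node_data: dict[str, dict[int, float]] = {}
    while i < len(lines):
        line = lines[i].strip()
        if line == "$Nodes":
            n = int(lines[i + 1])
            for j in range(i + 2, i + 2 + n):
                parts = lines[j].split()
                nodes_raw[int(parts[0])] = [float(v) for v in parts[1:4]]
            i = i + 2 + n
        elif line == "$Elements":
            n = int(lines[i + 1])
            for j in range(i + 2, i + 2 + n):
                parts = [int(v) for v in lines[j].split()]
                etype, ntags = parts[1], parts[2]
                if etype != 4:
                    raise MeshError(f"non-tetrahedral Gmsh element type {etype} rejected")
                phys = parts[3] if ntags >= 1 else 1
                conn = parts[3 + ntags: 7 + ntags]
                elems_raw.append((phys, conn))
            i = i + 2 + n
        elif line == "$NodeData":
            j = i + 1
            n_str_tags = int(lines[j]); j += 1
            name = lines[j].strip().strip('"'); j += n_str_tags
            n_real = int(lines[j]); j += 1 + n_real
            n_int = int(lines[j]); j += 1
            ints = [int(lines[j + k]) for k in range(n_int)]
            j += n_int
            n_vals = ints[-1]
            data = {}
            for k in range(n_vals):
                parts = lines[j + k].split()
                data[int(parts[0])] = float(parts[1])
            node_data[name] = data
            i = j + n_vals
        else:
            i += 1
    if not nodes_raw or not elems_raw:
        raise MeshError(f"{path} is not a valid Gmsh 2.2 mesh")
    ids = sorted(nodes_raw)
    remap = {nid: k for k, nid in enumerate(ids)}
    nodes = np.array([nodes_raw[nid] for nid in ids], dtype=float)
    elements = np.array(
        [[remap[v] for v in conn] for _, conn in elems_raw], dtype=np.int32
    )
    zone = np.array([phys for phys, _ in elems_raw], dtype=np.int32)
    if np.all(zone == zone[0]) and zone[0] == 0:
        zone = None  # no physical tags present
    tags = {}
    for name, data in node_data.items():
        if name.startswith("tag_"):
            tags[name[4:]] = np.array(
                sorted(remap[nid] for nid, v in data.items() if v > 0.5), dtype=np.int64
            )
    return nodes, elements, zone, tags
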