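"""Geometry and energy of the dimensionless 2D vertex model.

The apical surface of an epithelium is represented as a planar tessellation:
cells are simple polygons sharing vertices and edges.  The mechanical energy
of a configuration is

    E = sum_a 1/2 (A_a / A_a0 - 1)^2  +  sum_(ij) Lambda_ij l_ij
        + sum_a Gamma_a / 2 L_a^2

with A_a the apical area of cell a, A_a0 its resting area, l_ij the length
of junction (i, j), L_a the cell perimeter, Lambda_ij the dimensionless line
tension and Gamma_a the dimensionless perimeter contractility.  Lengths are
measured in units of sqrt(A0), so a mechanically unstressed cell has area 1.

This module owns the mesh data structures, polygon geometry, the energy
function and its incremental (single-vertex) form, the construction of a
disordered initial tissue, and mesh validation / serialisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import Voronoi

MESH_FORMAT_VERSION = 1

__all__ = [
    "ModelParams",
    "CellFace",
    "TissueMesh",
    "ValidationReport",
    "MeshError",
    "InvalidPolygonError",
    "DegeneratePolygonError",
    "GeometryViolationError",
    "SelectionError",
    "polygon_metrics",
    "circularity",
    "elastic_energy",
    "tissue_energy",
    "local_energy_delta",
    "build_initial_tissue",
    "select_tracked_cells",
    "validate_mesh",
    "write_mesh",
    "read_mesh",
]


class MeshError(ValueError):
    """Base class for mesh geometry/topology errors."""


class InvalidPolygonError(MeshError):
    """A polygon with fewer than three vertices."""


class DegeneratePolygonError(MeshError):
    """A polygon with (numerically) zero area."""


class GeometryViolationError(MeshError):
    """A vertex move that would make an incident face non-simple or inverted."""


class SelectionError(MeshError):
    """Not enough eligible cells for a tracked-cell selection."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless vertex-model parameters.

    Defaults are the published working point of the model: line tension
    0.06 and perimeter contractility 0.02 (area elasticity K = 1 by
    nondimensionalisation), boundary edges stiffened by a factor 1.6,
    Metropolis uphill acceptance probability 0.05, maximal trial
    displacement 0.005 sqrt(A0) per coordinate, T1 threshold distance 0.2,
    and 130,000 vertex iterations per simulation time step (sts).
    """

    line_tension_tilde: float = 0.06
    contractility_tilde: float = 0.02
    boundary_tension_factor: float = 1.6
    area_elasticity: float = 1.0
    p_accept: float = 0.05
    delta_max: float = 0.005
    d_min: float = 0.2
    iterations_per_sts: int = 130_000
    a0_min: float = 1e-3

    def __post_init__(self) -> None:
        for name in (
            "line_tension_tilde",
            "contractility_tilde",
            "boundary_tension_factor",
            "area_elasticity",
            "p_accept",
            "delta_max",
            "d_min",
            "a0_min",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"ModelParams.{name} must be strictly positive")
        if self.iterations_per_sts <= 0:
            raise ValueError("ModelParams.iterations_per_sts must be positive")
        if self.p_accept > 1:
            raise ValueError("ModelParams.p_accept must lie in (0, 1]")
        if not self.d_min > self.delta_max:
            raise ValueError("ModelParams.d_min must exceed delta_max")

    def boundary_tension(self) -> float:
        return self.boundary_tension_factor * self.line_tension_tilde

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Mesh data structures
# ---------------------------------------------------------------------------


@dataclass
class CellFace:
    """One cell: an ordered (counter-clockwise) ring of vertex ids plus
    its mechanical state."""

    vertex_ids: List[int]
    resting_area: float = 1.0
    contractility: float = 0.02
    tracked: bool = False

    def copy(self) -> "CellFace":
        return CellFace(
            list(self.vertex_ids), self.resting_area, self.contractility, self.tracked
        )


class TissueMesh:
    """Polygonal cell tessellation with disk topology.

    ``vertices`` is an (nv, 2) float array of positions in units of
    sqrt(A0); ``faces`` a list of :class:`CellFace`.  Edges and the
    edge -> incident-face adjacency are derived from the face rings;
    ``boundary_edges`` flags edges bordering a single cell.
    """

    def __init__(self, vertices: np.ndarray, faces: List[CellFace]):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = faces
        self._edge_map: Optional[Dict[Tuple[int, int], List[int]]] = None
        self._vertex_faces: Optional[Dict[int, List[int]]] = None

    # -- derived topology ---------------------------------------------------

    def invalidate_topology_cache(self) -> None:
        self._edge_map = None
        self._vertex_faces = None

    def edge_map(self) -> Dict[Tuple[int, int], List[int]]:
        """Map (u, v) with u < v to the list of incident face indices."""
        if self._edge_map is None:
            em: Dict[Tuple[int, int], List[int]] = {}
            for fi, face in enumerate(self.faces):
                ring = face.vertex_ids
                for k in range(len(ring)):
                    u, v = ring[k], ring[(k + 1) % len(ring)]
                    key = (u, v) if u < v else (v, u)
                    em.setdefault(key, []).append(fi)
            self._edge_map = em
        return self._edge_map

    def vertex_faces(self) -> Dict[int, List[int]]:
        if self._vertex_faces is None:
            vf: Dict[int, List[int]] = {}
            for fi, face in enumerate(self.faces):
                for v in face.vertex_ids:
                    vf.setdefault(v, []).append(fi)
            self._vertex_faces = vf
        return self._vertex_faces

    def boundary_edges(self) -> Set[Tuple[int, int]]:
        return {e for e, fs in self.edge_map().items() if len(fs) == 1}

    def boundary_faces(self) -> Set[int]:
        out: Set[int] = set()
        for e, fs in self.edge_map().items():
            if len(fs) == 1:
                out.add(fs[0])
        return out

    def face_coords(self, face_index: int) -> np.ndarray:
        return self.vertices[self.faces[face_index].vertex_ids]

    def n_cells(self) -> int:
        return len(self.faces)

    def used_vertex_ids(self) -> Set[int]:
        used: Set[int] = set()
        for f in self.faces:
            used.update(f.vertex_ids)
        return used

    def copy(self) -> "TissueMesh":
        return TissueMesh(self.vertices.copy(), [f.copy() for f in self.faces])

    # -- per-cell observables ----------------------------------------------

    def shape_observables(self, face_indices: Optional[Sequence[int]] = None):
        """(area, perimeter, circularity) arrays for the given faces
        (default: all)."""
        idx = range(len(self.faces)) if face_indices is None else face_indices
        A, P, C = [], [], []
        for fi in idx:
            a, p = polygon_metrics(self.face_coords(fi))
            A.append(a)
            P.append(p)
            C.append(circularity(a, p))
        return np.array(A), np.array(P), np.array(C)


# ---------------------------------------------------------------------------
# Polygon geometry
# ---------------------------------------------------------------------------


def signed_area(coords: np.ndarray) -> float:
    x = coords[:, 0]
    y = coords[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_metrics(ring_coordinates) -> Tuple[float, float]:
    """Area (shoelace, absolute value) and perimeter of a simple polygon."""
    coords = np.asarray(ring_coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 2:
        raise InvalidPolygonError("polygon needs at least 3 two-dimensional points")
    area = abs(signed_area(coords))
    if area <= 1e-300:
        raise DegeneratePolygonError("polygon has zero area")
    diffs = np.roll(coords, -1, axis=0) - coords
    perimeter = float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))
    return area, perimeter


def circularity(area: float, perimeter: float) -> float:
    """4*pi*area/perimeter^2 — 1 for a circle, < 1 for any polygon."""
    if not (area > 0 and perimeter > 0):
        raise ValueError("circularity requires positive area and perimeter")
    return 4.0 * math.pi * area / perimeter**2


def _segments_properly_intersect(p1, p2, p3, p4) -> bool:
    """True if open segments (p1,p2) and (p3,p4) cross."""

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 != d2 and d3 != d4


def polygon_is_simple(coords: np.ndarray) -> bool:
    """Pairwise-segment simplicity test, O(k^2) within a single ring."""
    k = len(coords)
    segs = [(coords[i], coords[(i + 1) % k]) for i in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            if j == i + 1 or (i == 0 and j == k - 1):
                continue  # adjacent segments share an endpoint
            if _segments_properly_intersect(*segs[i], *segs[j]):
                return False
    return True


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------


def elastic_energy(area: float, resting_area: float, a0_min: float = 1e-3) -> float:
    """Area-elasticity term.

    The dimensionless form 1/2 (A/A0 - 1)^2 diverges as the resting area
    A0 -> 0 under the resting-area protocol; below the floor ``a0_min`` the
    term switches to the dimensional form 1/2 K (A - A0)^2 (K = 1), which
    keeps the energy finite while preserving the drive toward zero area.
    """
    if resting_area >= a0_min:
        return 0.5 * (area / resting_area - 1.0) ** 2
    return 0.5 * (area - resting_area) ** 2


def _edge_tension(is_boundary: bool, params: ModelParams) -> float:
    return params.boundary_tension() if is_boundary else params.line_tension_tilde


def tissue_energy(mesh: TissueMesh, params: ModelParams) -> float:
    """Total mechanical energy of the tissue (each edge counted once)."""
    E = 0.0
    for face in mesh.faces:
        coords = mesh.vertices[face.vertex_ids]
        area, perim = polygon_metrics(coords)
        E += elastic_energy(area, face.resting_area, params.a0_min)
        E += 0.5 * face.contractility * perim**2
    for (u, v), fs in mesh.edge_map().items():
        lam = _edge_tension(len(fs) == 1, params)
        E += lam * float(np.hypot(*(mesh.vertices[u] - mesh.vertices[v])))
    return E


def local_energy_delta(
    mesh: TissueMesh,
    vertex_id: int,
    new_position,
    params: ModelParams,
    check_geometry: bool = True,
) -> float:
    """Energy change of moving one vertex, using only incident elements.

    Raises :class:`GeometryViolationError` if the move would make an
    incident face non-simple or non-positive in area (unless
    ``check_geometry`` is disabled).
    """
    new_position = np.asarray(new_position, dtype=float)
    if not np.all(np.isfinite(new_position)):
        raise ValueError("new_position must be finite")
    vf = mesh.vertex_faces()
    if vertex_id not in vf:
        raise KeyError(f"vertex {vertex_id} not part of any face")
    old = mesh.vertices[vertex_id].copy()

    dE = 0.0
    for fi in vf[vertex_id]:
        face = mesh.faces[fi]
        coords_old = mesh.vertices[face.vertex_ids]
        k = face.vertex_ids.index(vertex_id)
        coords_new = coords_old.copy()
        coords_new[k] = new_position
        a_old, p_old = polygon_metrics(coords_old)
        if check_geometry:
            new_signed = signed_area(coords_new)
            if new_signed <= 1e-12 or not polygon_is_simple(coords_new):
                raise GeometryViolationError(
                    f"move of vertex {vertex_id} inverts or self-intersects face {fi}"
                )
        try:
            a_new, p_new = polygon_metrics(coords_new)
        except DegeneratePolygonError as exc:
            raise GeometryViolationError(str(exc)) from exc
        dE += elastic_energy(a_new, face.resting_area, params.a0_min) - elastic_energy(
            a_old, face.resting_area, params.a0_min
        )
        dE += 0.5 * face.contractility * (p_new**2 - p_old**2)

    em = mesh.edge_map()
    neighbors: Set[int] = set()
    for fi in vf[vertex_id]:
        ring = mesh.faces[fi].vertex_ids
        k = ring.index(vertex_id)
        neighbors.add(ring[k - 1])
        neighbors.add(ring[(k + 1) % len(ring)])
    for u in neighbors:
        key = (u, vertex_id) if u < vertex_id else (vertex_id, u)
        lam = _edge_tension(len(em[key]) == 1, params)
        l_old = float(np.hypot(*(mesh.vertices[u] - old)))
        l_new = float(np.hypot(*(mesh.vertices[u] - new_position)))
        dE += lam * (l_new - l_old)
    return dE


# ---------------------------------------------------------------------------
# Initial tissue construction
# ---------------------------------------------------------------------------


def _voronoi_with_ghosts(points: np.ndarray, radius: float) -> Voronoi:
    """Voronoi diagram of the seeds plus two ghost rings outside the disk,
    guaranteeing every real region is finite and bounded."""
    n_ghost = max(64, int(4 * math.pi * radius))
    out = []
    for ring_r, phase in ((radius + 1.2, 0.0), (radius + 2.4, 0.5)):
        theta = (np.arange(n_ghost) + phase) * (2 * math.pi / n_ghost)
        out.append(np.c_[ring_r * np.cos(theta), ring_r * np.sin(theta)])
    return Voronoi(np.vstack([points] + out))


def _region_polygon(vor: Voronoi, point_index: int) -> List[int]:
    region = vor.regions[vor.point_region[point_index]]
    if -1 in region or len(region) < 3:
        raise MeshError("unbounded Voronoi region inside the tissue")
    return region


def build_initial_tissue(
    n_cells: int,
    seed: int,
    lloyd_steps: int = 3,
    initial_area_ratio: float = 3.7,
    params: Optional[ModelParams] = None,
) -> TissueMesh:
    """Build a disordered disk-shaped tissue of ``n_cells`` polygonal cells.

    Seeds are drawn uniformly in a disk, tessellated by a Voronoi diagram
    (kept finite by ghost points outside the disk), regularised by
    ``lloyd_steps`` Lloyd relaxation steps, and rescaled so the mean cell
    area equals ``initial_area_ratio`` (in units of the resting area).

    The default ``initial_area_ratio`` of 3.7 reproduces the published
    initial tracked-cell perimeter of ~7.6: the tissue starts pre-stretched
    relative to the resting area.  Because the tessellation conserves total
    area in the bulk, such a tissue is relaxation-limited and quasi-stable
    under control dynamics even though each cell is far from its resting
    area.  Every face starts with resting_area 1 and the model
    contractility; deterministic for a fixed seed.
    """
    if n_cells < 3:
        raise ValueError("n_cells must be at least 3")
    params = params or ModelParams()
    rng = np.random.default_rng(seed)
    radius = math.sqrt(n_cells / math.pi)

    # uniform points in the disk
    r = radius * np.sqrt(rng.random(n_cells))
    phi = 2 * math.pi * rng.random(n_cells)
    pts = np.c_[r * np.cos(phi), r * np.sin(phi)]

    vor = _voronoi_with_ghosts(pts, radius)
    for _ in range(lloyd_steps):
        new_pts = np.empty_like(pts)
        for i in range(n_cells):
            poly = vor.vertices[_region_polygon(vor, i)]
            # polygon centroid
            x, y = poly[:, 0], poly[:, 1]
            cross = x * np.roll(y, -1) - np.roll(x, -1) * y
            a = 0.5 * cross.sum()
            cx = np.sum((x + np.roll(x, -1)) * cross) / (6 * a)
            cy = np.sum((y + np.roll(y, -1)) * cross) / (6 * a)
            new_pts[i] = (cx, cy)
        pts = new_pts
        vor = _voronoi_with_ghosts(pts, radius)

    # collect regions, remap vertex ids
    vid_map: Dict[int, int] = {}
    verts: List[Tuple[float, float]] = []
    faces: List[CellFace] = []
    for i in range(n_cells):
        region = _region_polygon(vor, i)
        ring = []
        for vid in region:
            if vid not in vid_map:
                vid_map[vid] = len(verts)
                verts.append(tuple(vor.vertices[vid]))
            ring.append(vid_map[vid])
        coords = np.array([verts[j] for j in ring])
        if signed_area(coords) < 0:
            ring.reverse()
        faces.append(
            CellFace(ring, resting_area=1.0, contractility=params.contractility_tilde)
        )

    vertices = np.array(verts, dtype=float)
    mesh = TissueMesh(vertices, faces)
    areas, _, _ = mesh.shape_observables()
    scale = math.sqrt(initial_area_ratio / float(areas.mean()))
    mesh.vertices *= scale
    return mesh


def select_tracked_cells(
    mesh: TissueMesh,
    n: int,
    seed: int,
    min_boundary_distance: int = 3,
) -> List[int]:
    """Pick ``n`` cells scattered in the tissue interior and mark them tracked.

    Eligibility: at least ``min_boundary_distance`` cell-adjacency steps
    from any boundary cell (a boundary cell has distance 0).  Deterministic
    for a fixed seed; raises :class:`SelectionError` reporting the number of
    eligible cells when fewer than ``n`` exist.
    """
    if n == 0:
        return []
    # face adjacency graph
    adjacency: Dict[int, Set[int]] = {i: set() for i in range(len(mesh.faces))}
    for e, fs in mesh.edge_map().items():
        if len(fs) == 2:
            adjacency[fs[0]].add(fs[1])
            adjacency[fs[1]].add(fs[0])
    dist = {fi: 0 for fi in mesh.boundary_faces()}
    frontier = list(dist)
    while frontier:
        nxt = []
        for fi in frontier:
            for fj in adjacency[fi]:
                if fj not in dist:
                    dist[fj] = dist[fi] + 1
                    nxt.append(fj)
        frontier = nxt
    eligible = sorted(
        fi
        for fi in range(len(mesh.faces))
        if dist.get(fi, math.inf) >= min_boundary_distance
    )
    if len(eligible) < n:
        raise SelectionError(
            f"requested {n} tracked cells but only {len(eligible)} lie at "
            f">= {min_boundary_distance} steps from the boundary"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(eligible, size=n, replace=False).tolist())
    for fi in chosen:
        mesh.faces[fi].tracked = True
    return chosen


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    violations: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


def validate_mesh(mesh: TissueMesh) -> ValidationReport:
    """Check all mesh invariants; report-only (never raises).

    Checks: ring size >= 3, positive signed area under the CCW convention,
    simplicity of every face ring, edge incidence counts (1 for boundary,
    2 for internal), and the Euler relation V - E + F = 1 of a
    disk-topology tissue.
    """
    report = ValidationReport()
    for fi, face in enumerate(mesh.faces):
        ring = face.vertex_ids
        if len(ring) < 3:
            report.add(f"face {fi}: fewer than 3 vertices")
            continue
        if len(set(ring)) != len(ring):
            report.add(f"face {fi}: repeated vertex in ring")
            continue
        coords = mesh.vertices[ring]
        sa = signed_area(coords)
        if sa <= 0:
            report.add(f"face {fi}: non-positive signed area {sa:.3e}")
        if not polygon_is_simple(coords):
            report.add(f"face {fi}: non-simple polygon")
        if face.resting_area < 0:
            report.add(f"face {fi}: negative resting area")
    for e, fs in mesh.edge_map().items():
        if len(fs) not in (1, 2):
            report.add(f"edge {e}: incident to {len(fs)} faces")
    V = len(mesh.used_vertex_ids())
    E = len(mesh.edge_map())
    F = len(mesh.faces)
    if V - E + F != 1:
        report.add(f"Euler relation violated: V-E+F = {V}-{E}+{F} = {V - E + F}")
    return report


# ---------------------------------------------------------------------------
# Serialisation (versioned plain-text mesh snapshot)
# ---------------------------------------------------------------------------


def mesh_to_dict(mesh: TissueMesh) -> dict:
    em = mesh.edge_map()
    return {
        "format": "epiextrude-mesh",
        "version": MESH_FORMAT_VERSION,
        "vertices": [
            {"id": int(i), "x": float(x), "y": float(y)}
            for i, (x, y) in enumerate(mesh.vertices)
        ],
        "edges": [
            {"id": k, "v1": int(u), "v2": int(v), "boundary": len(fs) == 1}
            for k, ((u, v), fs) in enumerate(sorted(em.items()))
        ],
        "faces": [
            {
                "id": fi,
                "vertex_ring": [int(v) for v in f.vertex_ids],
                "resting_area": float(f.resting_area),
                "contractility": float(f.contractility),
                "tracked": bool(f.tracked),
            }
            for fi, f in enumerate(mesh.faces)
        ],
    }


def mesh_from_dict(d: dict) -> TissueMesh:
    if d.get("format") != "epiextrude-mesh":
        raise MeshError("not a mesh snapshot file")
    if d.get("version") != MESH_FORMAT_VERSION:
        raise MeshError(f"unsupported mesh format version {d.get('version')!r}")
    nv = max(v["id"] for v in d["vertices"]) + 1
    vertices = np.zeros((nv, 2))
    for v in d["vertices"]:
        vertices[v["id"]] = (v["x"], v["y"])
    faces = [
        CellFace(
            list(f["vertex_ring"]),
            resting_area=f["resting_area"],
            contractility=f["contractility"],
            tracked=f["tracked"],
        )
        for f in sorted(d["faces"], key=lambda f: f["id"])
    ]
    return TissueMesh(vertices, faces)


def write_mesh(mesh: TissueMesh, path) -> None:
    with open(path, "w") as fh:
        json.dump(mesh_to_dict(mesh), fh)


def read_mesh(path) -> TissueMesh:
    with open(path) as fh:
        return mesh_from_dict(json.load(fh))
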