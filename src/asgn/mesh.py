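"""Triangular meshes of rectangular domains and straight-ray traversal.

Coordinates have their origin at the domain's lower-left corner, x to the
right and y up; all lengths are in mm.  Meshes are conforming
triangulations with counter-clockwise elements; element ``j`` has area
``A_j`` and local edge ``e`` joining vertices ``(e, (e+1) % 3)``.

A single absolute tolerance of 1e-12 mm is used for point-on-edge and
intersection tests; rays that hit a vertex are recovered by nudging the
intersection point forward by 1e-9 mm and relocating, which avoids
infinite loops on degenerate crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernels

__all__ = [
    "Mesh2D",
    "RaySegmentChain",
    "build_rectangle_mesh",
    "locate_element",
    "trace_ray",
    "save_mesh",
    "load_mesh",
]

SIDES = ("left", "right", "top", "bottom")


@dataclass
class RaySegmentChain:
    """Ordered element crossings of a straight ray.

    ``points`` has one more row than segments: ``points[i]`` is the entry
    point of segment ``i`` and ``points[i + 1]`` its exit point.
    ``terminal`` is ``"boundary"`` (the ray left the domain) or
    ``"interior"`` (the requested length was consumed inside an element).
    """

    elements: np.ndarray
    points: np.ndarray
    lengths: np.ndarray
    terminal: str

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


@dataclass
class Mesh2D:
    """Conforming triangulation of a rectangle.

    Derived connectivity (areas, per-edge adjacency, outward boundary
    normals, side labels) is computed once at construction.
    ``element_adjacency[j, e]`` is the neighbour across local edge ``e``
    of element ``j``, or -1 on the boundary.
    """

    node_coords: np.ndarray
    triangles: np.ndarray
    width: float
    height: float
    element_areas: np.ndarray = field(init=False)
    element_adjacency: np.ndarray = field(init=False)
    edge_origin: np.ndarray = field(init=False)
    edge_normal: np.ndarray = field(init=False)
    centroids: np.ndarray = field(init=False)
    boundary_edges: list = field(init=False)

    def __post_init__(self):
        nodes = np.ascontiguousarray(self.node_coords, dtype=np.float64)
        tris = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if nodes.ndim != 2 or nodes.shape[1] != 2:
            raise ValueError("node_coords must be (n_nodes, 2)")
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise ValueError("triangles must be (n_elements, 3)")
        # orient counter-clockwise
        a = nodes[tris[:, 0]]
        b = nodes[tris[:, 1]]
        c = nodes[tris[:, 2]]
        cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
            c[:, 0] - a[:, 0]
        )
        flip = cross < 0
        tris[flip] = tris[flip][:, ::-1]
        cross = np.abs(cross)
        if np.any(cross <= 0):
            raise ValueError("degenerate (zero-area) element in triangulation")
        self.node_coords = nodes
        self.triangles = tris
        self.element_areas = 0.5 * cross
        self.centroids = nodes[tris].mean(axis=1)
        self._build_connectivity()

    def _build_connectivity(self):
        nodes, tris = self.node_coords, self.triangles
        n = tris.shape[0]
        adj = np.full((n, 3), -1, dtype=np.int64)
        edge_map: dict[tuple[int, int], tuple[int, int]] = {}
        for j in range(n):
            for e in range(3):
                key = tuple(sorted((int(tris[j, e]), int(tris[j, (e + 1) % 3]))))
                if key in edge_map:
                    j2, e2 = edge_map.pop(key)
                    adj[j, e] = j2
                    adj[j2, e2] = j
                else:
                    edge_map[key] = (j, e)
        self.element_adjacency = adj
        # per-edge origin and outward unit normal (CCW: right-hand normal)
        origin = np.empty((n, 3, 2))
        normal = np.empty((n, 3, 2))
        for e in range(3):
            a = nodes[tris[:, e]]
            b = nodes[tris[:, (e + 1) % 3]]
            d = b - a
            ln = np.hypot(d[:, 0], d[:, 1])
            origin[:, e, :] = a
            normal[:, e, 0] = d[:, 1] / ln
            normal[:, e, 1] = -d[:, 0] / ln
        self.edge_origin = np.ascontiguousarray(origin)
        self.edge_normal = np.ascontiguousarray(normal)
        self.boundary_edges = []
        for j, e in np.argwhere(adj == -1):
            nrm = normal[j, e]
            self.boundary_edges.append((int(j), int(e), nrm.copy(), _side_label(nrm)))

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def boundary_edges_on_side(self, side: str):
        if side not in SIDES:
            raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
        return [be for be in self.boundary_edges if be[3] == side]


def _side_label(normal: np.ndarray) -> str:
    nx, ny = normal
    if abs(nx) >= abs(ny):
        return "right" if nx > 0 else "left"
    return "top" if ny > 0 else "bottom"


def build_rectangle_mesh(
    width_mm: float, height_mm: float, target_n_elements: int
) -> Mesh2D:
    """Structured triangulation of a ``width_mm x height_mm`` rectangle.

    A regular grid is split into two triangles per cell; the grid
    resolution is chosen so the element count approaches
    ``target_n_elements`` (guaranteed within 25% for targets >= 2).
    """
    if width_mm <= 0 or height_mm <= 0:
        raise ValueError("domain dimensions must be positive")
    if target_n_elements < 2:
        raise ValueError("target_n_elements must be at least 2")
    scale = np.sqrt(target_n_elements / (2.0 * width_mm * height_mm))
    nx = max(1, int(round(width_mm * scale)))
    ny = max(1, int(round(height_mm * scale)))
    # refine the rounding if it drifted outside 25%
    best = (nx, ny)
    best_err = abs(2 * nx * ny - target_n_elements)
    for dx_ in (-1, 0, 1):
        for dy_ in (-1, 0, 1):
            cx, cy = nx + dx_, ny + dy_
            if cx < 1 or cy < 1:
                continue
            err = abs(2 * cx * cy - target_n_elements)
            if err < best_err:
                best, best_err = (cx, cy), err
    nx, ny = best
    xs = np.linspace(0.0, width_mm, nx + 1)
    ys = np.linspace(0.0, height_mm, ny + 1)
    xx, yy = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([xx.ravel(), yy.ravel()])

    def nid(ix, iy):
        return iy * (nx + 1) + ix

    tris = []
    for iy in range(ny):
        for ix in range(nx):
            n00 = nid(ix, iy)
            n10 = nid(ix + 1, iy)
            n01 = nid(ix, iy + 1)
            n11 = nid(ix + 1, iy + 1)
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
    return Mesh2D(nodes, np.asarray(tris, dtype=np.int64), float(width_mm), float(height_mm))


def locate_element(mesh: Mesh2D, point) -> int:
    """Element whose closed triangle contains ``point``.

    Points on shared edges resolve to the lowest incident element id.
    Raises ``ValueError`` for points outside the closed domain.
    """
    px, py = float(point[0]), float(point[1])
    e = _kernels.locate_kernel(px, py, mesh.node_coords, mesh.triangles, 1e-9)
    if e == -1:
        raise ValueError(f"point {point} is outside the domain")
    return int(e)


def trace_ray(
    mesh: Mesh2D,
    start,
    direction,
    start_element: int | None = None,
    max_length: float = np.inf,
) -> RaySegmentChain:
    """Trace a straight ray through the mesh from ``start``.

    The chain ends when ``max_length`` is consumed inside an element
    (terminal ``"interior"``) or when a boundary edge is crossed
    (terminal ``"boundary"``).
    """
    d = np.asarray(direction, dtype=float)
    nd = np.hypot(d[0], d[1])
    if nd < 1e-14:
        raise ValueError("ray direction must be nonzero")
    if abs(nd - 1.0) > 1e-9:
        raise ValueError("ray direction must have unit norm")
    if start_element is None:
        start_element = locate_element(mesh, start)
    cap = 4 * mesh.n_elements + 64
    out_elems = np.empty(cap, dtype=np.int64)
    out_pts = np.empty((cap + 1, 2))
    out_lens = np.empty(cap)
    if not np.isfinite(max_length):
        # any chord of the rectangle is shorter than its diagonal
        max_length = 2.0 * float(np.hypot(mesh.width, mesh.height))
    nseg, terminal = _kernels.trace_ray_kernel(
        float(start[0]),
        float(start[1]),
        float(d[0]),
        float(d[1]),
        int(start_element),
        float(max_length),
        mesh.node_coords,
        mesh.triangles,
        mesh.element_adjacency,
        mesh.edge_origin,
        mesh.edge_normal,
        out_elems,
        out_pts,
        out_lens,
    )
    term = "boundary" if terminal == _kernels.TERM_BOUNDARY else "interior"
    return RaySegmentChain(
        elements=out_elems[:nseg].copy(),
        points=out_pts[: nseg + 1].copy(),
        lengths=out_lens[:nseg].copy(),
        terminal=term,
    )


def save_mesh(mesh: Mesh2D, path: str) -> None:
    """Write nodes/triangles (0-based) to HDF5, or to plain text pairs
    ``<path>.nodes.txt`` / ``<path>.triangles.txt`` if ``path`` ends in
    ``.txt``."""
    if str(path).endswith(".txt"):
        base = str(path)[:-4]
        np.savetxt(base + ".nodes.txt", mesh.node_coords)
        np.savetxt(base + ".triangles.txt", mesh.triangles, fmt="%d")
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("nodes", data=mesh.node_coords)
        f.create_dataset("triangles", data=mesh.triangles)
        f.attrs["width_mm"] = mesh.width
        f.attrs["height_mm"] = mesh.height


def load_mesh(path: str) -> Mesh2D:
    """Read a mesh container written by :func:`save_mesh` (HDF5 or the
    plain-text pair); arbitrary conforming triangulations are accepted."""
    if str(path).endswith(".txt"):
        base = str(path)[:-4]
        nodes = np.loadtxt(base + ".nodes.txt", ndmin=2)
        tris = np.loadtxt(base + ".triangles.txt", dtype=np.int64, ndmin=2)
        width = float(nodes[:, 0].max() - nodes[:, 0].min())
        height = float(nodes[:, 1].max() - nodes[:, 1].min())
        return Mesh2D(nodes, tris, width, height)
    with h5py.File(path, "r") as f:
        nodes = f["nodes"][...]
        tris = f["triangles"][...]
        width = float(f.attrs.get("width_mm", nodes[:, 0].max() - nodes[:, 0].min()))
        height = float(f.attrs.get("height_mm", nodes[:, 1].max() - nodes[:, 1].min()))
    return Mesh2D(nodes, tris, width, height)
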