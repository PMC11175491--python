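"""Structured triangulation of the AAA slice.

Both material regions are mapped annuli meshed with a transfinite blend
between their bounding circles:

* thrombus: between the (possibly eccentric) lumen circle and the wall
  inner circle,
* wall: between the inner and outer wall circles.

For every admissible geometry (lumen strictly inside the cavity) the blend
``p(theta, s) = (1-s) L(theta) + s W(theta)`` is non-degenerate, because the
Jacobian condition reduces exactly to the containment inequality
``|offset| + r_lumen < r_inner``.  Rings share the angular discretisation, so
the wall-thrombus interface is bonded node-for-node.  Quads are split into
triangles with alternating diagonals; with the angular count a multiple of
16 the mesh is symmetric under 45-degree rotation (central case) and under
reflection about the anterior-posterior axis, which the symmetry tests rely
on.

Coordinates are millimetres throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, MeshQualityError
from .geometry import SliceGeometry

__all__ = ["Mesh", "build_mesh", "write_msh", "read_msh", "ring_interpolate"]

REGION_WALL = 1
REGION_THROMBUS = 2
REGION_NAMES = {REGION_WALL: "wall", REGION_THROMBUS: "thrombus"}

BOUNDARY_OUTER = 11
BOUNDARY_LINING = 12
BOUNDARY_NAMES = {BOUNDARY_OUTER: "outer_surface", BOUNDARY_LINING: "lumen_lining"}


@dataclass
class Mesh:
    """Conforming triangle mesh of the slice with region and boundary tags.

    ``outer_nodes`` / ``lining_nodes`` are the ordered boundary rings
    (outer counter-clockwise, lining clockwise around the lumen so that the
    solid is always to the left of each oriented boundary edge).
    """

    nodes: np.ndarray            # (n, 2) mm
    triangles: np.ndarray        # (m, 3) int
    tri_region: np.ndarray       # (m,) int, REGION_*
    boundary_edges: dict         # tag -> (e, 2) int, oriented solid-left
    outer_nodes: np.ndarray      # ordered ring indices
    lining_nodes: np.ndarray
    interface_nodes: np.ndarray  # wall-thrombus interface ring (empty if no thrombus)
    characteristic_size: dict = field(default_factory=dict)
    n_theta: int = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def min_angle_deg(self) -> float:
        p = self.nodes[self.triangles]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return float(np.min(angles))

    def region_area(self, region: int) -> float:
        return float(self.signed_areas()[self.tri_region == region].sum())

    def boundary_arc_weights(self, ring: np.ndarray) -> np.ndarray:
        """Arc length attributed to each node of a closed ring (trapezoidal)."""
        xy = self.nodes[ring]
        seg = np.linalg.norm(np.roll(xy, -1, axis=0) - xy, axis=1)
        return 0.5 * (seg + np.roll(seg, 1))


def _ring_count(circumference: float, h: float) -> int:
    n = int(math.ceil(circumference / h))
    return max(16, ((n + 15) // 16) * 16)


def _stack_rows(rows: list[np.ndarray]) -> tuple[np.ndarray, int]:
    nodes = np.vstack(rows)
    return nodes, rows[0].shape[0]


def _quad_rows_to_tris(n_rows: int, n_theta: int, row_offset: int = 0) -> np.ndarray:
    """Triangulate rows of quads with parity-alternating diagonals."""
    tris = []
    for i in range(n_rows - 1):
        base0 = (row_offset + i) * n_theta
        base1 = (row_offset + i + 1) * n_theta
        k = np.arange(n_theta)
        kp = (k + 1) % n_theta
        p00, p10 = base0 + k, base0 + kp
        p01, p11 = base1 + k, base1 + kp
        even = k % 2 == 0
        t = np.empty((n_theta, 2, 3), dtype=np.int64)
        # even k: diagonal p00-p11; odd k: diagonal p10-p01 (all CCW)
        t[even, 0] = np.stack([p00, p11, p10], axis=1)[even]
        t[even, 1] = np.stack([p00, p01, p11], axis=1)[even]
        t[~even, 0] = np.stack([p00, p01, p10], axis=1)[~even]
        t[~even, 1] = np.stack([p10, p01, p11], axis=1)[~even]
        tris.append(t.reshape(-1, 3))
    return np.vstack(tris) if tris else np.empty((0, 3), dtype=np.int64)


def build_mesh(
    geometry: SliceGeometry,
    h_tissue: float = 0.4,
    h_spine: float = 2.0,
    min_angle_floor: float = 1.0,
) -> Mesh:
    """Mesh the slice with characteristic tissue cell size ``h_tissue`` (mm).

    ``h_spine`` is kept for interface parity with the meshing conventions of
    the study (the rigid spine needs no own mesh in this formulation).

    Raises
    ------
    MeshQualityError
        If the minimum element angle falls below ``min_angle_floor`` degrees.
    """
    a = geometry.wall_inner_radius
    b = geometry.wall_outer_radius
    r_l = geometry.lumen_radius
    c = geometry.lumen_center

    n_theta = _ring_count(2.0 * math.pi * b, h_tissue)
    theta = 2.0 * math.pi * np.arange(n_theta) / n_theta
    e = np.stack([np.cos(theta), np.sin(theta)], axis=1)

    rows: list[np.ndarray] = []
    if geometry.has_thrombus:
        lumen_ring = c[None, :] + r_l * e
        inner_ring = a * e
        gaps = np.linalg.norm(inner_ring - lumen_ring, axis=1)
        n_r_thr = max(1, int(round(float(gaps.mean()) / h_tissue)))
        for i in range(n_r_thr):  # s in [0,1): lumen row .. last row before interface
            s = i / n_r_thr
            rows.append((1.0 - s) * lumen_ring + s * inner_ring)
        thrombus_rows = n_r_thr
    else:
        thrombus_rows = 0

    n_r_wall = max(1, int(round(geometry.wall_thickness / h_tissue)))
    for j in range(n_r_wall + 1):
        r = a + geometry.wall_thickness * j / n_r_wall
        rows.append(r * e)

    nodes = np.vstack(rows)
    n_rows_total = len(rows)

    tris = _quad_rows_to_tris(n_rows_total, n_theta)
    rows_per_tri_band = 2 * n_theta
    tri_region = np.full(tris.shape[0], REGION_WALL, dtype=np.int64)
    tri_region[: thrombus_rows * rows_per_tri_band] = REGION_THROMBUS

    k = np.arange(n_theta)
    outer_ring = (n_rows_total - 1) * n_theta + k
    lining_ring = k  # row 0 (lumen circle, or inner wall surface if no thrombus)
    interface_ring = (
        thrombus_rows * n_theta + k if thrombus_rows else np.empty(0, dtype=np.int64)
    )

    # solid-left orientation: outer loop CCW, lining loop CW
    outer_edges = np.stack([outer_ring, np.roll(outer_ring, -1)], axis=1)
    lining_edges = np.stack([np.roll(lining_ring, -1), lining_ring], axis=1)

    mesh = Mesh(
        nodes=nodes,
        triangles=tris,
        tri_region=tri_region,
        boundary_edges={BOUNDARY_OUTER: outer_edges, BOUNDARY_LINING: lining_edges},
        outer_nodes=outer_ring,
        lining_nodes=lining_ring[::-1].copy(),
        interface_nodes=interface_ring,
        characteristic_size={"tissue": h_tissue, "spine": h_spine},
        n_theta=n_theta,
    )
    if np.any(mesh.signed_areas() <= 0):
        raise MeshQualityError("inverted elements in structured mesh")
    min_ang = mesh.min_angle_deg()
    if min_ang < min_angle_floor:
        raise MeshQualityError(
            f"minimum element angle {min_ang:.2f} deg below floor "
            f"{min_angle_floor:.2f} deg; geometry too thin for h={h_tissue} mm"
        )
    return mesh


def ring_interpolate(
    ring_xy: np.ndarray,
    ring_values: np.ndarray,
    query_xy: np.ndarray,
    center: np.ndarray,
) -> np.ndarray:
    """Periodic linear interpolation of nodal values along a closed ring.

    Values are parameterised by the polar angle about ``center``; queries must
    lie on (or near) the ring.
    """
    ang = np.arctan2(ring_xy[:, 1] - center[1], ring_xy[:, 0] - center[0])
    order = np.argsort(ang)
    ang_s = ang[order]
    val_s = np.asarray(ring_values)[order]
    q = np.arctan2(query_xy[:, 1] - center[1], query_xy[:, 0] - center[0])
    ang_ext = np.concatenate([ang_s, ang_s[:1] + 2.0 * math.pi])
    val_ext = np.concatenate([val_s, val_s[:1]])
    q_mod = np.where(q < ang_s[0], q + 2.0 * math.pi, q)
    return np.interp(q_mod, ang_ext, val_ext)


# ---------------------------------------------------------------------------
# Gmsh MSH v2 (ASCII) export / import


def write_msh(mesh: Mesh, path) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII with physical tags for regions
    (1 wall, 2 thrombus) and boundary lines (11 outer surface, 12 lumen
    lining)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.16g} {y:.16g} 0")
    lines.append("$EndNodes")
    n_bnd = sum(len(e) for e in mesh.boundary_edges.values())
    lines += ["$Elements", str(mesh.n_elements + n_bnd)]
    eid = 1
    for tag, edges in sorted(mesh.boundary_edges.items()):
        for n1, n2 in edges:
            lines.append(f"{eid} 1 2 {tag} {tag} {n1 + 1} {n2 + 1}")
            eid += 1
    for tri, reg in zip(mesh.triangles, mesh.tri_region):
        lines.append(f"{eid} 2 2 {reg} {reg} {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path) -> Mesh:
    """Read a mesh previously written by :func:`write_msh`.

    Ring orderings are reconstructed from the oriented boundary line
    elements, so a written mesh round-trips.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)
    nodes, tris, regions, bnd = [], [], [], {}
    for line in it:
        if line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(parts[1]), float(parts[2])])
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype, ntags = int(parts[1]), int(parts[2])
                tags = [int(t) for t in parts[3 : 3 + ntags]]
                conn = [int(v) - 1 for v in parts[3 + ntags :]]
                if etype == 1:
                    bnd.setdefault(tags[0], []).append(conn)
                elif etype == 2:
                    tris.append(conn)
                    regions.append(tags[0])
    if not nodes or not tris:
        raise GeometryError(f"no mesh content in {path}")
    boundary_edges = {t: np.asarray(v, dtype=np.int64) for t, v in bnd.items()}

    def _ring_from_edges(edges: np.ndarray) -> np.ndarray:
        nxt = dict(zip(edges[:, 0].tolist(), edges[:, 1].tolist()))
        start = edges[0, 0]
        ring = [start]
        while True:
            n2 = nxt[ring[-1]]
            if n2 == start:
                break
            ring.append(n2)
        return np.asarray(ring, dtype=np.int64)

    outer = _ring_from_edges(boundary_edges.get(BOUNDARY_OUTER, np.empty((0, 2), int)))
    lining_edges = boundary_edges.get(BOUNDARY_LINING, np.empty((0, 2), int))
    lining = _ring_from_edges(lining_edges) if len(lining_edges) else np.empty(0, int)
    regions = np.asarray(regions, dtype=np.int64)
    tri_arr = np.asarray(tris, dtype=np.int64)
    wall_nodes = set(tri_arr[regions == REGION_WALL].ravel().tolist())
    thr_nodes = set(tri_arr[regions == REGION_THROMBUS].ravel().tolist())
    interface = np.asarray(sorted(wall_nodes & thr_nodes), dtype=np.int64)
    return Mesh(
        nodes=np.asarray(nodes, dtype=float),
        triangles=tri_arr,
        tri_region=regions,
        boundary_edges=boundary_edges,
        outer_nodes=outer,
        lining_nodes=lining,
        interface_nodes=interface,
        n_theta=len(outer),
    )
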