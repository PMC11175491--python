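"""Plane-strain elastostatics of the AAA slice.

Two solution modes on the same P1 triangle discretisation:

``solve_linear``
    Small-strain linear elasticity with dead pressure loads.  Serves as the
    verification mode against the thick-walled-cylinder (Lame) closed forms
    and as the fast engine for displacement sweeps.

``solve_finite_strain``
    Total-Lagrangian St. Venant-Kirchhoff formulation
    ``-div((I + grad u) S(E(u))) = 0`` with Green-Lagrange strain
    ``E = 1/2 (grad u + grad u^T + grad u^T grad u)`` and second
    Piola-Kirchhoff stress ``S = lambda tr(E) I + 2 mu E``, solved by Newton
    with load stepping.  Pressures follow the deformed boundary.  A Newton
    failure after automatic step halving is the model's "collapse" outcome
    and is reported, never silently swallowed.

The rigid spine is a fixed circle.  Contact is frictionless unilateral
penalty on the deformed gap; the tangency node (the wall point resting on
the spine) is pinned, which anchors the otherwise load-balanced slice
(uniform pressure on closed contours has zero resultant).  Weak grounding
springs regularise the remaining near-rigid modes; their stiffness is many
orders below the tissue stiffness and they carry no net load at equilibrium.

Mesh coordinates are mm; displacements and residuals are SI (m, N per unit
depth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import GeometryError, NonConvergence, SingularSystemError
from .geometry import SliceGeometry
from .mesh import BOUNDARY_LINING, BOUNDARY_OUTER, REGION_THROMBUS, REGION_WALL, Mesh

__all__ = [
    "MMHG_PA",
    "Material",
    "LoadCase",
    "DisplacementField",
    "solve_linear",
    "solve_finite_strain",
    "lame_annulus_displacement",
    "compound_cylinder_displacement",
    "equivalent_strain",
    "total_deformation",
]

MM = 1.0e-3
#: mmHg to Pa conversion used throughout.
MMHG_PA = 133.322


@dataclass(frozen=True)
class Material:
    """Isotropic material; Lame parameters derive from (E, nu)."""

    young_modulus: float  # Pa
    poisson_ratio: float

    def __post_init__(self):
        if self.young_modulus <= 0:
            raise GeometryError("Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise GeometryError("Poisson ratio must lie in [0, 0.5)")

    @property
    def lame_lambda(self) -> float:
        e, nu = self.young_modulus, self.poisson_ratio
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))

    @property
    def lame_mu(self) -> float:
        e, nu = self.young_modulus, self.poisson_ratio
        return e / (2.0 * (1.0 + nu))


@dataclass(frozen=True)
class LoadCase:
    """Pressures and spine-contact treatment for one solve.

    Defaults: 100 mmHg luminal pressure on the lumen lining, 6 mmHg
    intra-abdominal pressure on the outer surface.
    """

    lumen_pressure: float = 100.0 * MMHG_PA  # Pa
    external_pressure: float = 6.0 * MMHG_PA  # Pa
    spine_contact: str = "penalty"  # none | penalty | clamp
    penalty_stiffness: float = 1.0e12  # Pa/m
    load_steps: int = 5
    contact_margin: float = 10.0  # mm, candidate-node search band
    clamp_gap: float = 0.12  # mm, clamp-mode arc half-band
    spring_coef: float = 1.0e-8  # grounding springs, fraction of max E

    def __post_init__(self):
        if self.lumen_pressure < 0 or self.external_pressure < 0:
            raise GeometryError("pressures must be non-negative")
        if self.spine_contact not in ("none", "penalty", "clamp"):
            raise GeometryError(f"unknown spine_contact {self.spine_contact!r}")
        if self.spine_contact == "penalty" and self.penalty_stiffness <= 0:
            raise GeometryError("penalty stiffness must be positive")
        if self.load_steps < 1:
            raise GeometryError("load_steps must be >= 1")


@dataclass
class DisplacementField:
    """Nodal displacement solution with solver metadata."""

    mesh: Mesh
    u: np.ndarray  # (n, 2) m
    mode: str  # "linear" | "finite"
    converged: bool
    newton_iterations: int = 0
    residual_norm: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)

    def element_strain(self) -> np.ndarray:
        """Per-element in-plane strain tensor (m, 2, 2).

        Small strain in linear mode, Green-Lagrange in finite mode; the
        out-of-plane component is zero (plane strain) in both.
        """
        G, _ = _gradients(self.mesh)
        grad = np.einsum("eai,eaj->eij", self.u[self.mesh.triangles], G)
        if self.mode == "finite":
            return 0.5 * (grad + grad.transpose(0, 2, 1) + np.einsum("eki,ekj->eij", grad, grad))
        return 0.5 * (grad + grad.transpose(0, 2, 1))

    def principal_strains(self) -> np.ndarray:
        """Principal strains (m, 3); third component is the plane-strain zero."""
        e = self.element_strain()
        mean = 0.5 * (e[:, 0, 0] + e[:, 1, 1])
        radius = np.sqrt((0.5 * (e[:, 0, 0] - e[:, 1, 1])) ** 2 + e[:, 0, 1] ** 2)
        return np.stack([mean + radius, mean - radius, np.zeros_like(mean)], axis=1)


def total_deformation(fld: DisplacementField) -> np.ndarray:
    """Per-node displacement magnitude |u| (the 'Total Deformation' metric)."""
    return fld.magnitude()


def equivalent_strain(fld: DisplacementField, nu_eff: float = 0.5) -> np.ndarray:
    """Von Mises equivalent strain per element.

    ``eps_eq = 1/(1+nu') * sqrt(((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2)/2)``
    from principal strains with the plane-strain third component zero.
    """
    p = fld.principal_strains()
    e1, e2, e3 = p[:, 0], p[:, 1], p[:, 2]
    return (1.0 / (1.0 + nu_eff)) * np.sqrt(
        0.5 * ((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2)
    )


# ---------------------------------------------------------------------------
# closed-form oracles


def lame_annulus_displacement(a, b, material: Material, p_i, p_o, r):
    """Plane-strain thick-walled cylinder radial displacement u(r), metres.

    ``a``, ``b``, ``r`` in mm; pressures in Pa.  Standard Lame solution with
    A = (p_i a^2 - p_o b^2)/(b^2 - a^2), B = (p_i - p_o) a^2 b^2 / (b^2 - a^2),
    u(r) = (1+nu)/E * ((1 - 2 nu) A r + B / r).
    """
    if a >= b:
        raise GeometryError("inner radius must be smaller than outer radius")
    a, b, r = a * MM, b * MM, np.asarray(r, dtype=float) * MM
    e, nu = material.young_modulus, material.poisson_ratio
    big_a = (p_i * a * a - p_o * b * b) / (b * b - a * a)
    big_b = (p_i - p_o) * a * a * b * b / (b * b - a * a)
    return (1.0 + nu) / e * ((1.0 - 2.0 * nu) * big_a * r + big_b / r)


def compound_cylinder_displacement(
    a, c, b, inner_material: Material, outer_material: Material, p_i, p_o, r
):
    """Two-layer concentric plane-strain cylinder (inner layer a..c, outer
    c..b) under internal/external pressure; returns u(r) in metres.

    Each layer carries a Lame field ``u = C1 r + C2 / r``; the four constants
    follow from traction boundary conditions at ``a`` and ``b`` plus
    displacement and radial-stress continuity at the interface ``c``.
    """
    if not a < c < b:
        raise GeometryError("radii must satisfy a < c < b")
    a_m, c_m, b_m = a * MM, c * MM, b * MM

    def coeffs(mat: Material):
        lam, mu = mat.lame_lambda, mat.lame_mu
        # sigma_r(r) = 2(lam+mu) C1 - 2 mu C2 / r^2
        return 2.0 * (lam + mu), 2.0 * mat.lame_mu

    k1_i, k2_i = coeffs(inner_material)
    k1_o, k2_o = coeffs(outer_material)
    # unknowns [C1_i, C2_i, C1_o, C2_o]
    mat = np.array(
        [
            [k1_i, -k2_i / a_m**2, 0.0, 0.0],
            [0.0, 0.0, k1_o, -k2_o / b_m**2],
            [c_m, 1.0 / c_m, -c_m, -1.0 / c_m],
            [k1_i, -k2_i / c_m**2, -k1_o, k2_o / c_m**2],
        ]
    )
    rhs = np.array([-p_i, -p_o, 0.0, 0.0])
    c1i, c2i, c1o, c2o = np.linalg.solve(mat, rhs)
    r_arr = np.atleast_1d(np.asarray(r, dtype=float)) * MM
    inner = r_arr <= c_m
    out = np.where(inner, c1i * r_arr + c2i / r_arr, c1o * r_arr + c2o / r_arr)
    return out if np.ndim(r) else float(out[0])


# ---------------------------------------------------------------------------
# assembly helpers

def _gradients(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Reference P1 shape gradients G (m,3,2) and areas (m,) in SI units."""
    cached = getattr(mesh, "_grad_cache", None)
    if cached is not None:
        return cached
    x = mesh.nodes[mesh.triangles] * MM
    v1 = x[:, 1] - x[:, 0]
    v2 = x[:, 2] - x[:, 0]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    gx = np.stack(
        [x[:, 1, 1] - x[:, 2, 1], x[:, 2, 1] - x[:, 0, 1], x[:, 0, 1] - x[:, 1, 1]],
        axis=1,
    ) / det[:, None]
    gy = np.stack(
        [x[:, 2, 0] - x[:, 1, 0], x[:, 0, 0] - x[:, 2, 0], x[:, 1, 0] - x[:, 0, 0]],
        axis=1,
    ) / det[:, None]
    grads = np.stack([gx, gy], axis=2)
    mesh._grad_cache = (grads, 0.5 * det)
    return grads, 0.5 * det


def _element_lame(mesh: Mesh, materials: dict) -> tuple[np.ndarray, np.ndarray]:
    lam = np.empty(mesh.n_elements)
    mu = np.empty(mesh.n_elements)
    for region, name in ((REGION_WALL, "wall"), (REGION_THROMBUS, "thrombus")):
        sel = mesh.tri_region == region
        if not np.any(sel):
            continue
        if name not in materials:
            raise GeometryError(f"missing material for region {name!r}")
        m = materials[name]
        lam[sel] = m.lame_lambda
        mu[sel] = m.lame_mu
    return lam, mu


def _edof(mesh: Mesh) -> np.ndarray:
    t = mesh.triangles
    return np.stack(
        [2 * t[:, 0], 2 * t[:, 0] + 1, 2 * t[:, 1], 2 * t[:, 1] + 1, 2 * t[:, 2], 2 * t[:, 2] + 1],
        axis=1,
    )


def _scatter(mesh: Mesh, ke: np.ndarray, ndof: int) -> sp.csr_matrix:
    edof = _edof(mesh)
    rows = np.repeat(edof, 6, axis=1).ravel()
    cols = np.tile(edof, (1, 6)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()


def _linear_stiffness(mesh: Mesh, materials: dict) -> sp.csr_matrix:
    grads, areas = _gradients(mesh)
    lam, mu = _element_lame(mesh, materials)
    m = mesh.n_elements
    b = np.zeros((m, 3, 6))
    b[:, 0, 0::2] = grads[:, :, 0]
    b[:, 1, 1::2] = grads[:, :, 1]
    b[:, 2, 0::2] = grads[:, :, 1]
    b[:, 2, 1::2] = grads[:, :, 0]
    d = np.zeros((m, 3, 3))
    d[:, 0, 0] = d[:, 1, 1] = lam + 2.0 * mu
    d[:, 0, 1] = d[:, 1, 0] = lam
    d[:, 2, 2] = mu
    ke = areas[:, None, None] * np.einsum("eia,eij,ejb->eab", b, d, b, optimize=True)
    return _scatter(mesh, ke, 2 * mesh.n_nodes)


_R90 = np.array([[0.0, 1.0], [-1.0, 0.0]])  # d -> (dy, -dx)


def _pressure_force(mesh: Mesh, loads: LoadCase, u: np.ndarray | None, scale: float) -> np.ndarray:
    """Nodal pressure forces; follower (deformed edges) when ``u`` given."""
    f = np.zeros((mesh.n_nodes, 2))
    y = mesh.nodes * MM if u is None else mesh.nodes * MM + u
    for tag, p in ((BOUNDARY_LINING, loads.lumen_pressure), (BOUNDARY_OUTER, loads.external_pressure)):
        if p == 0.0 or tag not in mesh.boundary_edges:
            continue
        edges = mesh.boundary_edges[tag]
        d = y[edges[:, 1]] - y[edges[:, 0]]
        fe = -0.5 * scale * p * (d @ _R90.T)  # outward-normal * length, halved per node
        np.add.at(f, edges[:, 0], fe)
        np.add.at(f, edges[:, 1], fe)
    return f


def _pressure_tangent(mesh: Mesh, loads: LoadCase, scale: float, ndof: int) -> sp.csr_matrix:
    """-(d f_press / d u) for follower pressures (finite-strain tangent)."""
    rows, cols, vals = [], [], []
    for tag, p in ((BOUNDARY_LINING, loads.lumen_pressure), (BOUNDARY_OUTER, loads.external_pressure)):
        if p == 0.0 or tag not in mesh.boundary_edges:
            continue
        edges = mesh.boundary_edges[tag]
        half = 0.5 * scale * p
        for a_col in (0, 1):  # receiving node i or j
            recv = edges[:, a_col]
            for src_col, sign in ((0, -1.0), (1, 1.0)):  # d f_a/d u_src = -sign*half*R90...
                src = edges[:, src_col]
                # f_a = -half * R90 @ (y_j - y_i): df/du_j = -half R90, df/du_i = +half R90
                block = (half if sign < 0 else -half) * _R90
                for i in range(2):
                    for j in range(2):
                        if block[i, j] == 0.0:
                            continue
                        rows.append(2 * recv + i)
                        cols.append(2 * src + j)
                        vals.append(np.full(len(edges), -block[i, j]))  # minus: K -= dF_ext/du
    if not rows:
        return sp.csr_matrix((ndof, ndof))
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()


# ---------------------------------------------------------------------------
# spine contact


@dataclass
class _Contact:
    nodes: np.ndarray       # candidate node ids
    weights: np.ndarray     # reference arc length per node (m)
    center: np.ndarray      # spine centre (m)
    radius: float           # spine radius (m)
    stiffness: float        # Pa/m
    pinned: np.ndarray      # fully fixed node ids


def _setup_contact(mesh: Mesh, geometry: SliceGeometry | None, loads: LoadCase) -> _Contact | None:
    if loads.spine_contact == "none":
        return None
    if geometry is None:
        raise GeometryError("spine contact requires the slice geometry")
    center = geometry.spine_center * MM
    radius = geometry.spine_radius * MM
    ring = mesh.outer_nodes
    xy = mesh.nodes[ring] * MM
    gap = np.linalg.norm(xy - center, axis=1) - radius
    weights = mesh.boundary_arc_weights(ring) * MM
    if loads.spine_contact == "clamp":
        pinned = ring[gap <= loads.clamp_gap * MM]
        if pinned.size == 0:
            pinned = ring[[int(np.argmin(gap))]]
        return _Contact(np.empty(0, int), np.empty(0), center, radius, 0.0, pinned)
    cand = gap <= loads.contact_margin * MM
    pinned = ring[[int(np.argmin(gap))]]  # tangency node rests on the spine
    return _Contact(ring[cand], weights[cand], center, radius, loads.penalty_stiffness, pinned)


def _contact_force_tangent(
    contact: _Contact, mesh: Mesh, u: np.ndarray, ndof: int, linearized: bool
) -> tuple[np.ndarray, sp.csr_matrix, float]:
    """Penalty contact residual contribution (+= to r), tangent, total normal force."""
    f = np.zeros((mesh.n_nodes, 2))
    if contact is None or contact.nodes.size == 0 or contact.stiffness == 0.0:
        return f, sp.csr_matrix((ndof, ndof)), 0.0
    x_ref = mesh.nodes[contact.nodes] * MM
    if linearized:
        d0 = x_ref - contact.center
        r0 = np.linalg.norm(d0, axis=1)
        n = d0 / r0[:, None]
        g = (r0 - contact.radius) + np.einsum("ij,ij->i", n, u[contact.nodes])
    else:
        d = x_ref + u[contact.nodes] - contact.center
        r = np.linalg.norm(d, axis=1)
        n = d / r[:, None]
        g = r - contact.radius
    active = g < 0.0
    kw = contact.stiffness * contact.weights
    force_mag = np.where(active, -kw * g, 0.0)  # >= 0, pushes along +n
    f[contact.nodes] = force_mag[:, None] * n
    rows, cols, vals = [], [], []
    for i in range(2):
        for j in range(2):
            block = kw * active * n[:, i] * n[:, j]
            if not linearized:
                # curvature term k*g/r*(I - n n^T), active only
                block = block + kw * active * (g / r) * ((i == j) - n[:, i] * n[:, j])
            rows.append(2 * contact.nodes + i)
            cols.append(2 * contact.nodes + j)
            vals.append(block)
    kc = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()
    return f, kc, float(force_mag.sum())


def _free_mask(ndof: int, contact: _Contact | None) -> np.ndarray:
    free = np.ones(ndof, dtype=bool)
    if contact is not None:
        for node in contact.pinned:
            free[2 * node] = False
            free[2 * node + 1] = False
    return free


def _spring_stiffness(materials: dict, loads: LoadCase) -> float:
    e_max = max(m.young_modulus for m in materials.values())
    return loads.spring_coef * e_max


# ---------------------------------------------------------------------------
# solvers


def solve_linear(
    mesh: Mesh,
    materials: dict,
    loads: LoadCase,
    geometry: SliceGeometry | None = None,
    max_active_set_iters: int = 40,
) -> DisplacementField:
    """Small-strain solve with dead loads and linearized unilateral contact.

    The contact active set is resolved by fixed-point iteration on the
    linearized gap; the iteration terminates when the set repeats.
    """
    ndof = 2 * mesh.n_nodes
    if loads.spine_contact == "none" and loads.spring_coef <= 0.0:
        raise SingularSystemError(
            "no spine support and no grounding springs: rigid-body modes "
            "are unconstrained"
        )
    k_base = _linear_stiffness(mesh, materials)
    k_base = k_base + _spring_stiffness(materials, loads) * sp.identity(ndof, format="csr")
    f_ext = _pressure_force(mesh, loads, None, 1.0).ravel()
    contact = _setup_contact(mesh, geometry, loads)
    free = _free_mask(ndof, contact)

    u = np.zeros((mesh.n_nodes, 2))
    n_iter = 0
    prev_sets: list = []
    total_contact = 0.0
    while True:
        fc, kc, total_contact = _contact_force_tangent(contact, mesh, u, ndof, linearized=True)
        k = k_base + kc
        rhs = f_ext + fc.ravel() + kc @ u.ravel()  # re-linearize penalty about u
        k_ff = k[free][:, free]
        try:
            u_free = spla.spsolve(k_ff.tocsc(), rhs[free])
        except RuntimeError as exc:  # pragma: no cover - SuperLU failure path
            raise SingularSystemError(str(exc)) from exc
        if not np.all(np.isfinite(u_free)) or np.max(np.abs(u_free), initial=0.0) > 0.1:
            raise SingularSystemError(
                "linear solve produced non-finite or unbounded displacements "
                "(rigid-body modes likely unconstrained)"
            )
        u_new = np.zeros(ndof)
        u_new[free] = u_free
        u = u_new.reshape(-1, 2)
        n_iter += 1
        if contact is None or contact.nodes.size == 0:
            break
        x_ref = mesh.nodes[contact.nodes] * MM
        d0 = x_ref - contact.center
        r0 = np.linalg.norm(d0, axis=1)
        n = d0 / r0[:, None]
        g = (r0 - contact.radius) + np.einsum("ij,ij->i", n, u[contact.nodes])
        active = frozenset(np.nonzero(g < 0.0)[0].tolist())
        if prev_sets and active == prev_sets[-1]:
            break
        if active in prev_sets or n_iter >= max_active_set_iters:
            break  # cycling; accept current iterate (penetrations ~ penalty scale)
        prev_sets.append(active)

    residual = k_base @ u.ravel() - f_ext
    fc, _, total_contact = _contact_force_tangent(contact, mesh, u, ndof, linearized=True)
    residual -= fc.ravel()
    res_norm = float(np.linalg.norm(residual[free]))
    return DisplacementField(
        mesh=mesh,
        u=u,
        mode="linear",
        converged=True,
        newton_iterations=n_iter,
        residual_norm=res_norm,
        diagnostics={"contact_force": total_contact, "active_set_iters": n_iter},
    )


def _svk_internal(mesh, grads, areas, lam, mu, u):
    ue = u[mesh.triangles]
    grad = np.einsum("eai,eaj->eij", ue, grads)
    f = grad.copy()
    f[:, 0, 0] += 1.0
    f[:, 1, 1] += 1.0
    e = 0.5 * (np.einsum("eki,ekj->eij", f, f) - np.eye(2)[None])
    tr = e[:, 0, 0] + e[:, 1, 1]
    s = 2.0 * mu[:, None, None] * e
    s[:, 0, 0] += lam * tr
    s[:, 1, 1] += lam * tr
    p = np.einsum("eik,ekj->eij", f, s)
    f_int_e = areas[:, None, None] * np.einsum("eij,eaj->eai", p, grads)
    return f, s, f_int_e


def _svk_tangent(mesh, grads, areas, lam, mu, f, s):
    m = mesh.n_elements
    # nonlinear strain-displacement matrix BN (m, 3, 6), Voigt [E11, E22, 2E12]
    bn = np.zeros((m, 3, 6))
    for bnode in range(3):
        for j in range(2):
            col = 2 * bnode + j
            bn[:, 0, col] = f[:, j, 0] * grads[:, bnode, 0]
            bn[:, 1, col] = f[:, j, 1] * grads[:, bnode, 1]
            bn[:, 2, col] = f[:, j, 0] * grads[:, bnode, 1] + f[:, j, 1] * grads[:, bnode, 0]
    d = np.zeros((m, 3, 3))
    d[:, 0, 0] = d[:, 1, 1] = lam + 2.0 * mu
    d[:, 0, 1] = d[:, 1, 0] = lam
    d[:, 2, 2] = mu
    k_mat = np.einsum("eia,eij,ejb->eab", bn, d, bn, optimize=True)
    gs = np.einsum("eak,ekl,ebl->eab", grads, s, grads, optimize=True)
    k_geo = np.zeros((m, 6, 6))
    k_geo[:, 0::2, 0::2] = gs
    k_geo[:, 1::2, 1::2] = gs
    return areas[:, None, None] * (k_mat + k_geo)


def solve_finite_strain(
    mesh: Mesh,
    materials: dict,
    loads: LoadCase,
    geometry: SliceGeometry | None = None,
    u0: np.ndarray | None = None,
    newton_tol: float = 1.0e-8,
    max_newton_iters: int = 25,
    min_step_fraction: float = 1.0 / 64.0,
) -> DisplacementField:
    """Total-Lagrangian SVK solve with follower pressure and load stepping.

    Loads ramp in ``loads.load_steps`` increments; a failed step is halved
    automatically down to ``min_step_fraction`` of the nominal step, after
    which :class:`NonConvergence` is raised carrying the last converged load
    fraction (the "collapse" outcome of the study).  ``u0`` warm-starts the
    solve at full load, which the modulus continuation exploits.
    """
    ndof = 2 * mesh.n_nodes
    grads, areas = _gradients(mesh)
    lam, mu = _element_lame(mesh, materials)
    contact = _setup_contact(mesh, geometry, loads)
    free = _free_mask(ndof, contact)
    k_spring = _spring_stiffness(materials, loads)
    spring = k_spring * sp.identity(ndof, format="csr")
    edof = _edof(mesh)
    rows = np.repeat(edof, 6, axis=1).ravel()
    cols = np.tile(edof, (1, 6)).ravel()

    f_ref = np.linalg.norm(_pressure_force(mesh, loads, None, 1.0).ravel())
    atol = max(1.0e-12, 1.0e-12 * f_ref)

    def newton(u: np.ndarray, scale: float) -> tuple[np.ndarray, int, float] | None:
        tol = max(newton_tol * scale * f_ref, atol)
        for it in range(max_newton_iters):
            f_def, s, f_int_e = _svk_internal(mesh, grads, areas, lam, mu, u)
            r = np.zeros((mesh.n_nodes, 2))
            np.add.at(r, mesh.triangles.reshape(-1), f_int_e.reshape(-1, 2))
            r -= _pressure_force(mesh, loads, u, scale)
            fc, kc, _ = _contact_force_tangent(contact, mesh, u, ndof, linearized=False)
            r -= fc
            rv = r.ravel() + k_spring * u.ravel()
            res = float(np.linalg.norm(rv[free]))
            if not math.isfinite(res):
                return None
            if res <= tol:
                return u, it + 1, res
            ke = _svk_tangent(mesh, grads, areas, lam, mu, f_def, s)
            k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
            k = k + kc + spring + _pressure_tangent(mesh, loads, scale, ndof)
            try:
                du = spla.spsolve(k[free][:, free].tocsc(), -rv[free])
            except RuntimeError:
                return None
            if not np.all(np.isfinite(du)):
                return None
            u = u.copy()
            u.reshape(-1)[free] += du
            if np.max(np.abs(u)) > 1.0:  # > 1 m displacement: diverged
                return None
        # final check after last update
        _, _, f_int_e = _svk_internal(mesh, grads, areas, lam, mu, u)
        r = np.zeros((mesh.n_nodes, 2))
        np.add.at(r, mesh.triangles.reshape(-1), f_int_e.reshape(-1, 2))
        r -= _pressure_force(mesh, loads, u, scale)
        fc, _, _ = _contact_force_tangent(contact, mesh, u, ndof, linearized=False)
        r -= fc
        rv = r.ravel() + k_spring * u.ravel()
        res = float(np.linalg.norm(rv[free]))
        if math.isfinite(res) and res <= tol:
            return u, max_newton_iters, res
        return None

    total_iters = 0
    if f_ref == 0.0:  # unloaded: single Newton pass at full (zero) load
        out = newton(np.zeros((mesh.n_nodes, 2)), 1.0)
        if out is None:  # pragma: no cover - cannot fail at zero load
            raise NonConvergence("zero-load solve failed", 0.0)
        u, its, res = out
        return DisplacementField(mesh, u, "finite", True, its, res, {"contact_force": 0.0})
    if u0 is not None:
        out = newton(np.array(u0, dtype=float, copy=True), 1.0)
        if out is not None:
            u, its, res = out
            fc, _, cforce = _contact_force_tangent(contact, mesh, u, ndof, linearized=False)
            return DisplacementField(
                mesh, u, "finite", True, its, res, {"contact_force": cforce, "warm_start": True}
            )
        # fall through to ramped solve from scratch

    u = np.zeros((mesh.n_nodes, 2))
    nominal = 1.0 / loads.load_steps
    scale_done = 0.0
    step = nominal
    while scale_done < 1.0 - 1.0e-12:
        target = min(1.0, scale_done + step)
        out = newton(u.copy(), target)
        if out is None:
            step *= 0.5
            if step < nominal * min_step_fraction:
                raise NonConvergence(
                    f"Newton collapse at load fraction {scale_done:.4f} "
                    f"(step halved below {min_step_fraction:g} of nominal)",
                    last_converged_fraction=scale_done,
                )
            continue
        u, its, res = out
        total_iters += its
        scale_done = target
        step = min(nominal, step * 2.0)
    fc, _, cforce = _contact_force_tangent(contact, mesh, u, ndof, linearized=False)
    return DisplacementField(
        mesh,
        u,
        "finite",
        True,
        total_iters,
        res,
        {"contact_force": cforce, "load_steps_used": loads.load_steps},
    )
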