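"""XFEM enrichment basis and element quadrature.

The discontinuous displacement field is the standard three-term XFEM
expansion over the trilinear hex basis phi_i:

    u(x) = sum_I phi_i u_i
         + sum_J phi_j (H(x) - H(x_j)) a_j
         + sum_M phi_m sum_l (F_l(x) - F_l(x_m)) b_m^l,

with the shifted (nodal-value-preserving) convention: enrichment terms
vanish at nodes, so u_i keeps its interpolation meaning and crack-face
boundary conditions stay expressible.  H is the +/-1 Heaviside of the crack
level set phi; F_l are the four sqrt(r) crack-tip branch functions.

Elements crossed by the crack are integrated with a conforming subdivision:
each hex is split into 6 tetrahedra, each tetrahedron is cut by the phi = 0
plane into one-sided sub-tetrahedra, and a 4-point Gauss rule is applied per
sub-tet.  Uncut elements use the 2x2x2 Gauss rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import (HEX_CORNERS, HEX_TETS, EnrichedHexMesh, shape_functions,
                   shape_gradients, snap_phi)

__all__ = ["heaviside", "tip_branch_functions", "element_basis",
           "ElementQuadrature", "build_element_quadrature"]

# 2x2x2 Gauss abscissae in [-1, 1]
_G1 = 1.0 / np.sqrt(3.0)
GAUSS8 = np.array([[sx * _G1, sy * _G1, sz * _G1]
                   for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])

# 4-point tetrahedral rule (degree 2), barycentric coordinates
_TA, _TB = 0.5854101966249685, 0.1381966011250105
TET4_BARY = np.array([
    [_TA, _TB, _TB, _TB],
    [_TB, _TA, _TB, _TB],
    [_TB, _TB, _TA, _TB],
    [_TB, _TB, _TB, _TA],
])


def heaviside(phi) -> np.ndarray:
    """Generalised Heaviside H(phi) = sign(phi) in {-1, +1} (0 maps to +1)."""
    phi = np.asarray(phi, dtype=float)
    return np.where(phi >= 0, 1.0, -1.0)


def tip_branch_functions(r, theta) -> np.ndarray:
    """The four crack-tip branch functions, stacked on the last axis.

    {sqrt(r) sin(t/2), sqrt(r) cos(t/2), sqrt(r) sin(t/2) sin(t),
     sqrt(r) cos(t/2) sin(t)} for theta in (-pi, pi]; only the first is
    discontinuous across theta = +/-pi (the crack faces).
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    sr = np.sqrt(r)
    s2, c2 = np.sin(theta / 2.0), np.cos(theta / 2.0)
    st = np.sin(theta)
    return np.stack([sr * s2, sr * c2, sr * s2 * st, sr * c2 * st], axis=-1)


def _branch_and_gradients(phi, psi, n_hat, t_hat):
    """Branch values (..., 4) and spatial gradients (..., 4, 3).

    The tip polar frame is (r, theta) with r = hypot(phi, psi) and
    theta = atan2(phi, psi): theta = 0 ahead of the front, +/-pi on the
    crack faces.  n_hat = grad(phi), t_hat = grad(psi) (planar crack).
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    r = np.hypot(phi, psi)
    theta = np.arctan2(phi, psi)
    sr = np.sqrt(r)
    s2, c2 = np.sin(theta / 2.0), np.cos(theta / 2.0)
    st, ct = np.sin(theta), np.cos(theta)
    vals = np.stack([sr * s2, sr * c2, sr * s2 * st, sr * c2 * st], axis=-1)
    # dF/dr and dF/dtheta
    dr = np.stack([s2, c2, s2 * st, c2 * st], axis=-1) / (2.0 * sr[..., None])
    dth = np.stack([0.5 * c2, -0.5 * s2,
                    0.5 * c2 * st + s2 * ct,
                    -0.5 * s2 * st + c2 * ct], axis=-1) * sr[..., None]
    grad_r = (psi[..., None] * t_hat + phi[..., None] * n_hat) / r[..., None]
    grad_th = (psi[..., None] * n_hat - phi[..., None] * t_hat) / (r**2)[..., None]
    grads = dr[..., None] * grad_r[..., None, :] + dth[..., None] * grad_th[..., None, :]
    return vals, grads


def _tet_volume(v):
    return abs(np.linalg.det(np.stack([v[1] - v[0], v[2] - v[0], v[3] - v[0]]))) / 6.0


def _prism_tets(bot, top):
    """Staircase split of a (convex, planar-faced) wedge into 3 tets."""
    v = list(bot) + list(top)
    return [(v[0], v[1], v[2], v[3]), (v[1], v[2], v[3], v[4]),
            (v[2], v[3], v[4], v[5])]


def cut_tet_by_plane(verts, phiv):
    """Split a tetrahedron by the phi = 0 plane into one-sided sub-tets.

    ``phiv`` are the (already snapped, non-zero) level-set values at the four
    vertices (linear interpolation locates the cut).  Returns a list of
    ``(4x3 vertex array, side)`` with side = +/-1.
    """
    verts = np.asarray(verts, dtype=float)
    phiv = np.asarray(phiv, dtype=float)
    pos = phiv > 0
    npos = int(pos.sum())
    if npos in (0, 4):
        return [(verts, 1 if npos == 4 else -1)]

    def isect(i, j):
        t = phiv[i] / (phiv[i] - phiv[j])
        return verts[i] + t * (verts[j] - verts[i])

    out = []
    if npos in (1, 3):
        lone_side = 1 if npos == 1 else -1
        lone = int(np.flatnonzero(pos if npos == 1 else ~pos)[0])
        others = [i for i in range(4) if i != lone]
        cut_pts = [isect(lone, o) for o in others]
        out.append((np.array([verts[lone], *cut_pts]), lone_side))
        base = [verts[o] for o in others]
        for tet in _prism_tets(base, cut_pts):
            out.append((np.array(tet), -lone_side))
    else:  # 2-2 split
        p = list(np.flatnonzero(pos))
        a = list(np.flatnonzero(~pos))
        pa, pb = isect(p[0], a[0]), isect(p[0], a[1])
        qa, qb = isect(p[1], a[0]), isect(p[1], a[1])
        for tet in _prism_tets([verts[p[0]], pa, pb], [verts[p[1]], qa, qb]):
            out.append((np.array(tet), 1))
        for tet in _prism_tets([verts[a[0]], pa, qa], [verts[a[1]], pb, qb]):
            out.append((np.array(tet), -1))
    return [(t, s) for t, s in out if _tet_volume(t) > 0]


@dataclass
class ElementQuadrature:
    """Precomputed, state-independent integration data for one element.

    ``basis_dofs`` lists the global DOF triplets column-aligned with the
    scalar basis functions whose values/gradients are in ``N``/``G``;
    ordering matches :meth:`EnrichedHexMesh.element_dofs`.
    """

    eid: int
    points: np.ndarray       # (q, 3) world coordinates
    weights: np.ndarray      # (q,) physical volumes
    side: np.ndarray         # (q,) crack side (+/-1) of each point
    N: np.ndarray            # (q, n_b) scalar basis values
    G: np.ndarray            # (q, n_b, 3) scalar basis gradients
    dofs: np.ndarray         # (3 * n_b,) global DOF indices


def element_basis(enr: EnrichedHexMesh, eid: int, points: np.ndarray,
                  side: np.ndarray):
    """Scalar basis values and gradients at world points inside element eid.

    Returns (N, G) with the standard-then-Heaviside-then-tip column layout.
    ``side`` overrides the Heaviside sign at each point (callers pass the
    sign of phi, or a chosen side for on-crack evaluation).
    """
    mesh = enr.mesh
    conn = mesh.elements[eid]
    center = mesh.nodes[conn].mean(axis=0)
    xi = 2.0 * (points - center) / mesh.edge
    n_std = shape_functions(xi)                      # (q, 8)
    g_std = shape_gradients(xi, mesh.edge)           # (q, 8, 3)
    cols_n = [n_std]
    cols_g = [g_std]
    heav_local = [a for a in range(8) if int(conn[a]) in enr.heav_dof]
    tip_local = [a for a in range(8) if int(conn[a]) in enr.tip_dof]
    if heav_local:
        h_nodes = heaviside(enr.node_phi[conn[heav_local]])
        shift = side[:, None] - h_nodes[None, :]     # (q, nh)
        cols_n.append(n_std[:, heav_local] * shift)
        cols_g.append(g_std[:, heav_local, :] * shift[..., None])
    if tip_local:
        crack = enr.crack
        n_hat = crack.normal
        t_hat = crack.front_dir
        phi_q, psi_q = crack.level_set_pair(points)
        phi_q = snap_phi(phi_q, float(np.max(mesh.edge)))
        vals, grads = _branch_and_gradients(phi_q, psi_q, n_hat, t_hat)
        for a in tip_local:
            xn = mesh.nodes[conn[a]]
            fn = tip_branch_functions(
                np.hypot(enr.node_phi[conn[a]], enr.node_psi[conn[a]]),
                np.arctan2(enr.node_phi[conn[a]], enr.node_psi[conn[a]]))
            shift = vals - fn                         # (q, 4)
            cols_n.append(n_std[:, [a]] * shift)
            cols_g.append(g_std[:, [a], :] * shift[..., None]
                          + n_std[:, a, None, None] * grads)
    return np.concatenate(cols_n, axis=1), np.concatenate(cols_g, axis=1)


def build_element_quadrature(enr: EnrichedHexMesh, eid: int) -> ElementQuadrature:
    """Integration points, weights, sides and basis arrays for one element."""
    mesh = enr.mesh
    conn = mesh.elements[eid]
    corners = mesh.nodes[conn]
    center = corners.mean(axis=0)
    from .mesh import ELEM_STANDARD

    if enr.elem_class[eid] == ELEM_STANDARD:
        pts = center + GAUSS8 * (mesh.edge / 2.0)
        w = np.full(8, float(np.prod(mesh.edge)) / 8.0)
    else:
        pts_list, w_list = [], []
        phi_c, _ = (enr.crack.level_set_pair(corners) if enr.crack is not None
                    else (np.full(8, np.inf), None))
        phi_c = snap_phi(phi_c, float(np.max(mesh.edge)))
        for tet in HEX_TETS:
            tv = corners[tet]
            for sub, _s in cut_tet_by_plane(tv, phi_c[tet]):
                vol = _tet_volume(sub)
                pts_list.append(TET4_BARY @ sub)
                w_list.append(np.full(4, vol / 4.0))
        pts = np.concatenate(pts_list)
        w = np.concatenate(w_list)

    if enr.crack is None:
        side = np.ones(len(pts))
    else:
        phi_q = snap_phi(enr.crack.phi(pts), float(np.max(mesh.edge)))
        side = heaviside(phi_q)
    N, G = element_basis(enr, eid, pts, side)
    return ElementQuadrature(eid=eid, points=pts, weights=w, side=side,
                             N=N, G=G, dofs=enr.element_dofs(eid))
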