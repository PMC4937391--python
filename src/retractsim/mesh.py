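"""Uniform hexahedral meshing from a binary mask and level-set crack geometry.

The organ mask is meshed octree-style: a uniform axis-aligned grid of
8-node hexahedra whose edge length is the largest value not exceeding
``max_edge`` that tiles the mask bounding box, keeping every cell that
contains at least one masked voxel centre.  Uniformity means every element
shares one parent-space geometry, which the assembly code exploits heavily.

The retraction crack is carried by two level sets: ``phi`` (signed distance
normal to the crack surface) and ``psi`` (signed distance ahead of the crack
front); the crack is the set {phi = 0, psi <= 0}.  Elements fully crossed by
the crack get Heaviside-enriched nodes (set J), elements containing the front
get tip-enriched nodes (set M); all nodes form set I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HexMesh",
    "CrackGeometry",
    "EnrichedHexMesh",
    "build_hex_mesh",
    "classify_and_enrich",
]

# VTK_HEXAHEDRON corner ordering in the unit cell (i, j, k offsets)
HEX_CORNERS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=int)

# 6-tetrahedron decomposition of a hexahedron (corner indices into HEX_CORNERS),
# all sharing the 0-6 diagonal; used for conforming cut-element quadrature.
HEX_TETS = np.array([
    [0, 1, 2, 6], [0, 2, 3, 6], [0, 3, 7, 6],
    [0, 7, 4, 6], [0, 4, 5, 6], [0, 5, 1, 6],
], dtype=int)

ELEM_STANDARD, ELEM_CUT, ELEM_TIP = 0, 1, 2


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear hex shape functions at parent coordinates xi in [-1, 1]^3."""
    xi = np.asarray(xi, dtype=float)
    s = 2.0 * HEX_CORNERS - 1.0  # corner signs
    return np.prod(1.0 + xi[..., None, :] * s, axis=-1) / 8.0


def shape_gradients(xi: np.ndarray, edge) -> np.ndarray:
    """Gradients of the trilinear shape functions w.r.t. physical coordinates.

    ``edge`` is the (possibly anisotropic) element edge length; the uniform
    axis-aligned geometry makes the Jacobian diagonal, d(xi)/dx = 2/edge.
    """
    xi = np.asarray(xi, dtype=float)
    s = 2.0 * HEX_CORNERS - 1.0
    t = 1.0 + xi[..., None, :] * s  # (..., 8, 3)
    grad = np.empty(xi.shape[:-1] + (8, 3))
    for d in range(3):
        others = [o for o in range(3) if o != d]
        grad[..., d] = s[:, d] * t[..., others[0]] * t[..., others[1]] / 8.0
    return grad * (2.0 / np.asarray(edge, dtype=float))


@dataclass
class HexMesh:
    """Uniform axis-aligned hexahedral mesh in world millimetres."""

    nodes: np.ndarray          # (n_nodes, 3) mm
    elements: np.ndarray       # (n_elems, 8) node ids, VTK ordering
    edge: np.ndarray           # (3,) element edge lengths, mm
    origin: np.ndarray         # grid origin (corner of cell (0,0,0)), mm
    dims: tuple                # cells along each axis
    cell_ids: np.ndarray       # (nx, ny, nz) dense cell -> element id, -1 absent

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centers(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def locate(self, points: np.ndarray):
        """Element id containing each point (-1 outside), plus parent coords."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (points - self.origin) / self.edge
        idx = np.floor(rel).astype(int)
        # points exactly on the far boundary belong to the last cell
        for d in range(3):
            hi = rel[:, d] == self.dims[d]
            idx[hi, d] = self.dims[d] - 1
        inside = np.all((idx >= 0) & (idx < np.array(self.dims)), axis=1)
        eid = np.full(len(points), -1, dtype=int)
        eid[inside] = self.cell_ids[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        xi = 2.0 * (rel - idx) - 1.0
        return eid, xi

    def boundary_nodes(self) -> np.ndarray:
        """Nodes on faces not shared by two elements."""
        faces = {}
        face_local = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
                      (3, 2, 6, 7), (0, 3, 7, 4), (1, 2, 6, 5)]
        for conn in self.elements:
            for fl in face_local:
                key = tuple(sorted(conn[list(fl)]))
                faces[key] = faces.get(key, 0) + 1
        ids = set()
        for key, count in faces.items():
            if count == 1:
                ids.update(key)
        return np.array(sorted(ids), dtype=int)


def build_hex_mesh(mask: np.ndarray, spacing, max_edge: float,
                   origin=(0.0, 0.0, 0.0), min_voxels: int = 1) -> HexMesh:
    """Uniform hex mesh covering a binary mask, octree-style.

    Parameters
    ----------
    mask : 3-D bool/int array
        Binary segmentation; voxel (i, j, k) centre sits at
        ``origin + (i+0.5..) * spacing`` — axis-aligned world geometry.
    spacing : (3,) voxel size, mm.
    max_edge : float
        Upper bound on the element edge, mm (< 5 mm in the intended use).
    min_voxels : int
        Keep a cell if at least this many masked voxel centres fall inside.
    """
    mask = np.asarray(mask).astype(bool)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    origin = np.asarray(origin, dtype=float)
    if not mask.any():
        raise ValueError("mask is empty — nothing to mesh")
    if max_edge <= spacing.max():
        raise ValueError("max_edge must exceed the voxel spacing")

    vox = np.argwhere(mask)
    lo_v, hi_v = vox.min(axis=0), vox.max(axis=0)
    lo = origin + lo_v * spacing                # outer corner of first voxel
    hi = origin + (hi_v + 1) * spacing
    extent = hi - lo
    n_cells = np.maximum(1, np.ceil(extent / max_edge - 1e-12).astype(int))
    edge = extent / n_cells

    centers = (vox + 0.5) * spacing + origin
    cell_idx = np.floor((centers - lo) / edge).astype(int)
    cell_idx = np.minimum(cell_idx, n_cells - 1)
    flat = np.ravel_multi_index(cell_idx.T, n_cells)
    counts = np.bincount(flat, minlength=int(np.prod(n_cells)))
    keep = np.flatnonzero(counts >= min_voxels)
    if keep.size == 0:
        raise ValueError("no cell contains enough masked voxels")

    cells = np.array(np.unravel_index(keep, n_cells)).T  # (ne, 3)
    nxyz = tuple(int(n) for n in n_cells)
    cell_ids = np.full(nxyz, -1, dtype=int)
    cell_ids[cells[:, 0], cells[:, 1], cells[:, 2]] = np.arange(len(cells))

    # node grid: corners of kept cells
    corner_idx = cells[:, None, :] + HEX_CORNERS[None, :, :]  # (ne, 8, 3)
    flat_nodes = np.ravel_multi_index(
        corner_idx.reshape(-1, 3).T, tuple(n + 1 for n in nxyz))
    uniq, inv = np.unique(flat_nodes, return_inverse=True)
    node_grid = np.array(np.unravel_index(uniq, tuple(n + 1 for n in nxyz))).T
    nodes = lo + node_grid * edge
    elements = inv.reshape(len(cells), 8)
    return HexMesh(nodes=nodes, elements=elements, edge=edge, origin=lo,
                   dims=nxyz, cell_ids=cell_ids)


@dataclass
class CrackGeometry:
    """Planar crack described by two signed-distance level sets.

    ``phi(x) = (x - point) . normal`` changes sign across the crack surface;
    ``psi(x) = (x - front_point) . front_dir`` is positive ahead of the crack
    front.  The crack itself is {phi = 0, psi <= 0}.  A through-going crack
    (the default for retraction, where the blades span the exposed region)
    has no front: psi = -inf everywhere and no tip enrichment arises.

    ``level_set_fn`` may replace the planar formulas with an arbitrary
    callable ``x -> (phi, psi)`` for non-planar surfaces.
    """

    point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    front_point: np.ndarray | None = None
    front_dir: np.ndarray | None = None
    level_set_fn: object = None

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        if self.front_dir is not None:
            t = np.asarray(self.front_dir, dtype=float)
            t = t - (t @ self.normal) * self.normal  # front dir lies in-plane
            self.front_dir = t / np.linalg.norm(t)
            self.front_point = np.asarray(self.front_point, dtype=float)

    @property
    def through(self) -> bool:
        return self.level_set_fn is None and self.front_dir is None

    def level_set_pair(self, x: np.ndarray):
        """(phi, psi) at point(s) x, mm."""
        x = np.asarray(x, dtype=float)
        if self.level_set_fn is not None:
            return self.level_set_fn(x)
        phi = (x - self.point) @ self.normal
        if self.front_dir is None:
            psi = np.full(np.shape(phi), -np.inf)
        else:
            psi = (x - self.front_point) @ self.front_dir
        return phi, psi

    def phi(self, x):
        return self.level_set_pair(x)[0]

    def psi(self, x):
        return self.level_set_pair(x)[1]


def snap_phi(phi: np.ndarray, edge: float, rel: float = 1e-6) -> np.ndarray:
    """Shift near-zero level-set values off zero (deterministic + sign).

    Standard XFEM guard against degenerate cuts through nodes/quadrature
    points; threshold is ``rel`` times the element edge.
    """
    phi = np.asarray(phi, dtype=float).copy()
    eps = rel * edge
    phi[np.abs(phi) < eps] = eps
    return phi


@dataclass
class EnrichedHexMesh:
    """HexMesh + crack level sets + enrichment bookkeeping and DOF map.

    Nodes in J carry 3 Heaviside DOFs (a_j); nodes in M carry 12 tip DOFs
    (b_m^l, l = 1..4, 3 components each).  Standard DOFs come first
    (3 per node), then Heaviside blocks, then tip blocks — contiguous and
    unique, so ``n_dofs = 3|I| + 3|J| + 12|M|``.
    """

    mesh: HexMesh
    crack: CrackGeometry | None
    elem_class: np.ndarray          # (n_elems,) ELEM_*
    heaviside_nodes: np.ndarray     # sorted node ids, set J
    tip_nodes: np.ndarray           # sorted node ids, set M
    node_phi: np.ndarray            # snapped phi at nodes
    node_psi: np.ndarray
    heav_dof: dict = field(default_factory=dict)   # node -> first of 3 dofs
    tip_dof: dict = field(default_factory=dict)    # node -> first of 12 dofs
    n_dofs: int = 0

    @property
    def node_side(self) -> np.ndarray:
        return np.sign(self.node_phi).astype(int)

    def std_dofs(self, node_ids) -> np.ndarray:
        node_ids = np.asarray(node_ids, dtype=int)
        return (3 * node_ids[..., None] + np.arange(3)).reshape(
            node_ids.shape + (3,))

    def element_dofs(self, eid: int) -> np.ndarray:
        """All DOF indices of element eid: standard, then enriched blocks."""
        conn = self.mesh.elements[eid]
        dofs = list(self.std_dofs(conn).ravel())
        for n in conn:
            if n in self.heav_dof:
                d0 = self.heav_dof[n]
                dofs.extend(range(d0, d0 + 3))
        for n in conn:
            if n in self.tip_dof:
                d0 = self.tip_dof[n]
                dofs.extend(range(d0, d0 + 12))
        return np.array(dofs, dtype=int)

    def element_is_enriched(self, eid: int) -> bool:
        conn = self.mesh.elements[eid]
        return any(n in self.heav_dof or n in self.tip_dof for n in conn)


def classify_and_enrich(mesh: HexMesh, crack: CrackGeometry | None,
                        snap_rel: float = 1e-6) -> EnrichedHexMesh:
    """Label elements standard/cut/tip and build the enriched DOF map.

    An element whose snapped nodal phi changes sign is *cut* if the crack
    reaches past it (all nodal psi <= 0), a *tip* element if the front lies
    inside (nodal psi changes sign), and standard otherwise.  J collects the
    nodes of cut elements (minus tip nodes), M the nodes of tip elements.
    """
    n_nodes = mesh.n_nodes
    edge = float(np.max(mesh.edge))
    if crack is None:
        enr = EnrichedHexMesh(
            mesh=mesh, crack=None,
            elem_class=np.zeros(mesh.n_elements, dtype=int),
            heaviside_nodes=np.empty(0, dtype=int),
            tip_nodes=np.empty(0, dtype=int),
            node_phi=np.full(n_nodes, np.inf),
            node_psi=np.full(n_nodes, -np.inf))
        enr.n_dofs = 3 * n_nodes
        return enr

    phi_raw, psi = crack.level_set_pair(mesh.nodes)
    phi = snap_phi(phi_raw, edge, snap_rel)
    conn = mesh.elements
    ephi, epsi = phi[conn], psi[conn]
    sign_change = (ephi.min(axis=1) < 0) & (ephi.max(axis=1) > 0)
    all_behind = epsi.max(axis=1) <= 0
    front_inside = (epsi.min(axis=1) <= 0) & (epsi.max(axis=1) > 0)
    elem_class = np.zeros(mesh.n_elements, dtype=int)
    elem_class[sign_change & all_behind] = ELEM_CUT
    elem_class[sign_change & front_inside] = ELEM_TIP

    tip_nodes = np.unique(conn[elem_class == ELEM_TIP])
    heav = np.setdiff1d(np.unique(conn[elem_class == ELEM_CUT]), tip_nodes)

    enr = EnrichedHexMesh(mesh=mesh, crack=crack, elem_class=elem_class,
                          heaviside_nodes=heav, tip_nodes=tip_nodes,
                          node_phi=phi, node_psi=psi)
    next_dof = 3 * n_nodes
    for n in heav:
        enr.heav_dof[int(n)] = next_dof
        next_dof += 3
    for n in tip_nodes:
        enr.tip_dof[int(n)] = next_dof
        next_dof += 12
    enr.n_dofs = next_dof
    return enr
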