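"""Displacement-driven hyper-viscoelastic XFEM retraction model.

The quasi-static retraction problem is posed in the statsmodels idiom:
:class:`RetractionModel` is built from an enriched mesh, a material and a
boundary-condition set; :meth:`RetractionModel.fit` ramps the prescribed
crack-face displacements over a pseudo-time schedule, solving each increment
with Newton iterations on the total-Lagrangian residual (internal forces
only — the remaining surface is traction-free), and returns a
:class:`RetractionResults` carrying the solved DOF vector, the viscoelastic
state archive, per-increment convergence diagnostics and a summary table.

Prescribed DOFs are imposed exactly by elimination.  For a Heaviside node j
with face displacements u+ and u- the jump DOF is a_j = (u+ - u-)/2 and the
standard DOF u_j takes the value prescribed on the node's own side of the
crack (exact under the shifted enrichment basis).
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import OgdenPronyMaterial
from .mesh import EnrichedHexMesh, snap_phi
from .xfem import build_element_quadrature, element_basis, heaviside

__all__ = ["BCSet", "Schedule", "DisplacementField", "RetractionModel",
           "RetractionResults", "SolverError"]

_EYE = np.eye(3)


class SolverError(RuntimeError):
    pass


def _spatial_tangent(F, S, D):
    """First-elasticity tensor A_iJkL = d P_iJ / d F_kL, batched.

    A = delta_ik S_JL + 2 F_iI D_IJML F_kM, evaluated with batched matrix
    products (the pure-einsum form falls off the BLAS fast path).
    """
    N = F.shape[0]
    X = (F @ D.reshape(N, 3, 27)).reshape(N, 3, 3, 3, 3)   # i J M L
    Xt = X.transpose(0, 1, 2, 4, 3).reshape(N, 27, 3)       # (iJL), M
    Y = (Xt @ F.transpose(0, 2, 1)).reshape(N, 3, 3, 3, 3)  # i J L k
    A = 2.0 * Y.transpose(0, 1, 2, 4, 3)                    # i J k L
    for i in range(3):
        A[:, i, :, i, :] += S
    return A


def _element_stiffness(G, A):
    """Per-point stiffness blocks K_(ai)(bk) = G_aJ A_iJkL G_bL, batched.

    ``G`` is (N, nb, 3) scalar-basis gradients, ``A`` the (volume-weighted)
    spatial tangent; returns (N, 3*nb, 3*nb) with node-major DOF ordering.
    """
    N, nb, _ = G.shape
    T1 = (G @ A.transpose(0, 2, 1, 3, 4).reshape(N, 3, 27))  # (N, a, ikL)
    T2 = (T1.reshape(N, nb * 9, 3) @ G.transpose(0, 2, 1))   # (N, aik, b)
    K = T2.reshape(N, nb, 3, 3, nb).transpose(0, 1, 2, 4, 3)  # a i b k
    return K.reshape(N, 3 * nb, 3 * nb)


@dataclass
class BCSet:
    """Boundary conditions: the two families the retraction problem needs.

    fixed_nodes
        Node ids clamped to zero displacement (the brain-stem region); all
        DOFs of these nodes, enriched ones included, are zeroed.
    crack_face_bcs
        ``(node_id, face_sign, (dx, dy, dz))`` entries prescribing the
        displacement of a crack-face node on the +phi or -phi face, mm.
    node_displacements
        Optional directly prescribed nodal displacements (e.g. patch tests,
        externally supplied fields); standard DOFs only.
    """

    fixed_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    crack_face_bcs: list = field(default_factory=list)
    node_displacements: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=int)

    @property
    def empty(self) -> bool:
        return (len(self.fixed_nodes) == 0 and not self.crack_face_bcs
                and not self.node_displacements)

    def validate(self, enr: EnrichedHexMesh) -> None:
        n = enr.mesh.n_nodes
        fixed = set(int(i) for i in self.fixed_nodes)
        crack_nodes = set(int(nid) for nid, _, _ in self.crack_face_bcs)
        for nid in fixed | crack_nodes | set(self.node_displacements):
            if not (0 <= nid < n):
                raise ValueError(f"BC references invalid node id {nid}")
        both = fixed & crack_nodes
        if both:
            raise ValueError(
                f"nodes {sorted(both)[:5]} are both fixed and crack-prescribed")

    def prescribed_dofs(self, enr: EnrichedHexMesh):
        """Full-load prescribed DOF values -> (indices, values) arrays."""
        self.validate(enr)
        vals: dict[int, float] = {}

        def set3(d0, vec):
            for c in range(3):
                vals[d0 + c] = float(vec[c])

        for nid in self.fixed_nodes:
            nid = int(nid)
            set3(3 * nid, np.zeros(3))
            if nid in enr.heav_dof:
                set3(enr.heav_dof[nid], np.zeros(3))
            if nid in enr.tip_dof:
                d0 = enr.tip_dof[nid]
                for l in range(4):
                    set3(d0 + 3 * l, np.zeros(3))
        for nid, vec in self.node_displacements.items():
            set3(3 * int(nid), np.asarray(vec, dtype=float))

        faces: dict[int, dict[int, np.ndarray]] = {}
        for nid, sgn, vec in self.crack_face_bcs:
            faces.setdefault(int(nid), {})[int(np.sign(sgn))] = \
                np.asarray(vec, dtype=float)
        for nid, fv in faces.items():
            own = int(enr.node_side[nid]) if nid < len(enr.node_phi) else 1
            if +1 in fv and -1 in fv:
                if nid not in enr.heav_dof:
                    if np.allclose(fv[+1], fv[-1]):
                        set3(3 * nid, fv[+1])
                    else:
                        raise ValueError(
                            f"node {nid} has two distinct face displacements "
                            "but is not Heaviside-enriched")
                else:
                    set3(3 * nid, fv[own])
                    set3(enr.heav_dof[nid], 0.5 * (fv[+1] - fv[-1]))
            elif own in fv:
                set3(3 * nid, fv[own])
            else:
                raise ValueError(
                    f"node {nid}: only the far-side crack face is prescribed; "
                    "the standard DOF cannot be constrained alone")
        idx = np.array(sorted(vals), dtype=int)
        return idx, np.array([vals[i] for i in idx])


@dataclass(frozen=True)
class Schedule:
    """Pseudo-time loading schedule: total duration T (s) over N increments.

    T = 0 requests the instantaneous (unrelaxed) response in a single step.
    """

    T: float = 30.0
    n_increments: int = 10

    def __post_init__(self):
        if self.T < 0 or self.n_increments < 1:
            raise ValueError("T must be >= 0 and n_increments >= 1")

    @property
    def steps(self):
        n = 1 if self.T == 0 else self.n_increments
        dt = 0.0 if self.T == 0 else self.T / self.n_increments
        return [(k / n, dt) for k in range(1, n + 1)]


class DisplacementField:
    """Solved XFEM displacement field, evaluable anywhere in the mesh."""

    def __init__(self, enr: EnrichedHexMesh, dofs: np.ndarray,
                 convergence_log=None):
        if len(dofs) != enr.n_dofs:
            raise ValueError("DOF vector length does not match the mesh")
        self.enr = enr
        self.dofs = np.asarray(dofs, dtype=float)
        self.convergence_log = convergence_log or []

    def node_displacements(self) -> np.ndarray:
        """Standard (nodal) displacement vectors, (n_nodes, 3)."""
        return self.dofs[:3 * self.enr.mesh.n_nodes].reshape(-1, 3)

    def evaluate(self, points, side=None, outside="error") -> np.ndarray:
        """Displacement u(x) at world points, mm.

        ``side`` (scalar or per-point +/-1) overrides the crack side used for
        the Heaviside branch — needed when sampling exactly on or across the
        crack.  ``outside``: "error" | "zero" for points beyond the mesh.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        enr = self.enr
        mesh = enr.mesh
        eid, _ = mesh.locate(points)
        u = np.zeros((len(points), 3))
        bad = eid < 0
        if bad.any() and outside == "error":
            raise ValueError(
                f"{int(bad.sum())} point(s) outside the meshed domain")
        if side is None:
            if enr.crack is not None:
                phi = snap_phi(enr.crack.phi(points), float(np.max(mesh.edge)))
                side_arr = heaviside(phi)
            else:
                side_arr = np.ones(len(points))
        else:
            side_arr = np.broadcast_to(np.asarray(side, dtype=float),
                                       (len(points),)).copy()
        for e in np.unique(eid[eid >= 0]):
            m = eid == e
            N, _ = element_basis(enr, int(e), points[m], side_arr[m])
            d = self.dofs[enr.element_dofs(int(e))].reshape(-1, 3)
            u[m] = N @ d
        return u


class RetractionModel:
    """Quasi-static hyper-viscoelastic XFEM model of a retraction.

    Parameters
    ----------
    enriched_mesh : EnrichedHexMesh
    material : OgdenPronyMaterial or LinearElasticMaterial
    bcs : BCSet
        Must constrain the system (zero-displacement region + crack-face
        displacements in the intended retraction use).
    schedule : Schedule
        Loading ramp; default 30 s in 10 increments.
    rtol, atol : float
        Newton convergence on the free-residual norm, relative to the first
        iterate of each increment / absolute (N).
    max_iter : int
        Newton iterations per increment before declaring divergence.
    """

    def __init__(self, enriched_mesh: EnrichedHexMesh,
                 material=None, bcs: BCSet | None = None,
                 schedule: Schedule | None = None,
                 rtol: float = 1e-6, atol: float = 1e-10, max_iter: int = 60):
        self.enr = enriched_mesh
        self.material = material if material is not None else OgdenPronyMaterial()
        self.bcs = bcs if bcs is not None else BCSet()
        self.schedule = schedule if schedule is not None else Schedule()
        self.rtol, self.atol, self.max_iter = rtol, atol, max_iter
        if self.bcs.empty:
            raise ValueError("BCSet is empty — the system would be singular")
        self._setup_quadrature()

    # -- quadrature / sparsity setup ---------------------------------------

    def _setup_quadrature(self):
        enr = self.enr
        mesh = enr.mesh
        plain, special = [], []
        for e in range(mesh.n_elements):
            if enr.elem_class[e] == 0 and not enr.element_is_enriched(e):
                plain.append(e)
            else:
                special.append(e)
        self.plain = np.array(plain, dtype=int)
        self.special = [build_element_quadrature(enr, e) for e in special]

        # shared template for plain (uncut, unenriched, uniform) elements
        from .xfem import GAUSS8
        from .mesh import shape_gradients
        self._g_plain = shape_gradients(GAUSS8, mesh.edge)      # (8, 8, 3)
        self._w_plain = float(np.prod(mesh.edge)) / 8.0
        self._plain_dofs = enr.std_dofs(mesh.elements[self.plain]).reshape(
            len(self.plain), 24)

        rows, cols = [], []
        d = self._plain_dofs
        rows.append(np.repeat(d, 24, axis=1).ravel())
        cols.append(np.tile(d, (1, 24)).ravel())
        for q in self.special:
            nd = len(q.dofs)
            rows.append(np.repeat(q.dofs, nd))
            cols.append(np.tile(q.dofs, nd))
        self._rows = np.concatenate(rows)
        self._cols = np.concatenate(cols)
        self._nnz_plain = d.shape[0] * 24 * 24

    def fresh_states(self):
        mat = self.material
        n_sp = sum(len(q.weights) for q in self.special)
        return (mat.fresh_state((len(self.plain), 8)),
                mat.fresh_state((n_sp,)) if n_sp else mat.fresh_state((1,)))

    # -- assembly ----------------------------------------------------------

    def _deformation_gradients(self, dofs):
        enr = self.enr
        Fp = np.empty((len(self.plain), 8, 3, 3))
        if len(self.plain):
            d = dofs[self._plain_dofs].reshape(-1, 8, 3)
            Fp[:] = _EYE + np.einsum("eai,qaJ->eqiJ", d, self._g_plain)
        Fs_parts = []
        for q in self.special:
            d = dofs[q.dofs].reshape(-1, 3)
            Fs_parts.append(_EYE + np.einsum("ai,qaJ->qiJ", d, q.G))
        Fs = np.concatenate(Fs_parts) if Fs_parts else np.empty((0, 3, 3))
        return Fp, Fs

    def assemble(self, dofs, states, dt, need_tangent=True, chunk=512):
        """Internal-force residual and (optionally) the sparse tangent.

        The residual is the internal force vector (no external tractions);
        the tangent pairs the consistent material tangent with the geometric
        stiffness.  Cut elements use the precomputed conforming sub-tet rule.
        """
        enr = self.enr
        mat = self.material
        st_plain, st_special = states
        r = np.zeros(enr.n_dofs)
        data = np.empty(len(self._rows)) if need_tangent else None

        Fp, Fs = self._deformation_gradients(dofs)
        if np.any(np.linalg.det(Fp.reshape(-1, 3, 3)) <= 0) or \
           (len(Fs) and np.any(np.linalg.det(Fs) <= 0)):
            raise SolverError("inverted element during assembly")

        # plain elements, chunked stacked operations
        ne = len(self.plain)
        G = self._g_plain  # (8 qp, 8 basis, 3)
        for c0 in range(0, ne, chunk):
            c1 = min(c0 + chunk, ne)
            m = c1 - c0
            F = Fp[c0:c1]                                  # (m, 8, 3, 3)
            C = np.einsum("eqki,eqkj->eqij", F, F)
            sub = _slice_state(st_plain, (slice(c0, c1), slice(None)))
            S, _, _ = mat.pk2_update(C, sub, dt)
            P = np.einsum("eqiI,eqIJ->eqiJ", F, S)
            r_e = self._w_plain * np.einsum("eqiJ,qaJ->eai", P, G,
                                            optimize=True)
            np.add.at(r, self._plain_dofs[c0:c1], r_e.reshape(m, 24))
            if need_tangent:
                D = mat.tangent_dSdC(C, sub, dt)
                A = _spatial_tangent(F.reshape(-1, 3, 3),
                                     S.reshape(-1, 3, 3),
                                     D.reshape(-1, 3, 3, 3, 3))
                Gb = np.tile(G, (m, 1, 1))
                K_e = self._w_plain * _element_stiffness(Gb, A).reshape(
                    m, 8, 24, 24).sum(axis=1)
                data[c0 * 576:c1 * 576] = K_e.ravel()

        # special (cut / tip / blending) elements
        if self.special:
            C_s = np.einsum("qki,qkj->qij", Fs, Fs)
            S_s, _, _ = mat.pk2_update(C_s, st_special, dt)
            A_s = None
            if need_tangent:
                D_s = mat.tangent_dSdC(C_s, st_special, dt)
                A_s = _spatial_tangent(Fs, S_s, D_s)
            P_s = np.einsum("qiI,qIJ->qiJ", Fs, S_s)
            ptr = 0
            off = self._nnz_plain
            for q in self.special:
                nq = len(q.weights)
                sl = slice(ptr, ptr + nq)
                ptr += nq
                r_e = np.einsum("q,qiJ,qaJ->ai", q.weights, P_s[sl], q.G,
                                optimize=True)
                np.add.at(r, q.dofs, r_e.ravel())
                if need_tangent:
                    A_w = A_s[sl] * q.weights[:, None, None, None, None]
                    K_e = _element_stiffness(q.G, A_w).sum(axis=0)
                    nd = len(q.dofs)
                    data[off:off + nd * nd] = K_e.ravel()
                    off += nd * nd
        K = None
        if need_tangent:
            K = sp.coo_matrix((data, (self._rows, self._cols)),
                              shape=(enr.n_dofs, enr.n_dofs)).tocsr()
        return r, K

    def commit_states(self, dofs, states, dt):
        mat = self.material
        st_plain, st_special = states
        Fp, Fs = self._deformation_gradients(dofs)
        C = np.einsum("eqki,eqkj->eqij", Fp, Fp)
        _, h, s0 = mat.pk2_update(C, st_plain, dt)
        mat.commit(st_plain, h, s0, dt)
        if len(Fs):
            C_s = np.einsum("qki,qkj->qij", Fs, Fs)
            _, h, s0 = mat.pk2_update(C_s, st_special, dt)
            mat.commit(st_special, h, s0, dt)

    def strain_energy(self, dofs) -> float:
        """Total instantaneous strain energy of a DOF vector, Pa*mm^3."""
        mat = self.material
        Fp, Fs = self._deformation_gradients(dofs)
        total = 0.0
        if len(Fp):
            lam = np.sqrt(np.linalg.eigvalsh(
                np.einsum("eqki,eqkj->eqij", Fp, Fp)))
            total += self._w_plain * mat.energy_density(lam).sum()
        ptr = 0
        for q in self.special:
            F = Fs[ptr:ptr + len(q.weights)]
            ptr += len(q.weights)
            lam = np.sqrt(np.linalg.eigvalsh(np.einsum("qki,qkj->qij", F, F)))
            total += float(q.weights @ mat.energy_density(lam))
        return total

    # -- solve -------------------------------------------------------------

    def fit(self, verbose: bool = False) -> "RetractionResults":
        """Ramp the prescribed displacements and solve; returns results."""
        enr = self.enr
        t0 = _time.perf_counter()
        p_idx, p_val = self.bcs.prescribed_dofs(enr)
        if len(p_idx) == 0:
            raise ValueError("no prescribed DOFs — nothing drives the model")
        free = np.setdiff1d(np.arange(enr.n_dofs), p_idx)
        d = np.zeros(enr.n_dofs)
        states = self.fresh_states()
        log = []
        d_hist = [d.copy()]  # converged solutions of recent increments
        for k, (lam, dt) in enumerate(self.schedule.steps, start=1):
            d_safe = d.copy()
            if len(d_hist) == 2:
                # secant predictor: the ramp is smooth, so extrapolating
                # the previous increments lands close to the new solution
                d = 2.0 * d_hist[-1] - d_hist[-2]
            d[p_idx] = lam * p_val
            res_hist = []
            ref = None
            converged = False
            try:
                r, _ = self.assemble(d, states, dt, need_tangent=False)
            except SolverError:
                d = d_safe  # predictor overshot into element inversion
                d[p_idx] = lam * p_val
                r, _ = self.assemble(d, states, dt, need_tangent=False)
            lu = None  # LU of an earlier tangent, kept as preconditioner
            for it in range(self.max_iter + 1):
                rn = float(np.linalg.norm(r[free]))
                res_hist.append(rn)
                if ref is None:
                    # force scale: free residual or the boundary reactions
                    # (the predictor can land at a near-zero free residual)
                    ref = max(rn, float(np.linalg.norm(r[p_idx])), self.atol)
                if rn <= max(self.rtol * ref, self.atol):
                    converged = True
                    break
                if it == self.max_iter:
                    break
                # full Newton: fresh consistent tangent every iteration,
                # solved by LU-preconditioned GMRES; the factorisation is
                # refreshed only when the Krylov solve degrades
                _, K = self.assemble(d, states, dt)
                Kff = K[free][:, free].tocsc()
                dd = None
                if lu is not None:
                    n_kry = 0

                    def _count(_):
                        nonlocal n_kry
                        n_kry += 1

                    M = spla.LinearOperator(Kff.shape, lu.solve)
                    dd, info = spla.gmres(Kff, -r[free], M=M, rtol=1e-10,
                                          atol=0.0, restart=50, maxiter=2,
                                          callback=_count,
                                          callback_type="legacy")
                    if info != 0:
                        dd = None
                    elif n_kry > 30:
                        lu = None  # refactor next time round
                if dd is None:
                    try:
                        lu = spla.splu(Kff)
                    except RuntimeError as exc:  # singular factorization
                        raise SolverError(
                            "singular tangent — missing zero-displacement "
                            "BCs?") from exc
                    dd = lu.solve(-r[free])
                if not np.all(np.isfinite(dd)):
                    raise SolverError(
                        "singular tangent — missing zero-displacement BCs?")
                step = 1.0
                accepted = False
                for _ls in range(10):  # backtracking line search
                    d_try = d.copy()
                    d_try[free] += step * dd
                    try:
                        r_new, _ = self.assemble(d_try, states, dt,
                                                 need_tangent=False)
                    except SolverError:
                        step *= 0.5
                        continue
                    accepted = True
                    if np.linalg.norm(r_new[free]) <= rn or step < 1e-2:
                        break
                    step *= 0.5
                if not accepted:
                    raise SolverError(
                        f"line search failed in increment {k} "
                        "(element inversion at every step length)")
                d, r = d_try, r_new
            if not converged:
                raise SolverError(
                    f"Newton did not converge in increment {k}: "
                    f"residuals {res_hist}")
            self.commit_states(d, states, dt)
            d_hist = (d_hist + [d.copy()])[-2:]
            log.append({"increment": k, "load_factor": lam, "dt": dt,
                        "iterations": len(res_hist) - 1,
                        "residuals": res_hist})
            if verbose:
                print(f"  increment {k}: {len(res_hist)-1} iterations, "
                      f"residual {res_hist[-1]:.3e}")
        elapsed = _time.perf_counter() - t0
        return RetractionResults(self, DisplacementField(enr, d, log),
                                 states, log, elapsed)


class RetractionResults:
    """Converged solution: field, history archive and diagnostics."""

    def __init__(self, model, field: DisplacementField, states, log,
                 solve_time: float):
        self.model = model
        self.field = field
        self.states = states
        self.convergence_log = log
        self.solve_time = solve_time

    @property
    def dofs(self) -> np.ndarray:
        return self.field.dofs

    def node_displacements(self) -> np.ndarray:
        return self.field.node_displacements()

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.node_displacements(), axis=1).max())

    def strain_energy(self) -> float:
        return self.model.strain_energy(self.dofs)

    def summary(self) -> str:
        enr = self.model.enr
        mesh = enr.mesh
        un = np.linalg.norm(self.node_displacements(), axis=1)
        total_it = sum(e["iterations"] for e in self.convergence_log)
        lines = [
            "Hyper-viscoelastic XFEM retraction results",
            "=" * 46,
            f"nodes / elements       {mesh.n_nodes:>8d} / {mesh.n_elements}",
            f"Heaviside / tip nodes  {len(enr.heaviside_nodes):>8d} / "
            f"{len(enr.tip_nodes)}",
            f"total DOFs             {enr.n_dofs:>8d}",
            f"material               {type(self.model.material).__name__}",
            f"schedule               T={self.model.schedule.T:g} s, "
            f"{self.model.schedule.n_increments} increments",
            f"increments solved      {len(self.convergence_log):>8d}",
            f"Newton iterations      {total_it:>8d}",
            f"final residual (N)     {self.convergence_log[-1]['residuals'][-1]:>12.3e}",
            f"max |u| (mm)           {un.max():>12.4f}",
            f"mean |u| (mm)          {un.mean():>12.4f}",
            f"strain energy (uJ)     {self.strain_energy() * 1e-3:>12.4f}",
            f"solve time (s)         {self.solve_time:>12.2f}",
        ]
        return "\n".join(lines)


def _slice_state(state, key):
    """View into a ViscoState for a chunk of quadrature points."""
    from .constitutive import ViscoState
    sub = ViscoState.__new__(ViscoState)
    sub.n_terms = state.n_terms
    sub.h = state.h[(slice(None),) + (key if isinstance(key, tuple) else (key,))]
    sub.s_iso_prev = state.s_iso_prev[key]
    sub.shape = sub.s_iso_prev.shape[:-2]
    sub.time = state.time
    return sub
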