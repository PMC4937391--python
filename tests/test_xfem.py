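"""XFEM enrichment basis, cut-element quadrature and the nonlinear solve."""

import numpy as np
import pytest

from retractsim import OgdenPronyMaterial
from retractsim.mesh import (CrackGeometry, build_hex_mesh,
                             classify_and_enrich)
from retractsim.model import (BCSet, DisplacementField, RetractionModel,
                              Schedule)
from retractsim.xfem import (build_element_quadrature, cut_tet_by_plane,
                             heaviside, tip_branch_functions)


class TestHeaviside:
    def test_signs(self):
        assert heaviside(2.0) == 1.0
        assert heaviside(-0.1) == -1.0

    def test_jump_is_two(self):
        phi = np.linspace(-1, 1, 7)
        h = heaviside(phi)
        assert h.max() - h.min() == 2.0


class TestBranchFunctions:
    def test_zero_at_tip(self):
        assert np.allclose(tip_branch_functions(0.0, 0.3), 0.0)

    def test_value_on_crack_face(self):
        f = tip_branch_functions(1.0, np.pi)
        assert f[0] == pytest.approx(1.0)  # sqrt(r) sin(pi/2)

    def test_only_first_discontinuous_across_faces(self):
        r = 2.3
        up = tip_branch_functions(r, np.pi - 1e-9)
        dn = tip_branch_functions(r, -np.pi + 1e-9)
        assert up[0] - dn[0] == pytest.approx(2 * np.sqrt(r), rel=1e-6)
        assert np.allclose(up[1:], dn[1:], atol=1e-6)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            tip_branch_functions(-1.0, 0.0)


class TestCutTet:
    def _tet(self):
        return np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])

    def _vol(self, v):
        return abs(np.linalg.det(np.stack([v[1] - v[0], v[2] - v[0],
                                           v[3] - v[0]]))) / 6

    @pytest.mark.parametrize("phiv", [
        [1.0, 1.0, 1.0, 1.0], [-1.0, -1.0, -1.0, -1.0],
        [1.0, -1.0, -1.0, -1.0], [1.0, 1.0, -1.0, -1.0],
        [-0.2, 0.7, 0.3, -0.9], [0.5, -0.5, 0.5, -0.5],
    ])
    def test_pieces_tile_parent_volume(self, phiv):
        verts = self._tet()
        pieces = cut_tet_by_plane(verts, np.array(phiv))
        total = sum(self._vol(t) for t, _ in pieces)
        assert total == pytest.approx(self._vol(verts), rel=1e-12)

    def test_sides_match_plane_halves(self):
        verts = self._tet() * 2.0
        phiv = verts[:, 0] - 0.5  # plane x = 0.5
        pieces = cut_tet_by_plane(verts, phiv)
        for t, s in pieces:
            centroid = t.mean(axis=0)
            assert np.sign(centroid[0] - 0.5) == s


class TestElementQuadrature:
    def test_cut_element_weights_tile_volume(self, cube_enriched):
        enr = cube_enriched
        cut = np.flatnonzero(enr.elem_class == 1)
        q = build_element_quadrature(enr, int(cut[0]))
        assert q.weights.sum() == pytest.approx(float(np.prod(enr.mesh.edge)))
        # side volumes match the plane position within the element
        vol_plus = q.weights[q.side > 0].sum()
        corners = enr.mesh.nodes[enr.mesh.elements[cut[0]]]
        frac = (corners[:, 0].max() - 10.3) / enr.mesh.edge[0]
        assert vol_plus == pytest.approx(
            float(np.prod(enr.mesh.edge)) * frac, rel=1e-9)

    def test_standard_element_gauss_rule(self, cube_enriched):
        std = np.flatnonzero(cube_enriched.elem_class == 0)
        q = build_element_quadrature(cube_enriched, int(std[0]))
        assert len(q.weights) == 8
        assert q.weights.sum() == pytest.approx(
            float(np.prod(cube_enriched.mesh.edge)))


class TestDisplacementField:
    def test_classical_interpolation_when_enrichment_zero(self, cube_enriched):
        enr = cube_enriched
        rng = np.random.default_rng(5)
        dofs = np.zeros(enr.n_dofs)
        u_nodes = rng.normal(0, 0.5, (enr.mesh.n_nodes, 3))
        dofs[:3 * enr.mesh.n_nodes] = u_nodes.ravel()
        field = DisplacementField(enr, dofs)
        # at a node: exactly that node's displacement (shifted enrichment)
        nid = int(enr.heaviside_nodes[0])
        u = field.evaluate(enr.mesh.nodes[[nid]],
                           side=float(enr.node_side[nid]))
        assert np.allclose(u[0], u_nodes[nid], atol=1e-12)
        # inside a standard element: trilinear interpolation
        e = int(np.flatnonzero(enr.elem_class == 0)[0])
        center = enr.mesh.nodes[enr.mesh.elements[e]].mean(axis=0)
        u = field.evaluate(center[None])
        assert np.allclose(u[0],
                           u_nodes[enr.mesh.elements[e]].mean(axis=0),
                           atol=1e-12)

    def test_pure_heaviside_jump(self, cube_enriched):
        enr = cube_enriched
        a = np.array([0.7, -0.2, 0.4])
        dofs = np.zeros(enr.n_dofs)
        for nid in enr.heaviside_nodes:
            d0 = enr.heav_dof[int(nid)]
            dofs[d0:d0 + 3] = a
        field = DisplacementField(enr, dofs)
        pts = np.array([[10.3, y, z] for y in (4.0, 9.0) for z in (6.0, 14.0)])
        up = field.evaluate(pts, side=+1)
        um = field.evaluate(pts, side=-1)
        assert np.allclose(up - um, 2 * a, atol=1e-12)

    def test_outside_point_raises_or_zeroes(self, cube_enriched):
        field = DisplacementField(cube_enriched,
                                  np.zeros(cube_enriched.n_dofs))
        with pytest.raises(ValueError):
            field.evaluate(np.array([[100.0, 0, 0]]))
        u = field.evaluate(np.array([[100.0, 0, 0]]), outside="zero")
        assert np.allclose(u, 0.0)


class TestAssembly:
    def test_zero_dofs_zero_residual(self, cube_enriched, material):
        model = RetractionModel(cube_enriched, material,
                                BCSet(fixed_nodes=[0]), Schedule(T=0))
        r, K = model.assemble(np.zeros(cube_enriched.n_dofs),
                              model.fresh_states(), 0.0)
        assert np.allclose(r, 0.0, atol=1e-9)

    def test_rigid_translation_zero_residual(self, cube_enriched, material):
        model = RetractionModel(cube_enriched, material,
                                BCSet(fixed_nodes=[0]), Schedule(T=0))
        d = np.zeros(cube_enriched.n_dofs)
        d[:3 * cube_enriched.mesh.n_nodes] = np.tile([1.0, -2.0, 0.5],
                                                     cube_enriched.mesh.n_nodes)
        r, _ = model.assemble(d, model.fresh_states(), 0.0,
                              need_tangent=False)
        assert np.abs(r).max() < 1e-8

    def test_tangent_matches_residual_fd(self, two_elem_cut, material):
        model = RetractionModel(two_elem_cut, material, BCSet(fixed_nodes=[0]),
                                Schedule(T=0))
        rng = np.random.default_rng(1)
        d = rng.normal(0, 0.05, two_elem_cut.n_dofs)
        states = model.fresh_states()
        r, K = model.assemble(d, states, 0.0)
        K = K.toarray()
        h = 1e-6
        cols = rng.choice(two_elem_cut.n_dofs, size=20, replace=False)
        for j in cols:
            dp, dm = d.copy(), d.copy()
            dp[j] += h
            dm[j] -= h
            rp, _ = model.assemble(dp, states, 0.0, need_tangent=False)
            rm, _ = model.assemble(dm, states, 0.0, need_tangent=False)
            fd = (rp - rm) / (2 * h)
            assert np.abs(K[:, j] - fd).max() < 1e-4 * np.abs(K).max()

    def test_tangent_symmetric(self, two_elem_cut, material):
        model = RetractionModel(two_elem_cut, material, BCSet(fixed_nodes=[0]),
                                Schedule(T=0))
        d = np.random.default_rng(2).normal(0, 0.03, two_elem_cut.n_dofs)
        _, K = model.assemble(d, model.fresh_states(), 0.0)
        K = K.toarray()
        assert np.abs(K - K.T).max() < 1e-6 * np.abs(K).max()


def _affine_bcs(mesh, Fa):
    return BCSet(node_displacements={
        int(n): Fa @ mesh.nodes[n] for n in mesh.boundary_nodes()})


class TestSolve:
    def test_zero_prescription_gives_zero_field(self, cube_enriched, material):
        entries = [(int(n), s, np.zeros(3))
                   for n in cube_enriched.heaviside_nodes for s in (+1, -1)]
        model = RetractionModel(cube_enriched, material,
                                BCSet(fixed_nodes=[0], crack_face_bcs=entries),
                                Schedule(T=0))
        res = model.fit()
        assert np.allclose(res.dofs, 0.0, atol=1e-12)

    def test_patch_test_exact(self, cube_mesh, material):
        enr = classify_and_enrich(cube_mesh, None)
        Fa = np.diag([1.05, 0.98, 1.0]) - np.eye(3)
        model = RetractionModel(enr, material, _affine_bcs(cube_mesh, Fa),
                                Schedule(T=0), rtol=1e-12, atol=1e-12)
        res = model.fit()
        exact = cube_mesh.nodes @ Fa.T
        assert np.abs(res.node_displacements() - exact).max() < 1e-8

    def test_xfem_equals_fem_with_empty_crack(self, cube_mesh, material):
        Fa = np.diag([1.04, 0.99, 0.97]) - np.eye(3)
        bcs = _affine_bcs(cube_mesh, Fa)
        enr_fem = classify_and_enrich(cube_mesh, None)
        crack_out = CrackGeometry(point=[1e3, 0, 0], normal=[1, 0, 0])
        enr_x = classify_and_enrich(cube_mesh, crack_out)
        r1 = RetractionModel(enr_fem, material, bcs, Schedule(T=0)).fit()
        r2 = RetractionModel(enr_x, material, bcs, Schedule(T=0)).fit()
        assert np.array_equal(r1.dofs, r2.dofs)

    def test_through_crack_rigid_face_separation(self, cube_enriched,
                                                 material):
        """Equal-and-opposite face displacements: halves translate rigidly."""
        enr = cube_enriched
        a = np.array([1.5, 0.0, 0.0])
        entries = []
        for nid in enr.heaviside_nodes:
            entries.append((int(nid), +1, a))
            entries.append((int(nid), -1, -a))
        res = RetractionModel(enr, material, BCSet(crack_face_bcs=entries),
                              Schedule(T=0)).fit()
        assert res.strain_energy() < 1e-6
        pts = np.array([[10.3, 9.0, 9.0], [10.3, 4.0, 14.0]])
        up = res.field.evaluate(pts, side=+1)
        um = res.field.evaluate(pts, side=-1)
        assert np.allclose(up, a, atol=1e-7)
        assert np.allclose(um, -a, atol=1e-7)
        assert np.allclose(up - um, 2 * a, atol=1e-7)

    def test_energy_monotone_under_ramp(self, cube_mesh, material):
        enr = classify_and_enrich(cube_mesh, None)
        energies = []
        for s in (0.3, 0.6, 1.0):
            Fa = np.diag([1 + 0.06 * s, 1 - 0.02 * s, 1.0]) - np.eye(3)
            res = RetractionModel(enr, material, _affine_bcs(cube_mesh, Fa),
                                  Schedule(T=0)).fit()
            energies.append(res.strain_energy())
        assert energies[0] < energies[1] < energies[2]

    def test_node_reordering_invariance(self, material):
        from retractsim.mesh import HexMesh
        mesh = build_hex_mesh(np.ones((15, 15, 15), bool), 1.0, 5.0)
        Fa = np.diag([1.05, 0.97, 1.01]) - np.eye(3)
        res1 = RetractionModel(classify_and_enrich(mesh, None), material,
                               _affine_bcs(mesh, Fa), Schedule(T=0)).fit()
        rng = np.random.default_rng(9)
        perm = rng.permutation(mesh.n_nodes)
        inv = np.argsort(perm)
        mesh2 = HexMesh(nodes=mesh.nodes[perm],
                        elements=inv[mesh.elements],
                        edge=mesh.edge, origin=mesh.origin, dims=mesh.dims,
                        cell_ids=mesh.cell_ids)
        res2 = RetractionModel(classify_and_enrich(mesh2, None), material,
                               _affine_bcs(mesh2, Fa), Schedule(T=0)).fit()
        probes = np.array([[7.0, 7.0, 7.0], [4.0, 10.0, 6.0]])
        assert np.allclose(res1.field.evaluate(probes),
                           res2.field.evaluate(probes), atol=1e-8)

    def test_missing_constraints_rejected(self, cube_enriched, material):
        with pytest.raises(ValueError):
            RetractionModel(cube_enriched, material, BCSet(), Schedule(T=0))

    def test_slow_ramp_relaxes_reaction_forces(self, cube_mesh, material):
        """Viscoelasticity: a slow ramp carries lower boundary reactions
        than an instantaneous load of the same magnitude."""
        enr = classify_and_enrich(cube_mesh, None)
        lam = 1.08  # isochoric stretch so the non-relaxing bulk term is idle
        Fa = np.diag([lam, lam**-0.5, lam**-0.5]) - np.eye(3)
        bcs = _affine_bcs(cube_mesh, Fa)
        p_idx, _ = bcs.prescribed_dofs(enr)

        def reaction_norm(schedule):
            model = RetractionModel(enr, material, bcs, schedule)
            res = model.fit()
            dt = schedule.steps[-1][1]
            r, _ = model.assemble(res.dofs, res.states, dt,
                                  need_tangent=False)
            return np.linalg.norm(r[p_idx])

        fast = reaction_norm(Schedule(T=0))
        slow = reaction_norm(Schedule(T=500.0, n_increments=10))
        assert slow < 0.6 * fast  # substantial Prony relaxation
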