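import numpy as np
import pytest

from fbrmech import fem
from fbrmech.geometry import DomainSpec, Layer, MaterialSpec, generate_mesh
from fbrmech.loads import LoadSpec

from conftest import two_hex_mesh


# ---------------------------------------------------------------------------
# independent element oracle: shape functions from a Vandermonde solve,
# stiffness by volume quadrature of B'CB (B is constant, so a one-point
# rule is exact; the point is the independent construction of B and V)
# ---------------------------------------------------------------------------


def oracle_element_stiffness(coords, E, nu):
    V4 = np.hstack([np.ones((4, 1)), coords])  # N_a(x) = alpha_a + beta_a . x
    coeffs = np.linalg.inv(V4)  # column a: coefficients of N_a
    grads = coeffs[1:, :].T  # (4, 3)
    vol = abs(np.linalg.det(V4)) / 6.0

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu

    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        B[:, 3 * a : 3 * a + 3] = [
            [gx, 0, 0],
            [0, gy, 0],
            [0, 0, gz],
            [0, gz, gy],
            [gz, 0, gx],
            [gy, gx, 0],
        ]
    return vol * B.T @ C @ B


REF_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


class TestElementStiffness:
    def test_matches_quadrature_oracle_on_reference_tet(self):
        K = fem.element_stiffness(REF_TET, 1.0, 0.25)
        K_oracle = oracle_element_stiffness(REF_TET, 1.0, 0.25)
        assert np.allclose(K, K_oracle, atol=1e-14)

    def test_matches_oracle_on_random_tets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            coords = rng.normal(size=(4, 3))
            if np.linalg.det(coords[1:] - coords[0]) <= 0:
                coords[[1, 2]] = coords[[2, 1]]
            K = fem.element_stiffness(coords, 2.3e5, 0.33)
            assert np.allclose(K, oracle_element_stiffness(coords, 2.3e5, 0.33))

    def test_symmetry_and_linearity_in_E(self):
        K1 = fem.element_stiffness(REF_TET, 1.0, 0.3)
        K2 = fem.element_stiffness(REF_TET, 2.0, 0.3)
        assert np.allclose(K1, K1.T)
        assert np.allclose(K2, 2 * K1)

    def test_six_rigid_body_modes(self):
        K = fem.element_stiffness(REF_TET, 1.0, 0.25)
        w = np.linalg.eigvalsh(K)
        assert (np.abs(w) < 1e-12).sum() == 6
        assert w[6:].min() > 0

    def test_degenerate_tet_rejected(self):
        flat = REF_TET.copy()
        flat[3] = [0.5, 0.5, 0.0]
        with pytest.raises(ValueError, match="degenerate|volume"):
            fem.element_stiffness(flat, 1.0, 0.3)


def _roller_dofs(mesh, eps=1e-9):
    nd = mesh.nodes
    dofs = [3 * i + 0 for i in np.flatnonzero(nd[:, 0] <= eps)]
    dofs += [3 * i + 1 for i in np.flatnonzero(nd[:, 1] <= eps)]
    dofs += [3 * i + 2 for i in np.flatnonzero(nd[:, 2] <= eps)]
    return np.asarray(dofs)


def _uniaxial_problem(mesh, mat, traction):
    f = fem.face_traction_forces(
        mesh, lambda n: n[:, 0] >= n[:, 0].max() - 1e-9, np.array([traction, 0, 0])
    )
    return fem.ElasticityProblem(
        mesh=mesh,
        material_map={name: mat for name in set(mesh.region)},
        dirichlet=np.empty(0, int),
        nodal_forces=f,
        dirichlet_dofs=_roller_dofs(mesh),
    )


class TestAssembleAndSolve:
    def test_zero_load_zero_solution(self, block_spec, soft_tissue):
        mesh = generate_mesh(block_spec, 3.4)
        prob = fem.ElasticityProblem(
            mesh=mesh,
            material_map={"tissue": soft_tissue},
            dirichlet=mesh.node_sets["bottom_fixed"],
            nodal_forces=np.zeros((mesh.n_nodes, 3)),
        )
        sol = fem.assemble_and_solve(prob)
        assert np.allclose(sol.displacements, 0)
        assert np.allclose(sol.element_stress, 0)

    def test_uniaxial_patch_exact(self, block_spec, soft_tissue):
        E, t, L = soft_tissue.youngs_modulus, 1000.0, 10.0
        mesh = generate_mesh(block_spec, 2.6)
        sol = fem.assemble_and_solve(_uniaxial_problem(mesh, soft_tissue, t))
        sx = sol.element_stress[:, 0, 0]
        assert np.abs(sx - t).max() / t < 1e-10
        assert np.abs(sol.element_stress[:, 0, 1]).max() < 1e-10 * t
        tip = sol.displacements[mesh.nodes[:, 0] >= L - 1e-9, 0]
        exact = t / E * (L * 1e-3)
        assert np.abs(tip - exact).max() / exact < 1e-10

    def test_two_layer_series_bar(self):
        # stack along z, traction on top, rollers: series-spring compliance
        m1 = MaterialSpec("a", 5.0e4, 0.0)
        m2 = MaterialSpec("b", 2.0e5, 0.0)
        spec = DomainSpec(
            layers=[Layer("a", 6.0, m1), Layer("b", 4.0, m2)],
            lateral_extent=4.0,
            load=LoadSpec("static_force", 0.0),
        )
        mesh = generate_mesh(spec, 1.5)
        t = 500.0
        f = fem.face_traction_forces(
            mesh, lambda n: n[:, 2] >= 10.0 - 1e-9, np.array([0, 0, t])
        )
        prob = fem.ElasticityProblem(
            mesh=mesh,
            material_map={"a": m1, "b": m2},
            dirichlet=np.empty(0, int),
            nodal_forces=f,
            dirichlet_dofs=_roller_dofs(mesh),
        )
        sol = fem.assemble_and_solve(prob)
        top = sol.displacements[mesh.nodes[:, 2] >= 10.0 - 1e-9, 2]
        exact = t * (6.0e-3 / 5.0e4 + 4.0e-3 / 2.0e5)
        assert np.abs(top - exact).max() / exact < 1e-10

    def test_superposition(self, block_spec, soft_tissue):
        mesh = generate_mesh(block_spec, 3.4)
        p1 = _uniaxial_problem(mesh, soft_tissue, 100.0)
        p3 = _uniaxial_problem(mesh, soft_tissue, 300.0)
        u1 = fem.assemble_and_solve(p1).displacements
        u3 = fem.assemble_and_solve(p3).displacements
        assert np.abs(u3 - 3 * u1).max() <= 1e-10 * np.abs(u3).max()

    def test_dense_brute_force_agreement_small_mesh(self, soft_tissue):
        spec = DomainSpec(
            layers=[Layer("tissue", 6.0, soft_tissue)],
            lateral_extent=6.0,
            load=LoadSpec("static_force", 0.0),
        )
        mesh = generate_mesh(spec, 3.1)  # 27 nodes -> 81 DOF
        assert 3 * mesh.n_nodes <= 300
        rng = np.random.default_rng(1)
        forces = rng.normal(size=(mesh.n_nodes, 3))
        forces[mesh.node_sets["bottom_fixed"]] = 0
        prob = fem.ElasticityProblem(
            mesh=mesh,
            material_map={"tissue": soft_tissue},
            dirichlet=mesh.node_sets["bottom_fixed"],
            nodal_forces=forces,
        )
        sol = fem.assemble_and_solve(prob)

        # dense brute force: python-loop assembly + numpy dense solve
        n = 3 * mesh.n_nodes
        K = np.zeros((n, n))
        for tet in range(mesh.n_elements):
            ke = fem.element_stiffness(
                mesh.nodes[mesh.tets[tet]] * 1e-3,
                soft_tissue.youngs_modulus,
                soft_tissue.poisson_ratio,
            )
            dofs = np.concatenate([3 * mesh.tets[tet] + c for c in [0]]).tolist()
            dofs = [3 * nd + c for nd in mesh.tets[tet] for c in range(3)]
            K[np.ix_(dofs, dofs)] += ke
        fixed = np.concatenate(
            [3 * mesh.node_sets["bottom_fixed"] + c for c in range(3)]
        )
        free = np.setdiff1d(np.arange(n), fixed)
        u_dense = np.zeros(n)
        u_dense[free] = np.linalg.solve(
            K[np.ix_(free, free)], forces.ravel()[free]
        )
        assert np.allclose(sol.displacements.ravel(), u_dense, rtol=1e-9, atol=1e-15)

    def test_insufficiently_constrained_system_raises(self, soft_tissue):
        spec = DomainSpec(
            layers=[Layer("tissue", 6.0, soft_tissue)],
            lateral_extent=6.0,
            load=LoadSpec("static_force", 0.0),
        )
        mesh = generate_mesh(spec, 3.1)
        forces = np.zeros((mesh.n_nodes, 3))
        forces[-1, 0] = 1.0
        prob = fem.ElasticityProblem(
            mesh=mesh,
            material_map={"tissue": soft_tissue},
            dirichlet=np.empty(0, int),
            nodal_forces=forces,
            dirichlet_dofs=np.array([0]),  # one DOF cannot stop rigid modes
        )
        with pytest.raises((np.linalg.LinAlgError, RuntimeError)):
            fem.assemble_and_solve(prob)


class TestStressRecovery:
    def _solution_with_displacement(self, mesh, mat, u):
        prob = fem.ElasticityProblem(
            mesh=mesh,
            material_map={name: mat for name in set(mesh.region)},
            dirichlet=np.array([0]),
            nodal_forces=np.zeros((mesh.n_nodes, 3)),
        )
        return fem.FieldSolution(displacements=u, element_stress=np.empty(0),
                                 problem=prob)

    def test_uniform_strain_hookes_law(self, block_spec):
        mat = MaterialSpec("t", 1e5, 0.0)
        mesh = generate_mesh(block_spec, 3.4)
        u = np.zeros((mesh.n_nodes, 3))
        u[:, 0] = 0.01 * mesh.nodes[:, 0] * 1e-3  # eps_xx = 0.01
        sol = self._solution_with_displacement(mesh, mat, u)
        sigma = fem.recover_stress(sol)
        assert np.allclose(sigma[:, 0, 0], 0.01 * 1e5)
        off = sigma.copy()
        off[:, 0, 0] = 0
        assert np.abs(off).max() < 1e-8

    def test_rigid_translation_gives_zero_stress(self, block_spec, soft_tissue):
        mesh = generate_mesh(block_spec, 3.4)
        u = np.tile([1e-3, -2e-3, 5e-4], (mesh.n_nodes, 1))
        sol = self._solution_with_displacement(mesh, soft_tissue, u)
        # roundoff floor: E * (u / L) * eps ~ 1e-11 Pa
        assert np.abs(fem.recover_stress(sol)).max() < 1e-8

    def test_uniform_shear(self, block_spec):
        E, nu, gamma = 1e5, 0.3, 0.002
        mat = MaterialSpec("t", E, nu)
        mesh = generate_mesh(block_spec, 3.4)
        u = np.zeros((mesh.n_nodes, 3))
        u[:, 0] = gamma * mesh.nodes[:, 1] * 1e-3  # engineering shear xy
        sol = self._solution_with_displacement(mesh, mat, u)
        sigma = fem.recover_stress(sol)
        G = E / (2 * (1 + nu))
        assert np.allclose(sigma[:, 0, 1], G * gamma)


class TestInterfaceSummary:
    def test_homogeneous_implant_matches_far_field(self, block_spec, soft_tissue):
        # mark an inner band of elements "implant" with the same material:
        # interface stress must equal the uniform patch-test stress
        mesh = generate_mesh(block_spec, 2.6)
        centers = mesh.nodes[mesh.tets].mean(axis=1)
        inner = np.all(np.abs(centers - 5.0) < 2.0, axis=1)
        mesh.region = mesh.region.copy()
        mesh.region[inner] = "implant"
        from fbrmech.geometry import extract_node_sets

        mesh.node_sets = extract_node_sets(mesh)
        t = 1000.0
        prob = _uniaxial_problem(mesh, soft_tissue, t)
        sol = fem.assemble_and_solve(prob)
        summary = fem.interface_stress_summary(sol, mesh.node_sets["interface"])
        assert summary.max_tensile_sx == pytest.approx(t / 1e3, rel=1e-9)
        assert summary.max_abs_sx == pytest.approx(t / 1e3, rel=1e-9)

    def test_stiff_inclusion_sign_pattern(self, implant_spec):
        _, sol, summary = fem.solve_domain(implant_spec, 1.5)
        assert summary.max_tensile_sx > 0
        assert summary.max_compressive_sx < 0
        assert summary.max_abs_sx == pytest.approx(
            max(summary.max_tensile_sx, -summary.max_compressive_sx)
        )

    def test_empty_interface_rejected(self, block_spec, soft_tissue):
        mesh = generate_mesh(block_spec, 3.4)
        prob = _uniaxial_problem(mesh, soft_tissue, 10.0)
        sol = fem.assemble_and_solve(prob)
        with pytest.raises(ValueError, match="interface"):
            fem.interface_stress_summary(sol, np.empty(0, int))


class TestConvergenceCheck:
    def test_domain_without_implant_cannot_be_loaded(self, soft_tissue):
        spec = DomainSpec(
            layers=[Layer("a", 8.0, soft_tissue)],
            lateral_extent=8.0,
            load=LoadSpec("static_force", 0.01),
            implant=None,
        )
        with pytest.raises(ValueError, match="implant"):
            fem.solve_domain(spec, 3.0)

    def test_toy_model_convergence_report(self, implant_spec):
        report = fem.mesh_convergence_check(implant_spec, [2.4, 1.6], tol=np.inf)
        assert len(report["max_abs_sx_kpa"]) == 2
        assert report["converged"]  # tol = inf always converges

    def test_requires_two_resolutions(self, implant_spec):
        with pytest.raises(ValueError):
            fem.mesh_convergence_check(implant_spec, [2.0], tol=0.05)


class TestHarmonic:
    def test_zero_frequency_equals_static(self, implant_spec):
        mesh = generate_mesh(implant_spec, 2.0)
        prob = fem.build_problem(implant_spec, mesh)
        static = fem.assemble_and_solve(prob)
        harmonic = fem.harmonic_steady_state(prob, 0.0)
        assert np.allclose(static.displacements, harmonic.displacements)

    def test_single_free_dof_matches_scalar_oracle(self):
        mat = MaterialSpec("m", 1e6, 0.25, 2000.0)
        from fbrmech.geometry import Mesh, extract_node_sets

        nodes = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        tets = np.array([[0, 1, 2, 3]])
        mesh = Mesh(nodes=nodes, tets=tets, region=np.array(["m"], dtype=object))
        mesh.node_sets = extract_node_sets(mesh)
        f = np.zeros((4, 3))
        f[3, 2] = 1.0
        # clamp nodes 0-2 fully and node 3 in x, y: one free DOF (node 3, z)
        prob = fem.ElasticityProblem(
            mesh=mesh, material_map={"m": mat},
            dirichlet=np.array([0, 1, 2]), nodal_forces=f,
            dirichlet_dofs=np.array([9, 10]),
        )
        K = fem.assemble_global_stiffness(prob).toarray()
        k = K[11, 11]
        vol = mesh.volumes()[0] * 1e-9
        m_lumped = mat.density * vol / 4.0
        for freq in (0.0, 5.0, 20.0):
            omega = 2 * np.pi * freq
            sol = fem.harmonic_steady_state(prob, freq)
            expected = 1.0 / (k - omega**2 * m_lumped)
            assert sol.displacements[3, 2] == pytest.approx(expected, rel=1e-9)

    def test_low_frequency_close_to_static(self, implant_spec):
        mesh = generate_mesh(implant_spec, 2.0)
        prob = fem.build_problem(implant_spec, mesh)
        static = fem.assemble_and_solve(prob)
        low = fem.harmonic_steady_state(prob, 1.0)
        num = np.linalg.norm(low.displacements - static.displacements)
        assert num / np.linalg.norm(static.displacements) < 0.05
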