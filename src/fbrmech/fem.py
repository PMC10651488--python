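"""Small-strain linear elasticity on labelled tetrahedral meshes.

Constant-strain (linear) tetrahedra with exact one-point integration, direct
sparse factorisation, per-element stress recovery and interface stress
summaries.  Geometry arrives in mm (see :mod:`fbrmech.geometry`) and is
converted to SI internally: displacements are metres, stresses Pa, summary
extrema kPa.  Compression is negative; ``Sx`` is the normal stress along the
horizontal load axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from fbrmech.geometry import (
    IMPLANT_REGION,
    DomainSpec,
    MaterialSpec,
    Mesh,
    generate_mesh,
    tet_volumes,
)
from fbrmech.loads import LoadSpec, vibration_body_force

__all__ = [
    "ElasticityProblem",
    "FieldSolution",
    "StressSummary",
    "element_stiffness",
    "assemble_global_stiffness",
    "assemble_and_solve",
    "recover_stress",
    "interface_stress_summary",
    "mesh_convergence_check",
    "harmonic_steady_state",
    "solve_domain",
    "build_problem",
    "boundary_faces",
    "face_traction_forces",
    "elastic_moduli_matrix",
]

MM = 1e-3  # mm -> m


def elastic_moduli_matrix(E: float, nu: float) -> np.ndarray:
    """Isotropic stiffness in Voigt order (xx, yy, zz, yz, xz, xy)."""
    if E <= 0:
        raise ValueError("Young's modulus must be > 0")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must be in [0, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    return C


def _shape_gradients(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Gradients (4, 3) of the linear shape functions and the tet volume."""
    J = coords[1:] - coords[0]
    vol = float(np.linalg.det(J)) / 6.0
    if vol <= 0:
        raise ValueError("degenerate or inverted tetrahedron (volume <= 0)")
    grads123 = np.linalg.inv(J)  # columns are grad(lambda_1..3)
    g = np.empty((4, 3))
    g[1:] = grads123.T
    g[0] = -g[1:].sum(axis=0)
    return g, vol


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """6x12 strain-displacement matrix (Voigt, engineering shear strains)."""
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz
        B[3, c + 2] = gy
        B[4, c] = gz
        B[4, c + 2] = gx
        B[5, c] = gy
        B[5, c + 1] = gx
    return B


def element_stiffness(tet_coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness of a linear tetrahedron, K = V * B'CB.

    Units must be consistent (coords in m with E in Pa gives N/m).  The
    block is symmetric positive-semidefinite with six rigid-body modes and
    scales linearly in E.
    """
    coords = np.asarray(tet_coords, dtype=float)
    if coords.shape != (4, 3):
        raise ValueError("tet_coords must be 4x3")
    grads, vol = _shape_gradients(coords)
    B = _b_matrix(grads)
    C = elastic_moduli_matrix(E, nu)
    return vol * (B.T @ C @ B)


@dataclass
class ElasticityProblem:
    """Mesh + materials + constraints + nodal loads (N).

    ``dirichlet`` nodes are fully clamped (zero displacement).  The nodal
    force array is (n_nodes, 3) in newtons.
    """

    mesh: Mesh
    material_map: dict[str, MaterialSpec]
    dirichlet: np.ndarray
    nodal_forces: np.ndarray
    spec: Optional[DomainSpec] = None
    #: extra single-component constraints as global DOF indices (3*node+axis),
    #: e.g. roller/symmetry planes in verification problems
    dirichlet_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __post_init__(self) -> None:
        missing = set(np.unique(self.mesh.region)) - set(self.material_map)
        if missing:
            raise ValueError(f"regions without material: {sorted(missing)}")
        self.dirichlet = np.unique(np.asarray(self.dirichlet, dtype=np.int64))
        self.dirichlet_dofs = np.unique(np.asarray(self.dirichlet_dofs, dtype=np.int64))
        if self.dirichlet.size == 0 and self.dirichlet_dofs.size == 0:
            raise ValueError("dirichlet set empty: rigid-body motion unconstrained")
        self.nodal_forces = np.asarray(self.nodal_forces, dtype=float)
        if self.nodal_forces.shape != (self.mesh.n_nodes, 3):
            raise ValueError("nodal_forces must be (n_nodes, 3)")

    def fixed_dofs(self) -> np.ndarray:
        full = (3 * self.dirichlet[:, None] + np.arange(3)).ravel()
        return np.union1d(full, self.dirichlet_dofs)


@dataclass
class FieldSolution:
    """Nodal displacements (m) and per-element stress tensors (Pa)."""

    displacements: np.ndarray
    element_stress: np.ndarray
    problem: ElasticityProblem
    residual: float = 0.0


@dataclass
class StressSummary:
    """Interface extrema of Sx in kPa (compression negative)."""

    max_abs_sx: float
    max_tensile_sx: float
    max_compressive_sx: float
    location_node_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        assert self.max_tensile_sx >= 0 >= self.max_compressive_sx


def _element_materials(mesh: Mesh, material_map: dict[str, MaterialSpec]):
    E = np.empty(mesh.n_elements)
    nu = np.empty(mesh.n_elements)
    rho = np.empty(mesh.n_elements)
    for name, mat in material_map.items():
        m = mesh.region == name
        E[m], nu[m], rho[m] = mat.youngs_modulus, mat.poisson_ratio, mat.density
    return E, nu, rho


def _batched_geometry(mesh: Mesh):
    """Shape gradients (1/m) and volumes (m^3) for every element at once."""
    p = mesh.nodes[mesh.tets] * MM
    J = p[:, 1:] - p[:, 0:1]
    vol = np.linalg.det(J) / 6.0
    if np.any(vol <= 0):
        raise ValueError("mesh contains non-positively oriented tetrahedra")
    grads123 = np.linalg.inv(J)
    g = np.empty((mesh.n_elements, 4, 3))
    g[:, 1:] = np.transpose(grads123, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def assemble_global_stiffness(problem: ElasticityProblem) -> sp.csr_matrix:
    """Global stiffness (N/m) on 3*n_nodes DOF, vectorised over elements."""
    mesh = problem.mesh
    E, nu, _ = _element_materials(mesh, problem.material_map)
    grads, vol = _batched_geometry(mesh)

    m = mesh.n_elements
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 1] = gz
        B[:, 3, c + 2] = gy
        B[:, 4, c] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c] = gy
        B[:, 5, c + 1] = gx

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((m, 6, 6))
    C[:, :3, :3] = lam[:, None, None]
    idx = np.arange(3)
    C[:, idx, idx] += 2 * mu[:, None]
    C[:, idx + 3, idx + 3] = mu[:, None]

    Ke = vol[:, None, None] * np.einsum("eji,ejk,ekl->eil", B, C, B)

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(m, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def assemble_and_solve(problem: ElasticityProblem) -> FieldSolution:
    """Assemble, eliminate Dirichlet DOF, factorise and solve.

    The reduced system is symmetric positive definite; a singular system
    (insufficient constraints) raises rather than being regularised.  The
    solution is verified to relative residual <= 1e-8.
    """
    K = assemble_global_stiffness(problem)
    n = K.shape[0]
    f = problem.nodal_forces.ravel().copy()

    fixed = problem.fixed_dofs()
    free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)
    Kff = K[free][:, free].tocsc()
    ff = f[free]

    u = np.zeros(n)
    if free.size:
        # symmetric Jacobi equilibration keeps the factorisation accurate
        # under large stiffness contrasts (e.g. metal implant in fat)
        d = Kff.diagonal()
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("non-positive stiffness diagonal")
        dinv = 1.0 / np.sqrt(d)
        D = sp.diags(dinv)
        A = (D @ Kff @ D).tocsc()
        b = dinv * ff
        try:
            lu = spla.splu(A)
            x = lu.solve(b)
        except RuntimeError as exc:  # singular factorisation
            raise np.linalg.LinAlgError(f"singular stiffness system: {exc}") from exc
        if not np.all(np.isfinite(x)):
            raise np.linalg.LinAlgError("singular stiffness system (non-finite solve)")
        refb = float(np.linalg.norm(b))
        for _ in range(5):  # iterative refinement to machine-level residual
            r = b - A @ x
            if float(np.linalg.norm(r)) <= 1e-12 * (refb if refb > 0 else 1.0):
                break
            x = x + lu.solve(r)
        uf = dinv * x
        normK = float(np.abs(Kff).sum(axis=1).max())
        # unconstrained rigid-body modes factor into enormous solutions
        # rather than exact singularity once roundoff enters the assembly
        fmax = float(np.abs(ff).max())
        if fmax > 0 and normK * float(np.abs(uf).max()) / fmax > 1e14:
            raise np.linalg.LinAlgError(
                "singular stiffness system (insufficient constraints)"
            )
        # normwise backward error ||Ku-f|| / (||K|| ||u|| + ||f||): the
        # conditioning-independent measure of solve quality
        denom = normK * float(np.linalg.norm(uf)) + float(np.linalg.norm(ff))
        res = float(np.linalg.norm(Kff @ uf - ff)) / (denom if denom > 0 else 1.0)
        if res > 1e-8:
            raise np.linalg.LinAlgError(f"solver residual {res:.2e} exceeds 1e-8")
        u[free] = uf
    else:
        res = 0.0

    disp = u.reshape(-1, 3)
    sol = FieldSolution(
        displacements=disp, element_stress=np.empty(0), problem=problem, residual=res
    )
    sol.element_stress = recover_stress(sol)
    return sol


def recover_stress(solution: FieldSolution) -> np.ndarray:
    """Per-element stress tensors (Pa): sigma = C : eps, constant per tet."""
    problem = solution.problem
    mesh = problem.mesh
    E, nu, _ = _element_materials(mesh, problem.material_map)
    grads, _ = _batched_geometry(mesh)
    ue = solution.displacements[mesh.tets]  # (m, 4, 3)

    # displacement gradient H_ij = sum_a u_a,i * dN_a/dx_j
    H = np.einsum("eai,eaj->eij", ue, grads)
    eps = 0.5 * (H + np.transpose(H, (0, 2, 1)))

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    tr = np.trace(eps, axis1=1, axis2=2)
    sigma = 2 * mu[:, None, None] * eps
    sigma[:, np.arange(3), np.arange(3)] += (lam * tr)[:, None]
    return sigma


def interface_stress_summary(
    solution: FieldSolution, interface: Optional[np.ndarray] = None
) -> StressSummary:
    """Extrema of Sx over tissue elements adjacent to interface nodes, kPa."""
    mesh = solution.problem.mesh
    if interface is None:
        interface = mesh.node_sets.get("interface", np.empty(0, int))
    interface = np.asarray(interface)
    if interface.size == 0:
        raise ValueError("interface node set is empty")

    on_iface = np.zeros(mesh.n_nodes, dtype=bool)
    on_iface[interface] = True
    touches = on_iface[mesh.tets].any(axis=1)
    tissue = mesh.region != IMPLANT_REGION
    sel = touches & tissue
    if not np.any(sel):
        raise ValueError("no tissue elements adjacent to the interface")

    sx = solution.element_stress[sel, 0, 0] / 1e3  # kPa
    tens = float(max(sx.max(), 0.0))
    comp = float(min(sx.min(), 0.0))
    elems = np.flatnonzero(sel)
    loc = np.unique(
        np.concatenate(
            [
                mesh.tets[elems[np.argmax(sx)]],
                mesh.tets[elems[np.argmin(sx)]],
            ]
        )
    )
    return StressSummary(
        max_abs_sx=max(abs(tens), abs(comp)),
        max_tensile_sx=tens,
        max_compressive_sx=comp,
        location_node_ids=loc,
    )


# ---------------------------------------------------------------------------
# load construction and the preset-level driver
# ---------------------------------------------------------------------------


def _region_nodal_weights(mesh: Mesh, region: str) -> np.ndarray:
    """Lumped-volume weights over the nodes of a region (sum to 1)."""
    w = np.zeros(mesh.n_nodes)
    sel = mesh.region == region
    if not np.any(sel):
        raise ValueError(f"region {region!r} has no elements")
    vols = tet_volumes(mesh.nodes, mesh.tets)[sel]
    np.add.at(w, mesh.tets[sel].ravel(), np.repeat(vols / 4.0, 4))
    return w / w.sum()


def build_problem(spec: DomainSpec, mesh: Mesh) -> ElasticityProblem:
    """Nodal force vector from the DomainSpec load, applied to the implant.

    static_force: total force spread over implant nodes, lumped-volume
    weighted.  vibration: quasi-static peak body force a = amplitude_g * g
    acting on the implant mass (material density plus any lumped motor
    mass).  body_force: magnitude (N/kg) times implant mass, same spread.
    """
    if spec.implant is None:
        raise ValueError("domain has no implant to load")
    load = spec.load
    d = load.direction_vector()
    w = _region_nodal_weights(mesh, IMPLANT_REGION)

    if load.kind == "static_force":
        total = load.magnitude
    else:
        vol_m3 = mesh.region_volume(IMPLANT_REGION) * MM**3
        mass = vol_m3 * spec.implant.material.density + spec.implant.motor_mass
        accel = (
            vibration_body_force(load.amplitude_g)
            if load.kind == "vibration"
            else load.magnitude
        )
        total = mass * accel

    forces = np.outer(w, total * d)
    dirichlet = mesh.node_sets["bottom_fixed"]
    return ElasticityProblem(
        mesh=mesh, material_map=spec.material_map(), dirichlet=dirichlet,
        nodal_forces=forces, spec=spec,
    )


def solve_domain(
    spec: DomainSpec, edge_length: float
) -> tuple[Mesh, FieldSolution, StressSummary]:
    """Mesh, solve and summarise interface stress for a layered-domain spec."""
    mesh = generate_mesh(spec, edge_length)
    problem = build_problem(spec, mesh)
    solution = assemble_and_solve(problem)
    summary = interface_stress_summary(solution, mesh.node_sets["interface"])
    return mesh, solution, summary


def mesh_convergence_check(
    spec: DomainSpec, edge_lengths, tol: float
) -> dict:
    """Run a resolution sequence and report successive change of max |Sx|.

    ``edge_lengths`` must hold at least two decreasing values; the report
    lists max_abs_sx per resolution, the successive relative changes, and
    whether the final change is below ``tol``.
    """
    edges = list(edge_lengths)
    if len(edges) < 2:
        raise ValueError("need at least two edge lengths")
    values = []
    for h in edges:
        _, _, summary = solve_domain(spec, h)
        values.append(summary.max_abs_sx)
    changes = [
        abs(b - a) / max(abs(b), 1e-300) for a, b in zip(values, values[1:])
    ]
    return {
        "edge_lengths": edges,
        "max_abs_sx_kpa": values,
        "relative_changes": changes,
        "converged": changes[-1] < tol,
        "tol": tol,
    }


def harmonic_steady_state(problem: ElasticityProblem, frequency: float) -> FieldSolution:
    """Undamped steady-state response (K - w^2 M) u = F with lumped mass.

    Reduces to the static solve at frequency 0.  A frequency at (or
    numerically indistinguishable from) a resonance raises.
    """
    if frequency == 0:
        return assemble_and_solve(problem)
    mesh = problem.mesh
    _, _, rho = _element_materials(mesh, problem.material_map)
    vols = tet_volumes(mesh.nodes, mesh.tets) * MM**3
    node_mass = np.zeros(mesh.n_nodes)
    np.add.at(node_mass, mesh.tets.ravel(), np.repeat(rho * vols / 4.0, 4))

    K = assemble_global_stiffness(problem)
    omega = 2 * np.pi * frequency
    M = sp.diags(np.repeat(node_mass, 3))
    A = (K - omega**2 * M).tocsr()

    n = A.shape[0]
    f = problem.nodal_forces.ravel()
    fixed = problem.fixed_dofs()
    free = np.setdiff1d(np.arange(n), fixed)
    Aff = A[free][:, free].tocsc()
    try:
        uf = spla.splu(Aff).solve(f[free])
    except RuntimeError as exc:
        raise np.linalg.LinAlgError(
            f"frequency {frequency} Hz is at a resonance: {exc}"
        ) from exc
    if not np.all(np.isfinite(uf)):
        raise np.linalg.LinAlgError(f"frequency {frequency} Hz is at a resonance")
    ref = float(np.linalg.norm(f[free]))
    res = float(np.linalg.norm(Aff @ uf - f[free])) / (ref if ref > 0 else 1.0)
    if res > 1e-6:
        raise np.linalg.LinAlgError(
            f"harmonic solve residual {res:.2e}: near-resonant system"
        )
    u = np.zeros(n)
    u[free] = uf
    sol = FieldSolution(
        displacements=u.reshape(-1, 3), element_stress=np.empty(0),
        problem=problem, residual=res,
    )
    sol.element_stress = recover_stress(sol)
    return sol


# ---------------------------------------------------------------------------
# surface tractions (patch tests and verification problems)
# ---------------------------------------------------------------------------


def boundary_faces(mesh: Mesh) -> np.ndarray:
    """Triangular faces appearing in exactly one tetrahedron, (k, 3)."""
    faces = mesh.tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def face_traction_forces(
    mesh: Mesh,
    selector: Callable[[np.ndarray], np.ndarray],
    traction: np.ndarray,
) -> np.ndarray:
    """Consistent nodal forces (N) for a constant traction (Pa).

    ``selector`` maps node coordinates (mm) to a boolean mask; boundary
    triangles whose three nodes all satisfy it receive the traction.  Each
    triangle contributes t * A / 3 to its nodes (exact for linear elements).
    """
    traction = np.asarray(traction, dtype=float)
    mask = selector(mesh.nodes)
    tris = boundary_faces(mesh)
    tris = tris[mask[tris].all(axis=1)]
    if tris.size == 0:
        raise ValueError("selector matches no boundary triangles")
    p = mesh.nodes[tris] * MM
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    forces = np.zeros((mesh.n_nodes, 3))
    np.add.at(forces, tris.ravel(), np.outer(np.repeat(areas / 3.0, 3), traction))
    return forces
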