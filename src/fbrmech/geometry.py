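"""Layered tissue + disc implant geometry and structured tetrahedral meshing.

The domain is a rectangular box of horizontal extent ``lateral_extent`` (mm,
square footprint) with tissue layers stacked along z, bottom layer resting on
z = 0 (the fixed muscle/bone support).  An optional disc implant (radius,
height) is embedded in one host layer, centred laterally and vertically
within it.  Meshing uses a layer-conforming structured hexahedral grid, each
hexahedron subdivided into six tetrahedra by the Kuhn (Freudenthal) scheme;
the subdivision is translation-invariant, so faces of neighbouring cells
carry matching diagonals and the mesh is conforming.  The disc is
approximated by relabelling cells whose centres fall inside it, which bonds
implant and tissue through shared nodes (a perfect "tie").

Coordinates are in millimetres; z is vertical; the load axis is +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from fbrmech.loads import LoadSpec

__all__ = [
    "MaterialSpec",
    "Layer",
    "ImplantSpec",
    "DomainSpec",
    "Mesh",
    "build_layered_domain",
    "generate_mesh",
    "extract_node_sets",
    "tet_volumes",
]

IMPLANT_REGION = "implant"


@dataclass(frozen=True)
class MaterialSpec:
    """Isotropic linear-elastic material.

    youngs_modulus in Pa, density in kg/m^3.  Poisson ratio must lie in
    [0, 0.5) for a positive-definite stiffness.
    """

    name: str
    youngs_modulus: float
    poisson_ratio: float
    density: float = 1000.0

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError(f"material {self.name!r}: Young's modulus must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError(
                f"material {self.name!r}: Poisson ratio must be in [0, 0.5)"
            )
        if self.density < 0:
            raise ValueError(f"material {self.name!r}: density must be >= 0")


@dataclass(frozen=True)
class Layer:
    name: str
    thickness: float  # mm
    material: MaterialSpec


@dataclass(frozen=True)
class ImplantSpec:
    radius: float  # mm
    height: float  # mm
    material: MaterialSpec
    motor_mass: float = 0.0  # kg, lumped into the vibration load

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("implant radius and height must be > 0")
        if self.motor_mass < 0:
            raise ValueError("motor mass must be >= 0")


@dataclass
class DomainSpec:
    """Declarative description of a layered domain with an optional implant.

    ``layers`` run bottom (fixed muscle/bone support) to top (skin).
    Derived fields (``total_height``, ``implant_box``) are attached by
    :func:`build_layered_domain`.
    """

    layers: list[Layer]
    lateral_extent: float  # mm, square footprint
    load: LoadSpec
    implant: Optional[ImplantSpec] = None
    implant_layer: Optional[str] = None
    name: str = "domain"
    # derived (filled by build_layered_domain)
    total_height: float = field(default=0.0, compare=False)
    implant_box: Optional[tuple[float, float]] = field(default=None, compare=False)

    def layer_by_name(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(f"no layer named {name!r}")

    def material_map(self) -> dict[str, MaterialSpec]:
        mm = {layer.name: layer.material for layer in self.layers}
        if self.implant is not None:
            mm[IMPLANT_REGION] = self.implant.material
        return mm


def build_layered_domain(spec: DomainSpec) -> DomainSpec:
    """Validate a DomainSpec and attach derived geometry.

    Aggregates all validation failures into a single error.  Attaches the
    total stack height and, when an implant is present, its vertical
    extent (z_lo, z_hi): the disc is centred in its host layer.
    """

    errors: list[str] = []
    if not spec.layers:
        errors.append("at least one layer is required")
    for layer in spec.layers:
        if layer.thickness <= 0:
            errors.append(f"layer {layer.name!r} has non-positive thickness")
    names = [layer.name for layer in spec.layers]
    if len(set(names)) != len(names):
        errors.append("layer names must be unique")
    if spec.lateral_extent <= 0:
        errors.append("lateral extent must be > 0")

    total_height = sum(layer.thickness for layer in spec.layers if layer.thickness > 0)
    implant_box: Optional[tuple[float, float]] = None

    if spec.implant is not None:
        if spec.implant_layer is None:
            errors.append("implant present but implant_layer not set")
        elif spec.implant_layer not in names:
            errors.append(f"implant_layer {spec.implant_layer!r} is not a layer")
        else:
            z_lo = 0.0
            for layer in spec.layers:
                if layer.name == spec.implant_layer:
                    host = layer
                    break
                z_lo += layer.thickness
            if spec.implant.height > host.thickness:
                errors.append(
                    f"implant height {spec.implant.height} mm exceeds host layer "
                    f"{host.name!r} thickness {host.thickness} mm"
                )
            if 2 * spec.implant.radius > spec.lateral_extent:
                errors.append("implant diameter exceeds lateral extent")
            pad = (host.thickness - spec.implant.height) / 2.0
            implant_box = (z_lo + pad, z_lo + pad + spec.implant.height)

    if errors:
        raise ValueError("invalid DomainSpec: " + "; ".join(errors))

    return replace(spec, total_height=total_height, implant_box=implant_box)


@dataclass
class Mesh:
    """Labelled tetrahedral mesh.

    nodes: (n, 3) coordinates in mm; tets: (m, 4) node indices with positive
    signed volume; region: length-m array of region names (layer name or
    "implant"); node_sets: bottom_fixed / interface / implant_interior.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes in mm^3 (all positive for a valid mesh)."""
        return tet_volumes(self.nodes, self.tets)

    def region_volume(self, name: str) -> float:
        return float(self.volumes()[self.region == name].sum())


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


# Kuhn subdivision: six tetrahedra per hexahedron, every tet containing the
# main diagonal (0,0,0)-(1,1,1).  Local corner index = ix + 2*iy + 4*iz.
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
_AXIS_BIT = (1, 2, 4)


def _kuhn_tets() -> np.ndarray:
    tets = []
    for p in _KUHN_PERMS:
        v0 = 0
        v1 = _AXIS_BIT[p[0]]
        v2 = v1 + _AXIS_BIT[p[1]]
        v3 = 7
        tets.append((v0, v1, v2, v3))
    return np.asarray(tets, dtype=np.int64)


_KUHN = _kuhn_tets()
TETS_PER_HEX = 6


def _layer_z_grid(spec: DomainSpec, h: float) -> tuple[np.ndarray, np.ndarray]:
    """z node coordinates conforming to layer interfaces + per-cell layer index."""
    zs = [0.0]
    cell_layer: list[int] = []
    z0 = 0.0
    for li, layer in enumerate(spec.layers):
        n = int(np.ceil(layer.thickness / h - 1e-9))
        edges = z0 + layer.thickness * np.arange(1, n + 1) / n
        zs.extend(edges.tolist())
        cell_layer.extend([li] * n)
        z0 += layer.thickness
    return np.asarray(zs), np.asarray(cell_layer, dtype=np.int64)


def generate_mesh(spec: DomainSpec, target_edge_length: float) -> Mesh:
    """Mesh the layered domain into labelled tetrahedra.

    A structured grid with horizontal spacing ~``target_edge_length`` and
    layer-conforming vertical spacing is built and each cell is split into
    six tetrahedra (Kuhn scheme).  Cells whose centres fall inside the disc
    (radius and vertical extent) are labelled "implant".  Deterministic.
    """

    spec = build_layered_domain(spec)
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be > 0")
    thinnest = min(spec.layers, key=lambda l: l.thickness)
    if target_edge_length >= thinnest.thickness:
        raise ValueError(
            f"target_edge_length {target_edge_length} mm does not resolve layer "
            f"{thinnest.name!r} (thickness {thinnest.thickness} mm)"
        )

    L = spec.lateral_extent
    nx = int(np.ceil(L / target_edge_length - 1e-9))
    xs = L * np.arange(nx + 1) / nx
    ys = xs
    zs, cell_layer = _layer_z_grid(spec, target_edge_length)
    nz = len(zs) - 1

    nnx, nny, nnz = nx + 1, nx + 1, nz + 1
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(ix, iy, iz):
        return (ix * nny + iy) * nnz + iz

    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(nx), np.arange(nz), indexing="ij"
    )
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    # hex corner nodes in Kuhn local order (bit 0 -> x, bit 1 -> y, bit 2 -> z)
    corners = np.empty((ix.size, 8), dtype=np.int64)
    for c in range(8):
        corners[:, c] = nid(ix + (c & 1), iy + ((c >> 1) & 1), iz + ((c >> 2) & 1))

    tets = corners[:, _KUHN].reshape(-1, 4)

    # region labels per hex -> per tet
    layer_names = np.asarray([layer.name for layer in spec.layers], dtype=object)
    hex_region = layer_names[cell_layer[iz]]
    if spec.implant is not None:
        cx = cy = L / 2.0
        xc = (xs[ix] + xs[ix + 1]) / 2.0 - cx
        yc = (ys[iy] + ys[iy + 1]) / 2.0 - cy
        zc = (zs[iz] + zs[iz + 1]) / 2.0
        z_lo, z_hi = spec.implant_box
        inside = (
            (xc**2 + yc**2 <= spec.implant.radius**2)
            & (zc > z_lo)
            & (zc < z_hi)
            & (hex_region == spec.implant_layer)
        )
        hex_region = hex_region.copy()
        hex_region[inside] = IMPLANT_REGION
    region = np.repeat(hex_region, TETS_PER_HEX)

    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    if np.any(flip):
        tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()

    mesh = Mesh(nodes=nodes, tets=tets, region=region)
    mesh.node_sets = extract_node_sets(mesh)
    return mesh


def extract_node_sets(mesh: Mesh) -> dict[str, np.ndarray]:
    """Recover named boundary/interface node sets from geometry alone.

    bottom_fixed: all nodes at the minimal z coordinate.
    interface: nodes shared by implant-labelled and tissue-labelled elements.
    implant_interior: implant-element nodes not on the interface.
    All sets are ascending index arrays.
    """

    z = mesh.nodes[:, 2]
    tol = 1e-9 * max(1.0, float(np.abs(z).max()))
    bottom = np.flatnonzero(z <= z.min() + tol)

    is_implant = mesh.region == IMPLANT_REGION
    implant_nodes = np.unique(mesh.tets[is_implant])
    tissue_nodes = np.unique(mesh.tets[~is_implant])
    interface = np.intersect1d(implant_nodes, tissue_nodes)
    interior = np.setdiff1d(implant_nodes, tissue_nodes)

    return {
        "bottom_fixed": np.sort(bottom),
        "interface": interface,
        "implant_interior": interior,
    }
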