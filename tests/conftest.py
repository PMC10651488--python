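import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from fbrmech.geometry import DomainSpec, ImplantSpec, Layer, MaterialSpec, Mesh
from fbrmech.loads import LoadSpec


@pytest.fixture
def soft_tissue():
    return MaterialSpec("tissue", 1.0e5, 0.25, 1000.0)


@pytest.fixture
def block_spec(soft_tissue):
    """Homogeneous 10 mm cube, no implant: the patch-test workhorse."""
    return DomainSpec(
        layers=[Layer("tissue", 10.0, soft_tissue)],
        lateral_extent=10.0,
        load=LoadSpec("static_force", 0.0),
    )


@pytest.fixture
def implant_spec():
    """Small layered domain with a stiff disc implant, coarse-meshable."""
    fat = MaterialSpec("fat", 3e3, 0.45, 920.0)
    muscle = MaterialSpec("muscle", 5e4, 0.45, 1060.0)
    skin = MaterialSpec("skin", 1e5, 0.45, 1100.0)
    pdms = MaterialSpec("pdms", 2e6, 0.48, 970.0)
    return DomainSpec(
        layers=[
            Layer("muscle", 3.0, muscle),
            Layer("pocket", 6.0, fat),
            Layer("skin", 3.0, skin),
        ],
        lateral_extent=16.0,
        implant=ImplantSpec(radius=4.0, height=3.0, material=pdms),
        implant_layer="pocket",
        load=LoadSpec("static_force", 0.02),
        name="toy_implant",
    )


def two_hex_mesh() -> Mesh:
    """Two unit cubes side by side along x; left cube labelled implant."""
    from fbrmech.geometry import _KUHN, extract_node_sets

    nodes = []
    for ix in range(3):
        for iy in range(2):
            for iz in range(2):
                nodes.append((float(ix), float(iy), float(iz)))
    nodes = np.asarray(nodes)

    def nid(ix, iy, iz):
        return (ix * 2 + iy) * 2 + iz

    tets = []
    for hx in range(2):
        corners = [nid(hx + (c & 1), (c >> 1) & 1, (c >> 2) & 1) for c in range(8)]
        corners = np.asarray(corners)
        tets.extend(corners[_KUHN])
    tets = np.asarray(tets)
    region = np.asarray(["implant"] * 6 + ["tissue"] * 6, dtype=object)
    from fbrmech.geometry import tet_volumes

    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()
    mesh = Mesh(nodes=nodes, tets=tets, region=region)
    mesh.node_sets = extract_node_sets(mesh)
    return mesh


def toy_umi(counts_dense, mito_gene_ids=(), conditions=None):
    """UMIMatrix from a dense cells x genes array with generated ids."""
    from fbrmech.sc import UMIMatrix

    counts_dense = np.asarray(counts_dense)
    n_cells, n_genes = counts_dense.shape
    cells = pd.Index([f"c{i}" for i in range(n_cells)])
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    genes = pd.Index(
        [mito_gene_ids[i - (n_genes - len(mito_gene_ids))]
         if i >= n_genes - len(mito_gene_ids) else f"g{i}"
         for i in range(n_genes)]
    ) if mito_gene_ids else genes
    if conditions is None:
        conditions = ["SM"] * n_cells
    meta = pd.DataFrame({"condition": conditions}, index=cells)
    return UMIMatrix(
        counts=sp.csr_matrix(counts_dense),
        cell_ids=cells,
        gene_ids=genes,
        cell_metadata=meta,
        mito_gene_ids=list(mito_gene_ids),
    )
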