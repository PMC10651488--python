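"""Readers and writers for the pipeline's text formats.

Panel counts travel as CSV (genes x samples) with a sample-sheet CSV; UMI
matrices as a Matrix Market file plus barcodes/features TSV sidecars
(10x-style trio); DE tables and stress summaries as CSV; signatures as
plain-text gene lists; meshes and field solutions as legacy ASCII VTK.
Writers emit a provenance header (seed and parameters) as ``#`` comment
lines; integer data round-trips bit-identically.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from fbrmech.fem import FieldSolution, StressSummary
from fbrmech.geometry import DomainSpec, Mesh
from fbrmech.panel_de import CountMatrix, DEResult, Signature
from fbrmech.sc import UMIMatrix

__all__ = [
    "write_panel_counts",
    "read_panel_counts",
    "write_umi_matrix",
    "read_umi_matrix",
    "write_de_table",
    "read_de_table",
    "write_signature",
    "read_signature",
    "write_stress_summary",
    "write_vtk",
    "read_domain_config",
    "provenance_header",
]


def provenance_header(**params) -> str:
    items = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# provenance: {items}" if items else "# provenance:"


# ---------------------------------------------------------------------------
# panel counts
# ---------------------------------------------------------------------------


def write_panel_counts(cm: CountMatrix, counts_path, sample_sheet_path, **provenance):
    counts_path, sheet_path = Path(counts_path), Path(sample_sheet_path)
    with open(counts_path, "w") as fh:
        fh.write(provenance_header(**provenance) + "\n")
        cm.counts.to_csv(fh, index_label="gene")
    sheet = pd.DataFrame({"sample_id": cm.sample_ids, "group": cm.group.values})
    with open(sheet_path, "w") as fh:
        fh.write(provenance_header(**provenance) + "\n")
        sheet.to_csv(fh, index=False)


def read_panel_counts(counts_path, sample_sheet_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, comment="#", index_col="gene")
    sheet = pd.read_csv(sample_sheet_path, comment="#")
    group = pd.Series(sheet["group"].values, index=sheet["sample_id"].values)
    return CountMatrix(counts=counts.astype(np.int64), group=group)


# ---------------------------------------------------------------------------
# UMI matrices (MTX + barcodes/features TSV trio)
# ---------------------------------------------------------------------------


def write_umi_matrix(umi: UMIMatrix, directory, **provenance):
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(
        d / "matrix.mtx",
        sp.coo_matrix(umi.counts.T),  # genes x cells, 10x orientation
        comment=provenance_header(**provenance).lstrip("# "),
        field="integer",
    )
    feats = pd.DataFrame(
        {
            "gene_id": umi.gene_ids,
            "mito": np.where(umi.gene_ids.isin(umi.mito_gene_ids), "mito", "nuclear"),
        }
    )
    feats.to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(umi.cell_ids).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    umi.cell_metadata.to_csv(d / "metadata.csv", index_label="cell_id")


def read_umi_matrix(directory) -> UMIMatrix:
    d = Path(directory)
    mat = sio.mmread(d / "matrix.mtx").T.tocsr().astype(np.int64)
    feats = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    gene_ids = pd.Index(feats[0])
    mito = gene_ids[feats[1].values == "mito"].tolist() if feats.shape[1] > 1 else []
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0]
    meta = pd.read_csv(d / "metadata.csv", index_col="cell_id")
    return UMIMatrix(
        counts=mat,
        cell_ids=pd.Index(barcodes),
        gene_ids=gene_ids,
        cell_metadata=meta,
        mito_gene_ids=mito,
    )


# ---------------------------------------------------------------------------
# DE tables and signatures
# ---------------------------------------------------------------------------


def write_de_table(de: DEResult, path, **provenance):
    with open(path, "w") as fh:
        fh.write(provenance_header(group1=de.group1, group2=de.group2, **provenance) + "\n")
        de.table.to_csv(fh, index_label="gene")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col="gene")


def write_signature(sig: Signature, path, **provenance):
    with open(path, "w") as fh:
        fh.write(provenance_header(direction=sig.direction, k=sig.k, **provenance) + "\n")
        for g in sig.gene_ids:
            fh.write(f"{g}\n")


def read_signature(path) -> Signature:
    direction, k, genes = "up_in_group2", 0, []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for tok in line.split():
                if tok.startswith("direction="):
                    direction = tok.split("=", 1)[1]
                elif tok.startswith("k="):
                    k = int(tok.split("=", 1)[1])
        elif line.strip():
            genes.append(line.strip())
    return Signature(gene_ids=genes, direction=direction, k=k or len(genes))


# ---------------------------------------------------------------------------
# stress summaries and VTK fields
# ---------------------------------------------------------------------------


def write_stress_summary(summary: StressSummary, path, model: str = "", **provenance):
    df = pd.DataFrame(
        [
            {
                "model": model,
                "max_abs_sx_kpa": summary.max_abs_sx,
                "max_tensile_sx_kpa": summary.max_tensile_sx,
                "max_compressive_sx_kpa": summary.max_compressive_sx,
            }
        ]
    )
    with open(path, "w") as fh:
        fh.write(provenance_header(**provenance) + "\n")
        df.to_csv(fh, index=False)


def write_vtk(mesh: Mesh, path, solution: Optional[FieldSolution] = None,
              title: str = "fbrmech field output"):
    """Legacy ASCII VTK unstructured grid with region labels, node sets,
    and (when a solution is given) displacement and stress fields."""
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID"]
    n, m = mesh.n_nodes, mesh.n_elements
    lines.append(f"POINTS {n} double")
    lines.extend(" ".join(f"{v:.9g}" for v in row) for row in mesh.nodes)
    lines.append(f"CELLS {m} {5 * m}")
    lines.extend("4 " + " ".join(map(str, tet)) for tet in mesh.tets)
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["10"] * m)

    region_names = sorted(set(mesh.region))
    region_id = {name: i for i, name in enumerate(region_names)}
    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(region_id[r]) for r in mesh.region)
    if solution is not None:
        sx = solution.element_stress[:, 0, 0]
        lines.append("SCALARS sx_pa double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" for v in sx)

    lines.append(f"POINT_DATA {n}")
    iface = np.zeros(n, dtype=int)
    iface[mesh.node_sets.get("interface", np.empty(0, int))] = 1
    lines.append("SCALARS interface int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(map(str, iface))
    if solution is not None:
        lines.append("VECTORS displacement_m double")
        lines.extend(
            " ".join(f"{v:.9g}" for v in row) for row in solution.displacements
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_domain_config(path) -> DomainSpec:
    from fbrmech.synthetic import domain_from_config

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return domain_from_config(cfg)
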