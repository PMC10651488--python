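"""Single-cell workflow: QC, normalisation, embedding, markers, signatures.

Cells passing QC (>= 200 detected genes, mitochondrial fraction < 10%) are
depth-normalised to 10,000 counts, natural-log transformed with pseudocount
1, the mitochondrial fraction is regressed out gene-wise, the standardised
residuals are embedded with 15 principal components, and cells are
clustered with seeded k-means (a fully specified stand-in for graph
clustering).  Cluster markers use a one-vs-rest ROC (Mann-Whitney AUC) test
gated at \\|log fold change\\| >= 0.25, and cross-species gene signatures are
scored as the per-cell mean of normalised expression over the mapped genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans

from fbrmech.panel_de import Signature

__all__ = [
    "UMIMatrix",
    "NormalizedMatrix",
    "MarkerResult",
    "qc_filter",
    "lognormalize",
    "regress_out_mito",
    "pca_embed",
    "cluster_cells",
    "find_markers",
    "signature_score",
    "composition_table",
    "auc_scores",
]

SCALE_FACTOR = 10_000.0
MIN_GENES = 200
MAX_MITO_FRACTION = 0.10


@dataclass
class UMIMatrix:
    """Sparse cells x genes nonnegative integer UMI counts with metadata."""

    counts: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    cell_metadata: pd.DataFrame
    mito_gene_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("UMI counts must be nonnegative")
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("counts shape must be (n_cells, n_genes)")
        if not self.cell_ids.isin(self.cell_metadata.index).all():
            raise ValueError("cell_metadata must cover every cell")
        self.cell_metadata = self.cell_metadata.loc[self.cell_ids]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        return np.diff(self.counts.indptr)

    def mito_fractions(self) -> np.ndarray:
        lib = self.library_sizes()
        mask = self.gene_ids.isin(self.mito_gene_ids)
        mito = np.asarray(self.counts[:, mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, mito / np.maximum(lib, 1), 0.0)
        return frac


@dataclass
class NormalizedMatrix:
    """cells x genes ln(1 + 1e4 * count / library) values with QC metadata."""

    values: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    library_size: np.ndarray
    mito_fraction: np.ndarray
    cell_metadata: pd.DataFrame

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class MarkerResult:
    """Per (cluster, gene) one-vs-rest markers passing the logFC gate."""

    table: pd.DataFrame  # columns: cluster, gene, auc, log_fold_change, pct_in, pct_out


def qc_filter(umi: UMIMatrix, min_genes: int = MIN_GENES,
              max_mito: float = MAX_MITO_FRACTION) -> UMIMatrix:
    """Keep cells with >= ``min_genes`` detected genes (inclusive) and a
    mitochondrial fraction strictly below ``max_mito``; genes unchanged."""
    detected = umi.genes_detected()
    mito = umi.mito_fractions()
    keep = (detected >= min_genes) & (mito < max_mito)
    if not keep.any():
        raise ValueError(
            f"no cells pass QC (>= {min_genes} genes, mito < {max_mito:.0%})"
        )
    report = {
        "n_input": umi.n_cells,
        "n_kept": int(keep.sum()),
        "n_low_genes": int((detected < min_genes).sum()),
        "n_high_mito": int((mito >= max_mito).sum()),
    }
    out = UMIMatrix(
        counts=umi.counts[keep],
        cell_ids=umi.cell_ids[keep],
        gene_ids=umi.gene_ids,
        cell_metadata=umi.cell_metadata.loc[umi.cell_ids[keep]],
        mito_gene_ids=list(umi.mito_gene_ids),
    )
    out.qc_report = report
    return out


def lognormalize(umi: UMIMatrix, scale_factor: float = SCALE_FACTOR) -> NormalizedMatrix:
    """Depth-normalise to ``scale_factor`` counts per cell and ln(1 + x).

    Zeros stay zero, so sparsity is preserved; each cell's vector is
    invariant to rescaling all of its counts.
    """
    lib = umi.library_sizes()
    if np.any(lib <= 0):
        raise ValueError("cells with zero library size cannot be normalised")
    x = umi.counts.tocsr().astype(float)
    inv = scale_factor / lib
    x = sp.diags(inv) @ x
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        values=x.tocsr(),
        cell_ids=umi.cell_ids,
        gene_ids=umi.gene_ids,
        library_size=lib,
        mito_fraction=umi.mito_fractions(),
        cell_metadata=umi.cell_metadata,
    )


def regress_out_mito(nm: NormalizedMatrix) -> np.ndarray:
    """Residuals of gene-wise OLS of expression on mitochondrial fraction,
    standardised per gene (zero mean, unit variance; flat genes -> 0)."""
    X = nm.dense()
    n = X.shape[0]
    if n < 2:
        raise ValueError("regression needs at least two cells")
    mf = np.asarray(nm.mito_fraction, dtype=float)
    mc = mf - mf.mean()
    denom = float(mc @ mc)
    Xc = X - X.mean(axis=0, keepdims=True)
    if denom > 0:
        beta = (mc @ Xc) / denom
        resid = Xc - np.outer(mc, beta)
    else:  # constant regressor: residual = centred expression
        resid = Xc
    sd = resid.std(axis=0, ddof=0)
    # flat genes (incl. exactly-fitted ones) carry only roundoff: zero them
    tol = np.sqrt(np.finfo(float).eps) * max(1.0, float(np.abs(X).max()))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > tol, resid / np.where(sd > tol, sd, 1.0), 0.0)
    return out


def pca_embed(matrix: np.ndarray, n_components: int = 15) -> np.ndarray:
    """Scores of the leading principal components of a cells x genes matrix.

    Uses an exact SVD of the column-centred matrix.  Component signs follow
    the convention that each component's largest-magnitude gene loading is
    positive, making the embedding reproducible up to cell order.
    """
    X = np.asarray(matrix, dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int((S > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"matrix rank {rank} < requested {n_components}; returning {k} components"
        )
    flip = np.sign(Vt[:k][np.arange(k), np.argmax(np.abs(Vt[:k]), axis=1)])
    flip[flip == 0] = 1.0
    return (U[:, :k] * S[:k]) * flip


def cluster_cells(embedding: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded k-means on the PC embedding; deterministic for fixed inputs."""
    emb = np.asarray(embedding, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > emb.shape[0]:
        raise ValueError("k exceeds the number of cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(emb)


def auc_scores(values: np.ndarray, in_group: np.ndarray) -> float:
    """AUC of ``values`` as a classifier of ``in_group`` membership.

    Mann-Whitney U through midranks: AUC = (R_in - n_in(n_in+1)/2) /
    (n_in * n_out); ties contribute 1/2, matching pairwise enumeration.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(in_group, dtype=bool)
    n1 = int(g.sum())
    n0 = v.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(v)
    u = ranks[g].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def find_markers(
    nm: NormalizedMatrix,
    clusters: np.ndarray,
    lfc_threshold: float = 0.25,
    min_cells: int = 3,
) -> MarkerResult:
    """One-vs-rest ROC marker detection per cluster.

    The fold change is the natural-log ratio of mean expm1(normalised)
    expression in vs out of the cluster (pseudocount 1 on both means);
    genes with \\|lfc\\| >= threshold are scored by AUC and ranked by it.
    """
    clusters = np.asarray(clusters)
    labels = np.unique(clusters)
    if labels.size < 2:
        raise ValueError("need at least two clusters for marker detection")
    X = nm.dense()
    expm = np.expm1(X)
    rows = []
    for lab in labels:
        g = clusters == lab
        if g.sum() < min_cells:
            warnings.warn(f"cluster {lab!r} has < {min_cells} cells; skipped")
            continue
        mean_in = expm[g].mean(axis=0)
        mean_out = expm[~g].mean(axis=0)
        lfc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        pct_in = (X[g] > 0).mean(axis=0)
        pct_out = (X[~g] > 0).mean(axis=0)
        for j in np.flatnonzero(np.abs(lfc) >= lfc_threshold):
            rows.append(
                {
                    "cluster": lab,
                    "gene": nm.gene_ids[j],
                    "auc": auc_scores(X[:, j], g),
                    "log_fold_change": float(lfc[j]),
                    "pct_in": float(pct_in[j]),
                    "pct_out": float(pct_out[j]),
                }
            )
    table = pd.DataFrame(rows, columns=["cluster", "gene", "auc",
                                        "log_fold_change", "pct_in", "pct_out"])
    if not table.empty:
        table = table.sort_values(
            ["cluster", "auc"], ascending=[True, False], kind="mergesort"
        ).reset_index(drop=True)
    return MarkerResult(table=table)


def signature_score(
    nm: NormalizedMatrix,
    sig: Signature,
    ortholog_map: Optional[Mapping[str, str]] = None,
) -> np.ndarray:
    """Per-cell mean normalised expression over the mapped signature genes.

    ``ortholog_map`` translates signature gene ids to this dataset's ids;
    by default symbols are matched case-insensitively (human ALL-CAPS vs
    mouse Capitalised symbols).  Missing genes are dropped with a warning;
    an empty mapped set is an error listing the unmapped ids.
    """
    if len(sig) == 0:
        raise ValueError("signature is empty")
    lower_index = {g.lower(): i for i, g in enumerate(map(str, nm.gene_ids))}
    cols, unmapped = [], []
    for g in sig.gene_ids:
        target = ortholog_map.get(g, g) if ortholog_map else g
        idx = lower_index.get(str(target).lower())
        if idx is None:
            unmapped.append(g)
        else:
            cols.append(idx)
    if not cols:
        raise ValueError(f"no signature genes mapped; unmapped: {unmapped}")
    if unmapped:
        warnings.warn(f"{len(unmapped)} signature genes unmapped: {unmapped}")
    sub = nm.values[:, cols]
    return np.asarray(sub.mean(axis=1)).ravel()


def composition_table(
    clusters: np.ndarray, cell_metadata: pd.DataFrame, by: str = "condition"
) -> pd.DataFrame:
    """Fractions of each cluster within each metadata level (rows sum to 1)."""
    if by not in cell_metadata.columns:
        raise ValueError(f"metadata has no column {by!r}")
    df = pd.DataFrame({by: cell_metadata[by].values, "cluster": np.asarray(clusters)})
    counts = df.groupby([by, "cluster"], observed=True).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
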