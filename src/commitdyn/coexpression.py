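"""Co-expression fractions, thresholded networks and correlation matrices.

Heterogeneous expression of lineage regulators in single cells is summarised
by the fraction of cells co-expressing gene pairs: a gene counts as
expressed at a normalized value strictly above 1, and two genes are
connected in the co-expression network when their co-expression fraction
strictly exceeds 0.8.  Pearson correlation matrices over the same regulator
set (per time point) reveal which late regulators covary with early
regulators of the same lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CoexpressionMatrix",
    "CoexpressionNetwork",
    "coexpression_fraction",
    "build_network",
    "pearson_matrix",
]


@dataclass
class CoexpressionMatrix:
    fractions: pd.DataFrame  # gene x gene, diagonal = expressed fraction
    expr_threshold: float
    n_cells: int


@dataclass
class CoexpressionNetwork:
    edges: pd.DataFrame  # columns gene_a, gene_b, fraction
    degrees: pd.Series  # per node
    edge_threshold: float
    annotations: dict = field(default_factory=dict)


def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X, float)


def _subset(adata: AnnData, gene_set, cells, time_point):
    genes = list(gene_set) if gene_set is not None else list(adata.var_names)
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    sub = adata
    if time_point is not None:
        sub = sub[sub.obs["time_h"] == time_point]
    if cells is not None:
        sub = sub[cells]
    if sub.n_obs == 0:
        raise ValueError("empty cell set")
    return sub[:, genes], genes


def coexpression_fraction(
    adata: AnnData,
    gene_set=None,
    expr_threshold: float = 1.0,
    cells=None,
    time_point=None,
) -> CoexpressionMatrix:
    """Fraction of cells expressing both genes of each pair (value > threshold).

    The diagonal holds each gene's expressed fraction, so every off-diagonal
    entry is bounded by the smaller of the two diagonal entries.
    """
    sub, genes = _subset(adata, gene_set, cells, time_point)
    B = (_dense(sub) > expr_threshold).astype(float)
    frac = (B.T @ B) / B.shape[0]
    return CoexpressionMatrix(
        fractions=pd.DataFrame(frac, index=genes, columns=genes),
        expr_threshold=expr_threshold,
        n_cells=sub.n_obs,
    )


def build_network(
    cm: CoexpressionMatrix,
    edge_threshold: float = 0.8,
    annotations: dict | None = None,
) -> CoexpressionNetwork:
    """Edges between gene pairs whose co-expression strictly exceeds the threshold.

    Isolated nodes are retained (degree 0); there are no self-edges.
    """
    genes = list(cm.fractions.index)
    rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            f = cm.fractions.loc[a, b]
            if f > edge_threshold:
                rows.append((a, b, float(f)))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "fraction"])
    deg = pd.Series(0, index=genes, dtype=int)
    for _, r in edges.iterrows():
        deg[r["gene_a"]] += 1
        deg[r["gene_b"]] += 1
    return CoexpressionNetwork(
        edges=edges,
        degrees=deg,
        edge_threshold=edge_threshold,
        annotations=dict(annotations or {}),
    )


def pearson_matrix(
    adata: AnnData, gene_set=None, cells=None, time_point=None
) -> pd.DataFrame:
    """Gene-by-gene Pearson correlations over the selected cells.

    Zero-variance genes yield undefined correlations; their entries are
    masked as NaN (the diagonal of a varying gene is exactly 1).
    """
    sub, genes = _subset(adata, gene_set, cells, time_point)
    X = _dense(sub)
    var = X.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    bad = var == 0
    R[bad, :] = np.nan
    R[:, bad] = np.nan
    return pd.DataFrame(R, index=genes, columns=genes)
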