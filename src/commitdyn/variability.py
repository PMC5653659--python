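"""Fano-factor quantification of gene-expression variability.

On counts downsampled to a common depth, the Fano factor (variance over
mean) of a gene is 1 under pure Poisson counting noise; excess variability
reflects biological heterogeneity.  The population statistic is the Fano
factor of individual genes averaged over the significantly variable gene
set.  To ask whether variability is explained by discrete subpopulations,
cells are first split by correlation-distance k-means; the Fano factor is
computed separately within each cluster, averaged over clusters, and the
whole procedure is repeated and averaged over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .clustering import kmeans_correlation

__all__ = ["FanoReport", "fano_per_gene", "within_cluster_fano"]


@dataclass
class FanoReport:
    per_gene: pd.Series  # Fano per gene (NaN where mean is 0)
    summary: float  # unweighted mean over the evaluated gene set
    n_cells: int
    excluded: list  # genes excluded for zero mean
    per_cluster: pd.DataFrame | None = None  # k x repeat cluster-mean values
    n_repeats: int | None = None


def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X, float)


def _fano(X: np.ndarray, ddof: int) -> np.ndarray:
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)


def fano_per_gene(
    adata: AnnData, gene_set=None, ddof: int = 0
) -> FanoReport:
    """Per-gene variance/mean over cells, summarised over ``gene_set``.

    Uses the population (1/N) variance by default (``ddof=0``).  Genes with
    zero mean are excluded from the summary and reported.
    """
    if gene_set is None:
        gene_set = list(adata.var_names)
    else:
        gene_set = [g for g in gene_set if g in adata.var_names]
    X = _dense(adata[:, gene_set])
    f = _fano(X, ddof)
    per_gene = pd.Series(f, index=gene_set)
    excluded = list(per_gene.index[per_gene.isna()])
    return FanoReport(
        per_gene=per_gene,
        summary=float(per_gene.dropna().mean()),
        n_cells=adata.n_obs,
        excluded=excluded,
    )


def within_cluster_fano(
    adata: AnnData,
    gene_set=None,
    k: int = 2,
    n_repeats: int = 20,
    seed: int = 0,
    ddof: int = 0,
    cluster_genes=None,
) -> FanoReport:
    """Fano factor within k-means subpopulations, averaged over clusters and repeats.

    Each repeat clusters the cells (correlation-distance k-means on
    ``cluster_genes``, default the evaluated gene set), computes the summary
    Fano factor separately per cluster, and averages over clusters with
    equal weight; the reported value is the mean over repeats.
    """
    if k >= adata.n_obs:
        raise ValueError("k must be smaller than the number of cells")
    if gene_set is None:
        gene_set = list(adata.var_names)
    if cluster_genes is None:
        cluster_genes = gene_set
    X_cluster = _dense(adata[:, [g for g in cluster_genes if g in adata.var_names]])
    X_eval = _dense(adata[:, [g for g in gene_set if g in adata.var_names]])
    rng = np.random.default_rng(seed)
    per_cluster = np.full((n_repeats, k), np.nan)
    for r in range(n_repeats):
        asg = kmeans_correlation(
            X_cluster, k, n_restarts=3, seed=int(rng.integers(2**31))
        )
        for c in range(k):
            members = asg.labels == c + 1
            if members.sum() < 2:
                raise ValueError(f"cluster {c + 1} has fewer than 2 cells")
            f = _fano(X_eval[members], ddof)
            per_cluster[r, c] = np.nanmean(f)
    cluster_means = per_cluster.mean(axis=1)  # unweighted over clusters
    return FanoReport(
        per_gene=pd.Series(dtype=float),
        summary=float(cluster_means.mean()),
        n_cells=adata.n_obs,
        excluded=[],
        per_cluster=pd.DataFrame(
            per_cluster,
            index=[f"repeat_{r}" for r in range(n_repeats)],
            columns=[f"cluster_{c + 1}" for c in range(k)],
        ),
        n_repeats=n_repeats,
    )
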