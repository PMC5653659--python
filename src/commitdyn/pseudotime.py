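"""Correlation-based cell classification and pseudotime ordering.

Cells at every time point are classified by their Pearson correlation with
three anchor profiles: the mean expression of pluripotent cells at the first
time point and of the two robust subpopulations (ectoderm-like and XEN-like)
at the final time point.  A cell's label is the argmax of the three
correlations.  Differentiation progress is summarised by the pseudotime

    τ = R_pluri − 0.5 · (R_ect + R_xen),

which is large for pluripotent-like cells and decreases with commitment.
Each lineage branch (pluripotent ∪ that lineage's cells) is ordered by
decreasing τ and averaged over consecutive 50-cell bins to obtain gene-wise
z-score profiles and marker-panel trajectories along the branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CellClassification",
    "BranchProfile",
    "compute_centroids",
    "classify_by_correlation",
    "pseudotime_order",
    "class_frequencies",
    "bin_profiles",
]

CLASS_NAMES = ("mESC-like", "ectoderm-like", "XEN-like")
_R_COLS = ("R_pluri", "R_ect", "R_xen")


@dataclass
class CellClassification:
    table: pd.DataFrame  # per cell: R_pluri, R_ect, R_xen, label, tie
    genes: list  # gene set the correlations were computed on


@dataclass
class BranchProfile:
    z: pd.DataFrame  # gene x bin z-scores
    panel_means: pd.DataFrame  # panel x bin mean z over panel genes
    bin_size: int
    branch: str
    cells_per_bin: list


def _matrix(adata: AnnData, genes) -> np.ndarray:
    sub = adata[:, list(genes)]
    X = sub.X
    return X.toarray() if sp.issparse(X) else np.asarray(X, float)


def compute_centroids(
    adata: AnnData, anchors: dict, genes=None
) -> pd.DataFrame:
    """Mean expression profiles of the anchor populations.

    ``anchors`` maps the class names ('mESC-like', 'ectoderm-like',
    'XEN-like') to cell-id lists or boolean masks.  Profiles are restricted
    to ``genes`` (typically the variable-gene selection).
    """
    if set(anchors) != set(CLASS_NAMES):
        raise ValueError(f"anchors must be keyed by {CLASS_NAMES}")
    if genes is None:
        genes = list(adata.var_names)
    rows = {}
    for name, cells in anchors.items():
        if isinstance(cells, np.ndarray) and cells.dtype == bool:
            sub = adata[cells]
        else:
            sub = adata[list(cells)]
        if sub.n_obs == 0:
            raise ValueError(f"empty anchor set for {name}")
        rows[name] = _matrix(sub, genes).mean(axis=0)
    return pd.DataFrame(rows, index=list(genes)).T


def classify_by_correlation(
    adata: AnnData, centroids: pd.DataFrame
) -> CellClassification:
    """Per-cell Pearson correlations with the three centroids and argmax label.

    Exact ties in the argmax are broken toward the mESC-like class
    (conservative: avoids premature lineage calls) and flagged.
    """
    genes = list(centroids.columns)
    X = _matrix(adata, genes)
    if np.any(X.var(axis=1) == 0):
        raise ValueError("cell with zero-variance profile cannot be correlated")
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc /= np.linalg.norm(Xc, axis=1, keepdims=True)
    C = centroids.loc[list(CLASS_NAMES)].to_numpy()
    Cc = C - C.mean(axis=1, keepdims=True)
    Cc /= np.linalg.norm(Cc, axis=1, keepdims=True)
    R = Xc @ Cc.T  # cells x 3, order mESC, ect, xen

    best = R.argmax(axis=1)
    sorted_R = np.sort(R, axis=1)
    tie = np.isclose(sorted_R[:, -1], sorted_R[:, -2])
    # ties resolved toward the pluripotent class
    tie_max = np.isclose(R, R.max(axis=1, keepdims=True))
    best = np.where(tie, tie_max.argmax(axis=1), best)
    table = pd.DataFrame(R, columns=list(_R_COLS), index=adata.obs_names)
    table["label"] = np.array(CLASS_NAMES)[best]
    table["tie"] = tie
    if "time_h" in adata.obs:
        table["time_h"] = adata.obs["time_h"].to_numpy()
    return CellClassification(table=table, genes=genes)


def pseudotime_order(cls: CellClassification) -> pd.DataFrame:
    """Pseudotime τ = R_pluri − 0.5 (R_ect + R_xen) and branch membership.

    The ectoderm branch contains the mESC-like and ectoderm-like cells, the
    XEN branch the mESC-like and XEN-like cells; within each branch cells
    are ranked by decreasing τ (increasing differentiation).
    """
    t = cls.table.copy()
    t["tau"] = t["R_pluri"] - 0.5 * (t["R_ect"] + t["R_xen"])
    t["in_ect_branch"] = t["label"].isin(["mESC-like", "ectoderm-like"])
    t["in_xen_branch"] = t["label"].isin(["mESC-like", "XEN-like"])
    for branch, col in (("ect", "in_ect_branch"), ("xen", "in_xen_branch")):
        rank = t.loc[t[col], "tau"].rank(ascending=False, method="first")
        t.loc[t[col], f"rank_{branch}"] = rank
    return t


def class_frequencies(cls_or_table, by: str = "time_h") -> pd.DataFrame:
    """Class frequencies per group (time point or pseudotime bin); rows sum to 1."""
    t = cls_or_table.table if isinstance(cls_or_table, CellClassification) else cls_or_table
    freq = (
        t.groupby(by)["label"].value_counts(normalize=True).unstack(fill_value=0.0)
    )
    return freq.reindex(columns=list(CLASS_NAMES), fill_value=0.0)


def bin_profiles(
    adata: AnnData,
    pt: pd.DataFrame,
    branch: str = "ect",
    bin_size: int = 50,
    panels: dict | None = None,
    genes=None,
    drop_partial: bool = True,
) -> BranchProfile:
    """Average expression over consecutive pseudotime bins, as gene-wise z-scores.

    Cells of the branch are ordered by decreasing τ and averaged over
    non-overlapping windows of ``bin_size`` cells; each gene's binned
    profile is then z-scored across bins.  Panel trajectories are the mean
    z over the genes of each panel.  A trailing partial bin is dropped by
    default.
    """
    col = f"in_{branch}_branch"
    if col not in pt:
        raise ValueError(f"unknown branch {branch!r}")
    cells = pt.loc[pt[col]].sort_values("tau", ascending=False).index
    if len(cells) < bin_size:
        raise ValueError("branch smaller than one bin")
    if genes is None:
        genes = list(adata.var_names)
    X = _matrix(adata[list(cells)], genes)
    n_bins = len(cells) // bin_size
    rem = len(cells) - n_bins * bin_size
    edges = [(i * bin_size, (i + 1) * bin_size) for i in range(n_bins)]
    if rem and not drop_partial:
        edges.append((n_bins * bin_size, len(cells)))
    binned = np.vstack([X[a:b].mean(axis=0) for a, b in edges]).T  # genes x bins
    mu = binned.mean(axis=1, keepdims=True)
    sd = binned.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (binned - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=list(genes), columns=[f"bin_{i}" for i in range(len(edges))])
    panel_rows = {}
    if panels:
        for name, pgenes in panels.items():
            present = [g for g in pgenes if g in zdf.index]
            if present:
                panel_rows[name] = zdf.loc[present].mean(axis=0)
    panel_means = pd.DataFrame(panel_rows).T if panel_rows else pd.DataFrame()
    return BranchProfile(
        z=zdf,
        panel_means=panel_means,
        bin_size=bin_size,
        branch=branch,
        cells_per_bin=[b - a for a, b in edges],
    )
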