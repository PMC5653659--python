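"""QC, normalization and gene selection for shallow UMI count data.

The processing chain mirrors the bespoke treatment of plate-based UMI data in
asynchronous differentiation experiments:

1. discard cells with fewer than 2,000 (non-spike-in) UMIs — a cutoff that
   nearly minimises the per-gene counting-error bound ε = 1/√⟨UMI⟩·1/√#cells
   without losing detected genes;
2. normalize by dividing each cell by its total and multiplying by the median
   total of a reference population (cells grown in 2i/L);
3. for variance statistics, instead downsample every cell to exactly 2,000
   UMIs so the counting-error contribution is equal across cells;
4. select "significantly variable" genes as the top 5 % by the ratio of the
   CV to a moving average of the CV along the mean-expression ordering;
5. standardize selected genes to z-scores using the gene mean and the
   moving-average CV (z = (x − m)/(m·movingCV)), which preserves biological
   variability relative to the technical-noise trend;
6. calibrate transcript-recovery efficiency from spike-ins via a log-log
   linear fit of observed mean UMIs against input molecules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CountingErrorEstimate",
    "FilterReport",
    "GeneSelection",
    "SpikeCalibration",
    "filter_cells_by_umi",
    "counting_error",
    "normalize_by_reference_median",
    "downsample_umi",
    "select_variable_genes",
    "standardize_cv",
    "calibrate_spikeins",
]


def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _gene_mask(adata: AnnData) -> np.ndarray:
    """Boolean mask of biological (non-spike-in) genes."""
    if "is_spikein" in adata.var:
        return ~adata.var["is_spikein"].to_numpy(bool)
    return np.ones(adata.n_vars, bool)


def cell_totals(adata: AnnData, include_spikeins: bool = False) -> np.ndarray:
    """Per-cell UMI totals; spike-in counts excluded by default."""
    X = adata.X
    mask = (
        np.ones(adata.n_vars, bool) if include_spikeins else _gene_mask(adata)
    )
    if sp.issparse(X):
        return np.asarray(X[:, mask].sum(axis=1)).ravel()
    return np.asarray(X)[:, mask].sum(axis=1)


@dataclass
class CountingErrorEstimate:
    epsilon: float
    mean_umi: float
    n_cells: int


@dataclass
class FilterReport:
    n_retained: int
    n_discarded: int
    n_detected_genes: int
    min_total: int


@dataclass
class GeneSelection:
    stats: pd.DataFrame  # mean, cv, moving_cv, ratio per eligible gene
    selected: list  # gene ids, ranked by ratio
    window_size: int
    top_frac: float
    spikein_stats: pd.DataFrame | None = None


@dataclass
class SpikeCalibration:
    slope: float
    intercept: float
    efficiency: float
    n_species: int


def counting_error(mean_umi: float, n_cells: int) -> CountingErrorEstimate:
    """Upper bound of the per-gene counting error, ε = 1/√⟨UMI⟩ · 1/√#cells."""
    if mean_umi <= 0 or n_cells <= 0:
        raise ValueError("mean_umi and n_cells must be positive")
    eps = 1.0 / math.sqrt(mean_umi) / math.sqrt(n_cells)
    return CountingErrorEstimate(epsilon=eps, mean_umi=mean_umi, n_cells=n_cells)


def filter_cells_by_umi(
    adata: AnnData, min_total: int = 2000
) -> tuple[AnnData, FilterReport]:
    """Keep cells whose non-spike-in UMI total reaches ``min_total``.

    Detected genes are counted on the retained cells as genes with more than
    one UMI in more than one cell.
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    if adata.n_obs == 0:
        raise ValueError("empty matrix")
    totals = cell_totals(adata)
    keep = totals >= min_total
    out = adata[keep].copy()
    Xg = _dense(out)[:, _gene_mask(out)]
    detected = int(((Xg > 1).sum(axis=0) > 1).sum())
    report = FilterReport(
        n_retained=int(keep.sum()),
        n_discarded=int((~keep).sum()),
        n_detected_genes=detected,
        min_total=min_total,
    )
    return out, report


def normalize_by_reference_median(
    adata: AnnData, reference_cells=None
) -> AnnData:
    """Scale each cell to the median (non-spike-in) total of the reference cells.

    value(c, g) = count(c, g) / total(c) × median(total over reference cells).
    The reference is typically the pluripotent (2i/L, 0 h) population; by
    default all cells are used.  Within-cell gene proportions are conserved.
    """
    totals = cell_totals(adata)
    if np.any(totals == 0):
        raise ValueError("cell with zero total cannot be normalized")
    if reference_cells is None:
        ref_mask = np.ones(adata.n_obs, bool)
    elif isinstance(reference_cells, np.ndarray) and reference_cells.dtype == bool:
        ref_mask = reference_cells
    else:
        idx = adata.obs_names.get_indexer_for(pd.Index(reference_cells))
        if (idx < 0).any():
            raise ValueError("unknown reference cell id")
        ref_mask = np.zeros(adata.n_obs, bool)
        ref_mask[idx] = True
    if not ref_mask.any():
        raise ValueError("reference cell set is empty")
    ref_median = float(np.median(totals[ref_mask]))
    scale = ref_median / totals
    X = _dense(adata).astype(float) * scale[:, None]
    out = AnnData(X=X, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns))
    out.uns["reference_scale"] = ref_median
    return out


def downsample_umi(
    adata: AnnData, target: int = 2000, seed: int = 0
) -> AnnData:
    """Downsample every cell to exactly ``target`` UMIs without replacement.

    Cells with fewer than ``target`` non-spike-in UMIs are excluded.  The
    per-cell subsample is multivariate hypergeometric over genes, i.e. a
    uniform draw of ``target`` of the cell's UMIs.  Spike-in genes are
    dropped from the output (the equal-depth matrix feeds variance
    statistics of biological genes only).
    """
    if target <= 0:
        raise ValueError("target must be positive")
    gmask = _gene_mask(adata)
    X = _dense(adata)[:, gmask].astype(np.int64)
    totals = X.sum(axis=1)
    keep = totals >= target
    X = X[keep]
    rng = np.random.default_rng(seed)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        if X[i].sum() == target:
            out[i] = X[i]
        else:
            out[i] = rng.multivariate_hypergeometric(X[i], target, method="marginals")
    res = AnnData(
        X=sp.csr_matrix(out),
        obs=adata.obs.loc[np.asarray(keep)].copy(),
        var=adata.var.loc[gmask].copy(),
        uns=dict(adata.uns),
    )
    res.uns["downsample_target"] = target
    return res


def _moving_average_shrunken(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with windows shrunken at the edges."""
    s = pd.Series(values)
    return s.rolling(window=window, center=True, min_periods=1).mean().to_numpy()


def _cv_table(values: np.ndarray, genes: pd.Index, window: int) -> pd.DataFrame:
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    eligible = mean > 0
    df = pd.DataFrame({"mean": mean, "cv": np.where(eligible, sd / np.where(mean > 0, mean, 1.0), np.nan)}, index=genes)
    df = df[eligible].sort_values("mean", kind="mergesort")
    df["moving_cv"] = _moving_average_shrunken(df["cv"].to_numpy(), window)
    df["ratio"] = df["cv"] / df["moving_cv"]
    return df


def select_variable_genes(
    adata: AnnData,
    window_size: int | None = None,
    top_frac: float = 0.05,
) -> GeneSelection:
    """Select the most variable genes by the CV / moving-average-CV ratio.

    Genes are ordered by mean normalized expression over all cells (all time
    points); the moving average of the CV along that ordering captures the
    technical-noise trend, and the top ``top_frac`` fraction of genes by the
    ratio CV/movingCV is selected.  Spike-ins are excluded from selection but
    their CV statistics are reported alongside for diagnostics.  Ties are
    broken by higher mean, then gene id.
    """
    gmask = _gene_mask(adata)
    X = _dense(adata)
    if not np.any(X[:, gmask] > 0):
        raise ValueError("all-zero matrix")
    if window_size is None:
        n_eligible = int((X[:, gmask].mean(axis=0) > 0).sum())
        window_size = max(25, int(round(0.01 * n_eligible)))
    stats = _cv_table(X[:, gmask], adata.var_names[gmask], window_size)
    n_sel = math.ceil(top_frac * len(stats))
    ranked = stats.sort_values(
        by=["ratio", "mean"], ascending=[False, False], kind="mergesort"
    )
    # deterministic tie-break on gene id for exactly equal (ratio, mean)
    ranked = ranked.iloc[
        np.lexsort(
            (ranked.index.to_numpy(), -ranked["mean"].to_numpy(), -ranked["ratio"].to_numpy())
        )
    ]
    selected = list(ranked.index[:n_sel])
    spike = None
    if (~gmask).any():
        spike = _cv_table(X[:, ~gmask], adata.var_names[~gmask], window_size)
    return GeneSelection(
        stats=stats, selected=selected, window_size=window_size,
        top_frac=top_frac, spikein_stats=spike,
    )


def standardize_cv(adata: AnnData, sel: GeneSelection) -> AnnData:
    """z-scores preserving biological variability: z = (x − m)/(m · movingCV)."""
    genes = [g for g in sel.selected if g in adata.var_names]
    if len(genes) < len(sel.selected):
        missing = set(sel.selected) - set(genes)
        raise ValueError(f"selected genes missing from matrix: {sorted(missing)[:5]}")
    sub = adata[:, genes]
    X = _dense(sub).astype(float)
    m = sel.stats.loc[genes, "mean"].to_numpy()
    mcv = sel.stats.loc[genes, "moving_cv"].to_numpy()
    if np.any(m <= 0) or np.any(mcv <= 0):
        raise ValueError("gene with zero mean or zero moving CV cannot be standardized")
    Z = (X - m[None, :]) / (m * mcv)[None, :]
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite z-scores")
    return AnnData(X=Z, obs=adata.obs.copy(), var=sub.var.copy())


def calibrate_spikeins(
    adata: AnnData, concentrations=None
) -> SpikeCalibration:
    """Transcript-recovery calibration from spike-ins (log-log linear fit).

    Ordinary least squares of log10(mean observed UMI) on log10(input
    molecules), over spike-in species with non-zero mean counts.  Because
    the fitted slope need not be 1, the efficiency is defined as the fitted
    mean observed count divided by input molecules, evaluated at the
    geometric-mean input concentration.
    """
    if "is_spikein" not in adata.var or not adata.var["is_spikein"].any():
        raise ValueError("no spike-in genes flagged")
    smask = adata.var["is_spikein"].to_numpy(bool)
    mean_obs = _dense(adata)[:, smask].mean(axis=0)
    if concentrations is None:
        if "spikein_molecules" not in adata.var:
            raise ValueError("spike-in concentrations not provided")
        conc = adata.var.loc[smask, "spikein_molecules"].to_numpy(float)
    else:
        conc = np.asarray(concentrations, float)
    usable = mean_obs > 0
    if usable.sum() < 3:
        raise ValueError("need at least 3 spike-in species with non-zero mean counts")
    lx = np.log10(conc[usable])
    ly = np.log10(mean_obs[usable])
    slope, intercept = np.polyfit(lx, ly, 1)
    gm = lx.mean()  # log10 of the geometric-mean concentration
    efficiency = 10 ** (slope * gm + intercept) / 10**gm
    if not 0 < efficiency <= 1:
        warnings.warn(
            f"calibrated efficiency {efficiency:.3g} outside (0, 1]", stacklevel=2
        )
    return SpikeCalibration(
        slope=float(slope),
        intercept=float(intercept),
        efficiency=float(efficiency),
        n_species=int(usable.sum()),
    )
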