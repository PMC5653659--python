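"""Bootstrap normal-null differential-regulator analysis of RPKM-type data.

Lineage subpopulations are gated by surface-marker transcript expression
(Pdgfra-high for XEN-like, Cd24-high for ectoderm-like); the remaining
double-negative cells form a null pool assumed homogeneous up to biological
and technical noise.  For each gene, the null distribution of subpopulation
means is estimated by repeatedly resampling |target| cells with replacement
from the null pool, fitting a normal to the resampled means, and evaluating
the observed target mean against that normal.  Significant genes must
additionally survive Benjamini–Hochberg control at FDR 0.05, a minimal
fold-change of 2 and an absolute expression above 1 normalized RPKM, and
are usually restricted to a supplied set of transcriptional regulators.
Regulators are finally partitioned into "early" (robustly expressed —
normalized RPKM > 5 — in at least 50 % of 0 h cells) and "late" (expressed
in fewer than 5 %).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gate_by_marker",
    "bootstrap_null_de",
    "apply_de_filters",
    "classify_early_late",
]

EXPRESSED_RPKM = 5.0  # "robustly expressed" convention


def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X, float)


def gate_by_marker(
    adata: AnnData,
    markers: dict | None = None,
    threshold: float = EXPRESSED_RPKM,
    cells=None,
) -> pd.Series:
    """Label cells by marker expression: xen_like / ect_like / null_pool.

    ``markers`` maps labels to gating genes (default Pdgfra → xen_like,
    Cd24a → ect_like).  Cells above threshold on exactly one marker get that
    label; cells above both are flagged ``double_positive`` and excluded
    from all three groups; cells below both form the null pool.
    """
    if markers is None:
        markers = {"xen_like": "Pdgfra", "ect_like": "Cd24a"}
    if len(markers) != 2:
        raise ValueError("exactly two gating markers are required")
    missing = [g for g in markers.values() if g not in adata.var_names]
    if missing:
        raise ValueError(f"marker genes not in matrix: {missing}")
    sub = adata if cells is None else adata[cells]
    vals = {lab: _dense(sub[:, [g]]).ravel() for lab, g in markers.items()}
    labs = list(markers)
    hi0 = vals[labs[0]] > threshold
    hi1 = vals[labs[1]] > threshold
    out = np.where(
        hi0 & hi1, "double_positive",
        np.where(hi0, labs[0], np.where(hi1, labs[1], "null_pool")),
    )
    return pd.Series(out, index=sub.obs_names, name="gate")


def bootstrap_null_de(
    adata: AnnData,
    target_cells,
    null_pool,
    n_boot: int = 10000,
    seed: int = 0,
    two_sided: bool = True,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-gene p-values for target-subpopulation means under a resampling null.

    ``n_boot`` resamples of |target| cells are drawn with replacement from
    the null pool; per-gene resampled means are fit with a normal
    distribution, and the observed target mean is evaluated against it
    (two-sided by default).  Fold-change is observed mean over null mean
    with a small pseudocount in the denominator.
    """
    target = adata[list(target_cells)]
    pool = adata[list(null_pool)]
    n_t, n_p = target.n_obs, pool.n_obs
    if n_p < 2:
        raise ValueError("null pool must contain at least 2 cells")
    if n_t < 1:
        raise ValueError("target set is empty")
    Xp = _dense(pool)
    obs_mean = _dense(target).mean(axis=0)

    rng = np.random.default_rng(seed)
    # counts of how often each pool cell enters each resample -> mean matrix
    boot_means = np.empty((n_boot, adata.n_vars))
    chunk = max(1, int(5e7 // max(n_p, 1)))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, n_p, size=(stop - start, n_t))
        counts = np.zeros((stop - start, n_p))
        for r in range(stop - start):
            np.add.at(counts[r], idx[r], 1.0)
        boot_means[start:stop] = counts @ Xp / n_t
    mu = boot_means.mean(axis=0)
    sd = boot_means.std(axis=0, ddof=1)

    z = np.where(sd > 0, (obs_mean - mu) / np.where(sd > 0, sd, 1.0), np.nan)
    if two_sided:
        p = 2 * stats.norm.sf(np.abs(z))
    else:
        p = stats.norm.sf(z)
    degenerate = sd == 0
    p = np.where(degenerate, np.where(np.isclose(obs_mean, mu), 1.0, 0.0), p)
    p = np.clip(p, 0.0, 1.0)
    fc = (obs_mean + 0.0) / (mu + pseudocount)
    return pd.DataFrame(
        {
            "observed_mean": obs_mean,
            "null_mean": mu,
            "null_sd": sd,
            "z": z,
            "p": p,
            "fold_change": fc,
            "degenerate_null": degenerate,
        },
        index=adata.var_names,
    )


def apply_de_filters(
    records: pd.DataFrame,
    fdr: float = 0.05,
    min_fc: float = 2.0,
    min_expr: float = 1.0,
    regulator_set=None,
) -> tuple[list, pd.DataFrame]:
    """BH multiplicity control plus fold-change / expression / regulator filters.

    BH is applied within the tested (regulator-restricted, when a set is
    given) records.  A gene is significant when q ≤ fdr, its fold-change —
    in either direction — is at least ``min_fc`` and its observed mean
    exceeds ``min_expr`` normalized RPKM.
    """
    if records.empty:
        raise ValueError("no DE records supplied")
    rec = records.copy()
    if regulator_set is not None:
        rec = rec.loc[rec.index.isin(set(regulator_set))]
        if rec.empty:
            raise ValueError("no tested gene is in the regulator set")
    rec = rec.sort_index()  # order-invariance of the BH outcome
    reject, q, _, _ = multipletests(rec["p"].to_numpy(), alpha=fdr, method="fdr_bh")
    rec["q"] = q
    fc = rec["fold_change"].to_numpy()
    fc_pass = (fc >= min_fc) | (fc <= 1.0 / min_fc)
    rec["pass_fdr"] = reject
    rec["pass_fc"] = fc_pass
    rec["pass_expr"] = rec["observed_mean"] > min_expr
    rec["significant"] = rec["pass_fdr"] & rec["pass_fc"] & rec["pass_expr"]
    return list(rec.index[rec["significant"]]), rec


def classify_early_late(
    adata: AnnData,
    genes,
    expressed_value: float = EXPRESSED_RPKM,
    early_frac: float = 0.5,
    late_frac: float = 0.05,
    time_point: float = 0.0,
) -> pd.DataFrame:
    """Partition regulators by their pluripotent-state expression.

    early: expressed (> ``expressed_value``) in ≥ ``early_frac`` of 0 h
    cells; late: expressed in < ``late_frac``; otherwise neither.
    """
    if "time_h" not in adata.obs:
        raise ValueError("cell metadata must carry time_h")
    zero_h = adata[adata.obs["time_h"] == time_point]
    if zero_h.n_obs == 0:
        raise ValueError("no cells at the pluripotent time point")
    genes = [g for g in genes if g in adata.var_names]
    X = _dense(zero_h[:, genes])
    frac = (X > expressed_value).mean(axis=0)
    cls = np.where(frac >= early_frac, "early", np.where(frac < late_frac, "late", "neither"))
    return pd.DataFrame(
        {"expressed_fraction_0h": frac, "class": cls}, index=genes
    )
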