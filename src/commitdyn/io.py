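"""Plain-text I/O: Matrix Market counts with TSV annotations, JSON reports.

Count matrices are exchanged as Matrix Market (.mtx) files in cells × genes
orientation, with sibling ``<prefix>_cells.tsv`` and ``<prefix>_genes.tsv``
annotation tables (the gene table carries the ``is_spikein`` flag and
spike-in input molecule numbers).  Flow-cytometry events travel as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite


def write_matrix(adata: AnnData, prefix) -> None:
    """Write an AnnData as <prefix>.mtx + <prefix>_cells.tsv + <prefix>_genes.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.coo_matrix(np.asarray(adata.X))
    mmwrite(str(prefix) + ".mtx", X)
    adata.obs.to_csv(str(prefix) + "_cells.tsv", sep="\t")
    adata.var.to_csv(str(prefix) + "_genes.tsv", sep="\t")


def read_matrix(prefix) -> AnnData:
    """Read a matrix written by :func:`write_matrix`."""
    prefix = str(prefix)
    X = sp.csr_matrix(mmread(prefix + ".mtx"))
    obs = pd.read_csv(prefix + "_cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(prefix + "_genes.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return AnnData(X=X, obs=obs, var=var)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    raise TypeError(f"not JSON serialisable: {type(o)}")
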