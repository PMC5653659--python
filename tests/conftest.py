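"""Shared fixtures: one default synthetic time course and its QC chain.

Session-scoped so the expensive generation and normalization run once.
Tests must not mutate fixture objects in place.
"""

import numpy as np
import pytest

import commitdyn as cd


@pytest.fixture(scope="session")
def timecourse():
    """Default differentiation time course (seed 0) with ground truth."""
    adata, truth = cd.synthetic.generate_timecourse_umi(
        cd.synthetic.TimecourseConfig(seed=0)
    )
    return adata, truth


@pytest.fixture(scope="session")
def qc_chain(timecourse):
    """Filter -> reference-median normalize -> variable-gene selection."""
    adata, truth = timecourse
    filtered, report = cd.qc.filter_cells_by_umi(adata, 2000)
    reference = (filtered.obs["time_h"] == 0).to_numpy()
    norm = cd.qc.normalize_by_reference_median(filtered, reference)
    sel = cd.qc.select_variable_genes(norm)
    return {
        "truth": truth,
        "filtered": filtered,
        "filter_report": report,
        "norm": norm,
        "selection": sel,
    }


@pytest.fixture(scope="session")
def downsampled(timecourse):
    adata, _ = timecourse
    return cd.qc.downsample_umi(adata, 2000, seed=0)


@pytest.fixture(scope="session")
def pseudotime_chain(qc_chain):
    """Anchored classification and pseudotime on the default time course."""
    truth = qc_chain["truth"].cells
    norm, sel = qc_chain["norm"], qc_chain["selection"]
    anchors = {
        "mESC-like": (norm.obs["time_h"] == 0).to_numpy(),
        "ectoderm-like": list(
            truth.index[(truth.time_h == 96) & (truth.label == "ectoderm")]
        ),
        "XEN-like": list(truth.index[(truth.time_h == 96) & (truth.label == "xen")]),
    }
    centroids = cd.pseudotime.compute_centroids(norm, anchors, genes=sel.selected)
    cls = cd.pseudotime.classify_by_correlation(norm, centroids)
    pt = cd.pseudotime.pseudotime_order(cls)
    return {"centroids": centroids, "cls": cls, "pt": pt}


@pytest.fixture(scope="session")
def regulator_data():
    """Default regulator RPKM profiles with planted early/late classes."""
    return cd.synthetic.generate_regulator_rpkm(seed=0)


@pytest.fixture(scope="session")
def facs_truth_params():
    return cd.facs.MixtureParams(
        f1=0.30, f2=0.25, f3=0.25,
        mux_low=1.0, mux_high=4.0, muy_low=1.5, muy_high=4.5,
        sigma_x=0.5, sigma_y=0.6,
    )


def assert_labels_match_up_to_permutation(a, b):
    """True clustering equality irrespective of label naming."""
    a, b = np.asarray(a), np.asarray(b)
    assert a.shape == b.shape
    mapping = {}
    for la, lb in zip(a, b):
        if la in mapping:
            assert mapping[la] == lb, "clusterings differ"
        else:
            mapping[la] = lb
    assert len(set(mapping.values())) == len(mapping), "clusterings differ"
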