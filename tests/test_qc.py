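"""QC chain: hand-computed oracles on small matrices plus statistical checks."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats as sps

import commitdyn.qc as qc


def make_adata(X, spike_flags=None, molecules=None, obs=None):
    X = np.asarray(X)
    n, g = X.shape
    var = pd.DataFrame(index=[f"g{j}" for j in range(g)])
    if spike_flags is not None:
        var["is_spikein"] = spike_flags
        if molecules is not None:
            var["spikein_molecules"] = molecules
    obs = obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(n)])
    return AnnData(X=sp.csr_matrix(X.astype(float)), obs=obs, var=var)


class TestTotalsAndError:
    def test_counting_error_hand_value(self):
        # 1/sqrt(2500)/sqrt(400) = 1/(50*20) = 0.001
        est = qc.counting_error(2500.0, 400)
        assert est.epsilon == pytest.approx(0.001)

    def test_counting_error_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            qc.counting_error(0.0, 10)
        with pytest.raises(ValueError):
            qc.counting_error(10.0, 0)

    def test_cell_totals_exclude_spikeins(self):
        ad = make_adata([[1, 2, 7], [3, 4, 9]], spike_flags=[False, False, True])
        assert np.array_equal(qc.cell_totals(ad), [3, 7])
        assert np.array_equal(qc.cell_totals(ad, include_spikeins=True), [10, 16])


class TestFilter:
    def test_threshold_is_inclusive(self):
        X = np.zeros((3, 2))
        X[0, 0], X[1, 0], X[2, 0] = 1999, 2000, 2001
        ad = make_adata(X)
        out, rep = qc.filter_cells_by_umi(ad, 2000)
        assert list(out.obs_names) == ["c1", "c2"]
        assert (rep.n_retained, rep.n_discarded) == (2, 1)

    def test_detected_genes_oracle(self):
        # detected = >1 UMI in >1 cell, counted on retained cells
        X = np.array(
            [
                [2, 2, 1, 0],
                [2, 1, 2, 9],
                [2, 2, 0, 0],
            ]
        )
        ad = make_adata(X)
        _, rep = qc.filter_cells_by_umi(ad, 0)
        expected = int((((X > 1).sum(axis=0)) > 1).sum())  # g0, g1
        assert expected == 2
        assert rep.n_detected_genes == expected

    def test_empty_matrix_raises(self):
        ad = make_adata(np.zeros((1, 2)))[:0]
        with pytest.raises(ValueError):
            qc.filter_cells_by_umi(ad.copy())


class TestNormalize:
    def test_hand_example(self):
        # totals 10 and 40; reference = both cells -> median total 25
        ad = make_adata([[4, 6], [10, 30]])
        out = qc.normalize_by_reference_median(ad)
        expected = np.array([[4 / 10 * 25, 6 / 10 * 25], [10 / 40 * 25, 30 / 40 * 25]])
        assert np.allclose(np.asarray(out.X), expected)

    def test_reference_subset_by_mask_and_ids(self):
        ad = make_adata([[4, 6], [10, 30]])
        by_mask = qc.normalize_by_reference_median(ad, np.array([True, False]))
        by_ids = qc.normalize_by_reference_median(ad, ["c0"])
        assert np.allclose(np.asarray(by_mask.X), np.asarray(by_ids.X))
        # reference total is 10 -> first cell unchanged
        assert np.allclose(np.asarray(by_mask.X)[0], [4, 6])

    def test_zero_total_cell_raises(self):
        ad = make_adata([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="zero total"):
            qc.normalize_by_reference_median(ad)

    def test_unknown_reference_id_raises(self):
        ad = make_adata([[1, 1], [1, 1]])
        with pytest.raises(ValueError, match="unknown"):
            qc.normalize_by_reference_median(ad, ["nope"])

    def test_proportions_conserved(self, qc_chain):
        filtered, norm = qc_chain["filtered"], qc_chain["norm"]
        x0 = np.asarray(filtered.X.todense())[0]
        y0 = np.asarray(norm.X)[0]
        mask = ~filtered.var["is_spikein"].to_numpy()
        assert np.allclose(
            x0[mask] / x0[mask].sum(), y0[mask] / y0[mask].sum()
        )


class TestDownsample:
    def test_exact_totals_and_upper_bound(self, timecourse, downsampled):
        adata, _ = timecourse
        ds = downsampled
        totals = np.asarray(ds.X.sum(axis=1)).ravel()
        assert (totals == 2000).all()
        orig = adata[ds.obs_names, ds.var_names]
        assert ((ds.X > orig.X).sum()) == 0  # never exceeds source counts
        assert not ds.var.get("is_spikein", pd.Series(dtype=bool)).any()

    def test_cells_below_target_dropped(self):
        X = np.zeros((2, 3), int)
        X[0] = [5, 5, 5]
        X[1] = [1, 1, 1]
        ad = make_adata(X)
        ds = qc.downsample_umi(ad, 10, seed=0)
        assert list(ds.obs_names) == ["c0"]
        assert np.asarray(ds.X.sum()) == 10

    def test_marginals_are_hypergeometric(self):
        # one cell, two genes with 30 and 10 UMIs, downsample to 20:
        # gene0 marginal ~ Hypergeometric(N=40, K=30, n=20)
        reps = 400
        draws = np.empty(reps)
        for r in range(reps):
            ad = make_adata([[30, 10]])
            draws[r] = np.asarray(
                qc.downsample_umi(ad, 20, seed=r).X.todense()
            )[0, 0]
        expected_mean = 20 * 30 / 40
        expected_var = 20 * (30 / 40) * (10 / 40) * (40 - 20) / (40 - 1)
        assert draws.mean() == pytest.approx(expected_mean, abs=4 * np.sqrt(expected_var / reps))
        assert draws.var() == pytest.approx(expected_var, rel=0.35)

    def test_determinism(self, timecourse):
        adata, _ = timecourse
        a = qc.downsample_umi(adata[:50], 2000, seed=5)
        b = qc.downsample_umi(adata[:50], 2000, seed=5)
        assert (a.X != b.X).nnz == 0


class TestVariableGenes:
    def test_selected_count_is_ceil(self, qc_chain):
        sel = qc_chain["selection"]
        assert len(sel.selected) == math.ceil(0.05 * len(sel.stats))

    def test_planted_variable_gene_is_found(self):
        rng = np.random.default_rng(0)
        n_cells, n_genes = 300, 100
        means = np.linspace(5, 50, n_genes)
        X = rng.poisson(means, size=(n_cells, n_genes)).astype(float)
        # plant one bimodal gene: same mean but far higher CV
        on = rng.random(n_cells) < 0.2
        X[:, 37] = np.where(on, rng.poisson(125, n_cells), 0)
        ad = make_adata(X)
        sel = qc.select_variable_genes(ad, window_size=15, top_frac=0.02)
        assert "g37" in sel.selected

    def test_spikeins_never_selected(self, qc_chain):
        sel = qc_chain["selection"]
        assert not any(g.startswith("ERCC-") for g in sel.selected)
        assert sel.spikein_stats is not None

    def test_ratio_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(10, size=(50, 30)).astype(float)
        ad = make_adata(X)
        sel = qc.select_variable_genes(ad, window_size=7)
        mean, sd = X.mean(axis=0), X.std(axis=0)
        order = np.argsort(mean, kind="mergesort")
        cv = (sd / mean)[order]
        mov = (
            pd.Series(cv).rolling(7, center=True, min_periods=1).mean().to_numpy()
        )
        expected = pd.Series(cv / mov, index=ad.var_names[order])
        got = sel.stats["ratio"]
        assert np.allclose(got.loc[expected.index], expected)

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            qc.select_variable_genes(make_adata(np.zeros((3, 3))))


class TestStandardize:
    def test_z_formula(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(20, size=(80, 40)).astype(float)
        ad = make_adata(X)
        sel = qc.select_variable_genes(ad, window_size=9, top_frac=0.1)
        z = qc.standardize_cv(ad, sel)
        g = sel.selected[0]
        j = list(ad.var_names).index(g)
        m = sel.stats.loc[g, "mean"]
        mcv = sel.stats.loc[g, "moving_cv"]
        assert np.allclose(np.asarray(z[:, g].X).ravel(), (X[:, j] - m) / (m * mcv))

    def test_missing_gene_raises(self):
        ad = make_adata(np.ones((5, 4)) + np.eye(5, 4))
        sel = qc.select_variable_genes(ad, window_size=3, top_frac=0.5)
        with pytest.raises(ValueError, match="missing"):
            qc.standardize_cv(ad[:, ["g0"]], sel)


class TestSpikeCalibration:
    def test_linear_fit_oracle(self):
        conc = np.logspace(1, 5, 10)
        eff = 0.02
        X = np.tile(eff * conc, (5, 1))  # exact proportionality
        ad = make_adata(
            X, spike_flags=[True] * 10, molecules=conc
        )
        cal = qc.calibrate_spikeins(ad)
        lr = sps.linregress(np.log10(conc), np.log10(eff * conc))
        assert cal.slope == pytest.approx(lr.slope) == pytest.approx(1.0)
        assert cal.efficiency == pytest.approx(eff)

    def test_sublinear_efficiency_at_geometric_mean(self):
        # slope 0.8: efficiency depends on where it is evaluated; the
        # convention is the geometric-mean concentration
        conc = np.logspace(1, 5, 12)
        obs = 0.05 * conc**0.8
        ad = make_adata(np.tile(obs, (3, 1)), spike_flags=[True] * 12, molecules=conc)
        cal = qc.calibrate_spikeins(ad)
        gm = 10 ** np.mean(np.log10(conc))
        assert cal.slope == pytest.approx(0.8)
        assert cal.efficiency == pytest.approx(0.05 * gm**0.8 / gm)

    def test_recovers_generator_efficiency(self, qc_chain):
        cal = qc.calibrate_spikeins(qc_chain["filtered"])
        assert cal.slope == pytest.approx(1.0, abs=0.05)
        assert cal.efficiency == pytest.approx(0.009, rel=0.1)

    def test_requires_spikeins(self):
        ad = make_adata(np.ones((3, 3)))
        with pytest.raises(ValueError):
            qc.calibrate_spikeins(ad)
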