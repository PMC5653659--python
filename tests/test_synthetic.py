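"""Generator invariants: shapes, ground-truth bookkeeping, determinism."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import commitdyn as cd
from commitdyn import synthetic as syn


class TestTimecourse:
    def test_shapes_and_metadata(self, timecourse):
        adata, truth = timecourse
        cfg = syn.TimecourseConfig()
        n_cells = cfg.n_cells_per_time * len(cfg.time_points)
        assert adata.n_obs == n_cells == 9 * 120
        assert int(adata.var["is_spikein"].sum()) == 20
        spikes = adata.var.loc[adata.var["is_spikein"], "spikein_molecules"]
        assert np.array_equal(
            spikes.to_numpy(), np.round(np.logspace(1, 5, 20))
        )
        assert truth.cells.shape[0] == n_cells
        assert truth.program_means.shape[1] == 4  # pluri, epi, ect, xen

    def test_counts_are_nonnegative_integers(self, timecourse):
        adata, _ = timecourse
        x = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        assert (x >= 0).all()
        assert np.allclose(x, np.round(x))

    def test_weights_form_a_convex_mixture(self, timecourse):
        _, truth = timecourse
        c = truth.cells
        total = c.w_pluri + c.w_epi + c.w_ect + c.w_xen
        assert np.allclose(total, 1.0)
        for col in ("w_pluri", "w_epi", "w_ect", "w_xen"):
            assert (c[col] >= 0).all() and (c[col] <= 1).all()

    def test_endpoints_of_the_trajectory(self, timecourse):
        _, truth = timecourse
        c = truth.cells
        # fully pluripotent at 0 h, fully committed at 96 h
        assert (c.loc[c.time_h == 0, "w_pluri"] == 1).all()
        final = c[c.time_h == 96]
        assert np.allclose(final.w_ect + final.w_xen, 1.0)
        assert set(final.label) <= {"ectoderm", "xen"}
        # exactly one lineage weight is nonzero per cell
        assert ((c.w_ect == 0) | (c.w_xen == 0)).all()

    def test_priming_precedes_commitment(self, timecourse):
        """Pluripotency declines before any cell reaches its exit time."""
        _, truth = timecourse
        c = truth.cells
        before_exit = c[(c.time_h > 0) & (c.time_h < c.exit_time)]
        assert len(before_exit) > 100
        assert (before_exit.w_pluri < 1).all()
        assert (before_exit.w_ect + before_exit.w_xen == 0).all()
        assert (before_exit.w_epi > 0).all()

    def test_exit_times_within_window(self, timecourse):
        _, truth = timecourse
        lo, hi = syn.TimecourseConfig().exit_window
        assert truth.cells.exit_time.between(lo, hi).all()

    def test_lineage_fraction_near_p_xen(self, timecourse):
        _, truth = timecourse
        p = syn.TimecourseConfig().p_xen
        frac = (truth.cells.lineage == "xen").mean()
        se = np.sqrt(p * (1 - p) / len(truth.cells))
        assert abs(frac - p) < 4 * se

    def test_capture_is_a_thinning(self, timecourse):
        adata, truth = timecourse
        x = np.asarray(adata.X.todense())
        assert (x <= truth.true_counts).all()
        bio = ~adata.var["is_spikein"].to_numpy()
        ratio = x[:, bio].sum() / truth.cells.true_total.sum()
        assert ratio == pytest.approx(0.009, rel=0.05)

    def test_spikeins_have_identical_input_per_cell(self, timecourse):
        adata, truth = timecourse
        spike = adata.var["is_spikein"].to_numpy()
        true_spike = truth.true_counts[:, spike]
        assert (true_spike == true_spike[0]).all()

    def test_noiseless_mode_matches_mixture_mean(self):
        cfg = syn.TimecourseConfig(
            biological_noise_shape=None, n_cells_per_time=5, seed=3
        )
        _, truth = syn.generate_timecourse_umi(cfg)
        sig = truth.program_means
        w = truth.cells[["w_pluri", "w_epi", "w_ect", "w_xen"]].to_numpy()
        cols = ["pluripotent", "epiblast", "ectoderm", "xen"]
        expected = np.rint(w @ sig[cols].to_numpy().T).astype(int)
        bio = truth.true_counts[:, : sig.shape[0]]
        assert np.array_equal(bio, expected)

    def test_determinism_and_seed_sensitivity(self):
        cfg = syn.TimecourseConfig(n_cells_per_time=10)
        a1, _ = syn.generate_timecourse_umi(cfg)
        a2, _ = syn.generate_timecourse_umi(syn.TimecourseConfig(n_cells_per_time=10))
        a3, _ = syn.generate_timecourse_umi(
            syn.TimecourseConfig(n_cells_per_time=10, seed=1)
        )
        assert (a1.X != a2.X).nnz == 0
        assert (a1.X != a3.X).nnz > 0

    def test_invalid_configs_raise(self):
        with pytest.raises(ValueError):
            syn.TimecourseConfig(capture_efficiency=0.0)
        with pytest.raises(ValueError):
            syn.TimecourseConfig(time_points=(0.0, 0.0, 12.0))
        with pytest.raises(ValueError):
            syn.TimecourseConfig(n_cells_per_time=0)
        with pytest.raises(ValueError):
            syn.generate_timecourse_umi(
                syn.TimecourseConfig(exit_window=(24.0, 200.0))
            )

    def test_two_state_fallback_without_epiblast_program(self):
        progs = [
            p
            for p in syn.default_programs(n_genes=420, seed=0)
            if p.name != syn.EPIBLAST
        ]
        cfg = syn.TimecourseConfig(n_cells_per_time=8, seed=2)
        _, truth = syn.generate_timecourse_umi(cfg, progs)
        c = truth.cells
        assert (c.w_epi == 0).all()
        assert (c.loc[c.time_h <= 24, "w_pluri"] == 1).all()

    def test_program_validation(self):
        progs = syn.default_programs(n_genes=420)
        with pytest.raises(ValueError, match="pluripotent"):
            syn.generate_timecourse_umi(
                programs=[p for p in progs if p.name != syn.PLURIPOTENT]
            )
        bad = pd.Series([-1.0, 2.0], index=["g1", "g2"])
        with pytest.raises(ValueError, match="negative"):
            syn.ProgramSpec(name="x", signature=bad)


class TestRegulatorRpkm:
    def test_planted_structure(self, regulator_data):
        adata, truth = regulator_data
        at0 = adata[adata.obs["time_h"] == 0]
        x0 = np.asarray(at0.X)
        for j, g in enumerate(adata.var_names):
            cls = truth.gene_class[g]
            frac = (x0[:, j] > 5).mean()
            if cls == "early":
                assert frac >= 0.5, g
            elif cls == "late":
                assert frac < 0.05, g

    def test_markers_gate_their_lineage(self, regulator_data):
        adata, truth = regulator_data
        x = pd.DataFrame(
            np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
        )
        for lin, marker in (("xen", "Pdgfra"), ("ect", "Cd24a")):
            own = truth.cell_lineage == lin
            assert (x.loc[own.to_numpy(), marker] > 5).all()

    def test_effect_genes_shift_means(self):
        adata, truth = cd.synthetic.generate_regulator_rpkm(
            n_effect=20, n_null=50, seed=1
        )
        x = pd.DataFrame(
            np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
        )
        xen = (truth.cell_lineage == "xen").to_numpy()
        eff = truth.gene_class[truth.gene_class == "effect"].index
        ratios = x.loc[xen, eff].mean() / x.loc[~xen, eff].mean()
        assert (ratios > 2).all()

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            cd.synthetic.generate_regulator_rpkm(n_early=-1)


class TestSmfishGenerators:
    def test_gamma_moments(self):
        df = cd.synthetic.generate_smfish_counts([(2.0, 30.0)], 20000, seed=0)
        v = df.iloc[:, 0].to_numpy()
        assert v.mean() == pytest.approx(60.0, rel=0.05)
        assert v.var() == pytest.approx(2.0 * 30.0**2, rel=0.1)

    def test_latent_factor_induces_correlation(self):
        params = [(2.0, 30.0), (2.0, 30.0)]
        ind = cd.synthetic.generate_smfish_counts(params, 5000, seed=0)
        dep = cd.synthetic.generate_smfish_counts(
            params, 5000, seed=0, latent_rho=0.6
        )
        r_ind = np.corrcoef(ind.T)[0, 1]
        r_dep = np.corrcoef(dep.T)[0, 1]
        assert abs(r_ind) < 0.05
        assert r_dep > 0.4

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            cd.synthetic.generate_smfish_counts([(0.0, 1.0)], 10)
        with pytest.raises(ValueError):
            cd.synthetic.generate_smfish_counts([(1.0, 1.0)], 10, latent_rho=1.0)

    def test_bimodal_generator(self):
        counts, on = cd.synthetic.generate_bimodal_smfish(4000, 0.3, seed=0)
        assert counts.dtype == np.int64
        se = np.sqrt(0.3 * 0.7 / 4000)
        assert abs(on.mean() - 0.3) < 4 * se
        assert counts[on].mean() > 20 * max(counts[~on].mean(), 0.1)


class TestFacsGenerator:
    def test_event_moments_and_labels(self, facs_truth_params):
        p = facs_truth_params
        df = cd.synthetic.generate_facs_events(p, 20000, seed=0)
        assert set(df.true_component.unique()) == {1, 2, 3, 4}
        # component 4 is (high, high)
        c4 = df[df.true_component == 4]
        assert c4.pdgfra.mean() == pytest.approx(p.mux_high, abs=0.05)
        assert c4.cd24.mean() == pytest.approx(p.muy_high, abs=0.05)
        assert c4.pdgfra.std(ddof=0) == pytest.approx(p.sigma_x, rel=0.1)
        counts = df.true_component.value_counts(normalize=True)
        for i, f in enumerate(p.weights, start=1):
            assert counts[i] == pytest.approx(f, abs=4 * np.sqrt(f * (1 - f) / 20000))

    def test_empty_and_invalid(self, facs_truth_params):
        assert cd.synthetic.generate_facs_events(facs_truth_params, 0).empty
        with pytest.raises(ValueError):
            cd.synthetic.generate_facs_events(facs_truth_params, -1)
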