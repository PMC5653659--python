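# commitdyn

Single-cell analysis and stochastic modelling of a binary lineage decision.

When mouse embryonic stem cells (mESCs) are released from the pluripotency
ground state and exposed to retinoic acid (RA), the population splits into two
lineages: an ectoderm-like fate and an extraembryonic-endoderm-like (XEN-like)
fate.  Single-cell RNA-seq time courses of this transition show cells exiting
pluripotency through a short post-implantation-epiblast-like state and then
committing to one of the two branches, with commitment governed by a bistable
cross-repression circuit between the two lineage programs.  RA biases the
decision toward XEN, and the timing of RA exposure — not just its dose —
determines the outcome.

`commitdyn` packages the full quantitative workflow behind this kind of study:

- **`synthetic`** — generators for ground-truthed UMI-count time courses
  (pluripotent → epiblast → ectoderm/XEN programs, binomial molecule capture,
  spike-ins), regulator RPKM profiles with planted effect/early/late genes,
  flow-cytometry events, and smFISH transcript counts.
- **`qc`** — UMI-total cell filtering, Poisson counting-error estimates,
  reference-median normalization, downsampling to a common UMI total, and
  variable-gene selection by the ratio of a gene's coefficient of variation to
  a moving average of CVs at similar mean expression.
- **`clustering`** — k-means with Pearson-correlation distance, complete-linkage
  hierarchical clustering, bootstrap Jaccard cluster-stability scores, and
  robust-k selection.
- **`pseudotime`** — anchored centroid classification (mESC-like /
  ectoderm-like / XEN-like by correlation), the pseudotime coordinate
  τ = R_pluri − ½(R_ect + R_xen), per-branch ordering, and binned marker-panel
  profiles along pseudotime.
- **`variability`** — Fano factors per gene and the within-cluster vs
  population comparison that separates subpopulation structure from
  measurement noise.
- **`diffexpr`** — a bootstrap resampling null for target-subpopulation mean
  expression with Benjamini–Hochberg FDR, fold-change and expression filters,
  plus early/late classification of regulators by their expression at 0 h.
- **`coexpression`** — thresholded Pearson co-expression networks of
  lineage regulators.
- **`grn`** — a Langevin simulation of the two-gene cross-repression /
  auto-activation toggle switch (Euler–Maruyama), deterministic fixed-point
  and stability analysis, attractor classification, and RA pulse/delay
  protocol sweeps.
- **`facs`** — a constrained 9-parameter EM fit of a 4-component bivariate
  Gaussian mixture (tied means on each axis, shared per-axis σ) to two-marker
  flow data, event assignment, and subpopulation fractions.
- **`smfish`** — Gamma fits to smFISH transcript-count distributions,
  positive-cell classification via the antimode of a two-component mixture,
  and per-time-point pairwise correlations.
- **`pipeline`** — a deterministic, seeded driver that chains
  synthesize → qc → cluster → classify → fano → de → coexpr and writes a
  hashed run report.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import commitdyn as cd
import commitdyn.grn as grn

# 1. synthesize a 0-96 h differentiation time course with ground truth
adata, truth = cd.synthetic.generate_timecourse_umi(
    cd.synthetic.TimecourseConfig(seed=0)
)
print(f"cells: {adata.n_obs}, genes: {adata.n_vars}")

# 2. QC: UMI filter, reference-median normalization, variable genes
filtered, report = cd.qc.filter_cells_by_umi(adata, 2000)
print(f"retained {report.n_retained} cells, {report.n_detected_genes} detected genes")
norm = cd.qc.normalize_by_reference_median(
    filtered, (filtered.obs["time_h"] == 0).to_numpy()
)
sel = cd.qc.select_variable_genes(norm)
print(f"selected {len(sel.selected)} variable genes")

# 3. cluster stability at the final time point
final = norm[norm.obs["time_h"] == 96.0, sel.selected]
k = cd.clustering.choose_robust_k(final, [2, 3, 4], n_boot=50, seed=0)
stab = cd.clustering.bootstrap_jaccard_stability(final, k, n_boot=50, seed=0)
print(f"robust k = {k}, per-cluster mean Jaccard = {np.round(stab.mean_jaccard, 3)}")

# 4. anchored classification and pseudotime
cells = truth.cells
anchors = {
    "mESC-like": (norm.obs["time_h"] == 0).to_numpy(),
    "ectoderm-like": list(cells.index[(cells.time_h == 96) & (cells.label == "ectoderm")]),
    "XEN-like": list(cells.index[(cells.time_h == 96) & (cells.label == "xen")]),
}
centroids = cd.pseudotime.compute_centroids(norm, anchors, genes=sel.selected)
cls = cd.pseudotime.classify_by_correlation(norm, centroids)
pt = cd.pseudotime.pseudotime_order(cls)
for br in ("ect", "xen"):
    mask = pt[f"in_{br}_branch"]
    rho, _ = spearmanr(-pt.loc[mask[mask].index, "tau"],
                       cells.loc[mask[mask].index, "time_h"])
    print(f"{br} branch: {int(mask.sum())} cells, Spearman(-tau, age) = {rho:.2f}")

# 5. stochastic toggle switch: continuous RA vs RA delayed to 36 h
p = grn.GRNParams()
cont = grn.simulate_ensemble(
    p, grn.Protocol(ra_intervals=((0.0, 96.0),)), n_traj=2000, seed=0
)
late = grn.simulate_ensemble(
    p, grn.Protocol(ra_intervals=((36.0, 96.0),)), n_traj=2000, seed=0
)
print(f"XEN fraction: continuous RA {cont.xen_fraction:.2f}, "
      f"RA from 36 h {late.xen_fraction:.2f}")
```

Output:

```text
cells: 1080, genes: 1220
retained 1080 cells, 1197 detected genes
selected 60 variable genes
robust k = 2, per-cluster mean Jaccard = [1. 1.]
ect branch: 798 cells, Spearman(-tau, age) = 0.93
xen branch: 711 cells, Spearman(-tau, age) = 0.93
XEN fraction: continuous RA 0.49, RA from 36 h 0.10
```

The two planted final-time subpopulations are perfectly stable under
bootstrap reclustering (Jaccard 1.0), pseudotime recovers each cell's true
age within both branches, and the toggle-switch model reproduces the timing
effect: continuous RA splits the population ~50/50, whereas the same total
dose arriving after cells have settled into the ectoderm attractor rescues
only ~10 % to the XEN fate.

## Command line

Each module has a thin CLI wrapper:

```bash
commitdyn run config.yaml          # full pipeline; outdir/seed set in the config
commitdyn qc --matrix counts --out qc/ --seed 0
commitdyn cluster --matrix counts --out clust/ --k 2 --n-boot 100 --seed 0
commitdyn grn --protocol pulse --length 48 --n-traj 10000 --seed 0 --out grn.json
commitdyn facs --fit-reference ref.csv --events events.csv --out facs/ --seed 0
commitdyn smfish --counts counts.tsv --out fish/
```

## Reproduction

All computations are deterministic given a seed.  To reproduce the headline
numbers:

```bash
pip install --no-build-isolation -e .
python -m pytest -q tests/                         # full test suite
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`scripts/acceptance.py` runs every major computation at full size (10,000
trajectories per GRN condition, 10,000-resample bootstrap null, 10,000
flow-cytometry events, 100 cluster bootstraps) and writes each quantity as
`{"value": ..., "n": ...}`; it finishes in about half a minute.  Model
assumptions, parameter choices, and generator design notes are documented in
[docs/methods.md](docs/methods.md).
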