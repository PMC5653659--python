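# Methods

Model assumptions, parameter choices, and design notes for `commitdyn`.

## Synthetic time-course generator

### Expression model

A cell's true transcriptome is a convex mixture of four program signatures
over a shared 1,220-gene panel (1,200 biological genes + 20 spike-in
species):

- **pluripotent** — the ground state (named markers `Rex1`, `Tbx3`),
- **epiblast** — a transient post-implantation-epiblast-like intermediate
  (`Pou3f1`, `Fgf5`),
- **ectoderm** (`Pax6`, `Gbx2`, `Cd24a`) and **xen** (`Gata6`, `Pdgfra`) —
  the two terminal lineages.

Each program has 80 specific genes (on-level lognormal(log 20, 0.6), scaled
so specific genes carry 20 % of the program's transcript mass; off-state
basal expression is ~5 % of the on-level with lognormal scatter).  The
remaining 880 genes are housekeeping, shared by all programs
(lognormal(log 40, 1.0)).  Program totals are normalized to 3×10⁵
transcripts per cell.

### Differentiation kinetics

Each cell draws a pluripotency exit time uniformly in 24–48 h and a latent
terminal lineage (Bernoulli, P(xen) = 0.4).  Mixture weights evolve
deterministically in the cell's age `t`:

```
prime  = clip(t / exit_time, 0, 1)
commit = clip((t - exit_time) / 24 h, 0, 1)
w_pluripotent = 1 - prime
w_epiblast    = prime * (1 - commit)
w_lineage     = prime * commit
```

so cells prime continuously from 0 h — pluripotency factors fall and
epiblast markers rise *before* the branch point — and then hand the epiblast
weight to the terminal lineage over a 24 h ramp.  This mirrors the observed
kinetics of the mESC → ectoderm/XEN transition, where down-regulation of the
pluripotency network precedes lineage divergence and post-implantation
epiblast markers peak at intermediate times.  The per-cell ground-truth
label is the argmax of (pluripotent, epiblast, lineage) weights.

A two-state fallback (constant pluripotent until exit, then a direct ramp to
the lineage) is used automatically when a custom program set lacks an
`"epiblast"` program.

### Measurement model

True counts are Poisson draws around Gamma-modulated means (Gamma shape 2
models biological burst noise; `biological_noise_shape=None` gives pure
Poisson).  Observed UMI counts are a binomial thinning of true counts at
capture efficiency 0.9 %, applied identically to 20 spike-in species whose
input molecule numbers (log-spaced over 10–10⁵) are the same in every cell.
With 3×10⁵ true transcripts this yields ~2,700 UMIs per cell, a realistic
depth for shallow UMI protocols, and a spike-in calibration slope near 1 in
log-log space with efficiency ≈ 0.9 %.

### Realism and limitations

- Weights are deterministic given (exit time, lineage); there is no
  stochastic switching between lineages after commitment, no cell cycle, no
  doublets, and no ambient RNA.
- All cells at a time point are sampled independently; there are no batch
  effects between time points.
- The generator's defaults are the study conditions used throughout the
  tests and the pipeline; they were chosen for realism (depth, gene counts,
  kinetics) when the generator was designed, not adjusted to test outcomes.

## QC and normalization

- **Counting error**: the relative sampling error of a mean over a cluster
  is estimated as 1/√⟨UMI⟩ · 1/√n_cells (Poisson counting statistics).
- **Cell filter**: cells with ≥ 2,000 total UMIs are retained (inclusive
  threshold); a gene counts as detected if > 1 UMI in > 1 cell.
- **Normalization**: per-cell totals are scaled to the median total of a
  designated reference subpopulation (the 0 h cells in the pipeline).
- **Downsampling**: exact sampling without replacement to a fixed total per
  cell (multivariate hypergeometric marginals).  Downsampled matrices drop
  spike-in genes: downsampling equalizes *biological* sampling depth, and
  spike-ins are not used downstream of it.
- **Variable genes**: genes are ranked by CV divided by the moving average
  of CVs over a mean-expression window (window = max(25, 1 % of eligible
  genes)); the top 5 % are selected.  Ties break by ratio, then mean, then
  gene id, making selection deterministic.

## Clustering and stability

k-means uses 1 − Pearson correlation as the distance; emptied clusters keep
their previous centroid rather than being reseeded, which keeps the
iteration deterministic.  Stability is the mean Jaccard similarity between
each reference cluster and its best-matching cluster across bootstrap
resamples (cells resampled with replacement, reclustered, compared on the
intersection).  `choose_robust_k` returns the largest k whose worst cluster
exceeds the stability threshold (0.75 default).

## Classification and pseudotime

Cells are classified by Pearson correlation to anchored centroids (mESC-like
at 0 h plus the two terminal populations), restricted to the variable genes.
The pseudotime coordinate is τ = R_pluri − ½(R_ect + R_xen); branch
membership requires the branch correlation to exceed the other lineage's,
and cells are ordered by decreasing τ within each branch.  Binned profiles
average marker panels over consecutive 50-cell bins along the ordering.

## Variability

Fano factors (variance/mean) are computed per gene on depth-equalized
counts; zero-mean genes are excluded from the summary but kept as NaN in the
per-gene table.  The within-cluster statistic reclusters the cells (k-means,
k=2 default, several seeds) and averages per-cluster Fano factors,
quantifying how much apparent super-Poisson variability is explained by
subpopulation structure.

## Differential expression

The null distribution of a target subpopulation's per-gene mean is built by
resampling |target| cells with replacement from a null pool (n_boot
resamples); a normal distribution is fit to the resampled means and the
observed target mean is evaluated two-sided.  Benjamini–Hochberg controls
FDR at 0.05, followed by fold-change ≥ 2 (observed over null mean, 0.1
pseudocount) and expression > 1 filters.  Regulators are classified *early*
if expressed (RPKM > 5) in ≥ 50 % of 0 h cells and *late* if in < 5 %.

Calibration note: the construction under which this test's p-values are
exactly uniform is a target drawn *with replacement from the pool itself* —
that is precisely the resampling null.  A without-replacement subset of the
pool is conservative (finite-population correction), and a disjoint sample
with a small pool is anti-conservative because σ/√n_target omits the pool-
mean uncertainty.  With a pool much larger than the target all three
constructions converge.

## GRN simulator

Two-variable Langevin toggle switch (Euler–Maruyama):

```
dX = (a_X · X⁴/(θ⁴+X⁴) + b · θ⁴/(θ⁴+E⁴) − kX) Δ + √(DΔ) N(0,1)
dE = (a_E · E⁴/(θ⁴+E⁴) + b · θ⁴/(θ⁴+X⁴) − kE) Δ + √(DΔ) N(0,1)
```

Parameters: Hill exponent n = 4, θ = 0.5, Δ = 0.05, degradation k = 10
(pluripotency) switching to k = 1 at 12 h (iteration 25 of 200; the 200
post-equilibration iterations map to 96 h), a_E = 0.5, a_X = 0.5 with RA and
0 without, D ∈ {10⁻⁴, 10⁻²}, initial X, E ~ U[0, 0.1], 100 equilibration
iterations under the t = 0 regime.

- **b = 1**: the basal production b is a free choice; b = 1 places the
  pluripotency fixed point b/k = 0.1 at the upper edge of the initialization
  range, and the differentiation + RA regime is verified bistable at this b
  (a loud error is raised otherwise).
- Values are clipped at 0 after each step (a reflecting boundary is
  available by flag); one independent Gaussian increment per variable per
  step from a deterministically split stream, which makes the X↔E swap
  symmetry exact under seed coupling.
- Attractors are called by relaxing the noiseless dynamics from the final
  state and labelling by sign(X − E) (|X − E| < 10⁻⁶ ⇒ undecided).
- Fixed points come from multi-start root finding on [0, (a+b)/k]² with
  Jacobian-eigenvalue stability classification; residuals are < 10⁻⁸.
- **Protocol sweeps**: pulse of length L = RA on [0, L]; delay of length
  L = RA on [L, 96].  Each condition's random substream is keyed by the
  condition content (mode, length, D), so results are independent of which
  other conditions are swept.  An optional common-random-numbers mode reuses
  one substream across conditions, the standard pairing for comparing a
  stochastic response across protocol variants.
- **Timing asymmetry**: a delay of L and a pulse of 96 − L deliver the same
  RA dose at different times; the difference |pulse(96 − L) − delay(L)|
  isolates the timing effect, and gene-expression noise reduces it (noise
  lets late RA rescue cells already settled in the ectoderm basin).

## Flow-cytometry mixture

The two-marker density is a 4-component bivariate Gaussian mixture with tied
means (each axis has one low and one high mean shared across components) and
shared per-axis σ — 9 free parameters (3 independent weights + 4 means +
2 σ).  The constrained EM M-step averages sufficient statistics across the
components sharing a parameter; the log-likelihood trace is checked to be
non-decreasing.  Events are assigned to the maximum-posterior component.

## smFISH Gamma fits

Transcript counts are fit by maximum likelihood to a Gamma distribution
(location fixed at 0) after adding 0.5 to counts, the standard
half-integer continuity correction for integer data.  Goodness of fit is the
R² between empirical and fitted CDFs on the observed support.  Positive
cells are separated at the antimode of a two-component 1-D Gaussian mixture
when the counts are bimodal, with a fallback fixed threshold (5 molecules)
for unimodal data.

## Pipeline and reproducibility

The pipeline derives one seed per stage from the master seed by hashing the
stage name (CRC-32) into a `SeedSequence`, so all stage seeds are < 2³¹,
stable, and independent of stage order.  Reports are canonically serialized
(sorted JSON keys) and hashed; rerunning with the same configuration and
seed reproduces every output file bit-for-bit.  `scripts/acceptance.py`
derives its section seeds the same way from `--seed`.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` /
  `SeedSequence`; no global seeding.
- Spike-in calibration fits log₁₀(observed + pseudocount) on
  log₁₀(input) by least squares; efficiency is evaluated at the geometric
  mean input concentration.
- Bootstrap resampling in the DE null is chunked so peak memory stays
  bounded regardless of n_boot.
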