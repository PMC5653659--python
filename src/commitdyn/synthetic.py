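"""Synthetic data generators with known ground truth.

These generators emulate the data modalities of a retinoic-acid-driven mESC
differentiation time course so that every downstream analysis stage can be
exercised and validated without external downloads:

* a 9-time-point (0–96 h) UMI count time course in which cells leave a
  pluripotent expression program asynchronously between 24 h and 48 h and
  commit to one of two diverging lineage programs (ectoderm-like or
  XEN-like), observed through shallow capture (~0.9 % of transcripts) with
  ERCC-like spike-ins of known input abundance;
* full-length (RPKM-like) profiles of lowly expressed transcriptional
  regulators with planted "early" (already on in the pluripotent state) and
  "late" (off at 0 h, lineage-specifically induced) classes;
* long-tailed single-molecule FISH transcript-count tables drawn from Gamma
  distributions, optionally coupled through a shared latent factor;
* two-channel flow-cytometry events from the tied-mean 4-component bivariate
  Gaussian mixture.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

from .facs import MixtureParams

__all__ = [
    "ProgramSpec",
    "TimecourseConfig",
    "GroundTruth",
    "RegulatorTruth",
    "default_programs",
    "generate_timecourse_umi",
    "generate_regulator_rpkm",
    "generate_smfish_counts",
    "generate_bimodal_smfish",
    "generate_facs_events",
]

PLURIPOTENT = "pluripotent"
EPIBLAST = "epiblast"
ECTODERM = "ectoderm"
XEN = "xen"

#: Marker genes named for readability of tests and reports.
MARKERS = {
    PLURIPOTENT: ["Rex1", "Tbx3"],
    EPIBLAST: ["Pou3f1", "Fgf5"],
    ECTODERM: ["Pax6", "Gbx2", "Cd24a"],
    XEN: ["Gata6", "Pdgfra"],
}


@dataclass
class ProgramSpec:
    """One expression program: a per-gene mean transcript abundance."""

    name: str
    signature: pd.Series  # gene -> mean abundance (transcripts), >= 0
    marker_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.signature < 0).any():
            raise ValueError(f"program {self.name}: negative signature values")
        if not (self.signature > 0).any():
            raise ValueError(f"program {self.name}: signature has no positive entry")


@dataclass
class TimecourseConfig:
    time_points: tuple = tuple(float(t) for t in range(0, 97, 12))
    n_cells_per_time: int = 120
    exit_window: tuple = (24.0, 48.0)
    exit_ramp_h: float = 24.0
    capture_efficiency: float = 0.009
    spikein_concentrations: np.ndarray | None = None  # molecules per species
    biological_noise_shape: float | None = 2.0  # Gamma shape; None = noiseless
    p_xen: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.capture_efficiency <= 1:
            raise ValueError("capture_efficiency must be in (0, 1]")
        tp = np.asarray(self.time_points, float)
        if np.any(np.diff(tp) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.n_cells_per_time <= 0:
            raise ValueError("n_cells_per_time must be positive")
        if self.spikein_concentrations is None:
            # 20 species log-spaced over 4 decades
            self.spikein_concentrations = np.round(
                np.logspace(1, 5, 20)
            ).astype(int)


@dataclass
class GroundTruth:
    """Planted per-cell and per-gene truth accompanying a generated matrix."""

    cells: pd.DataFrame  # time_h, exit_time, lineage, w_*, label, true_total
    program_means: pd.DataFrame  # gene x program signature means
    true_counts: np.ndarray | None = None  # cells x genes true transcripts


def default_programs(
    n_genes: int = 1200, total_transcripts: float = 3.0e5, seed: int = 0
) -> list[ProgramSpec]:
    """Four expression programs over a shared synthetic gene set.

    The programs are the pluripotent ground state, a transient
    post-implantation-epiblast-like intermediate, and the two terminal
    lineages (ectoderm-like and XEN-like).  Roughly 80 % of each program's
    transcript mass sits in shared housekeeping genes (lognormal means); the
    rest is spread over 80 program-specific genes per program.  A
    program-specific gene keeps a low but detectable basal level in the
    other programs (lognormal around 5 % of its own on-level), as real
    "off" lineage genes do.  The default total of 3e5 transcripts per cell
    yields a median of roughly 2,700 observed UMIs at the default 0.9 %
    capture efficiency.
    """
    rng = np.random.default_rng(seed)
    n_specific = 80
    order = (PLURIPOTENT, EPIBLAST, ECTODERM, XEN)
    prefix = {PLURIPOTENT: "pluri", EPIBLAST: "epi", ECTODERM: "ect", XEN: "xen"}
    specific = {
        name: [f"{prefix[name]}_{i:03d}" for i in range(n_specific - len(MARKERS[name]))]
        + MARKERS[name]
        for name in order
    }
    n_house = max(n_genes - len(order) * n_specific, 20)
    house = [f"hk_{i:04d}" for i in range(n_house)]
    genes = house + [g for name in order for g in specific[name]]

    house_means = rng.lognormal(mean=np.log(40.0), sigma=1.0, size=n_house)
    house_means *= 0.8 * total_transcripts / house_means.sum()

    on_level = {}
    for name in order:
        own = rng.lognormal(mean=np.log(20.0), sigma=0.6, size=n_specific)
        on_level[name] = own * (0.2 * total_transcripts) / own.sum()

    programs = []
    for name in order:
        sig = pd.Series(0.0, index=genes)
        sig[house] = house_means
        sig[specific[name]] = on_level[name]
        for other in order:
            if other != name:
                basal = rng.lognormal(np.log(0.05), 0.5, n_specific)
                sig[specific[other]] = basal * on_level[other]
        programs.append(
            ProgramSpec(name=name, signature=sig, marker_genes=MARKERS[name])
        )
    return programs


def _validate_programs(programs: list[ProgramSpec]) -> pd.DataFrame:
    if len(programs) < 3:
        raise ValueError("need at least three programs (one pluripotent)")
    names = [p.name for p in programs]
    if PLURIPOTENT not in names:
        raise ValueError("one program must be named 'pluripotent'")
    idx = programs[0].signature.index
    for p in programs[1:]:
        if not p.signature.index.equals(idx):
            raise ValueError("inconsistent gene sets across programs")
    lineage_markers = [
        set(p.marker_genes)
        for p in programs
        if p.name not in (PLURIPOTENT, EPIBLAST)
    ]
    for i in range(len(lineage_markers)):
        for j in range(i + 1, len(lineage_markers)):
            if lineage_markers[i] & lineage_markers[j]:
                raise ValueError("lineage marker genes must be disjoint")
    return pd.DataFrame({p.name: p.signature for p in programs})


def generate_timecourse_umi(
    config: TimecourseConfig | None = None,
    programs: list[ProgramSpec] | None = None,
) -> tuple[AnnData, GroundTruth]:
    """Simulate the differentiation time course as observed by shallow UMI capture.

    Each cell's true abundance is a convex mixture of the program signatures.
    From the start of the time course every cell primes continuously: the
    pluripotent weight decays linearly and is replaced by an
    epiblast-like intermediate program, reaching full priming at the cell's
    own exit time (uniform over ``exit_window``).  After the exit time the
    epiblast weight is handed over linearly, over ``exit_ramp_h``, to a
    latent terminal lineage drawn Bernoulli(``p_xen``) per cell.  This
    mirrors observed differentiation kinetics, where pluripotency factors
    are already down-regulated and post-implantation-epiblast markers
    up-regulated before the two lineages branch.  If no program named
    ``"epiblast"`` is supplied, cells instead stay fully pluripotent until
    their exit time and transfer weight directly to the lineage (a
    two-state fallback for custom program sets).

    True transcript counts add Gamma-distributed biological noise
    around the mixture mean (Poisson-sampled to integers); observed counts
    are a binomial thinning at ``capture_efficiency``.  Spike-in species with
    identical input molecule numbers in every cell are appended and observed
    through the same thinning.
    """
    if config is None:
        config = TimecourseConfig()
    if programs is None:
        programs = default_programs()
    sig = _validate_programs(programs)
    lo, hi = config.exit_window
    tp = np.asarray(config.time_points, float)
    if not (tp[0] <= lo <= hi <= tp[-1]):
        raise ValueError("exit_window must lie within the time range")

    rng = np.random.default_rng(config.seed)
    n_per = config.n_cells_per_time
    n_cells = n_per * len(tp)
    has_epi = EPIBLAST in sig.columns
    lineages = [n for n in sig.columns if n not in (PLURIPOTENT, EPIBLAST)]

    time_h = np.repeat(tp, n_per)
    exit_time = rng.uniform(lo, hi, n_cells)
    is_xen = rng.random(n_cells) < config.p_xen
    lineage = np.where(is_xen, XEN if XEN in lineages else lineages[-1], lineages[0])

    # Commitment progress: 0 at the cell's exit time, 1 a ramp later.
    commit = np.clip((time_h - exit_time) / config.exit_ramp_h, 0.0, 1.0)
    weights = pd.DataFrame(0.0, index=range(n_cells), columns=sig.columns)
    if has_epi:
        # Priming progress: pluripotent -> epiblast-like, complete at exit.
        prime = np.clip(time_h / exit_time, 0.0, 1.0)
        weights[PLURIPOTENT] = 1.0 - prime
        weights[EPIBLAST] = prime * (1.0 - commit)
        w_lineage = prime * commit
    else:
        weights[PLURIPOTENT] = 1.0 - commit
        w_lineage = commit
    for lin in lineages:
        weights.loc[lineage == lin, lin] = w_lineage[lineage == lin]
    w_pluri = weights[PLURIPOTENT].to_numpy()

    mean = weights.to_numpy() @ sig.to_numpy().T  # cells x genes
    shape = config.biological_noise_shape
    if shape is None:
        true_counts = np.rint(mean).astype(np.int64)
    else:
        lam = np.where(mean > 0, rng.gamma(shape, 1.0, mean.shape) * mean / shape, 0.0)
        true_counts = rng.poisson(lam).astype(np.int64)

    conc = np.asarray(config.spikein_concentrations, int)
    spike_true = np.tile(conc, (n_cells, 1))
    all_true = np.hstack([true_counts, spike_true])
    observed = rng.binomial(all_true, config.capture_efficiency)

    genes = list(sig.index) + [f"ERCC-{i:04d}" for i in range(len(conc))]
    # Label each cell by its dominant program (lineage programs collapsed
    # to the cell's latent lineage).
    state = pd.DataFrame(
        {
            PLURIPOTENT: weights[PLURIPOTENT],
            EPIBLAST: weights[EPIBLAST] if has_epi else 0.0,
            "lineage": w_lineage,
        }
    )
    label = state.idxmax(axis=1).to_numpy()
    label = np.where(label == "lineage", lineage, label)
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {"time_h": time_h, "true_label": label}, index=cell_ids
    )
    var = pd.DataFrame(
        {
            "is_spikein": [False] * sig.shape[0] + [True] * len(conc),
            "spikein_molecules": [np.nan] * sig.shape[0] + list(conc.astype(float)),
        },
        index=genes,
    )
    adata = AnnData(
        X=sp.csr_matrix(observed), obs=obs, var=var,
        uns={"capture_efficiency": config.capture_efficiency},
    )
    cells = pd.DataFrame(
        {
            "time_h": time_h,
            "exit_time": exit_time,
            "lineage": lineage,
            "w_pluri": weights[PLURIPOTENT].to_numpy(),
            "w_epi": weights[EPIBLAST].to_numpy() if has_epi else 0.0,
            "w_ect": weights[lineages[0]].to_numpy(),
            "w_xen": weights[lineages[-1]].to_numpy() if len(lineages) > 1 else 0.0,
            "label": label,
            "true_total": true_counts.sum(axis=1),
        },
        index=cell_ids,
    )
    return adata, GroundTruth(cells=cells, program_means=sig, true_counts=all_true)


@dataclass
class RegulatorTruth:
    gene_class: pd.Series  # gene -> early | late | null | effect | marker
    gene_lineage: pd.Series  # gene -> xen | ect | none
    cell_lineage: pd.Series  # cell -> pluripotent | xen | ect | uncommitted


def generate_regulator_rpkm(
    n_early: int = 10,
    n_late: int = 10,
    n_null: int = 200,
    n_effect: int = 0,
    effect_fold: float = 4.0,
    n_cells_0h: int = 60,
    n_cells_final: int = 80,
    p_xen: float = 0.4,
    p_uncommitted: float = 0.4,
    final_time_h: float = 96.0,
    seed: int = 0,
) -> tuple[AnnData, RegulatorTruth]:
    """Normalized-RPKM regulator profiles with planted early/late classes.

    Early regulators of a lineage are already robustly expressed (value > 5)
    in at least half of the 0 h cells and rise further in their lineage;
    late regulators are expressed in < 5 % of 0 h cells and induced
    lineage-specifically at the final time point.  Gating markers (Pdgfra
    for XEN-like, Cd24a for ectoderm-like) are always included; uncommitted
    final-time cells express neither and form the null pool for the
    bootstrap differential-expression test.  Optional ``n_effect`` genes are
    planted at ``effect_fold`` times the null mean in XEN-like cells only,
    on a background of ``n_null`` exchangeable null genes.
    """
    if n_early < 0 or n_late < 0:
        raise ValueError("regulator counts must be non-negative")
    rng = np.random.default_rng(seed)

    lineage_of = {"xen": "Pdgfra", "ect": "Cd24a"}
    genes, gclass, glin = [], [], []
    for marker_lin, marker in lineage_of.items():
        genes.append(marker)
        gclass.append("marker")
        glin.append(marker_lin)
    for i in range(n_early):
        lin = "xen" if i % 2 == 0 else "ect"
        genes.append(f"early_{lin}_{i:03d}")
        gclass.append("early")
        glin.append(lin)
    for i in range(n_late):
        lin = "xen" if i % 2 == 0 else "ect"
        genes.append(f"late_{lin}_{i:03d}")
        gclass.append("late")
        glin.append(lin)
    for i in range(n_effect):
        genes.append(f"effect_{i:03d}")
        gclass.append("effect")
        glin.append("xen")
    for i in range(n_null):
        genes.append(f"null_{i:04d}")
        gclass.append("null")
        glin.append("none")
    gene_class = pd.Series(gclass, index=genes)
    gene_lineage = pd.Series(glin, index=genes)

    n_cells = n_cells_0h + n_cells_final
    time_h = np.array([0.0] * n_cells_0h + [final_time_h] * n_cells_final)
    u = rng.random(n_cells_final)
    final_lin = np.where(
        u < p_uncommitted, "uncommitted", np.where(
            rng.random(n_cells_final) < p_xen, "xen", "ect"
        ),
    )
    cell_lin = np.concatenate([np.array(["pluripotent"] * n_cells_0h), final_lin])

    def gamma_at(mean: float, size: int) -> np.ndarray:
        return rng.gamma(2.0, mean / 2.0, size)

    null_mean = 10.0
    X = np.zeros((n_cells, len(genes)))
    for j, g in enumerate(genes):
        cls, lin = gene_class[g], gene_lineage[g]
        if cls == "null":
            X[:, j] = gamma_at(null_mean, n_cells)
        elif cls == "effect":
            on = cell_lin == "xen"
            X[on, j] = gamma_at(effect_fold * null_mean, on.sum())
            X[~on, j] = gamma_at(null_mean, (~on).sum())
        elif cls == "marker":
            on = cell_lin == lin
            X[on, j] = gamma_at(50.0, on.sum()) + 10.0  # robustly above gate
            X[~on, j] = rng.exponential(0.3, (~on).sum())
        elif cls == "early":
            base = gamma_at(20.0, n_cells) + 6.0  # >5 in every 0 h cell
            own = cell_lin == lin
            other = (cell_lin != lin) & (time_h > 0) & (cell_lin != "uncommitted")
            base[own] = gamma_at(60.0, own.sum()) + 6.0
            base[other] = rng.exponential(1.0, other.sum())
            X[:, j] = base
        elif cls == "late":
            vals = rng.exponential(0.5, n_cells)  # P(>5) ~ 4.5e-5 at 0 h
            on = cell_lin == lin
            vals[on] = gamma_at(30.0, on.sum()) + 6.0
            X[:, j] = vals

    cell_ids = [f"rcell_{i:04d}" for i in range(n_cells)]
    adata = AnnData(
        X=X,
        obs=pd.DataFrame({"time_h": time_h, "true_lineage": cell_lin}, index=cell_ids),
        var=pd.DataFrame(
            {"gene_class": gene_class, "gene_lineage": gene_lineage}, index=genes
        ),
    )
    truth = RegulatorTruth(
        gene_class=gene_class,
        gene_lineage=gene_lineage,
        cell_lineage=pd.Series(cell_lin, index=cell_ids),
    )
    return adata, truth


def generate_smfish_counts(
    gene_params: list[tuple[float, float]],
    n_cells: int,
    seed: int = 0,
    latent_rho: float = 0.0,
    gene_names: list[str] | None = None,
) -> pd.DataFrame:
    """Gamma-distributed transcript counts per cell, rounded to integers.

    Pairwise dependence is introduced through a Gaussian copula with a
    shared latent factor: each gene's latent normal is
    sqrt(rho)*F + sqrt(1-rho)*eps, so every gene pair has latent correlation
    ``latent_rho`` (the count-scale Pearson correlation is slightly
    attenuated by the marginal transform).
    """
    for a, s in gene_params:
        if a <= 0 or s <= 0:
            raise ValueError("Gamma shape and scale must be positive")
    if not 0 <= latent_rho < 1:
        raise ValueError("latent_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_genes = len(gene_params)
    if latent_rho > 0:
        f = rng.standard_normal((n_cells, 1))
        eps = rng.standard_normal((n_cells, n_genes))
        z = np.sqrt(latent_rho) * f + np.sqrt(1 - latent_rho) * eps
        u = stats.norm.cdf(z)
        counts = np.column_stack(
            [
                stats.gamma.ppf(u[:, j], a=a, scale=s)
                for j, (a, s) in enumerate(gene_params)
            ]
        )
    else:
        counts = np.column_stack(
            [rng.gamma(a, s, n_cells) for a, s in gene_params]
        )
    counts = np.clip(np.rint(counts), 0, None).astype(np.int64)
    if gene_names is None:
        gene_names = [f"gene_{j}" for j in range(n_genes)]
    return pd.DataFrame(
        counts, columns=gene_names, index=[f"fcell_{i:05d}" for i in range(n_cells)]
    )


def generate_bimodal_smfish(
    n_cells: int,
    on_fraction: float,
    seed: int = 0,
    off_lambda: float = 0.5,
    on_shape: float = 2.0,
    on_scale: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts from a mixture of an "off" Poisson mode and an "on" Gamma mode.

    Returns (counts, is_on) where is_on is the planted state per cell.
    """
    rng = np.random.default_rng(seed)
    on = rng.random(n_cells) < on_fraction
    counts = rng.poisson(off_lambda, n_cells).astype(float)
    counts[on] = np.rint(rng.gamma(on_shape, on_scale, on.sum()))
    return counts.astype(np.int64), on


def generate_facs_events(
    params: MixtureParams, n_events: int, seed: int = 0
) -> pd.DataFrame:
    """Flow events from the tied-mean 4-component mixture, with true labels."""
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    rng = np.random.default_rng(seed)
    if n_events == 0:
        return pd.DataFrame(columns=["pdgfra", "cd24", "true_component"])
    comp = rng.choice(4, size=n_events, p=params.weights)
    means = params.means[comp]
    x = rng.normal(means[:, 0], params.sigma_x)
    y = rng.normal(means[:, 1], params.sigma_y)
    return pd.DataFrame({"pdgfra": x, "cd24": y, "true_component": comp + 1})
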