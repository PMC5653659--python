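"""Constrained Gaussian-mixture quantification of two-marker flow cytometry.

Two surface markers (PDGFRA on x, CD24 on y) separate four subpopulations of
differentiating cells: double-negative, CD24 single-positive (ectoderm-like),
PDGFRA single-positive (XEN-like) and double-positive.  The event density is
modelled as a sum of four bivariate normal components whose means are tied —
each axis admits only a "low" and a "high" level shared across components —
and whose per-axis standard deviations are shared by all components.  That
leaves 9 free parameters: three weights (the fourth is the complement), four
mean levels and two standard deviations.

The model is fit to a reference sample by maximum likelihood (EM with pooled
M-step updates); other samples are then quantified by assigning each event to
the component it was most likely drawn from and counting the four classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MixtureParams",
    "FitResult",
    "FractionReport",
    "COMPONENT_LABELS",
    "BIOLOGICAL_NAMES",
    "fit_reference_mixture",
    "assign_events",
    "quantify_fractions",
]

#: Component order: (x-level, y-level) = (low,low), (low,high), (high,low), (high,high).
COMPONENT_LABELS = ("neg_neg", "neg_pos", "pos_neg", "pos_pos")

#: Biological reading of each class in (x=PDGFRA, y=CD24) space.
BIOLOGICAL_NAMES = {
    "neg_neg": "double-negative",
    "neg_pos": "ectoderm-like (CD24+)",
    "pos_neg": "XEN-like (PDGFRA+)",
    "pos_pos": "double-positive",
}


@dataclass
class MixtureParams:
    """The 9 free parameters of the tied-mean 4-component bivariate mixture.

    Weights ``f1..f3`` belong to the (low,low), (low,high) and (high,low)
    components; the (high,high) weight is ``1 - f1 - f2 - f3``.
    """

    f1: float
    f2: float
    f3: float
    mux_low: float
    mux_high: float
    muy_low: float
    muy_high: float
    sigma_x: float
    sigma_y: float

    def __post_init__(self) -> None:
        w = np.array([self.f1, self.f2, self.f3])
        if np.any(w < -1e-12) or w.sum() > 1 + 1e-9:
            raise ValueError("component weights must lie in the simplex")
        if not (self.mux_low < self.mux_high and self.muy_low < self.muy_high):
            raise ValueError("low mean level must be below high level on each axis")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("standard deviations must be positive")

    @property
    def f4(self) -> float:
        return 1.0 - self.f1 - self.f2 - self.f3

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4])

    @property
    def means(self) -> np.ndarray:
        """4 × 2 array of component means, in COMPONENT_LABELS order."""
        return np.array(
            [
                [self.mux_low, self.muy_low],
                [self.mux_low, self.muy_high],
                [self.mux_high, self.muy_low],
                [self.mux_high, self.muy_high],
            ]
        )

    def transposed(self) -> "MixtureParams":
        """Parameters after exchanging the x and y axes (components 2 and 3 swap)."""
        return MixtureParams(
            f1=self.f1,
            f2=self.f3,
            f3=self.f2,
            mux_low=self.muy_low,
            mux_high=self.muy_high,
            muy_low=self.mux_low,
            muy_high=self.mux_high,
            sigma_x=self.sigma_y,
            sigma_y=self.sigma_x,
        )


@dataclass
class FitResult:
    params: MixtureParams
    log_likelihood: float
    log_likelihood_trace: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class FractionReport:
    fractions: pd.Series  # indexed by COMPONENT_LABELS
    standard_errors: pd.Series  # multinomial SE of each fraction
    n_events: int
    biological_names: dict = field(default_factory=lambda: dict(BIOLOGICAL_NAMES))


def _as_xy(events) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        cols = [c for c in ("pdgfra", "cd24") if c in events.columns]
        if len(cols) == 2:
            return events[cols].to_numpy(float)
        return events.iloc[:, :2].to_numpy(float)
    arr = np.asarray(events, float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("events must be an (n, 2) table of (x, y) values")
    return arr[:, :2]


def _log_component_densities(xy: np.ndarray, p: MixtureParams) -> np.ndarray:
    """n × 4 matrix of per-component log densities (no weights)."""
    x, y = xy[:, 0][:, None], xy[:, 1][:, None]
    mx = p.means[:, 0][None, :]
    my = p.means[:, 1][None, :]
    lx = -0.5 * ((x - mx) / p.sigma_x) ** 2 - math.log(p.sigma_x)
    ly = -0.5 * ((y - my) / p.sigma_y) ** 2 - math.log(p.sigma_y)
    return lx + ly - math.log(2 * math.pi)


def _log_likelihood(xy: np.ndarray, p: MixtureParams) -> float:
    logd = _log_component_densities(xy, p)
    with np.errstate(divide="ignore"):
        logw = np.log(np.clip(p.weights, 1e-300, None))
    m = logd + logw[None, :]
    mmax = m.max(axis=1, keepdims=True)
    return float((mmax[:, 0] + np.log(np.exp(m - mmax).sum(axis=1))).sum())


def _em_once(
    xy: np.ndarray, init: MixtureParams, max_iter: int, tol: float
) -> FitResult:
    p = init
    trace = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        # E step: responsibilities under the current tied parameters
        logd = _log_component_densities(xy, p)
        with np.errstate(divide="ignore"):
            m = logd + np.log(np.clip(p.weights, 1e-300, None))[None, :]
        mmax = m.max(axis=1, keepdims=True)
        r = np.exp(m - mmax)
        ll = float((mmax[:, 0] + np.log(r.sum(axis=1))).sum())
        r /= r.sum(axis=1, keepdims=True)
        trace.append(ll)
        if ll - prev < tol and it > 0:
            converged = True
            break
        prev = ll

        # M step with pooling across tied components
        nk = r.sum(axis=0)
        x, y = xy[:, 0], xy[:, 1]
        # x-levels: components (0,1) share mux_low, (2,3) share mux_high
        wlo_x = r[:, 0] + r[:, 1]
        whi_x = r[:, 2] + r[:, 3]
        mux_low = float((wlo_x * x).sum() / wlo_x.sum())
        mux_high = float((whi_x * x).sum() / whi_x.sum())
        # y-levels: components (0,2) share muy_low, (1,3) share muy_high
        wlo_y = r[:, 0] + r[:, 2]
        whi_y = r[:, 1] + r[:, 3]
        muy_low = float((wlo_y * y).sum() / wlo_y.sum())
        muy_high = float((whi_y * y).sum() / whi_y.sum())
        mx = np.array([mux_low, mux_low, mux_high, mux_high])
        my = np.array([muy_low, muy_high, muy_low, muy_high])
        var_x = float((r * (x[:, None] - mx[None, :]) ** 2).sum() / len(x))
        var_y = float((r * (y[:, None] - my[None, :]) ** 2).sum() / len(y))
        if var_x < 1e-12 or var_y < 1e-12:
            raise RuntimeError("degenerate EM collapse: a pooled variance reached 0")
        if not (mux_low < mux_high and muy_low < muy_high):
            # levels crossed; re-order to keep the low<high convention
            mux_low, mux_high = sorted((mux_low, mux_high))
            muy_low, muy_high = sorted((muy_low, muy_high))
            if mux_high - mux_low < 1e-12:
                mux_high = mux_low + 1e-6
            if muy_high - muy_low < 1e-12:
                muy_high = muy_low + 1e-6
        f = nk / nk.sum()
        p = MixtureParams(
            f1=float(f[0]),
            f2=float(f[1]),
            f3=float(f[2]),
            mux_low=mux_low,
            mux_high=mux_high,
            muy_low=muy_low,
            muy_high=muy_high,
            sigma_x=math.sqrt(var_x),
            sigma_y=math.sqrt(var_y),
        )
    return FitResult(
        params=p,
        log_likelihood=trace[-1],
        log_likelihood_trace=np.array(trace),
        n_iter=len(trace),
        converged=converged,
    )


def _moment_init(xy: np.ndarray, rng: np.random.Generator, jitter: float) -> MixtureParams:
    """Initial parameters from per-axis median splits, with optional jitter."""
    x, y = xy[:, 0], xy[:, 1]
    inits = {}
    for name, v in (("x", x), ("y", y)):
        med = np.median(v)
        lo = v[v <= med].mean()
        hi = v[v > med].mean() if np.any(v > med) else lo + v.std() + 1e-6
        inits[name] = (lo, hi, max(v.std() / 2, 1e-3))
    scale_x = inits["x"][1] - inits["x"][0] + 1e-9
    scale_y = inits["y"][1] - inits["y"][0] + 1e-9
    jx = rng.normal(0, jitter * scale_x, 2) if jitter else np.zeros(2)
    jy = rng.normal(0, jitter * scale_y, 2) if jitter else np.zeros(2)
    mux = np.sort(np.array([inits["x"][0], inits["x"][1]]) + jx)
    muy = np.sort(np.array([inits["y"][0], inits["y"][1]]) + jy)
    if mux[1] - mux[0] < 1e-9:
        mux[1] = mux[0] + 1e-6
    if muy[1] - muy[0] < 1e-9:
        muy[1] = muy[0] + 1e-6
    return MixtureParams(
        f1=0.25,
        f2=0.25,
        f3=0.25,
        mux_low=float(mux[0]),
        mux_high=float(mux[1]),
        muy_low=float(muy[0]),
        muy_high=float(muy[1]),
        sigma_x=float(inits["x"][2]),
        sigma_y=float(inits["y"][2]),
    )


def fit_reference_mixture(
    events,
    init: MixtureParams | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood fit of the tied-mean mixture to a reference sample.

    EM with pooled M-step updates (means pooled across the two components
    sharing each axis level, variances pooled across all four components),
    so the log-likelihood is non-decreasing over iterations.  The best of
    ``n_restarts`` jittered moment initialisations is returned, unless an
    explicit ``init`` is given.
    """
    xy = _as_xy(events)
    if len(xy) < 8:
        raise ValueError("too few events to fit a 9-parameter mixture")
    rng = np.random.default_rng(seed)
    if init is not None:
        return _em_once(xy, init, max_iter, tol)
    best: FitResult | None = None
    for i in range(n_restarts):
        start = _moment_init(xy, rng, jitter=0.0 if i == 0 else 0.25)
        try:
            res = _em_once(xy, start, max_iter, tol)
        except RuntimeError:
            continue
        if best is None or res.log_likelihood > best.log_likelihood:
            best = res
    if best is None:
        raise RuntimeError("all EM restarts collapsed")
    return best


def assign_events(
    events, params: MixtureParams, weighted: bool = True
) -> pd.DataFrame:
    """Assign each event to the component it was most likely drawn from.

    With ``weighted=True`` the posterior weight × density is maximised; with
    ``weighted=False`` only the component density is compared.  Exact ties go
    to the lower-index component and are flagged.
    """
    xy = _as_xy(events)
    logd = _log_component_densities(xy, params)
    if weighted:
        with np.errstate(divide="ignore"):
            logd = logd + np.log(np.clip(params.weights, 1e-300, None))[None, :]
    order = np.argsort(-logd, axis=1)
    best = order[:, 0]
    second = order[:, 1]
    tie = np.isclose(
        logd[np.arange(len(xy)), best], logd[np.arange(len(xy)), second]
    )
    # ties resolved to the lower component index
    best = np.where(tie, np.minimum(best, second), best)
    labels = np.array(COMPONENT_LABELS)[best]
    return pd.DataFrame({"label": labels, "component": best + 1, "tie": tie})


def quantify_fractions(labels) -> FractionReport:
    """Subpopulation fractions with multinomial standard errors."""
    if isinstance(labels, pd.DataFrame):
        labels = labels["label"]
    labels = pd.Series(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("empty sample")
    counts = labels.value_counts().reindex(COMPONENT_LABELS, fill_value=0)
    frac = counts / n
    se = np.sqrt(frac * (1 - frac) / n)
    return FractionReport(
        fractions=frac.astype(float),
        standard_errors=se.astype(float),
        n_events=n,
    )


def arcsinh_transform(values, cofactor: float = 150.0):
    """Standard arcsinh compression for raw cytometer channel values."""
    return np.arcsinh(np.asarray(values, float) / cofactor)
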