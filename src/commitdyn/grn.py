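"""Stochastic simulation of a minimal bistable lineage-decision network.

Two mutually repressing, auto-activating programs X (XEN-like) and E
(ectoderm-like) follow the Langevin dynamics

    dX = ( a_X · Xⁿ/(θⁿ+Xⁿ) + b · θⁿ/(θⁿ+Eⁿ) − kX ) Δ + √(DΔ) N(0,1)
    dE = ( a_E · Eⁿ/(θⁿ+Eⁿ) + b · θⁿ/(θⁿ+Xⁿ) − kE ) Δ + √(DΔ) N(0,1)

integrated by the Euler–Maruyama method.  Pluripotency is modelled as a high
degradation rate k that keeps both programs low; exit from pluripotency
switches k from 10 to 1 after 12 h (25 iterations), letting the system fall
into one of two attractors.  Retinoic acid (RA) acts by switching the XEN
auto-activation a_X from 0 to 0.5, biasing the decision; its timing is set
by a protocol of RA-on intervals (pulses or delayed onset).  Trajectories
are initialised uniformly in [0, 0.1]², equilibrated for 100 iterations in
the pluripotency regime, propagated for 200 iterations spanning 96 h, and
classified by relaxing the endpoint under the noiseless final-regime
dynamics to an attractor.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GRNParams",
    "Protocol",
    "Trajectory",
    "SimulationResult",
    "FixedPoint",
    "vector_field",
    "find_fixed_points",
    "simulate_ensemble",
    "simulate_trajectory",
    "classify_attractor",
    "run_protocol_sweep",
    "verify_bistability",
]


@dataclass
class GRNParams:
    a_x_on: float = 0.5  # XEN auto-activation with RA
    a_x_off: float = 0.0  # without RA
    a_e: float = 0.5  # ectoderm auto-activation
    b: float = 1.0  # basal production, repressed by the opposing program
    theta: float = 0.5  # Hill threshold
    hill_n: int = 4  # Hill exponent
    k_pluri: float = 10.0  # degradation while pluripotent
    k_diff: float = 1.0  # degradation after exit
    D: float = 0.01  # noise power per time
    dt: float = 0.05  # Euler time step

    def __post_init__(self) -> None:
        positives = {
            "a_e": self.a_e, "b": self.b, "theta": self.theta,
            "hill_n": self.hill_n, "k_pluri": self.k_pluri,
            "k_diff": self.k_diff, "dt": self.dt,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.a_x_on < 0 or self.a_x_off < 0 or self.D < 0:
            raise ValueError("a_x and D must be non-negative")


@dataclass
class Protocol:
    """Timing of pluripotency exit and RA exposure.

    The iteration↔hour mapping is n_iter iterations = t_final_h hours
    (default 200 = 96 h, so the 12 h exit falls on iteration 25).
    """

    t_exit_h: float = 12.0
    ra_intervals: tuple = ((0.0, 96.0),)
    n_equil: int = 100
    n_iter: int = 200
    t_final_h: float = 96.0

    def __post_init__(self) -> None:
        for s, e in self.ra_intervals:
            if not (0 <= s <= e <= self.t_final_h):
                raise ValueError("RA intervals must lie within [0, t_final_h]")

    @property
    def dt_h(self) -> float:
        return self.t_final_h / self.n_iter

    def ra_on(self, hour: float) -> bool:
        return any(s <= hour < e for s, e in self.ra_intervals)


@dataclass
class Trajectory:
    X: np.ndarray  # levels at iterations 0..n_iter of the propagation phase
    E: np.ndarray
    hours: np.ndarray
    label: str


@dataclass
class SimulationResult:
    final_X: np.ndarray
    final_E: np.ndarray
    labels: np.ndarray  # "XEN" / "ectoderm" / "undecided"
    xen_fraction: float
    se: float  # binomial standard error
    n_traj: int
    seed: int
    trajectories: tuple | None = None  # (X, E) iteration x trajectory arrays


@dataclass
class FixedPoint:
    x: float
    e: float
    stable: bool
    eigenvalues: np.ndarray
    residual: float


def _hill_act(v: np.ndarray, theta: float, n: int) -> np.ndarray:
    vn = np.power(v, n)
    return vn / (theta**n + vn)


def _hill_rep(v: np.ndarray, theta: float, n: int) -> np.ndarray:
    tn = theta**n
    return tn / (tn + np.power(v, n))


def vector_field(x, e, p: GRNParams, k: float, a_x: float):
    """Deterministic drift (dX/dt, dE/dt) in a given regime."""
    fx = a_x * _hill_act(x, p.theta, p.hill_n) + p.b * _hill_rep(e, p.theta, p.hill_n) - k * x
    fe = p.a_e * _hill_act(e, p.theta, p.hill_n) + p.b * _hill_rep(x, p.theta, p.hill_n) - k * e
    return fx, fe


def _jacobian(x: float, e: float, p: GRNParams, k: float, a_x: float) -> np.ndarray:
    n, th = p.hill_n, p.theta
    tn = th**n

    def dact(v):  # d/dv vⁿ/(θⁿ+vⁿ)
        return n * tn * v ** (n - 1) / (tn + v**n) ** 2 if v > 0 else 0.0

    def drep(v):  # d/dv θⁿ/(θⁿ+vⁿ)
        return -n * tn * v ** (n - 1) / (tn + v**n) ** 2 if v > 0 else 0.0

    return np.array(
        [
            [a_x * dact(x) - k, p.b * drep(e)],
            [p.b * drep(x), p.a_e * dact(e) - k],
        ]
    )


def find_fixed_points(
    p: GRNParams,
    regime: str = "differentiation",
    ra: bool = True,
    n_grid: int = 12,
    tol: float = 1e-12,
) -> list[FixedPoint]:
    """All fixed points of the noiseless vector field in a regime, with stability.

    Multi-start root finding over a grid covering [0, (a+b)/k]²; converged
    roots are deduplicated and classified by the eigenvalues of the analytic
    Jacobian (stable ⇔ both real parts negative).
    """
    k = p.k_pluri if regime == "pluripotency" else p.k_diff
    a_x = p.a_x_on if ra else p.a_x_off
    hi = (max(a_x, p.a_e) + p.b) / k * 1.2 + 0.1

    def fun(v):
        fx, fe = vector_field(v[0], v[1], p, k, a_x)
        return [fx, fe]

    roots: list[FixedPoint] = []
    for x0 in np.linspace(0, hi, n_grid):
        for e0 in np.linspace(0, hi, n_grid):
            sol = optimize.root(fun, [x0, e0], method="hybr", tol=tol)
            if not sol.success:
                continue
            x, e = sol.x
            if x < -1e-9 or e < -1e-9:
                continue
            x, e = max(x, 0.0), max(e, 0.0)
            res = float(np.hypot(*fun([x, e])))
            if res > 1e-9:
                continue
            if any(np.hypot(x - r.x, e - r.e) < 1e-6 for r in roots):
                continue
            eig = np.linalg.eigvals(_jacobian(x, e, p, k, a_x))
            roots.append(
                FixedPoint(
                    x=float(x), e=float(e),
                    stable=bool(np.all(eig.real < 0)),
                    eigenvalues=eig, residual=res,
                )
            )
    if not roots:
        raise RuntimeError("fixed-point search did not converge from any start")
    return sorted(roots, key=lambda r: (r.x, r.e))


def verify_bistability(p: GRNParams) -> None:
    """Fail loudly if differentiation+RA is not bistable at the chosen b."""
    fps = find_fixed_points(p, regime="differentiation", ra=True)
    n_stable = sum(fp.stable for fp in fps)
    if n_stable < 2:
        raise RuntimeError(
            f"differentiation+RA regime is not bistable at b={p.b}: "
            f"{n_stable} stable fixed point(s) found"
        )


def _relax(
    X: np.ndarray,
    E: np.ndarray,
    p: GRNParams,
    k: float,
    a_x: float,
    max_steps: int = 50000,
    ftol: float = 1e-10,
):
    """Noiseless Euler relaxation to convergence of the drift."""
    X, E = X.astype(float).copy(), E.astype(float).copy()
    for _ in range(max_steps):
        fx, fe = vector_field(X, E, p, k, a_x)
        X += fx * p.dt
        E += fe * p.dt
        np.clip(X, 0.0, None, out=X)
        np.clip(E, 0.0, None, out=E)
        if max(np.abs(fx).max(), np.abs(fe).max()) < ftol:
            return X, E
    raise RuntimeError("noiseless relaxation did not converge")


def classify_attractor(
    final_X,
    final_E,
    p: GRNParams,
    proto: Protocol | None = None,
    method: str = "relax",
    tol: float = 1e-6,
) -> np.ndarray:
    """Label endpoint states as XEN / ectoderm / undecided.

    ``relax`` (default) runs the noiseless final-regime dynamics from each
    endpoint to convergence and compares X and E there; ``endpoint``
    compares the raw final levels.
    """
    if proto is None:
        proto = Protocol()
    X = np.atleast_1d(np.asarray(final_X, float))
    E = np.atleast_1d(np.asarray(final_E, float))
    final_hour = proto.t_final_h - proto.dt_h / 2
    k = p.k_pluri if final_hour < proto.t_exit_h else p.k_diff
    a_x = p.a_x_on if proto.ra_on(final_hour) else p.a_x_off
    if method == "relax":
        X, E = _relax(X, E, p, k, a_x)
    elif method != "endpoint":
        raise ValueError("method must be 'relax' or 'endpoint'")
    diff = X - E
    return np.where(diff > tol, "XEN", np.where(diff < -tol, "ectoderm", "undecided"))


def simulate_ensemble(
    p: GRNParams,
    proto: Protocol | None = None,
    n_traj: int = 10000,
    seed: int = 0,
    store_trajectories: bool = False,
    classify: str = "relax",
    boundary: str = "clip",
    swap_streams: bool = False,
) -> SimulationResult:
    """Euler–Maruyama integration of ``n_traj`` independent trajectories.

    X and E each draw their initial condition and Gaussian increments from
    their own child stream of the seed, split deterministically; with
    ``swap_streams`` the two streams are exchanged, which together with
    swapping a_X ↔ a_E realises the exact X↔E exchange symmetry.
    """
    if proto is None:
        proto = Protocol()
    ss = np.random.SeedSequence(seed)
    ss_x, ss_e = ss.spawn(2)
    if swap_streams:
        ss_x, ss_e = ss_e, ss_x
    rng_x = np.random.default_rng(ss_x)
    rng_e = np.random.default_rng(ss_e)

    X = rng_x.uniform(0.0, 0.1, n_traj)
    E = rng_e.uniform(0.0, 0.1, n_traj)
    amp = np.sqrt(p.D * p.dt)

    def step(X, E, k, a_x):
        fx, fe = vector_field(X, E, p, k, a_x)
        X = X + fx * p.dt + amp * rng_x.standard_normal(n_traj)
        E = E + fe * p.dt + amp * rng_e.standard_normal(n_traj)
        if boundary == "clip":
            np.clip(X, 0.0, None, out=X)
            np.clip(E, 0.0, None, out=E)
        elif boundary == "reflect":
            X = np.abs(X)
            E = np.abs(E)
        else:
            raise ValueError("boundary must be 'clip' or 'reflect'")
        if np.abs(X).max() > 1e6 or np.abs(E).max() > 1e6:
            raise RuntimeError("trajectory divergence: time step too large")
        return X, E

    # equilibration in the t=0 regime, with noise on
    a_x0 = p.a_x_on if proto.ra_on(0.0) else p.a_x_off
    for _ in range(proto.n_equil):
        X, E = step(X, E, p.k_pluri, a_x0)

    traj = None
    if store_trajectories:
        tX = np.empty((proto.n_iter + 1, n_traj))
        tE = np.empty((proto.n_iter + 1, n_traj))
        tX[0], tE[0] = X, E
    for i in range(proto.n_iter):
        hour = i * proto.dt_h
        k = p.k_pluri if hour < proto.t_exit_h else p.k_diff
        a_x = p.a_x_on if proto.ra_on(hour) else p.a_x_off
        X, E = step(X, E, k, a_x)
        if store_trajectories:
            tX[i + 1], tE[i + 1] = X, E
    if store_trajectories:
        traj = (tX, tE)

    labels = classify_attractor(X, E, p, proto, method=classify)
    f = float(np.mean(labels == "XEN"))
    return SimulationResult(
        final_X=X, final_E=E, labels=labels,
        xen_fraction=f, se=float(np.sqrt(f * (1 - f) / n_traj)),
        n_traj=n_traj, seed=seed, trajectories=traj,
    )


def simulate_trajectory(
    p: GRNParams, proto: Protocol | None = None, seed: int = 0, **kwargs
) -> Trajectory:
    """A single stored trajectory (propagation phase) with its attractor label."""
    if proto is None:
        proto = Protocol()
    res = simulate_ensemble(
        p, proto, n_traj=1, seed=seed, store_trajectories=True, **kwargs
    )
    tX, tE = res.trajectories
    hours = np.arange(proto.n_iter + 1) * proto.dt_h
    return Trajectory(X=tX[:, 0], E=tE[:, 0], hours=hours, label=str(res.labels[0]))


def run_protocol_sweep(
    p: GRNParams,
    lengths,
    mode: str = "pulse",
    D_list=(0.0001, 0.01),
    n_traj: int = 10000,
    seed: int = 0,
    t_exit_h: float = 12.0,
    common_random_numbers: bool = False,
) -> pd.DataFrame:
    """XEN-attractor frequency versus RA-pulse length or RA-onset delay.

    ``pulse``: RA on during [0, L]; ``delay``: RA on during [L, 96].  The
    pluripotency network is switched off after 12 h in all conditions.
    Each condition runs ``n_traj`` trajectories; fractions come with
    binomial standard errors.

    With ``common_random_numbers`` every condition reuses the same noise
    realisations (the same ``seed``), so differences between conditions
    reflect only the protocol — the standard pairing for monotonicity
    comparisons along the sweep.  By default each condition draws its own
    substream keyed by (mode, length, D), making every condition's result
    independent of which other conditions are swept.
    """
    if mode not in ("pulse", "delay"):
        raise ValueError("mode must be 'pulse' or 'delay'")
    verify_bistability(p)
    rows = []
    base = Protocol(t_exit_h=t_exit_h)
    for D in D_list:
        pD = GRNParams(**{**p.__dict__, "D": D})
        for L in lengths:
            if not 0 <= L <= base.t_final_h:
                raise ValueError("sweep lengths must lie in [0, t_final_h]")
            interval = (0.0, float(L)) if mode == "pulse" else (float(L), base.t_final_h)
            proto = Protocol(t_exit_h=t_exit_h, ra_intervals=(interval,))
            if common_random_numbers:
                cond_seed = int(seed)
            else:
                # tag by condition content, so a condition's substream does
                # not depend on which other conditions are swept alongside it
                tag = zlib.crc32(f"{mode}:{float(L):.10g}:{D:.10g}".encode()) % 2**31
                cond_seed = int(
                    np.random.SeedSequence([seed, tag]).generate_state(1)[0] % 2**31
                )
            res = simulate_ensemble(pD, proto, n_traj=n_traj, seed=cond_seed)
            rows.append(
                {
                    "mode": mode, "length_h": float(L), "D": D,
                    "xen_fraction": res.xen_fraction, "se": res.se,
                    "n_traj": n_traj,
                    "undecided_fraction": float(np.mean(res.labels == "undecided")),
                }
            )
    return pd.DataFrame(rows)
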