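"""Kinetic building blocks for delayed enzyme-kinetics biosensor models.

Two mechanisms for the irreversible one-complex enzyme reaction are covered:

* the Brown-type scheme, where enzyme and product reappear a random time
  ``tau`` after binding, with ``tau`` drawn from a shifted gamma density
  (no explicit complex variable), and
* the two-delay Michaelis-Menten scheme, where complex formation lags the
  encounter by ``tau1`` and complex breakdown lags by ``tau2``.

All concentrations are in mM, all times in seconds and all rate constants per
second (bimolecular rates per mM per second).  The time unit is a convention
of this package: amperometric responses of a few minutes and identified delays
of order 5-16 make seconds the natural scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "RateParamsBrown",
    "RateParamsMM",
    "SystemState",
    "HistorySpec",
    "Trajectory",
    "gamma_delay_density",
    "delay_mean",
    "delay_horizon",
    "rhs_brown",
    "rhs_mm2d",
    "product_integral",
    "gauss_legendre_panels",
]

MM_COLUMNS = ("nS", "nE", "nC", "nP")
BROWN_COLUMNS = ("nS", "nE", "nP")


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RateParamsBrown:
    """Rates of the distributed-delay (Brown) mechanism.

    Parameters
    ----------
    kd : float
        Bimolecular encounter rate, 1/(mM*s).
    a : float
        Rate parameter of the gamma delay density, 1/s.
    m : float
        Shape offset of the gamma density (dimensionless, >= 0).
    tau_min : float
        Minimal delay before enzyme/product reappear, s.
    c : float
        Confidence level in (0, 1) used to truncate the delay kernel at the
        horizon ``tau_M`` (Chebyshev one-sided bound).
    """

    kd: float
    a: float
    m: float
    tau_min: float
    c: float = 0.95

    def __post_init__(self) -> None:
        if self.kd < 0 or not self.a > 0:
            # kd = 0 is the degenerate no-reaction case (constant trajectory);
            # a must stay positive for the density to exist
            raise ValueError("kd must be >= 0 and a > 0")
        if self.m < 0:
            raise ValueError("gamma shape offset m must be >= 0")
        if self.tau_min < 0:
            raise ValueError("tau_min must be >= 0")
        if not (0.0 < self.c < 1.0):
            raise ValueError("confidence level c must lie in (0, 1)")


@dataclass(frozen=True)
class RateParamsMM:
    """Rates and delays of the two-delay Michaelis-Menten mechanism.

    ``k1`` (1/(mM*s)) drives complex formation with lag ``tau1``; ``k_m1``
    (1/s) is undelayed unbinding; ``k2`` (1/s) drives product release with
    lag ``tau2``.
    """

    k1: float
    k_m1: float
    k2: float
    tau1: float = 0.0
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k1, self.k_m1, self.k2) < 0:
            # zero rates give degenerate but well-defined (constant) dynamics
            raise ValueError("rate constants must be >= 0")
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("delays must be >= 0")
        if not (math.isfinite(self.tau1) and math.isfinite(self.tau2)):
            raise ValueError("delays must be finite")

    @property
    def tau_max(self) -> float:
        return max(self.tau1, self.tau2)


@dataclass(frozen=True)
class SystemState:
    """Concentrations (mM) of substrate, free enzyme, complex and product.

    Positivity is a property of trajectories, not enforced here: for large
    delays the model genuinely loses it.
    """

    nS: float
    nE: float
    nC: float = 0.0
    nP: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.nS, self.nE, self.nC, self.nP):
            if not math.isfinite(v):
                raise ValueError("state components must be finite")

    def as_array(self, columns: Sequence[str] = MM_COLUMNS) -> np.ndarray:
        return np.array([getattr(self, c) for c in columns], dtype=float)


@dataclass(frozen=True)
class HistorySpec:
    """Constant pre-history applied on ``[-tau_max, 0]``.

    The delayed model needs the state on a segment of length ``tau_max``
    before time zero; a constant segment equal to the initial state is the
    minimal admissible choice and the package default.
    """

    tau_max: float
    values: SystemState

    def __post_init__(self) -> None:
        if self.tau_max < 0:
            raise ValueError("tau_max must be >= 0")
        v = self.values
        if min(v.nS, v.nE, v.nC, v.nP) < 0:
            raise ValueError("history values must be non-negative")


# --------------------------------------------------------------------------
# trajectory container with cubic-Hermite dense output
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Uniform-grid time course with cubic Hermite dense interpolation.

    ``times`` is a strictly increasing uniform grid over ``[0, t_end]``;
    ``states``/``derivs`` hold the state and its time derivative at each
    node (the derivative grid makes the interpolant third order, matching
    the RK4 stepper that produces it).  Queries at ``t < 0`` return the
    constant history, so the trajectory effectively covers
    ``[-tau_max, t_end]``.
    """

    times: np.ndarray
    states: np.ndarray
    derivs: np.ndarray
    columns: tuple
    tau_max: float
    history: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.derivs = np.asarray(self.derivs, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two grid nodes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (len(self.times), len(self.columns)):
            raise ValueError("states shape does not match grid/columns")
        if self.derivs.shape != self.states.shape:
            raise ValueError("derivs shape does not match states")

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def at(self, t, *, extrapolate: bool = False) -> np.ndarray:
        """Dense state at time(s) ``t``; shape (d,) for scalar input.

        Raises ``ValueError`` outside ``[-tau_max, t_end]`` unless
        ``extrapolate`` (used internally by the steppers for sub-step
        overshoot of at most one grid interval).
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        tol = 1e-9 * max(1.0, abs(self.t_end))
        if not extrapolate:
            if np.any(t_arr < -self.tau_max - tol) or np.any(t_arr > self.t_end + tol):
                raise ValueError(
                    f"query time outside trajectory span [{-self.tau_max}, {self.t_end}]"
                )
        out = np.empty((len(t_arr), self.states.shape[1]))
        neg = t_arr < 0.0
        if np.any(neg):
            out[neg] = self.history
        pos = ~neg
        if np.any(pos):
            tq = t_arr[pos]
            h = self.step
            idx = np.clip((tq / h).astype(int), 0, len(self.times) - 2)
            th = (tq - self.times[idx]) / h
            th2 = th * th
            th3 = th2 * th
            h00 = 2 * th3 - 3 * th2 + 1
            h10 = th3 - 2 * th2 + th
            h01 = -2 * th3 + 3 * th2
            h11 = th3 - th2
            out[pos] = (
                h00[:, None] * self.states[idx]
                + (h * h10)[:, None] * self.derivs[idx]
                + h01[:, None] * self.states[idx + 1]
                + (h * h11)[:, None] * self.derivs[idx + 1]
            )
        if np.isscalar(t) or np.ndim(t) == 0:
            return out[0]
        return out

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.column_index(name)]

    def to_csv(self, path) -> None:
        """Write the grid as CSV with columns time,nS,nE[,nC],nP."""
        import pandas as pd

        df = pd.DataFrame({"time": self.times})
        for j, c in enumerate(self.columns):
            df[c] = self.states[:, j]
        df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# gamma delay kernel
# --------------------------------------------------------------------------

def gamma_delay_density(s, p: RateParamsBrown):
    """Shifted-gamma probability density of the regeneration delay.

    Zero for ``s <= tau_min``; for larger ``s`` equals
    ``a^(m+1)/Gamma(m+1) * (s-tau_min)^m * exp(-a (s-tau_min))``.
    Accepts scalars or arrays.
    """
    s_arr = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s_arr)):
        raise ValueError("delay argument must be finite")
    x = s_arr - p.tau_min
    out = np.zeros_like(s_arr, dtype=float)
    pos = x > 0
    if np.any(pos):
        logf = (
            (p.m + 1.0) * math.log(p.a)
            - math.lgamma(p.m + 1.0)
            + p.m * np.log(x[pos])
            - p.a * x[pos]
        )
        out[pos] = np.exp(logf)
    if np.isscalar(s) or np.ndim(s) == 0:
        return float(out)
    return out


def delay_mean(p: RateParamsBrown) -> float:
    """Mean regeneration delay E(tau) = tau_min + (m+1)/a."""
    return p.tau_min + (p.m + 1.0) / p.a


def delay_horizon(p: RateParamsBrown) -> float:
    """Kernel truncation horizon tau_M at confidence level ``p.c``.

    mean + sd/sqrt(1-c): by the one-sided Chebyshev bound, at most a
    fraction 1-c of the delay mass lies beyond this point.  Strictly
    increasing in c.
    """
    sd = math.sqrt(p.m + 1.0) / p.a
    return delay_mean(p) + sd / math.sqrt(1.0 - p.c)


def gauss_legendre_panels(lo: float, hi: float, n_panels: int = 8,
                          n_nodes: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights on [lo, hi] (>= 64 nodes default)."""
    x, w = leggauss(n_nodes)
    edges = np.linspace(lo, hi, n_panels + 1)
    nodes, weights = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        nodes.append(0.5 * (b - a) * x + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * w)
    return np.concatenate(nodes), np.concatenate(weights)


# --------------------------------------------------------------------------
# right-hand sides
# --------------------------------------------------------------------------

def distributed_binding_rate(t: float, history, p: RateParamsBrown,
                             nodes: np.ndarray | None = None,
                             weights: np.ndarray | None = None) -> float:
    """Quadrature of the delayed mass-action term D(t).

    D(t) = integral over the delay sigma in [tau_min, tau_M] of
    f(sigma) * nE(t - sigma) * nS(t - sigma), with the density evaluated
    exactly and the past state read from ``history`` (a callable mapping an
    array of times to an (n, >=2) array whose first two columns are nS, nE).
    """
    if nodes is None or weights is None:
        nodes, weights = gauss_legendre_panels(p.tau_min, delay_horizon(p))
    dens = gamma_delay_density(nodes, p)
    past = history(t - nodes)
    past = np.atleast_2d(np.asarray(past, dtype=float))
    return float(np.sum(weights * dens * past[:, 0] * past[:, 1]))


def rhs_brown(t: float, history, p: RateParamsBrown,
              nodes: np.ndarray | None = None,
              weights: np.ndarray | None = None) -> np.ndarray:
    """Time derivative of (nS, nE, nP) for the distributed-delay model.

    ``history`` must be queryable on ``[t - tau_M, t]`` (same convention as
    :func:`distributed_binding_rate`).  Substrate is consumed at the current
    encounter rate; enzyme and product are regenerated at the delayed rate D.
    """
    cur = np.atleast_2d(np.asarray(history(np.array([t])), dtype=float))[0]
    nS, nE = cur[0], cur[1]
    D = distributed_binding_rate(t, history, p, nodes, weights)
    enc = p.kd * nE * nS
    return np.array([-enc, -enc + p.kd * D, p.kd * D])


def rhs_mm2d(t: float, lagged: dict, p: RateParamsMM) -> np.ndarray:
    """Time derivative of (nS, nE, nC, nP) for the two-delay MM model.

    ``lagged`` supplies ``nS_lag1``/``nE_lag1`` (values at t - tau1),
    ``nC_lag2`` (value at t - tau2) and ``nC_now``.  The rows satisfy the
    conservation identities d(nE + nC)/dt = 0 and d(nS + nC + nP)/dt = 0
    exactly.
    """
    for v in lagged.values():
        if not math.isfinite(v):
            raise ValueError("lagged values must be finite")
    binding = p.k1 * lagged["nS_lag1"] * lagged["nE_lag1"]
    release = p.k2 * lagged["nC_lag2"]
    unbind = p.k_m1 * lagged["nC_now"]
    dS = unbind - binding
    dP = release
    dC = -dS - dP  # = binding - release - unbind; exact row-sum zero
    return np.array([dS, -dC, dC, dP])


def product_integral(nC_path, k2: float, tau2: float, nP0: float,
                     t: float, n_points: int = 2049) -> float:
    """Accumulated product nP(t) = nP0 + k2 * integral_0^t nC(s - tau2) ds.

    ``nC_path`` is a callable defined on [-tau2, t].  Composite-Simpson
    quadrature on a fine uniform grid; nondecreasing in t when the complex
    path is non-negative.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return float(nP0)
    from scipy.integrate import simpson

    s = np.linspace(0.0, t, n_points)
    vals = np.asarray([float(nC_path(si - tau2)) for si in s])
    return float(nP0 + k2 * simpson(vals, x=s))
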