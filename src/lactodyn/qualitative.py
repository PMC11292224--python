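"""Poincare sections and delay-induced bifurcations of the two-delay model.

A trajectory is cut with the plane nE = d, where d is the midline
(min nE + max nE)/2 of the post-transient window; the substrate values at
the upward crossings summarize the attractor: a point for a stable focus, a
finite set for a (possibly period-doubled) limit cycle, a scatter for more
complex dynamics.  Sweeping the binding delay tau1 with everything else
fixed at the identified optimum produces the bifurcation diagram; the first
tau1 whose crossing spread exceeds a small threshold locates the Hopf
bifurcation.

Trajectories that lose positivity are still sectioned (the loss time rides
along in the metadata); trajectories that escape to infinity — which
genuinely happens for large tau1 once positivity is gone — are recorded as
per-point failures and the sweep continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .dde_engine import DEFAULT_STEP, integrate_mm2d
from .model_core import HistorySpec, RateParamsMM, SystemState, Trajectory

__all__ = [
    "SectionPlane",
    "PoincareSection",
    "BifurcationDiagram",
    "midline_plane",
    "poincare_section",
    "bifurcation_sweep",
    "hopf_threshold",
    "cluster_count",
]

DEFAULT_SWEEP_TAU2 = 5.357829
DEFAULT_SWEEP_HORIZON = 2000.0
DEFAULT_TRANSIENT_FRAC = 0.5
DEFAULT_EPS = 1e-5  # mM; below the smallest reported cycle radius ~1e-4


@dataclass(frozen=True)
class SectionPlane:
    """Plane nE = d with a crossing direction filter."""

    d: float
    direction: Literal["up", "down", "both"] = "up"

    def __post_init__(self) -> None:
        if not np.isfinite(self.d):
            raise ValueError("plane level must be finite")
        if self.direction not in ("up", "down", "both"):
            raise ValueError("direction must be 'up', 'down' or 'both'")


@dataclass
class PoincareSection:
    """Crossing times and (nS, nC) states on the plane."""

    times: np.ndarray
    nS: np.ndarray
    nC: np.ndarray
    plane: SectionPlane
    transient_frac: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nS = np.asarray(self.nS, dtype=float)
        self.nC = np.asarray(self.nC, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("crossing times must be increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def spread(self) -> float:
        """max - min of the substrate crossing values (0 if < 2 points)."""
        if len(self.nS) < 2:
            return 0.0
        return float(self.nS.max() - self.nS.min())


@dataclass
class BifurcationDiagram:
    """Per-tau1 Poincare-section substrate values and their spreads."""

    tau1_grid: np.ndarray
    sections: list
    spreads: np.ndarray
    cluster_counts: np.ndarray
    failures: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau1_grid = np.asarray(self.tau1_grid, dtype=float)
        self.spreads = np.asarray(self.spreads, dtype=float)
        if np.any(np.diff(self.tau1_grid) <= 0):
            raise ValueError("tau1 grid must be increasing")

    def to_frame(self):
        """Long-format (tau1, nS) table of all section points."""
        import pandas as pd

        rows = [
            (t1, v)
            for t1, sec in zip(self.tau1_grid, self.sections)
            for v in np.asarray(sec, dtype=float)
        ]
        return pd.DataFrame(rows, columns=["tau1", "nS"])


def midline_plane(traj: Trajectory, transient_frac: float = DEFAULT_TRANSIENT_FRAC,
                  direction: str = "up") -> SectionPlane:
    """Section plane at the nE midline of the post-transient window."""
    if not (0.0 <= transient_frac < 1.0):
        raise ValueError("transient_frac must be in [0, 1)")
    nE = traj.column("nE")
    start = int(transient_frac * (len(nE) - 1))
    window = nE[start:]
    lo, hi = float(window.min()), float(window.max())
    if hi - lo < 1e-12:
        raise ValueError("nE is constant; the midline plane is degenerate")
    return SectionPlane(d=0.5 * (lo + hi), direction=direction)


def poincare_section(traj: Trajectory, plane: SectionPlane,
                     transient_frac: float = DEFAULT_TRANSIENT_FRAC) -> PoincareSection:
    """Locate plane crossings on the retained (post-transient) window.

    Sign changes of nE - d on the stored grid are refined with Brent root
    finding on the dense cubic interpolant, then the full state at the
    crossing time is interpolated.  Only the configured direction is kept
    (an empty section is a valid result).
    """
    if not (0.0 <= transient_frac < 1.0):
        raise ValueError("transient_frac must be in [0, 1)")
    iE = traj.column_index("nE")
    iS = traj.column_index("nS")
    iC = traj.column_index("nC") if "nC" in traj.columns else None
    start = int(transient_frac * (len(traj.times) - 1))
    t = traj.times[start:]
    g = traj.states[start:, iE] - plane.d

    up = (g[:-1] < 0) & (g[1:] >= 0)
    down = (g[:-1] > 0) & (g[1:] <= 0)
    if plane.direction == "up":
        hits = np.nonzero(up)[0]
    elif plane.direction == "down":
        hits = np.nonzero(down)[0]
    else:
        hits = np.nonzero(up | down)[0]

    times, s_vals, c_vals = [], [], []
    for i in hits:
        a, b = t[i], t[i + 1]
        if g[i + 1] == 0.0:
            t_star = b
        else:
            t_star = brentq(lambda x: traj.at(x)[iE] - plane.d, a, b,
                            xtol=1e-12, rtol=8.9e-16)
        state = traj.at(t_star)
        times.append(t_star)
        s_vals.append(state[iS])
        c_vals.append(state[iC] if iC is not None else 0.0)
    return PoincareSection(times=np.array(times), nS=np.array(s_vals),
                           nC=np.array(c_vals), plane=plane,
                           transient_frac=transient_frac)


def cluster_count(values: np.ndarray, gap: float) -> int:
    """Number of gap-separated clusters of section values (period indicator)."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        return 0
    return int(1 + np.sum(np.diff(v) > gap))


def bifurcation_sweep(p: RateParamsMM, tau1_grid,
                      init: SystemState,
                      hist: HistorySpec | None = None,
                      horizon: float = DEFAULT_SWEEP_HORIZON,
                      transient_frac: float = DEFAULT_TRANSIENT_FRAC,
                      step: float = DEFAULT_STEP,
                      eps: float = DEFAULT_EPS,
                      direction: str = "up") -> BifurcationDiagram:
    """Sweep tau1, sectioning each trajectory on its own nE midline.

    ``p`` supplies all parameters except tau1, which is replaced per grid
    point (tau2 stays fixed).  Integration failures (finite-time escape
    after positivity loss) are recorded in ``failures`` and the sweep
    continues; those grid points carry empty sections and NaN spreads.
    Deterministic for fixed inputs.
    """
    tau1_grid = np.asarray(tau1_grid, dtype=float)
    sections: list[np.ndarray] = []
    spreads = np.empty(len(tau1_grid))
    counts = np.empty(len(tau1_grid), dtype=int)
    failures: dict[float, str] = {}
    first_negative: dict[float, float | None] = {}
    for k, tau1 in enumerate(tau1_grid):
        p_k = replace(p, tau1=float(tau1))
        h_k = hist
        if h_k is not None and h_k.tau_max < p_k.tau_max:
            h_k = HistorySpec(tau_max=p_k.tau_max, values=h_k.values)
        try:
            traj = integrate_mm2d(p_k, init, hist=h_k, t_end=horizon, step=step)
        except (RuntimeError, FloatingPointError) as exc:
            failures[float(tau1)] = str(exc)
            sections.append(np.array([]))
            spreads[k] = np.nan
            counts[k] = 0
            continue
        first_negative[float(tau1)] = traj.metadata.get("first_negative_time")
        try:
            plane = midline_plane(traj, transient_frac, direction)
        except ValueError:
            sections.append(np.array([]))
            spreads[k] = 0.0
            counts[k] = 0
            continue
        sec = poincare_section(traj, plane, transient_frac)
        sections.append(sec.nS)
        spreads[k] = sec.spread
        counts[k] = cluster_count(sec.nS, gap=10.0 * eps)
    return BifurcationDiagram(
        tau1_grid=tau1_grid,
        sections=sections,
        spreads=spreads,
        cluster_counts=counts,
        failures=failures,
        metadata={
            "horizon": horizon,
            "transient_frac": transient_frac,
            "step": step,
            "eps": eps,
            "tau2": p.tau2,
            "first_negative_times": first_negative,
        },
    )


def hopf_threshold(diag: BifurcationDiagram, eps: float = DEFAULT_EPS):
    """Smallest tau1 whose section spread exceeds ``eps`` (None if none)."""
    if len(diag.tau1_grid) == 0:
        raise ValueError("empty bifurcation diagram")
    if eps <= 0:
        raise ValueError("eps must be positive")
    for tau1, spread in zip(diag.tau1_grid, diag.spreads):
        if np.isfinite(spread) and spread > eps:
            return float(tau1)
    return None


def phase_plot(diag_or_traj, kind: str = "nS_nE", ax=None):
    """Phase-plane plot (nS, nE) or (nS, nP) of a trajectory (diagnostic)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    traj: Trajectory = diag_or_traj
    x = traj.column("nS")
    y = traj.column("nE" if kind == "nS_nE" else "nP")
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(x, y, lw=0.7)
    ax.set_xlabel("nS (mM)")
    ax.set_ylabel(("nE" if kind == "nS_nE" else "nP") + " (mM)")
    return ax
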