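"""Product-to-current transduction for amperometric readout.

The measured current is tied to the accumulated product through a
Kohlrausch-form law ``I = Lambda_m0 * nP - K * nP**(3/2)``: the leading term
is linear in concentration (molar-conductivity-like gain at fixed potential)
and the 3/2-power term is the ionic-strength correction familiar from strong
electrolyte conductance.  Current units are arbitrary instrument units; the
two coefficients absorb the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Trajectory

__all__ = [
    "TransductionParams",
    "ResponseSeries",
    "current_from_product",
    "response_from_trajectory",
]

# Simulated product can undershoot zero by roundoff near the nP=0 start;
# anything below this is treated as genuine (upstream) positivity loss.
_NEG_TOL = 1e-9


@dataclass(frozen=True)
class TransductionParams:
    """Gain (current units per mM) and Kohlrausch coefficient (per mM^{3/2})."""

    lambda_m0: float
    K_kohl: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_m0 < 0 or self.K_kohl < 0:
            raise ValueError("transduction coefficients must be >= 0")


@dataclass
class ResponseSeries:
    """Sampled current vs time for one initial substrate concentration."""

    times: np.ndarray
    currents: np.ndarray
    nS0: float
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times.shape != self.currents.shape or self.times.ndim != 1:
            raise ValueError("times and currents must be equal-length 1-D arrays")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.nS0 > 0:
            raise ValueError("initial substrate concentration must be positive")


def current_from_product(nP, tp: TransductionParams):
    """Current for product concentration(s) nP >= 0 (mM).

    Raises on negative nP: transduction is only defined on physical
    concentrations, so upstream positivity loss must be surfaced rather than
    silently mapped.
    """
    nP_arr = np.asarray(nP, dtype=float)
    if np.any(nP_arr < 0):
        raise ValueError("current_from_product requires nP >= 0")
    out = tp.lambda_m0 * nP_arr - tp.K_kohl * nP_arr ** 1.5
    if np.isscalar(nP) or np.ndim(nP) == 0:
        return float(out)
    return out


def response_from_trajectory(traj: Trajectory, tp: TransductionParams,
                             sample_times) -> ResponseSeries:
    """Sample the trajectory's product at ``sample_times`` and transduce it.

    Product values within roundoff of zero (>= -1e-9 mM) are clamped to
    zero before transduction; anything more negative propagates the
    positivity error.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    vals = traj.at(sample_times)
    nP = vals[:, traj.column_index("nP")].copy()
    tiny = (nP < 0) & (nP >= -_NEG_TOL)
    nP[tiny] = 0.0
    nS0 = float(traj.at(0.0)[traj.column_index("nS")])
    return ResponseSeries(
        times=sample_times,
        currents=current_from_product(nP, tp),
        nS0=nS0 if nS0 > 0 else float(traj.states[0, traj.column_index("nS")]),
    )
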