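"""Synthetic amperometric response data.

The study's raw currents are not deposited, so this module generates
responses with the statistical structure the analysis assumes: one response
per initial substrate concentration (0.1, 0.5, 1.0, 2.5 mM by default),
about five minutes long at 1 s sampling, produced by the chosen kinetic
model plus the Kohlrausch transduction, with additive Gaussian noise whose
standard deviation defaults to 1% of each series' peak current.  Baseline
and washing phases of the real measurement cycle are not simulated; each
response starts at substrate addition (t = 0).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .identification import (
    DEFAULT_FIT_STEP,
    ParamVector,
    _simulate_response,
)
from .transduction import ResponseSeries

__all__ = ["ExperimentDesign", "generate_responses", "roundtrip_csv",
           "write_series_csv", "read_series_csv", "ResponseParseError"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling plan and noise level of the emulated experiment."""

    nS0_list: tuple = (0.1, 0.5, 1.0, 2.5)
    nE0: float = 1.139071
    nC0: float = 1e-9
    nP0: float = 1e-9
    sampling_interval: float = 1.0
    duration: float = 300.0
    noise_sd_frac: float = 0.01  # fraction of per-series peak current
    noise_sd: float | None = None  # absolute override, current units
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.nS0_list):
            raise ValueError("initial substrate concentrations must be positive")
        if min(self.nE0, self.nC0, self.nP0) <= 0:
            raise ValueError("initial concentrations must be strictly positive")
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("duration and sampling interval must be positive")
        if (self.noise_sd_frac < 0
                or (self.noise_sd is not None and self.noise_sd < 0)):
            raise ValueError("noise sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def sample_times(self) -> np.ndarray:
        n = int(math.floor(self.duration / self.sampling_interval + 1e-9))
        return self.sampling_interval * np.arange(1, n + 1)


def generate_responses(truth: ParamVector, design: ExperimentDesign,
                       model_kind: str | None = None,
                       step: float = DEFAULT_FIT_STEP) -> list:
    """Simulate noisy responses for every concentration (and replicate).

    Noise is independent Gaussian from a generator seeded with
    ``design.seed``; each series records the truth parameters and the seed
    in its label-free metadata (returned series carry ``nS0`` and a label
    ``nS0=<value>[_rep<r>]``).
    """
    if model_kind is not None and model_kind != truth.model_kind:
        raise ValueError("model_kind disagrees with the truth vector")
    rng = np.random.default_rng(design.seed)
    times = design.sample_times
    out: list[ResponseSeries] = []
    template = (design.nE0, design.nC0, design.nP0)
    for nS0 in design.nS0_list:
        clean = _simulate_response(
            truth,
            ResponseSeries(times=times, currents=np.zeros_like(times), nS0=nS0),
            init_template=template, step=step,
        )
        if design.noise_sd is not None:
            sd = design.noise_sd
        else:
            sd = design.noise_sd_frac * float(np.max(np.abs(clean)))
        for rep in range(design.replicates):
            noisy = clean + (rng.normal(0.0, sd, size=clean.shape) if sd > 0
                             else 0.0)
            label = f"nS0={nS0:g}" + (f"_rep{rep + 1}" if design.replicates > 1 else "")
            out.append(ResponseSeries(times=times.copy(), currents=noisy,
                                      nS0=nS0, label=label))
    return out


# --------------------------------------------------------------------------
# CSV round trip
# --------------------------------------------------------------------------

class ResponseParseError(ValueError):
    """Malformed response CSV; the message names the offending line."""


def write_series_csv(series: ResponseSeries, path) -> None:
    """Full-precision CSV: metadata comment line, header, then rows.

    Floats are written with ``repr`` (shortest round-trip form), so a
    read-back reproduces them bit for bit.
    """
    with open(path, "w") as fh:
        fh.write(f"# nS0_mM={float(series.nS0)!r}\n")
        fh.write("time,current\n")
        for t, i in zip(series.times, series.currents):
            fh.write(f"{float(t)!r},{float(i)!r}\n")


def read_series_csv(path) -> ResponseSeries:
    path = Path(path)
    nS0 = None
    times, currents = [], []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "nS0_mM=" in line:
                    try:
                        nS0 = float(line.split("nS0_mM=")[1].strip())
                    except ValueError as exc:
                        raise ResponseParseError(
                            f"{path}:{lineno}: bad nS0_mM value"
                        ) from exc
                continue
            if not header_seen:
                if line.replace(" ", "") != "time,current":
                    raise ResponseParseError(
                        f"{path}:{lineno}: expected header 'time,current'"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ResponseParseError(
                    f"{path}:{lineno}: expected two comma-separated values"
                )
            try:
                times.append(float(parts[0]))
                currents.append(float(parts[1]))
            except ValueError as exc:
                raise ResponseParseError(
                    f"{path}:{lineno}: non-numeric value"
                ) from exc
    if nS0 is None:
        raise ResponseParseError(
            f"{path}: missing '# nS0_mM=<value>' metadata line"
        )
    return ResponseSeries(times=np.array(times), currents=np.array(currents),
                          nS0=nS0, label=path.stem)


def roundtrip_csv(series_list, path) -> list:
    """Write every series under ``path`` (a directory) and read them back.

    A ``manifest.json`` lists the files in order; an empty input produces
    an empty manifest.  The read-back series reproduce times and currents
    bit for bit.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = []
    for k, series in enumerate(series_list):
        stem = series.label or f"series_{k}"
        stem = stem.replace("=", "_").replace(".", "p")
        fname = f"response_{stem}.csv"
        write_series_csv(series, path / fname)
        files.append(fname)
    with open(path / "manifest.json", "w") as fh:
        json.dump({"files": files}, fh, indent=2)
    return [read_series_csv(path / f) for f in files]
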