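"""PSMC output parsing and coalescent-to-natural-unit scaling.

PSMC infers historical effective population size from a diploid genome and
reports, per EM round, a scaled mutation rate theta0 and piecewise-constant
relative sizes lambda_k over time intervals t_k expressed in units of 2*N0
generations.  Converting to natural units follows the upstream plotting
convention::

    N0      = theta0 / (4 * u * s)
    Ne_k    = N0 * lambda_k
    years_k = 2 * N0 * t_k * g

with u the per-site per-generation substitution rate, s the bin size of the
consensus input (bp per site, conventionally 100) and g the generation time
in years.  Bootstrap replicates are aggregated into a median trajectory and
a pointwise quantile envelope on the union time grid (step interpolation,
so no Ne level is invented).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "PsmcResult",
    "NeTrajectory",
    "Envelope",
    "PsmcParseError",
    "parse_psmc_output",
    "scale_trajectory",
    "bootstrap_envelope",
]


class PsmcParseError(ValueError):
    """Raised when PSMC text output cannot be parsed."""


@dataclass
class PsmcResult:
    """Final-round PSMC parameters: theta0, rho0 and (t_k, lambda_k) segments."""

    theta0: float
    rho0: float
    segments: List[Tuple[float, float]]  # (t_k in 2N0 units, lambda_k)
    round_index: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise PsmcParseError("no segments")
        times = [t for t, _ in self.segments]
        if times[0] != 0.0:
            raise PsmcParseError(f"t_0 must be 0, got {times[0]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise PsmcParseError("t_k not strictly increasing")
        if any(lam <= 0 for _, lam in self.segments):
            raise PsmcParseError("lambda_k must be positive")


@dataclass
class NeTrajectory:
    """Piecewise-constant (years, Ne) history with its scaling constants."""

    years: np.ndarray
    ne: np.ndarray
    u: float
    s: float
    g: float

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if self.years.shape != self.ne.shape:
            raise ValueError("years and ne must have equal length")


@dataclass
class Envelope:
    years: np.ndarray
    median: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    quantiles: Tuple[float, float]


def parse_psmc_output(text: str) -> PsmcResult:
    """Parse PSMC text output, selecting the last round (RD block).

    Expects the TR line (theta0, rho0) and RS lines
    ``RS <k> <t_k> <lambda_k> ...`` of each round.
    """
    rounds: List[dict] = []
    current: dict | None = None
    for line in text.splitlines():
        fields = line.split()
        if not fields:
            continue
        tag = fields[0]
        if tag == "RD":
            current = {"index": int(fields[1]), "tr": None, "rs": []}
            rounds.append(current)
        elif tag == "TR" and current is not None:
            current["tr"] = (float(fields[1]), float(fields[2]))
        elif tag == "RS" and current is not None:
            current["rs"].append((float(fields[2]), float(fields[3])))
    rounds = [r for r in rounds if r["rs"]]
    if not rounds:
        raise PsmcParseError("no RS lines found in PSMC output")
    last = rounds[-1]
    if last["tr"] is None:
        raise PsmcParseError(f"round {last['index']} has no TR line")
    theta0, rho0 = last["tr"]
    return PsmcResult(theta0=theta0, rho0=rho0, segments=last["rs"], round_index=last["index"])


def scale_trajectory(
    res: PsmcResult,
    u: float = 2.5e-8,
    s: float = 100.0,
    g: float = 1.0,
) -> NeTrajectory:
    """Scale coalescent-unit segments to (years, Ne)."""
    if u <= 0:
        raise ValueError(f"u must be positive, got {u}")
    if s < 1:
        raise ValueError(f"s must be >= 1, got {s}")
    if g <= 0:
        raise ValueError(f"g must be positive, got {g}")
    n0 = res.theta0 / (4.0 * u * s)
    t = np.array([tk for tk, _ in res.segments])
    lam = np.array([lk for _, lk in res.segments])
    return NeTrajectory(years=2.0 * n0 * t * g, ne=n0 * lam, u=u, s=s, g=g)


def _step_values(traj: NeTrajectory, grid: np.ndarray) -> np.ndarray:
    """Step-interpolate a trajectory onto ``grid`` (value of the last point
    at or before each grid time; the first level extends back to t=0)."""
    idx = np.searchsorted(traj.years, grid, side="right") - 1
    idx = np.clip(idx, 0, len(traj.years) - 1)
    return traj.ne[idx]


def bootstrap_envelope(
    trajectories: Sequence[NeTrajectory],
    quantiles: Tuple[float, float] = (0.025, 0.975),
) -> Envelope:
    """Pointwise median and quantile band over bootstrap trajectories.

    Trajectories are resampled to the union of all time grids by step
    interpolation before the pointwise statistics are taken.
    """
    if not trajectories:
        raise ValueError("bootstrap_envelope needs at least one trajectory")
    grid = np.unique(np.concatenate([t.years for t in trajectories]))
    mat = np.vstack([_step_values(t, grid) for t in trajectories])
    lo_q, hi_q = quantiles
    return Envelope(
        years=grid,
        median=np.median(mat, axis=0),
        lo=np.quantile(mat, lo_q, axis=0),
        hi=np.quantile(mat, hi_q, axis=0),
        quantiles=quantiles,
    )
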