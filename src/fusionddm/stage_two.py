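"""Stage two: Ratcliff drift-diffusion decision stage.

A decision variable X starts at z between two absorbing boundaries (0 for
choice 'B', a for choice 'A') and follows the Langevin equation

    dX = v(t) dt + sigma dW,

with the Ratcliff across-trial variabilities: the starting point z and the
non-decision time t_nd are uniform (mean +/- width/2), and a Gaussian offset
with standard deviation eta is added to the drift once per trial.  The
reaction time is the non-decision time plus the first-passage time.

The diffusion coefficient sigma is an explicit parameter (default 1 in
boundary units per sqrt(ms)); fixing it sets the scale that makes boundary
separation and drift identifiable.  Simulation is Euler-Maruyama with a
Brownian-bridge absorption check (see ``_kernels``); ``t_start`` lets the
caller begin the diffusion at the decision-stage onset T2, with the drift
profile still evaluated on the stimulus clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._kernels import simulate_ddm
from .stage_one import DriftProfile

__all__ = [
    "StageTwoParams",
    "TrialOutcome",
    "simulate_trial",
    "simulate_condition",
    "hit_probability_constant_drift",
    "rt_distribution",
]


@dataclass(frozen=True)
class StageTwoParams:
    """Decision-stage parameters (boundary units are multiples of sigma-scale).

    a : boundary separation; upper boundary position (> 0).
    z_mean, z_width : starting-point mean and uniform range, inside (0, a).
    eta : across-trial drift standard deviation, boundary units per ms.
    tnd_mean, tnd_width : non-decision time mean and uniform range, ms.  The
        mean absorbs the decision-stage onset T2, buffering and motor delays.
    sigma : within-trial diffusion coefficient, boundary units per sqrt(ms).
    dt : Euler step, ms (<= 0.5).
    t_max : decision deadline, ms; trials that never cross are 'none'.
    """

    a: float = 1.0
    z_mean: float = 0.5
    z_width: float = 0.0
    eta: float = 0.0
    tnd_mean: float = 0.0
    tnd_width: float = 0.0
    sigma: float = 1.0
    dt: float = 0.1
    t_max: float = 5000.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and math.isfinite(self.a)):
            raise ValueError(f"a must be finite and > 0, got {self.a}")
        if self.z_width < 0 or self.tnd_width < 0 or self.eta < 0:
            raise ValueError("z_width, tnd_width and eta must be >= 0")
        if not (self.z_mean - self.z_width / 2 > 0 and self.z_mean + self.z_width / 2 < self.a):
            raise ValueError("starting-point range must lie strictly inside (0, a)")
        if self.tnd_mean - self.tnd_width / 2 < 0:
            raise ValueError("non-decision time range must be non-negative")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (0 < self.dt <= 0.5):
            raise ValueError(f"dt must be in (0, 0.5], got {self.dt}")
        if self.t_max <= 0:
            raise ValueError(f"t_max must be > 0, got {self.t_max}")


@dataclass(frozen=True)
class TrialOutcome:
    """One decision: choice 'A' (upper), 'B' (lower) or 'none' (deadline)."""

    choice: str
    rt: float
    condition_label: str = ""


def _drift_to_arrays(drift, t_start: float, dt: float, t_max: float):
    """Sample a drift specification onto the kernel's step grid.

    ``drift`` may be a number (constant), a :class:`DriftProfile` (sampled
    until its freeze time, constant afterwards) or a generic callable of
    absolute time (sampled over the whole horizon).  Midpoint sampling keeps
    the piecewise-constant approximation second-order accurate.
    """
    if isinstance(drift, (int, float, np.floating, np.integer)):
        return np.empty(0), float(drift)
    if isinstance(drift, DriftProfile):
        if drift.freeze_time <= t_start:
            return np.empty(0), float(drift.frozen_drift)
        n = int(math.ceil((drift.freeze_time - t_start) / dt))
        ts = t_start + (np.arange(n) + 0.5) * dt
        return np.asarray(drift(ts), dtype=float), float(drift.frozen_drift)
    if callable(drift):
        n = int(math.ceil(t_max / dt))
        ts = t_start + (np.arange(n) + 0.5) * dt
        try:
            arr = np.asarray(drift(ts), dtype=float)
            if arr.shape != ts.shape:
                raise TypeError
        except TypeError:
            arr = np.array([float(drift(t)) for t in ts])
        return arr, float(arr[-1]) if arr.size else 0.0
    raise TypeError(f"unsupported drift specification: {drift!r}")


def simulate_condition(
    p: StageTwoParams,
    drift,
    n: int,
    seed: int,
    t_start: float = 0.0,
    condition_label: str = "",
) -> pd.DataFrame:
    """Simulate ``n`` independent trials; reproducible for a given seed.

    Returns a trial table with columns condition_label, choice, rt_ms.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    arr, const = _drift_to_arrays(drift, t_start, p.dt, p.t_max)
    if not (np.all(np.isfinite(arr)) and math.isfinite(const)):
        raise ValueError("drift takes non-finite values")
    choices, rts = simulate_ddm(
        int(n),
        p.a,
        p.z_mean,
        p.z_width,
        p.eta,
        p.tnd_mean,
        p.tnd_width,
        p.sigma,
        p.dt,
        p.t_max,
        arr,
        const,
        int(seed) % (2**31 - 1),
    )
    label = np.array(["B", "none", "A"], dtype=object)
    return pd.DataFrame(
        {
            "condition_label": condition_label,
            "choice": label[choices.astype(int) + 1],
            "rt_ms": rts,
        }
    )


def simulate_trial(p: StageTwoParams, drift, seed: int, t_start: float = 0.0) -> TrialOutcome:
    """Simulate a single trial (see :func:`simulate_condition`)."""
    row = simulate_condition(p, drift, 1, seed, t_start=t_start).iloc[0]
    return TrialOutcome(choice=row["choice"], rt=float(row["rt_ms"]), condition_label="")


def hit_probability_constant_drift(v: float, p: StageTwoParams) -> float:
    """Exact probability of hitting the upper boundary under constant drift.

    P('A') = (1 - exp(-2 v z / sigma^2)) / (1 - exp(-2 v a / sigma^2)) for
    v != 0 and z/a at v = 0 (pure diffusion).  Assumes eta = z_width = 0.
    Evaluated in an overflow-safe form for drifts of either sign.
    """
    c = 2.0 * v / (p.sigma**2)
    if c == 0.0:
        return p.z_mean / p.a
    # both branches keep every exponent non-positive
    if c > 0:
        return float(np.expm1(-c * p.z_mean) / np.expm1(-c * p.a))
    return float(1.0 - np.expm1(c * (p.a - p.z_mean)) / np.expm1(c * p.a))


def rt_distribution(
    p: StageTwoParams,
    drift,
    n: int,
    seed: int,
    grid: np.ndarray | None = None,
    t_start: float = 0.0,
) -> dict:
    """Empirical signed-RT distribution of the model for one condition.

    The joint choice+RT distribution encodes 'B' decisions as negative and
    'A' decisions as positive reaction times, so both response channels form
    a single distribution (the device used for distribution-level fitting).

    Returns a dict with the sorted signed samples, per-choice marginals, the
    decided fraction, and the joint empirical CDF evaluated on ``grid`` (if
    given), normalised by the total trial count so it saturates at the
    decided fraction.
    """
    table = simulate_condition(p, drift, n, seed, t_start=t_start)
    decided = table[table["choice"] != "none"]
    signed = np.where(decided["choice"] == "A", decided["rt_ms"], -decided["rt_ms"])
    signed = np.sort(signed.astype(float))
    out = {
        "signed": signed,
        "rt_a": np.sort(decided.loc[decided["choice"] == "A", "rt_ms"].to_numpy()),
        "rt_b": np.sort(decided.loc[decided["choice"] == "B", "rt_ms"].to_numpy()),
        "decided_fraction": len(decided) / len(table),
    }
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        out["grid"] = grid
        out["cdf"] = np.searchsorted(signed, grid, side="right") / len(table)
    return out
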