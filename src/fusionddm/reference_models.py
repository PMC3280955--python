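"""One-stage reference models: the architectures the two-stage model is
contrasted against.

All variants share the stage-two noise and boundary conventions so that
differences between models isolate the integration architecture:

* ``one_stage_simulate`` -- the standard drift-diffusion model whose drift is
  the raw (delayed) input, zero after stimulus end.  For equal-duration fused
  pairs it predicts dominance of the *first* stimulus that grows with
  duration.
* ``leaky_one_stage_simulate`` -- an Ornstein-Uhlenbeck decision variable
  whose leak attracts toward the starting point; the leak pushes X toward the
  start, never across it, so the first stimulus still dominates.
* ``leak_off_variant_simulate`` -- leaky dynamics while the stimulus is on;
  at stimulus offset the leak is removed and the accumulated value serves as
  the initial condition of a free, unbiased diffusion.  This variant does
  produce second-stimulus dominance at intermediate durations (converting to
  first-stimulus dominance for long ones) but ties the integration result to
  the starting point rather than the drift.
* ``preprocessed_one_stage_simulate`` -- the leaky-integrator output k*E(t)
  used directly as a time-varying drift from the sensory delay onward, with
  no buffer and no fixed decision-stage onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import simulate_ddm, simulate_leaky
from .stage_one import StageOneParams, integrate_evidence
from .stage_two import StageTwoParams, simulate_condition
from .stimuli import StimulusSchedule, make_fusion_schedule, offset_time, signal_values

__all__ = [
    "OneStageParams",
    "one_stage_simulate",
    "leaky_one_stage_simulate",
    "leak_off_variant_simulate",
    "preprocessed_one_stage_simulate",
    "dominance_curve",
]


@dataclass(frozen=True)
class OneStageParams:
    """One-stage model parameters on top of the shared decision-stage set.

    mu : drift magnitude per unit input, boundary units per ms.
    leak : leak rate of the decision variable, per ms (0 for the leak-free
        standard model).
    delta : sensory delay, ms.
    """

    mu: float
    stage_two: StageTwoParams
    leak: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if self.leak < 0:
            raise ValueError(f"leak must be >= 0, got {self.leak}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")


def _stimulus_end(s: StimulusSchedule, delta: float) -> float:
    try:
        return offset_time(s) + delta
    except ValueError:  # all-blank schedule: zero input throughout
        return s.total_duration + delta


def _input_drift_arrays(p: OneStageParams, s: StimulusSchedule):
    """mu * u(t - delta) sampled at step midpoints; zero after stimulus end."""
    st = p.stage_two
    horizon = _stimulus_end(s, p.delta)
    n = int(math.ceil(horizon / st.dt))
    ts = (np.arange(n) + 0.5) * st.dt
    arr = p.mu * signal_values(s, ts - p.delta)
    return arr, 0.0


def one_stage_simulate(p: OneStageParams, s: StimulusSchedule, n: int, seed: int) -> pd.DataFrame:
    """Standard one-stage drift-diffusion: drift = mu * u(t - delta)."""
    if p.leak != 0:
        raise ValueError("one_stage_simulate requires leak = 0")
    arr, const = _input_drift_arrays(p, s)
    return _run(p.stage_two, arr, const, n, seed, s.condition_label, leak=0.0, leak_off=np.inf)


def leaky_one_stage_simulate(
    p: OneStageParams, s: StimulusSchedule, n: int, seed: int
) -> pd.DataFrame:
    """Leaky one-stage model: dX = (mu u(t-delta) - leak (X - z)) dt + sigma dW."""
    if p.leak <= 0:
        raise ValueError("leaky_one_stage_simulate requires leak > 0")
    arr, const = _input_drift_arrays(p, s)
    return _run(
        p.stage_two, arr, const, n, seed, s.condition_label, leak=p.leak, leak_off=np.inf
    )


def leak_off_variant_simulate(
    p: OneStageParams, s: StimulusSchedule, n: int, seed: int
) -> pd.DataFrame:
    """Leaky integration while the stimulus is on, free diffusion afterwards.

    At stimulus offset the leak is set to zero, so the accumulated value is
    the initial condition of an unbiased diffusion.
    """
    if p.leak <= 0:
        raise ValueError("leak_off_variant_simulate requires leak > 0")
    arr, const = _input_drift_arrays(p, s)
    return _run(
        p.stage_two,
        arr,
        const,
        n,
        seed,
        s.condition_label,
        leak=p.leak,
        leak_off=_stimulus_end(s, p.delta),
    )


def preprocessed_one_stage_simulate(
    p: OneStageParams,
    s: StimulusSchedule,
    tau: float,
    k: float,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Leaky-integrator output used directly as a time-variant drift.

    v(t) = k * E(t) from the sensory delay onward -- no buffer, no fixed
    decision-stage onset; after the stimulus E decays freely toward zero.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    st = p.stage_two
    s1 = StageOneParams(tau=tau, k=k, delta=p.delta, T2=p.delta + 1e-9 if p.delta else 1e-9)
    horizon = _stimulus_end(s, p.delta) + 10.0 * tau  # E has decayed to ~0 beyond
    m = int(math.ceil(horizon / st.dt))
    ts = (np.arange(m) + 0.5) * st.dt
    arr = k * np.asarray(integrate_evidence(s, s1, ts), dtype=float)
    return _run(st, arr, 0.0, n, seed, s.condition_label, leak=0.0, leak_off=np.inf)


def _run(st, arr, const, n, seed, label, leak, leak_off):
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    seed = int(seed) % (2**31 - 1)
    if leak == 0.0 and np.isinf(leak_off):
        choices, rts = simulate_ddm(
            int(n), st.a, st.z_mean, st.z_width, st.eta, st.tnd_mean, st.tnd_width,
            st.sigma, st.dt, st.t_max, np.asarray(arr, dtype=float), float(const), seed,
        )
    else:
        choices, rts = simulate_leaky(
            int(n), st.a, st.z_mean, st.z_width, st.tnd_mean, st.tnd_width,
            st.sigma, st.dt, st.t_max, np.asarray(arr, dtype=float), float(const),
            float(leak), float(leak_off), seed,
        )
    lab = np.array(["B", "none", "A"], dtype=object)
    return pd.DataFrame(
        {"condition_label": label, "choice": lab[choices.astype(int) + 1], "rt_ms": rts}
    )


def dominance_curve(
    simulator,
    durations,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """First-stimulus dominance of a simulator over equal-duration fused pairs.

    ``simulator(schedule, n, seed) -> trial table``.  Returns one row per
    per-vernier duration with the fraction of 'A' decisions among decided
    trials and its binomial standard error.
    """
    durations = list(durations)
    if not durations:
        raise ValueError("durations must be nonempty")
    rows = []
    for i, d in enumerate(durations):
        s = make_fusion_schedule(d, d, 0.0)
        table = simulator(s, n, seed + 1000 * i)
        decided = table[table["choice"] != "none"]
        nd = len(decided)
        p_a = float((decided["choice"] == "A").mean()) if nd else np.nan
        se = math.sqrt(p_a * (1 - p_a) / nd) if nd else np.nan
        rows.append({"duration_ms": d, "p_first": p_a, "se": se, "n_decided": nd})
    return pd.DataFrame(rows)
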