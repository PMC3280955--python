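"""Stage one: noise-free leaky evidence integration, buffering, novelty trigger.

The sensory input u(t) (+1 for vernier 'A', -1 for 'B', 0 for blank) is
low-pass filtered by a leaky integrator

    dE/dt = (u(t - delta) - E) / tau,        E(0) = 0,

whose fixed point under constant input u is u itself, so E stays in [-1, 1]
for bounded input; any input gain is absorbed into the drift scaling k of the
decision stage.  Because the input is piecewise constant, E has an exact
piecewise-exponential closed form, which is what this module evaluates.

At stimulus termination (plus the sensory delay delta) the integrated
evidence is frozen ("written into a buffer").  The decision stage starts at a
fixed time T2 after stimulus onset:

* stimulus ends before T2  ->  the buffered value k*E(t_off) is the constant
  mean drift of the decision stage;
* stimulus outlasts T2     ->  the momentary k*E(t) drives the decision stage
  until the offset, after which the drift is frozen at the buffered value.

The moment of buffering is set by a Bayesian novelty detector: a hidden-state
filter over {A, B, blank} watching a noisy sample of the stimulus.  The
novelty channel observes stimulus *presence* (|u|), so a direct A -> B switch
produces no novelty transient, while onsets from and offsets into the blank
background do -- the model's account of why fused verniers are not perceived
individually unless a blank gap separates them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stimuli import StimulusSchedule, offset_time, signal_values

__all__ = [
    "StageOneParams",
    "EvidenceTrace",
    "NoveltyParams",
    "NoveltyTrace",
    "DriftProfile",
    "integrate_evidence",
    "evidence_trace",
    "evidence_at_offset",
    "drift_profile",
    "novelty_trace",
    "buffer_time_from_novelty",
]


@dataclass(frozen=True)
class StageOneParams:
    """Leaky-integration stage parameters.

    tau : leak time constant, ms (> 0).
    k : drift scaling, boundary units per ms per unit of integrated evidence.
    delta : sensory delay, ms; shifts the input in time only, the rest of the
        latency is folded into the non-decision time of the decision stage.
    T2 : decision-stage onset, ms after stimulus onset.
    """

    tau: float
    k: float
    delta: float = 0.0
    T2: float = 100.0

    def __post_init__(self) -> None:
        for name in ("tau", "k", "delta", "T2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.T2 <= self.delta:
            raise ValueError(f"T2 ({self.T2}) must exceed delta ({self.delta})")


@dataclass(frozen=True)
class EvidenceTrace:
    """Sampled evidence E(t) together with the buffered value."""

    times: np.ndarray
    values: np.ndarray
    buffer_time: float
    buffered_value: float


def _input_pieces(s: StimulusSchedule, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Edges and values of the delayed input u(t - delta).

    Returns (edges, u) where the input equals u[i] on [edges[i], edges[i+1])
    and 0 on [edges[-1], inf).  edges[0] = 0.
    """
    seg_edges = s.boundaries() + delta
    pols = s.polarities()
    edges = [0.0]
    vals: list[float] = []
    if delta > 0:
        vals.append(0.0)
        edges.append(seg_edges[0])
    for i, p in enumerate(pols):
        if seg_edges[i + 1] > edges[-1]:
            vals.append(float(p))
            edges.append(float(seg_edges[i + 1]))
    return np.asarray(edges), np.asarray(vals)


def _evidence_at_edges(edges: np.ndarray, u: np.ndarray, tau: float) -> np.ndarray:
    """E at every input edge, by the exact per-segment exponential update."""
    E = np.zeros(len(edges))
    for i in range(len(u)):
        d = edges[i + 1] - edges[i]
        decay = math.exp(-d / tau)
        E[i + 1] = u[i] * (1.0 - decay) + E[i] * decay
    return E


def integrate_evidence(s: StimulusSchedule, p: StageOneParams, t):
    """Closed-form E(t) of the leaky integrator driven by the delayed input.

    Accepts a scalar or array ``t`` (ms); E(t) = 0 for t <= 0.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    edges, u = _input_pieces(s, p.delta)
    E_edges = _evidence_at_edges(edges, u, p.tau)
    idx = np.searchsorted(edges, t_arr, side="right") - 1
    idx = np.clip(idx, 0, None)
    out = np.zeros_like(t_arr)
    pos = t_arr > 0
    # inside piece i: relax from E(edge_i) toward u_i
    inside = pos & (idx < len(u))
    if np.any(inside):
        i = idx[inside]
        dtau = (t_arr[inside] - edges[i]) / p.tau
        out[inside] = u[i] + (E_edges[i] - u[i]) * np.exp(-dtau)
    # beyond the last edge: free decay toward 0
    after = pos & (idx >= len(u))
    if np.any(after):
        dtau = (t_arr[after] - edges[-1]) / p.tau
        out[after] = E_edges[-1] * np.exp(-dtau)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def evidence_at_offset(s: StimulusSchedule, p: StageOneParams) -> float:
    """Buffered evidence: E at stimulus termination plus the sensory delay."""
    return float(integrate_evidence(s, p, offset_time(s) + p.delta))


def evidence_trace(s: StimulusSchedule, p: StageOneParams, times: np.ndarray) -> EvidenceTrace:
    t_off = offset_time(s) + p.delta
    return EvidenceTrace(
        times=np.asarray(times, dtype=float),
        values=np.asarray(integrate_evidence(s, p, times), dtype=float),
        buffer_time=t_off,
        buffered_value=evidence_at_offset(s, p),
    )


class DriftProfile:
    """Mean drift rate v(t) of the decision stage for one stimulus schedule.

    v(t) = 0 before the decision-stage onset T2.  If the (delayed) stimulus
    ends at t_off <= T2 the buffered value k*E(t_off) is the constant drift
    for all t >= T2; otherwise the momentary k*E(t) drives the decision stage
    on [T2, t_off] and is frozen at the buffered value afterwards.
    """

    def __init__(self, schedule: StimulusSchedule, params: StageOneParams):
        self.schedule = schedule
        self.params = params
        self.onset = params.T2
        self.freeze_time = offset_time(schedule) + params.delta
        self.frozen_drift = params.k * evidence_at_offset(schedule, params)
        #: True when the stimulus ended before T2 and the drift is constant.
        self.is_buffered = self.freeze_time <= params.T2

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full_like(t_arr, self.frozen_drift)
        if not self.is_buffered:
            live = (t_arr >= self.onset) & (t_arr <= self.freeze_time)
            if np.any(live):
                out[live] = self.params.k * integrate_evidence(
                    self.schedule, self.params, t_arr[live]
                )
        out[t_arr < self.onset] = 0.0
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "buffered" if self.is_buffered else "time-varying"
        return (
            f"DriftProfile({self.schedule.condition_label!r}, {kind}, "
            f"frozen={self.frozen_drift:.4g}, t_off={self.freeze_time:g})"
        )


def drift_profile(s: StimulusSchedule, p: StageOneParams) -> DriftProfile:
    """Drift of the decision stage implied by stage one for this schedule."""
    return DriftProfile(s, p)


# ---------------------------------------------------------------------------
# Bayesian novelty trigger
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoveltyParams:
    """Parameters of the change-detection filter that triggers buffering.

    hazard : per-ms prior probability that the hidden stimulus state changes.
    obs_sd : standard deviation of the Gaussian observation noise (signal units).
    threshold : novelty level whose upward crossing marks a trigger event.
    dt : sampling step of the discrete-time filter, ms.
    """

    hazard: float = 0.01
    obs_sd: float = 0.2
    threshold: float = 0.5
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.hazard < 1:
            raise ValueError(f"hazard must be in (0, 1), got {self.hazard}")
        if self.obs_sd <= 0:
            raise ValueError(f"obs_sd must be > 0, got {self.obs_sd}")
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")


@dataclass(frozen=True)
class NoveltyTrace:
    """Novelty signal, trigger events and the signed-hypothesis posterior."""

    times: np.ndarray
    novelty: np.ndarray
    events: np.ndarray  # times of upward threshold crossings
    posterior: np.ndarray  # (n_times, 3) over hypotheses (A, B, blank)


def _gauss(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mean) / sd) ** 2)


def novelty_trace(
    s: StimulusSchedule,
    np_params: NoveltyParams,
    rng_seed: int,
    pad: float = 25.0,
) -> NoveltyTrace:
    """Run the Bayesian change detector over one stimulus schedule.

    Two observation channels are sampled every ``dt`` from the noise-free
    signal with independent Gaussian noise: a signed channel (means +1/-1/0
    under A/B/blank) that feeds the three-hypothesis posterior, and a
    presence channel (|u| + noise, means 1/0) that feeds the novelty signal.

    The novelty signal compares the hazard-weighted predictive probability of
    the current presence observation under persistence of the running
    maximum-posterior presence hypothesis against the best alternative
    presence level:

        N(t) = 1 - (1-h) p(y|persist) / [(1-h) p(y|persist) + h p(y|alt)]

    so N exceeds 1/2 exactly when a change of presence is the better (prior-
    weighted) explanation of the sample.  Events are upward crossings of
    ``threshold``; a direct A -> B switch leaves the presence channel flat
    and produces none.
    """
    rng = np.random.default_rng(rng_seed)
    dt = np_params.dt
    n = int(math.floor((s.total_duration + pad) / dt)) + 1
    times = np.arange(n) * dt
    u = signal_values(s, times)
    y_signed = u + rng.normal(0.0, np_params.obs_sd, size=n)
    y_pres = np.abs(u) + rng.normal(0.0, np_params.obs_sd, size=n)

    hz = min(np_params.hazard * dt, 0.5)
    sd = np_params.obs_sd

    # --- three-hypothesis (A, B, blank) posterior on the signed channel ----
    means3 = np.array([1.0, -1.0, 0.0])
    post3 = np.zeros((n, 3))
    p3 = np.array([0.0, 0.0, 1.0])  # blank background before the trial
    trans_stay = 1.0 - hz
    for j in range(n):
        pred = trans_stay * p3 + (hz / 2.0) * (p3.sum() - p3)
        like = _gauss(y_signed[j], means3, sd)
        p3 = pred * like
        tot = p3.sum()
        p3 = p3 / tot if tot > 0 else np.array([1 / 3, 1 / 3, 1 / 3])
        post3[j] = p3

    # --- presence-channel filter and novelty signal ------------------------
    means2 = np.array([1.0, 0.0])  # (present, absent)
    p2 = np.array([0.0, 1.0])
    novelty = np.zeros(n)
    for j in range(n):
        map_idx = int(np.argmax(p2))  # persistence hypothesis from t - dt
        like = _gauss(y_pres[j], means2, sd)
        w_persist = (1.0 - hz) * like[map_idx]
        w_alt = hz * like[1 - map_idx]
        denom = w_persist + w_alt
        novelty[j] = 1.0 - (w_persist / denom) if denom > 0 else 1.0
        pred = np.array(
            [trans_stay * p2[0] + hz * p2[1], trans_stay * p2[1] + hz * p2[0]]
        )
        p2 = pred * like
        tot = p2.sum()
        p2 = p2 / tot if tot > 0 else np.array([0.5, 0.5])

    above = novelty >= np_params.threshold
    prev = np.concatenate([[False], above[:-1]])
    events = times[above & ~prev]
    return NoveltyTrace(times=times, novelty=novelty, events=events, posterior=post3)


def buffer_time_from_novelty(events: np.ndarray, s: StimulusSchedule) -> float:
    """First offset-type novelty event: the trigger that freezes integration.

    Offset-type means the schedule has entered a blank (or ended) at the event
    time; for a fused A->B pair this is the termination of 'B'.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("no novelty events supplied")
    pres = np.abs(signal_values(s, events))
    off = events[pres == 0]
    if off.size == 0:
        raise ValueError("no stimulus-offset event found: stimulus unterminated")
    return float(off[0])
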