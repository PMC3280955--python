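"""Distribution-level fitting of the decision stage and stage-one recovery.

The decision stage is fitted to joint choice/reaction-time data: per
condition, 'B' decisions are encoded as negative and 'A' decisions as
positive reaction times ("signed RTs") so that both response channels form a
single distribution.  The fit quality of a parameter set is the product over
conditions of the two-sample Kolmogorov-Smirnov p-values between the data
and a model-simulated sample; the product is *maximised*.  Model samples use
fixed nested seeds (common random numbers) so the objective is deterministic
for the optimiser.

Stage-one parameters (tau, k) are then recovered from per-condition fitted
drifts by least squares against the buffered evidence k*E(t_off; tau), with
tau scanned on a grid and k solved in closed form per tau.  The decision-
stage onset T2 is located by a line scan minimising the mean squared error
of the predicted dominance, using conditions long enough to outlast T2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stage_one import StageOneParams, drift_profile, evidence_at_offset
from .stage_two import StageTwoParams, hit_probability_constant_drift, simulate_condition
from .stimuli import StimulusSchedule

__all__ = [
    "FitConfig",
    "FitResult",
    "FreeDriftFit",
    "signed_rt",
    "ks_pvalue",
    "ks_product_objective",
    "fit_decision_stage",
    "fit_free_drifts",
    "fit_stage_one_from_drifts",
    "calibrate_stage_one_to_dominance",
    "scan_T2",
    "compare_drifts",
]

_SHARED_FIELDS = ("a", "z_mean", "z_width", "eta", "tnd_mean", "tnd_width")

_DEFAULT_BOUNDS = {
    "a": (0.5, 4.0),
    "z_mean": (0.05, 3.95),
    "z_width": (0.0, 1.0),
    "eta": (0.0, 0.02),
    "tnd_mean": (100.0, 600.0),
    "tnd_width": (0.0, 300.0),
    "drift": (-0.05, 0.05),
}


@dataclass
class FitConfig:
    """Settings of the KS product fit.

    free_parameters : names of parameters allowed to vary.  Shared decision-
        stage fields by name ('a', 'z_mean', ...); per-condition entries as
        '<field>:<label>' (e.g. 'drift:A20_I0_B20', 'eta:A10_I0_B10').
    bounds : per-parameter (lo, hi); missing names fall back to defaults
        ('drift:<label>' falls back to the 'drift' entry).
    n_model_trials : simulated trials per condition per objective evaluation.
    optimizer_seed : base seed for the nested common-random-number streams.
    restarts : number of simplex starts (first from the initial values, the
        rest drawn uniformly inside bounds).
    """

    free_parameters: tuple[str, ...] = ()
    bounds: dict = field(default_factory=dict)
    n_model_trials: int = 10_000
    optimizer_seed: int = 0
    restarts: int = 5

    def __post_init__(self) -> None:
        self.free_parameters = tuple(self.free_parameters)
        if self.n_model_trials < 10_000:
            raise ValueError("n_model_trials must be >= 10^4")
        for name, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lo < hi")

    def bound_for(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        base = name.split(":", 1)[0]
        if base in self.bounds:
            return self.bounds[base]
        if base in _DEFAULT_BOUNDS:
            return _DEFAULT_BOUNDS[base]
        raise KeyError(f"no bounds known for parameter {name!r}")


@dataclass
class FitResult:
    """Fitted parameters with per-condition KS diagnostics."""

    params: StageTwoParams
    drifts: dict
    objective: float
    per_condition: dict  # label -> (D, p)
    converged: bool
    trace: list = field(default_factory=list)


@dataclass
class FreeDriftFit:
    """One condition's free-drift estimate."""

    drift: float
    D: float
    p: float
    se: float | None = None
    bootstrap: np.ndarray | None = None


def signed_rt(table: pd.DataFrame) -> np.ndarray:
    """Signed reaction times: +rt for choice 'A', -rt for choice 'B'."""
    if (table["choice"] == "none").any():
        raise ValueError("signed_rt requires decided trials only")
    return np.where(table["choice"] == "A", table["rt_ms"], -table["rt_ms"]).astype(float)


def _ks_sorted(data: np.ndarray, model: np.ndarray) -> tuple[float, float]:
    """Two-sample KS (D, asymptotic p) for pre-sorted samples.

    D is the exact supremum distance between the two empirical CDFs; the
    p-value is the asymptotic Kolmogorov distribution evaluated at
    (en + 0.12 + 0.11/en) * D with en = sqrt(n1 n2 / (n1 + n2)), the
    classical finite-sample-corrected form.
    """
    n1, n2 = data.size, model.size
    grid = np.concatenate([data, model])
    cdf1 = np.searchsorted(data, grid, side="right") / n1
    cdf2 = np.searchsorted(model, grid, side="right") / n2
    d = float(np.max(np.abs(cdf1 - cdf2)))
    en = math.sqrt(n1 * n2 / (n1 + n2))
    return d, float(min(stats.kstwobign.sf((en + 0.12 + 0.11 / en) * d), 1.0))


def ks_pvalue(data: np.ndarray, model: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value, data vs model sample."""
    data = np.asarray(data, dtype=float)
    model = np.asarray(model, dtype=float)
    if data.size == 0 or model.size == 0:
        raise ValueError("both samples must be nonempty")
    if data.size < 5 or model.size < 5:
        warnings.warn("fewer than 5 observations in a KS sample; p-value unreliable")
    return _ks_sorted(np.sort(data), np.sort(model))


def _condition_seed(base: int, index: int) -> int:
    return (int(base) * 7919 + 104729 * (index + 1)) % (2**31 - 1)


def _simulate_signed(params: StageTwoParams, drift, n: int, seed: int, t_start: float):
    table = simulate_condition(params, drift, n, seed, t_start=t_start)
    decided = table[table["choice"] != "none"]
    if len(decided) == 0:
        return np.empty(0)
    return signed_rt(decided)


def ks_product_objective(
    data_by_condition: dict,
    drifts_by_condition: dict,
    params: StageTwoParams,
    config: FitConfig,
    t_starts: dict | None = None,
    overrides: dict | None = None,
    details: bool = False,
):
    """Product over conditions of KS p-values between data and model samples.

    ``drifts_by_condition`` maps label -> constant drift or drift profile;
    ``overrides`` maps label -> dict of StageTwoParams replacements (used for
    per-condition free parameters such as eta).  A condition whose model run
    yields no decided trials contributes p = 0.  To be maximised.
    """
    labels = sorted(data_by_condition)
    per = {}
    prod = 1.0
    for i, label in enumerate(labels):
        if label not in drifts_by_condition:
            raise KeyError(f"no drift specified for condition {label!r}")
        p_c = params if not overrides or label not in overrides else replace(
            params, **overrides[label]
        )
        t0 = 0.0 if t_starts is None else float(t_starts.get(label, 0.0))
        model = _simulate_signed(
            p_c,
            drifts_by_condition[label],
            config.n_model_trials,
            _condition_seed(config.optimizer_seed, i),
            t0,
        )
        if model.size == 0:
            warnings.warn(f"condition {label!r}: no decided model trials, p = 0")
            per[label] = (1.0, 0.0)
            prod = 0.0
            continue
        D, p = ks_pvalue(np.asarray(data_by_condition[label], dtype=float), model)
        per[label] = (D, p)
        prod *= p
    return (prod, per) if details else prod


def _unpack(vec, names, base_params: StageTwoParams, base_drifts: dict):
    shared = {}
    overrides: dict[str, dict] = {}
    drifts = dict(base_drifts)
    for name, value in zip(names, vec):
        fld, _, label = name.partition(":")
        if fld == "drift":
            drifts[label] = float(value)
        elif label:
            overrides.setdefault(label, {})[fld] = float(value)
        else:
            shared[fld] = float(value)
    try:
        params = replace(base_params, **shared)
    except ValueError:
        return None, None, None
    for label, ov in overrides.items():
        try:
            replace(params, **ov)
        except ValueError:
            return None, None, None
    return params, drifts, overrides


def fit_decision_stage(
    data_by_condition: dict,
    config: FitConfig,
    base_params: StageTwoParams,
    drifts_by_condition: dict | None = None,
    t_starts: dict | None = None,
) -> FitResult:
    """Maximise the KS p-value product over the free parameters.

    Derivative-free simplex (Nelder-Mead) on the summed log p-values, with
    ``config.restarts`` starts; shared parameters are common across
    conditions, per-condition entries ('drift:<label>', 'eta:<label>') vary
    independently.  Parameters not freed keep their values from
    ``base_params`` / ``drifts_by_condition``.
    """
    names = list(config.free_parameters)
    if not names:
        raise ValueError("config.free_parameters must be nonempty")
    base_drifts = dict(drifts_by_condition or {})
    for name in names:
        fld, _, label = name.partition(":")
        if fld == "drift":
            base_drifts.setdefault(label, 0.0)
    missing = set(data_by_condition) - set(base_drifts)
    if missing:
        raise KeyError(f"no drift for conditions {sorted(missing)}")
    bounds = [config.bound_for(n) for n in names]
    rng = np.random.default_rng(config.optimizer_seed)
    trace: list[float] = []

    def neg_log_obj(vec):
        params, drifts, overrides = _unpack(vec, names, base_params, base_drifts)
        if params is None:
            return 1e9
        prod = ks_product_objective(
            data_by_condition, drifts, params, config, t_starts=t_starts, overrides=overrides
        )
        trace.append(prod)
        if prod <= 0:
            return 1e9
        return -math.log(prod)

    def initial_vector():
        out = []
        for name, (lo, hi) in zip(names, bounds):
            fld, _, label = name.partition(":")
            if fld == "drift":
                v0 = base_drifts.get(label, 0.0)
                v0 = v0.frozen_drift if hasattr(v0, "frozen_drift") else float(v0)
            else:
                src = base_params
                v0 = getattr(src, fld)
            out.append(min(max(float(v0), lo), hi))
        return np.array(out)

    best = None
    converged = False
    starts = [initial_vector()] + [
        np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        for _ in range(max(0, config.restarts - 1))
    ]
    for x0 in starts:
        res = optimize.minimize(
            neg_log_obj,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-4, "fatol": 1e-3, "maxiter": 400 * len(names)},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    params, drifts, overrides = _unpack(best.x, names, base_params, base_drifts)
    prod, per = ks_product_objective(
        data_by_condition, drifts, params, config,
        t_starts=t_starts, overrides=overrides, details=True,
    )
    return FitResult(
        params=params, drifts=drifts, objective=prod,
        per_condition=per, converged=converged, trace=trace,
    )


# ---------------------------------------------------------------------------
# Gridded per-condition free-drift fit (library of model samples shared
# across conditions; used by the parameter-recovery study)
# ---------------------------------------------------------------------------


def _drift_library(params: StageTwoParams, v_grid: np.ndarray, n: int, seed: int):
    """Sorted signed-RT model samples, one per grid drift.

    A single seed is shared by every grid entry (common random numbers in the
    drift), so the KS objective varies smoothly along the grid and its argmax
    is not jittered by independent model-sampling noise.
    """
    lib_seed = _condition_seed(seed, 0)
    return [
        np.sort(_simulate_signed(params, float(v), n, lib_seed, 0.0)) for v in v_grid
    ]


def _grid_argmax_refine(v_grid, logp, drop: float = 2.0):
    """Sub-grid drift estimate: vertex of a quadratic fitted to the log-p
    peak region (all contiguous grid points within ``drop`` log units of the
    maximum, at least five points).  Averaging over the peak keeps the
    estimate stable against point-to-point jitter of the KS objective."""
    i = int(np.argmax(logp))
    lo = i
    while lo > 0 and logp[lo - 1] >= logp[i] - drop:
        lo -= 1
    hi = i
    while hi < len(logp) - 1 and logp[hi + 1] >= logp[i] - drop:
        hi += 1
    if hi - lo < 4:
        lo, hi = max(0, i - 2), min(len(v_grid) - 1, i + 2)
    vv, yy = v_grid[lo : hi + 1], logp[lo : hi + 1]
    if len(vv) >= 3 and np.all(np.isfinite(yy)):
        c = np.polyfit(vv, yy, 2)
        if c[0] < 0:
            vertex = -c[1] / (2.0 * c[0])
            return float(np.clip(vertex, vv[0], vv[-1])), i
    return float(v_grid[i]), i


def fit_free_drifts(
    data_by_condition: dict,
    base_params: StageTwoParams,
    config: FitConfig,
    v_grid: np.ndarray,
    n_bootstrap: int = 0,
) -> dict:
    """Per-condition constant-drift fits by the same KS objective.

    Because all conditions share the decision-stage parameters and a constant
    drift, one library of model signed-RT samples (one entry per grid drift)
    serves every condition: each condition picks the drift maximising its KS
    p-value, refined by a local parabola on log p.  With ``n_bootstrap`` > 0
    the data are resampled and refitted against the same library to attach a
    bootstrap standard error to each drift.

    Returns {label: FreeDriftFit}.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    lib = _drift_library(base_params, v_grid, config.n_model_trials, config.optimizer_seed)
    rng = np.random.default_rng(config.optimizer_seed + 1)
    out = {}
    for label in sorted(data_by_condition):
        data = np.sort(np.asarray(data_by_condition[label], dtype=float))
        Ds = np.empty(len(v_grid))
        ps = np.empty(len(v_grid))
        for j, model in enumerate(lib):
            Ds[j], ps[j] = _ks_sorted(data, model)
        logp = np.log(np.maximum(ps, 1e-300))
        v_hat, i = _grid_argmax_refine(v_grid, logp)
        boot = None
        se = None
        if n_bootstrap > 0:
            boot = np.empty(n_bootstrap)
            for b in range(n_bootstrap):
                resample = np.sort(rng.choice(data, size=data.size, replace=True))
                lp = np.array(
                    [np.log(max(_ks_sorted(resample, model)[1], 1e-300)) for model in lib]
                )
                boot[b], _ = _grid_argmax_refine(v_grid, lp)
            se = float(np.std(boot, ddof=1))
        out[label] = FreeDriftFit(drift=v_hat, D=float(Ds[i]), p=float(ps[i]), se=se, bootstrap=boot)
    return out


# ---------------------------------------------------------------------------
# Stage-one recovery from fitted drifts
# ---------------------------------------------------------------------------


def fit_stage_one_from_drifts(
    drifts: dict,
    schedules: dict,
    delta: float,
    T2: float,
    tau_grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Least-squares (tau, k) such that v_c ~ k * E(t_off; tau) per condition.

    tau is scanned on a grid (default 1-200 ms, step 0.5) with k solved in
    closed form for each tau (regression through the origin).  Requires at
    least three conditions with distinct schedules.
    """
    labels = sorted(drifts)
    if len(labels) < 3:
        raise ValueError("need at least 3 conditions to fit (tau, k)")
    sigs = {
        tuple((seg.polarity, seg.duration) for seg in schedules[lab].segments) for lab in labels
    }
    if len(sigs) < 3:
        raise ValueError("need at least 3 distinct schedules to fit (tau, k)")
    if tau_grid is None:
        tau_grid = np.arange(1.0, 200.0 + 0.25, 0.5)
    v = np.array([float(drifts[lab]) for lab in labels])
    best = (np.inf, np.nan, np.nan)
    for tau in tau_grid:
        p1 = StageOneParams(tau=float(tau), k=1.0, delta=delta, T2=T2)
        E = np.array([evidence_at_offset(schedules[lab], p1) for lab in labels])
        ee = float(E @ E)
        if ee == 0:
            continue
        k = float(v @ E) / ee
        sse = float(np.sum((v - k * E) ** 2))
        if sse < best[0]:
            best = (sse, float(tau), k)
    return best[1], best[2]


def calibrate_stage_one_to_dominance(
    dominance_b_percent: dict,
    stage_two: StageTwoParams,
    T2: float = 100.0,
    delta: float = 0.0,
) -> StageOneParams:
    """Fit (tau, k) so the analytic hit probability reproduces observed
    second-stimulus dominance for equal-duration fused pairs.

    ``dominance_b_percent`` maps per-vernier duration d (ms) to the observed
    percentage of 'B' decisions for the d+d fused pair.  For buffered (short)
    stimuli the drift is the constant -k (1 - exp(-d/tau))^2 and, with a
    symmetric start, P('A') is logistic in the drift, so two target values
    determine (tau, k) exactly; more are fitted in the least-squares sense.
    """
    ds = np.array(sorted(dominance_b_percent), dtype=float)
    targets = np.array([dominance_b_percent[d] / 100.0 for d in ds])

    def resid(x):
        log_tau, log_k = x
        tau, k = math.exp(log_tau), math.exp(log_k)
        v = -k * (1.0 - np.exp(-ds / tau)) ** 2
        p_b = np.array([1.0 - hit_probability_constant_drift(vi, stage_two) for vi in v])
        return p_b - targets

    sol = optimize.least_squares(resid, x0=[math.log(20.0), math.log(0.5)], xtol=1e-14, ftol=1e-14)
    tau, k = math.exp(sol.x[0]), math.exp(sol.x[1])
    return StageOneParams(tau=tau, k=k, delta=delta, T2=T2)


def scan_T2(
    table: pd.DataFrame,
    schedules: dict,
    stage_one: StageOneParams,
    stage_two: StageTwoParams,
    grid,
    n: int = 10_000,
    seed: int = 0,
) -> float:
    """Line scan of the decision-stage onset T2.

    For every grid value, the full two-stage model is simulated per condition
    (common random numbers across grid values) and the mean squared error
    between model and observed per-condition dominance is computed; the
    minimising grid value is returned (ties -> smallest).  Only conditions
    whose stimulation outlasts T2 are sensitive to it, so the data should
    include long-duration conditions.
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    # the decision stage cannot start before any (delayed) input has arrived
    grid = [g for g in grid if g > stage_one.delta]
    if not grid:
        raise ValueError("every grid value lies at or below the sensory delay")
    labels = sorted(schedules)
    obs = {}
    for label in labels:
        sub = table[(table["condition_label"] == label) & (table["choice"] != "none")]
        if len(sub) == 0:
            raise ValueError(f"no decided trials for condition {label!r}")
        obs[label] = float((sub["choice"] == "A").mean())
    best_t2, best_mse = grid[0], np.inf
    for t2 in grid:
        s1 = replace(stage_one, T2=t2)
        errs = []
        for i, label in enumerate(labels):
            prof = drift_profile(schedules[label], s1)
            sim = simulate_condition(
                stage_two, prof, n, _condition_seed(seed, i), t_start=t2
            )
            decided = sim[sim["choice"] != "none"]
            p_a = float((decided["choice"] == "A").mean()) if len(decided) else 0.5
            errs.append((p_a - obs[label]) ** 2)
        mse = float(np.mean(errs))
        if mse < best_mse - 1e-15:
            best_mse, best_t2 = mse, t2
    return best_t2


def compare_drifts(free_drifts: np.ndarray, predicted_drifts: np.ndarray) -> tuple[float, float]:
    """Two-way repeated-measures ANOVA: model variant x stimulus condition.

    ``free_drifts`` and ``predicted_drifts`` are matched (observer x
    condition) grids of per-condition drift rates from the free-drift fit and
    the stage-one prediction.  Returns the F statistic and p-value of the
    variant main effect; p > alpha means the stage-one prediction is
    statistically indistinguishable from the unconstrained fit.
    """
    free = np.asarray(free_drifts, dtype=float)
    pred = np.asarray(predicted_drifts, dtype=float)
    if free.shape != pred.shape or free.ndim != 2:
        raise ValueError("inputs must be matched 2-D (observer x condition) grids")
    if not (np.all(np.isfinite(free)) and np.all(np.isfinite(pred))):
        raise ValueError("drift grids must be finite (unbalanced grid?)")
    if np.allclose(free, pred):
        return 0.0, 1.0
    # the 2-level variant main effect is a paired t-test on subject means of
    # the difference grid; when those means have (near-)zero spread the RM
    # error term vanishes and the F ratio degenerates numerically
    subj_means = (free - pred).mean(axis=1)
    if np.std(subj_means) <= 1e-10 * (np.abs(subj_means).max() + 1e-30):
        return math.inf, 0.0
    n_obs, n_cond = free.shape
    rows = []
    for o in range(n_obs):
        for c in range(n_cond):
            rows.append({"subject": o, "variant": "free", "condition": c, "value": free[o, c]})
            rows.append({"subject": o, "variant": "predicted", "condition": c, "value": pred[o, c]})
    df = pd.DataFrame(rows)
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(df, depvar="value", subject="subject", within=["variant", "condition"]).fit()
    tab = res.anova_table
    return float(tab.loc["variant", "F Value"]), float(tab.loc["variant", "Pr > F"])
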