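"""Numba first-passage kernels for the two-boundary diffusion stage.

Euler-Maruyama with a Brownian-bridge absorption check: after every step the
probability that the within-step bridge touched either boundary,

    p = exp(-2 (b - x0)(b - x1) / (sigma^2 dt)),

is evaluated and a crossing is drawn accordingly.  For piecewise-constant
drift the Gaussian step is exact in distribution, so the bridge check removes
the leading O(sqrt(dt)) bias of naive Euler first-passage simulation; the
residual error (double crossings within one step) is exponentially small for
the step sizes used here.

Drift is passed as a per-step array plus a constant used beyond the array:
drift at step j is ``drift_arr[j]`` while j < len(drift_arr), afterwards
``drift_const`` (the buffered value).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_ddm", "simulate_leaky"]


@njit(cache=True)
def simulate_ddm(
    n,
    a,
    z_mean,
    z_width,
    eta,
    tnd_mean,
    tnd_width,
    sigma,
    dt,
    t_max,
    drift_arr,
    drift_const,
    seed,
):
    """Simulate n trials of the Ratcliff diffusion between boundaries 0 and a.

    Returns (choice, rt): choice is +1 for the upper boundary ('A'), -1 for
    the lower ('B'), 0 if no boundary is reached by t_max; rt is the
    non-decision time plus the first-passage time (NaN for undecided trials).
    """
    np.random.seed(seed)
    choices = np.zeros(n, dtype=np.int8)
    rts = np.full(n, np.nan)
    m = drift_arr.shape[0]
    sq = sigma * np.sqrt(dt)
    s2dt = sigma * sigma * dt
    # beyond this distance product the bridge crossing probability is < e^-30
    skip = 15.0 * s2dt
    n_steps = int(t_max / dt)
    for i in range(n):
        z = z_mean
        if z_width > 0.0:
            z += z_width * (np.random.random() - 0.5)
        tnd = tnd_mean
        if tnd_width > 0.0:
            tnd += tnd_width * (np.random.random() - 0.5)
        voff = 0.0
        if eta > 0.0:
            voff = eta * np.random.standard_normal()
        x = z
        for j in range(n_steps):
            v = (drift_arr[j] if j < m else drift_const) + voff
            xn = x + v * dt + sq * np.random.standard_normal()
            t = (j + 1) * dt
            if xn >= a:
                choices[i] = 1
                rts[i] = tnd + t
                break
            if xn <= 0.0:
                choices[i] = -1
                rts[i] = tnd + t
                break
            du = (a - x) * (a - xn)
            dl = x * xn
            if du < skip or dl < skip:
                pu = np.exp(-2.0 * du / s2dt) if du < skip else 0.0
                pl = np.exp(-2.0 * dl / s2dt) if dl < skip else 0.0
                uu = np.random.random()
                if uu < pu:
                    choices[i] = 1
                    rts[i] = tnd + t
                    break
                elif uu < pu + pl:
                    choices[i] = -1
                    rts[i] = tnd + t
                    break
            x = xn
    return choices, rts


@njit(cache=True)
def simulate_leaky(
    n,
    a,
    z_mean,
    z_width,
    tnd_mean,
    tnd_width,
    sigma,
    dt,
    t_max,
    drift_arr,
    drift_const,
    leak,
    leak_off_time,
    seed,
):
    """Leaky (Ornstein-Uhlenbeck) variant: dX = (v(t) - leak (X - z)) dt + ...

    The leak attracts toward the trial's own starting point z and is switched
    off for t >= leak_off_time (pass inf to keep it on throughout).  Used by
    the one-stage reference models.
    """
    np.random.seed(seed)
    choices = np.zeros(n, dtype=np.int8)
    rts = np.full(n, np.nan)
    m = drift_arr.shape[0]
    sq = sigma * np.sqrt(dt)
    s2dt = sigma * sigma * dt
    skip = 15.0 * s2dt
    n_steps = int(t_max / dt)
    for i in range(n):
        z = z_mean
        if z_width > 0.0:
            z += z_width * (np.random.random() - 0.5)
        tnd = tnd_mean
        if tnd_width > 0.0:
            tnd += tnd_width * (np.random.random() - 0.5)
        x = z
        for j in range(n_steps):
            t0 = j * dt
            v = drift_arr[j] if j < m else drift_const
            lk = leak if t0 < leak_off_time else 0.0
            xn = x + (v - lk * (x - z)) * dt + sq * np.random.standard_normal()
            t = (j + 1) * dt
            if xn >= a:
                choices[i] = 1
                rts[i] = tnd + t
                break
            if xn <= 0.0:
                choices[i] = -1
                rts[i] = tnd + t
                break
            du = (a - x) * (a - xn)
            dl = x * xn
            if du < skip or dl < skip:
                pu = np.exp(-2.0 * du / s2dt) if du < skip else 0.0
                pl = np.exp(-2.0 * dl / s2dt) if dl < skip else 0.0
                uu = np.random.random()
                if uu < pu:
                    choices[i] = 1
                    rts[i] = tnd + t
                    break
                elif uu < pu + pl:
                    choices[i] = -1
                    rts[i] = tnd + t
                    break
            x = xn
    return choices, rts
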