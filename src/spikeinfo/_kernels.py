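"""Numba inner loops for the integrate-and-fire style simulators.

Each kernel advances the subthreshold dynamics with an exact exponential
update per sample (input held constant over a step), checks the threshold,
linearly interpolates the crossing instant and applies the reset.  Spike
times are returned in milliseconds relative to the start of the trace.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lif_kernel(x, a, v_th, v_reset, v0, dt):
    n = x.shape[0]
    out = np.empty(n, np.float64)
    m = 0
    v = v0
    for k in range(n):
        v_new = a * v + (1.0 - a) * x[k]
        if v_new >= v_th:
            dv = v_new - v
            frac = (v_th - v) / dv if dv > 0.0 else 1.0
            if frac > 1.0:
                frac = 1.0
            elif frac < 0.0:
                frac = 0.0
            out[m] = (k + frac) * dt
            m += 1
            v = v_reset
        else:
            v = v_new
    return out[:m]


@njit(cache=True)
def alif_kernel(x, e11, e12, e21, e22, g1, g2, v_th, v_reset, v0, w0, dt):
    # exact 2x2 matrix-exponential update of the coupled (V, w) system;
    # the adaptation variable w is continuous through the spike
    n = x.shape[0]
    out = np.empty(n, np.float64)
    m = 0
    v = v0
    w = w0
    for k in range(n):
        v_new = e11 * v + e12 * w + g1 * x[k]
        w_new = e21 * v + e22 * w + g2 * x[k]
        if v_new >= v_th:
            dv = v_new - v
            frac = (v_th - v) / dv if dv > 0.0 else 1.0
            if frac > 1.0:
                frac = 1.0
            elif frac < 0.0:
                frac = 0.0
            out[m] = (k + frac) * dt
            m += 1
            v = v_reset
        else:
            v = v_new
        w = w_new
    return out[:m]


@njit(cache=True)
def eif_kernel(x, a, delta_t, v_th, v_reset, v0, dt):
    # exponential Euler for the leak, explicit spike-initiation term; the
    # exponent is capped so a step can never overflow between samples
    n = x.shape[0]
    out = np.empty(n, np.float64)
    m = 0
    v = v0
    for k in range(n):
        arg = (v - v_th) / delta_t
        if arg > 20.0:
            arg = 20.0
        psi = delta_t * np.exp(arg)
        v_new = a * v + (1.0 - a) * (x[k] + psi)
        if v_new >= v_th:
            dv = v_new - v
            frac = (v_th - v) / dv if dv > 0.0 else 1.0
            if frac > 1.0:
                frac = 1.0
            elif frac < 0.0:
                frac = 0.0
            out[m] = (k + frac) * dt
            m += 1
            v = v_reset
        else:
            v = v_new
    return out[:m]
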