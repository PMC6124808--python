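"""Fixed-step time-domain integrator for the three-population sources.

The Euler core is written in nopython-compatible form and compiled with
numba when available; a pure-Python fallback with identical semantics is
used otherwise (slow, but only exercised in stripped-down environments).
"""

from __future__ import annotations

import math

import numpy as np


def _euler_core(x, u, dt, te, ti, g, afwd, abwd, lead, w_p, blowup, out):  # pragma: no cover - compiled
    """Integrate the network ODEs in place.

    Parameters
    ----------
    x : (n, 10) state array, modified in place. Per-source layout:
        [aE, aE', aP, aP', aI, aI', bI, bI', bP, bP'] where a* are
        excitatory and b* inhibitory post-synaptic compartments.
    u : (n_steps, n) exogenous input per source.
    te, ti : (n,) effective time constants in seconds.
    g : (n, 5) effective intrinsic gains H1..H5.
    afwd, abwd : (n, n) effective extrinsic gains (masked entries zero).
    lead : (n,) observation gains.
    w_p : relative weight of the noise stream entering the projection
        population's inhibitory compartment (the excitatory interneuron
        population receives the same stream with weight 1). The second
        route passes the slow inhibitory kernel, which keeps the H2
        input-path gain spectrally distinguishable from a plain
        amplitude change.
    out : (n_steps, n) output buffer receiving lead * v_P.

    Returns the step index at which |state| exceeded ``blowup`` (first
    offence), or -1 on clean completion.
    """
    n_steps = u.shape[0]
    n = u.shape[1]
    sp = np.empty(n)
    dx = np.empty((n, 10))
    for k in range(n_steps):
        for i in range(n):
            sp[i] = math.tanh(x[i, 2] - x[i, 8])
        for i in range(n):
            ve = x[i, 0]
            vi = x[i, 4] - x[i, 6]
            se = math.tanh(ve)
            si = math.tanh(vi)
            fwd_in = 0.0
            bwd_in = 0.0
            for j in range(n):
                fwd_in += afwd[i, j] * sp[j]
                bwd_in += abwd[i, j] * sp[j]
            te2 = te[i] * te[i]
            ti2 = ti[i] * ti[i]
            # second-order unit-DC synaptic kernels
            dx[i, 0] = x[i, 1]
            dx[i, 1] = (g[i, 0] * sp[i] + fwd_in + u[k, i]) / te2 \
                - 2.0 * x[i, 1] / te[i] - x[i, 0] / te2
            dx[i, 2] = x[i, 3]
            dx[i, 3] = (g[i, 1] * se + bwd_in) / te2 \
                - 2.0 * x[i, 3] / te[i] - x[i, 2] / te2
            dx[i, 4] = x[i, 5]
            dx[i, 5] = (g[i, 2] * sp[i]) / te2 \
                - 2.0 * x[i, 5] / te[i] - x[i, 4] / te2
            dx[i, 6] = x[i, 7]
            dx[i, 7] = (g[i, 4] * si) / ti2 \
                - 2.0 * x[i, 7] / ti[i] - x[i, 6] / ti2
            dx[i, 8] = x[i, 9]
            dx[i, 9] = (g[i, 3] * si + w_p * u[k, i]) / ti2 \
                - 2.0 * x[i, 9] / ti[i] - x[i, 8] / ti2
        bad = False
        for i in range(n):
            for s in range(10):
                x[i, s] += dt * dx[i, s]
                if abs(x[i, s]) > blowup:
                    bad = True
            out[k, i] = lead[i] * (x[i, 2] - x[i, 8])
        if bad:
            return k
    return -1


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    euler_core = njit(cache=True, fastmath=False)(_euler_core)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    euler_core = _euler_core
    HAVE_NUMBA = False
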