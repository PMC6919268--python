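"""Numba-accelerated cohort likelihood kernel.

Same recursions as :func:`igtrl.models.cohort_log_likelihood`'s pure-numpy
path; compiled per subject with explicit loops. Falls back silently if
numba is unavailable (``HAVE_NUMBA`` is False and the numpy path is used).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap


MODEL_IDS = {"pvl_decay": 0, "pvl_delta": 1, "vpp": 2}


@njit(cache=True)
def ll_kernel(model_id, theta, choices, nets):  # pragma: no cover - exercised via wrapper
    n, T = choices.shape
    ll = np.zeros(n)
    for i in range(n):
        A = theta[i, 0]
        alpha = theta[i, 1]
        sens = 3.0 ** theta[i, 2] - 1.0
        lam = theta[i, 3]
        ep = theta[i, 4]
        en = theta[i, 5]
        k = theta[i, 6]
        w = theta[i, 7]
        ev = np.zeros(4)
        ps = np.zeros(4)
        v = np.zeros(4)
        for t in range(T):
            j = choices[i, t]
            if j < 0:
                continue
            if model_id == 2:
                for d in range(4):
                    v[d] = w * ev[d] + (1.0 - w) * ps[d]
            else:
                for d in range(4):
                    v[d] = ev[d]
            m = sens * v[0]
            for d in range(1, 4):
                s = sens * v[d]
                if s > m:
                    m = s
            z = 0.0
            for d in range(4):
                z += np.exp(sens * v[d] - m)
            ll[i] += sens * v[j] - m - np.log(z)
            x = nets[i, t]
            ax = abs(x)
            u = ax**alpha if x >= 0 else -lam * ax**alpha
            if model_id == 0:
                for d in range(4):
                    ev[d] *= A
                ev[j] += u
            else:
                ev[j] += A * (u - ev[j])
            if model_id == 2:
                for d in range(4):
                    ps[d] *= k
                ps[j] += ep if x >= 0 else en
    return ll
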