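"""Optional numba acceleration of the per-trial likelihood/gradient kernel.

The numpy implementation in :mod:`.model` is the reference; this fused loop
computes exactly the same quantities (stable logistic forms) roughly 3x
faster, which matters inside HMC where the kernel runs once per leapfrog
step.  Falls back silently when numba is unavailable.
"""

from __future__ import annotations

import math

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally installed
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f
        return deco


@njit(cache=False)
def loglik_grad_kernel(a, b, c, ln_gain, ln_L, ln_G, has_loss, has_guar, y):
    """Summed log-likelihood and d ll / d (log rho, log lam, log mu) per trial."""
    n = a.size
    ga = a * 0.0
    gb = a * 0.0
    gc = a * 0.0
    ll = 0.0
    for i in range(n):
        rho = math.exp(a[i])
        lam = math.exp(b[i])
        mu = math.exp(c[i])
        A = math.exp(rho * ln_gain[i])
        B = math.exp(rho * ln_L[i]) if has_loss[i] else 0.0
        C = math.exp(rho * ln_G[i]) if has_guar[i] else 0.0
        du = 0.5 * A - 0.5 * lam * B - C
        s = mu * du
        # stable log sigmoid: log σ(s) and log σ(−s)
        if s >= 0:
            l1 = math.log1p(math.exp(-s))
            ll += -l1 if y[i] == 1.0 else -s - l1
            p = 1.0 / (1.0 + math.exp(-s))
        else:
            l1 = math.log1p(math.exp(s))
            ll += s - l1 if y[i] == 1.0 else -l1
            es = math.exp(s)
            p = es / (1.0 + es)
        r = y[i] - p
        ddu = 0.5 * A * ln_gain[i] - 0.5 * lam * B * ln_L[i] - C * ln_G[i]
        ga[i] = r * mu * rho * ddu
        gb[i] = r * mu * (-0.5 * lam * B)
        gc[i] = r * s
    return ll, ga, gb, gc
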