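"""Numba-accelerated inner training loop for the restricted neuron.

The full-batch hinge-loss loop is a few dense array passes per epoch; at
typical problem sizes (P up to ~1000, N up to a few hundred) the numpy
implementation spends most of its time in temporaries.  This kernel runs the
identical update in a fused loop.  It is used automatically when numba is
importable; :mod:`parasyn.restricted` falls back to the numpy loop otherwise,
and both paths are exercised by the test suite through the same public API.

The kernel covers the tanh parameterization (the default training form).
Resurrection draws its redraw thresholds from a pre-generated pool so that
the random stream is controlled by the caller.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True)
def train_loop_tanh(X, y, a, s, t, theta, lr_a, lr_s, lr_t, lr_theta,
                    margin, max_epochs, res_every, floor_a, res_pool,
                    anneal_tau, anneal_cycle, patience):
    """Full-batch hinge-descent epochs; mutates a, s, t in place.

    The step size is modulated by a square-root annealing schedule that
    restarts every ``anneal_cycle`` epochs; training stops early when the
    best error count has not improved for ``patience`` epochs (0 disables).
    Returns (theta, status, epochs_run, resurrections) with status 1 for
    zero-error success, 0 for budget/patience exhaustion, -1 for divergence.
    """
    P, N = X.shape
    M = a.shape[1]
    pool_idx = 0
    resurrections = 0
    epochs_run = 0
    best_errors = P + 1
    best_epoch = 0

    T = np.empty((N, M))
    D = np.empty((N, M))
    da = np.empty((N, M))
    ds = np.empty((N, M))
    dt = np.empty((N, M))

    for epoch in range(max_epochs):
        errors = 0
        for k in range(N):
            for j in range(M):
                da[k, j] = 0.0
                ds[k, j] = 0.0
                dt[k, j] = 0.0
        dth = 0.0
        finite = True
        decay = 1.0 / np.sqrt(1.0 + (epoch % anneal_cycle) / anneal_tau)
        for mu in range(P):
            z = 0.0
            for k in range(N):
                xk = X[mu, k]
                for j in range(M):
                    d = xk - t[k, j]
                    u = s[k, j] * d
                    # tanh rounds to +-1.0 in double beyond |u| ~ 19.06
                    if u >= 20.0:
                        th_ = 1.0
                    elif u <= -20.0:
                        th_ = -1.0
                    else:
                        th_ = np.tanh(u)
                    T[k, j] = th_
                    D[k, j] = d
                    z += a[k, j] * a[k, j] * th_
            if not np.isfinite(z):
                finite = False
                break
            marg = (z - theta) * y[mu]
            if marg <= 0.0:
                errors += 1
            if margin - marg > 0.0:
                yv = float(y[mu])
                for k in range(N):
                    for j in range(M):
                        th_ = T[k, j]
                        da[k, j] += yv * 2.0 * a[k, j] * th_
                        core = a[k, j] * a[k, j] * (1.0 - th_ * th_)
                        if core != 0.0:
                            ds[k, j] += yv * core * D[k, j]
                            dt[k, j] -= yv * core * s[k, j]
                dth += yv
        if not finite:
            return theta, -1, epochs_run, resurrections
        if errors == 0:
            return theta, 1, epochs_run, resurrections
        if errors < best_errors:
            best_errors = errors
            best_epoch = epoch
        elif patience > 0 and epoch - best_epoch >= patience:
            return theta, 0, epochs_run, resurrections
        for k in range(N):
            for j in range(M):
                a[k, j] += decay * lr_a * da[k, j]
                s[k, j] += decay * lr_s * ds[k, j]
                if s[k, j] < 0.0:
                    s[k, j] = 0.0
                t[k, j] += decay * lr_t * dt[k, j]
        theta -= decay * lr_theta * dth
        epochs_run = epoch + 1
        if epochs_run % res_every == 0:
            for k in range(N):
                for j in range(M):
                    if 2.0 * a[k, j] * a[k, j] < floor_a:
                        a[k, j] = np.sqrt(floor_a / 2.0)
                        t[k, j] = res_pool[pool_idx % res_pool.shape[0]]
                        pool_idx += 1
                        resurrections += 1
    return theta, 0, epochs_run, resurrections
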