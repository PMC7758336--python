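"""Numba-compiled inner loops for sequential training at scale.

These kernels implement the same update rules as the pure-Python module
surfaces (:mod:`twopathway.perceptron`, :mod:`twopathway.pathways`); the
module functions delegate to them for Monte-Carlo estimation where millions
of presentations are needed.  All kernels mutate weight arrays in place.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SQRT2 = np.sqrt(2.0)


@njit(cache=True)
def sp_train_sequential(X, zhat, w, kappa):
    """One supervised presentation per row of X, in order (margin rule)."""
    P, N_x = X.shape
    for mu in range(P):
        u = np.dot(w, X[mu])
        if u * zhat[mu] < kappa:
            c = (kappa * zhat[mu] - u) / N_x
            for j in range(N_x):
                w[j] += c * X[mu, j]


@njit(cache=True)
def sp_train_cycled(X, zhat, w, kappa, max_epochs, tol):
    """Cycle full passes until a pass makes zero updates.

    A margin within ``tol`` of ``kappa`` counts as satisfied: the by-N_x
    step only reaches the margin asymptotically (its effective step size
    ``|x|^2 / N_x`` fluctuates around 1), so an exact test would chatter
    forever on vanishing corrections.  Returns the number of epochs used on
    convergence, or -1 if the epoch budget is exhausted.
    """
    P, N_x = X.shape
    for epoch in range(max_epochs):
        updates = 0
        for mu in range(P):
            u = np.dot(w, X[mu])
            if u * zhat[mu] < kappa - tol:
                c = (kappa * zhat[mu] - u) / N_x
                for j in range(N_x):
                    w[j] += c * X[mu, j]
                updates += 1
        if updates == 0:
            return epoch + 1
    return -1


@njit(cache=True)
def sp_train_gradient(X, zhat, w, kappa, lr, n_steps):
    """Sequential hinge-loss gradient descent: many small steps per pattern."""
    P, N_x = X.shape
    for mu in range(P):
        for _ in range(n_steps):
            u = np.dot(w, X[mu])
            if u * zhat[mu] < kappa:
                c = lr * zhat[mu] / N_x
                for j in range(N_x):
                    w[j] += c * X[mu, j]
            else:
                break


@njit(cache=True)
def tp_train_neuron(X, Y, zhat, order, w, v, alpha, beta, kappa, nbar):
    """Single-readout two-pathway training along a presentation order.

    Each presentation applies the supervised margin rule to ``w`` using the
    total input, then the Hebbian decay/strengthening rule to ``v`` with a
    single-presentation repetition factor (per-repetition application).
    """
    N_x = X.shape[1]
    N_y = Y.shape[1]
    for k in range(order.shape[0]):
        mu = order[k]
        u = np.dot(w, X[mu])
        if N_y > 0:
            u += np.dot(v, Y[mu])
        z = zhat[mu]
        if u * z < kappa:
            c = (kappa * z - u) / N_x
            for j in range(N_x):
                w[j] += c * X[mu, j]
        if N_y > 0:
            decay = 1.0 - alpha / (N_y * nbar)
            g = SQRT2 * beta * z / (N_y * nbar)
            for j in range(N_y):
                v[j] = decay * v[j] + g * Y[mu, j]


@njit(cache=True)
def tp_repeated_lag_run(X, Y, zhat, xs, ys, zs, n_burn, n_rep, lags,
                        alpha, beta, kappa, nbar):
    """Error indicators for one repeated probe pattern tested at several lags.

    ``X``, ``Y``, ``zhat`` hold the pregenerated filler sequence: the first
    ``n_burn`` rows are burn-in to the stationary weight regime, the rest
    are the patterns trained after the probe.  The probe ``(xs, ys, zs)`` is
    trained ``n_rep`` consecutive times after the burn-in and classified at
    every lag in ``lags`` (sorted, in units of patterns after the probe).
    """
    N_x = X.shape[1]
    N_y = Y.shape[1]
    w = np.zeros(N_x)
    v = np.zeros(N_y)
    dec = 1.0 - alpha / (N_y * nbar) if N_y > 0 else 1.0
    heb = SQRT2 * beta / (N_y * nbar) if N_y > 0 else 0.0
    n_lags = lags.shape[0]
    out = np.zeros(n_lags, dtype=np.uint8)
    pos = 0
    max_lag = lags[n_lags - 1] if n_lags > 0 else 0

    # burn-in fillers
    for step in range(n_burn):
        x = X[step]
        z = zhat[step]
        u = np.dot(w, x)
        if N_y > 0:
            y = Y[step]
            u += np.dot(v, y)
        if u * z < kappa:
            c = (kappa * z - u) / N_x
            for j in range(N_x):
                w[j] += c * x[j]
        if N_y > 0:
            g = heb * z
            for j in range(N_y):
                v[j] = dec * v[j] + g * y[j]

    # probe pattern, repeated n_rep times consecutively
    for _ in range(n_rep):
        u = np.dot(w, xs)
        if N_y > 0:
            u += np.dot(v, ys)
        if u * zs < kappa:
            c = (kappa * zs - u) / N_x
            for j in range(N_x):
                w[j] += c * xs[j]
        if N_y > 0:
            g = heb * zs
            for j in range(N_y):
                v[j] = dec * v[j] + g * ys[j]
    while pos < n_lags and lags[pos] == 0:
        u = np.dot(w, xs)
        if N_y > 0:
            u += np.dot(v, ys)
        zread = 1.0 if u >= 0.0 else -1.0
        out[pos] = 1 if zread != zs else 0
        pos += 1

    # post-probe fillers, probing at the requested lags
    for lag in range(1, max_lag + 1):
        row = n_burn + lag - 1
        x = X[row]
        z = zhat[row]
        u = np.dot(w, x)
        if N_y > 0:
            y = Y[row]
            u += np.dot(v, y)
        if u * z < kappa:
            c = (kappa * z - u) / N_x
            for j in range(N_x):
                w[j] += c * x[j]
        if N_y > 0:
            g = heb * z
            for j in range(N_y):
                v[j] = dec * v[j] + g * y[j]
        while pos < n_lags and lags[pos] == lag:
            u = np.dot(w, xs)
            if N_y > 0:
                u += np.dot(v, ys)
            zread = 1.0 if u >= 0.0 else -1.0
            out[pos] = 1 if zread != zs else 0
            pos += 1
    return out
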