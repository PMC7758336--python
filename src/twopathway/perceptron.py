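"""The margin perceptron: one-step supervised learning and forgetting.

A single readout neuron classifies Gaussian input patterns by the sign of
its summed input ``u = w . x``.  Training applies a one-step rule: if the
signed margin ``u * zhat`` is below the margin parameter ``kappa``, the
weights jump so that the new margin reaches ``kappa``; otherwise nothing
happens.  Trained on a long sequence of patterns, each new item partially
overwrites older ones, producing a forgetting curve: recall error as a
function of the normalized lag ``tau = (P - nu) / N_x`` between training
and testing a pattern.

Two normalizations of the update step are provided.  ``by_N_x`` divides by
the input dimension (the form used throughout the package; for Gaussian
inputs ``|x|^2 ~ N_x`` so the post-update margin is ``kappa`` up to an
``O(1/sqrt(N_x))`` fluctuation).  ``by_input_norm`` divides by ``|x|^2`` and
attains the margin exactly, which is the geometrically exact statement of
the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .patterns import PatternEnsemble, child_seeds, generate_patterns
from .results import ForgettingCurve

__all__ = [
    "SinglePathwayState",
    "supervised_update",
    "train_sequential",
    "train_cycled",
    "train_gradient_descent",
    "estimate_forgetting_curve",
    "estimate_capacity",
    "capacity_crossing",
    "sign",
]


def sign(u):
    """Readout sign with the tie ``sign(0) = +1`` fixed for determinism."""
    return np.where(np.asarray(u) >= 0.0, 1.0, -1.0)


@dataclass
class SinglePathwayState:
    """Weights and margin of a single supervised readout neuron."""

    w: np.ndarray
    kappa: float = 1.0
    normalization: str = "by_N_x"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.normalization not in ("by_N_x", "by_input_norm"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def zeros(cls, N_x: int, kappa: float = 1.0,
              normalization: str = "by_N_x") -> "SinglePathwayState":
        return cls(w=np.zeros(N_x), kappa=kappa, normalization=normalization)


def supervised_update(state: SinglePathwayState, x: np.ndarray, zhat: float,
                      u: float | None = None) -> bool:
    """Apply the one-step margin rule in place; return whether it fired.

    ``u`` is the total summed input used in the margin test.  It is accepted
    from the caller so the same rule serves the two-pathway model, where the
    second pathway's current contributes to ``u`` but only ``w`` is updated.
    When omitted it defaults to ``w . x``.
    """
    if zhat not in (-1, 1):
        raise ValueError("zhat must be +1 or -1")
    x = np.asarray(x, dtype=np.float64)
    if u is None:
        u = float(state.w @ x)
    if u * zhat >= state.kappa:
        return False
    if state.normalization == "by_N_x":
        D = x.shape[0]
    else:
        D = float(x @ x)
    state.w += (state.kappa * zhat - u) / D * x
    return True


def train_sequential(ensemble: PatternEnsemble,
                     state: SinglePathwayState | None = None,
                     record_snapshots: bool = False):
    """Train each pattern once, in order; no revisiting of earlier patterns.

    Returns the final state, or ``(state, snapshots)`` where ``snapshots[mu]``
    is the weight vector right after training pattern ``mu``.
    """
    if ensemble.N_y != 0:
        raise ValueError("single-pathway training requires N_y = 0")
    if state is None:
        state = SinglePathwayState.zeros(ensemble.N_x)
    zh = ensemble.Zhat[:, 0]
    if record_snapshots:
        snaps = np.empty((ensemble.P, ensemble.N_x))
        for mu in range(ensemble.P):
            supervised_update(state, ensemble.X[mu], zh[mu])
            snaps[mu] = state.w
        return state, snaps
    if state.normalization == "by_N_x":
        _kernels.sp_train_sequential(ensemble.X, zh, state.w, state.kappa)
    else:
        for mu in range(ensemble.P):
            supervised_update(state, ensemble.X[mu], zh[mu])
    return state


@dataclass
class CycledResult:
    converged: bool
    epochs: int
    state: SinglePathwayState


def train_cycled(ensemble: PatternEnsemble,
                 state: SinglePathwayState | None = None,
                 max_epochs: int = 10_000, tol: float = 1e-6) -> CycledResult:
    """Cycle through all patterns until a full pass makes zero updates.

    ``tol`` is the absolute slack on the margin test during cycling: a
    pattern with signed margin ``>= kappa - tol`` triggers no update.
    Without it the by-N_x step, whose effective size fluctuates around 1,
    approaches the margin from below forever and a clean pass never occurs.
    """
    if ensemble.N_y != 0:
        raise ValueError("single-pathway training requires N_y = 0")
    if state is None:
        state = SinglePathwayState.zeros(ensemble.N_x)
    zh = ensemble.Zhat[:, 0]
    epochs = _kernels.sp_train_cycled(ensemble.X, zh, state.w, state.kappa,
                                      max_epochs, tol)
    return CycledResult(converged=epochs > 0,
                        epochs=epochs if epochs > 0 else max_epochs,
                        state=state)


def train_gradient_descent(ensemble: PatternEnsemble, learning_rate: float,
                           n_steps: int,
                           state: SinglePathwayState | None = None
                           ) -> SinglePathwayState:
    """Sequential training by many small hinge-loss gradient steps.

    Per pattern, up to ``n_steps`` steps of gradient descent on the loss
    ``max(0, kappa - u * zhat)`` are taken (stopping early once the margin
    is reached) before moving to the next pattern.  A smooth stand-in for
    the one-step rule; its forgetting curve has the same monotone shape.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    if ensemble.N_y != 0:
        raise ValueError("single-pathway training requires N_y = 0")
    if state is None:
        state = SinglePathwayState.zeros(ensemble.N_x)
    _kernels.sp_train_gradient(ensemble.X, ensemble.Zhat[:, 0], state.w,
                               state.kappa, learning_rate, n_steps)
    return state


def estimate_forgetting_curve(N_x: int, P: int | None = None,
                              n_runs: int = 100, seed: int = 0,
                              kappa: float = 1.0,
                              burn_in: int | None = None,
                              gradient_descent: tuple[float, int] | None = None
                              ) -> ForgettingCurve:
    """Monte-Carlo forgetting curve of the sequentially trained perceptron.

    Each run draws a fresh ensemble of ``burn_in + P`` patterns (burn-in
    defaults to ``4 * N_x`` so tested patterns see the stationary weight
    regime), trains sequentially, then classifies the last ``P`` patterns
    with the final weights.  Errors are averaged over runs at each exact lag
    ``tau = (P - nu) / N_x``.

    ``gradient_descent=(learning_rate, n_steps)`` switches the training rule
    to the accumulated-small-steps variant.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if P is None:
        P = 2 * N_x
    if burn_in is None:
        burn_in = 4 * N_x
    err_counts = np.zeros(P)
    for run_seed in child_seeds(seed, n_runs):
        ens = generate_patterns(burn_in + P, N_x, 0, 1, seed=run_seed)
        w = np.zeros(N_x)
        zh = ens.Zhat[:, 0]
        if gradient_descent is None:
            _kernels.sp_train_sequential(ens.X, zh, w, kappa)
        else:
            lr, n_steps = gradient_descent
            _kernels.sp_train_gradient(ens.X, zh, w, kappa, lr, n_steps)
        u = ens.X[burn_in:] @ w
        err_counts += sign(u) != zh[burn_in:]
    # pattern nu (1-based within the tested block) has lag P - nu
    lags = np.arange(P - 1, -1, -1)
    tau = lags / N_x
    order = np.argsort(tau)
    p = err_counts / n_runs
    se = np.sqrt(p * (1 - p) / n_runs)
    return ForgettingCurve(tau=tau[order], error=p[order], se=se[order],
                           n_runs=n_runs, label="single_pathway",
                           meta={"N_x": N_x, "P": P, "burn_in": burn_in,
                                 "kappa": kappa})


def estimate_capacity(N_x: int = 200,
                      ratios: np.ndarray | None = None,
                      n_seeds: int = 20, max_epochs: int = 10_000,
                      seed: int = 0):
    """Converged fraction of cycled training on a grid of loads P/N_x.

    Returns ``(ratios, fractions)``; use :func:`capacity_crossing` to locate
    the load at which the converged fraction crosses one half, the empirical
    storage-capacity estimate.
    """
    if ratios is None:
        ratios = np.arange(1.5, 2.51, 0.1)
    ratios = np.asarray(ratios, dtype=float)
    fractions = np.zeros(len(ratios))
    seeds = child_seeds(seed, len(ratios) * n_seeds)
    k = 0
    for i, ratio in enumerate(ratios):
        P = int(round(ratio * N_x))
        conv = 0
        for _ in range(n_seeds):
            ens = generate_patterns(P, N_x, 0, 1, seed=seeds[k])
            k += 1
            res = train_cycled(ens, max_epochs=max_epochs)
            conv += res.converged
        fractions[i] = conv / n_seeds
    return ratios, fractions


def capacity_crossing(ratios: np.ndarray, fractions: np.ndarray) -> float:
    """Interpolate the load P/N_x at which the converged fraction hits 0.5."""
    ratios = np.asarray(ratios, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    order = np.argsort(ratios)
    r, f = ratios[order], fractions[order]
    if f[0] < 0.5:
        return float(r[0])
    for i in range(len(r) - 1):
        if f[i] >= 0.5 > f[i + 1]:
            if f[i] == f[i + 1]:
                return float(r[i])
            t = (f[i] - 0.5) / (f[i] - f[i + 1])
            return float(r[i] + t * (r[i + 1] - r[i]))
    return float(r[-1])
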