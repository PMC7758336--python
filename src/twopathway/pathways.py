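"""The two-pathway learner: fast supervised plus slow Hebbian plasticity.

A readout population of ``N_z`` units receives currents from two input
pathways, ``m = W x`` (fast, trained by the one-step supervised margin rule
on the *total* input) and ``h = V y`` (slow, trained by a Hebbian rule with
weight decay).  Repeating a pattern lets the Hebbian pathway accumulate an
association between ``y`` and the target, which both protects the pattern
from being overwritten by later learning and gradually transfers control of
the readout from the first pathway to the second.

The Hebbian rule for one presentation of pattern ``mu`` is

    dV = -(alpha * n_mu / (N_y * nbar)) V
         + sqrt(2) * (beta * n_mu / (N_y * nbar)) zhat y^T

where ``n_mu`` is the pattern's repetition count and ``nbar`` the mean
repetition count over patterns.  By default each of the ``n`` physical
presentations applies the rule with ``n_mu = 1`` (``per_repetition``); the
``aggregated`` mode applies one combined update with ``n_mu = n`` after the
first supervised step, matching the written form of the rule exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .patterns import (PatternEnsemble, RepetitionSchedule, child_seeds,
                       generate_patterns, make_repetition_schedule)
from .perceptron import sign
from .results import ForgettingCurve

__all__ = [
    "TwoPathwayState",
    "PathwayDecomposition",
    "hebbian_update",
    "present_pattern",
    "train_two_pathway",
    "estimate_two_pathway_forgetting_curve",
    "repeated_pattern_error",
    "repetitions_to_threshold",
    "lesion_test",
    "population_similarity",
]

SQRT2 = np.sqrt(2.0)


@dataclass
class TwoPathwayState:
    """Fast-pathway and slow-pathway weight matrices with their rates."""

    W: np.ndarray  # (N_z, N_x)
    V: np.ndarray  # (N_z, N_y)
    alpha: float = 1.0
    beta: float = 1.0
    kappa: float = 1.0
    nbar: float = 1.0
    hebbian_application: str = "per_repetition"

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=np.float64))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=np.float64))
        if self.W.shape[0] != self.V.shape[0]:
            raise ValueError("W and V must agree on N_z")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.nbar <= 0:
            raise ValueError("nbar must be positive")
        if self.hebbian_application not in ("per_repetition", "aggregated"):
            raise ValueError(
                f"unknown hebbian_application {self.hebbian_application!r}")

    @classmethod
    def zeros(cls, N_x: int, N_y: int, N_z: int = 1, **kwargs
              ) -> "TwoPathwayState":
        return cls(W=np.zeros((N_z, N_x)), V=np.zeros((N_z, N_y)), **kwargs)

    @property
    def N_x(self) -> int:
        return self.W.shape[1]

    @property
    def N_y(self) -> int:
        return self.V.shape[1]

    @property
    def N_z(self) -> int:
        return self.W.shape[0]

    def decompose(self, x: np.ndarray, y: np.ndarray) -> "PathwayDecomposition":
        """Input currents from each pathway for one pattern."""
        m = self.W @ np.asarray(x, dtype=np.float64)
        if self.N_y > 0:
            h = self.V @ np.asarray(y, dtype=np.float64)
        else:
            h = np.zeros(self.N_z)
        return PathwayDecomposition(m=m, h=h)


@dataclass
class PathwayDecomposition:
    """Per-pattern currents ``m`` and ``h`` with alignment summaries."""

    m: np.ndarray
    h: np.ndarray

    @property
    def alignment(self) -> float:
        """Normalized overlap ``m . h / (|m| |h|)``; 0 if either is zero."""
        nm = np.linalg.norm(self.m)
        nh = np.linalg.norm(self.h)
        if nm == 0.0 or nh == 0.0:
            return 0.0
        return float(self.m @ self.h / (nm * nh))

    def control_ratio(self, zhat: np.ndarray) -> float:
        """Share of the readout-direction drive carried by the slow pathway.

        ``(h . zhat) / ((m + h) . zhat)``; by convention 0 when ``h = 0``
        and 1 when ``m = 0``.
        """
        zhat = np.asarray(zhat, dtype=np.float64)
        if not np.any(self.h):
            return 0.0
        if not np.any(self.m):
            return 1.0
        denom = float((self.m + self.h) @ zhat)
        if denom == 0.0:
            return np.nan
        return float(self.h @ zhat / denom)

    def readout(self) -> np.ndarray:
        return sign(self.m + self.h)


def hebbian_update(V: np.ndarray, y: np.ndarray, zhat: np.ndarray,
                   alpha: float, beta: float, n_mu: int = 1,
                   nbar: float = 1.0) -> np.ndarray:
    """Apply the decaying Hebbian rule to ``V`` in place (no-op if N_y = 0).

    Row ``i`` is updated with that readout unit's target:
    ``V_i <- (1 - alpha n_mu / (N_y nbar)) V_i
    + sqrt(2) beta n_mu / (N_y nbar) zhat_i y``.
    """
    if n_mu < 1:
        raise ValueError("n_mu must be >= 1")
    if nbar <= 0:
        raise ValueError("nbar must be positive")
    N_y = V.shape[-1]
    if N_y == 0:
        return V
    y = np.asarray(y, dtype=np.float64)
    zhat = np.asarray(zhat, dtype=np.float64)
    scale = n_mu / (N_y * nbar)
    V *= 1.0 - alpha * scale
    V += SQRT2 * beta * scale * np.outer(zhat, y)
    return V


def _supervised_step(state: TwoPathwayState, x: np.ndarray,
                     zhat: np.ndarray, m: np.ndarray, h: np.ndarray) -> None:
    """Margin rule per readout row, using the total current ``m + h``."""
    u = m + h
    viol = u * zhat < state.kappa
    if np.any(viol):
        coef = (state.kappa * zhat[viol] - u[viol]) / state.N_x
        state.W[viol] += np.outer(coef, x)


def present_pattern(state: TwoPathwayState, x: np.ndarray, y: np.ndarray,
                    zhat: np.ndarray, n: int = 1
                    ) -> list[PathwayDecomposition]:
    """Train one pattern for ``n`` repetitions; return per-repetition traces.

    Each repetition computes the currents, applies the supervised rule to
    ``W`` wherever the total margin is violated (the fast step precedes the
    slow one), then applies the Hebbian rule to ``V`` using the target.  In
    ``aggregated`` mode the Hebbian rule fires once with ``n_mu = n`` after
    the first supervised step instead of once per repetition.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    zhat = np.asarray(zhat, dtype=np.float64)
    traces: list[PathwayDecomposition] = []
    aggregated = state.hebbian_application == "aggregated"
    reps = 1 if aggregated else n
    for rep in range(reps):
        dec = state.decompose(x, y)
        _supervised_step(state, x, zhat, dec.m, dec.h)
        hebbian_update(state.V, y, zhat, state.alpha, state.beta,
                       n_mu=n if aggregated else 1, nbar=state.nbar)
        traces.append(state.decompose(x, y))
    return traces


def train_two_pathway(ensemble: PatternEnsemble,
                      schedule: RepetitionSchedule | None = None,
                      state: TwoPathwayState | None = None,
                      record: bool = False):
    """Train through a presentation schedule; optionally record traces.

    Returns the final state or ``(state, traces)``, where ``traces`` is a
    tidy frame with one row per presentation: pattern index, repetition
    number, alignment, and control ratio measured right after the updates.
    """
    if schedule is None:
        schedule = make_repetition_schedule(ensemble.P)
    if state is None:
        state = TwoPathwayState.zeros(ensemble.N_x, ensemble.N_y,
                                      ensemble.N_z, nbar=schedule.nbar)
    single = (state.N_z == 1 and ensemble.N_y > 0 and not record
              and state.hebbian_application == "per_repetition")
    if single:
        _kernels.tp_train_neuron(ensemble.X, ensemble.Y, ensemble.Zhat[:, 0],
                                 schedule.order, state.W[0], state.V[0],
                                 state.alpha, state.beta, state.kappa,
                                 state.nbar)
        return state
    rows = []
    seen: dict[int, int] = {}
    for mu in schedule.order:
        mu = int(mu)
        seen[mu] = seen.get(mu, 0) + 1
        traces = present_pattern(state, ensemble.X[mu], ensemble.Y[mu],
                                 ensemble.Zhat[mu], n=1)
        if record:
            dec = traces[-1]
            rows.append({"pattern": mu, "repetition": seen[mu],
                         "alignment": dec.alignment,
                         "control_ratio": dec.control_ratio(ensemble.Zhat[mu])})
    if record:
        return state, pd.DataFrame(rows)
    return state


def repeated_pattern_error(N_x: int, N_y: int, alpha: float, beta: float,
                           n_rep: int, lags, n_runs: int = 200,
                           seed: int = 0, kappa: float = 1.0,
                           nbar: float = 1.0,
                           burn_in: int | None = None) -> ForgettingCurve:
    """Recall error of one ``n_rep``-times-repeated pattern vs. lag.

    Monte-Carlo over ``n_runs`` independent networks: burn in on fresh
    patterns, train the probe pattern ``n_rep`` consecutive times, then keep
    training fresh single-shot patterns and classify the probe at each lag
    (in patterns).  Serves the repetition-shift, practice, and
    repetitions-to-threshold analyses.
    """
    if burn_in is None:
        burn_in = 4 * max(N_x, int(np.ceil(N_y / max(alpha, 0.25))))
    lags = np.asarray(sorted(int(l) for l in np.atleast_1d(lags)),
                      dtype=np.int64)
    counts = np.zeros(len(lags))
    n_fill = burn_in + int(lags[-1]) if len(lags) else burn_in
    for s in child_seeds(seed, n_runs):
        rng = np.random.default_rng(s)
        X = rng.standard_normal((n_fill, N_x))
        Y = rng.standard_normal((n_fill, N_y))
        zh = np.where(rng.random(n_fill) < 0.5, -1.0, 1.0)
        xs = rng.standard_normal(N_x)
        ys = rng.standard_normal(N_y)
        zs = -1.0 if rng.random() < 0.5 else 1.0
        counts += _kernels.tp_repeated_lag_run(X, Y, zh, xs, ys, zs, burn_in,
                                               n_rep, lags, alpha, beta,
                                               kappa, nbar)
    p = counts / n_runs
    se = np.sqrt(p * (1 - p) / n_runs)
    return ForgettingCurve(tau=lags / N_x, error=p, se=se, n_runs=n_runs,
                           label=f"repeated_n{n_rep}",
                           meta={"N_x": N_x, "N_y": N_y, "alpha": alpha,
                                 "beta": beta, "n_rep": n_rep,
                                 "burn_in": burn_in})


def estimate_two_pathway_forgetting_curve(N_x: int, N_y: int,
                                          alpha: float = 1.0,
                                          beta: float = 1.0,
                                          P: int | None = None,
                                          repeated: dict[int, int] | None = None,
                                          n_runs: int = 100, seed: int = 0,
                                          kappa: float = 1.0,
                                          burn_in: int | None = None
                                          ) -> dict[str, ForgettingCurve]:
    """Forgetting curves of a sequentially trained two-pathway neuron.

    Each run trains ``burn_in`` throwaway patterns plus ``P`` tested
    patterns (those listed in ``repeated`` are presented consecutively the
    given number of times) and classifies every tested pattern with the
    final weights via ``sign(m + h)``.  Returns curves keyed ``"repeated"``
    and ``"unrepeated"`` (the former only if ``repeated`` is nonempty).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if P is None:
        P = 2 * (N_x + N_y) // 2
    if burn_in is None:
        burn_in = 4 * max(N_x, int(np.ceil(N_y / max(alpha, 0.25))))
    repeated = dict(repeated or {})
    special = {burn_in + idx: n for idx, n in repeated.items()}
    schedule = make_repetition_schedule(burn_in + P, special)
    nbar_tested = (P - len(repeated) + sum(repeated.values())) / P
    err = np.zeros(P)
    for s in child_seeds(seed, n_runs):
        ens = generate_patterns(burn_in + P, N_x, N_y, 1, seed=s)
        state = TwoPathwayState.zeros(N_x, N_y, 1, alpha=alpha, beta=beta,
                                      kappa=kappa, nbar=nbar_tested)
        train_two_pathway(ens, schedule, state)
        u = ens.X[burn_in:] @ state.W[0] + ens.Y[burn_in:] @ state.V[0]
        err += sign(u) != ens.Zhat[burn_in:, 0]
    p = err / n_runs
    se = np.sqrt(p * (1 - p) / n_runs)
    lags = np.arange(P - 1, -1, -1)
    tau = lags / N_x
    rep_mask = np.zeros(P, dtype=bool)
    for idx in repeated:
        rep_mask[idx] = True
    out: dict[str, ForgettingCurve] = {}
    for name, mask in (("unrepeated", ~rep_mask), ("repeated", rep_mask)):
        if not np.any(mask):
            continue
        order = np.argsort(tau[mask])
        out[name] = ForgettingCurve(
            tau=tau[mask][order], error=p[mask][order], se=se[mask][order],
            n_runs=n_runs, label=name,
            meta={"N_x": N_x, "N_y": N_y, "alpha": alpha, "beta": beta,
                  "P": P, "burn_in": burn_in})
    return out


def repetitions_to_threshold(N_x: int, N_y: int, alpha: float, beta: float,
                             interval: int, p_theta: float,
                             n_runs: int = 200, seed: int = 0,
                             n_cap: int = 4096, kappa: float = 1.0):
    """Smallest repetition count whose recall error beats ``p_theta``.

    Monte-Carlo error of the repeated pattern at the given train-test
    interval (in patterns), searched by doubling then bisection on the
    repetition count.  Returns ``(n, attained)``; ``attained`` is False if
    even ``n_cap`` repetitions do not reach the threshold.
    """
    if not (0 < p_theta < 0.5):
        raise ValueError("p_theta must be in (0, 0.5)")

    def err(n: int) -> float:
        curve = repeated_pattern_error(N_x, N_y, alpha, beta, n, [interval],
                                       n_runs=n_runs, seed=seed + n,
                                       kappa=kappa)
        return float(curve.error[0])

    n = 1
    while err(n) > p_theta:
        if n >= n_cap:
            return n_cap, False
        n = min(2 * n, n_cap)
    lo, hi = n // 2, n  # err(hi) <= p_theta; lo either 0 or failed
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if err(mid) <= p_theta:
            hi = mid
        else:
            lo = mid
    return hi, True


def lesion_test(state: TwoPathwayState, ensemble: PatternEnsemble,
                mode: str = "intact", sigma_m: float = 0.0,
                n_noise: int = 100, seed: int = 0) -> np.ndarray:
    """Per-pattern error rates with a pathway silenced or perturbed.

    ``mode`` is ``"intact"`` (optionally with Gaussian noise of amplitude
    ``sigma_m`` added to ``m``, averaged over ``n_noise`` draws),
    ``"m_zero"`` or ``"h_zero"``.  The error for a pattern is the fraction
    of readout units whose sign disagrees with the target.
    """
    if mode not in ("intact", "m_zero", "h_zero"):
        raise ValueError(f"unknown mode {mode!r}")
    if sigma_m < 0:
        raise ValueError("sigma_m must be nonnegative")
    if sigma_m > 0 and mode != "intact":
        raise ValueError("noise applies only in intact mode")
    M = ensemble.X @ state.W.T          # (P, N_z)
    H = ensemble.Y @ state.V.T if ensemble.N_y > 0 else np.zeros_like(M)
    if mode == "m_zero":
        U = H
    elif mode == "h_zero":
        U = M
    else:
        U = M + H
    if mode == "intact" and sigma_m > 0:
        rng = np.random.default_rng(seed)
        errs = np.zeros(ensemble.P)
        for _ in range(n_noise):
            xi = rng.standard_normal(U.shape)
            errs += np.mean(sign(U + sigma_m * xi) != ensemble.Zhat, axis=1)
        return errs / n_noise
    return np.mean(sign(U) != ensemble.Zhat, axis=1)


def population_similarity(state: TwoPathwayState, x: np.ndarray,
                          y: np.ndarray) -> tuple[float, float]:
    """Overlaps of the readout pattern under single-pathway silencing.

    Returns ``(overlap(z|m=0, z|h=0), overlap(z|m=0, z intact))``, each a
    normalized dot product of +/-1 population vectors (in [-1, 1]).
    """
    if state.N_z < 2:
        raise ValueError("population similarity needs N_z >= 2")
    dec = state.decompose(x, y)
    z_m0 = sign(dec.h)
    z_h0 = sign(dec.m)
    z_in = sign(dec.m + dec.h)
    N_z = state.N_z
    return float(z_m0 @ z_h0 / N_z), float(z_m0 @ z_in / N_z)
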