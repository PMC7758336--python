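"""Reinforcement learning in the fast pathway: REINFORCE with a baseline.

Instead of a supervised margin rule, the readout units fire stochastically
(``z_i = +1`` with probability ``sigma(m_i + h_i)``) and the fast weights
are trained to maximize the scalar reward ``R = z . zhat / sqrt(N_z)`` by
the REINFORCE policy gradient with a low-pass-filtered reward baseline:

    dW_ij = (eta / N_x) (R - Rbar) z_i sigma(-z_i (m_i + h_i)) x_j
    Rbar  <- (1 - 1/tau_R) Rbar + R / tau_R

Three variants are supported: ``RL_only`` (no second pathway learning),
``RL_plus_HL`` (slow Hebbian learning of ``V``, the model of the
cortical/subcortical division of labor), and ``RL_plus_RL`` (a slow copy of
the same REINFORCE rule on ``V``, the control showing that input alignment
and control transfer need an associative rule, not just a slow one).

The habit experiment trains one input-target association for ``n_nu``
trials, switches the target, and counts post-switch trials until the
readout matches the new target at a criterion accuracy; with Hebbian
learning in the second pathway, the old response persists (a habit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathways import PathwayDecomposition, hebbian_update
from .patterns import child_seeds

__all__ = [
    "RLState",
    "stochastic_readout",
    "compute_reward",
    "reinforce_update",
    "update_baseline",
    "train_rl",
    "habit_experiment",
    "HabitResult",
]

VARIANTS = ("RL_only", "RL_plus_HL", "RL_plus_RL")


def _sigmoid(lam):
    return 1.0 / (1.0 + np.exp(-lam))


@dataclass
class RLState:
    """Weights and learning configuration of the RL two-pathway model."""

    W: np.ndarray  # (N_z, N_x)
    V: np.ndarray  # (N_z, N_y)
    eta: float = 1.0          # fast-pathway REINFORCE rate (eta_1)
    eta2: float = 0.01        # slow-pathway REINFORCE rate (RL_plus_RL)
    beta: float = 0.01        # slow-pathway Hebbian rate (RL_plus_HL)
    alpha: float = 1.0        # Hebbian decay rate (RL_plus_HL)
    Rbar: float = 0.0
    tau_R: float = 10.0
    variant: str = "RL_plus_HL"

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=np.float64))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=np.float64))
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.tau_R < 1:
            raise ValueError("tau_R must be >= 1")

    @classmethod
    def zeros(cls, N_x: int, N_y: int, N_z: int = 10, **kwargs) -> "RLState":
        return cls(W=np.zeros((N_z, N_x)), V=np.zeros((N_z, N_y)), **kwargs)

    @classmethod
    def random(cls, N_x: int, N_y: int, N_z: int = 10, seed: int = 0,
               **kwargs) -> "RLState":
        """Random initial weights giving O(1) input currents.

        Needed for the alignment/control-transfer readouts to be
        informative: from zero weights the two currents trained on a single
        pattern are exact scalar multiples of each other, so their
        alignment is identically 1 in every variant.
        """
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((N_z, N_x)) / np.sqrt(N_x)
        V = rng.standard_normal((N_z, N_y)) / np.sqrt(max(N_y, 1))
        return cls(W=W, V=V, **kwargs)

    @property
    def N_x(self) -> int:
        return self.W.shape[1]

    @property
    def N_y(self) -> int:
        return self.V.shape[1]

    @property
    def N_z(self) -> int:
        return self.W.shape[0]


def stochastic_readout(m: np.ndarray, h: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Sample the readout: ``z_i = +1`` with probability ``sigma(m_i + h_i)``."""
    p = _sigmoid(np.asarray(m) + np.asarray(h))
    return np.where(rng.random(p.shape) < p, 1.0, -1.0)


def compute_reward(z: np.ndarray, zhat: np.ndarray) -> float:
    """Alignment reward ``R = z . zhat / sqrt(N_z)``."""
    z = np.asarray(z, dtype=np.float64)
    zhat = np.asarray(zhat, dtype=np.float64)
    return float(z @ zhat / np.sqrt(z.shape[0]))


def reinforce_update(W: np.ndarray, x: np.ndarray, z: np.ndarray,
                     m: np.ndarray, h: np.ndarray, R: float, Rbar: float,
                     eta: float) -> np.ndarray:
    """Apply the policy-gradient step to ``W`` in place."""
    gain = (eta / W.shape[1]) * (R - Rbar) * z * _sigmoid(-z * (m + h))
    W += np.outer(gain, x)
    return W


def update_baseline(Rbar: float, R: float, tau_R: float) -> float:
    """One step of the low-pass reward filter."""
    if tau_R < 1:
        raise ValueError("tau_R must be >= 1")
    return (1.0 - 1.0 / tau_R) * Rbar + R / tau_R


def _rl_trial(state: RLState, x, y, zhat, rng,
              hebbian_target: str = "target"
              ) -> tuple[PathwayDecomposition, np.ndarray, float]:
    """One stochastic trial: readout, reward, baseline, weight updates."""
    m = state.W @ x
    h = state.V @ y if state.N_y > 0 else np.zeros(state.N_z)
    z = stochastic_readout(m, h, rng)
    R = compute_reward(z, zhat)
    reinforce_update(state.W, x, z, m, h, R, state.Rbar, state.eta)
    if state.variant == "RL_plus_RL" and state.N_y > 0:
        reinforce_update(state.V, y, z, m, h, R, state.Rbar, state.eta2)
    elif state.variant == "RL_plus_HL" and state.N_y > 0:
        post = zhat if hebbian_target == "target" else z
        hebbian_update(state.V, y, post, state.alpha, state.beta)
    state.Rbar = update_baseline(state.Rbar, R, state.tau_R)
    return PathwayDecomposition(m=m, h=h), z, R


def train_rl(state: RLState, x: np.ndarray, y: np.ndarray,
             zhat: np.ndarray, n_trials: int, seed: int = 0,
             hebbian_target: str = "target") -> pd.DataFrame:
    """Train on one pattern for ``n_trials`` stochastic trials.

    Returns a tidy per-trial trace: reward, baseline, input alignment,
    control ratio, realized match fraction with the target, and the
    expected stochastic-readout accuracy with either pathway silenced
    (``match_m_removed`` / ``match_h_removed``).

    ``hebbian_target`` selects whether the Hebbian rule in the RL+HL
    variant associates ``y`` with the target ``zhat`` (default, valid when
    the slow rule lags the fast one) or with the realized output ``z``.
    """
    if hebbian_target not in ("target", "output"):
        raise ValueError("hebbian_target must be 'target' or 'output'")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    zhat = np.asarray(zhat, dtype=np.float64)
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        dec, z, R = _rl_trial(state, x, y, zhat, rng, hebbian_target)
        rows.append({
            "trial": trial,
            "reward": R,
            "Rbar": state.Rbar,
            "alignment": dec.alignment,
            "control_ratio": dec.control_ratio(zhat),
            "match_fraction": float(np.mean(z == zhat)),
            # expected stochastic-readout accuracy with one pathway silenced
            "match_m_removed": float(np.mean(_sigmoid(dec.h * zhat))),
            "match_h_removed": float(np.mean(_sigmoid(dec.m * zhat))),
        })
    return pd.DataFrame(rows)


@dataclass
class HabitResult:
    """Outcome of one habit-formation run."""

    n_nu: int
    variant: str
    trials_to_criterion: int | None   # None if unattained at the cap
    attained: bool
    trace: pd.DataFrame | None = field(default=None, repr=False)


def habit_experiment(variant: str = "RL_plus_HL", n_nu: int = 1000,
                     accuracy_criterion: float = 0.75,
                     N_x: int = 1000, N_y: int = 1000, N_z: int = 10,
                     eta: float = 1.0, beta: float = 0.01,
                     eta2: float = 0.01, alpha: float = 1.0,
                     window: int = 20, trial_cap: int = 10_000,
                     seed: int = 0, keep_trace: bool = False,
                     hebbian_target: str = "output") -> HabitResult:
    """Train one association, switch the target, count trials to re-learn.

    The model is trained on ``(x, zhat_1)`` for ``n_nu`` trials, then the
    target switches to an independent random ``zhat_2`` while the input
    stays the same.  Post-switch trials are counted until the moving
    average (window ``window``) of the per-unit match with the new target
    reaches ``accuracy_criterion``; if the cap is reached first the run is
    reported as unattained.
    """
    if not (0.5 < accuracy_criterion <= 1.0):
        raise ValueError("accuracy_criterion must be in (0.5, 1]")
    s_pat, s_pre, s_post = child_seeds(seed, 3)
    rng = np.random.default_rng(s_pat)
    x = rng.standard_normal(N_x)
    y = rng.standard_normal(N_y)
    zhat1 = np.where(rng.random(N_z) < 0.5, -1.0, 1.0)
    zhat2 = np.where(rng.random(N_z) < 0.5, -1.0, 1.0)
    state = RLState.zeros(N_x, N_y, N_z, eta=eta, beta=beta, eta2=eta2,
                          alpha=alpha, variant=variant)
    if n_nu > 0:
        train_rl(state, x, y, zhat1, n_nu, seed=s_pre,
                 hebbian_target=hebbian_target)

    rng_post = np.random.default_rng(s_post)
    recent = np.zeros(window)
    rows = []
    reached: int | None = None
    for trial in range(trial_cap):
        _, z, _ = _rl_trial(state, x, y, zhat2, rng_post, hebbian_target)
        match = float(np.mean(z == zhat2))
        recent[trial % window] = match
        if keep_trace:
            rows.append({"trial": trial, "match_new": match,
                         "match_old": float(np.mean(z == zhat1))})
        if trial + 1 >= window and recent.mean() >= accuracy_criterion:
            reached = trial + 1
            break
    return HabitResult(n_nu=n_nu, variant=variant,
                       trials_to_criterion=reached, attained=reached is not None,
                       trace=pd.DataFrame(rows) if keep_trace else None)
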